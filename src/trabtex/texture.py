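"""Image features of the segmented trabecular pattern.

Three feature families are computed from the two-phase binary ROI:

* **Segment morphometry** — connected white (trabecular) and black
  (intertrabecular) segments are counted and characterised by number
  density, mean area, mean perimeter and mean width.
* **LFD orientation profile** — for each of 12 line directions (0°–165° in
  15° steps) the image is sampled along parallel digital lines; the spread
  (population SD) of the per-line white fractions is largest for lines
  running along the trabecular grain, so the 12-value profile is an
  orientation signature identical for opposite directions.
* **Strut statistics** — each phase is thinned to a one-pixel skeleton;
  pixels with three or more skeleton neighbours are nodes, pixels with
  exactly one are endpoints, and the maximal paths between such terminals
  are struts whose mean length is reported.

All physical quantities use the ROI's pixel calibration (areas in mm²,
lengths in mm, densities per cm²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .preprocess import BinaryROI, PreprocessParams, preprocess_chain
from .roi_io import GrayROI

__all__ = [
    "LFD_ANGLES",
    "PhaseMorphometry",
    "LFDProfile",
    "StrutStats",
    "FeatureVector",
    "label_segments",
    "phase_morphometry",
    "lfd_profile",
    "dominant_orientation",
    "skeletonize_phase",
    "strut_statistics",
    "extract_feature_vector",
]

#: The 12 sampling directions, degrees counterclockwise from horizontal.
LFD_ANGLES = tuple(range(0, 180, 15))

# digital-topology duality: 8-connectivity for white, 4 for black
_STRUCT8 = np.ones((3, 3), dtype=int)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


def _phase_mask(binary: BinaryROI, phase: str) -> np.ndarray:
    if phase == "white":
        return binary.phase
    if phase == "black":
        return ~binary.phase
    raise ValueError(f"phase must be 'white' or 'black', got {phase!r}")


def label_segments(binary: BinaryROI, phase: str) -> tuple[np.ndarray, int]:
    """Connected components of one phase; labels 1..K.

    White segments use 8-connectivity, black segments 4-connectivity (the
    standard duality that keeps crossing phases from both being connected).
    """
    mask = _phase_mask(binary, phase)
    structure = _STRUCT8 if phase == "white" else _STRUCT4
    labels, k = ndimage.label(mask, structure=structure)
    return labels, int(k)


@dataclass(frozen=True)
class PhaseMorphometry:
    """Per-phase segment morphometry in physical units."""

    phase: str
    segment_count: int
    number_density: float  # segments per cm^2 of ROI
    mean_area: float  # mm^2
    mean_perimeter: float  # mm
    mean_width: float  # mm


def _perimeter_px(mask: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Per-label count of pixel edges facing the other phase or the border."""
    per = np.zeros(k + 1)
    padded = np.pad(mask, 1, constant_values=False)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = padded[1 + dr : padded.shape[0] - 1 + dr,
                    1 + dc : padded.shape[1] - 1 + dc]
        edge = mask & ~nb
        per += np.bincount(labels[edge], minlength=k + 1)
    return per[1:]


def phase_morphometry(
    binary: BinaryROI, phase: str, min_area_px: int = 0
) -> PhaseMorphometry:
    """Count the phase's segments and average their area, perimeter, width.

    * area: pixel count x spacing²
    * perimeter: count of pixel edges adjacent to the other phase or the
      image border, x spacing (an exact integer in pixel units)
    * width: 2 x the mean distance-to-background sampled on the segment's
      skeleton pixels, x spacing — for an elongated segment this is its
      transverse thickness
    * number density: segment count per cm² of ROI area

    Segments touching the ROI border are included; segments smaller than
    ``min_area_px`` pixels are discarded before measuring (default: none).
    An empty phase yields all-zero statistics.
    """
    mask = _phase_mask(binary, phase)
    structure = _STRUCT8 if phase == "white" else _STRUCT4
    labels, k = ndimage.label(mask, structure=structure)
    sp = binary.pixel_spacing  # mm per px
    h, w = mask.shape
    roi_area_cm2 = h * w * sp * sp / 100.0

    if k and min_area_px > 0:
        areas = np.bincount(labels.ravel(), minlength=k + 1)[1:]
        keep = np.flatnonzero(areas >= min_area_px) + 1
        mask = np.isin(labels, keep)
        labels, k = ndimage.label(mask, structure=structure)

    if k == 0:
        return PhaseMorphometry(phase, 0, 0.0, 0.0, 0.0, 0.0)

    areas_px = np.bincount(labels.ravel(), minlength=k + 1)[1:]
    perim_px = _perimeter_px(mask, labels, k)

    edt = ndimage.distance_transform_edt(mask)
    skel = skeletonize(mask)
    widths = np.empty(k)
    sums = ndimage.sum_labels(edt, labels, index=np.arange(1, k + 1))
    skel_counts = ndimage.sum_labels(skel, labels, index=np.arange(1, k + 1))
    skel_sums = ndimage.sum_labels(
        np.where(skel, edt, 0.0), labels, index=np.arange(1, k + 1)
    )
    for i in range(k):
        if skel_counts[i] > 0:
            widths[i] = 2.0 * skel_sums[i] / skel_counts[i]
        else:  # skeleton vanished (cannot happen for skimage, kept for safety)
            widths[i] = 2.0 * sums[i] / areas_px[i]

    return PhaseMorphometry(
        phase=phase,
        segment_count=k,
        number_density=k / roi_area_cm2,
        mean_area=float(areas_px.mean()) * sp * sp,
        mean_perimeter=float(perim_px.mean()) * sp,
        mean_width=float(widths.mean()) * sp,
    )


# ---------------------------------------------------------------------------
# LFD orientation profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LFDProfile:
    """12 line-fraction-deviation values indexed by angle 0°,15°,…,165°."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (12,):
            raise ValueError("LFD profile must have exactly 12 values")
        if (v < 0).any():
            raise ValueError("LFD values are standard deviations, hence >= 0")
        object.__setattr__(self, "values", v)

    def value_at(self, angle: int) -> float:
        return float(self.values[LFD_ANGLES.index(angle)])


def _line_fractions(mask: np.ndarray, angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """White-pixel count and length for each digital line at one angle.

    Lines run at ``angle_deg`` counterclockwise from horizontal (x = column,
    y = row with row increasing downward, so the row slope is -tan(angle)).
    The family is centred on the image midpoint and indexed by integer
    offsets, which makes it closed under 180° rotation; 0° and 90° fall back
    to exact rows/columns.
    """
    h, w = mask.shape
    th = math.radians(angle_deg)
    dx, dy = math.cos(th), -math.sin(th)  # direction in (col, row) steps

    if abs(dx) >= abs(dy):  # x-driven: one pixel per column
        s = dy / dx
        if abs(s) < 1e-12:
            counts = mask.sum(axis=1).astype(float)
            return counts, np.full(h, float(w))
        rmid, cmid = (h - 1) / 2.0, (w - 1) / 2.0
        bmax = int(math.ceil((h - 1) / 2.0 + abs(s) * (w - 1) / 2.0))
        b = np.arange(-bmax, bmax + 1)
        c = np.arange(w)
        rows = np.rint(rmid + b[:, None] + (c[None, :] - cmid) * s).astype(int)
        valid = (rows >= 0) & (rows < h)
        vals = mask[np.clip(rows, 0, h - 1), c[None, :]] & valid
    else:  # y-driven: one pixel per row
        s = dx / dy
        if abs(s) < 1e-12:
            counts = mask.sum(axis=0).astype(float)
            return counts, np.full(w, float(h))
        rmid, cmid = (h - 1) / 2.0, (w - 1) / 2.0
        bmax = int(math.ceil((w - 1) / 2.0 + abs(s) * (h - 1) / 2.0))
        b = np.arange(-bmax, bmax + 1)
        r = np.arange(h)
        cols = np.rint(cmid + b[:, None] + (r[None, :] - rmid) * s).astype(int)
        valid = (cols >= 0) & (cols < w)
        vals = mask[r[None, :], np.clip(cols, 0, w - 1)] & valid

    lengths = valid.sum(axis=1).astype(float)
    counts = vals.sum(axis=1).astype(float)
    return counts, lengths


def lfd_profile(binary: BinaryROI, min_line_length: int = 65) -> LFDProfile:
    """Line-fraction-deviation orientation profile in 12 directions.

    For each angle the grid is sampled along parallel digital lines one
    pixel apart; every line of at least ``min_line_length`` pixels
    contributes its white fraction, and LFD_θ is the population SD of those
    fractions.  Uniform images (all white or all black) give an all-zero
    profile; the profile of an image and its 180° rotation are identical.
    """
    mask = binary.phase
    out = np.empty(12)
    for i, ang in enumerate(LFD_ANGLES):
        counts, lengths = _line_fractions(mask, ang)
        keep = lengths >= min_line_length
        fr = counts[keep] / lengths[keep]
        out[i] = fr.std() if fr.size else 0.0
    return LFDProfile(values=out)


def dominant_orientation(profile: LFDProfile) -> int | None:
    """Angle (deg) of the profile maximum; ties go to the smallest angle.

    Returns None for an all-zero profile, where orientation is undefined.
    """
    if not profile.values.any():
        return None
    return LFD_ANGLES[int(np.argmax(profile.values))]


# ---------------------------------------------------------------------------
# skeleton strut statistics
# ---------------------------------------------------------------------------


def skeletonize_phase(binary: BinaryROI, phase: str) -> np.ndarray:
    """One-pixel-wide, topology-preserving thinning of the phase."""
    return skeletonize(_phase_mask(binary, phase))


@dataclass(frozen=True)
class StrutStats:
    """Node/endpoint census and strut lengths of one phase's skeleton."""

    phase: str
    node_count: int
    endpoint_count: int
    strut_count: int
    mean_strut_length: float  # mm


_ORTH = [(-1, 0), (1, 0), (0, -1), (0, 1)]
_DIAG = [(-1, -1), (-1, 1), (1, -1), (1, 1)]


def _shift(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """a shifted so out[r, c] = a[r+dr, c+dc], False outside."""
    out = np.zeros_like(a)
    h, w = a.shape
    rs = slice(max(dr, 0), h + min(dr, 0))
    cs = slice(max(dc, 0), w + min(dc, 0))
    rd = slice(max(-dr, 0), h + min(-dr, 0))
    cd = slice(max(-dc, 0), w + min(-dc, 0))
    out[rd, cd] = a[rs, cs]
    return out


def skeleton_degree(skeleton: np.ndarray) -> np.ndarray:
    """Per-pixel count of skeleton neighbours in the pruned 8-adjacency.

    Base adjacency is the 8-neighbourhood; a diagonal link is pruned when
    its two pixels also share an orthogonal skeleton neighbour, so the
    connection is already carried by two unit steps.  Without the pruning,
    two 1-px lines crossing at a pixel would show four spurious extra
    nodes where the arms touch diagonally.
    """
    skel = np.asarray(skeleton).astype(bool)
    deg = np.zeros(skel.shape, dtype=int)
    for dr, dc in _ORTH:
        deg += _shift(skel, dr, dc)
    for dr, dc in _DIAG:
        link = _shift(skel, dr, dc) & ~(_shift(skel, dr, 0) | _shift(skel, 0, dc))
        deg += link
    deg[~skel] = 0
    return deg


def strut_statistics(
    skeleton: np.ndarray, pixel_spacing: float = 1.0, phase: str = "white"
) -> StrutStats:
    """Count nodes, endpoints and struts of a 1-px skeleton.

    A skeleton pixel with exactly one neighbour on the skeleton is an
    endpoint, one with three or more is a node (neighbours in the pruned
    8-adjacency of :func:`skeleton_degree`); struts are the maximal
    skeleton paths between such terminals, with orthogonal steps of length
    1 px and diagonal steps of length sqrt(2) px.  Closed loops containing
    no terminal are not counted as struts.  An empty skeleton gives zeros.
    """
    skel = np.asarray(skeleton).astype(bool)
    deg = skeleton_degree(skel)
    nodes = skel & (deg >= 3)
    ends = skel & (deg == 1)
    terminal = nodes | ends

    skel_set = set(zip(*np.nonzero(skel)))
    term_set = set(zip(*np.nonzero(terminal)))
    visited: set[frozenset] = set()
    lengths: list[float] = []

    def neighbors(p):
        r, c = p
        out = [
            (r + dr, c + dc) for dr, dc in _ORTH if (r + dr, c + dc) in skel_set
        ]
        for dr, dc in _DIAG:
            q = (r + dr, c + dc)
            if q in skel_set and not (
                (r + dr, c) in skel_set or (r, c + dc) in skel_set
            ):
                out.append(q)
        return out

    def step(p, q):
        return math.sqrt(2.0) if (p[0] != q[0] and p[1] != q[1]) else 1.0

    for t in sorted(term_set):
        for nb in neighbors(t):
            edge = frozenset((t, nb))
            if edge in visited:
                continue
            visited.add(edge)
            length = step(t, nb)
            prev, cur = t, nb
            while cur not in term_set:
                nxt = [q for q in neighbors(cur) if q != prev]
                if not nxt:
                    break
                visited.add(frozenset((cur, nxt[0])))
                length += step(cur, nxt[0])
                prev, cur = cur, nxt[0]
            lengths.append(length)

    return StrutStats(
        phase=phase,
        node_count=int(nodes.sum()),
        endpoint_count=int(ends.sum()),
        strut_count=len(lengths),
        mean_strut_length=(float(np.mean(lengths)) * pixel_spacing) if lengths else 0.0,
    )


# ---------------------------------------------------------------------------
# full feature vector
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureVector:
    """Complete per-ROI feature bundle in the documented column order."""

    brightness: float
    contrast: float
    white_morph: PhaseMorphometry
    black_morph: PhaseMorphometry
    lfd: LFDProfile
    white_struts: StrutStats
    black_struts: StrutStats

    def to_row(self) -> dict[str, float]:
        """Flatten to the canonical CSV schema (fixed column order)."""
        row: dict[str, float] = {
            "brightness": self.brightness,
            "contrast": self.contrast,
        }
        for m in (self.white_morph, self.black_morph):
            p = m.phase
            row[f"{p}_segment_count"] = m.segment_count
            row[f"{p}_number_density"] = m.number_density
            row[f"{p}_mean_area"] = m.mean_area
            row[f"{p}_mean_perimeter"] = m.mean_perimeter
            row[f"{p}_mean_width"] = m.mean_width
        for ang, v in zip(LFD_ANGLES, self.lfd.values):
            row[f"lfd_{ang:03d}"] = float(v)
        for s in (self.white_struts, self.black_struts):
            p = s.phase
            row[f"{p}_node_count"] = s.node_count
            row[f"{p}_endpoint_count"] = s.endpoint_count
            row[f"{p}_strut_count"] = s.strut_count
            row[f"{p}_mean_strut_length"] = s.mean_strut_length
        return row

    @classmethod
    def from_row(cls, row: dict[str, float]) -> "FeatureVector":
        def morph(p):
            return PhaseMorphometry(
                phase=p,
                segment_count=int(row[f"{p}_segment_count"]),
                number_density=row[f"{p}_number_density"],
                mean_area=row[f"{p}_mean_area"],
                mean_perimeter=row[f"{p}_mean_perimeter"],
                mean_width=row[f"{p}_mean_width"],
            )

        def struts(p):
            return StrutStats(
                phase=p,
                node_count=int(row[f"{p}_node_count"]),
                endpoint_count=int(row[f"{p}_endpoint_count"]),
                strut_count=int(row[f"{p}_strut_count"]),
                mean_strut_length=row[f"{p}_mean_strut_length"],
            )

        return cls(
            brightness=row["brightness"],
            contrast=row["contrast"],
            white_morph=morph("white"),
            black_morph=morph("black"),
            lfd=LFDProfile(
                values=np.array([row[f"lfd_{a:03d}"] for a in LFD_ANGLES])
            ),
            white_struts=struts("white"),
            black_struts=struts("black"),
        )


def extract_feature_vector(
    roi: GrayROI, params: PreprocessParams | None = None
) -> FeatureVector:
    """Run the full texture-analysis chain on one grayscale ROI.

    Order of operations: brightness and contrast on the raw ROI, 3x3 median
    filter, unsharp self-masking, zero-threshold segmentation, then segment
    morphometry for both phases, the 12-direction LFD profile, and skeleton
    strut statistics for both phases.  Deterministic for identical inputs.
    """
    params = params or PreprocessParams()
    binary, brightness, contrast = preprocess_chain(roi, params)
    return features_from_binary(binary, brightness, contrast)


def features_from_binary(
    binary: BinaryROI, brightness: float = 0.0, contrast: float = 0.0
) -> FeatureVector:
    """Assemble the feature bundle from an already-segmented binary ROI."""
    sp = binary.pixel_spacing
    return FeatureVector(
        brightness=brightness,
        contrast=contrast,
        white_morph=phase_morphometry(binary, "white"),
        black_morph=phase_morphometry(binary, "black"),
        lfd=lfd_profile(binary),
        white_struts=strut_statistics(
            skeletonize_phase(binary, "white"), sp, "white"
        ),
        black_struts=strut_statistics(
            skeletonize_phase(binary, "black"), sp, "black"
        ),
    )
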