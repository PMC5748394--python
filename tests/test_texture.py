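"""Morphometry, LFD orientation profile and skeleton strut statistics,
checked against independent brute-force oracles."""

from collections import deque

import numpy as np
import pytest
from skimage.morphology import skeletonize

from trabtex import (
    BinaryROI,
    GrayROI,
    TextureParams,
    dominant_orientation,
    extract_feature_vector,
    generate_texture,
    label_segments,
    lfd_profile,
    phase_morphometry,
    skeletonize_phase,
    strut_statistics,
    toy_shapes,
)
from trabtex.texture import LFDProfile, skeleton_degree

from conftest import random_blobs

# ---------------------------------------------------------------------------
# oracles (deliberately naive: explicit loops, no scipy.ndimage)
# ---------------------------------------------------------------------------

ORTH = [(-1, 0), (1, 0), (0, -1), (0, 1)]
DIAG = [(-1, -1), (-1, 1), (1, -1), (1, 1)]


def flood_fill_components(mask, connect8):
    """Label connected components by explicit BFS flood fill."""
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    offsets = ORTH + DIAG if connect8 else ORTH
    k = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                k += 1
                queue = deque([(r0, c0)])
                labels[r0, c0] = k
                while queue:
                    r, c = queue.popleft()
                    for dr, dc in offsets:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = k
                            queue.append((rr, cc))
    return labels, k


def perimeter_oracle(mask, labels, k):
    """Per-label pixel-edge count facing the other phase or the border."""
    h, w = mask.shape
    per = np.zeros(k + 1)
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                for dr, dc in ORTH:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                        per[labels[r, c]] += 1
    return per[1:]


def edt_oracle(mask):
    """Brute-force Euclidean distance to the nearest background pixel."""
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape)
    for r, c in np.argwhere(mask):
        out[r, c] = np.sqrt(((bg - (r, c)) ** 2).sum(axis=1).min())
    return out


def census_oracle(skel):
    """Node/endpoint counts by per-pixel neighbour enumeration with the
    pruned 8-adjacency (diagonal link dropped when an orthogonal skeleton
    neighbour is shared)."""
    h, w = skel.shape
    nodes = ends = 0
    for r in range(h):
        for c in range(w):
            if not skel[r, c]:
                continue
            deg = 0
            for dr, dc in ORTH:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and skel[rr, cc]:
                    deg += 1
            for dr, dc in DIAG:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w and skel[rr, cc]):
                    continue
                shared = False
                if 0 <= r + dr < h and skel[r + dr, c]:
                    shared = True
                if 0 <= c + dc < w and skel[r, c + dc]:
                    shared = True
                if not shared:
                    deg += 1
            if deg == 1:
                ends += 1
            elif deg >= 3:
                nodes += 1
    return nodes, ends


def line_fraction_sd_oracle(mask, angle_deg, min_len=65):
    """LFD at one angle by explicit per-line pixel walking."""
    import math

    h, w = mask.shape
    th = math.radians(angle_deg)
    dx, dy = math.cos(th), -math.sin(th)
    rmid, cmid = (h - 1) / 2.0, (w - 1) / 2.0
    fractions = []
    if abs(dx) >= abs(dy):
        s = dy / dx
        if abs(s) < 1e-12:
            for r in range(h):
                fractions.append(mask[r, :].mean())
        else:
            bmax = int(math.ceil((h - 1) / 2.0 + abs(s) * (w - 1) / 2.0))
            for b in range(-bmax, bmax + 1):
                hits, n = 0, 0
                for c in range(w):
                    r = round(rmid + b + (c - cmid) * s)
                    if 0 <= r < h:
                        n += 1
                        hits += mask[r, c]
                if n >= min_len:
                    fractions.append(hits / n)
    else:
        s = dx / dy
        if abs(s) < 1e-12:
            for c in range(w):
                fractions.append(mask[:, c].mean())
        else:
            bmax = int(math.ceil((w - 1) / 2.0 + abs(s) * (h - 1) / 2.0))
            for b in range(-bmax, bmax + 1):
                hits, n = 0, 0
                for r in range(h):
                    c = round(cmid + b + (r - rmid) * s)
                    if 0 <= c < w:
                        n += 1
                        hits += mask[r, c]
                if n >= min_len:
                    fractions.append(hits / n)
    return float(np.std(fractions)) if fractions else 0.0


# ---------------------------------------------------------------------------
# segment labelling and morphometry
# ---------------------------------------------------------------------------


class TestLabelSegments:
    def test_single_square_gives_one_segment_per_phase(self):
        b = toy_shapes("square", side=30)
        _, kw = label_segments(b, "white")
        _, kb = label_segments(b, "black")
        assert (kw, kb) == (1, 1)

    def test_diagonal_white_pixels_connect(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        _, k = label_segments(BinaryROI(phase=mask, pixel_spacing=1.0), "white")
        assert k == 1

    def test_black_uses_4_connectivity(self):
        # a diagonal white line separates black into two 4-connected parts
        mask = np.eye(5, dtype=bool)
        _, k = label_segments(BinaryROI(phase=mask, pixel_spacing=1.0), "black")
        assert k == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_flood_fill_oracle(self, seed):
        b = random_blobs(40, seed=seed)
        for phase, connect8 in (("white", True), ("black", False)):
            mask = b.phase if phase == "white" else ~b.phase
            _, k = label_segments(b, phase)
            _, k_oracle = flood_fill_components(mask, connect8)
            assert k == k_oracle


class TestPhaseMorphometry:
    def test_interior_square_analytic_values(self):
        b = toy_shapes("square", side=30)  # 10x10 white square, spacing 1 mm
        m = phase_morphometry(b, "white")
        assert m.segment_count == 1
        assert m.mean_area == pytest.approx(100.0)
        assert m.mean_perimeter == pytest.approx(40.0)
        assert m.number_density == pytest.approx(1 / (30 * 30 / 100.0))

    def test_band_width_equals_band_height(self):
        b = toy_shapes("band", side=60)  # height-10 full-width band
        m = phase_morphometry(b, "white")
        assert m.mean_width == pytest.approx(10.0, abs=0.5)

    def test_mean_area_independent_of_square_count(self):
        def k_squares(k):
            mask = np.zeros((20, 20 * k), dtype=bool)
            for i in range(k):
                mask[5:10, 20 * i + 5 : 20 * i + 10] = True
            return BinaryROI(phase=mask, pixel_spacing=1.0)

        areas = [phase_morphometry(k_squares(k), "white").mean_area for k in (1, 3, 5)]
        assert areas[0] == areas[1] == areas[2] == pytest.approx(25.0)

    def test_empty_phase_gives_zeros(self):
        b = BinaryROI(phase=np.ones((10, 10), dtype=bool), pixel_spacing=1.0)
        m = phase_morphometry(b, "black")
        assert m.segment_count == 0
        assert m.mean_area == m.mean_perimeter == m.mean_width == 0.0

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_brute_force_oracles(self, seed):
        b = random_blobs(48, seed=seed)
        for phase, connect8 in (("white", True), ("black", False)):
            mask = b.phase if phase == "white" else ~b.phase
            m = phase_morphometry(b, phase)
            labels, k = flood_fill_components(mask, connect8)
            assert m.segment_count == k
            areas = np.bincount(labels.ravel(), minlength=k + 1)[1:]
            assert m.mean_area == pytest.approx(areas.mean())
            assert m.mean_perimeter == pytest.approx(
                perimeter_oracle(mask, labels, k).mean()
            )
            edt = edt_oracle(mask)
            skel = skeletonize(mask)
            widths = []
            for lab in range(1, k + 1):
                sel = skel & (labels == lab)
                if sel.any():
                    widths.append(2.0 * edt[sel].mean())
                else:
                    widths.append(2.0 * edt[labels == lab].mean())
            assert m.mean_width == pytest.approx(np.mean(widths))

    def test_min_area_filter_drops_small_segments(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:12, 2:12] = True
        mask[15, 15] = True
        b = BinaryROI(phase=mask, pixel_spacing=1.0)
        assert phase_morphometry(b, "white").segment_count == 2
        assert phase_morphometry(b, "white", min_area_px=5).segment_count == 1


# ---------------------------------------------------------------------------
# LFD profile
# ---------------------------------------------------------------------------


class TestLFDProfile:
    def test_uniform_images_give_all_zero_profile(self):
        for value in (True, False):
            b = BinaryROI(phase=np.full((100, 100), value), pixel_spacing=1.0)
            assert (lfd_profile(b).values == 0).all()

    def test_vertical_stripes_peak_at_90(self):
        b = toy_shapes("stripes", side=200)
        prof = lfd_profile(b)
        assert dominant_orientation(prof) == 90
        assert prof.value_at(0) < 0.05

    def test_matches_per_line_walking_oracle(self):
        b = random_blobs(80, seed=9)
        prof = lfd_profile(b)
        for i, ang in enumerate(range(0, 180, 15)):
            assert prof.values[i] == pytest.approx(
                line_fraction_sd_oracle(b.phase, ang), abs=1e-12
            )

    @pytest.mark.parametrize("seed,orientation", [(0, 30.0), (1, 115.0)])
    def test_invariant_under_180_rotation(self, seed, orientation):
        _, truth = generate_texture(
            TextureParams(side=260, orientation=orientation, anisotropy=3.0, seed=seed)
        )
        p = lfd_profile(truth).values
        rot = BinaryROI(phase=truth.phase[::-1, ::-1], pixel_spacing=1.0)
        assert np.abs(p - lfd_profile(rot).values).max() < 1e-9

    @pytest.mark.parametrize("seed", [2, 3])
    def test_90_rotation_shifts_profile_by_six(self, seed):
        _, truth = generate_texture(
            TextureParams(side=260, orientation=45.0, anisotropy=3.0, seed=seed)
        )
        p = lfd_profile(truth).values
        rot = BinaryROI(phase=np.rot90(truth.phase), pixel_spacing=1.0)
        assert np.abs(np.roll(p, 6) - lfd_profile(rot).values).max() < 0.02


class TestDominantOrientation:
    def test_unique_maximum(self):
        v = np.zeros(12)
        v[4] = 0.3  # 60 degrees
        assert dominant_orientation(LFDProfile(values=v)) == 60

    def test_flat_nonzero_profile_ties_to_smallest_angle(self):
        assert dominant_orientation(LFDProfile(values=np.full(12, 0.1))) == 0

    def test_all_zero_profile_is_undefined(self):
        assert dominant_orientation(LFDProfile(values=np.zeros(12))) is None

    def test_recovers_generator_orientation(self):
        _, truth = generate_texture(
            TextureParams(side=650, orientation=60.0, anisotropy=4.0, seed=1)
        )
        assert dominant_orientation(lfd_profile(truth)) == 60


# ---------------------------------------------------------------------------
# skeletons and struts
# ---------------------------------------------------------------------------


class TestSkeleton:
    def test_three_px_bar_thins_to_line(self):
        mask = np.zeros((9, 20), dtype=bool)
        mask[3:6, 2:18] = True
        skel = skeletonize_phase(BinaryROI(phase=mask, pixel_spacing=1.0), "white")
        assert skel.sum(axis=0).max() == 1
        assert skel.any()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_topology_preserved_on_random_blobs(self, seed):
        b = random_blobs(50, seed=seed)
        skel = skeletonize_phase(b, "white")
        _, k_in = flood_fill_components(b.phase, connect8=True)
        _, k_out = flood_fill_components(skel, connect8=True)
        assert k_in == k_out


class TestStrutStatistics:
    def test_plus_sign_hand_count(self):
        s = strut_statistics(toy_shapes("plus", side=21).phase)
        assert (s.node_count, s.endpoint_count, s.strut_count) == (1, 4, 4)
        assert s.mean_strut_length == pytest.approx(4.0)

    def test_straight_line_hand_count(self):
        s = strut_statistics(toy_shapes("line", side=31).phase)
        assert (s.node_count, s.endpoint_count, s.strut_count) == (0, 2, 1)
        assert s.mean_strut_length == pytest.approx(19.0)

    def test_empty_skeleton_gives_zeros(self):
        s = strut_statistics(np.zeros((10, 10), dtype=bool))
        assert (s.node_count, s.endpoint_count, s.strut_count) == (0, 0, 0)
        assert s.mean_strut_length == 0.0

    def test_diagonal_step_counts_sqrt2(self):
        mask = np.zeros((10, 10), dtype=bool)
        for i in range(5):
            mask[i, i] = True
        s = strut_statistics(mask)
        assert s.mean_strut_length == pytest.approx(4 * np.sqrt(2.0))

    @pytest.mark.parametrize("seed", [5, 6, 7, 8])
    def test_counts_match_neighbour_census_oracle(self, seed):
        b = random_blobs(64, seed=seed)
        skel = skeletonize_phase(b, "white")
        s = strut_statistics(skel)
        nodes, ends = census_oracle(skel)
        assert (s.node_count, s.endpoint_count) == (nodes, ends)

    def test_degree_grid_matches_walk_adjacency(self):
        b = random_blobs(40, seed=12)
        skel = skeletonize_phase(b, "white")
        deg = skeleton_degree(skel)
        nodes, ends = census_oracle(skel)
        assert int((deg >= 3).sum()) == nodes
        assert int((deg == 1).sum()) == ends


# ---------------------------------------------------------------------------
# full feature vector
# ---------------------------------------------------------------------------


class TestFeatureVector:
    def test_constant_roi_degenerate_chain(self):
        roi = GrayROI(pixels=np.full((120, 120), 77.0), pixel_spacing=1.0)
        from trabtex.preprocess import PreprocessParams

        fv = extract_feature_vector(roi, PreprocessParams(blur_window=31))
        assert fv.brightness == 77.0
        assert fv.contrast == 0.0
        assert fv.white_morph.segment_count == 1  # all white by the tie rule
        assert fv.black_morph.segment_count == 0
        assert (fv.lfd.values == 0).all()

    def test_dense_texture_finer_than_sparse(self):
        from trabtex import generate_reference_pattern
        from trabtex.texture import features_from_binary

        _, dense = generate_reference_pattern("dense", seed=4, side=300)
        _, sparse = generate_reference_pattern("sparse", seed=4, side=300)
        fd = features_from_binary(dense)
        fs = features_from_binary(sparse)
        assert fd.white_morph.number_density > fs.white_morph.number_density
        assert fd.black_morph.mean_area < fs.black_morph.mean_area

    def test_repeated_run_bit_identical(self):
        gray, _ = generate_texture(TextureParams(side=160, seed=13))
        from trabtex.preprocess import PreprocessParams

        p = PreprocessParams(blur_window=41)
        r1 = extract_feature_vector(gray, p).to_row()
        r2 = extract_feature_vector(gray, p).to_row()
        assert r1 == r2

    @pytest.mark.parametrize("seed", [0, 1])
    def test_phase_pixel_conservation(self, seed):
        b = random_blobs(100, seed=seed)
        assert b.phase.sum() + (~b.phase).sum() == 100 * 100
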