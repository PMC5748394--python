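"""Synthetic trabecular textures and fracture cohorts.

No radiograph archive ships with the package, so every pipeline stage is
exercised on synthetic data with known ground truth:

* **Textures** — a seeded Gaussian random field, smoothed with an
  anisotropic kernel and rotated to the requested orientation, is
  thresholded at the exact quantile giving the target white-area fraction.
  The resulting binary truth is rendered to gray by assigning the two
  phases distinct gray levels, blurring the boundary slightly (focal blur),
  and adding a low-order polynomial background (the cortex/soft-tissue
  confounder that self-masking must remove) plus Gaussian noise.
* **Reference patterns** — the three visual-scoring archetypes: dense
  (many fine trabeculae, small marrow spaces), sparse (few coarse
  trabeculae, large spaces) and alternating (dense cervically/top, sparse
  apically/bottom).
* **Cohorts** — subjects with a 3-level ordinal score drawn from given
  prevalences, fracture outcome drawn per score, Gaussian clinical
  variables, and optional image features correlated with the score.

All generators are pure functions of their parameters and seed; one global
seed expands into independent substreams (field, background, noise) so
repeated calls are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

import pandas as pd

from .preprocess import BinaryROI
from .roi_io import DEFAULT_PIXEL_SPACING_MM, GrayROI
from .stats import CohortRecord

__all__ = [
    "TextureParams",
    "CohortParams",
    "generate_texture",
    "generate_reference_pattern",
    "generate_cohort",
    "generate_logistic_cohort",
    "toy_shapes",
]

# ndimage.rotate(angle>0) turns array content counterclockwise on screen
# (row axis pointing down), matching the LFD angle convention directly.
_ROT_SIGN = 1.0

# gray rendering: phase levels sit symmetrically about this midtone
_MID_GRAY = 120.0
_EDGE_BLUR_SIGMA = 0.7  # px, emulates scanner/focal blur at phase boundaries


@dataclass(frozen=True)
class TextureParams:
    """Parameters of one synthetic trabecular texture.

    side
        ROI side in pixels (650 matches the analysis window).
    area_fraction
        Target white (trabecular) area fraction, hit exactly by quantile
        thresholding of the latent field.
    orientation
        Grain direction, degrees counterclockwise from horizontal in
        [0, 180).
    anisotropy
        Ratio of the correlation lengths along/across the grain; 1 is
        isotropic.
    coarseness
        Across-grain correlation length in pixels (>= 2); trabecular
        spacing scales with it.
    gradient_amplitude
        Peak-to-peak gray range of the superimposed low-order polynomial
        background.
    noise_sd
        SD of the additive Gaussian pixel noise, gray units.
    phase_contrast
        Gray-level separation between the white and black phases.
    """

    side: int = 650
    area_fraction: float = 0.5
    orientation: float = 0.0
    anisotropy: float = 1.0
    coarseness: float = 8.0
    gradient_amplitude: float = 40.0
    noise_sd: float = 8.0
    phase_contrast: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.area_fraction < 1:
            raise ValueError("area_fraction must lie strictly in (0, 1)")
        if not 0 <= self.orientation < 180:
            raise ValueError("orientation must lie in [0, 180)")
        if self.anisotropy < 1:
            raise ValueError("anisotropy must be >= 1")
        if self.coarseness < 2:
            raise ValueError("coarseness must be >= 2 px")
        if self.side < 10:
            raise ValueError("side must be >= 10 px")
        if self.gradient_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("gradient_amplitude and noise_sd must be >= 0")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _latent_field(params: TextureParams) -> np.ndarray:
    """Oriented latent field cropped to the ROI side.

    Seeded white noise is smoothed with an anisotropic Gaussian (correlation
    length ``coarseness`` across the grain, ``anisotropy`` times that along
    it).  For anisotropy > 1 a band-pass component — the second derivative
    across the grain — is blended in with weight 1 - 1/anisotropy: it turns
    the elongated blobs into quasi-periodic strut-like ridges, which both
    resembles trabecular bone more closely and sharpens the orientation
    signature.  At anisotropy 1 the field is exactly isotropic.
    """
    side = params.side
    big = int(np.ceil(side * 1.5)) + 1  # margin for lossless rotation crop
    noise = _rng(params.seed, 0).standard_normal((big, big))
    sigma_short = params.coarseness / 2.0
    sigma_long = sigma_short * params.anisotropy
    field = ndimage.gaussian_filter(noise, sigma=(sigma_short, sigma_long))
    if params.anisotropy > 1.0:
        ridges = ndimage.gaussian_filter(field, sigma=(sigma_short, 0), order=(2, 0))
        w = 1.0 - 1.0 / params.anisotropy
        field = (1.0 - w) * field / field.std() + w * ridges / ridges.std()
    if params.orientation != 0.0:
        field = ndimage.rotate(
            field,
            _ROT_SIGN * params.orientation,
            reshape=False,
            order=3,
            mode="reflect",
        )
    lo = (big - side) // 2
    return field[lo : lo + side, lo : lo + side]


def _threshold_at_fraction(field: np.ndarray, area_fraction: float) -> np.ndarray:
    """Binary mask whose True fraction equals area_fraction to within 1/N."""
    flat = field.ravel()
    k = int(round((1.0 - area_fraction) * flat.size))
    k = min(max(k, 0), flat.size - 1)
    t = np.partition(flat, k)[k]
    return field >= t


def _polynomial_background(side: int, amplitude: float, rng) -> np.ndarray:
    """Zero-mean quadratic background with the given peak-to-peak range."""
    u = np.linspace(-1.0, 1.0, side)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    terms = np.stack([uu, vv, uu * vv, uu**2, vv**2])
    coef = rng.standard_normal(5)
    g = np.tensordot(coef, terms, axes=1)
    span = g.max() - g.min()
    if span > 0 and amplitude > 0:
        g = (g - g.mean()) * (amplitude / span)
    else:
        g = np.zeros_like(g)
    return g


def _render(truth: np.ndarray, params: TextureParams) -> GrayROI:
    levels = np.where(
        truth,
        _MID_GRAY + params.phase_contrast / 2.0,
        _MID_GRAY - params.phase_contrast / 2.0,
    )
    gray = ndimage.gaussian_filter(levels, sigma=_EDGE_BLUR_SIGMA)
    gray = gray + _polynomial_background(
        params.side, params.gradient_amplitude, _rng(params.seed, 1)
    )
    gray = gray + _rng(params.seed, 2).normal(0.0, params.noise_sd, gray.shape)
    return GrayROI(
        pixels=np.clip(gray, 0.0, 255.0),
        pixel_spacing=DEFAULT_PIXEL_SPACING_MM,
    )


def generate_texture(params: TextureParams) -> tuple[GrayROI, BinaryROI]:
    """Synthesize one grayscale texture plus its ground-truth binary."""
    field = _latent_field(params)
    truth_mask = _threshold_at_fraction(field, params.area_fraction)
    truth = BinaryROI(phase=truth_mask, pixel_spacing=DEFAULT_PIXEL_SPACING_MM)
    return _render(truth_mask, params), truth


#: Archetype parameters for the three observer-score reference patterns.
#: Dense keeps the white fraction below the percolation regime so the many
#: fine trabeculae remain countable as separate segments.
_REFERENCE_KINDS = {
    "dense": dict(area_fraction=0.55, coarseness=5.0),
    "sparse": dict(area_fraction=0.40, coarseness=13.0),
}


def generate_reference_pattern(
    kind: str, seed: int = 0, side: int = 650
) -> tuple[GrayROI, BinaryROI]:
    """One of the three scoring archetypes: dense, sparse or alternating.

    Dense has a high trabecular area fraction and fine spacing; sparse a
    low fraction and coarse spacing; alternating blends linearly from the
    dense fraction at the top (cervical) rows to the sparse fraction at the
    bottom (apical) rows.
    """
    if kind in _REFERENCE_KINDS:
        params = TextureParams(side=side, seed=seed, **_REFERENCE_KINDS[kind])
        return generate_texture(params)
    if kind != "alternating":
        raise ValueError(
            f"unknown reference kind {kind!r}; expected dense, sparse or alternating"
        )
    params = TextureParams(side=side, seed=seed, coarseness=9.0)
    fld = _latent_field(params)
    af_top = _REFERENCE_KINDS["dense"]["area_fraction"]
    af_bot = _REFERENCE_KINDS["sparse"]["area_fraction"]
    # dense plateau in the top (cervical) third, sparse plateau in the
    # bottom (apical) third, linear transition between
    r = np.linspace(0.0, 1.0, side)
    blend = np.clip((r - 1.0 / 3.0) * 3.0, 0.0, 1.0)
    af_rows = af_top + (af_bot - af_top) * blend
    # per-row threshold at the global field quantile for that row's fraction
    thresholds = np.quantile(fld, 1.0 - af_rows)
    truth_mask = fld >= thresholds[:, None]
    truth = BinaryROI(phase=truth_mask, pixel_spacing=DEFAULT_PIXEL_SPACING_MM)
    return _render(truth_mask, params), truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortParams:
    """Parameters of a synthetic fracture cohort.

    Defaults reproduce the published 304-subject cohort: score prevalences
    49/146/109 out of 304 and per-score fracture probabilities 1/49, 35/146
    and 79/109, with clinical variables drawn from the cohort's reported
    means and SDs (age in years, weight kg, height cm, BMI kg/m²).
    ``feature_effects`` optionally maps a feature name to a loading gamma;
    that feature is then drawn as gamma * score + N(0, 1), i.e. associated
    with fracture only through the score.
    """

    n: int = 304
    score_prevalence: tuple[float, float, float] = (49 / 304, 146 / 304, 109 / 304)
    fracture_prob_by_score: tuple[float, float, float] = (1 / 49, 35 / 146, 79 / 109)
    clinical_means: dict = field(
        default_factory=lambda: dict(age=54.1, weight=66.3, height=163.5, bmi=24.8)
    )
    clinical_sds: dict = field(
        default_factory=lambda: dict(age=4.0, weight=10.6, height=5.9, bmi=3.6)
    )
    feature_effects: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.score_prevalence, dtype=float)
        if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("score_prevalence must be 3 probabilities summing to 1")
        q = np.asarray(self.fracture_prob_by_score, dtype=float)
        if q.shape != (3,) or (q < 0).any() or (q > 1).any():
            raise ValueError("fracture_prob_by_score must be 3 probabilities")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def generate_cohort(params: CohortParams) -> list[CohortRecord]:
    """Draw a cohort with the configured score/fracture/clinical structure."""
    rng = _rng(params.seed, 3)
    scores = rng.choice(3, size=params.n, p=np.asarray(params.score_prevalence))
    probs = np.asarray(params.fracture_prob_by_score)[scores]
    fracture = (rng.random(params.n) < probs).astype(int)
    clin = {
        name: rng.normal(params.clinical_means[name], params.clinical_sds[name], params.n)
        for name in ("age", "weight", "height", "bmi")
    }
    feats = {}
    if params.feature_effects:
        for name, gamma in params.feature_effects.items():
            feats[name] = gamma * scores + rng.standard_normal(params.n)
    records = []
    for i in range(params.n):
        records.append(
            CohortRecord(
                id=f"sim{i:05d}",
                score=int(scores[i]),
                fracture=int(fracture[i]),
                age=float(np.abs(clin["age"][i])),
                weight=float(np.abs(clin["weight"][i])),
                height=float(np.abs(clin["height"][i])),
                bmi=float(np.abs(clin["bmi"][i])),
                features={k: float(v[i]) for k, v in feats.items()},
            )
        )
    return records


def generate_logistic_cohort(
    n: int,
    betas: dict[str, float],
    n_noise: int = 0,
    intercept: float = -1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Direct logistic simulation: standard-normal covariates, known logit.

    ``betas`` maps covariate names to true coefficients; ``n_noise`` extra
    pure-noise covariates named noise1.. are appended.  Returns a DataFrame
    with the covariates and a 0/1 ``fracture`` column.
    """
    rng = _rng(seed, 4)
    cols = {}
    logit = np.full(n, float(intercept))
    for name, b in betas.items():
        x = rng.standard_normal(n)
        cols[name] = x
        logit += b * x
    for j in range(1, n_noise + 1):
        cols[f"noise{j}"] = rng.standard_normal(n)
    p = 1.0 / (1.0 + np.exp(-logit))
    cols["fracture"] = (rng.random(n) < p).astype(int)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# analytic fixtures
# ---------------------------------------------------------------------------


def toy_shapes(name: str, side: int = 650, pixel_spacing: float = 1.0) -> BinaryROI:
    """Deterministic analytic binary fixtures for the feature oracles.

    square
        One 10x10 white square centred in a black field.
    band
        A full-width horizontal white band of height 10.
    plus
        Two 9-pixel lines crossing at the centre (1 node, 4 endpoints).
    line
        A single straight horizontal 20-pixel line.
    stripes
        Vertical stripes, alternating 10 white / 10 black columns.
    """
    mask = np.zeros((side, side), dtype=bool)
    mid = side // 2
    if name == "square":
        mask[mid - 5 : mid + 5, mid - 5 : mid + 5] = True
    elif name == "band":
        mask[mid - 5 : mid + 5, :] = True
    elif name == "plus":
        mask[mid, mid - 4 : mid + 5] = True
        mask[mid - 4 : mid + 5, mid] = True
    elif name == "line":
        mask[mid, mid - 10 : mid + 10] = True
    elif name == "stripes":
        cols = (np.arange(side) // 10) % 2 == 0
        mask[:, cols] = True
    else:
        raise ValueError(f"unknown toy shape {name!r}")
    return BinaryROI(phase=mask, pixel_spacing=pixel_spacing)
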