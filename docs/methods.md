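# Methods

This note records the scientific and numerical choices behind `trabtex`:
what each stage computes, which parameters matter, what the synthetic
generator does and does not emulate, and the known limitations.

## Image model and preprocessing

A scanned panoramic radiograph is treated as a calibrated gray grid in
[0, 255] with a default pixel spacing of 10/236 mm (236 px/cm scan
resolution). The analysis unit is a square 650 × 650 px ROI
(2.75 × 2.75 cm) in the mandibular premolar/molar region; the crop around
a chosen centre spans rows `center−325 … center+324` (the fixed convention
for the even window side). RGB scans are collapsed by the unweighted
channel mean — radiographs are gray, so channel weighting is immaterial —
and 16-bit rasters are rescaled by their full dtype range.

The preprocessing chain is:

1. **Brightness/contrast** on the raw ROI: arithmetic mean and population
   SD (divisor N) of the gray values. These are declared conventions:
   "brightness" and "contrast" have no universal formula, and the contrast
   defined this way is also the `contrast` feature column used in risk
   models, so the definition is load-bearing and documented here.
2. **3 × 3 median filter** with edge replication, removing isolated
   deviating pixels without shrinking the grid. Note the filter is *not*
   idempotent on arbitrary binary-valued grids (a 3 × 3 median acts as a
   majority vote and only "root signals" are fixed points); it is
   idempotent on features wider than the window, which is the regime it is
   used in.
3. **Unsharp self-masking**: subtract a square uniform mean blur of side
   `blur_window` (default 101 px ≈ 4.3 mm, several trabecular widths) from
   the image. The residual is signed; constants are removed exactly and a
   linear ramp is removed exactly at every pixel ≥ blur_window//2 from the
   border (a symmetric mean filter reproduces linear functions in the
   interior). For general inputs the interior residual mean is only
   approximately zero — exact mean removal is a property of locally linear
   backgrounds, not of arbitrary images.
4. **Segmentation**: white (trabecula) iff residual ≥ `threshold_offset`
   (default 0, ties to white). Self-masking centres the local background
   at zero, so the zero threshold separates locally bright texture from
   locally dark without any histogram-based tuning; adaptive thresholds
   (Otsu etc.) are deliberately out of scope.

## Image features

**Connectivity.** White segments use 8-connectivity and black segments
4-connectivity — the standard digital-topology duality that prevents both
phases from being connected across a diagonal crossing.

**Morphometry** per phase: segment count and number density (per cm² of
ROI); mean area (pixel count × spacing²); mean perimeter (count of pixel
edges facing the other phase or the image border × spacing — an exact
integer in pixel units, chosen over Crofton-style estimators so tests can
compare against an exact oracle); mean width (2 × mean Euclidean distance
to background sampled on the segment's skeleton pixels × spacing, the
transverse thickness for elongated segments). Segments touching the ROI
border are included by default; `min_area_px` can drop speckle segments.
All choices are logged in the feature schema so values are comparable
across runs.

**LFD orientation profile.** For each of the 12 directions θ = 0°, 15°,
…, 165° the grid is sampled along parallel digital lines one pixel apart;
every line of at least 65 px (`min_line_length`) contributes its white
fraction, and LFD_θ is the population SD of those fractions. The profile
is maximal along the trabecular grain: lines running with the grain are
either mostly inside or mostly outside trabeculae, so their fractions
spread widely, while lines across the grain all average the same mixture.
By construction the profile is identical for opposite directions. The
line families are centred on the image midpoint, which makes them closed
under 180° rotation (the identity is exact, not approximate); θ = 0°/90°
use exact rows/columns (slopes below 1e-12 are treated as zero — the
floating-point cosine of 90° is 6e-17, and routing it through the general
path would hit round-half-to-even ties at the half-integer centre). Under
90° rotation the profile shifts cyclically by 6 index positions up to line
discretisation (observed < 0.02, typically exact). The per-line-fraction
SD is one concrete operationalisation of an orientation statistic for
which no closed formula is in circulation; the feature is therefore
reproduced *in role* (an orientation-selective predictor) rather than as
a numerically identical quantity to any prior software.

**Strut statistics.** Each phase is thinned to a one-pixel skeleton by
topology-preserving thinning (`skimage.morphology.skeletonize`), which
matches the node/endpoint language of strut analysis better than
fixed-element morphological erosion. On the skeleton graph, base
adjacency is the 8-neighbourhood with one standard pruning rule: a
diagonal link is dropped when its two pixels also share an orthogonal
skeleton neighbour, because that connection is already carried by two unit
steps. Without pruning, two clean 1-px lines crossing at a pixel would
show four spurious nodes where the arms touch diagonally; with it, the
crossing is exactly one node with four endpoints. Endpoints have degree
1, nodes degree ≥ 3; struts are maximal paths between such terminals with
orthogonal steps of 1 px and diagonal steps of √2 px. Closed loops
containing no terminal are not counted as struts. Isolated single pixels
(degree 0) are neither nodes nor endpoints.

## Risk statistics

The ordinal observer score enters everywhere as a single numeric 0/1/2
(dense/alternating/sparse). For a three-level predictor the fitted
probabilities of any monotone model are monotone in the score, so the
ROC/AUC is identical under ordinal-numeric or dummy coding; the simpler
coding is used.

* **Odds ratios**: cross-product ratio of a 2 × 2 table with the Wald
  interval exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)). Zero cells are rejected
  by default; an explicit flag applies the Haldane–Anscombe 0.5
  correction. On the packaged table this reproduces the published
  intervals to one decimal.
* **Ordinal AUC**: tie-corrected pairwise concordance over all
  case–control pairs, algebraically equal to the trapezoidal ROC area of
  any monotone score model; the package tests both routes against each
  other to 1e-12.
* **Cohen's kappa** is implemented directly from (p₀ − pₑ)/(1 − pₑ) and
  cross-checked against scikit-learn in the test suite; it is undefined
  (returns None) when chance agreement is 1.
* **Welch's t** uses the Satterthwaite degrees of freedom via
  `scipy.stats.ttest_ind(equal_var=False)`.
* **Forward stepwise logistic regression** starts from the intercept-only
  model (prevalence prediction). Each step fits every remaining candidate
  with `statsmodels` Logit and enters the one with the largest
  likelihood-ratio improvement if its χ²₁ p-value is below α (default
  0.05); there is no removal step. The LRT was chosen as the entry test
  for transparency and testability over score-test variants found in
  legacy software. Candidates that produce a degenerate fit — runaway
  coefficients or every fitted probability pinned to 0/1, the signatures
  of (quasi-)separation under a quietly converging quasi-Newton optimiser
  — are excluded with a warning rather than silently accepted. No
  multiple-testing correction is applied across candidate t tests; the
  CLI reports raw p-values (a Bonferroni view for k comparisons is a
  one-line postprocessing step left to the caller).

## Synthetic data

**Textures.** Seeded white noise is smoothed with an anisotropic Gaussian
(σ across the grain = coarseness/2, along the grain anisotropy × that).
For anisotropy > 1, a band-pass component — the second derivative across
the grain — is blended in with weight 1 − 1/anisotropy and unit-variance
normalisation. This turns elongated blobs into quasi-periodic strut-like
ridges, which resembles trabecular bone more closely than a pure Gaussian
blob field and gives the LFD profile a sharp angular peak; at anisotropy 1
the field is exactly isotropic. The oriented field is produced by
rotating a larger field and cropping the centre, then thresholded at the
order statistic that yields the requested white fraction *exactly* (to
within one pixel in the count). Rendering assigns the phases gray levels
`120 ± phase_contrast/2` (default separation 60 gray), blurs the boundary
with a 0.7 px Gaussian (focal/scanner blur), and adds a zero-mean random
quadratic background with peak-to-peak range `gradient_amplitude` (the
cortex/soft-tissue confounder, default 40 gray) plus Gaussian pixel noise
(default SD 8 gray). One integer seed feeds independent substreams for
field, background and noise, so all outputs are bit-reproducible.

What the generator does *not* emulate: anatomic structures (teeth, roots,
mandibular canal, cortical borders), projection geometry, scanner MTF and
film grain, or observer behaviour. Passing tests therefore demonstrate
the correctness and internal consistency of the pipeline on controlled
textures with known truth — not clinical performance on real radiographs.

**Reference archetypes.** Dense: white fraction 0.55 at coarseness 5 px;
sparse: 0.40 at 13 px; alternating: a single field thresholded with a
row-dependent quantile following a plateau–ramp–plateau profile (dense in
the top/cervical third, sparse in the bottom/apical third). The dense
fraction is kept below the percolation regime deliberately: at higher
fractions the white phase merges into few large segments and the defining
property of the dense pattern — many distinct trabeculae with small
marrow spaces — would invert. With these archetypes the dense pattern has
both a higher white number density and a smaller black mean area than the
sparse one across seeds.

**Cohorts.** Scores are drawn from configurable prevalences (default
49/146/109 out of 304), fracture outcome per score from configurable
probabilities (default 1/49, 35/146, 79/109 — the rates in the packaged
table, implying a sparse-vs-rest OR of 11.6), and clinical variables from
independent Gaussians with the cohort's reported means and SDs (age
54.1 ± 4.0 y, weight 66.3 ± 10.6 kg, height 163.5 ± 5.9 cm, BMI
24.8 ± 3.6 kg/m²). Optional image features are drawn as
γ·score + N(0, 1), i.e. associated with fracture only through the score —
sufficient for exercising variable selection and the nesting behaviour of
combined models. In the record-level expansion of the packaged table used
by the stepwise demonstration, the clinical covariates are null by
construction; each new seed draws fresh null covariates, so a false entry
at α = 0.05 occurs in a predictable minority of seeds (the stepwise
report counts extra entered variables for exactly this reason).

## Problem sizes and numerics

Tests and the acceptance script run textures at the full 650 px analysis
size where the claim concerns the study geometry (orientation recovery,
full-chain area-fraction recovery) and at 48–300 px where a property is
size-independent and a brute-force oracle must stay cheap (flood-fill
labelling, per-window median sort, Euclidean-distance transforms, skeleton
census). Orientation recovery is evaluated over 100 seeded replicates at
anisotropy 4; cohort odds-ratio recovery at n = 100 000; logistic
coefficient coverage (estimate within 2 SE of truth) over 100 replicates
at n = 5000. Thresholding ties in `segment_binary` go to white; argmax
ties in `dominant_orientation` go to the smallest angle; an all-zero LFD
profile has undefined orientation (None). Degenerate inputs are accepted
where scientifically meaningful (a constant ROI segments to all white and
yields a complete, finite feature vector).

## Known limitations

* The brightness/contrast formulas, the self-masking blur scale and the
  LFD statistic are declared conventions of this package; results should
  not be read as numerically identical to any legacy implementation of
  the same analysis ideas.
* Perimeter is an edge-count measure and overestimates smooth-boundary
  length by up to a factor ~1.27 (4/π) relative to geometric perimeter;
  it is exact, deterministic and internally comparable, which is what the
  feature is used for.
* The stepwise procedure inherits the usual caveats of in-sample variable
  selection (optimistic AUC, no shrinkage); no AUC confidence intervals
  are produced.
* Cohort generators draw clinical variables independently of outcome and
  of each other; they are statistical twins of marginal summaries, not of
  joint clinical structure.
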