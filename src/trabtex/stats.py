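"""Fracture-risk statistics for ordinal trabecular-pattern scores.

The observer score of the mandibular trabecular pattern is a three-level
ordinal rating (dense < alternating < sparse) that predicts postcranial
fractures in postmenopausal women.  This module implements the statistics
used to quantify that association:

* cross-tabulation of fracture outcome against the score and odds ratios
  with Wald confidence intervals,
* sensitivity/specificity for a score cutoff,
* the ordinal ROC area (tie-corrected pairwise concordance),
* Cohen's kappa for observer agreement,
* Welch's t for group comparisons of clinical variables,
* forward stepwise logistic regression with a likelihood-ratio entry test,
  and ROC construction from fitted probabilities.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "SCORE_LABELS",
    "SCORE_CODES",
    "CohortRecord",
    "ContingencyTable",
    "StepwiseModel",
    "ROCResult",
    "build_contingency",
    "odds_ratio_ci",
    "sensitivity_specificity",
    "ordinal_auc",
    "cohens_kappa",
    "welch_t",
    "forward_stepwise_logistic",
    "roc_from_scores",
    "load_table2",
    "expand_table",
]

#: Ordinal observer-score categories, coarsest trabecular pattern last.
SCORE_LABELS = ("dense", "alternating", "sparse")
SCORE_CODES = {label: code for code, label in enumerate(SCORE_LABELS)}


@dataclass
class CohortRecord:
    """One subject of the fracture-risk cohort.

    ``score`` is the ordinal observer score (dense=0, alternating=1,
    sparse=2); ``fracture`` is 1 if the subject sustained a fracture during
    follow-up.  Clinical variables may be missing (``None``); ``features``
    optionally holds per-subject image features keyed by column name.
    """

    id: str
    score: int
    fracture: int
    age: float | None = None
    weight: float | None = None
    height: float | None = None
    bmi: float | None = None
    features: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.score not in (0, 1, 2):
            raise ValueError(f"score must be 0, 1 or 2, got {self.score!r}")
        if self.fracture not in (0, 1):
            raise ValueError(f"fracture must be 0 or 1, got {self.fracture!r}")
        for name in ("age", "weight", "height", "bmi"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive when present, got {v!r}")

    @property
    def score_label(self) -> str:
        return SCORE_LABELS[self.score]


class ContingencyTable:
    """Fracture outcome x observer score counts.

    Rows: fractured, fracture-free.  Columns: dense, alternating, sparse.
    """

    def __init__(self, counts) -> None:
        counts = np.asarray(counts, dtype=int)
        if counts.shape != (2, 3):
            raise ValueError(f"expected a 2x3 count grid, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def collapse(self, positive_scores: set[int] | frozenset[int]) -> np.ndarray:
        """Collapse to a 2x2 exposure table [[a, b], [c, d]].

        ``a`` = fractured with a positive score, ``b`` = fractured otherwise,
        ``c``/``d`` the same split among the fracture-free, so the odds ratio
        a*d/(b*c) is the fracture odds ratio of the positive-score group.
        """
        pos = sorted(positive_scores)
        if not pos or len(pos) >= 3:
            raise ValueError("positive_scores must be a non-empty proper subset of {0,1,2}")
        neg = [s for s in range(3) if s not in pos]
        c = self.counts
        return np.array(
            [
                [c[0, pos].sum(), c[0, neg].sum()],
                [c[1, pos].sum(), c[1, neg].sum()],
            ],
            dtype=int,
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, ContingencyTable) and bool(
            (self.counts == other.counts).all()
        )

    def __repr__(self) -> str:
        return f"ContingencyTable({self.counts.tolist()})"


def build_contingency(records: list[CohortRecord]) -> ContingencyTable:
    """Cross-tabulate fracture outcome against the observer score."""
    if not records:
        raise ValueError("cannot build a contingency table from an empty cohort")
    counts = np.zeros((2, 3), dtype=int)
    for r in records:
        counts[0 if r.fracture else 1, r.score] += 1
    return ContingencyTable(counts)


def odds_ratio_ci(
    table2x2, level: float = 0.95, zero_correction: bool = False
) -> tuple[float, float, float]:
    """Cross-product odds ratio with a Wald confidence interval.

    ``table2x2`` is [[a, b], [c, d]]; the returned OR is a*d/(b*c) and the
    interval exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).  Zero cells are
    rejected unless ``zero_correction`` adds the Haldane-Anscombe 0.5 to
    every cell.
    """
    t = np.asarray(table2x2, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t == 0).any():
        if not zero_correction:
            raise ValueError(
                "table contains a zero cell; pass zero_correction=True to apply "
                "the 0.5 continuity correction"
            )
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + level / 2)
    lo = math.exp(math.log(or_) - z * se)
    hi = math.exp(math.log(or_) + z * se)
    return or_, lo, hi


def sensitivity_specificity(
    table: ContingencyTable, positive_scores: set[int] | frozenset[int]
) -> tuple[float, float]:
    """Sensitivity and specificity of a score cutoff for fracture.

    A subject tests positive when their score lies in ``positive_scores``
    (or when ``positive_scores`` covers all three levels, in which case the
    degenerate 100%/0% cutoff is returned).
    """
    pos = sorted(set(positive_scores))
    if not pos:
        raise ValueError("positive_scores must be non-empty")
    neg = [s for s in range(3) if s not in pos]
    c = table.counts
    n_frac, n_free = table.row_totals
    if n_frac == 0 or n_free == 0:
        raise ValueError("both outcome groups must be non-empty")
    sensitivity = c[0, pos].sum() / n_frac
    specificity = c[1, neg].sum() / n_free if neg else 0.0
    return float(sensitivity), float(specificity)


def ordinal_auc(table: ContingencyTable) -> float | None:
    """ROC area of the ordinal score: tie-corrected pairwise concordance.

    Over all fractured x fracture-free pairs, a pair counts 1 when the
    fractured subject has the higher (sparser) score and 0.5 on ties; the
    sum divided by the pair count is the AUC, identical to the ROC area of
    any monotone model of the score.  Returns None if either outcome group
    is empty.
    """
    cases = table.counts[0].astype(float)
    controls = table.counts[1].astype(float)
    n_pairs = cases.sum() * controls.sum()
    if n_pairs == 0:
        return None
    wins = sum(
        cases[j] * controls[k] for j in range(3) for k in range(3) if j > k
    )
    ties = float((cases * controls).sum())
    return float((wins + 0.5 * ties) / n_pairs)


def cohens_kappa(ratings_a, ratings_b) -> float | None:
    """Chance-corrected agreement between two categorical raters.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and p_e
    the agreement expected from the raters' marginal frequencies.  Returns
    None when chance agreement is 1 (both raters constant and equal), where
    kappa is undefined.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be two equal-length 1-D sequences")
    if a.size == 0:
        raise ValueError("ratings must be non-empty")
    cats = np.union1d(a, b)
    n = a.size
    p_o = float(np.mean(a == b))
    p_e = sum(
        float(np.sum(a == c)) / n * float(np.sum(b == c)) / n for c in cats
    )
    if p_e >= 1.0 - 1e-15:
        return None
    return (p_o - p_e) / (1.0 - p_e)


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t test with Satterthwaite df, two-sided p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance; t is undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# forward stepwise logistic regression
# ---------------------------------------------------------------------------


@dataclass
class StepwiseModel:
    """Result of a forward stepwise logistic regression.

    ``selected`` lists the entered variables in entry order; ``steps`` holds
    one (variable, LR statistic, p value) triple per entry.  ``params`` maps
    "const" and each selected variable to its logit-scale coefficient;
    ``fitted`` are per-record event probabilities; ``excluded`` lists
    candidates dropped for perfect separation or non-convergence.
    """

    selected: list[str]
    steps: list[tuple[str, float, float]]
    params: dict[str, float]
    fitted: np.ndarray
    llf: float
    excluded: list[str] = field(default_factory=list)

    @property
    def intercept(self) -> float:
        return self.params["const"]


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Fit a logit model; return the result or None if it is unusable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
                disp=0, maxiter=200, method="lbfgs"
            )
        except Exception:
            return None
    if not np.isfinite(res.llf) or not np.all(np.isfinite(res.params)):
        return None
    # (quasi-)separation: runaway parameters, or every fitted probability
    # pinned to 0/1 (the in-sample likelihood is then spuriously perfect)
    if np.abs(np.asarray(res.params)).max() > 1e3:
        return None
    fitted = np.asarray(res.predict())
    if np.all((fitted < 1e-4) | (fitted > 1.0 - 1e-4)):
        return None
    return res


def forward_stepwise_logistic(
    data: pd.DataFrame | list[CohortRecord],
    candidates: list[str],
    outcome: str = "fracture",
    alpha: float = 0.05,
) -> StepwiseModel:
    """Forward stepwise logistic regression with a likelihood-ratio entry test.

    Starts from the intercept-only model (prediction by prevalence).  At each
    step, every remaining candidate is added in turn; the one giving the
    largest likelihood-ratio improvement enters if its LRT p value (chi2 with
    1 df) is below ``alpha``, otherwise selection stops.  There is no removal
    step.  Candidates on which the fit degenerates (perfect separation,
    non-convergence) are excluded with a warning.

    ``data`` is a DataFrame with the outcome column and candidate columns, or
    a list of :class:`CohortRecord` (the score and clinical variables become
    columns; feature dict entries become columns too).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if isinstance(data, list):
        data = records_to_frame(data)
    missing = [c for c in candidates if c not in data.columns]
    if missing:
        raise KeyError(f"candidate columns missing from data: {missing}")
    y = data[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")

    n = len(y)
    p1 = y.mean()
    llf_cur = n * (p1 * math.log(p1) + (1 - p1) * math.log(1 - p1))
    selected: list[str] = []
    steps: list[tuple[str, float, float]] = []
    excluded: list[str] = []
    remaining = list(candidates)
    res_cur = None

    while remaining:
        best = None  # (p, -lr, name, res) so min() prefers small p then big LR
        for name in list(remaining):
            res = _fit_logit(y, data[selected + [name]])
            if res is None:
                warnings.warn(
                    f"candidate {name!r} excluded: separation or non-convergence",
                    stacklevel=2,
                )
                remaining.remove(name)
                excluded.append(name)
                continue
            lr = 2.0 * (res.llf - llf_cur)
            p = float(sps.chi2.sf(max(lr, 0.0), df=1))
            if best is None or (p, -lr) < (best[0], best[1]):
                best = (p, -lr, name, res)
        if best is None or best[0] >= alpha:
            break
        p, neg_lr, name, res = best
        selected.append(name)
        steps.append((name, -neg_lr, p))
        remaining.remove(name)
        llf_cur = res.llf
        res_cur = res

    if res_cur is None:
        params = {"const": math.log(p1 / (1 - p1))}
        fitted = np.full(n, p1)
    else:
        params = {k: float(v) for k, v in res_cur.params.items()}
        fitted = np.asarray(res_cur.predict())
    return StepwiseModel(
        selected=selected,
        steps=steps,
        params=params,
        fitted=fitted,
        llf=float(llf_cur),
        excluded=excluded,
    )


def records_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    """Flatten cohort records into a modelling DataFrame.

    The ordinal score enters as a single numeric column (0/1/2); feature
    dict entries become additional columns.
    """
    rows = []
    for r in records:
        row: dict[str, object] = {
            "id": r.id,
            "score": r.score,
            "fracture": r.fracture,
            "age": r.age,
            "weight": r.weight,
            "height": r.height,
            "bmi": r.bmi,
        }
        row.update(r.features)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC construction
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    """ROC points (FPR, TPR ordered by threshold sweep) and trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_from_scores(scores, outcomes) -> ROCResult | None:
    """ROC curve from per-record risk scores by threshold sweep.

    Returns None when only one outcome class is present (the curve is
    undefined).  The AUC is the trapezoidal area, invariant under any
    strictly monotone transform of the scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be equal-length 1-D vectors")
    if len(np.unique(y)) < 2:
        return None
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc)


# ---------------------------------------------------------------------------
# packaged observer-score table
# ---------------------------------------------------------------------------


def load_table2() -> ContingencyTable:
    """The packaged 304-subject observer-score cross-tabulation.

    Counts reconstructed uniquely from the published margins; see
    ``data/table2.csv`` for the arithmetic.
    """
    ref = importlib.resources.files("trabtex.data").joinpath("table2.csv")
    with ref.open() as fh:
        df = pd.read_csv(fh, comment="#")
    counts = np.zeros((2, 3), dtype=int)
    for _, row in df.iterrows():
        i = 0 if int(row["fracture"]) == 1 else 1
        counts[i, SCORE_CODES[str(row["score"]).lower()]] = int(row["count"])
    return ContingencyTable(counts)


def expand_table(
    table: ContingencyTable,
    seed: int | None = None,
    clinical: bool = False,
) -> list[CohortRecord]:
    """Expand a contingency table into one record per subject.

    With ``clinical=True`` (requires ``seed``), Gaussian clinical variables
    are drawn independently of both score and outcome — null covariates for
    exercising variable selection.
    """
    records: list[CohortRecord] = []
    rng = np.random.default_rng(seed) if clinical else None
    k = 0
    for i, frac in ((0, 1), (1, 0)):
        for score in range(3):
            for _ in range(int(table.counts[i, score])):
                extra = {}
                if rng is not None:
                    height = rng.normal(163.5, 5.9)
                    weight = rng.normal(66.3, 10.6)
                    extra = dict(
                        age=rng.normal(54.1, 4.0),
                        weight=weight,
                        height=height,
                        bmi=weight / (height / 100.0) ** 2,
                    )
                records.append(
                    CohortRecord(id=f"s{k:04d}", score=score, fracture=frac, **extra)
                )
                k += 1
    return records
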