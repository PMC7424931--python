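"""Agreement statistics for cone identifications and densities.

Point-level agreement between an ordered (ground truth, comparison) pair of
annotators is summarized by

    true positive rate  TPR  = n_tp / n_ground_truth
    false positive rate FPR  = n_fp / n_comparison
    Dice's coefficient  Dice = 2 n_tp / (n_ground_truth + n_comparison)

Density-level agreement across annotators uses Bland–Altman analysis
(bias and 95% limits of agreement, with an automatic log10 transform when
the raw paired differences fail a Shapiro–Wilk normality test), the
two-way random-effects absolute-agreement single-measure intraclass
correlation ICC(2,1) with its F-based 95% CI, a repeated-measures one-way
ANOVA with Bonferroni-corrected post hoc paired t-tests, and the per-ROI
coefficient of variation of density.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .io import ConePoints
from .matching import (
    ClusterSet,
    ConfusionCounts,
    cluster_multigrader,
    confusion_from_clusters,
)

__all__ = [
    "AgreementRates",
    "BlandAltmanResult",
    "ICCResult",
    "PairwiseTestTable",
    "agreement_rates",
    "rotate_ground_truth",
    "bland_altman",
    "icc",
    "repeated_measures_anova",
    "density_cov",
    "cicchetti_band",
]

#: Cicchetti's qualitative interpretation bands for ICC values.
CICCHETTI_CUTS = ((0.75, "excellent"), (0.60, "good"), (0.40, "fair"))


@dataclass(frozen=True)
class AgreementRates:
    """TPR, FPR and Dice for one ordered annotator pair."""

    tpr: float
    fpr: float
    dice: float


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and limits of agreement between two paired measurement series,
    on the analysis scale (`transform` is "log10" when the raw differences
    failed normality and both series were log10-transformed first)."""

    transform: str
    normality_p: float
    bias: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,1) with its 95% CI and Cicchetti qualitative band."""

    icc: float
    ci_low: float
    ci_high: float
    n_targets: int
    n_raters: int
    qualitative_band: str


@dataclass
class PairwiseTestTable:
    """Omnibus repeated-measures ANOVA plus Bonferroni-corrected post hoc
    paired t-tests; `degenerate` is set when there is no variance to test."""

    f_stat: float
    p_omnibus: float
    pairs: list[tuple[str, str]]
    p_raw: list[float]
    p_adjusted: list[float]
    degenerate: bool = False


def agreement_rates(c: ConfusionCounts) -> AgreementRates:
    """TPR, FPR and Dice from confusion counts.

    Dice is equivalently the harmonic mean of TPR and precision
    (1 − FPR) whenever n_tp > 0.
    """
    if c.n_gt == 0 or c.n_comp == 0:
        raise ValueError(
            f"rates undefined for empty sets (n_gt={c.n_gt}, n_comp={c.n_comp})"
        )
    return AgreementRates(
        tpr=c.n_tp / c.n_gt,
        fpr=c.n_fp / c.n_comp,
        dice=2.0 * c.n_tp / (c.n_gt + c.n_comp),
    )


def rotate_ground_truth(
    sets: list[ConePoints], clusters: ClusterSet | None = None
) -> dict[tuple[str, str], AgreementRates]:
    """Agreement rates for every ordered annotator pair of one ROI.

    The annotators' selections are clustered once (at most one selection
    per annotator per cluster); each annotator then takes a turn as ground
    truth against each of the others, giving k(k−1) table entries for k
    annotators.
    """
    if clusters is None:
        clusters = cluster_multigrader(sets)
    labels = clusters.graders
    out: dict[tuple[str, str], AgreementRates] = {}
    for gt, comp in itertools.permutations(labels, 2):
        out[(gt, comp)] = agreement_rates(
            confusion_from_clusters(clusters, gt, comp)
        )
    return out


def bland_altman(
    values_a: np.ndarray, values_b: np.ndarray, alpha: float = 0.05
) -> BlandAltmanResult:
    """Bland–Altman bias and 95% limits of agreement for paired densities.

    The Shapiro–Wilk test is applied to the raw differences ``b − a``; if
    normality is rejected at ``alpha`` both series are log10-transformed
    (densities must then be positive) and the analysis is done on the log
    scale.  Limits of agreement are bias ± 1.96 × SD of the differences.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("need ≥ 3 pairs")
    diffs = b - a
    if np.ptp(diffs) < 1e-12:
        # Constant differences: Shapiro-Wilk is undefined; nothing to
        # reject, keep the identity scale.
        p = 1.0
    else:
        p = float(sps.shapiro(diffs).pvalue)
    transform = "identity"
    if p < alpha:
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("log10 transform requires positive values")
        a, b = np.log10(a), np.log10(b)
        diffs = b - a
        transform = "log10"
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltmanResult(
        transform=transform,
        normality_p=p,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=len(diffs),
    )


def cicchetti_band(icc_value: float) -> str:
    """Qualitative agreement band for an ICC (poor/fair/good/excellent)."""
    for cut, band in CICCHETTI_CUTS:
        if icc_value >= cut:
            return band
    return "poor"


def icc(density_matrix: np.ndarray) -> ICCResult:
    """ICC(2,1) — two-way random effects, absolute agreement, single
    measure — of a complete targets × raters matrix, with 95% CI.

    Parameters
    ----------
    density_matrix : (n_targets, n_raters) array
        E.g. per-ROI bound densities, one column per annotator; must be
        complete (no NaN), with ≥ 3 targets and ≥ 2 raters.
    """
    m = np.asarray(density_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError(f"need a (≥3 targets) × (≥2 raters) matrix, got {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix must be complete (finite values only)")
    n, k = m.shape
    long = pd.DataFrame(
        {
            "target": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "rating": m.ravel(),
        }
    )
    table = pg.intraclass_corr(
        data=long, targets="target", raters="rater", ratings="rating"
    ).set_index("Type")
    # Two-way random, absolute agreement, single measure: labeled ICC2 in
    # the Shrout–Fleiss scheme and ICC(A,1) in McGraw–Wong's.
    key = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
    row = table.loc[key]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    value = float(row["ICC"])
    ci_low, ci_high = (float(x) for x in row[ci_col])
    return ICCResult(
        icc=value,
        ci_low=ci_low,
        ci_high=ci_high,
        n_targets=n,
        n_raters=k,
        qualitative_band=cicchetti_band(value),
    )


def icc21_closed_form(density_matrix: np.ndarray) -> float:
    """ICC(2,1) from the two-way ANOVA mean squares:
    (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n).

    Kept as an independent closed-form route for cross-validation.
    """
    m = np.asarray(density_matrix, dtype=float)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def repeated_measures_anova(
    matrix: np.ndarray, condition_labels: list[str] | None = None
) -> PairwiseTestTable:
    """Within-subject one-way ANOVA over conditions plus Bonferroni-adjusted
    post hoc paired t-tests.

    Parameters
    ----------
    matrix : (n_subjects, n_conditions) array
        Complete; subjects are e.g. ROIs, conditions e.g. annotator pairs.
    condition_labels
        Names for the columns; defaults to ``c0, c1, ...``.

    Degenerate input (zero variance within and between conditions) is
    flagged and reported with omnibus p = 1 and no significant pair.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError(f"need (≥3 subjects) × (≥2 conditions), got {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix must be complete")
    n, k = m.shape
    labels = condition_labels or [f"c{j}" for j in range(k)]
    if len(labels) != k:
        raise ValueError("label count mismatch")

    pairs = list(itertools.combinations(labels, 2))
    n_pairs = len(pairs)
    col = {lab: m[:, j] for j, lab in enumerate(labels)}

    centered = m - m.mean(axis=1, keepdims=True)
    if np.ptp(m) < 1e-12 or np.max(np.abs(centered)) < 1e-12:
        return PairwiseTestTable(
            f_stat=float("nan"),
            p_omnibus=1.0,
            pairs=pairs,
            p_raw=[1.0] * n_pairs,
            p_adjusted=[1.0] * n_pairs,
            degenerate=True,
        )

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "condition": np.tile(labels, n),
            "value": m.ravel(),
        }
    )
    aov = pg.rm_anova(
        data=long, dv="value", within="condition", subject="subject", detailed=True
    )
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    f_stat = float(aov.loc[0, "F"])
    p_omnibus = float(aov.loc[0, pcol])

    p_raw = []
    for la, lb in pairs:
        if np.ptp(col[la] - col[lb]) < 1e-12:
            p_raw.append(1.0)
        else:
            p_raw.append(float(sps.ttest_rel(col[la], col[lb]).pvalue))
    p_adj = [min(1.0, p * n_pairs) for p in p_raw]
    return PairwiseTestTable(
        f_stat=f_stat,
        p_omnibus=p_omnibus,
        pairs=pairs,
        p_raw=p_raw,
        p_adjusted=p_adj,
    )


def density_cov(densities: np.ndarray) -> float:
    """Coefficient of variation (sample SD / mean) of per-annotator
    densities for one ROI."""
    d = np.asarray(densities, dtype=float)
    if len(d) < 2:
        raise ValueError("need ≥ 2 values")
    mean = float(np.mean(d))
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    return float(np.std(d, ddof=1) / mean)
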