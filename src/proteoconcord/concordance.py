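"""Cross-cohort reproducibility scoring: Bland-Altman, ICC, and the GSI.

The Global Similarity Index (GSI) scores the agreement of two cohorts'
proteomic profiles on [0, 1] as a weighted average of five statistics:
Pearson correlation (25%), intraclass correlation coefficient ICC(2,1)
(25%), percent similarity (20%), Bland-Altman percent difference (15%) and
standardized Z-score (15%).  Pearson and ICC are global — computed once on
the two per-protein cohort mean vectors and shared by every protein —
while percent similarity, percent difference and Z are per protein; a
per-protein correlation across two cohorts would be undefined.

Component normalizations onto [0, 1]:

    c1 = (pearson + 1) / 2               c4_g = 1 - min(pdiff_g, 100) / 100
    c2 = max(0, icc)                     c5_g = max(0, 1 - |z_g| / z_crit)
    c3_g = psim_g / 100

gsi_g = 0.25 c1 + 0.25 c2 + 0.20 c3_g + 0.15 c4_g + 0.15 c5_g, and the
global GSI is the mean of gsi_g over proteins.  Categories: very_high
(>= 0.90), high (>= 0.75), moderate (>= 0.50), low otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .quantio import LOG2, QuantMatrix, SampleMetadata

__all__ = [
    "GsiWeights",
    "BlandAltmanResult",
    "ConcordanceResult",
    "CohortConcordance",
    "cohort_means",
    "pearson_between",
    "icc_between",
    "percent_similarity",
    "percent_difference",
    "bland_altman",
    "compute_gsi",
    "classify_similarity",
]

CATEGORY_THRESHOLDS = (("very_high", 0.90), ("high", 0.75), ("moderate", 0.50))
CATEGORIES = ("very_high", "high", "moderate", "low")


@dataclass(frozen=True)
class GsiWeights:
    """The five GSI component weights (must sum to 1) and the Z cutoff."""

    w_pearson: float = 0.25
    w_icc: float = 0.25
    w_psim: float = 0.20
    w_pdiff: float = 0.15
    w_z: float = 0.15
    z_crit: float = 1.96

    def __post_init__(self) -> None:
        total = self.w_pearson + self.w_icc + self.w_psim + self.w_pdiff + self.w_z
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"GSI weights must sum to 1, got {total}")
        if self.z_crit <= 0:
            raise ValueError("z_crit must be positive")


@dataclass
class BlandAltmanResult:
    """Per-protein differences with bias, limits of agreement and Z-scores."""

    d: np.ndarray  # mean_A - mean_B per protein, log2 units
    mean_d: float  # bias
    sd_d: float
    loa_low: float  # mean_d - 1.96 sd_d
    loa_high: float  # mean_d + 1.96 sd_d
    z: np.ndarray  # (d - mean_d) / sd_d; all 0 when sd_d == 0
    flag: np.ndarray  # |z| > z_crit
    z_crit: float = 1.96


@dataclass
class ConcordanceResult:
    """Full GSI decomposition for one cohort pair."""

    protein_ids: list[str]
    pearson: float
    icc: float
    psim: np.ndarray  # percent similarity per protein, [0, 100]
    pdiff: np.ndarray  # percent difference per protein, >= 0
    bland_altman: BlandAltmanResult
    components: np.ndarray  # n_proteins x 5, columns c1..c5
    gsi: np.ndarray
    category: np.ndarray
    global_gsi: float
    global_similarity_pct: float  # mean percent similarity
    weights: GsiWeights = field(default_factory=GsiWeights)

    def category_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.category == c)) for c in CATEGORIES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                "d": self.bland_altman.d,
                "z": self.bland_altman.z,
                "flag": self.bland_altman.flag,
                "psim": self.psim,
                "pdiff": self.pdiff,
                "c1_pearson": self.components[:, 0],
                "c2_icc": self.components[:, 1],
                "c3_psim": self.components[:, 2],
                "c4_pdiff": self.components[:, 3],
                "c5_z": self.components[:, 4],
                "gsi": self.gsi,
                "category": self.category,
            }
        )


def cohort_means(
    matrix: QuantMatrix, metadata: Sequence[SampleMetadata], cohort: str
) -> np.ndarray:
    """Per-protein arithmetic mean over one cohort's samples."""
    by_id = {m.sample_id: m for m in metadata}
    cols = [
        j
        for j, s in enumerate(matrix.sample_ids)
        if s in by_id and by_id[s].cohort == cohort
    ]
    if not cols:
        raise ValueError(f"cohort {cohort!r} absent from the matrix")
    if not matrix.mask[:, cols].all():
        raise ValueError("cohort_means expects a complete (imputed) matrix")
    return matrix.values[:, cols].mean(axis=1)


def pearson_between(mA: np.ndarray, mB: np.ndarray) -> float:
    """Sample Pearson correlation across proteins between cohort means."""
    mA = np.asarray(mA, dtype=float)
    mB = np.asarray(mB, dtype=float)
    if mA.size < 3 or mA.size != mB.size:
        raise ValueError("need two equal-length vectors of length >= 3")
    a = mA - mA.mean()
    b = mB - mB.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise ValueError("zero variance in a cohort mean vector")
    # clamp away round-off so self-comparison scores exactly 1
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def icc_between(mA: np.ndarray, mB: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Proteins are the subjects (n rows) and the two cohorts the raters
    (k = 2); a systematic offset between cohorts therefore lowers the ICC.
    From the two-way ANOVA mean squares of the n x 2 table [mA, mB]:

        (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    A fully degenerate table (every value identical) is defined as ICC 1.
    """
    Y = np.column_stack([np.asarray(mA, float), np.asarray(mB, float)])
    n, k = Y.shape
    if n < 3:
        raise ValueError("need at least 3 proteins")
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((Y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return 1.0  # every value identical: perfect agreement by convention
    # ss_err can round to a tiny negative for identical raters; cap at 1
    return float(min((msr - mse) / denom, 1.0))


def percent_similarity(mA: np.ndarray, mB: np.ndarray) -> np.ndarray:
    """Per-protein percent similarity, 100 (1 - |dA - dB| / pair mean).

    Clamped to [0, 100]; a non-positive pair mean scores 0 with a warning
    (cannot happen for log2 intensities of real DIA signals, which sit far
    above zero).
    """
    mA = np.asarray(mA, dtype=float)
    mB = np.asarray(mB, dtype=float)
    pair_mean = (mA + mB) / 2.0
    psim = np.zeros(mA.size)
    bad = pair_mean <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} proteins have non-positive pair means; "
            "percent similarity set to 0",
            UserWarning,
            stacklevel=2,
        )
    ok = ~bad
    psim[ok] = 100.0 * (1.0 - np.abs(mA[ok] - mB[ok]) / pair_mean[ok])
    return np.clip(psim, 0.0, 100.0)


def percent_difference(mA: np.ndarray, mB: np.ndarray) -> np.ndarray:
    """Per-protein percent difference |dA - dB| / pair mean * 100 (>= 0)."""
    mA = np.asarray(mA, dtype=float)
    mB = np.asarray(mB, dtype=float)
    pair_mean = (mA + mB) / 2.0
    out = np.full(mA.size, 100.0)
    ok = pair_mean > 0
    out[ok] = 100.0 * np.abs(mA[ok] - mB[ok]) / pair_mean[ok]
    return out


def bland_altman(
    mA: np.ndarray, mB: np.ndarray, z_crit: float = 1.96
) -> BlandAltmanResult:
    """Bland-Altman agreement: bias, 1.96-sd limits, standardized Z-scores.

    Identical vectors give sd_d = 0; every z is then defined as 0 and no
    protein is flagged, so self-comparison is well-behaved.
    """
    mA = np.asarray(mA, dtype=float)
    mB = np.asarray(mB, dtype=float)
    if mA.size < 3 or mA.size != mB.size:
        raise ValueError("need two equal-length vectors of length >= 3")
    d = mA - mB
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d > 0:
        z = (d - mean_d) / sd_d
    else:
        z = np.zeros_like(d)
    return BlandAltmanResult(
        d=d,
        mean_d=mean_d,
        sd_d=sd_d,
        loa_low=mean_d - 1.96 * sd_d,
        loa_high=mean_d + 1.96 * sd_d,
        z=z,
        flag=np.abs(z) > z_crit,
        z_crit=z_crit,
    )


def classify_similarity(gsi: np.ndarray) -> np.ndarray:
    """Bin GSI scores into very_high / high / moderate / low."""
    gsi = np.asarray(gsi, dtype=float)
    out = np.full(gsi.size, "low", dtype=object)
    for name, cut in reversed(CATEGORY_THRESHOLDS):
        out[gsi >= cut] = name
    return out.astype(str)


class CohortConcordance(BaseEstimator):
    """GSI concordance estimator for a pair of cohorts.

    Parameters
    ----------
    cohort_a, cohort_b : str
        Cohort labels to compare (order only flips the sign of d; the GSI
        is symmetric).
    metadata : sequence of SampleMetadata
    weights : GsiWeights

    Attributes (after ``fit``)
    --------------------------
    result_ : ConcordanceResult
    global_gsi_, pearson_, icc_ : headline statistics
    """

    def __init__(self, cohort_a=None, cohort_b=None, metadata=None, weights=None):
        self.cohort_a = cohort_a
        self.cohort_b = cohort_b
        self.metadata = metadata
        self.weights = weights

    def fit(self, X: QuantMatrix, y=None):
        w = self.weights if self.weights is not None else GsiWeights()
        if X.scale != LOG2:
            raise ValueError("concordance expects a preprocessed log2 matrix")
        mA = cohort_means(X, self.metadata, self.cohort_a)
        mB = cohort_means(X, self.metadata, self.cohort_b)

        pearson = pearson_between(mA, mB)
        icc = icc_between(mA, mB)
        psim = percent_similarity(mA, mB)
        pdiff = percent_difference(mA, mB)
        ba = bland_altman(mA, mB, z_crit=w.z_crit)

        n = mA.size
        c1 = np.full(n, (pearson + 1.0) / 2.0)
        c2 = np.full(n, max(0.0, icc))
        c3 = psim / 100.0
        c4 = 1.0 - np.minimum(pdiff, 100.0) / 100.0
        c5 = np.maximum(0.0, 1.0 - np.abs(ba.z) / w.z_crit)
        components = np.column_stack([c1, c2, c3, c4, c5])
        gsi = (
            w.w_pearson * c1
            + w.w_icc * c2
            + w.w_psim * c3
            + w.w_pdiff * c4
            + w.w_z * c5
        )
        self.result_ = ConcordanceResult(
            protein_ids=list(X.protein_ids),
            pearson=pearson,
            icc=icc,
            psim=psim,
            pdiff=pdiff,
            bland_altman=ba,
            components=components,
            gsi=gsi,
            category=classify_similarity(gsi),
            global_gsi=float(gsi.mean()),
            global_similarity_pct=float(psim.mean()),
            weights=w,
        )
        self.global_gsi_ = self.result_.global_gsi
        self.pearson_ = pearson
        self.icc_ = icc
        return self


def compute_gsi(
    matrix: QuantMatrix,
    metadata: Sequence[SampleMetadata],
    cohort_a: str,
    cohort_b: str,
    weights: GsiWeights | None = None,
) -> ConcordanceResult:
    est = CohortConcordance(cohort_a, cohort_b, metadata, weights)
    return est.fit(matrix).result_
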