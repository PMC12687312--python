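"""Preprocessing stages: valid-value filtering, log2, quantile normalization,
PCA imputation, cohort centering, and PCA sample scores.

Each stage is a scikit-learn-style transformer over :class:`QuantMatrix`
(``fit``/``transform``, ``get_params``/``set_params``, fitted attributes with
a trailing underscore); the module-level functions are thin wrappers.  The
canonical stage order is

    filter -> log2 -> quantile_normalize -> pca_impute -> center_cohorts

and the scale flag on :class:`QuantMatrix` stops stages from being applied
out of order (log2 refuses a log2 matrix, quantile normalization refuses a
raw one, and so on).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .quantio import LOG2, RAW, QuantMatrix, SampleMetadata

__all__ = [
    "FilterRule",
    "ValidFractionFilter",
    "Log2Transformer",
    "QuantileNormalizer",
    "PCAImputer",
    "CohortCenterer",
    "filter_by_valid_fraction",
    "log2_transform",
    "quantile_normalize",
    "pca_impute",
    "center_cohorts",
    "pca_scores",
]


@dataclass(frozen=True)
class FilterRule:
    """Valid-value filter rule.

    ``any_group`` keeps a protein observed in at least ``min_fraction`` of
    the samples of *some* biological group (default 0.60); ``each_cohort``
    keeps a protein observed in at least ``min_fraction`` of the samples of
    *every* cohort (default 0.35).  The mode determines the grouping key.
    """

    mode: str = "any_group"
    min_fraction: float | None = None

    DEFAULTS = {"any_group": 0.60, "each_cohort": 0.35}

    def __post_init__(self) -> None:
        if self.mode not in self.DEFAULTS:
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if self.min_fraction is None:
            object.__setattr__(self, "min_fraction", self.DEFAULTS[self.mode])
        if not 0.0 < self.min_fraction <= 1.0:
            raise ValueError("min_fraction must lie in (0, 1]")

    @property
    def grouping_key(self) -> str:
        return "group" if self.mode == "any_group" else "cohort"


def _metadata_map(
    matrix: QuantMatrix, metadata: Sequence[SampleMetadata]
) -> dict[str, SampleMetadata]:
    by_id = {m.sample_id: m for m in metadata}
    missing = [s for s in matrix.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    return by_id


class ValidFractionFilter(BaseEstimator, TransformerMixin):
    """Drop proteins with too few observed values per group or cohort.

    Parameters
    ----------
    mode : {"any_group", "each_cohort"}
    min_fraction : float or None
        Defaults to 0.60 for ``any_group`` and 0.35 for ``each_cohort``.
    metadata : sequence of SampleMetadata
    """

    def __init__(self, mode="any_group", min_fraction=None, metadata=None):
        self.mode = mode
        self.min_fraction = min_fraction
        self.metadata = metadata

    def fit(self, X: QuantMatrix, y=None):
        rule = FilterRule(self.mode, self.min_fraction)
        by_id = _metadata_map(X, self.metadata)
        key = rule.grouping_key
        labels = np.array([getattr(by_id[s], key) for s in X.sample_ids])
        fractions = {}
        for lab in np.unique(labels):
            cols = labels == lab
            fractions[lab] = X.mask[:, cols].mean(axis=1)
        frac = np.column_stack([fractions[lab] for lab in sorted(fractions)])
        if rule.mode == "any_group":
            keep = (frac >= rule.min_fraction).any(axis=1)
        else:
            keep = (frac >= rule.min_fraction).all(axis=1)
        self.rule_ = rule
        self.keep_ = keep
        self.n_kept_ = int(keep.sum())
        self.n_dropped_ = int((~keep).sum())
        if self.n_kept_ == 0:
            warnings.warn("filter removed every protein", UserWarning, stacklevel=2)
        return self

    def transform(self, X: QuantMatrix) -> QuantMatrix:
        return X.select_rows(np.flatnonzero(self.keep_))


class Log2Transformer(BaseEstimator, TransformerMixin):
    """Replace observed raw intensities with their log2; record the scale."""

    def fit(self, X: QuantMatrix, y=None):
        return self

    def transform(self, X: QuantMatrix) -> QuantMatrix:
        if X.scale != RAW:
            raise ValueError("matrix is already on the log2 scale")
        observed = X.values[X.mask]
        if observed.size and np.any(observed <= 0):
            raise ValueError("log2 transform requires strictly positive values")
        out = X.copy()
        out.values[out.mask] = np.log2(out.values[out.mask])
        out.scale = LOG2
        return out


def _reference_curve(values: np.ndarray, mask: np.ndarray, length: int) -> np.ndarray:
    """Mean quantile curve over columns, each interpolated to `length` points."""
    grid = np.linspace(0.0, 1.0, length)
    curves = []
    for j in range(values.shape[1]):
        col = values[mask[:, j], j]
        if col.size < 2:
            raise ValueError(f"column {j} has fewer than 2 observed values")
        srt = np.sort(col)
        pos = np.linspace(0.0, 1.0, srt.size)
        curves.append(np.interp(grid, pos, srt))
    return np.mean(curves, axis=0)


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Map every sample column onto the mean quantile curve.

    Complete columns end up with identical sorted value multisets; columns
    with missing cells are mapped by interpolating the reference curve at
    fractional quantile positions (the referenced implementation's
    behaviour).  Tied values receive the mean of the reference quantiles
    their ranks span; missing cells stay missing.
    """

    def fit(self, X: QuantMatrix, y=None):
        if X.scale != LOG2:
            raise ValueError("quantile normalization expects a log2 matrix")
        self.reference_ = _reference_curve(X.values, X.mask, X.n_proteins)
        return self

    def transform(self, X: QuantMatrix) -> QuantMatrix:
        ref = self.reference_
        grid = np.linspace(0.0, 1.0, ref.size)
        out = X.copy()
        for j in range(X.n_samples):
            rows = np.flatnonzero(X.mask[:, j])
            col = X.values[rows, j]
            if col.size < 2:
                raise ValueError(f"column {X.sample_ids[j]!r} has fewer than 2 observed values")
            order = np.argsort(col, kind="stable")
            pos = np.linspace(0.0, 1.0, col.size)
            mapped_sorted = np.interp(pos, grid, ref)
            mapped = np.empty_like(col)
            mapped[order] = mapped_sorted
            # ties: mean of the reference quantiles the tied ranks span
            if np.unique(col).size < col.size:
                df = pd.Series(mapped).groupby(pd.Series(col)).transform("mean")
                mapped = df.to_numpy()
            out.values[rows, j] = mapped
        return out


class PCAImputer(BaseEstimator, TransformerMixin):
    """Iterative low-rank (rank-k) completion of missing log2 intensities.

    Missing cells start at their protein (row) means; each iteration
    row-centers the completed matrix, takes its rank-``n_components`` SVD
    approximation, restores row means, and overwrites only the missing
    cells, until the largest absolute change at a missing cell falls below
    ``tol`` or ``max_iter`` is reached (then a warning carries the final
    delta).  Observed cells are bit-identical before and after; the imputed
    cells are recorded on the output's ``imputed`` attribute.
    """

    def __init__(self, n_components=2, max_iter=500, tol=1e-6, seed=0):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, X: QuantMatrix, y=None):
        return self

    def transform(self, X: QuantMatrix) -> QuantMatrix:
        if X.scale != LOG2:
            raise ValueError("pca_impute expects a log2 matrix")
        n, m = X.shape
        if self.n_components >= min(n, m):
            raise ValueError("n_components must be < min(n_proteins, n_samples)")
        if np.any(~X.mask.any(axis=1)):
            raise ValueError("every protein needs at least one observed value")
        if np.any(~X.mask.any(axis=0)):
            raise ValueError("every sample needs at least one observed value")
        out = X.copy()
        if X.is_complete():
            self.n_iter_, self.delta_ = 0, 0.0
            out.imputed = np.zeros(X.shape, dtype=bool)
            return out

        mask = X.mask
        miss = ~mask
        work = X.values.copy()
        row_means = np.array([work[i, mask[i]].mean() for i in range(n)])
        work[miss] = np.broadcast_to(row_means[:, None], (n, m))[miss]

        delta = np.inf
        it = 0
        for it in range(1, self.max_iter + 1):
            centered = work - work.mean(axis=1, keepdims=True)
            U, s, Vt = np.linalg.svd(centered, full_matrices=False)
            k = self.n_components
            approx = (U[:, :k] * s[:k]) @ Vt[:k]
            approx += work.mean(axis=1, keepdims=True)
            delta = float(np.max(np.abs(approx[miss] - work[miss])))
            work[miss] = approx[miss]
            if delta < self.tol:
                break
        else:
            warnings.warn(
                f"pca_impute did not converge in {self.max_iter} iterations "
                f"(final delta {delta:.3e})",
                UserWarning,
                stacklevel=2,
            )
        self.n_iter_, self.delta_ = it, delta
        out.values = work
        out.values[mask] = X.values[mask]  # observed cells bit-identical
        out.mask = np.ones(X.shape, dtype=bool)
        out.imputed = miss
        return out


class CohortCenterer(BaseEstimator, TransformerMixin):
    """Scalar per-cohort batch centering.

    Subtracts each cohort's grand mean over its observed cells and adds the
    global grand mean back, so per-protein between-cohort contrasts are
    preserved up to a single scalar per cohort.
    """

    def __init__(self, metadata=None):
        self.metadata = metadata

    def fit(self, X: QuantMatrix, y=None):
        if X.scale != LOG2:
            raise ValueError("center_cohorts expects a log2 matrix")
        by_id = _metadata_map(X, self.metadata)
        cohorts = np.array([by_id[s].cohort for s in X.sample_ids])
        self.global_mean_ = float(X.values[X.mask].mean())
        self.cohort_means_ = {}
        for cohort in np.unique(cohorts):
            cols = cohorts == cohort
            sub, submask = X.values[:, cols], X.mask[:, cols]
            if not submask.any():
                raise ValueError(f"cohort {cohort!r} has no observed cells")
            self.cohort_means_[cohort] = float(sub[submask].mean())
        self.cohorts_ = cohorts
        return self

    def transform(self, X: QuantMatrix) -> QuantMatrix:
        out = X.copy()
        for cohort, mu in self.cohort_means_.items():
            cols = self.cohorts_ == cohort
            shift = mu - self.global_mean_
            block = out.values[:, cols]
            block[out.mask[:, cols]] -= shift
            out.values[:, cols] = block
        return out


# ---------------------------------------------------------------------------
# functional wrappers


def filter_by_valid_fraction(
    matrix: QuantMatrix,
    metadata: Sequence[SampleMetadata],
    rule: FilterRule,
) -> QuantMatrix:
    f = ValidFractionFilter(rule.mode, rule.min_fraction, metadata)
    return f.fit_transform(matrix)


def log2_transform(matrix: QuantMatrix) -> QuantMatrix:
    return Log2Transformer().fit_transform(matrix)


def quantile_normalize(matrix: QuantMatrix) -> QuantMatrix:
    return QuantileNormalizer().fit_transform(matrix)


def pca_impute(
    matrix: QuantMatrix,
    n_components: int = 2,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> QuantMatrix:
    return PCAImputer(n_components, max_iter, tol, seed).fit_transform(matrix)


def center_cohorts(
    matrix: QuantMatrix, metadata: Sequence[SampleMetadata]
) -> QuantMatrix:
    return CohortCenterer(metadata).fit_transform(matrix)


def pca_scores(matrix: QuantMatrix, n_components: int = 2) -> pd.DataFrame:
    """Sample scores on the leading principal components (QC view).

    Proteins are centered; samples are projected onto the first
    ``n_components`` right singular vectors.  Sign convention: within each
    component the loading of largest magnitude is made positive, so scores
    are deterministic.
    """
    if not matrix.is_complete():
        raise ValueError("pca_scores requires a complete matrix; impute first")
    X = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = int(n_components)
    loadings = U[:, :k]  # per-protein loadings
    scores = (Vt[:k].T * s[:k])  # samples x components
    for c in range(k):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] = -loadings[:, c]
            scores[:, c] = -scores[:, c]
    return pd.DataFrame(
        scores,
        index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
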