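"""Stratified k-fold cross-validation of cross-cohort concordance.

Samples are partitioned into k folds within each (cohort, group) stratum —
shuffled by seed and dealt round-robin, so fold sizes within a stratum
differ by at most one.  For every fold the per-protein cross-cohort mean
difference d_g is estimated on the training samples (everything outside the
fold) and on the test samples (the fold); a protein is robust when the two
estimates correlate across folds and the test estimates are stable:

    corr_g      = Pearson over the k (d_train, d_test) pairs
    stability_g = 1 - sd_folds(d_test) / (|mean_folds(d_test)| + eps),
                  clamped to [0, 1]
    composite_g = 0.5 * (corr_g + 1) / 2 + 0.5 * stability_g

Proteins are ranked by descending composite, ties broken by protein id.
Degenerate zero-difference proteins: when both the sd and the |mean| of the
test estimates are below eps the protein is perfectly stable at zero
(stability 1); when only the mean vanishes, stability is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .quantio import QuantMatrix, SampleMetadata
from .concordance import cohort_means

__all__ = [
    "FoldPlan",
    "CrossValResult",
    "ConcordanceCrossValidator",
    "make_stratified_folds",
    "crossval_concordance",
    "crossval_report",
]

EPS = 1e-8


@dataclass
class FoldPlan:
    """Assignment of every sample to one of k folds, stratified."""

    k: int
    assignment: dict[str, int]  # sample_id -> fold in [1, k]
    strata: list[tuple[str, str]]
    seed: int

    def fold_samples(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.assignment), "fold": list(self.assignment.values())}
        )


@dataclass
class CrossValResult:
    """Per-protein cross-fold correlation, stability, composite and rank."""

    protein_ids: list[str]
    corr: np.ndarray
    stability: np.ndarray
    composite: np.ndarray
    rank: np.ndarray  # 1 = most robust
    d_train: np.ndarray  # n_proteins x k
    d_test: np.ndarray  # n_proteins x k

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                "corr": self.corr,
                "stability": self.stability,
                "composite": self.composite,
                "rank": self.rank,
            }
        )


def make_stratified_folds(
    metadata: Sequence[SampleMetadata],
    k: int = 4,
    seed: int = 0,
    allow_small_strata: bool = False,
) -> FoldPlan:
    """Deal samples round-robin to k folds within each (cohort, group) stratum.

    Within every stratum the samples are shuffled by ``seed`` first, so the
    plan is deterministic per seed and fold sizes differ by at most 1.  A
    stratum smaller than k is an error unless ``allow_small_strata``.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    strata: dict[tuple[str, str], list[str]] = {}
    for m in metadata:
        strata.setdefault((m.cohort, m.group), []).append(m.sample_id)
    assignment: dict[str, int] = {}
    for key in sorted(strata):
        ids = sorted(strata[key])
        if len(ids) < k and not allow_small_strata:
            raise ValueError(
                f"stratum {key} has {len(ids)} samples, fewer than k={k}"
            )
        order = rng.permutation(len(ids))
        for pos, idx in enumerate(order):
            assignment[ids[idx]] = pos % k + 1
    return FoldPlan(k=k, assignment=assignment, strata=sorted(strata), seed=seed)


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between two n x k matrices."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
    out = np.zeros(x.shape[0])
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return np.clip(out, -1.0, 1.0)


class ConcordanceCrossValidator(BaseEstimator):
    """Cross-validated robustness of per-protein cross-cohort differences.

    Parameters
    ----------
    cohort_a, cohort_b : str
    metadata : sequence of SampleMetadata
    k : int
        Number of folds (default 4; fewer than 3 would make the per-protein
        train/test correlation meaningless, so k < 3 is rejected).
    seed : int
    plan : FoldPlan, optional
        Pre-built fold plan; overrides ``k``/``seed``.
    """

    def __init__(self, cohort_a=None, cohort_b=None, metadata=None, k=4, seed=0, plan=None):
        self.cohort_a = cohort_a
        self.cohort_b = cohort_b
        self.metadata = metadata
        self.k = k
        self.seed = seed
        self.plan = plan

    def fit(self, X: QuantMatrix, y=None):
        plan = self.plan
        if plan is None:
            plan = make_stratified_folds(self.metadata, k=self.k, seed=self.seed)
        if plan.k < 3:
            raise ValueError("k must be at least 3 for a usable fold correlation")
        by_id = {m.sample_id: m for m in self.metadata}
        n, k = X.n_proteins, plan.k
        d_train = np.empty((n, k))
        d_test = np.empty((n, k))
        for f in range(1, k + 1):
            test_ids = [s for s in X.sample_ids if plan.assignment.get(s) == f]
            train_ids = [s for s in X.sample_ids if plan.assignment.get(s) != f]
            for which, ids, target in (
                ("test", test_ids, d_test),
                ("train", train_ids, d_train),
            ):
                sub = X.select_samples(ids)
                for cohort in (self.cohort_a, self.cohort_b):
                    if not any(by_id[s].cohort == cohort for s in ids if s in by_id):
                        raise ValueError(
                            f"fold {f} has no {which} samples from cohort {cohort!r}"
                        )
                mA = cohort_means(sub, self.metadata, self.cohort_a)
                mB = cohort_means(sub, self.metadata, self.cohort_b)
                target[:, f - 1] = mA - mB

        corr = _pearson_rows(d_train, d_test)
        mean_abs = np.abs(d_test.mean(axis=1))
        sd = d_test.std(axis=1, ddof=1)
        stability = np.clip(1.0 - sd / (mean_abs + EPS), 0.0, 1.0)
        # degenerate zero-difference proteins: stable at zero when the spread
        # vanishes too, noise-dominated (0) when only the mean does
        both_zero = (sd < EPS) & (mean_abs < EPS)
        stability[both_zero] = 1.0
        composite = 0.5 * (corr + 1.0) / 2.0 + 0.5 * stability
        order = sorted(
            range(n), key=lambda i: (-composite[i], X.protein_ids[i])
        )
        rank = np.empty(n, dtype=int)
        for pos, i in enumerate(order):
            rank[i] = pos + 1
        self.plan_ = plan
        self.result_ = CrossValResult(
            protein_ids=list(X.protein_ids),
            corr=corr,
            stability=stability,
            composite=composite,
            rank=rank,
            d_train=d_train,
            d_test=d_test,
        )
        return self


def crossval_concordance(
    matrix: QuantMatrix,
    metadata: Sequence[SampleMetadata],
    plan: FoldPlan,
    cohort_a: str,
    cohort_b: str,
) -> CrossValResult:
    est = ConcordanceCrossValidator(cohort_a, cohort_b, metadata, plan=plan)
    return est.fit(matrix).result_


def crossval_report(result: CrossValResult, top_n: int | None = None) -> pd.DataFrame:
    """Top proteins by composite score; ties broken by protein id."""
    df = result.to_frame().sort_values(
        ["rank", "protein_id"], kind="stable", ignore_index=True
    )
    if top_n is not None:
        df = df.head(top_n)
    return df
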