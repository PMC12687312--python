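"""Two-group differential expression with empirical-Bayes variance moderation.

The construction is the classical moderated t-statistic: per-protein pooled
variances s2_g with df_g residual degrees of freedom are shrunk toward a
scaled inverse-chi-square prior (d0, s0^2) fitted across proteins by moments
on log variances,

    s2_post_g = (d0 * s0^2 + df_g * s2_g) / (d0 + df_g)
    t_mod_g   = effect_g / sqrt(s2_post_g * (1/n1 + 1/n2))

with two-sided p-values from a t distribution on df_g + d0 degrees of
freedom (standard normal in the d0 = infinity limit), Benjamini-Hochberg
step-up FDR adjustment, and up/down DEP calls at q < fdr.  Everything here
is implemented from first principles; no external DE package is called.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .quantio import LOG2, QuantMatrix, SampleMetadata

__all__ = [
    "ModeratedTestResult",
    "ModeratedTTest",
    "fit_two_group",
    "estimate_prior",
    "trigamma_inverse",
    "moderated_t",
    "bh_adjust",
    "call_deps",
]


@dataclass
class ModeratedTestResult:
    """Per-protein moderated-t results for one two-group contrast."""

    protein_ids: list[str]
    effect: np.ndarray  # mean log2 difference, group2 - group1
    s2: np.ndarray  # pooled within-group variance
    df: np.ndarray  # residual degrees of freedom, n1 + n2 - 2
    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance
    s2_post: np.ndarray  # shrunken variance
    t_mod: np.ndarray
    p: np.ndarray
    q: np.ndarray
    call: np.ndarray  # "up" / "down" / "none"

    @property
    def n_up(self) -> int:
        return int(np.sum(self.call == "up"))

    @property
    def n_down(self) -> int:
        return int(np.sum(self.call == "down"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                "logFC": self.effect,
                "s2": self.s2,
                "df": self.df,
                "s2_post": self.s2_post,
                "t_mod": self.t_mod,
                "p": self.p,
                "q": self.q,
                "call": self.call,
            }
        )


def fit_two_group(
    matrix: QuantMatrix,
    metadata: Sequence[SampleMetadata],
    group1: str,
    group2: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    """Per-protein effect, pooled variance and df for a two-group contrast.

    Returns ``(effect, s2, df, n1, n2)`` with effect = mean(group2) -
    mean(group1), s2 the pooled within-group variance and df = n1 + n2 - 2.
    """
    if matrix.scale != LOG2:
        raise ValueError("fit_two_group expects a log2 matrix")
    if not matrix.is_complete():
        raise ValueError("fit_two_group expects a complete (imputed) matrix")
    by_id = {m.sample_id: m for m in metadata}
    groups = np.array(
        [by_id[s].group if s in by_id else "" for s in matrix.sample_ids]
    )
    cols1 = np.flatnonzero(groups == group1)
    cols2 = np.flatnonzero(groups == group2)
    for label, cols in ((group1, cols1), (group2, cols2)):
        if cols.size == 0:
            raise ValueError(f"group label {label!r} absent from metadata")
        if cols.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
    n1, n2 = cols1.size, cols2.size
    x1, x2 = matrix.values[:, cols1], matrix.values[:, cols2]
    effect = x2.mean(axis=1) - x1.mean(axis=1)
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = np.full(matrix.n_proteins, n1 + n2 - 2, dtype=float)
    s2 = (ss1 + ss2) / df
    return effect, s2, df, n1, n2


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0.

    Newton iteration on the monotone decreasing trigamma, with a bisection
    fallback when a step leaves the bracket.  For y <= 0 the root is at
    infinity (returned as ``inf``).
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)  # trigamma(x) ~ 1/x^2 near 0
    trigamma = lambda x: float(special.polygamma(1, x))
    # bracket the root: trigamma decreases from inf to 0
    lo, hi = 1e-8, 1.0
    while trigamma(hi) > y:
        hi *= 2.0
    x = 0.5 + 1.0 / y  # limma-style starting value, x ~ 1/y for small y
    x = min(max(x, lo), hi)
    for _ in range(max_iter):
        f = trigamma(x) - y
        if abs(f) < tol * y:
            return x
        if f > 0:
            lo = x
        else:
            hi = x
        deriv = float(special.polygamma(2, x))
        step = x - f / deriv
        x = step if lo < step < hi else 0.5 * (lo + hi)
    return x


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Works on z_g = log(s2_g): under the hierarchical model s2_g is a scaled
    F variate, so z_g has mean log(s0^2) + [digamma(df/2) - log(df/2)] -
    [digamma(d0/2) - log(d0/2)] and excess variance trigamma(d0/2) beyond
    the sampling floor trigamma(df/2).  d0 comes from inverting the trigamma
    equation; zero or negative excess variance yields d0 = inf (complete
    shrinkage to a single variance).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    usable = s2 > 0
    if usable.sum() < 10:
        raise ValueError("need at least 10 proteins with positive variance")
    s2u, dfu = s2[usable], df[usable]
    z = np.log(s2u)
    if np.ptp(z) < 1e-12:  # point mass: complete shrinkage to the common value
        return np.inf, float(np.exp(z.mean()))
    e = z - special.digamma(dfu / 2.0) + np.log(dfu / 2.0)
    e_mean = float(e.mean())
    n = e.size
    excess = float(((e - e_mean) ** 2).sum() / (n - 1)) - float(
        np.mean(special.polygamma(1, dfu / 2.0))
    )
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t(
    effect: np.ndarray,
    s2: np.ndarray,
    df: np.ndarray,
    d0: float,
    s0_sq: float,
    n1: int,
    n2: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shrunken variances, moderated t-statistics and two-sided p-values."""
    effect = np.asarray(effect, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = np.zeros_like(effect)
    nonzero_se = se > 0
    t[nonzero_se] = effect[nonzero_se] / se[nonzero_se]
    df_total = df + d0
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # degenerate variances: zero spread with zero effect is a non-signal,
    # zero spread with a real effect is infinitely significant
    degenerate = ~nonzero_se
    if degenerate.any():
        zero_eff = degenerate & (effect == 0)
        p[zero_eff] = 1.0
        t[zero_eff] = 0.0
        hot = degenerate & (effect != 0)
        if hot.any():
            warnings.warn(
                f"{int(hot.sum())} proteins have zero posterior variance with "
                "nonzero effect; p set to 0",
                UserWarning,
                stacklevel=2,
            )
            p[hot] = 0.0
            t[hot] = np.sign(effect[hot]) * np.inf
    return s2_post, t, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min over j >= i of m * p_(j) / j, clipped to [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_deps(
    effect: np.ndarray, q: np.ndarray, fdr: float = 0.05
) -> tuple[np.ndarray, int, int]:
    """Signed DEP calls at the given FDR: up/down/none plus tallies."""
    call = np.full(len(q), "none", dtype=object)
    sig = np.asarray(q) < fdr
    call[sig & (np.asarray(effect) > 0)] = "up"
    call[sig & (np.asarray(effect) < 0)] = "down"
    n_up = int(np.sum(call == "up"))
    n_down = int(np.sum(call == "down"))
    return call.astype(str), n_up, n_down


class ModeratedTTest(BaseEstimator):
    """Moderated two-group t-test estimator.

    Parameters
    ----------
    group1, group2 : str
        Biological group labels; the reported effect is group2 - group1 in
        log2 units.
    metadata : sequence of SampleMetadata
    fdr : float
        BH-FDR threshold for DEP calls (default 0.05).
    moderate : bool
        When False, skip variance shrinkage and report plain pooled-t
        statistics (d0 = 0); BH adjustment is still applied.

    Attributes (after ``fit``)
    --------------------------
    result_ : ModeratedTestResult
    d0_, s0_sq_ : fitted prior parameters
    n_up_, n_down_ : DEP tallies at ``fdr``
    """

    def __init__(self, group1=None, group2=None, metadata=None, fdr=0.05, moderate=True):
        self.group1 = group1
        self.group2 = group2
        self.metadata = metadata
        self.fdr = fdr
        self.moderate = moderate

    def fit(self, X: QuantMatrix, y=None):
        effect, s2, df, n1, n2 = fit_two_group(
            X, self.metadata, self.group1, self.group2
        )
        if self.moderate:
            d0, s0_sq = estimate_prior(s2, df)
        else:
            d0, s0_sq = 0.0, float(np.median(s2))
        s2_post, t, p = moderated_t(effect, s2, df, d0, s0_sq, n1, n2)
        q = bh_adjust(p)
        call, n_up, n_down = call_deps(effect, q, self.fdr)
        self.result_ = ModeratedTestResult(
            protein_ids=list(X.protein_ids),
            effect=effect,
            s2=s2,
            df=df,
            d0=d0,
            s0_sq=s0_sq,
            s2_post=s2_post,
            t_mod=t,
            p=p,
            q=q,
            call=call,
        )
        self.d0_, self.s0_sq_ = d0, s0_sq
        self.n_up_, self.n_down_ = n_up, n_down
        return self
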