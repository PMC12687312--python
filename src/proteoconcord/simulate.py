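"""Two-cohort, two-group synthetic DIA proteomics data with known ground truth.

The generator emulates the study design the pipeline targets: two study
centers of unequal size profiling the same tissue groups, a few thousand
proteins with log-normal abundance, a configurable fraction of
differentially expressed proteins (DEPs) with symmetric +/- log2 effects,
a scalar cohort-level batch shift, and missingness that mixes a
missing-completely-at-random (MCAR) component with an abundance-dependent
(MNAR, left-censoring) component logistic in log2 abundance.

On the log2 scale a cell is

    baseline_g + group_effect_g(group_j) + batch_shift * [cohort_j is the
    batch cohort] + eps,   eps ~ Normal(0, residual_sd)

with baseline_g ~ Normal(baseline_log2_mean, baseline_log2_sd) per protein;
the matrix is returned on the raw scale (2**log2) with a full mask so the
pipeline's own log2 step is exercised.  All randomness flows from the single
``seed`` in :class:`SimConfig`: cohort simulation and missingness injection
each draw from a fixed, documented sub-stream of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .quantio import QuantMatrix, SampleMetadata, RAW

__all__ = ["SimConfig", "GroundTruth", "simulate_cohorts", "inject_missingness"]


@dataclass
class SimConfig:
    """Configuration of the two-cohort simulation.

    ``n_samples_per_group_per_cohort`` maps ``(cohort, group)`` to a sample
    count, e.g. ``{("USP", "ACC"): 8, ("SNUH", "ACC"): 58}``.  The group
    named by ``affected_group`` carries the DEP effects; the cohort named by
    ``batch_cohort`` (default: the second declared cohort) receives the
    scalar ``batch_shift_log2``.
    """

    n_proteins: int = 3024
    n_samples_per_group_per_cohort: dict[tuple[str, str], int] = field(
        default_factory=lambda: {("USP", "ACC"): 8, ("SNUH", "ACC"): 58}
    )
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    residual_sd: float = 0.5
    dep_fraction: float = 0.0
    dep_effect_log2: float = 1.0
    affected_group: str = "ACC"
    batch_shift_log2: float = 0.0
    batch_cohort: str | None = None
    mnar_steepness: float = 0.0
    mnar_midpoint_log2: float = -np.inf
    mcar_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if not self.n_samples_per_group_per_cohort:
            raise ValueError("declare at least one (cohort, group) stratum")
        for key, n in self.n_samples_per_group_per_cohort.items():
            if n <= 0:
                raise ValueError(f"stratum {key} must have at least one sample")
        for name in ("dep_fraction", "mcar_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.baseline_log2_sd <= 0 or self.residual_sd < 0:
            raise ValueError("baseline_log2_sd must be > 0 and residual_sd >= 0")
        if self.dep_effect_log2 < 0:
            raise ValueError("dep_effect_log2 must be non-negative")
        if self.mnar_steepness < 0:
            raise ValueError("mnar_steepness must be non-negative")

    @property
    def cohorts(self) -> list[str]:
        seen: list[str] = []
        for cohort, _ in self.n_samples_per_group_per_cohort:
            if cohort not in seen:
                seen.append(cohort)
        return seen

    def resolved_batch_cohort(self) -> str | None:
        if self.batch_cohort is not None:
            return self.batch_cohort
        cohorts = self.cohorts
        return cohorts[1] if len(cohorts) > 1 else None


@dataclass
class GroundTruth:
    """Which proteins are true DEPs and what was injected."""

    dep_index: np.ndarray  # sorted row indices of the true DEPs
    dep_sign: np.ndarray  # +1/-1 per DEP, aligned with dep_index
    true_effect_log2: np.ndarray  # per protein; 0 off the DEP set
    batch_shift_log2: float


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # one seed, fixed sub-streams: 0 = cohort simulation, 1 = missingness
    return np.random.default_rng([int(config.seed), stream])


def simulate_cohorts(
    config: SimConfig,
) -> tuple[QuantMatrix, list[SampleMetadata], GroundTruth]:
    """Draw a fully observed raw-scale matrix plus metadata and ground truth.

    Draw order (fixed so outputs are bit-reproducible per seed): protein
    baselines, DEP row choice, DEP signs, then the residual matrix.
    """
    rng = _rng(config, 0)
    n = config.n_proteins
    baselines = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)

    n_dep = int(round(config.dep_fraction * n))
    dep_index = np.sort(rng.choice(n, size=n_dep, replace=False))
    dep_sign = rng.choice([-1.0, 1.0], size=n_dep)
    true_effect = np.zeros(n)
    true_effect[dep_index] = dep_sign * config.dep_effect_log2

    samples: list[SampleMetadata] = []
    columns: list[tuple[str, str]] = []
    counters: dict[str, int] = {}
    for (cohort, group), count in config.n_samples_per_group_per_cohort.items():
        for _ in range(count):
            counters[cohort] = counters.get(cohort, 0) + 1
            sid = f"{cohort}_{group}_{counters[cohort]:02d}"
            samples.append(SampleMetadata(sample_id=sid, cohort=cohort, group=group))
            columns.append((cohort, group))

    batch_cohort = config.resolved_batch_cohort()
    m = len(columns)
    log2 = np.tile(baselines[:, None], (1, m))
    for j, (cohort, group) in enumerate(columns):
        if group == config.affected_group:
            log2[:, j] += true_effect
        if batch_cohort is not None and cohort == batch_cohort:
            log2[:, j] += config.batch_shift_log2
    log2 += rng.normal(0.0, config.residual_sd, size=(n, m))

    matrix = QuantMatrix(
        protein_ids=[f"P{i:05d}" for i in range(n)],
        sample_ids=[s.sample_id for s in samples],
        values=np.exp2(log2),
        mask=np.ones((n, m), dtype=bool),
        scale=RAW,
    )
    truth = GroundTruth(
        dep_index=dep_index,
        dep_sign=dep_sign,
        true_effect_log2=true_effect,
        batch_shift_log2=config.batch_shift_log2,
    )
    return matrix, samples, truth


def missingness_probability(log2_values: np.ndarray, config: SimConfig) -> np.ndarray:
    """Per-cell missingness probability.

    ``mcar_rate + (1 - mcar_rate) * logistic(-steepness * (x - midpoint))``
    with x the cell's log2 abundance.  With ``midpoint = -inf`` (the default)
    the logistic term vanishes and missingness is pure MCAR; steepness 0
    with a finite midpoint puts the logistic term at 1/2 everywhere.
    """
    with np.errstate(invalid="ignore"):
        arg = -config.mnar_steepness * (log2_values - config.mnar_midpoint_log2)
    # steepness 0 with midpoint -inf yields 0 * inf; resolve to the logistic limit
    arg = np.where(np.isnan(arg), -np.inf, arg)
    return config.mcar_rate + (1.0 - config.mcar_rate) * expit(arg)


def inject_missingness(matrix: QuantMatrix, config: SimConfig) -> QuantMatrix:
    """Mask cells of a fully observed raw-scale matrix; values untouched."""
    if matrix.scale != RAW:
        raise ValueError("inject_missingness expects a raw-scale matrix")
    if not matrix.is_complete():
        raise ValueError("matrix already has missing cells")
    rng = _rng(config, 1)
    p = missingness_probability(np.log2(matrix.values), config)
    drop = rng.random(size=matrix.shape) < p
    out = matrix.copy()
    out.mask = ~drop
    out.values[drop] = np.nan
    return out
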