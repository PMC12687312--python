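"""End-to-end pipeline orchestration.

`run_pipeline` wires the stages in the canonical order —

    simulate (optional) -> filter -> log2 -> quantile normalize ->
    pca impute -> cohort centering (optional) -> differential expression
    (each contrast) -> concordance (GSI) -> cross-validation

— writing each stage's TSV/JSON outputs plus a run log and a summary JSON
into one output directory.  A single global seed fans out to per-stage
seeds by fixed offsets (simulation seed, imputation seed + 1, CV seed + 2),
so a config + seed pair reproduces every artifact byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import concordance, crossval, diffexpr, preprocess, quantio, simulate

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to a single YAML/JSON file."""

    output_dir: str = "pipeline_out"
    quant_table: str | None = None  # omit to simulate instead
    metadata_table: str | None = None
    dialect: str = "generic_tsv"
    simulate: dict[str, Any] = field(default_factory=dict)  # SimConfig overrides
    filter_mode: str = "each_cohort"
    min_fraction: float | None = None
    n_components: int = 2
    batch_center: bool = True
    contrasts: list[list[str]] = field(default_factory=list)  # [group1, group2]
    fdr: float = 0.05
    cohort_a: str | None = None
    cohort_b: str | None = None
    gsi_weights: dict[str, float] = field(default_factory=dict)
    cv_k: int = 4
    top_n: int = 50
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return PipelineConfig(**data)


def _sim_config(cfg: PipelineConfig) -> simulate.SimConfig:
    kwargs = dict(cfg.simulate)
    if "n_samples_per_group_per_cohort" in kwargs:
        kwargs["n_samples_per_group_per_cohort"] = {
            tuple(k.split("/")): v
            for k, v in kwargs["n_samples_per_group_per_cohort"].items()
        }
    kwargs.setdefault("seed", cfg.seed)
    return simulate.SimConfig(**kwargs)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage; return the summary dict (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, message: str) -> None:
        log_lines.append(f"[{stage}] {message}")

    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    # --- input: load or simulate ------------------------------------------
    if config.quant_table is not None:
        matrix = quantio.read_quant_table(config.quant_table, dialect=config.dialect)
        metadata = quantio.read_metadata(config.metadata_table)
        log("input", f"loaded {matrix.n_proteins} proteins x {matrix.n_samples} samples")
    else:
        sim_cfg = _sim_config(config)
        matrix, metadata, truth = simulate.simulate_cohorts(sim_cfg)
        if sim_cfg.mcar_rate > 0 or sim_cfg.mnar_steepness > 0:
            matrix = simulate.inject_missingness(matrix, sim_cfg)
        quantio.write_quant_table(matrix, out / "simulated_quant.tsv")
        quantio.write_metadata(metadata, out / "simulated_metadata.tsv")
        _write_truth(truth, matrix, out / "simulated_truth.tsv")
        log(
            "simulate",
            f"{matrix.n_proteins} proteins x {matrix.n_samples} samples, "
            f"{int((~matrix.mask).sum())} missing cells",
        )

    cohorts = sorted({m.cohort for m in metadata})
    cohort_a = config.cohort_a or cohorts[0]
    cohort_b = config.cohort_b or (cohorts[1] if len(cohorts) > 1 else cohorts[0])

    # --- preprocessing -----------------------------------------------------
    rule = preprocess.FilterRule(config.filter_mode, config.min_fraction)
    filtered = preprocess.filter_by_valid_fraction(matrix, metadata, rule)
    log("filter", f"{matrix.n_proteins} -> {filtered.n_proteins} proteins "
        f"({rule.mode} @ {rule.min_fraction})")
    logged = preprocess.log2_transform(filtered)
    normed = preprocess.quantile_normalize(logged)
    imputer = preprocess.PCAImputer(
        n_components=config.n_components, seed=config.seed + 1
    )
    imputed = imputer.fit_transform(normed)
    log(
        "impute",
        f"{int(imputed.imputed.sum())} cells imputed in {imputer.n_iter_} "
        f"iterations (delta {imputer.delta_:.2e})",
    )
    if config.batch_center and len(cohorts) > 1:
        final = preprocess.center_cohorts(imputed, metadata)
        log("center", f"cohort centering applied over {len(cohorts)} cohorts")
    else:
        final = imputed
        log("center", "cohort centering skipped")
    quantio.write_quant_table(final, out / "preprocessed.tsv")

    summary: dict[str, Any] = {
        "n_proteins_input": matrix.n_proteins,
        "n_proteins_kept": filtered.n_proteins,
        "n_samples": matrix.n_samples,
        "cohorts": cohorts,
        "seed": config.seed,
    }

    # --- differential expression ------------------------------------------
    summary["contrasts"] = {}
    for group1, group2 in config.contrasts:
        est = diffexpr.ModeratedTTest(group1, group2, metadata, fdr=config.fdr)
        est.fit(final)
        name = f"{group2}_vs_{group1}"
        est.result_.to_frame().to_csv(out / f"dea_{name}.tsv", sep="\t", index=False)
        summary["contrasts"][name] = {
            "n_up": est.n_up_,
            "n_down": est.n_down_,
            "d0": est.d0_,
            "s0_sq": est.s0_sq_,
        }
        log("dea", f"{name}: {est.n_up_} up, {est.n_down_} down at FDR {config.fdr}")

    # --- concordance -------------------------------------------------------
    if len(cohorts) > 1:
        weights = concordance.GsiWeights(**config.gsi_weights)
        conc = concordance.compute_gsi(final, metadata, cohort_a, cohort_b, weights)
        conc.to_frame().to_csv(out / "concordance.tsv", sep="\t", index=False)
        summary["concordance"] = {
            "pearson": conc.pearson,
            "icc": conc.icc,
            "mean_d": conc.bland_altman.mean_d,
            "loa": [conc.bland_altman.loa_low, conc.bland_altman.loa_high],
            "global_gsi": conc.global_gsi,
            "global_similarity_pct": conc.global_similarity_pct,
            "categories": conc.category_counts(),
        }
        log("concord", f"global GSI {conc.global_gsi:.4f}, "
            f"mean similarity {conc.global_similarity_pct:.2f}%")

        # --- cross-validation ---------------------------------------------
        plan = crossval.make_stratified_folds(
            metadata, k=config.cv_k, seed=config.seed + 2
        )
        plan.to_frame().to_csv(out / "folds.tsv", sep="\t", index=False)
        cv = crossval.crossval_concordance(final, metadata, plan, cohort_a, cohort_b)
        crossval.crossval_report(cv, config.top_n).to_csv(
            out / "crossval.tsv", sep="\t", index=False
        )
        summary["crossval"] = {
            "k": plan.k,
            "median_composite": float(np.median(cv.composite)),
            "top_protein": cv.protein_ids[int(np.argmin(cv.rank))],
        }
        log("cv", f"k={plan.k}, median composite {np.median(cv.composite):.4f}")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _write_truth(truth: simulate.GroundTruth, matrix, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein_id\ttrue_effect_log2\tis_dep\n")
        dep = set(truth.dep_index.tolist())
        for i, pid in enumerate(matrix.protein_ids):
            fh.write(f"{pid}\t{truth.true_effect_log2[i]!r}\t{int(i in dep)}\n")
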