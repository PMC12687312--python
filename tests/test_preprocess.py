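"""Preprocessing stages against brute-force oracles and contracts."""

import subprocess
import textwrap

import numpy as np
import pytest

from proteoconcord.preprocess import (
    FilterRule,
    PCAImputer,
    QuantileNormalizer,
    center_cohorts,
    filter_by_valid_fraction,
    log2_transform,
    pca_impute,
    pca_scores,
    quantile_normalize,
)
from proteoconcord.quantio import LOG2
from proteoconcord.simulate import SimConfig, simulate_cohorts

from conftest import make_matrix, make_metadata


# ---------------------------------------------------------------------------
# valid-fraction filter


def brute_force_filter(mask, labels, mode, min_fraction):
    """Independent per-protein fraction oracle."""
    keep = []
    uniq = sorted(set(labels))
    for row in mask:
        fracs = [
            np.mean([row[j] for j in range(len(labels)) if labels[j] == lab])
            for lab in uniq
        ]
        if mode == "any_group":
            keep.append(any(f >= min_fraction for f in fracs))
        else:
            keep.append(all(f >= min_fraction for f in fracs))
    return keep


def test_each_cohort_boundary_fractions_kept():
    """3/8 of cohort A (0.375) and 21/58 of cohort B (0.362) pass 35%."""
    mask = np.zeros((1, 66), dtype=bool)
    mask[0, :3] = True  # 3 of 8 in A
    mask[0, 8 : 8 + 21] = True  # 21 of 58 in B
    values = np.where(mask, 100.0, np.nan)
    m = make_matrix(values, mask=mask)
    md = make_metadata(["A"] * 8 + ["B"] * 58)
    rule = FilterRule("each_cohort", 0.35)
    assert filter_by_valid_fraction(m, md, rule).n_proteins == 1


def test_fully_missing_protein_dropped_everywhere():
    values = [[100.0, 200.0], [None, None]]
    m = make_matrix(values)
    md = make_metadata(["A", "B"], ["g1", "g2"])
    for rule in (FilterRule("any_group", 0.6), FilterRule("each_cohort", 0.35)):
        out = filter_by_valid_fraction(m, md, rule)
        assert out.protein_ids == ["P0"]


def test_any_group_kept_when_complete_in_one_group():
    mask = np.array([[True, True, False, False]])
    m = make_matrix(np.where(mask, 10.0, np.nan), mask=mask)
    md = make_metadata(["A"] * 4, ["g1", "g1", "g2", "g2"])
    out = filter_by_valid_fraction(m, md, FilterRule("any_group", 0.60))
    assert out.n_proteins == 1


@pytest.mark.parametrize("mode,frac", [("any_group", 0.6), ("each_cohort", 0.35)])
def test_filter_matches_brute_force_oracle(rng, mode, frac):
    mask = rng.random((60, 12)) > 0.4
    values = np.where(mask, 50.0, np.nan)
    labels = ["A"] * 5 + ["B"] * 7
    m = make_matrix(values, mask=mask)
    md = make_metadata(labels, labels)  # group == cohort label
    out = filter_by_valid_fraction(m, md, FilterRule(mode, frac))
    expected = brute_force_filter(mask, labels, mode, frac)
    assert out.protein_ids == [f"P{i}" for i, k in enumerate(expected) if k]


def test_filter_default_thresholds():
    assert FilterRule("any_group").min_fraction == 0.60
    assert FilterRule("each_cohort").min_fraction == 0.35
    with pytest.raises(ValueError, match="mode"):
        FilterRule("per_sample")


# ---------------------------------------------------------------------------
# log2


def test_log2_closed_form_and_inverse(rng):
    m = make_matrix([[8.0, 1.0]])
    out = log2_transform(m)
    assert out.values[0, 0] == 3.0 and out.values[0, 1] == 0.0
    assert out.scale == LOG2

    vals = rng.lognormal(10, 1, size=(30, 5))
    mask = rng.random((30, 5)) > 0.3
    m2 = make_matrix(np.where(mask, vals, np.nan), mask=mask)
    back = np.exp2(log2_transform(m2).values)
    np.testing.assert_allclose(back[mask], m2.values[mask], rtol=1e-12)


def test_log2_refuses_double_transform():
    m = make_matrix([[8.0, 2.0]])
    out = log2_transform(m)
    with pytest.raises(ValueError, match="already"):
        log2_transform(out)


# ---------------------------------------------------------------------------
# quantile normalization


def brute_force_quantile_normalize(values):
    """Rank-then-average oracle for complete matrices, ties averaged."""
    values = np.asarray(values, dtype=float)
    sorted_cols = np.sort(values, axis=0)
    ref = sorted_cols.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty_like(col)
        mapped[order] = ref
        for v in np.unique(col):
            tied = col == v
            if tied.sum() > 1:
                mapped[tied] = mapped[tied].mean()
        out[:, j] = mapped
    return out


FIXTURE_4x3 = [[5.0, 4.0, 3.0], [2.0, 1.0, 4.0], [3.0, 4.0, 6.0], [4.0, 2.0, 8.0]]


def test_quantile_normalize_matches_oracle_on_fixture():
    m = make_matrix(FIXTURE_4x3, scale=LOG2)
    out = quantile_normalize(m)
    expected = brute_force_quantile_normalize(FIXTURE_4x3)
    np.testing.assert_allclose(out.values, expected, atol=1e-12)
    ref = np.sort(np.array(FIXTURE_4x3), axis=0).mean(axis=1)
    # tie-free columns acquire the mean-quantile vector exactly; the tied
    # column (index 1) averages its spanned quantiles, preserving the sum
    for j in (0, 2):
        np.testing.assert_allclose(np.sort(out.values[:, j]), ref, atol=1e-12)
    assert out.values[:, 1].sum() == pytest.approx(ref.sum(), abs=1e-12)


@pytest.mark.parametrize("with_missing", [False, True])
def test_quantile_normalize_matches_limma_reference(tmp_path, rng, with_missing):
    """Independent oracle: the reference R quantile-normalization routine.

    Covers both complete matrices (including a tied column) and matrices
    with missing cells, where observed values interpolate the mean quantile
    curve at fractional rank positions.
    """
    import pandas as pd

    values = rng.normal(20, 2, size=(30, 5))
    if with_missing:
        mask = rng.random((30, 5)) > 0.2
        values = np.where(mask, values, np.nan)
    else:
        # inject a within-column tie; on complete columns the tie-averaging
        # convention coincides with the reference implementation's
        values[5, 0] = values[9, 0]
    m = make_matrix(values, scale=LOG2)
    out = quantile_normalize(m)

    inp = tmp_path / "in.tsv"
    np.savetxt(inp, values, delimiter="\t")
    script = textwrap.dedent(f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.table("{inp}", sep="\\t"))
        write.table(normalizeQuantiles(x), "{tmp_path / 'out.tsv'}",
                    sep="\\t", row.names=FALSE, col.names=FALSE)
    """)
    proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert proc.returncode == 0, proc.stderr
    expected = pd.read_csv(
        tmp_path / "out.tsv", sep="\t", header=None, na_values="NA"
    ).to_numpy()
    obs = ~np.isnan(values)
    np.testing.assert_allclose(out.values[obs], expected[obs], atol=1e-10)


def test_quantile_normalize_identical_columns_fixed_point():
    col = np.array([[3.0], [1.0], [2.0], [5.0]])
    m = make_matrix(np.tile(col, (1, 4)), scale=LOG2)
    out = quantile_normalize(m)
    np.testing.assert_allclose(out.values, m.values, atol=1e-12)


def test_quantile_normalize_idempotent_on_complete(rng):
    m = make_matrix(rng.normal(20, 2, size=(40, 6)), scale=LOG2)
    once = quantile_normalize(m)
    twice = quantile_normalize(once)
    np.testing.assert_allclose(twice.values, once.values, atol=1e-9)


def test_quantile_normalize_missing_interpolation_oracle():
    """Columns with missing cells interpolate the reference at fractional ranks."""
    values = [[5.0, 4.0, 3.0], [2.0, None, 4.0], [3.0, 4.0, 6.0], [4.0, 2.0, 8.0]]
    m = make_matrix(values, scale=LOG2)
    out = quantile_normalize(m)

    # explicit oracle: mean quantile curve over per-column interpolated curves
    grid = np.linspace(0, 1, 4)
    curves = []
    for j, col in enumerate(np.array(
        [[5, 2, 3, 4], [4, np.nan, 4, 2], [3, 4, 6, 8]], dtype=float
    )):
        obs = np.sort(col[~np.isnan(col)])
        curves.append(np.interp(grid, np.linspace(0, 1, obs.size), obs))
    ref = np.mean(curves, axis=0)

    # column 1 has observed values (4, 4, 2) at ranks -> positions 0, .5, 1;
    # the two tied 4s share the mean of the top two reference quantiles
    expected_low = np.interp(0.0, grid, ref)
    expected_tied = (np.interp(0.5, grid, ref) + np.interp(1.0, grid, ref)) / 2
    assert out.values[3, 1] == pytest.approx(expected_low, abs=1e-12)
    assert out.values[0, 1] == pytest.approx(expected_tied, abs=1e-12)
    assert out.values[2, 1] == pytest.approx(expected_tied, abs=1e-12)
    assert np.isnan(out.values[1, 1]) and not out.mask[1, 1]


def test_quantile_normalize_rejects_raw_and_tiny_columns():
    with pytest.raises(ValueError, match="log2"):
        quantile_normalize(make_matrix([[1.0, 2.0], [3.0, 4.0]]))
    m = make_matrix([[1.0, None], [2.0, 3.0], [3.0, None]], scale=LOG2)
    with pytest.raises(ValueError, match="fewer than 2"):
        quantile_normalize(m)


# ---------------------------------------------------------------------------
# PCA imputation


def test_impute_fixed_point_on_complete(rng):
    m = make_matrix(rng.normal(20, 1, size=(10, 5)), scale=LOG2)
    out = pca_impute(m, n_components=2)
    np.testing.assert_array_equal(out.values, m.values)
    assert out.imputed.sum() == 0


def test_impute_recovers_rank1_cell():
    """Closed form: a deleted cell of a rank-1 outer product is recoverable."""
    u = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    v = np.array([2.0, 3.0, 4.0, 5.0])
    full = np.outer(u, v) + 10.0  # keep values well away from 0
    values = full.copy()
    values[2, 1] = np.nan
    m = make_matrix(values, scale=LOG2)
    out = pca_impute(m, n_components=1, tol=1e-9)
    assert out.values[2, 1] == pytest.approx(full[2, 1], abs=1e-6)


def test_impute_preserves_observed_cells_bitwise(rng):
    vals = rng.normal(20, 1, size=(30, 8))
    mask = rng.random((30, 8)) > 0.2
    m = make_matrix(np.where(mask, vals, np.nan), mask=mask, scale=LOG2)
    out = pca_impute(m, n_components=2)
    assert np.array_equal(out.values[mask], m.values[mask])
    assert out.mask.all()
    assert np.array_equal(out.imputed, ~mask)


def test_impute_rejects_empty_rows_and_bad_rank(rng):
    m = make_matrix([[1.0, None], [None, None]], scale=LOG2)
    with pytest.raises(ValueError, match="protein"):
        pca_impute(m, n_components=1)
    full = make_matrix(rng.normal(20, 1, (4, 3)), scale=LOG2)
    with pytest.raises(ValueError, match="n_components"):
        pca_impute(full, n_components=3)


def test_impute_nonconvergence_warns():
    vals = np.random.default_rng(0).normal(20, 1, size=(20, 6))
    vals[3, 2] = np.nan
    m = make_matrix(vals, scale=LOG2)
    imputer = PCAImputer(n_components=2, max_iter=1, tol=1e-15)
    with pytest.warns(UserWarning, match="converge"):
        imputer.fit_transform(m)


# ---------------------------------------------------------------------------
# cohort centering


def test_centering_fixed_point_when_means_match():
    values = np.array([[1.0, 3.0, 2.0, 2.0], [5.0, 3.0, 4.0, 4.0]])
    m = make_matrix(values, scale=LOG2)
    md = make_metadata(["A", "A", "B", "B"])
    out = center_cohorts(m, md)  # both cohorts share grand mean 3
    np.testing.assert_allclose(out.values, values, atol=1e-12)


def test_centering_removes_constant_cohort_offset(rng):
    base = rng.normal(20, 1, size=(15, 4))
    values = np.column_stack([base, base + 2.5])
    m = make_matrix(values, scale=LOG2)
    md = make_metadata(["A"] * 4 + ["B"] * 4)
    out = center_cohorts(m, md)
    d = out.values[:, 4:].mean(axis=1) - out.values[:, :4].mean(axis=1)
    np.testing.assert_allclose(d, 0.0, atol=1e-9)


def test_centering_reduces_simulated_batch_shift():
    cfg = SimConfig(
        n_proteins=400,
        n_samples_per_group_per_cohort={("USP", "ACC"): 8, ("SNUH", "ACC"): 58},
        batch_shift_log2=1.5,
        residual_sd=0.5,
        seed=21,
    )
    matrix, metadata, _ = simulate_cohorts(cfg)
    m = center_cohorts(log2_transform(matrix), metadata)
    usp = [j for j, s in enumerate(metadata) if s.cohort == "USP"]
    snuh = [j for j, s in enumerate(metadata) if s.cohort == "SNUH"]
    residual = abs(m.values[:, snuh].mean() - m.values[:, usp].mean())
    assert residual < 0.05


# ---------------------------------------------------------------------------
# PCA scores


def test_pca_scores_duplicate_samples_identical(rng):
    vals = rng.normal(20, 1, size=(12, 5))
    vals[:, 4] = vals[:, 0]
    m = make_matrix(vals, scale=LOG2)
    scores = pca_scores(m, 2)
    np.testing.assert_allclose(scores.iloc[0], scores.iloc[4], atol=1e-9)


def test_pca_scores_match_eigendecomposition_oracle(rng):
    vals = rng.normal(0, 1, size=(10, 6))
    m = make_matrix(vals + 30, scale=LOG2)
    scores = pca_scores(m, 3).to_numpy()

    X = (m.values - m.values.mean(axis=1, keepdims=True)).T  # samples x proteins
    cov = X.T @ X
    w, V = np.linalg.eigh(cov)
    idx = np.argsort(w)[::-1][:3]
    expected = X @ V[:, idx]
    for c in range(3):
        got, exp = scores[:, c], expected[:, c]
        assert np.allclose(got, exp, atol=1e-8) or np.allclose(got, -exp, atol=1e-8)


def test_pca_scores_variance_bounded(rng):
    m = make_matrix(rng.normal(20, 1, size=(15, 8)), scale=LOG2)
    scores = pca_scores(m, 3).to_numpy()
    total = ((m.values - m.values.mean(axis=1, keepdims=True)) ** 2).sum()
    assert (scores**2).sum() <= total + 1e-9


def test_pca_scores_requires_complete():
    m = make_matrix([[1.0, None], [2.0, 3.0]], scale=LOG2)
    with pytest.raises(ValueError, match="impute"):
        pca_scores(m)
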