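import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from atacage import AgingPopulationSpec, simulate_expression_matrix
from atacage.expression import (
    cluster_genes,
    fit_expression_slopes,
    grs_comparison,
    moving_average,
    telomere_distance_profile,
)

SPECS = [
    AgingPopulationSpec(strain=s, replicate=r, ave_budscars=a)
    for r in ["r1", "r2"]
    for s in ["WT", "sir2"]
    for a in [0.0, 12.0, 25.0]
]


def _design(specs):
    return pd.DataFrame(
        [(f"x{i}", s.strain, s.replicate, s.ave_budscars) for i, s in enumerate(specs)],
        columns=["sample", "strain", "replicate", "ave_budscars"],
    )


def test_constant_gene_has_zero_slope():
    em = simulate_expression_matrix(["g1", "g2"], SPECS, {}, noise_sd=0.0, seed=0)
    res = fit_expression_slopes(em.tpm, em.design)
    assert np.allclose(res["beta"], 0.0, atol=1e-10)


def test_batch_offsets_do_not_bias_slopes():
    # +/- 1 log2-unit batch offsets, zero noise: replicate covariate absorbs them
    em = simulate_expression_matrix(
        [f"g{i}" for i in range(40)], SPECS, {}, noise_sd=0.0, batch_sd=1.0, seed=1
    )
    res = fit_expression_slopes(em.tpm, em.design)
    assert res["beta"].abs().max() < 0.005


def test_ols_matches_statsmodels_single_gene():
    em = simulate_expression_matrix(
        [f"g{i}" for i in range(5)], SPECS, {"g0": 0.08}, noise_sd=0.2, seed=2
    )
    res = fit_expression_slopes(em.tpm, em.design, pseudocount=0.5)
    y = np.log2(em.tpm.loc["g0"].to_numpy() + 0.5)
    X = pd.get_dummies(
        em.design[["replicate", "strain"]], drop_first=True, dtype=float
    )
    X["ave_budscars"] = em.design["ave_budscars"].to_numpy()
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    assert res.loc["g0", "beta"] == pytest.approx(fit.params["ave_budscars"], rel=1e-9)
    assert res.loc["g0", "se"] == pytest.approx(fit.bse["ave_budscars"], rel=1e-9)
    assert res.loc["g0", "p"] == pytest.approx(fit.pvalues["ave_budscars"], rel=1e-9)


def test_interaction_model_recovers_strain_scaled_slopes():
    true = {f"g{i}": 0.06 for i in range(8)}
    em = simulate_expression_matrix(
        [f"g{i}" for i in range(300)], SPECS, true,
        strain_slope_factor={"WT": 1.0, "sir2": 1.5}, noise_sd=0.15, seed=3,
    )
    res = fit_expression_slopes(em.tpm, em.design, model="interaction")
    sig = res.loc[list(true)]
    assert sig["beta_WT"].mean() == pytest.approx(0.06, abs=0.015)
    assert sig["beta_sir2"].mean() == pytest.approx(0.09, abs=0.015)


# -- clustering --------------------------------------------------------------


def _brute_average_linkage(X):
    """Exhaustive average-linkage agglomeration under cosine distance."""
    from scipy.spatial.distance import cosine

    n = len(X)
    base = [[cosine(X[i], X[j]) for j in range(n)] for i in range(n)]
    active = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(active) > 1:
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if a >= b:
                    continue
                d = np.mean([base[i][j] for i in active[a] for j in active[b]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d, len(active[a]) + len(active[b])))
        active[next_id] = active.pop(a) + active.pop(b)
        next_id += 1
    return merges


def test_duplicate_rows_merge_first_at_zero():
    m = pd.DataFrame([[1, 2, 3], [4, 0, 1], [1, 2, 3]], index=["a", "b", "a2"])
    out = cluster_genes(m)
    first = out["linkage"][0]
    assert {int(first[0]), int(first[1])} == {0, 2}
    assert first[2] == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("n_rows,seed", [(4, 0), (5, 1), (6, 2)])
def test_average_linkage_matches_bruteforce(n_rows, seed):
    rng = np.random.default_rng(seed)
    m = pd.DataFrame(rng.uniform(0.1, 5.0, size=(n_rows, 6)))
    Z = cluster_genes(m)["linkage"]
    brute = _brute_average_linkage(m.to_numpy())
    for row, (_, _, d, size) in zip(Z, brute):
        assert row[2] == pytest.approx(d, rel=1e-9)
        assert int(row[3]) == size


def test_zero_norm_rows_excluded_with_warning():
    m = pd.DataFrame([[1, 2], [0, 0], [2, 4]], index=["a", "zero", "b"])
    with pytest.warns(UserWarning):
        out = cluster_genes(m)
    assert out["excluded"] == ["zero"]
    assert set(out["kept"]) == {"a", "b"}


# -- moving average ----------------------------------------------------------


def test_moving_average_hand_cases():
    assert np.allclose(moving_average([7.0] * 10, 3), 7.0)
    assert np.allclose(moving_average([1, 2, 3, 4, 5], 3), [1.5, 2, 3, 4, 4.5])
    # window longer than the vector collapses to the global mean
    assert np.allclose(moving_average([1, 2, 3], 100), 2.0)
    # missing values excluded per window
    out = moving_average([1.0, np.nan, 3.0], 3)
    assert out[1] == pytest.approx(2.0)


# -- GRS comparison ----------------------------------------------------------


def _slopes_frame(beta, q=None, index=None):
    index = index if index is not None else [f"g{i}" for i in range(len(beta))]
    return pd.DataFrame(
        {"beta": beta, "q": q if q is not None else np.full(len(beta), 0.01)}, index=index
    )


def test_grs_perfect_anticorrelation():
    rng = np.random.default_rng(0)
    beta = rng.normal(0, 1, 100)
    slopes = _slopes_frame(beta)
    grs = pd.Series(-beta, index=slopes.index)
    out = grs_comparison(slopes, grs)
    assert out["r_all"] == pytest.approx(-1.0)


def test_grs_recovers_population_correlation():
    rng = np.random.default_rng(1)
    n = 2000
    cov = [[1, -0.5], [-0.5, 1]]
    xy = rng.multivariate_normal([0, 0], cov, size=n)
    slopes = _slopes_frame(xy[:, 0])
    grs = pd.Series(xy[:, 1], index=slopes.index)
    out = grs_comparison(slopes, grs)
    assert out["r_all"] == pytest.approx(-0.5, abs=0.05)


def test_grs_bound_filters_stress_dependent_genes():
    slopes = _slopes_frame([1.0, 0.8, -0.2], q=[0.01, 0.01, 0.5], index=["in", "out", "ns"])
    grs = pd.Series({"in": 2.0, "out": 6.0, "ns": 1.0})
    out = grs_comparison(slopes, grs, bound=5.0, min_overlap=2)
    # |GRS| >= bound excluded; non-significant agers excluded
    assert out["stress_independent"] == {"in"}


def test_grs_symmetric_under_reordering():
    rng = np.random.default_rng(2)
    beta = rng.normal(0, 1, 80)
    slopes = _slopes_frame(beta)
    grs = pd.Series(rng.normal(0, 3, 80), index=slopes.index)
    r1 = grs_comparison(slopes, grs)["r_all"]
    perm = rng.permutation(80)
    r2 = grs_comparison(slopes.iloc[perm], grs)["r_all"]
    assert r1 == pytest.approx(r2, rel=1e-12)


def test_grs_insufficient_overlap_errors():
    slopes = _slopes_frame([0.1, 0.2])
    grs = pd.Series({"g0": 1.0})
    with pytest.raises(ValueError):
        grs_comparison(slopes, grs)


# -- telomere distance -------------------------------------------------------


def test_telomere_distances_by_hand(genome):
    g0 = genome.genes.iloc[0]
    length = genome.chrom_lengths[g0.chrom]
    expected = min(g0.tss, length - g0.tss)
    slopes = _slopes_frame([0.0], index=[g0.gene_id])
    prof = telomere_distance_profile(slopes, genome, n_bins=4)
    b = np.searchsorted(prof["dist_hi"].to_numpy(), expected)
    assert prof.loc[b, "n_genes"] == 1


def test_subtelomeric_bonus_recovered(genome):
    em = simulate_expression_matrix(
        list(genome.genes.gene_id), SPECS, {}, noise_sd=0.15,
        genome=genome, subtelomere_bonus=0.05, seed=4,
    )
    res = fit_expression_slopes(em.tpm, em.design)
    prof = telomere_distance_profile(res, genome, n_bins=6)
    near = prof.loc[prof["n_genes"] >= 5].iloc[0]["median_slope"]
    overall = res["beta"].median()
    assert near - overall == pytest.approx(0.05, abs=0.02)
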