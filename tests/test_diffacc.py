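import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from atacage.diffacc import (
    SingularDesignError,
    assign_bins_to_genes,
    bh_adjust,
    classify_bins,
    fit_aging_slopes,
    hypergeom_enrich,
    quantile_norm_factors,
)

DESIGN = pd.DataFrame(
    {
        "sample": [f"s{i}" for i in range(6)],
        "replicate": ["r1", "r1", "r1", "r2", "r2", "r2"],
        "strain": ["WT"] * 6,
        "ave_budscars": [0.0, 10.0, 20.0, 0.0, 10.0, 20.0],
    }
)


# -- quantile normalization factors ----------------------------------------


def test_identical_distributions_give_unit_factors():
    bins = pd.DataFrame({"a": [5.0, 1.0, 3.0, 9.0], "b": [1.0, 3.0, 9.0, 5.0]})
    f = quantile_norm_factors(bins)
    assert np.allclose(f.to_numpy(), 1.0)


def test_scaled_sample_factors_reflect_depth():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    bins = pd.DataFrame({"a": a, "b": 2 * a})
    f = quantile_norm_factors(bins)
    # same ranks: reference is 1.5*a, so a-factors = 2/3, b-factors = 4/3
    assert np.allclose(f["b"] / f["a"], 2.0)
    assert np.allclose(f["a"], 2 / 3)


def test_tied_counts_yield_finite_positive_factors():
    bins = pd.DataFrame({"a": [0.0, 2.0, 2.0, 5.0], "b": [1.0, 1.0, 4.0, 7.0]})
    f = quantile_norm_factors(bins)
    assert np.isfinite(f.to_numpy()).all()
    assert (f.to_numpy() > 0).all()


def test_all_zero_sample_rejected():
    with pytest.raises(ValueError):
        quantile_norm_factors(pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0]}))


# -- NB aging slopes --------------------------------------------------------


def test_constant_counts_give_null_slope():
    bins = pd.DataFrame([[50] * 6, [200] * 6], index=["b1", "b2"], columns=DESIGN["sample"])
    res = fit_aging_slopes(bins, DESIGN)
    assert np.allclose(res["beta"].abs(), 0.0, atol=1e-8)
    assert (res["p"] > 0.5).all()


def test_slope_units_are_per_bud_scar():
    rng = np.random.default_rng(0)
    bins = pd.DataFrame(
        rng.poisson(np.exp(4 + 0.05 * DESIGN["ave_budscars"].to_numpy()), size=(5, 6)),
        columns=DESIGN["sample"],
    )
    res1 = fit_aging_slopes(bins, DESIGN)
    doubled = DESIGN.copy()
    doubled["ave_budscars"] *= 2
    res2 = fit_aging_slopes(bins, doubled)
    assert np.allclose(res2["beta"], res1["beta"] / 2, rtol=1e-6)


def test_singular_design_names_collinear_columns():
    bad = DESIGN.copy()
    bad["strain"] = ["WT", "WT", "WT", "mut", "mut", "mut"]  # strain == replicate
    bins = pd.DataFrame([[10] * 6], columns=DESIGN["sample"])
    with pytest.raises(SingularDesignError, match="strain"):
        fit_aging_slopes(bins, bad)


def test_all_zero_bins_skipped_not_fatal():
    bins = pd.DataFrame([[0] * 6, [9, 11, 10, 10, 9, 12]], index=["z", "ok"], columns=DESIGN["sample"])
    res = fit_aging_slopes(bins, DESIGN)
    assert not res.loc["z", "tested"]
    assert res.loc["ok", "tested"]
    assert math.isnan(res.loc["z", "beta"])


# -- BH --------------------------------------------------------------------


def _bh_bruteforce(p):
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(p[i] * m / rank_from_top, prev)
        q[i] = val
        prev = val
    return q


def test_bh_known_values():
    assert bh_adjust(np.array([0.01]))[0] == pytest.approx(0.01)
    q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04, 0.05]))
    assert np.allclose(q, 0.05)


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        bh_adjust(np.array([0.5, 1.2]))


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
def test_bh_equals_bruteforce_and_statsmodels(p):
    p = np.asarray(p)
    q = bh_adjust(p)
    assert np.allclose(q, _bh_bruteforce(p))
    assert np.allclose(q, multipletests(p, method="fdr_bh")[1])
    assert q.min() >= p.min() - 1e-12


# -- genomic context classification -----------------------------------------


def _results_for_bins(index, betas):
    return pd.DataFrame(
        {
            "beta": betas,
            "se": 0.01,
            "p": 1e-9,
            "q": 1e-9,
            "direction": np.where(np.asarray(betas) > 0, "opening", "closing"),
            "tested": True,
        },
        index=index,
    )


def test_classification_precedence(genome):
    # pick a mid-chromosome plus-strand gene whose promoter gap holds no ARS
    candidates = genome.genes[(genome.genes.strand == "+") & (genome.genes.chrom == "chrI")]
    gene = candidates.iloc[len(candidates) // 2]
    # a bin 350 bp upstream of the TSS lies in the promoter (<=400 bp)
    prom_bin = (gene.tss - 350) // 100 * 100
    body_bin = (gene.start + gene.end) // 2 // 100 * 100
    ars = genome.ars_intervals.iloc[0]
    ars_bin = (ars.start + 50) // 100 * 100
    idx = [
        f"{gene.chrom}:{prom_bin}-{prom_bin + 100}",
        f"{gene.chrom}:{body_bin}-{body_bin + 100}",
        f"{ars.chrom}:{ars_bin}-{ars_bin + 100}",
    ]
    res = _results_for_bins(idx, [0.1, -0.1, -0.2])
    category, summary = classify_bins(res, genome, q_cut=1e-6)
    assert category.iloc[0] == "promoter"
    assert category.iloc[1] == "gene_body"
    assert category.iloc[2] == "ARS"
    assert summary.loc[summary.category == "promoter", "frac_opening"].iloc[0] == 1.0


def test_bin_to_gene_assignment(genome):
    gene = genome.genes.iloc[0]
    body_bin = (gene.start + gene.end) // 2 // 100 * 100
    idx = pd.Index([f"{gene.chrom}:{body_bin}-{body_bin + 100}", "chrI:199900-200000"])
    assigned = assign_bins_to_genes(idx, genome)
    assert assigned.iloc[0] == gene.gene_id


# -- hypergeometric ----------------------------------------------------------


def _hyper_bruteforce(k, M, n, N):
    return sum(
        math.comb(n, i) * math.comb(M - n, N - i) / math.comb(M, N)
        for i in range(k, min(n, N) + 1)
    )


def test_hypergeometric_example_matches_enumeration():
    uni = set(range(20))
    target = set(range(5))
    selected = set(range(4)) | set(range(10, 14))
    res = hypergeom_enrich(selected, target, uni)
    assert res["overlap"] == 4
    assert res["p"] == pytest.approx(_hyper_bruteforce(4, 20, 5, 8), rel=1e-12)
    assert res["p"] == pytest.approx(0.0578, abs=2e-4)


def test_hypergeometric_degenerate_cases():
    uni = set(range(10))
    res = hypergeom_enrich(set(range(3)), set(), uni)
    assert res["p"] == 1.0 and math.isnan(res["fold"])
    res2 = hypergeom_enrich(uni, set(range(4)), uni)
    assert res2["p"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        hypergeom_enrich(set(), set(), set())


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.data())
def test_hypergeometric_matches_enumeration_small_universes(data):
    M = data.draw(st.integers(1, 30))
    n = data.draw(st.integers(0, M))
    N = data.draw(st.integers(0, M))
    uni = set(range(M))
    target = set(range(n))
    rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
    selected = set(rng.choice(M, size=N, replace=False).tolist())
    res = hypergeom_enrich(selected, target, uni)
    if n and N:
        assert res["p"] == pytest.approx(
            _hyper_bruteforce(res["overlap"], M, n, N), rel=1e-9, abs=1e-12
        )
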