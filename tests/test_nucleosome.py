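import numpy as np
import pandas as pd
import pytest

from atacage.insertions import InsertionTrack
from atacage.nucleosome import (
    SizeDistribution,
    downsample_fragments,
    estimate_occupancy,
    fit_size_components,
    fragment_centers,
    metagene_profile,
    pooled_size_distribution,
    select_reference_nucleosomes,
)


def _frags(sizes, chrom="chrI", start=1000):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": [start + s for s in sizes],
            "first_mate_strand": "+",
            "mapq": 60,
            "viability": "live",
            "cell_id": "c",
        }
    )


def test_metagene_uniform_track_is_flat():
    track = InsertionTrack(counts={"chrI": np.full(4000, 3.25)})
    anchors = pd.DataFrame({"chrom": "chrI", "pos": [1000, 2000, 3000]})
    prof = metagene_profile(track, anchors, halfwidth=200)
    assert np.all(np.abs(prof["density"] - 3.25) < 1e-9)


def test_metagene_delta_and_strand_reflection():
    counts = {"chrI": np.zeros(4000)}
    counts["chrI"][980] = 1.0  # offset -20 from anchor at 1000
    track = InsertionTrack(counts=counts)
    plus = metagene_profile(track, pd.DataFrame({"chrom": ["chrI"], "pos": [1000], "strand": ["+"]}), 50)
    assert plus.loc[plus.offset == -20, "density"].iloc[0] == 1.0
    assert plus["density"].sum() == 1.0
    minus = metagene_profile(track, pd.DataFrame({"chrom": ["chrI"], "pos": [1000], "strand": ["-"]}), 50)
    assert minus.loc[minus.offset == 20, "density"].iloc[0] == 1.0


def test_metagene_excludes_edge_anchors():
    track = InsertionTrack(counts={"chrI": np.ones(500)})
    anchors = pd.DataFrame({"chrom": "chrI", "pos": [10, 250]})
    prof = metagene_profile(track, anchors, halfwidth=100)
    assert prof.attrs["n_used"] == 1
    assert prof.attrs["n_skipped"] == 1
    with pytest.raises(ValueError):
        metagene_profile(track, pd.DataFrame({"chrom": ["chrI"], "pos": [10]}), 100)


def test_pooled_size_distribution_identity_and_average():
    one = pooled_size_distribution([_frags([60, 60, 147])])
    assert one.prob_of(np.array([60]))[0] == pytest.approx(2 / 3)
    two = pooled_size_distribution([_frags([60] * 5), _frags([147] * 9)])
    assert two.prob_of(np.array([60]))[0] == pytest.approx(0.5)
    assert two.prob_of(np.array([147]))[0] == pytest.approx(0.5)
    assert two.pmf.sum() == pytest.approx(1.0)


def test_pooled_size_distribution_empty_handling():
    with pytest.warns(UserWarning):
        d = pooled_size_distribution([_frags([100]), _frags([])])
    assert d.pmf.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        pooled_size_distribution([_frags([])])


def test_size_component_split():
    pooled = pooled_size_distribution([_frags([60] * 3), _frags([147] * 3)])
    f_free, f_nuc = fit_size_components(pooled, split=115)
    assert f_free.prob_of(np.array([60]))[0] == pytest.approx(1.0)
    assert f_nuc.prob_of(np.array([147]))[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        fit_size_components(pooled, split=50)


def test_size_components_from_default_simulation(size_components):
    f_free, f_nuc = size_components
    assert 130 <= f_nuc.mode() <= 160
    assert f_free.pmf.sum() == pytest.approx(1.0)
    assert f_nuc.pmf.sum() == pytest.approx(1.0)


@pytest.fixture()
def components():
    f_free = SizeDistribution(np.arange(30, 100), np.exp(-0.5 * ((np.arange(30, 100) - 60) / 12.0) ** 2))
    f_nuc = SizeDistribution(np.arange(110, 200), np.exp(-0.5 * ((np.arange(110, 200) - 147) / 15.0) ** 2))
    return f_free, f_nuc


def test_occupancy_pure_components(components):
    f_free, f_nuc = components
    rng = np.random.default_rng(0)
    nuc_sizes = rng.choice(f_nuc.sizes, 200, p=f_nuc.pmf)
    free_sizes = rng.choice(f_free.sizes, 200, p=f_free.pmf)
    assert estimate_occupancy(nuc_sizes, f_nuc, f_free).theta >= 0.95
    assert estimate_occupancy(free_sizes, f_nuc, f_free).theta <= 0.05


def test_occupancy_grid_oracle_at_half(components):
    """theta-hat from the refined optimizer agrees with a brute-force grid
    MLE on the same draw and recovers a 50/50 mixture."""
    f_free, f_nuc = components
    rng = np.random.default_rng(1)
    sizes = np.concatenate(
        [rng.choice(f_nuc.sizes, 500, p=f_nuc.pmf), rng.choice(f_free.sizes, 500, p=f_free.pmf)]
    )
    est = estimate_occupancy(sizes, f_nuc, f_free)
    grid = np.linspace(0, 1, 100001)
    pn, pf = f_nuc.prob_of(sizes), f_free.prob_of(sizes)
    ll = np.log(np.clip(grid[:, None] * pn + (1 - grid)[:, None] * pf, 1e-300, None)).sum(axis=1)
    brute = grid[np.argmax(ll)]
    assert est.theta == pytest.approx(brute, abs=2e-4)
    assert 0.45 <= est.theta <= 0.55


def test_occupancy_monotone_in_mixture_composition(components):
    f_free, f_nuc = components
    rng = np.random.default_rng(2)
    nuc_sizes = rng.choice(f_nuc.sizes, 400, p=f_nuc.pmf)
    free_sizes = rng.choice(f_free.sizes, 400, p=f_free.pmf)
    thetas = []
    for k in [0, 100, 200, 300, 400]:
        sizes = np.concatenate([nuc_sizes[:k], free_sizes[k:]])
        thetas.append(estimate_occupancy(sizes, f_nuc, f_free).theta)
    assert all(b >= a - 1e-9 for a, b in zip(thetas, thetas[1:]))


def test_occupancy_min_fragments_flagging(components):
    f_free, f_nuc = components
    est = estimate_occupancy(np.array([147] * 5), f_nuc, f_free, min_fragments=20)
    assert not est.ok and np.isnan(est.theta)


def test_reference_nucleosome_selection_rules():
    dyads = pd.DataFrame(
        {"chrom": "chrI", "pos": [100, 300, 500], "score": [2.1, 2.1, 1.5], "gene_id": "g", "rank": 1}
    )
    opens = pd.DataFrame({"chrom": ["chrI"], "start": [0], "end": [400]})
    occ = {
        "s1": pd.DataFrame({"chrom": "chrI", "pos": [100, 300, 500], "theta": [0.7, 0.45, 0.9], "ok": True}),
        "s2": pd.DataFrame({"chrom": "chrI", "pos": [100, 300, 500], "theta": [0.5, 0.35, 0.9], "ok": True}),
    }
    sel = select_reference_nucleosomes(dyads, occ, opens)
    # pos 100: score>2, open, median 0.6 -> kept
    # pos 300: median 0.4 < 0.5 -> dropped; pos 500: outside open + low score
    assert list(sel["pos"]) == [100]
    empty = select_reference_nucleosomes(dyads.iloc[:0], occ, opens)
    assert len(empty) == 0


def test_fragment_centers_definition():
    f = pd.DataFrame({"start": [10, 10], "end": [20, 21]})
    assert list(fragment_centers(f)) == [14, 15]


def test_downsample_contract():
    frags = _frags(list(range(50, 100)))
    same = downsample_fragments(frags, len(frags), seed=3)
    assert sorted(same["end"]) == sorted(frags["end"])
    sub1 = downsample_fragments(frags, 10, seed=4)
    sub2 = downsample_fragments(frags, 10, seed=4)
    assert len(sub1) == 10
    pd.testing.assert_frame_equal(sub1, sub2)
    with pytest.raises(ValueError):
        downsample_fragments(frags, 1000, seed=0)
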