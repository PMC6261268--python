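"""Metagene profiles, fragment-size distributions, and occupancy estimation.

Nucleosomes protect roughly 140 bp around their dyads from transposition,
so live-cell insertion density collapses there; fragment sizes split into a
sub-nucleosomal and a nucleosomal-sized component.  Occupancy of a dyad is
estimated as the weight ``theta`` of the nucleosomal component in a
two-component mixture fitted by maximum likelihood to the sizes of the
fragments whose centers fall within a window of the dyad:

    theta_hat = argmax_theta  sum_i log[ theta f_nuc(s_i) + (1-theta) f_free(s_i) ]

with the component distributions derived from a pooled (equal-weight
average across samples) fragment-size distribution split at a size
threshold.  This is a deliberately self-contained occupancy estimator; it
aims at the qualitative behavior of full ATAC nucleosome callers (flat
occupancy with age once dead-cell DNA is removed), not at numerical
equivalence with them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "SizeDistribution",
    "OccupancyEstimate",
    "metagene_profile",
    "central_depletion_width",
    "pooled_size_distribution",
    "fit_size_components",
    "estimate_occupancy",
    "occupancy_table",
    "select_reference_nucleosomes",
    "downsample_fragments",
    "fragment_centers",
]


@dataclass
class SizeDistribution:
    """Probability mass over fragment sizes on a contiguous bp support."""

    sizes: np.ndarray
    pmf: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.pmf = np.asarray(self.pmf, dtype=float)
        if np.any(self.pmf < 0):
            raise ValueError("size distribution has negative mass")
        total = self.pmf.sum()
        if total <= 0:
            raise ValueError("size distribution has zero mass")
        self.pmf = self.pmf / total

    @classmethod
    def from_sizes(cls, sizes: np.ndarray) -> "SizeDistribution":
        sizes = np.asarray(sizes, dtype=int)
        if len(sizes) == 0:
            raise ValueError("no fragment sizes")
        lo, hi = sizes.min(), sizes.max()
        pmf = np.bincount(sizes - lo, minlength=hi - lo + 1).astype(float)
        return cls(np.arange(lo, hi + 1), pmf)

    def prob_of(self, sizes: np.ndarray) -> np.ndarray:
        """Mass at each query size (0 outside the support)."""
        sizes = np.asarray(sizes, dtype=int)
        idx = sizes - self.sizes[0]
        ok = (idx >= 0) & (idx < len(self.pmf))
        out = np.zeros(len(sizes))
        out[ok] = self.pmf[idx[ok]]
        return out

    def mode(self) -> int:
        return int(self.sizes[np.argmax(self.pmf)])


@dataclass
class OccupancyEstimate:
    dyad_id: object
    theta: float
    n_fragments: int
    loglik: float
    ok: bool = True


def metagene_profile(
    track,
    anchors: pd.DataFrame,
    halfwidth: int,
) -> pd.DataFrame:
    """Mean insertion density by signed offset around a set of anchors.

    ``anchors`` needs columns ``chrom, pos`` and optionally ``strand``;
    minus-strand anchors are reflected so that positive offsets point
    downstream.  Anchors closer than ``halfwidth`` to a chromosome edge are
    excluded (tallied in the result's ``attrs``).  Returns a DataFrame with
    ``offset`` (-halfwidth..+halfwidth) and ``density``.
    """
    if len(anchors) == 0:
        raise ValueError("no anchors given")
    width = 2 * halfwidth + 1
    acc = np.zeros(width)
    used = 0
    skipped = 0
    has_strand = "strand" in anchors.columns
    for row in anchors.itertuples(index=False):
        arr = track.counts[row.chrom]
        p = int(row.pos)
        if p - halfwidth < 0 or p + halfwidth + 1 > len(arr):
            skipped += 1
            continue
        win = arr[p - halfwidth : p + halfwidth + 1]
        if has_strand and row.strand == "-":
            win = win[::-1]
        acc += win
        used += 1
    if used == 0:
        raise ValueError("all anchors excluded (too close to chromosome edges)")
    out = pd.DataFrame({"offset": np.arange(-halfwidth, halfwidth + 1), "density": acc / used})
    out.attrs["n_used"] = used
    out.attrs["n_skipped"] = skipped
    return out


def central_depletion_width(
    profile: pd.DataFrame,
    flank: tuple[int, int] = (300, 500),
    fraction: float = 0.5,
) -> float:
    """Width (bp) of the contiguous central region whose density is below
    ``fraction`` of the mean density at offsets ``flank[0]..flank[1]`` on
    both sides.  The central region is the run of sub-threshold offsets
    containing offset 0."""
    off = profile["offset"].to_numpy()
    dens = profile["density"].to_numpy()
    fl = (np.abs(off) >= flank[0]) & (np.abs(off) <= flank[1])
    if not fl.any():
        raise ValueError("flank range outside profile")
    thresh = fraction * dens[fl].mean()
    below = dens < thresh
    center = int(np.where(off == 0)[0][0])
    if not below[center]:
        return 0.0
    left = center
    while left > 0 and below[left - 1]:
        left -= 1
    right = center
    while right < len(below) - 1 and below[right + 1]:
        right += 1
    return float(right - left + 1)


def fragment_centers(fragments: pd.DataFrame) -> np.ndarray:
    """Fragment center = floor((start + end - 1) / 2)."""
    return (fragments["start"].to_numpy() + fragments["end"].to_numpy() - 1) // 2


def pooled_size_distribution(samples: list[pd.DataFrame]) -> SizeDistribution:
    """Equal-weight average of per-sample empirical size distributions.

    Empty samples are skipped with a warning; all-empty input is an error.
    Sample depth does not weight the average: every sample's empirical mass
    function contributes equally before renormalization.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    dists = []
    for i, s in enumerate(samples):
        sizes = (s["end"] - s["start"]).to_numpy()
        if len(sizes) == 0:
            warnings.warn(f"sample {i} has no fragments; excluded from pooled size distribution")
            continue
        dists.append(SizeDistribution.from_sizes(sizes))
    if not dists:
        raise ValueError("all samples empty")
    lo = min(d.sizes[0] for d in dists)
    hi = max(d.sizes[-1] for d in dists)
    pmf = np.zeros(hi - lo + 1)
    for d in dists:
        pmf[d.sizes[0] - lo : d.sizes[-1] - lo + 1] += d.pmf
    return SizeDistribution(np.arange(lo, hi + 1), pmf / len(dists))


def fit_size_components(
    pooled: SizeDistribution, split: int = 115
) -> tuple[SizeDistribution, SizeDistribution]:
    """Split the pooled distribution at ``split`` bp into nucleosome-free
    (``< split``) and nucleosomal (``>= split``) components, renormalized."""
    below = pooled.sizes < split
    if not below.any() or below.all():
        raise ValueError(f"pooled distribution has no mass on one side of split={split}")
    f_free = SizeDistribution(pooled.sizes[below], pooled.pmf[below])
    f_nuc = SizeDistribution(pooled.sizes[~below], pooled.pmf[~below])
    return f_free, f_nuc


def _mixture_loglik(theta: float, p_nuc: np.ndarray, p_free: np.ndarray) -> float:
    lik = theta * p_nuc + (1.0 - theta) * p_free
    return float(np.log(np.clip(lik, 1e-300, None)).sum())


def estimate_occupancy(
    sizes: np.ndarray,
    f_nuc: SizeDistribution,
    f_free: SizeDistribution,
    min_fragments: int = 20,
    dyad_id: object = None,
    grid_step: float = 1e-3,
) -> OccupancyEstimate:
    """MLE of the nucleosomal mixture weight from fragment sizes.

    A grid search at ``grid_step`` resolution brackets the optimum, which is
    then refined by bounded 1-D optimization.  Returns boundary values when
    the optimum lies at 0 or 1; estimates from fewer than ``min_fragments``
    sizes are flagged not-ok rather than raising.
    """
    sizes = np.asarray(sizes, dtype=int)
    n = len(sizes)
    if n < min_fragments:
        return OccupancyEstimate(dyad_id, np.nan, n, np.nan, ok=False)
    p_nuc = f_nuc.prob_of(sizes)
    p_free = f_free.prob_of(sizes)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    # vectorized grid log-likelihood
    lik = grid[:, None] * p_nuc[None, :] + (1.0 - grid)[:, None] * p_free[None, :]
    ll = np.log(np.clip(lik, 1e-300, None)).sum(axis=1)
    best = int(np.argmax(ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda t: -_mixture_loglik(t, p_nuc, p_free), bounds=(lo, hi), method="bounded"
        )
        theta = float(res.x)
        if _mixture_loglik(theta, p_nuc, p_free) < ll[best]:
            theta = float(grid[best])
    else:
        theta = float(grid[best])
    theta = min(max(theta, 0.0), 1.0)
    return OccupancyEstimate(dyad_id, theta, n, _mixture_loglik(theta, p_nuc, p_free))


def occupancy_table(
    fragments: pd.DataFrame,
    dyads: pd.DataFrame,
    f_nuc: SizeDistribution,
    f_free: SizeDistribution,
    window: int = 60,
    min_fragments: int = 20,
) -> pd.DataFrame:
    """Occupancy estimate for every dyad in ``dyads``.

    Fragments are associated to a dyad when their *center* lies within
    ``dyad +/- window``; centers (not insertion points) carry the occupancy
    semantics.  Returns one row per dyad: ``chrom, pos, theta, n_fragments,
    loglik, ok``.
    """
    results = []
    sizes_all = (fragments["end"] - fragments["start"]).to_numpy()
    centers_all = fragment_centers(fragments)
    chrom_arr = fragments["chrom"].to_numpy()
    by_chrom = {}
    for chrom in dyads["chrom"].unique():
        m = chrom_arr == chrom
        order = np.argsort(centers_all[m], kind="stable")
        by_chrom[chrom] = (centers_all[m][order], sizes_all[m][order])
    for row in dyads.itertuples(index=False):
        centers, sizes = by_chrom[row.chrom]
        lo = np.searchsorted(centers, row.pos - window, side="left")
        hi = np.searchsorted(centers, row.pos + window, side="right")
        est = estimate_occupancy(
            sizes[lo:hi], f_nuc, f_free, min_fragments=min_fragments, dyad_id=(row.chrom, row.pos)
        )
        results.append((row.chrom, row.pos, est.theta, est.n_fragments, est.loglik, est.ok))
    return pd.DataFrame(results, columns=["chrom", "pos", "theta", "n_fragments", "loglik", "ok"])


def select_reference_nucleosomes(
    dyads: pd.DataFrame,
    occupancies: dict[str, pd.DataFrame],
    open_intervals: pd.DataFrame,
    score_cut: float = 2.0,
    occupancy_cut: float = 0.5,
) -> pd.DataFrame:
    """Reference dyads: positioning score above ``score_cut``, inside an
    open-chromatin interval, and median occupancy across samples at least
    ``occupancy_cut``.

    ``occupancies`` maps sample id -> occupancy_table output aligned on
    (chrom, pos); missing (not-ok) estimates are ignored in the median.
    """
    if len(dyads) == 0:
        return dyads.copy()
    keep_score = dyads["score"] > score_cut
    in_open = np.zeros(len(dyads), dtype=bool)
    for chrom, sub in open_intervals.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        m = (dyads["chrom"] == chrom).to_numpy()
        pos = dyads.loc[m, "pos"].to_numpy()
        hit = np.zeros(len(pos), dtype=bool)
        for s, e in zip(starts, ends):
            hit |= (pos >= s) & (pos < e)
        in_open[m] = hit
    med = []
    key = list(zip(dyads["chrom"], dyads["pos"]))
    tables = []
    for occ in occupancies.values():
        t = occ.set_index(["chrom", "pos"])
        tables.append(t)
    for k in key:
        vals = []
        for t in tables:
            if k in t.index:
                r = t.loc[k]
                if bool(r["ok"]) and np.isfinite(r["theta"]):
                    vals.append(float(r["theta"]))
        med.append(np.median(vals) if vals else np.nan)
    med = np.asarray(med)
    keep = keep_score.to_numpy() & in_open & (med >= occupancy_cut)
    out = dyads.loc[keep].copy()
    out["median_occupancy"] = med[keep]
    return out


def downsample_fragments(fragments: pd.DataFrame, n: int, seed: int = 0) -> pd.DataFrame:
    """Uniform sample of ``n`` fragments without replacement, deterministic
    per seed; original row order is preserved.  Requesting more fragments
    than available is an error (fixed-depth contract)."""
    if n > len(fragments):
        raise ValueError(f"cannot downsample {len(fragments)} fragments to {n}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(fragments), size=n, replace=False))
    return fragments.iloc[idx].reset_index(drop=True)
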