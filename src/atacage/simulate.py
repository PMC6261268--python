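"""Synthetic ATAC fragments and expression matrices for aging populations.

The generator emulates the statistical structure the downstream analyses
rely on:

* live-cell Tn5 insertions follow an accessibility-weighted density --
  NFRs and promoter-proximal linkers are hot, nucleosomal DNA (dyad +/- 70
  bp) is strongly protected, and per-bin accessibility changes
  exponentially with replicative age (``exp(beta_b * ave_budscars)``);
* dead-cell (naked DNA) insertions are uniform per bp over the genome, with
  the rDNA unit weighted by copy number;
* the rDNA unit is sampled proportionally to ``base_copies * rdna_fold``,
  attenuated by a per-copy mappability weight (tandem repeats collapse onto
  one represented unit under unique mapping);
* fragment sizes come from a two-component distribution (sub-nucleosomal
  and nucleosomal-sized) for live cells and a broad mixture for dead cells;
* expression follows ``E[log2 TPM] = intercept + slope * ave_budscars +
  batch + strain`` with columns renormalized to one million.

A fragment is generated by drawing its first Tn5 insertion point from the
weight density, a size from the size model, and accepting the paired second
insertion point with probability proportional to the local weight; the
reported BED-like coordinates then back off the insertion points by the
strand-specific 4/5-bp transposase offsets, so that insertion extraction
recovers the simulated cut sites exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeAnnotation

__all__ = [
    "AgingPopulationSpec",
    "FragmentSizeModel",
    "WeightConfig",
    "insertion_weights",
    "simulate_atac_sample",
    "ExpressionMatrix",
    "simulate_expression_matrix",
]

# distance between the two Tn5 insertion points of a fragment of size s is
# s - 10: the +4 / -5 shifts from the fragment ends onto the centers of the
# two 9-bp transposase duplications consume 10 bp in total
_PAIR_OFFSET = 10


@dataclass
class AgingPopulationSpec:
    """One sequencing sample of an aging (or young) population.

    Parameters
    ----------
    strain : str
        Genotype label (e.g. ``WT``, ``sir2``).
    dead_fraction : float
        Proportion of fragments arising from dead (membrane-compromised)
        cells whose naked DNA yields a uniform insertion signal.
    ave_budscars : float
        Mean bud-scar count of the population, i.e. replicative age.
    rdna_fold : float
        rDNA copy-number multiplier relative to the genomic baseline,
        capturing ERC accumulation in aged mothers.
    bin_slopes : dict
        Optional map of global 100-bp bin index -> per-bud-scar log
        accessibility slope applied to live-cell weights.
    replicate : str
        Batch / biological replicate label.
    is_daughter : bool
        Daughter cells do not inherit ERCs; their effective rdna_fold is
        reset to 1 (asymmetric retention).
    """

    strain: str = "WT"
    dead_fraction: float = 0.0
    ave_budscars: float = 0.0
    rdna_fold: float = 1.0
    bin_slopes: dict[int, float] | None = None
    replicate: str = "r1"
    is_daughter: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError(f"dead_fraction must be in [0, 1], got {self.dead_fraction}")
        if self.rdna_fold < 0:
            raise ValueError("rdna_fold must be non-negative")
        if self.ave_budscars < 0:
            raise ValueError("ave_budscars must be non-negative")

    @property
    def effective_rdna_fold(self) -> float:
        return 1.0 if self.is_daughter else self.rdna_fold


def _discrete_pmf(dist, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
    sizes = np.arange(lo, hi + 1)
    pmf = dist.cdf(sizes + 0.5) - dist.cdf(sizes - 0.5)
    pmf = np.clip(pmf, 0.0, None)
    return sizes, pmf / pmf.sum()


@dataclass
class FragmentSizeModel:
    """Two-component fragment-size model.

    Sub-nucleosomal sizes are a discretized gamma with mode near 60 bp
    (fragments from open DNA between protections); nucleosomal sizes are a
    discretized normal(147, 15) truncated to [100, 250] (fragments spanning
    one nucleosome).  Dead-cell fragments draw from an even mixture of both
    components, since naked DNA retains no footprint structure.
    """

    sub_shape: float = 6.0
    sub_scale: float = 12.0
    sub_min: int = 20
    sub_max: int = 160
    nuc_mean: float = 147.0
    nuc_sd: float = 15.0
    nuc_min: int = 100
    nuc_max: int = 250
    live_sub_fraction: float = 0.4
    dead_sub_fraction: float = 0.5

    def _mixture(self, sub_fraction: float) -> tuple[np.ndarray, np.ndarray]:
        lo = min(self.sub_min, self.nuc_min)
        hi = max(self.sub_max, self.nuc_max)
        sizes = np.arange(lo, hi + 1)
        pmf = np.zeros(len(sizes))
        s_sizes, s_pmf = _discrete_pmf(stats.gamma(self.sub_shape, scale=self.sub_scale), self.sub_min, self.sub_max)
        n_sizes, n_pmf = _discrete_pmf(stats.norm(self.nuc_mean, self.nuc_sd), self.nuc_min, self.nuc_max)
        pmf[s_sizes - lo] += sub_fraction * s_pmf
        pmf[n_sizes - lo] += (1.0 - sub_fraction) * n_pmf
        return sizes, pmf / pmf.sum()

    def live(self) -> tuple[np.ndarray, np.ndarray]:
        return self._mixture(self.live_sub_fraction)

    def dead(self) -> tuple[np.ndarray, np.ndarray]:
        return self._mixture(self.dead_sub_fraction)


@dataclass
class WeightConfig:
    """Per-bp live-cell insertion weights by annotation class.

    Weights are relative rates, not probabilities.  Promoter-proximal
    linkers are the hottest class so that reference nucleosomes accumulate
    enough spanning fragments for occupancy estimation at desk-scale depth.
    ``rdna_per_copy`` is a mappability attenuation: each of the collapsed
    tandem copies contributes this weight per bp, for live and dead
    fragments alike.
    """

    intergenic: float = 1.0
    nfr: float = 8.0
    proximal_linker: float = 12.0
    body_linker: float = 0.15
    dyad: float = 0.02
    mito: float = 1.0
    rdna_per_copy: float = 0.004
    bin_width: int = 100  # width of aging-slope bins


def _interval_fill(arr: np.ndarray, df: pd.DataFrame, chrom: str, value: float) -> None:
    for _, r in df[df.chrom == chrom].iterrows():
        arr[int(r.start) : int(r.end)] = value


def insertion_weights(
    genome: GenomeAnnotation,
    spec: AgingPopulationSpec,
    weights: WeightConfig | None = None,
    protect_halfwidth: int = 70,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Live and dead per-bp insertion weight tables.

    Returns ``(live, dead)``, each mapping chromosome -> float array.  These
    tables are the generator's ground truth: expected insertion densities
    are proportional to them, which the proportionality tests exploit.
    """
    w = weights or WeightConfig()
    live: dict[str, np.ndarray] = {}
    dead: dict[str, np.ndarray] = {}
    rdna_weight = w.rdna_per_copy * genome.rdna_base_copies * spec.effective_rdna_fold
    open_by_gene = dict(zip(genome.genes.gene_id, zip(genome.open_intervals.start, genome.open_intervals.end)))

    for chrom, length in genome.chrom_lengths.items():
        if chrom == genome.mito_chrom:
            live[chrom] = np.full(length, w.mito)
            dead[chrom] = np.ones(length)
            continue
        arr = np.full(length, w.intergenic)
        # gene bodies: deep linker background, then promoter-proximal open
        # segment, then nucleosomal protection on top
        sub = genome.genes[genome.genes.chrom == chrom]
        for _, g in sub.iterrows():
            arr[g.start : g.end] = w.body_linker
        for _, g in sub.iterrows():
            s, e = open_by_gene[g.gene_id]
            os = max(g.start, s)
            oe = min(g.end, e)
            if oe > os:
                arr[os:oe] = w.proximal_linker
        _interval_fill(arr, genome.nfr_intervals, chrom, w.nfr)
        dsub = genome.dyads[genome.dyads.chrom == chrom]
        for p in dsub["pos"].to_numpy():
            arr[max(p - protect_halfwidth, 0) : p + protect_halfwidth + 1] = w.dyad
        _interval_fill(arr, genome.ars_intervals, chrom, w.nfr)  # origins are open
        d_arr = np.ones(length)
        if chrom == genome.rdna_chrom:
            s, e = genome.rdna_interval
            arr[s:e] = rdna_weight
            d_arr[s:e] = rdna_weight
        if spec.bin_slopes and spec.ave_budscars != 0:
            offset = genome.chrom_offsets()[chrom]
            for b, beta in spec.bin_slopes.items():
                lo = b * w.bin_width - offset
                if -w.bin_width < lo < length:
                    arr[max(lo, 0) : lo + w.bin_width] *= math.exp(beta * spec.ave_budscars)
        live[chrom] = arr
        dead[chrom] = d_arr
    return live, dead


def _concat_weights(tables: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    chroms = list(tables)
    w = np.concatenate([tables[c] for c in chroms])
    bounds = np.concatenate([[0], np.cumsum([len(tables[c]) for c in chroms])])
    return w, bounds, chroms


def _sample_fragments(
    w: np.ndarray,
    bounds: np.ndarray,
    sizes: np.ndarray,
    pmf: np.ndarray,
    n: int,
    rng: np.random.Generator,
    accept: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n`` fragments; returns global (start, end, first_strand_sign).

    The first insertion point is drawn from the density ``w``; the paired
    second point (at the size-determined distance, random orientation) is
    accepted with probability ``accept[p2]`` when an acceptance array is
    given, which couples fragment placement to the protection landscape.
    """
    if n == 0:
        z = np.array([], dtype=np.int64)
        return z, z.copy(), z.copy()
    cum = np.cumsum(w)
    total = cum[-1]
    outs, oute, outd = [], [], []
    got = 0
    attempts = 0
    # acceptance rate is unknown a priori; grow batches adaptively
    batch = max(4 * n, 10_000)
    while got < n:
        m = batch
        attempts += m
        p1 = np.searchsorted(cum, rng.random(m) * total, side="right")
        s = rng.choice(sizes, size=m, p=pmf)
        sign = rng.integers(0, 2, m) * 2 - 1
        p2 = p1 + sign * (s - _PAIR_OFFSET)
        ci = np.searchsorted(bounds, p1, side="right") - 1
        lo = bounds[ci]
        hi = bounds[ci + 1]
        pl = np.minimum(p1, p2)
        pr = np.maximum(p1, p2)
        ok = (pl - 4 >= lo) & (pr + 6 <= hi)
        if accept is not None:
            ok &= rng.random(m) < accept[np.clip(p2, 0, len(w) - 1)]
        outs.append((pl - 4)[ok])
        oute.append((pr + 6)[ok])
        outd.append(sign[ok])
        got += int(ok.sum())
        rate = got / attempts if got else 0.05
        batch = max(int(1.5 * (n - got) / max(rate, 1e-3)), 10_000)
    start = np.concatenate(outs)[:n]
    end = np.concatenate(oute)[:n]
    sign = np.concatenate(outd)[:n]
    return start, end, sign


def simulate_atac_sample(
    genome: GenomeAnnotation,
    spec: AgingPopulationSpec,
    n_fragments: int = 200_000,
    seed: int = 0,
    size_model: FragmentSizeModel | None = None,
    weights: WeightConfig | None = None,
    low_mapq_fraction: float = 0.0,
) -> pd.DataFrame:
    """Simulate one ATAC-seq sample as a table of aligned fragments.

    Returns a DataFrame with columns ``chrom, start, end, first_mate_strand,
    mapq, viability, cell_id`` (0-based half-open coordinates).  Each
    fragment is labeled dead with probability ``spec.dead_fraction``.
    Deterministic per seed.
    """
    if n_fragments < 0:
        raise ValueError("n_fragments must be non-negative")
    rng = np.random.default_rng(seed)
    sm = size_model or FragmentSizeModel()
    live_tab, dead_tab = insertion_weights(genome, spec, weights)

    dead_mask = rng.random(n_fragments) < spec.dead_fraction
    n_dead = int(dead_mask.sum())
    n_live = n_fragments - n_dead

    lw, bounds, chroms = _concat_weights(live_tab)
    dw, _, _ = _concat_weights(dead_tab)
    # second-end acceptance follows the local weight; within the collapsed
    # rDNA unit both ends sit on the same repeat copy with no protection
    # structure, so the pair is always accepted there -- this keeps the rDNA
    # insertion rate exactly linear in copy number
    ridx = list(genome.chrom_lengths).index(genome.rdna_chrom)
    roff = bounds[ridx]
    rs, re = genome.rdna_interval
    nonrdna_max = np.delete(lw, np.s_[roff + rs : roff + re]).max()
    accept = np.minimum(lw / nonrdna_max, 1.0)
    accept[roff + rs : roff + re] = 1.0
    ls, lp = sm.live()
    ds, dp = sm.dead()
    s1, e1, d1 = _sample_fragments(lw, bounds, ls, lp, n_live, rng, accept=accept)
    s2, e2, d2 = _sample_fragments(dw, bounds, ds, dp, n_dead, rng, accept=None)

    start = np.empty(n_fragments, dtype=np.int64)
    end = np.empty(n_fragments, dtype=np.int64)
    sign = np.empty(n_fragments, dtype=np.int64)
    start[~dead_mask], end[~dead_mask], sign[~dead_mask] = s1, e1, d1
    start[dead_mask], end[dead_mask], sign[dead_mask] = s2, e2, d2

    ci = np.searchsorted(bounds, start, side="right") - 1
    chrom_arr = np.asarray(chroms, dtype=object)[ci]
    local_start = start - bounds[ci]
    local_end = end - bounds[ci]

    mapq = np.full(n_fragments, 60, dtype=np.int64)
    if low_mapq_fraction > 0:
        mapq[rng.random(n_fragments) < low_mapq_fraction] = 10

    frags = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "start": local_start,
            "end": local_end,
            "first_mate_strand": np.where(sign > 0, "+", "-"),
            "mapq": mapq,
            "viability": np.where(dead_mask, "dead", "live"),
            "cell_id": [f"cell{i:07d}" for i in range(n_fragments)],
        }
    )
    return frags


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM matrix with simulation truth attached.

    ``tpm`` columns each sum to 1e6; ``raw`` holds the pre-renormalization
    linear abundances, convenient for closed-form checks of the generative
    model.  ``design`` has one row per sample with ``sample, strain,
    replicate, ave_budscars`` columns.
    """

    tpm: pd.DataFrame
    raw: pd.DataFrame
    design: pd.DataFrame
    true_slopes: pd.Series


def simulate_expression_matrix(
    genes: list[str],
    design: list[AgingPopulationSpec],
    true_slopes: dict[str, float] | pd.Series,
    noise_sd: float = 0.25,
    batch_sd: float = 0.0,
    strain_sd: float = 0.0,
    strain_slope_factor: dict[str, float] | None = None,
    intercepts: pd.Series | None = None,
    genome: GenomeAnnotation | None = None,
    subtelomere_bonus: float = 0.0,
    subtelomere_dist: int = 20_000,
    seed: int = 0,
) -> ExpressionMatrix:
    """Simulate a TPM matrix with per-gene aging slopes.

    ``log2`` abundance of gene g in sample j is
    ``intercept_g + slope_g * f_strain * age_j + batch_{g,rep(j)} +
    strain_{g,strain(j)} + noise`` and columns are renormalized to 1e6.
    Requires at least two distinct ages in the design.

    When a genome and a nonzero ``subtelomere_bonus`` are given, genes
    whose TSS lies within ``subtelomere_dist`` of a chromosome end get the
    bonus added to their slope (loss of subtelomeric silencing with age);
    the bonus is included in the returned ``true_slopes``.
    """
    ages = {s.ave_budscars for s in design}
    if len(ages) < 2:
        raise ValueError("design must contain at least two distinct ave_budscars values")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    slopes = pd.Series(true_slopes, dtype=float).reindex(genes).fillna(0.0)
    if genome is not None and subtelomere_bonus:
        gt = genome.genes.set_index("gene_id")
        for gid in slopes.index:
            if gid in gt.index:
                tss = gt.loc[gid, "tss"]
                length = genome.chrom_lengths[gt.loc[gid, "chrom"]]
                if min(tss, length - tss) <= subtelomere_dist:
                    slopes[gid] += subtelomere_bonus
    if intercepts is None:
        intercepts = pd.Series(rng.normal(3.0, 2.0, len(genes)), index=genes)
    sfac = strain_slope_factor or {}

    reps = sorted({s.replicate for s in design})
    strains = sorted({s.strain for s in design})
    batch_off = {r: rng.normal(0.0, batch_sd, len(genes)) if batch_sd else np.zeros(len(genes)) for r in reps}
    strain_off = {s: rng.normal(0.0, strain_sd, len(genes)) if strain_sd else np.zeros(len(genes)) for s in strains}

    cols, names, rows = [], [], []
    for j, s in enumerate(design):
        name = f"{s.strain}_{s.replicate}_a{s.ave_budscars:g}_{j}"
        log2 = (
            intercepts.to_numpy()
            + slopes.to_numpy() * sfac.get(s.strain, 1.0) * s.ave_budscars
            + batch_off[s.replicate]
            + strain_off[s.strain]
        )
        if noise_sd:
            log2 = log2 + rng.normal(0.0, noise_sd, len(genes))
        cols.append(np.exp2(log2))
        names.append(name)
        rows.append((name, s.strain, s.replicate, s.ave_budscars))
    raw = pd.DataFrame(np.column_stack(cols), index=genes, columns=names)
    tpm = raw / raw.sum(axis=0) * 1e6
    des = pd.DataFrame(rows, columns=["sample", "strain", "replicate", "ave_budscars"])
    return ExpressionMatrix(tpm=tpm, raw=raw, design=des, true_slopes=slopes)
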