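"""Dead-cell (naked DNA) background: detection, correction, artifact curve.

DNA from membrane-compromised cells has lost its chromatin structure and
contributes a virtually uniform insertion signal.  Under fixed-total
normalization this background *competes* with real signal: for a dead
fragment fraction f, the expected normalized density at any addressable
position x is

    s_f(x) = (1 - f) * s0(x) + f * T / G

where s0 is the live-cell density, T the normalization target and G the
addressable (non-rDNA, non-mito) genome length.  Closed regions
(mid-gene bodies) have s0 ~ 0, so their mean density estimates the uniform
level u, and f_hat = u * G / T.

Experimentally the background is removed with PMA, which blocks
amplification of dead-cell DNA; ``apply_insilico_pma`` is the computational
analogue for labeled synthetic data, and ``deconvolve_track`` is the
computational analogue for unlabeled tracks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .genome import GenomeAnnotation
from .insertions import InsertionTrack, extract_insertions, normalize_track
from .nucleosome import (
    SizeDistribution,
    fit_size_components,
    occupancy_table,
    pooled_size_distribution,
)
from .simulate import AgingPopulationSpec, FragmentSizeModel, WeightConfig, simulate_atac_sample

__all__ = [
    "BackgroundModel",
    "apply_insilico_pma",
    "default_closed_regions",
    "estimate_background",
    "deconvolve_track",
    "artifact_curve",
]


@dataclass
class BackgroundModel:
    """Uniform background level and implied dead fraction.

    ``u`` is in normalized insertions per bp; ``f_hat`` in [0, 1];
    ``closed_bp`` is the total closed-region length used for estimation.
    """

    u: float
    f_hat: float
    closed_bp: int
    target_total: float
    addressable_length: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "BackgroundModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def apply_insilico_pma(fragments: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove dead-labeled fragments, mimicking PMA treatment.

    Returns ``(live_fragments, n_removed)``.  Requires the ``viability``
    column; unlabeled data should go through :func:`estimate_background`
    and :func:`deconvolve_track` instead.
    """
    if "viability" not in fragments.columns:
        raise ValueError(
            "fragments carry no viability labels; use estimate_background/"
            "deconvolve_track for unlabeled data"
        )
    keep = fragments["viability"] == "live"
    return fragments.loc[keep].reset_index(drop=True), int((~keep).sum())


def default_closed_regions(
    genome: GenomeAnnotation,
    min_body_length: int = 2000,
    central_fraction: float = 0.5,
) -> pd.DataFrame:
    """Mid-gene-body intervals: the central ``central_fraction`` of gene
    bodies longer than ``min_body_length``, minus NFR/open-chromatin
    overlap.  These are the canonically inaccessible parts of the genome
    used to read off the uniform background level."""
    rows = []
    opens = pd.concat([genome.nfr_intervals, genome.open_intervals], ignore_index=True)
    for g in genome.genes.itertuples(index=False):
        length = g.end - g.start
        if length < min_body_length:
            continue
        pad = int(length * (1 - central_fraction) / 2)
        s, e = g.start + pad, g.end - pad
        # clip out any open-chromatin overlap
        pieces = [(s, e)]
        for o in opens[opens.chrom == g.chrom].itertuples(index=False):
            nxt = []
            for ps, pe in pieces:
                if o.end <= ps or o.start >= pe:
                    nxt.append((ps, pe))
                else:
                    if ps < o.start:
                        nxt.append((ps, o.start))
                    if o.end < pe:
                        nxt.append((o.end, pe))
            pieces = nxt
        for ps, pe in pieces:
            if pe > ps:
                rows.append((g.chrom, ps, pe))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def estimate_background(
    track: InsertionTrack,
    closed_regions: pd.DataFrame,
    genome: GenomeAnnotation,
    min_closed_bp: int = 10_000,
) -> BackgroundModel:
    """Estimate the uniform background from closed-region density.

    ``u`` = mean normalized density over closed positions; ``f_hat`` =
    ``u * G / T`` clipped to [0, 1].  Residual live-cell insertions in
    closed regions bias f_hat upward slightly; the estimator deliberately
    ignores them.
    """
    if not track.normalized or track.target_total is None:
        raise ValueError("estimate_background requires a normalized track")
    if len(closed_regions) == 0:
        raise ValueError("empty closed-region set")
    total = 0.0
    bp = 0
    for r in closed_regions.itertuples(index=False):
        total += track.region_sum(r.chrom, int(r.start), int(r.end))
        bp += int(r.end) - int(r.start)
    if bp < min_closed_bp:
        raise ValueError(f"closed regions cover {bp} bp < required {min_closed_bp}")
    u = total / bp
    G = genome.addressable_length()
    f_hat = float(np.clip(u * G / track.target_total, 0.0, 1.0))
    return BackgroundModel(
        u=float(u),
        f_hat=f_hat,
        closed_bp=bp,
        target_total=float(track.target_total),
        addressable_length=G,
    )


def deconvolve_track(
    track: InsertionTrack,
    model: BackgroundModel,
    genome: GenomeAnnotation,
    smooth_bp: int = 147,
) -> InsertionTrack:
    """Subtract the uniform background and rescale.

    ``corrected(x) = max(0, density(x) - u) / (1 - f_hat)``, where
    ``density`` is the track averaged over a ``smooth_bp`` moving window
    (one nucleosome footprint by default).  Subtracting a fractional
    background directly from sparse per-bp integer counts would be
    floor-biased wherever counts are 0/1, so the subtraction operates on
    the local density.  The result is floored at zero and renormalized to
    the original target so downstream invariants hold; a fully dead
    mixture cannot be deconvolved.  With ``u = 0`` the track is returned
    unchanged (nothing to subtract).
    """
    if model.f_hat >= 1.0:
        raise ValueError("f_hat = 1: degenerate mixture, nothing to deconvolve")
    if not track.normalized:
        raise ValueError("deconvolve_track requires a normalized track")
    out = track.copy()
    if model.u == 0:
        return out
    for c in out.counts:
        dens = uniform_filter1d(out.counts[c], size=smooth_bp, mode="nearest")
        out.counts[c] = np.maximum(dens - model.u, 0.0) / (1.0 - model.f_hat)
    return normalize_track(out, genome, target_total=track.target_total)


def _mean_density(track: InsertionTrack, regions: pd.DataFrame) -> float:
    tot, bp = 0.0, 0
    for r in regions.itertuples(index=False):
        tot += track.region_sum(r.chrom, int(r.start), int(r.end))
        bp += int(r.end) - int(r.start)
    return tot / bp


def artifact_curve(
    genome: GenomeAnnotation,
    base_spec: AgingPopulationSpec,
    dead_fractions: list[float],
    n_fragments: int = 200_000,
    seed: int = 0,
    target_total: float = 1e6,
    window: int = 60,
    min_fragments: int = 20,
    split: int = 115,
    size_model: FragmentSizeModel | None = None,
    weights: WeightConfig | None = None,
) -> pd.DataFrame:
    """Apparent accessibility and occupancy versus dead fraction.

    For each dead fraction f the full chain is run twice: once on the mixed
    sample (no PMA) and once after in-silico PMA.  The PMA arm is simulated
    at depth ``n_fragments / (1 - f)`` before dead-fragment removal so both
    arms are compared at matched post-processing depth (the fixed-depth
    downsampling convention).  Mixture components for occupancy come from
    the pooled size distribution of the no-PMA series.

    Returns one row per f with closed-region and NFR densities and the
    median occupancy over reference dyads (score > 2, in open chromatin),
    with and without PMA.
    """
    for f in dead_fractions:
        if not 0.0 <= f < 1.0:
            raise ValueError("dead fractions must lie in [0, 1)")
    closed = default_closed_regions(genome)
    ref_dyads = select_open_dyads(genome)
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(2 * len(dead_fractions))

    samples = []
    for i, f in enumerate(dead_fractions):
        spec = AgingPopulationSpec(
            strain=base_spec.strain,
            dead_fraction=f,
            ave_budscars=base_spec.ave_budscars,
            rdna_fold=base_spec.rdna_fold,
            bin_slopes=base_spec.bin_slopes,
            replicate=base_spec.replicate,
            is_daughter=base_spec.is_daughter,
        )
        mixed = simulate_atac_sample(
            genome, spec, n_fragments, seed=int(child[2 * i].generate_state(1)[0] % 2**31),
            size_model=size_model, weights=weights,
        )
        n_pma = int(np.ceil(n_fragments / (1.0 - f))) if f > 0 else n_fragments
        pma_input = simulate_atac_sample(
            genome, spec, n_pma, seed=int(child[2 * i + 1].generate_state(1)[0] % 2**31),
            size_model=size_model, weights=weights,
        )
        pma, _ = apply_insilico_pma(pma_input)
        samples.append((f, mixed, pma))

    pooled = pooled_size_distribution([mixed for _, mixed, _ in samples])
    f_free, f_nuc = fit_size_components(pooled, split=split)

    rows = []
    for f, mixed, pma in samples:
        row = {"dead_fraction": f}
        for label, frags in [("nopma", mixed), ("pma", pma)]:
            tr = extract_insertions(frags, genome.chrom_lengths, sample_id=f"f{f}_{label}")
            norm = normalize_track(tr, genome, target_total=target_total)
            occ = occupancy_table(
                frags, ref_dyads, f_nuc, f_free, window=window, min_fragments=min_fragments
            )
            est = occ.loc[occ.ok, "theta"]
            row[f"closed_density_{label}"] = _mean_density(norm, closed)
            row[f"nfr_density_{label}"] = _mean_density(norm, genome.nfr_intervals)
            row[f"median_theta_{label}"] = float(est.median()) if len(est) else np.nan
            row[f"n_dyads_{label}"] = int(len(est))
        rows.append(row)
    return pd.DataFrame(rows)


def select_open_dyads(genome: GenomeAnnotation, score_cut: float = 2.0) -> pd.DataFrame:
    """Well-positioned dyads (score above cut) inside open-chromatin
    intervals; the dyad set occupancy comparisons are made on."""
    d = genome.dyads
    keep = d["score"] > score_cut
    in_open = np.zeros(len(d), dtype=bool)
    for chrom, sub in genome.open_intervals.groupby("chrom", sort=False):
        m = (d["chrom"] == chrom).to_numpy()
        pos = d.loc[m, "pos"].to_numpy()
        hit = np.zeros(len(pos), dtype=bool)
        for r in sub.itertuples(index=False):
            hit |= (pos >= r.start) & (pos < r.end)
        in_open[m] = hit
    return d.loc[keep.to_numpy() & in_open].reset_index(drop=True)
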