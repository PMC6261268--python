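"""Tn5 insertion tracks from aligned fragments.

Each sequenced ATAC fragment reports two transposition events.  The 5'
fragment end on the '+' strand is shifted +4 bp and the 5' end on the '-'
strand is shifted 5 bp in its 3' direction to land on the centers of the
two 9-bp transposase duplications.  On 0-based half-open fragment
coordinates ``[start, end)`` the two insertion points are therefore

    plus insertion  = start + 4
    minus insertion = (end - 1) - 5 = end - 6

The ``end - 6`` arithmetic is the single place where half-open coordinate
dialects differ by 1 bp; it is fixed here and used consistently.

Normalization scales every position (including rDNA and mito) by one global
factor chosen so that the summed insertions outside the rDNA and the
mitochondrial chromosome hit a fixed target, making samples with different
depth and different rDNA content comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation

__all__ = [
    "InsertionTrack",
    "extract_insertions",
    "normalize_track",
    "bin_counts",
    "make_bin_table",
]

PLUS_SHIFT = 4
MINUS_SHIFT = 6  # subtracted from the exclusive end coordinate


class NormalizationError(ValueError):
    pass


@dataclass
class InsertionTrack:
    """Per-base-pair insertion counts for one sample.

    ``counts`` maps chromosome -> float array (raw tracks hold integers
    stored as floats; normalized tracks are real-valued).  ``qc`` tallies
    dropped fragments by reason.
    """

    counts: dict[str, np.ndarray]
    sample_id: str = "sample"
    normalized: bool = False
    target_total: float | None = None
    qc: dict[str, int] = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(a.sum() for a in self.counts.values()))

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        return float(self.counts[chrom][start:end].sum())

    def nonexcluded_total(self, genome: GenomeAnnotation) -> float:
        tot = 0.0
        for chrom, arr in self.counts.items():
            if chrom == genome.mito_chrom:
                continue
            s = arr.sum()
            if chrom == genome.rdna_chrom:
                rs, re = genome.rdna_interval
                s -= arr[rs:re].sum()
            tot += s
        return float(tot)

    def copy(self) -> "InsertionTrack":
        return InsertionTrack(
            counts={c: a.copy() for c, a in self.counts.items()},
            sample_id=self.sample_id,
            normalized=self.normalized,
            target_total=self.target_total,
            qc=dict(self.qc),
        )


def extract_insertions(
    fragments: pd.DataFrame,
    chrom_lengths: dict[str, int],
    min_mapq: int = 30,
    require_fr: bool = True,
    sample_id: str = "sample",
) -> InsertionTrack:
    """Convert a fragment table to a raw per-bp insertion track.

    Fragments with ``mapq < min_mapq`` or (if ``require_fr``) an invalid
    first-mate strand are dropped and tallied; so are fragments whose
    shifted insertion coordinates fall outside the chromosome.  Every
    passing fragment contributes exactly two insertions.
    """
    counts = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    qc = {"n_input": len(fragments), "low_mapq": 0, "bad_orientation": 0, "out_of_bounds": 0, "passed": 0}
    if len(fragments) == 0:
        return InsertionTrack(counts=counts, sample_id=sample_id, qc=qc)

    keep = fragments["mapq"].to_numpy() >= min_mapq
    qc["low_mapq"] = int((~keep).sum())
    if require_fr:
        orient_ok = fragments["first_mate_strand"].isin(["+", "-"]).to_numpy()
        qc["bad_orientation"] = int((keep & ~orient_ok).sum())
        keep &= orient_ok
    sub = fragments.loc[keep]

    for chrom, grp in sub.groupby("chrom", sort=False):
        n = chrom_lengths[chrom]
        plus = grp["start"].to_numpy() + PLUS_SHIFT
        minus = grp["end"].to_numpy() - MINUS_SHIFT
        ok = (plus >= 0) & (plus < n) & (minus >= 0) & (minus < n)
        qc["out_of_bounds"] += int((~ok).sum())
        np.add.at(counts[chrom], plus[ok], 1.0)
        np.add.at(counts[chrom], minus[ok], 1.0)
        qc["passed"] += int(ok.sum())
    return InsertionTrack(counts=counts, sample_id=sample_id, qc=qc)


def normalize_track(
    track: InsertionTrack, genome: GenomeAnnotation, target_total: float = 1e6
) -> InsertionTrack:
    """Scale a track so non-rDNA, non-mito insertions sum to ``target_total``.

    The scale factor is global: rDNA and mito positions are excluded from
    the denominator but are themselves rescaled by the same factor.
    """
    denom = track.nonexcluded_total(genome)
    if denom <= 0:
        raise NormalizationError("track has no insertions outside rDNA and mito")
    factor = target_total / denom
    out = track.copy()
    for c in out.counts:
        out.counts[c] *= factor
    out.normalized = True
    out.target_total = float(target_total)
    return out


def bin_counts(track: InsertionTrack, width: int = 100) -> pd.DataFrame:
    """Sum insertions into non-overlapping genome-tiling bins.

    Bins start at coordinate 0 of each chromosome; a trailing partial bin is
    retained and flagged.  Returns columns ``chrom, start, end, partial,
    count``; binning conserves the track total.
    """
    if width < 1:
        raise ValueError("bin width must be >= 1")
    rows = []
    for chrom, arr in track.counts.items():
        n = len(arr)
        edges = np.arange(0, n, width)
        sums = np.add.reduceat(arr, edges)
        ends = np.minimum(edges + width, n)
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": edges, "end": ends, "partial": ends - edges < width, "count": sums}
            )
        )
    return pd.concat(rows, ignore_index=True)


def make_bin_table(tracks: list[InsertionTrack], width: int = 100) -> pd.DataFrame:
    """Bin several samples into one bins x samples count matrix.

    The index is ``chrom:start-end``; column order follows the input.  For
    differential accessibility, feed *raw* tracks so that counts stay
    integer-valued.
    """
    cols = {}
    index = None
    for tr in tracks:
        b = bin_counts(tr, width=width)
        idx = b["chrom"].astype(str) + ":" + b["start"].astype(str) + "-" + b["end"].astype(str)
        if index is None:
            index = idx
        cols[tr.sample_id] = b["count"].to_numpy()
    return pd.DataFrame(cols, index=index)
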