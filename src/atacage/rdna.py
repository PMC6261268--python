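"""rDNA insertional density and copy-number comparison.

The tandemly repeated rDNA locus collapses onto a single represented unit
under unique mapping, so its insertion share reports on copy number as
well as accessibility.  The headline quantity is the percent insertional
density relative to the non-repetitive genome,

    100 * (insertions in rDNA) / (insertions outside rDNA, mito and
                                  annotated repeats)

which is invariant to the fixed-total normalization (the scale factor
cancels), and is compared across ages and strains with copy-number truth
(generator-supplied in synthetic mode, or a qPCR-style relative-copies
table in real mode) to separate accessibility from ERC-driven copy
expansion.  Daughters of old mothers do not inherit ERCs, so their density
returns to the young baseline (asymmetric retention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation
from .insertions import InsertionTrack

__all__ = ["rdna_relative_density", "density_vs_copy_number"]


def rdna_relative_density(
    track: InsertionTrack,
    genome: GenomeAnnotation,
    repeat_intervals: pd.DataFrame | None = None,
) -> float:
    """Percent rDNA insertional density relative to the non-repetitive
    genome.  ``repeat_intervals`` (chrom, start, end) may flag additional
    repeats to exclude from the denominator.  Works identically on raw and
    normalized tracks."""
    rs, re = genome.rdna_interval
    rdna = track.region_sum(genome.rdna_chrom, rs, re)
    denom = track.nonexcluded_total(genome)
    if repeat_intervals is not None:
        for r in repeat_intervals.itertuples(index=False):
            if r.chrom != genome.mito_chrom:
                denom -= track.region_sum(r.chrom, int(r.start), int(r.end))
    if denom <= 0:
        raise ValueError("no insertions in the non-repetitive genome")
    return 100.0 * rdna / denom


def density_vs_copy_number(summaries: pd.DataFrame) -> pd.DataFrame:
    """Fold changes of rDNA density and copy number versus each strain's
    youngest mother sample.

    ``summaries`` needs columns ``sample, strain, ave_budscars,
    is_daughter, percent_density, rel_copy_number``.  Within each strain
    the reference is the youngest mother sample; daughter rows are compared
    against that same young-mother baseline.  Returns the input plus
    ``density_fold`` and ``copy_fold`` columns.
    """
    req = {"sample", "strain", "ave_budscars", "is_daughter", "percent_density", "rel_copy_number"}
    missing = req - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns: {sorted(missing)}")
    out = summaries.copy()
    out["density_fold"] = np.nan
    out["copy_fold"] = np.nan
    for strain, grp in out.groupby("strain", sort=False):
        mothers = grp[~grp["is_daughter"].astype(bool)]
        if len(mothers) == 0:
            raise ValueError(f"strain {strain!r} has no mother reference sample")
        ref = mothers.loc[mothers["ave_budscars"].idxmin()]
        out.loc[grp.index, "density_fold"] = grp["percent_density"] / ref["percent_density"]
        out.loc[grp.index, "copy_fold"] = grp["rel_copy_number"] / ref["rel_copy_number"]
    return out
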