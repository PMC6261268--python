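"""Plain-text readers and writers.

Fragments travel as BED-like TSV (chrom, start, end, name=cell_id,
score=mapq, strand, viability); tracks as bedGraph; the genome as a JSON
manifest plus per-feature BED/TSV files; bins, factors, expression and
result tables as TSV.  All coordinates on disk are 0-based half-open, the
BED convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation
from .insertions import InsertionTrack

FRAGMENT_COLUMNS = ["chrom", "start", "end", "cell_id", "mapq", "first_mate_strand", "viability"]


def write_fragments(fragments: pd.DataFrame, path) -> None:
    fragments[FRAGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_fragments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=FRAGMENT_COLUMNS)
    return df


def write_bedgraph(track: InsertionTrack, path) -> None:
    """Sparse bedGraph: runs of equal nonzero value become one record."""
    with open(path, "w") as fh:
        for chrom, arr in track.counts.items():
            nz = np.flatnonzero(arr)
            if len(nz) == 0:
                continue
            start = nz[0]
            val = arr[start]
            prev = start
            for p in nz[1:]:
                if p == prev + 1 and arr[p] == val:
                    prev = p
                    continue
                fh.write(f"{chrom}\t{start}\t{prev + 1}\t{val:g}\n")
                start, prev, val = p, p, arr[p]
            fh.write(f"{chrom}\t{start}\t{prev + 1}\t{val:g}\n")


def read_bedgraph(path, chrom_lengths: dict[str, int], sample_id: str = "sample") -> InsertionTrack:
    counts = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    for r in df.itertuples(index=False):
        counts[r.chrom][int(r.start) : int(r.end)] = r.value
    return InsertionTrack(counts=counts, sample_id=sample_id)


def write_genome(genome: GenomeAnnotation, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "chrom_lengths": genome.chrom_lengths,
        "rdna_chrom": genome.rdna_chrom,
        "rdna_interval": list(genome.rdna_interval),
        "rdna_base_copies": genome.rdna_base_copies,
        "mito_chrom": genome.mito_chrom,
        "telomere_positions": {c: list(v) for c, v in genome.telomere_positions.items()},
    }
    (out / "genome.json").write_text(json.dumps(manifest, indent=1))
    genome.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    genome.dyads.to_csv(out / "dyads.tsv", sep="\t", index=False)
    for name, df in [
        ("nfr", genome.nfr_intervals),
        ("open", genome.open_intervals),
        ("ars", genome.ars_intervals),
    ]:
        df.to_csv(out / f"{name}.bed", sep="\t", header=False, index=False)


def read_genome(indir) -> GenomeAnnotation:
    ind = Path(indir)
    manifest = json.loads((ind / "genome.json").read_text())
    beds = {}
    for name in ["nfr", "open", "ars"]:
        p = ind / f"{name}.bed"
        if p.stat().st_size:
            beds[name] = pd.read_csv(p, sep="\t", header=None, names=["chrom", "start", "end"])
        else:
            beds[name] = pd.DataFrame(columns=["chrom", "start", "end"])
    return GenomeAnnotation(
        chrom_lengths=manifest["chrom_lengths"],
        genes=pd.read_csv(ind / "genes.tsv", sep="\t"),
        dyads=pd.read_csv(ind / "dyads.tsv", sep="\t"),
        nfr_intervals=beds["nfr"],
        open_intervals=beds["open"],
        ars_intervals=beds["ars"],
        rdna_chrom=manifest["rdna_chrom"],
        rdna_interval=tuple(manifest["rdna_interval"]),
        rdna_base_copies=manifest["rdna_base_copies"],
        mito_chrom=manifest["mito_chrom"],
        telomere_positions={c: tuple(v) for c, v in manifest["telomere_positions"].items()},
    )


def write_sample_sheet(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_set(path) -> set:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def read_grs(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "grs"])
    return df.set_index("gene_id")["grs"]
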