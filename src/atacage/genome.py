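"""Synthetic yeast-like genome annotation.

Builds a desk-scale genome that carries the annotation classes the aging
analyses need: genes with TSSs and bodies, regularly spaced nucleosome dyads
with positioning scores, nucleosome-free regions (NFRs) and open-chromatin
intervals at promoters, replication origins (ARS), a single rDNA repeat unit
whose copy number is a sampling weight, and a mitochondrial chromosome.

All coordinates are 0-based, half-open throughout the package.  Use
:func:`to_one_based` / :func:`from_one_based` when exchanging coordinates
with 1-based, closed-interval conventions (GFF, SGD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeConfig",
    "GenomeAnnotation",
    "build_genome",
    "to_one_based",
    "from_one_based",
]


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based closed coordinates."""
    return start + 1, end


def from_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based closed interval to 0-based half-open coordinates."""
    return start - 1, end


class GenomeConfigError(ValueError):
    """Raised when mandatory genome features cannot be placed."""


@dataclass
class GenomeConfig:
    """Parameters of the synthetic genome.

    The defaults describe a desk-scale caricature of the budding-yeast
    genome: three 200-kb nuclear chromosomes, an 80-kb mitochondrial
    chromosome, and one 9-kb rDNA repeat unit on the last nuclear chromosome
    represented once and weighted by copy number (multi-mapping collapses the
    tandem repeat onto a single unit, so copy number acts as a sampling
    weight, not as sequence).  The budding-yeast rDNA locus carries roughly
    100-200 tandem copies; the default base copy number is 150.
    """

    n_nuclear: int = 3
    nuclear_length: int = 200_000
    mito_length: int = 80_000
    genes_per_chrom: int = 50
    nucs_per_gene: int = 13
    nfr_length: int = 200
    first_dyad_offset: int = 80  # TSS to +1 dyad
    spacing_mean: float = 165.0  # nucleosome repeat length
    spacing_sd: float = 12.0
    min_spacing: int = 150
    max_spacing: int = 200
    protect_halfwidth: int = 70  # nucleosomal protection, dyad +/- 70 bp
    open_nucs: int = 3  # promoter-proximal nucleosomes inside "open" chromatin
    telomere_buffer: int = 2_000
    gap_min: int = 400
    gap_max: int = 900
    rdna_length: int = 9_000
    rdna_base_copies: int = 150
    rdna_buffer: int = 12_000  # gene-free zone around the rDNA
    ars_per_chrom: int = 2
    ars_length: int = 300
    score_max: float = 5.0  # positioning scores drawn uniformly on [0, score_max]

    def validate(self) -> None:
        if self.n_nuclear < 1 or self.nuclear_length <= 0 or self.mito_length <= 0:
            raise GenomeConfigError("chromosome counts and lengths must be positive")
        if self.min_spacing < 147:
            raise GenomeConfigError(
                "nucleosome spacing must be at least 147 bp (one nucleosome footprint)"
            )
        if self.genes_per_chrom < 0 or self.nucs_per_gene < 0:
            raise GenomeConfigError("gene and nucleosome counts must be non-negative")
        if self.rdna_length + 2 * self.rdna_buffer + 2 * self.telomere_buffer >= self.nuclear_length:
            raise GenomeConfigError("rDNA region does not fit on its chromosome")


@dataclass
class GenomeAnnotation:
    """Container for all annotation tracks used by the analyses.

    Attributes
    ----------
    chrom_lengths : dict
        Chromosome name -> length in bp.
    genes : pandas.DataFrame
        Columns ``gene_id, chrom, strand, tss, start, end`` (body interval).
    dyads : pandas.DataFrame
        Columns ``chrom, pos, score, gene_id, rank`` where ``rank`` counts
        nucleosomes from the TSS (+1 nucleosome has rank 1).
    nfr_intervals, open_intervals, ars_intervals : pandas.DataFrame
        Columns ``chrom, start, end``.
    rdna_chrom, rdna_interval : str, (int, int)
        Location of the single represented rDNA unit.
    rdna_base_copies : int
        Genomic copy number represented by the unit at baseline.
    mito_chrom : str
    telomere_positions : dict
        Chromosome -> (left end, right end) coordinates, nuclear only.
    """

    chrom_lengths: dict[str, int]
    genes: pd.DataFrame
    dyads: pd.DataFrame
    nfr_intervals: pd.DataFrame
    open_intervals: pd.DataFrame
    ars_intervals: pd.DataFrame
    rdna_chrom: str
    rdna_interval: tuple[int, int]
    rdna_base_copies: int
    mito_chrom: str
    telomere_positions: dict[str, tuple[int, int]] = field(default_factory=dict)

    # -- coordinate helpers ------------------------------------------------
    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def nuclear_chroms(self) -> list[str]:
        return [c for c in self.chrom_lengths if c != self.mito_chrom]

    def chrom_offsets(self) -> dict[str, int]:
        """Offset of each chromosome in the concatenated genome."""
        out, cum = {}, 0
        for c, n in self.chrom_lengths.items():
            out[c] = cum
            cum += n
        return out

    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def addressable_length(self) -> int:
        """Length of the non-repetitive genome: everything outside the rDNA
        unit and the mitochondrial chromosome."""
        s, e = self.rdna_interval
        return self.total_length() - self.chrom_lengths[self.mito_chrom] - (e - s)

    def excluded_mask(self, chrom: str) -> np.ndarray | None:
        """Boolean mask of rDNA/mito positions, or None if the chromosome has
        none (saves allocating masks for plain chromosomes)."""
        n = self.chrom_lengths[chrom]
        if chrom == self.mito_chrom:
            return np.ones(n, dtype=bool)
        if chrom == self.rdna_chrom:
            m = np.zeros(n, dtype=bool)
            s, e = self.rdna_interval
            m[s:e] = True
            return m
        return None

    def validate(self) -> None:
        for df, what in [
            (self.nfr_intervals, "NFR"),
            (self.open_intervals, "open"),
            (self.ars_intervals, "ARS"),
        ]:
            for _, r in df.iterrows():
                if not (0 <= r.start < r.end <= self.chrom_lengths[r.chrom]):
                    raise GenomeConfigError(f"{what} interval out of bounds: {tuple(r)}")
        for _, g in self.genes.iterrows():
            if not (0 <= g.start < g.end <= self.chrom_lengths[g.chrom]):
                raise GenomeConfigError(f"gene out of bounds: {g.gene_id}")
        if len(self.dyads):
            for chrom, sub in self.dyads.groupby("chrom", sort=False):
                pos = np.sort(sub["pos"].to_numpy())
                if len(pos) > 1 and np.min(np.diff(pos)) < 147:
                    raise GenomeConfigError("dyads closer than minimum spacing")
        s, e = self.rdna_interval
        on_rdna = self.genes[self.genes.chrom == self.rdna_chrom]
        if ((on_rdna.start < e) & (on_rdna.end > s)).any():
            raise GenomeConfigError("gene bodies overlap the rDNA interval")


def _place_genes(
    cfg: GenomeConfig,
    chrom: str,
    length: int,
    region: tuple[int, int],
    rng: np.random.Generator,
    gene_counter: int,
) -> tuple[list, list, list, list, int]:
    """Tile genes into ``region`` of one chromosome.

    Each gene (plus-strand layout) is: [NFR (nfr_length bp)][TSS ... body].
    Dyads sit at tss + first_dyad_offset + cumulative jittered spacings.
    Minus-strand genes are mirror images.  Raises if the requested number of
    genes does not fit.
    """
    genes, dyads, nfrs, opens = [], [], [], []
    lo, hi = region
    cursor = lo
    for _ in range(cfg.genes_per_chrom):
        gap = int(rng.integers(cfg.gap_min, cfg.gap_max + 1))
        spacings = np.clip(
            np.rint(rng.normal(cfg.spacing_mean, cfg.spacing_sd, max(cfg.nucs_per_gene - 1, 0))),
            cfg.min_spacing,
            cfg.max_spacing,
        ).astype(int)
        body_len = (
            cfg.first_dyad_offset + int(spacings.sum()) + cfg.protect_halfwidth
            if cfg.nucs_per_gene > 0
            else 500
        )
        footprint = cfg.nfr_length + body_len
        start = cursor + gap
        if start + footprint > hi:
            raise GenomeConfigError(
                f"cannot place {cfg.genes_per_chrom} genes on {chrom}: ran out of room"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene_{gene_counter:04d}"
        if strand == "+":
            nfr = (start, start + cfg.nfr_length)
            tss = start + cfg.nfr_length
            body = (tss, tss + body_len)
            dpos = tss + cfg.first_dyad_offset + np.concatenate([[0], np.cumsum(spacings)])
        else:
            body = (start, start + body_len)
            tss = start + body_len - 1
            nfr = (start + body_len, start + body_len + cfg.nfr_length)
            dpos = tss - cfg.first_dyad_offset - np.concatenate([[0], np.cumsum(spacings)])
        if cfg.nucs_per_gene == 0:
            dpos = np.array([], dtype=int)
        scores = rng.uniform(0.0, cfg.score_max, len(dpos))
        for k, (p, sc) in enumerate(zip(dpos, scores), start=1):
            dyads.append((chrom, int(p), float(sc), gid, k))
        # open chromatin: NFR plus the first `open_nucs` nucleosomes
        n_open = min(cfg.open_nucs, len(dpos))
        if n_open:
            if strand == "+":
                open_iv = (nfr[0], int(dpos[n_open - 1]) + cfg.protect_halfwidth)
            else:
                open_iv = (int(dpos[n_open - 1]) - cfg.protect_halfwidth, nfr[1])
        else:
            open_iv = nfr
        genes.append((gid, chrom, strand, int(tss), int(body[0]), int(body[1])))
        nfrs.append((chrom, int(nfr[0]), int(nfr[1])))
        opens.append((chrom, int(open_iv[0]), int(open_iv[1])))
        cursor = start + footprint
        gene_counter += 1
    return genes, dyads, nfrs, opens, gene_counter


def build_genome(config: GenomeConfig | None = None, seed: int = 0) -> GenomeAnnotation:
    """Construct a synthetic genome annotation, deterministic per seed."""
    cfg = config or GenomeConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    chrom_lengths: dict[str, int] = {}
    nuclear = [f"chr{'I' * (i + 1)}" for i in range(cfg.n_nuclear)]
    for c in nuclear:
        chrom_lengths[c] = cfg.nuclear_length
    mito = "chrM"
    chrom_lengths[mito] = cfg.mito_length

    rdna_chrom = nuclear[-1]
    rdna_start = cfg.nuclear_length - cfg.telomere_buffer - cfg.rdna_buffer - cfg.rdna_length
    rdna_interval = (rdna_start, rdna_start + cfg.rdna_length)

    genes, dyads, nfrs, opens, ars = [], [], [], [], []
    counter = 0
    for c in nuclear:
        hi = cfg.nuclear_length - cfg.telomere_buffer
        if c == rdna_chrom:
            hi = rdna_start - cfg.rdna_buffer
        g, d, nf, op, counter = _place_genes(
            cfg, c, cfg.nuclear_length, (cfg.telomere_buffer, hi), rng, counter
        )
        genes += g
        dyads += d
        nfrs += nf
        opens += op
        # ARS elements sit in intergenic gaps between evenly spaced gene pairs
        if cfg.ars_per_chrom and len(g) >= cfg.ars_per_chrom + 1:
            idx = np.linspace(1, len(g) - 1, cfg.ars_per_chrom).astype(int)
            for i in idx:
                prev_end = max(g[i - 1][4], g[i - 1][5])
                next_start = min(g[i][4], g[i][5]) - cfg.nfr_length
                mid = (prev_end + next_start) // 2
                s = max(prev_end + 10, mid - cfg.ars_length // 2)
                ars.append((c, int(s), int(s + cfg.ars_length)))

    genome = GenomeAnnotation(
        chrom_lengths=chrom_lengths,
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "strand", "tss", "start", "end"]),
        dyads=pd.DataFrame(dyads, columns=["chrom", "pos", "score", "gene_id", "rank"]),
        nfr_intervals=pd.DataFrame(nfrs, columns=["chrom", "start", "end"]),
        open_intervals=pd.DataFrame(opens, columns=["chrom", "start", "end"]),
        ars_intervals=pd.DataFrame(ars, columns=["chrom", "start", "end"]),
        rdna_chrom=rdna_chrom,
        rdna_interval=rdna_interval,
        rdna_base_copies=cfg.rdna_base_copies,
        mito_chrom=mito,
        telomere_positions={c: (0, chrom_lengths[c]) for c in nuclear},
    )
    genome.validate()
    return genome
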