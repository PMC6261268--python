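# Methods

This note documents the models, defaults, and numerical choices behind
`atacage`, and what the synthetic-data tests do and do not establish about
real data.

## Coordinates and insertion arithmetic

All coordinates are 0-based, half-open; `atacage.genome.to_one_based` /
`from_one_based` convert at the boundary with 1-based closed conventions.
A fragment `[start, end)` contributes insertions at `start + 4` and
`end − 6`.  The minus-end value is the 5′ base of the minus-strand read
(`end − 1`) shifted 5 bp in its 3′ direction; half-open dialects differ by
1 bp exactly here, so the package fixes `end − 6` once and uses it
everywhere (extraction, and in reverse when the generator emits fragment
coordinates from simulated cut sites).  Insertions whose shifted
coordinate leaves the chromosome drop the whole fragment, tallied in QC.

Fragment *centers* (`floor((start + end − 1)/2)`), not insertion points,
associate fragments to dyads for occupancy estimation: occupancy is a
statement about what the fragment spans, accessibility about where the
transposase cut.

## The synthetic genome and fragment model

The default genome is a desk-scale caricature: 3 nuclear chromosomes of
200 kb, an 80-kb mitochondrial chromosome, and one 9-kb rDNA unit on the
last nuclear chromosome.  The tandem rDNA repeat is represented once and
its copy number (default 150, inside the ~100–200 range characteristic of
the locus) acts as a sampling weight — the choice a unique-mapping
pipeline forces, since multi-mapping collapses the repeats.  Each
chromosome carries 50 genes: a 200-bp NFR, then a 13-nucleosome array with
jittered spacing ~N(165, 12²) clipped to [150, 200] bp and positioning
scores uniform on [0, 5].  Open-chromatin intervals span the NFR plus the
first three nucleosomes.  Two 300-bp ARS elements per chromosome sit in
intergenic gaps.

Live-cell insertion weights per bp: intergenic 1.0, NFR 8.0,
promoter-proximal linkers 12.0, deep gene-body linkers 0.15, dyad ± 70 bp
0.02, mito 1.0, rDNA 0.004 per copy.  The real insertion-rate landscape is
not known at this level of detail; this weight scheme is a stand-in with
the features the analyses rely on.  Two of the numbers are deliberate
desk-scale calibrations, fixed at design time from expectation
calculations rather than from data: promoter-proximal linkers are the
hottest class so that reference dyads collect ≈25–30 fragment centers at
the default depth of 2×10⁵ fragments (the occupancy estimator's
`min_fragments=20` default then mostly succeeds), and the rDNA per-copy
weight puts the young-cell rDNA insertion share at ~4% of the
non-repetitive genome, a single-digit share as in real young samples.

A fragment is generated by drawing its first cut site from the weight
density, a size from the size model, a random orientation, and accepting
the implied second cut site with probability `w(p2)/max(w)`; reported
fragment coordinates then back the cut sites off by the +4/−5 offsets so
extraction recovers them exactly.  Pair acceptance makes nucleosome-
spanning fragments emerge naturally (both ends must land in linkers).  Two
consequences are worth noting: realized densities in cold regions scale
roughly like the *square* of the weight (both ends are penalized), and a
per-bin aging factor `exp(β·age)` on the weights produces a realized
per-bin log-slope somewhat above β (empirically ≈1.2×β for hot bins).
Recovery tests on the full chain therefore assert *correlation* with
truth, while statistical-calibration tests simulate counts directly from
the regression model.  Within the rDNA unit the second end is always
accepted (a collapsed repeat has no protection structure), which keeps the
rDNA insertion rate exactly linear in copy number — the property the
copy-number analyses measure.  Daughter samples reset `rdna_fold` to 1:
ERCs are retained by the mother.

Fragment sizes: sub-nucleosomal = discretized gamma(shape 6, scale 12)
(mode ≈60 bp) on [20, 160]; nucleosomal = discretized N(147, 15²)
truncated to [100, 250]; live cells mix them 40/60, dead cells 50/50.
Dead-cell cut sites are uniform per bp (rDNA again weighted by copy
number), since naked DNA has no footprint structure.  Every stochastic
operation takes an explicit seed; there is no global random state.

## Fixed-total normalization and the dead-cell mixture

Each sample is scaled by one global factor so that insertions outside the
rDNA and the mitochondrial genome sum to a fixed target (default 10⁶ at
desk scale; real pipelines use depths of ≥25 million fragments per
sample, and the occupancy module's `downsample_fragments` exists to equalize
depth first).  The factor is applied to rDNA/mito positions too; they are
only excluded from the denominator.

Under this normalization a dead fragment fraction *f* gives expected
density `(1−f)·s₀(x) + f·T/G` at every addressable position (G =
addressable genome length).  The background estimator reads the uniform
level *u* off closed regions — operationalized as the central 50% of gene
bodies longer than 2 kb minus any NFR/open overlap — and reports
`f̂ = u·G/T` clipped to [0, 1].  Residual live-cell insertions in closed
regions bias f̂ upward; with the default weights this leakage is <1% of
the genome-mean density, and the generator-truth test requires
|f̂ − f| < 0.05 at f = 0.3.

Deconvolution computes `max(0, density − u)/(1 − f̂)` and renormalizes.
The subtraction operates on a 147-bp moving-average density, not on raw
per-bp counts: at finite depth per-bp counts are 0/1-sparse, and flooring
`count − u` at zero would systematically *add* mass wherever counts are
zero, defeating the correction precisely in the protected regions it is
meant to restore.  One nucleosome footprint is the natural smoothing
scale.  With `u = 0` the track is returned unchanged.

In-silico PMA simply removes dead-labeled fragments — the computational
analogue of PMA treatment, which blocks amplification of DNA in
membrane-compromised cells.  The artifact curve runs the full
simulate → extract → normalize → occupancy chain across a series of dead
fractions, with the PMA arm simulated at depth n/(1−f) before removal so
both arms are compared at matched depth (the fixed-depth downsampling
convention).

## Occupancy estimation

The pooled fragment-size distribution averages per-sample empirical
distributions with equal weight (a depth-weighted average is a
configuration choice, not the default) and is split at 115 bp into
nucleosome-free and nucleosomal components; neither the split nor the
60-bp association window is canonical, and both are exposed as
parameters.  θ̂ maximizes the two-component mixture log-likelihood over a
10⁻³ grid followed by bounded local refinement; boundary optima are
returned as 0 or 1, and dyads with fewer than `min_fragments` (20)
associated centers are flagged missing rather than failing.  Reference
nucleosomes are those with positioning score > 2, inside open chromatin,
with median occupancy ≥ 0.5 across samples.

This estimator is deliberately self-contained: it reproduces the
qualitative behavior of full ATAC nucleosome callers (monotone response to
nucleosomal-fragment enrichment; flat occupancy with age once dead
fragments are removed) but no numerical equivalence with any external
caller is claimed.  On the default genome nucleosomes are fully occupied,
so live-only estimates sit at the θ = 1 boundary; the informative signal
is the *decline* of apparent occupancy with the dead fraction and its
disappearance under in-silico PMA.

## Differential accessibility and expression slopes

Bin counts (non-overlapping 100-bp tiling bins, raw integer counts) are
modeled per bin as negative binomial with log link, design
`~ replicate + strain + ave_budscars` (common) or
`+ strain:ave_budscars` (interaction, giving per-strain slopes), and
offsets `log(factor)` from quantile normalization: each sample is
quantile-normalized against the across-sample mean order-statistic
reference (ties averaged), and `factor = raw/Q` where `Q > 0`, else 1.
Dispersion is estimated per bin by method of moments — the α at which the
Pearson statistic equals the residual degrees of freedom — floored at
10⁻⁸, with no shrinkage trend across bins (a documented simplification of
shrinkage-based count pipelines).  Coefficients come from IRLS
(statsmodels GLM).

Wald statistics are referred to a **t distribution with residual degrees
of freedom**, not the normal.  At a dozen samples and ~5 coefficients the
normal reference is visibly anti-conservative (empirical type-I ≈ 0.074
at nominal 0.05 in the package's own calibration simulations); with the t
reference the same simulations give type-I ≈ 0.050 and 95%-interval
coverage ≈ 0.95.  All-zero bins are skipped and flagged; BH q-values are
computed over tested bins only.  A singular design raises an error naming
the collinear columns.

Expression slopes use OLS of log₂(TPM + 0.5) on the same designs,
vectorized across genes; the 0.5 pseudocount is a configurable choice (the
field uses various values; 2 TPM appears in batch-correction contexts).
Replacing a count-error model with OLS on log TPM is a simplification
whose adequacy the recovery tests establish: ≥90% nominal-95% coverage of
simulated slopes and bias < 0.005 under ±1 log₂-unit batch offsets.
Because TPM columns are renormalized to 10⁶, slopes are identifiable only
relative to the compositional total; simulations therefore balance signal
genes so the total stays ~constant, and real-data interpretation carries
the same caveat.

Aging slopes are *per bud scar* (per cell division): doubling all ages
halves β̂ exactly, which a unit test pins.

Bin classification precedence is ARS > promoter (≤400 bp upstream of the
TSS, strand-aware) > gene body > other, with 1-bp overlap sufficing.  Two
significance presets exist in the literature of this analysis style
(q < 10⁻⁶ for calling changing bins, q < 10⁻³ for summarizing fractions);
`q_cut` is exposed and defaults to 10⁻⁶.  Enrichment is an upper-tail
hypergeometric test over a universe of genes with ≥1 tested bin.

## Expression comparisons

Clustering: average linkage on 1 − uncentered Pearson correlation
(= cosine distance), zero-norm rows excluded with a warning, ties broken
deterministically by input order; equivalence with exhaustive
agglomeration is asserted for ≤6 rows.  Moving averages are centered with
shrinking edges, NaNs excluded per window, window default 100 genes; a
window longer than the vector collapses to the global mean.  The GRS
comparison reports Pearson r between aging slopes and growth-rate slopes
and defines the stress-independent set as significant agers (q < 0.05)
with |GRS| below a bound (default 5; 4 is the other preset in circulation).
Telomere distance = min(TSS, chromosome length − TSS), summarized as
median and IQR of slopes in log-spaced distance bins.

## rDNA quantification

Percent relative density = 100 × (rDNA insertions)/(insertions outside
rDNA, mito, and flagged repeats).  The ratio cancels the normalization
factor, so raw and normalized tracks give identical values (asserted
algebraically) — which also renders moot the question of which to use.
Fold tables compare each sample against its strain's youngest mother;
daughters are compared against the same young-mother baseline.  Copy
number ground truth comes from the generator in synthetic mode; in real
mode a two-column relative-copies table (normalized to a single-copy
reference such as ACT1) is accepted verbatim — qPCR curve fitting is out
of scope.  Whether density fold tracks copy fold or lags it depends on
whether per-copy accessibility is held constant or reduced with age; both
regimes are reachable through generator parameters, and only the
constant-accessibility regime is asserted quantitatively (folds within
15%).

## Problem sizes and determinism

Default simulations use 2×10⁵ fragments per sample and the 680-kb
genome, keeping the full pipeline and test suite in the minutes range;
these sizes are the package's desk-scale study conditions, not tuning
knobs.  Calibration tests use 500 replicate fits and 2000 null features.
All randomness flows from explicit seeds through `numpy` generators;
identical seeds give byte-identical outputs.

## What the synthetic tests do not show

The generator emulates the *statistical structure* the analyses assume —
protection footprints, uniform dead background, exponential per-division
trends, copy-number-weighted rDNA — not real chromatin.  It has no
sequence (no FASTQ, no Tn5 sequence bias, no PCR duplicates), no ploidy,
no partially occupied or fuzzy nucleosomes, no transcription-coupled
accessibility, and its "open chromatin" annotation is a generator label
rather than an empirical call.  Passing tests therefore certify the
correctness and calibration of the *machinery* on data satisfying its
assumptions, and the internal consistency of the dead-cell mixture
arithmetic; they do not certify that real aged-yeast libraries satisfy
those assumptions.
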