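# Methods

This note documents the models, parameter choices and numerical conventions
behind `rockroi`, and what the synthetic-data tests do and do not establish
about real data.

## Barcode model and demultiplexing

Read 1 is parsed purely structurally. WTA reads follow
`prepend-N{9}-GTGA-N{9}-GACA-N{9}-UMI` with the prepend drawn from
{none, T, GT, TCA}; TSO reads follow `N{9}-AATG-N{9}-CCAC-N{9}-UMI`. The
parser requires both 4-nt linkers of a modality to match exactly at the
offsets implied by some prepend; prepends are trialled shortest-first and
the first structural match wins (a tie across offsets would require both
linkers to recur at a shifted position, which is vanishingly rare). A read
matching both modality structures, or neither, is unassigned; too-short
reads are unassigned rather than errors. `N` never matches a linker or a
whitelist base. The UMI is the 8 nt following the third segment and is kept
verbatim (UMIs are not whitelist-constrained, so a single `N` survives).

Whitelist correction replaces each 9-mer segment by its exact whitelist
entry or, at `max_dist=1`, by a unique Hamming-1 neighbour; any miss or
ambiguity rejects the whole read rather than guessing. The bundled synthetic
whitelists (96 entries per segment, minimum pairwise Hamming distance 3) are
for testing and simulation; real runs supply vendor lists. Correction is
quality-score-blind by design — the assay's error budget at 27 informative
positions makes one-substitution rescue the right operating point, and
anything deeper would need per-base qualities the structural parser ignores.

## Quantification

Coordinates are 0-based half-open internally; GTF input is 1-based closed;
junctions derive from consecutive exons of each transcript. A feature id may
own several genomic intervals (a tandem-duplicated target is one feature at
two loci); counting keys on the id.

For a read aligning to `x` loci and overlapping `y` counted features at a
locus, each (locus, feature) pair receives weight `1/(x·y)`. Unique modes
(`wta_unique`, `tso_off_and_ontarget_unique`) retain only `x = y = 1` reads
at weight 1 and share one feature space; `tso_ontarget_multi` restricts the
feature space to targets and keeps any read with at least one on-target
overlap. A molecule whose loci all overlap features therefore contributes
total mass 1; in particular a molecule from a feature duplicated at two loci
contributes ½ + ½ = 1 to that feature.

UMI collapse is exact-match within (cell barcode, feature): no 1-mismatch
UMI network is built, keeping deduplication deterministic and auditable;
directional-network collapse is a known alternative and deliberately out of
scope. The molecule's weight comes from one representative read — smallest
`x`, ties broken lexicographically by read id — so PCR depth cannot change a
molecule's mass. Assignment is sense-stranded by default (`--unstranded`
available); one overlapping aligned base suffices (no minimum-overlap
fraction). Junction counts add `1/x` per alignment gap exactly matching an
annotated junction, UMI-collapsed the same way; junctions are reported once
their summed count reaches 1.

## Empty-droplet detection

The ambient profile pools counts of barcodes with totals at or below
`low_count_threshold` (default 100 UMIs) and smooths with a pseudo-count of
0.5 per feature — a simpler, deterministic stand-in for Good–Turing
smoothing; its only job is to keep every feature's ambient proportion
strictly positive. Each barcode above the threshold is scored by the
Dirichlet-multinomial log-likelihood of its counts at concentration
`α·p_ambient` (α default 100), and its Monte-Carlo p-value is
`(1 + #{simulated draws at the same total with log-likelihood ≤ observed}) /
(n_iter + 1)` (default `n_iter` 10 000), so p is never exactly 0. Draws are
grouped by total and sampled by a Dirichlet draw followed by a conditional
binomial chain, vectorised over iterations.

Knee retention works on the log-total vs log-rank curve over *distinct*
totals (rank = number of barcodes at or above that total). The inflection is
the steepest log-log segment; the knee is the point of maximum perpendicular
distance below the chord from the curve's start to the inflection, falling
back to the inflection itself on shelf-and-cliff curves where no interior
point dips below that chord. The cell-calling driver restricts the curve to
totals above the ambient threshold before locating either point — the far
tail of a desk-scale rank curve consists of near-singleton totals whose
log-rank spacing shrinks toward zero and would otherwise masquerade as the
steepest cliff. Retention is the union of the knee rule and the
Benjamini–Hochberg-corrected test at `α_fdr` (default 0.01); lowering
`α_fdr` can only shrink the retained set.

TSO matrices are never tested for emptiness: targeted transcriptional
complexity is undefined, so the TSO matrix is simply restricted to the
WTA-retained barcodes.

## Fusion detection

A ROI primer is a constant adapter (`TCAGACGTGTGCTCTTCCGATCT`) plus a 12-nt
gene-specific part identical to the coding strand; only the 12-mer appears
in cDNA reads. Trimming finds the leftmost occurrence of any primer 12-mer
(0 or 1 substitutions) and keeps the suffix from the primer onward.

The realignment is a Gotoh semiglobal alignment: the entire trimmed read is
consumed (no soft-clipping), reference overhangs are free, internal gaps are
affine. Defaults: match +1, mismatch −1, gap open −2 (first gap base),
extend −1; ties resolve to the leftmost reference interval, and across
references to panel order (fusion references before decoys). Reads ≤ 180 nt
against ~300-nt junction references keep the quadratic DP cheap, and
identical trimmed sequences — the overwhelming case for position-anchored
ROI reads — are cached.

A fusion call requires the best alignment to land on a junction reference
with identity ≥ 0.9 (identical aligned pairs / query length) and at least 5
matched bases on each side of the breakpoint. The two-sided anchor is what
rejects artifactually primed products that terminate at the breakpoint; a
primer-bearing read whose best alignment is a decoy, or which fails
identity/anchor, is an APP; reads without a primer are unassigned. These
three categories partition every read. The anchor and identity thresholds
are config-exposed (`FusionParams`); the defaults are this package's own
operating point, chosen so a single sequencing error near the breakpoint
cannot flip a call. Only the forward orientation is aligned, because the
primer anchors the read to the coding strand.

Detection rates are UMI-level: percent of cells of a type with at least one
supporting molecule per junction reference.

## QC statistics

Per-cell QC reports UMI totals, detected genes and mitochondrial percentage
(summed over all mitochondrial features, hence over both species in mixing
designs); mitochondrial features are recognised by gene-name prefixes
(`mt-`, `MT-`) or contig names (`chrM`, `MT`). Filter bounds are strict
inequalities, matching thresholds quoted as "counts > N" and
"N% < mito < M%"; a gene-level floor drops genes below a minimum total.
Species assignment is majority vote with a strict >50% rule; exact ties and
zero-count cells are `unknown` and flagged for removal. Positive-cell rate
is the percentage of retained cells with non-zero (possibly fractional)
summed target counts. Detection efficiency is
`100 · mean counts/cell ÷ mean(imaging replicate means)`, reported to two
decimals. Pseudobulk correlation aggregates mean log1p-normalised counts
(library-size factors scaled to their median — an approximation of the
scran/scuttle log-normalisation) per gene per group, keeping genes with
mean logcount > 0.1 and variance > 0.5; a log-CPM (prior count 1)
aggregation over group totals is selectable for mixing-style comparisons.
Fold enrichment is a plain count ratio, with zero denominators flagged
infinite and 0/0 undefined.

## The simulator

The generator's defaults are the package's study conditions: 300 cells,
3000 empty droplets, three on-target and one off-target gene (the
off-target gene on the minus strand), two-exon genes (400-nt exons, 200-nt
intron), 60-nt R1 and 62-nt R2, one target tandem-duplicated at a second
locus with identical sequence. Expression is negative binomial per
(cell, gene) with mean 60 and size 10 — moderate, cell-line-like
overdispersion; target capture adds NB(mean 10) TSO molecules to
Bernoulli(0.5)-positive cells, of which 30% are ROI-primed. Off-target
molecules are emitted as TSO background at rate 0.1. Ambient molecules
(Poisson mean 20 per empty droplet, drawn uniformly across genes) populate
empty droplets, with 2% leaking into real cell barcodes. APPs arrive at
Poisson rate 0.5 per cell. The fusion plan mirrors a three-line mixing
design: one cell type 90% positive for one junction, one 18% positive for
another, one negative, with 1 + Poisson(2) supporting molecules per positive
cell.

Read positions follow the assay: WTA and ambient reads sit a truncated
Exp(300 nt) from the 3′ end; on-target TSO reads are Gaussian-peaked
(σ = 15 nt) at the capture site; ROI-primed reads start exactly at the
primer 12-mer; off-target TSO reads are uniform; APP reads are the primer
followed by decoy sequence; fusion reads start at the primer position 40 nt
upstream of the breakpoint, covering it with both anchors. R1 is composed
through the barcode model and padded with random bases to 60 nt.
Substitution errors apply at a configurable per-base rate (default 0, the
condition under which closure is exact); there is no PCR-bias, quality or
indel model. UMIs are drawn without replacement within each
(barcode, feature, modality) group so that exact-match UMI collapse recovers
molecule counts exactly; at 4^8 possible UMIs and desk-scale depths this
removes collisions without distorting the count distribution. All
randomness flows from a single numpy PCG64 generator per stage, seeded from
`SimConfig.seed`, making every output byte-reproducible.

Truth is recorded per molecule and per read (coordinate-sorted SAM with
CB/UB tags, one record per origin locus with `NH` set, read class in an
auxiliary tag; junction/decoy-origin reads are recorded unmapped since they
have no genomic locus).

What passing these tests shows: the implementation's bookkeeping —
structure parsing, weighting, collapse, retention logic, breakpoint
anchoring — is exact under the generator's assumptions. What it does not
show: robustness to real-world artifacts the generator omits (indels,
quality-correlated errors, barcode swapping, PCR chimeras beyond the APP
model, ambient profiles that differ from the cell profile mixture).

## Problem sizes

The shipped validation runs use a 300-cell / 3000-empty simulation
(~200 000 read pairs) for pipeline closure, 100 random ≤50-read instances
for the recount oracle, 500 null barcodes × 1000 Monte-Carlo iterations for
calibration, and `n_iter` 2000 for pipeline cell calling; these sizes give
exact (closure, oracle) or tightly bounded (calibration, recovery) checks
while keeping a full run in tens of seconds. The package defaults
(`n_iter` 10 000) remain higher than the validation sizes.
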