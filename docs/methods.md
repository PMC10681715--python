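# Methods

This note documents the models, conventions and numerical choices behind
`msrrbs`, and what its synthetic data can and cannot show about real
libraries.

## Library model

msRRBS library construction is modeled only through its data-facing
consequence. Each sequenced molecule is an MspI fragment (cut `C^CGG`, so
internal fragments begin `CGG` and end `C`) within the recovered size
window, carrying the barcode adapter on both ends. Both mates therefore
read, 5′→3′:

```
[4-bp marker GGTG][6-bp cell barcode][bisulfite-converted insert]
[revcomp(barcode+marker)][sequencing adapter...]      (when insert < read)
```

Adapter cytosines are methylated during construction (the fill-in uses
methylated dCTP), so marker, barcode and read-through survive conversion
unchanged. The A-tailing/BciVI excision chemistry that produces this layout
does not alter read content and is not modeled further. Either strand of
the double-stranded fragment can seed a molecule (50/50 by default): read 1
is the converted molecule strand, read 2 its reverse complement. Because
adapters ligate to native MspI overhangs without end repair, fragment-end
CpGs carry true methylation; no end-repair masking exists in the simulator
or the caller.

## Simulator parameters

| parameter | default | meaning |
|---|---|---|
| `conversion_failure` | 0.004 | P(unmethylated C stays C); matches a 99.6% conversion chemistry |
| `overconversion` | 0.0 | P(methylated C reads T) |
| `error_rate` | 0.001 | per-base substitution rate (uniform Q30 qualities, consistent with it) |
| `read_length` | 150 | paired-end read length |
| `insert_window` | (30, 200) | recovered fragment sizes; the 175–350 bp library size maps to 30–200 bp inserts after adapters; wider windows (30–400, 30–600) model the 175–550/175–750 bp libraries |
| `spike_fraction` | 0.05 | unmethylated control pairs as a fraction of genomic pairs; the protocol specifies a spike-in mass (60 fg per cell), not a read fraction, so a realistic value was fixed once |
| `pcr_duplication_rate` | 0.0 | optional duplicate pairs; the caller can collapse duplicates by (fragment, offsets, cell) |

Per-cell methylomes draw each CpG's methylation probability from a
two-component Beta archetype: Beta(1, 9) inside CpG islands (mean 0.10) and
Beta(6, 2) elsewhere (mean 0.75), reproducing the canonical island
hypomethylation against a methylated background. Non-CpG cytosines are
unmethylated by default. Each sequenced molecule draws its own Bernoulli
methylation states from these probabilities, so per-site calls are binomial
in coverage.

The unmethylated control is a packaged synthetic 48,502-bp seeded random
sequence (`lambda_like_control()`), regenerated deterministically in code;
only its cytosine positions matter to the conversion-rate estimator. The
control is spiked per cell in the protocol, so simulated control reads
carry the cells' barcodes and flow through demultiplexing and alignment
like any other read.

The synthetic genome generator draws an i.i.d. background at 50% GC, then
destroys 80% of background CG dinucleotides — echoing the methylation-driven
CpG depletion of vertebrate genomes (observed/expected ≈ 0.2) — and plants
CpG-island segments (~400 bp, CG- and CCGG-dense) roughly every 6 kb. This
gives the two properties that make RRBS meaningful: MspI sites concentrate
in islands, and the island/background methylation contrast is detectable.
What the generator does **not** emulate: repeats, chromatin-driven coverage
biases, allele-specific methylation, indels, PCR chimeras, and quality-score
degradation along the read. Pipeline guarantees demonstrated on this data
(round-trip exactness, unbiased level recovery, conversion-rate recovery)
are guarantees about the *processing rules*, not about robustness to those
real-data artifacts.

## Processing conventions

**Coordinates.** 0-based, half-open everywhere internally (BED convention);
1-based positions appear only in CGmap-style output.

**Demultiplexing.** Both mates must carry the same whitelisted barcode with
zero mismatches; pairs whose barcode bases average below Q20 on either mate
are removed entirely (counted separately from unassigned). The accounting
identity `assigned + unassigned + quality_filtered = total` is asserted at
run time.

**Trimming.** The 10 structural bases are removed, then each mate is
scanned left-to-right for the earliest occurrence (≤1 mismatch for
overlaps ≥6 bp, exact below that, minimum overlap 3 bp) of
revcomp(barcode+marker) or the adapter stub; everything from there on is
cut. An insert whose own tail resembles the pattern can pre-empt the cut by
a few bases — a known and accepted property of earliest-match adapter
trimming. Residual read-through shorter than the minimum overlap (1–2
bases) survives trimming and is clipped at alignment instead.

**Alignment.** The mapping space is the size-selected fragment catalog, not
the genome: msRRBS reads begin at MspI cut sites by construction, so
fragment space is lossless for correctly structured reads. This is the key
desk-scale simplification; fragment-space mapping rates are not comparable
to whole-genome mapper rates on real data. Both strand frames of each
fragment are indexed as C→T-converted 20-mers; candidates are verified
bisulfite-aware (reference C against read T is free), mates must place at
opposite ends of the same frame, up to 2 non-bisulfite mismatches per mate.
Ties on total mismatches are ambiguous and excluded from calling; reads may
overhang the frame by ≤2 bases (the residual read-through), which is
clipped.

**Calling.** One observation per pair per covered position; where the mates
overlap, the observation is kept only if both mates agree on the base —
this mate-consistency rule suppresses sequencing-error miscalls (a T→C
error otherwise reads as spurious methylation at rate error/3, ~0.03% at
default error rate — comparable to the conversion-failure floor itself).
CpG calls from the two strands are merged (destranded) onto the plus-strand
C, following the CGmap ecosystem convention; a flag keeps strands separate,
and the merged counts equal the per-strand sums exactly. Non-CpG
observations accumulate into per-chromosome CHG/CHH totals. The conversion
rate uses all cytosine contexts of the spike-in, since the control is fully
unmethylated. Cell QC passes at ≥0.2 M detected CpG sites by default
(inclusive), with the threshold configurable for toy genomes.

**Element definitions.** CpG islands are called with a 200-bp sliding
window (step 1): GC ≥ 0.50, length ≥ 200 bp, observed/expected CpG > 0.6
with expected = (#C × #G)/length; overlapping qualifying windows are
merged and the merged region re-validated, trimming one base at a time from
the worse-scoring end if needed. Shores are the 2-kb flanks minus island
bases, shelves the next 2 kb outward, computed by interval-set arithmetic
(equivalent to per-base precedence island > shore > shelf). Promoters are
strand-aware TSS −1500/+500 intervals; overlap with an island is recorded
as a `contains_cgi` attribute, not used as a filter, since either reading
of "promoters containing CGIs" remains representable. Elements with
identical (chrom, start, end) are deduplicated regardless of strand.

**Cohort analytics.** Window and metagene levels are coverage-weighted
(Σm/Σtotal), the bulk-caller convention, rather than means of site levels.
Pairwise Pearson correlation is computed over sites covered at least
`min_cov`× in both members (default 1 for single cells; 3/5/10/15/20
presets for bulk-style comparisons), requiring ≥3 shared sites. Saturation
downsights clean read pairs (the protocol's depth unit) without
replacement, 5 replicates by default; the curve equals exhaustive counts at
full depth by construction. For embeddings, windows missing in >80% of
cells are dropped and remaining gaps mean-imputed, since neighbor-embedding
methods need complete input; PCA/tSNE/MDS are delegated to scikit-learn
with a fixed random state.

**Differential methylation.** Per-CpG testing (not per-window) across
cells: the Mann–Whitney U p-value is exact by enumeration of all
C(n+m, n) group assignments for n+m ≤ 20 (correct under the heavy ties of
level data; midranks, two-sided by deviation from the null mean nm/2), and
a tie-corrected normal approximation beyond. Sites need ≥3 covered cells
per group. Significant sites (raw p < 0.05; no multiple-testing correction
by default, Benjamini–Hochberg available but off) with the same direction
are chained while consecutive gaps stay below 100 bp; a chain becomes a DMR
iff it has ≥3 member CpGs and spans ≥50 bp (first to last member C,
inclusive). An opposite-direction significant site breaks the chain, since
a region has one direction. Fisher's exact test on pooled counts is
available as a two-sample mode.

## Degenerate inputs and tie-breaks

Empty chromosomes are skipped with a warning; chromosomes shorter than the
CGI window yield no calls. A catalog emptied by size selection is an error.
Cells with zero unique alignments get undefined species fractions (flagged
`None`). Correlation entries with <3 shared sites, windows with no covered
CpG, and metagene bins with no observation are missing (NaN), never zero.
Identical best-scoring placements are ambiguous rather than first-wins.
All randomness flows through `numpy.random.default_rng` seeds; one global
seed derives per-stage seeds by stable string hashing, so stages are
independently reproducible and byte-identical on rerun.

## Problem sizes

The test and acceptance workloads use 20–80 kb genomes, 4–16 cells, and
10³–10⁵ read pairs — sizes at which every guarantee is checked exactly
(round trips against truth tables, enumeration oracles, binomial bounds)
in minutes on one core. Statistical checks compare observed violations of
per-site binomial error bounds against their exact binomial expectation
rather than asserting the bound at every site, which no finite sample can
satisfy.

## Known limitations

Fragment-space alignment cannot measure off-target or partially degraded
reads, so mapping rates on simulated data are near 1 and say nothing about
real-library mapping rates. The exact MWU enumeration grows as C(n+m, n)
and is capped at n+m = 20; beyond that the normal approximation is used.
The trimmer's earliest-match rule can shave a few genuine insert bases
(~5% of reads); alignment and calling are insensitive to this. CTCF and
enhancer elements are loaded from BED only, never derived.
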