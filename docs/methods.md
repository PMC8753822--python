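# Methods

This note documents the models, conventions and open design choices behind
`sequintools`. It describes what the code computes and why; every number
quoted as an output here is produced by the test suite or
`scripts/acceptance.py` at run time.

## The mirror-image control model

A control molecule is the character-by-character reversal of a
natural-orientation template (no complementation). Reversal is an
involution and preserves length and base composition, but — because DNA
sequence is directional — the mirrored string generally matches neither
strand of the natural template. Reads from controls therefore align only
to the decoy contig in a combined reference, which is what makes
alignment-based partitioning exact. The inverse transform ("flip":
reverse the read and its quality string) restores natural orientation.

Controls representing genetic variation come in overlapping
reference/variant pairs that differ only at designed sites. Only the
reference member is placed on the decoy; variant-member reads pile up at
the same coordinates and present the alternate alleles at the designed
frequency. Variant sites are recorded in natural-template coordinates and
reflected into decoy coordinates at assembly time: a natural span
`[s, e)` on a template of length `L` lands at `[L-e, L-s)` within the
placement, with allele strings reversed.

## Decoy assembly

Placed sequins are concatenated spacer-free into four regions — p1 (small
variants, repeats, microsatellites, haplotype blocks), p2 (structural
variants), p3 (HLA), p4 (immune receptors) — and tracked by a placement
table. Sequin boundaries are not padded with N: boundary artifacts are
neutralized analytically by an **edge mask** covering the terminal 400 nt
of each placement (configurable; capped at half the molecule for short
molecules). The mask models the coverage decay within one fragment length
of a linear molecule's ends; masked positions are excluded from every
profiling summary.

Coordinates are 0-based half-open everywhere internally and in BED
output; VCF writers convert to 1-based anchored records (indels and SV
breakpoints anchor on the preceding base, so the truth VCF's REF field
always equals the decoy FASTA slice at POS — asserted at build time and
re-checked from the written files in tests). One htslib subtlety forced
the anchored convention: for symbolic alleles, END is recomputed from
SVLEN, so unanchored records would drift by one.

## Default census

The default build (seeded, fully regenerable) realizes:

* 41 small-variant pairs × 33 variants = 1353 truth records; ~80% SNV,
  10% 1–3 nt insertions, 10% deletions, cycled over neutral / GC-rich
  (70% GC) / GC-poor (30%) / short-repeat contexts. Designed VAFs: 30
  pairs het (0.5), 3 hom-alt (1.0), and a somatic series at 10%, 5%, 2%
  and 1% (two pairs each).
* 12 Bethesda-panel microsatellites: stable NR27, NR24, NR22, NR21,
  MONO27, D18S55, CAT25; unstable BAT-25, BAT-26, D2S123, D5S346,
  D17S250. Mononucleotide tract lengths follow the marker names;
  dinucleotide loci are CA repeats. Unstable loci are pairs whose variant
  member carries a designed contraction (1–4 repeat units), the
  deletion-biased signature of mismatch-repair deficiency; contractions
  keep variant members colinear with their references.
* 2 repeat-control molecules carrying a designed homopolymer ladder
  (8–27 nt) spanning the small (≤5), medium (6–15) and large (>15)
  classes, placed clear of the edge mask.
* 24 haplotype block pairs labelled chr1–22, X, Y. Block lengths are
  symmetric offsets about 5.9 kb (spread ±1.5 kb), so the build's mean
  is exactly the designed 5.9 kb; het SNVs every ~300 nt (±60 jitter).
* 54 structural variants: 10 DEL, 6 INS, 11 DUP, 10 INV, 9 viral
  insertions (synthetic HPV-like payloads of 300–500 nt, not real viral
  genomes), 8 reciprocal translocations (two contexts, two junctions,
  both derivative products in the mixture). Sizes 60–800 nt by type —
  scaled to the ~2 kb molecules rather than genome-scale SVs.
* 8 HLA alleles (2 per gene for HLA-A/-B/-C/-DQB1), each a 2 kb molecule
  with exon 2/3 intervals; second alleles differ at 6 exonic SNVs.
* 20 immune loci: 10 rearranged clonotypes (2 per locus across IGL, IGK,
  TRG, TRD, TRB; D segments for TRB/TRD) and 10 germline (non-rearranged)
  V/J segment molecules. Rearranged sequences are V′+junction+J′ with the
  CDR3 interval anchored by the conserved cysteine codon near the V 3'
  end and tryptophan codon near the J 5' start; synthetic segment
  libraries only — no real IMGT content.

Every count and size is a `DesignCensus` field. All templates come from a
seeded i.i.d. nucleotide model with per-context GC; seeds are mandatory
for every stochastic step.

## Mixture model

Shares are molar over near-equal-length molecules; the simulator weights
fragment sampling by share × length, so *coverage* (the quantity all the
evaluation statistics use) tracks the designed share even when lengths
differ. Pair-local shares encode genotype: variant share = VAF, reference
share = 1 − VAF, so het is 1:1 and a 1% somatic design is 99:1
reference:variant. Whether physical mixtures are molar or mass-based is
not observable from coverage alone at equal lengths; molar-with-length-
weighting is the documented choice. The clonotype ladder is log-spaced
over two orders of magnitude and normalized within the immune section.
The spike fraction defaults to 2% (down-sampling expected downstream);
`required_spike_fraction(span, genome)` gives the equal-coverage fraction
`span/genome` (~0.05% at production scale: 1.7 Mb vs 3.2 Gb).

## Read simulator

Fragments: molecule chosen ∝ share × length; truncated-normal fragment
length (resampled within [read length, molecule length]); uniform start;
optional quadratic GC-bias acceptance weight (clipped at zero). Paired
mode emits FR pairs (R2 reverse-complemented in FASTQ); long mode emits
single reads capped by the molecule, reflecting that short control
molecules bound long-read length.

Errors: per-base substitution with transition probability
titv/(titv+1); insertion/deletion baselines multiplied by a
homopolymer-run curve that grows linearly with run length and plateaus at
15 nt (the empirical shape of slippage errors), with insertions realized
as same-base duplications. Every event is logged with molecule
coordinates, making the simulator its own truth source: tests reconcile
pileup mismatch counts and repeat-length observations against the event
log exactly. Quality strings are a constant score; no quality weighting
anywhere downstream. Named profiles (`pcrfree_like`, `pcr_like`,
`nanopore_like`) encode qualitative orderings (long-read error ≫
short-read; PCR adds indel and GC bias) for demonstration only — no
instrument calibration is claimed.

Pre-aligned output: each read's aligned tokens are mapped through a
per-molecule decoy map (identity for placed references; the designed
variant alignment, mirror-reflected, for SNV/INS/DEL-type variant
members). CIGARs carry both designed and injected indels. INV/DUP/TRA
variant molecules have no single-segment linear alignment, so their reads
are emitted unmapped; SV evaluation consumes caller VCFs, not read
alignments, so nothing downstream depends on them.

## Profiling statistics

Per-base profile: depth, matches, mismatches by substituted base,
insertion events (anchored at the preceding aligned base) and deletion
events (one per read at every spanned position — event counting, not
length weighting). Normalized coverage divides by the mean depth over
unmasked positions (mean, not median — switchable), so the unmasked mean
is 1 by construction and the coverage IQR is comparable across libraries.
GC stratification uses non-overlapping 100-nt tiles (a step flag allows
sliding windows; tiling keeps window means independent) with low/high
strata at <30% / >65% GC. Error rates are averaged in 1000-nt windows;
zero-depth positions leave the denominators and are tallied as coverage
gaps. The substitution spectrum (12 types; transitions = A↔G, C↔T)
excludes masked and designed-variant positions.

The permissive caller (min depth 50, 1 supporting read, AF ≥ 1e-5, no
strand filter) is a sensitivity-maximizing candidate generator for
measuring the error floor, not a production caller. FP-by-AF bins
candidates on log-spaced AF bins (1e-4 to 1 by default); a candidate is a
false positive iff its (position, ref, alt) key is absent from the design
truth. The AUC summary is the trapezoid of per-bin FDR over the log-AF
axis normalized by the axis span — an internal comparison statistic whose
absolute value is tied to this binning choice.

## Repeat, SV, phasing and immune metrics

**Repeats.** Homopolymers are maximal runs (small ≤5, medium 6–15, large
>15 nt). Observed per-read length = designed interval length + inserted −
deleted bases within the interval, by CIGAR walk; only reads spanning the
interval plus a 5-nt flank count, and reads soft-clipped inside the
flanked window are excluded and tallied. Insertions anchored at a base
inside the run extend it (slippage semantics); insertions at the left
flank boundary do not — the boundary rule is pinned by a truth-log oracle
test. Dinucleotide loci measure total interval length, robust to
half-motif indels.

**Structural variants.** A called breakpoint within |Δ| ≤ 10 nt
(inclusive) of an unmatched, type-compatible truth breakpoint is a TP;
matching is greedy one-to-one by ascending offset, position-ordered on
ties. Compatibility is exact type except VIR truth ↔ INS calls and TRA
truth ↔ BND calls; the DUP-as-INS rule additionally accepts an insertion
call inside a truth duplication's span with the duplication's size
(± tolerance), satisfying *both* duplication breakpoints. SV-level
recovery requires all breakpoints matched. Greedy nearest-first is not a
maximum matching on adversarial overlapping clusters; for breakpoints
separated by more than two tolerances (the designed geometry) it is, and
the test suite verifies equality with the Hungarian-algorithm optimum on
such instances.

**Phasing.** Phaser output is grouped by phase-set identifier; each block
is scored under both global orientations and the better one counts
(standard practice; the per-site agree/disagree sequence ordered by
position yields switch errors as its transitions). Sites absent from the
truth are reported as false-positive variants and excluded from the
correctly-phased denominator. Block length is span-based (first to last
phased site); variant counts are reported alongside. Note that
best-of-two scoring of *random* phase is biased above one half for finite
blocks (E[max(k, n−k)]/n), so the random-phaser harness test compares
against a Monte-Carlo Bernoulli oracle of the same scoring rule rather
than 0.5 exactly. A truth-aware trivial phaser (scores 1.0 by
construction) is bundled as a harness self-test.

**Immune/HLA.** CDR3 error rate = (mismatches + insertion events +
deletion events) per 100 aligned bases within the designed interval.
Clonotype observed frequency = mean CDR3 depth / total over clonotypes —
unnormalized by length, as designed clonotypes are near-equal length;
RMSE and R² are computed on the linear frequency scale (log-RMSE over
detected clonotypes reported alongside), with undetected clonotypes
contributing zeros. HLA consensus is per-position majority vote (base
support = matches for the reference base + mismatch counts for
alternatives; ties fall to the reference and are flagged; positions under
5× mark the result low-confidence), compared to the designed allele by
unit-cost Levenshtein distance.

## What the synthetic data does and does not show

The simulator emulates coverage proportionality, Ti/Tv-structured
substitution error, homopolymer-scaled slippage indels, GC-dependent
coverage bias, fragment-length-limited phasing and edge-decay masking. It
does not model PCR duplicates, quality-score miscalibration, strand
bias, chimeric fragments, mappability artifacts from genome-wide
repetitiveness, or instrument-specific error motifs. Passing tests
therefore validate the *bookkeeping and statistics* — truth-set
consistency, estimator correctness against oracles, parameter recovery
within sampling error — not any claim about real-instrument performance;
published per-instrument numbers (error rates, IQRs, AUCs, exact-match
percentages) require physical standards and are out of scope.

## Problem sizes and numerics

The default decoy is ~432 kb (production-scale sets are ~1.7 Mb); the
package scales the census rather than the per-molecule geometry, keeping
every designed feature at realistic local scale (2 kb molecules, 5.9 kb
blocks). Simulation-based tests use 1e6–2e7 sequenced bases with 3σ
binomial/Poisson tolerances from the corresponding oracles; manifest
normalization asserts to 1e-12; VAF recovery is exact by construction.
Degenerate inputs are contracts, not crashes: empty candidate lists give
all-zero FDR tables, zero-coverage intervals are flagged absent rather
than scored, empty distance bins are omitted rather than reported as
zero, and target-above-achieved down-sampling is rejected with the
achieved value.
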