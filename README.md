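# sequintools

Design and benchmarking toolkit for **mirror-image DNA spike-in controls**
("sequins") on an in silico decoy chromosome.

## The problem

Difficult regions of the human genome — low-complexity repeats and
microsatellites, GC-rich/poor contexts, structural variants, polymorphic
HLA genes, and rearranged immune-receptor loci — are where sequencing and
analysis pipelines fail most, and where clinical calls matter most.
Spike-in controls give a ground truth: synthetic DNA molecules whose
sequence is the **mirror image** (character-by-character reversal, *not*
reverse complement) of a natural-style template. Because DNA is read
5'→3', a mirrored sequence is distinct from both strands of the natural
genome, so control reads can be partitioned unambiguously from sample
reads in a combined-reference alignment, then *flipped* (reversed) back
to natural orientation for analysis against known coordinates on an
artificial decoy contig (`chrQ`).

`sequintools` implements the full desk-side workflow:

| stage | module | what it does |
|---|---|---|
| design | `sequintools.design` | generate mirror-image controls for each feature class and assemble them into `chrQ` with truth sets (FASTA/VCF/BED/TSV) |
| mixture | `sequintools.mixture` | encode genotypes and somatic VAFs as concentration ratios (het = 1:1; 1% VAF = 1:99 variant:reference), plus a clonotype abundance ladder |
| simulate | `sequintools.readsim` | seeded short/long-read simulator with Ti/Tv structure, homopolymer-scaled indel rates and GC bias; emits FASTQ and pre-aligned records |
| partition | `sequintools.partition` | split decoy reads from host reads, flip to natural orientation, down-sample to target coverage |
| profile | `sequintools.profiling` | per-base coverage/error profiles, 100-bp GC windows, 1000-bp error windows, substitution spectra, permissive calling, FP-rate-by-AF curves |
| evaluate | `repeat_eval`, `sv_eval`, `phase_eval`, `immune_eval` | repeat-length accuracy, SV breakpoint matching (10-nt tolerance, DUP-as-INS rule), phasing scores, CDR3/clonotype/HLA metrics |

The default build reproduces the reference composition of the control set
this toolkit models: 1353 small variants across 41 reference/variant pairs,
the 12 Bethesda-panel microsatellites (7 stable, 5 unstable), 24 haplotype
block pairs averaging 5.9 kb, 54 structural variants (10 DEL, 6 INS, 11 DUP,
10 INV, 9 viral insertions, 8 reciprocal translocations), 8 HLA alleles and
20 immune-receptor loci — every count configurable via `DesignCensus`.

## Worked example

```sh
$ sequintools design --seed 42 --outdir design
decoy chrQ: 431558 nt, 169 placements
  decoy_fasta: design/decoy.fa
  ...
```

The decoy is ~432 kb: 169 placed molecules (only the *reference* member of
each pair is placed; variant-member reads co-locate at the same
coordinates). `design/` now holds the decoy FASTA, natural- and
mirrored-orientation sequin FASTAs, the cytoband/placement/edge-mask/feature
BEDs, truth VCFs for small variants and SVs, the phasing truth and the
mixture manifest.

Simulate a library from the mixture (shares encode every designed VAF):

```sh
$ sequintools simulate --manifest design/mixture_manifest.tsv \
    --fasta design/sequins_mirrored.fa --profile pcrfree_like \
    --depth 2 --seed 42 --out-prefix lib
10582 reads -> lib_R1.fastq, lib_R2.fastq
```

What spike fraction would give this control set the same mean coverage as
a 3.2 Gb genome? Coverage scales with mass per nucleotide, so it is simply
`span_controls / span_genome`:

```sh
$ sequintools spike-fraction --control-span 431571
1.349e-04 (0.0135%)
```

(The ~1.7 Mb production-scale control set needs ~0.05%.)

Benchmark an SV callset against the designed truth — here the truth against
itself, which must score perfectly (93 breakpoints: two per DEL/DUP/INV/TRA,
one per insertion):

```sh
$ sequintools eval-sv --calls design/truth_svs.vcf \
    --truth design/truth_svs.vcf --tol 10
{"tp": 93, "fp": 0, "fn": 0, "sensitivity": 1.0, "precision": 1.0}
```

Other subcommands: `partition`, `profile`, `call-permissive`, `fp-by-af`,
`eval-repeats`, `eval-phase`, `eval-immune`, `eval-hla`. Every evaluation is
also available as a library function operating on in-memory objects; see
`docs/methods.md` for the statistical definitions and design choices.

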