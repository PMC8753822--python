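"""Default design build: generate every control family from a seeded RNG.

The build draws all templates from a uniform nucleotide model (with
context-specific GC content) and realizes the full default census:
small-variant pairs, Bethesda-panel microsatellites, homopolymer repeat
controls, haplotype block pairs, structural variants, HLA alleles, and an
immune-receptor section with a clonotype abundance ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..sequence import TRANSITIONS, random_dna
from .census import BETHESDA_PANEL, DesignCensus
from .immune import D_LOCI, IMMUNE_LOCI, Segment, build_clonotype, make_segment, nonrearranged_sequin
from .sv import SVBuild, build_structural_variant
from .types import (
    FeatureAnnotation,
    FeatureKind,
    HaplotypeBlockPair,
    HLAAlleleDesign,
    MicrosatelliteDesign,
    SequinDefinition,
    StructuralVariantDesign,
    SVType,
    VariantClass,
    VariantContext,
    VariantRecord,
)
from .variants import build_variant_pair

_CONTEXT_CYCLE = (
    VariantContext.NEUTRAL,
    VariantContext.GC_RICH,
    VariantContext.GC_POOR,
    VariantContext.REPEAT,
)
_CONTEXT_GC = {
    VariantContext.NEUTRAL: 0.50,
    VariantContext.GC_RICH: 0.70,
    VariantContext.GC_POOR: 0.30,
    VariantContext.REPEAT: 0.50,
}
# one in ten variants is an insertion, one in ten a deletion
_VCLASS_CYCLE = (
    VariantClass.SNV, VariantClass.SNV, VariantClass.SNV, VariantClass.INS,
    VariantClass.SNV, VariantClass.SNV, VariantClass.SNV, VariantClass.DEL,
    VariantClass.SNV, VariantClass.SNV,
)


@dataclass
class SmallVariantPair:
    pair_id: str
    template: str
    variants: list[VariantRecord]
    vaf: float
    context: VariantContext
    ref: SequinDefinition = None  # type: ignore[assignment]
    var: SequinDefinition = None  # type: ignore[assignment]


@dataclass
class MicrosatellitePair:
    design: MicrosatelliteDesign
    ref: SequinDefinition
    var: SequinDefinition | None  # unstable loci carry a shifted variant member
    variant_copies: int


@dataclass
class HaplotypeBuild:
    pair: HaplotypeBlockPair
    maternal: SequinDefinition
    paternal: SequinDefinition


@dataclass
class HLABuild:
    design: HLAAlleleDesign
    sequin: SequinDefinition


@dataclass
class ImmuneBuild:
    segments: dict[str, Segment]
    clonotypes: list  # (ClonotypeDesign, SequinDefinition)
    nonrearranged: list[SequinDefinition]


@dataclass
class DesignBundle:
    """Everything the default build produced, prior to decoy assembly."""

    census: DesignCensus
    seed: int
    smallvar_pairs: list[SmallVariantPair] = field(default_factory=list)
    repeat_sequins: list[SequinDefinition] = field(default_factory=list)
    microsatellites: list[MicrosatellitePair] = field(default_factory=list)
    haplotypes: list[HaplotypeBuild] = field(default_factory=list)
    svs: list[SVBuild] = field(default_factory=list)
    hla: list[HLABuild] = field(default_factory=list)
    immune: ImmuneBuild = None  # type: ignore[assignment]

    def all_sequins(self) -> list[SequinDefinition]:
        out: list[SequinDefinition] = []
        for p in self.smallvar_pairs:
            out.extend([p.ref, p.var])
        out.extend(self.repeat_sequins)
        for m in self.microsatellites:
            out.append(m.ref)
            if m.var is not None:
                out.append(m.var)
        for h in self.haplotypes:
            out.extend([h.maternal, h.paternal])
        for s in self.svs:
            out.extend(s.refs)
            out.extend(s.variants)
        out.extend(h.sequin for h in self.hla)
        out.extend(s for _, s in self.immune.clonotypes)
        out.extend(self.immune.nonrearranged)
        ids = [s.id for s in out]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sequin ids in design")
        return out

    def placed_sequins(self) -> dict[str, list[SequinDefinition]]:
        """Sequins placed on the decoy, by region.  Only the reference
        member of each pair is placed; variant reads co-locate there."""
        p1: list[SequinDefinition] = [p.ref for p in self.smallvar_pairs]
        p1 += self.repeat_sequins
        p1 += [m.ref for m in self.microsatellites]
        p1 += [h.maternal for h in self.haplotypes]
        p2 = [r for s in self.svs for r in s.refs]
        p3 = [h.sequin for h in self.hla]
        p4 = [s for _, s in self.immune.clonotypes] + list(self.immune.nonrearranged)
        return {"p1": p1, "p2": p2, "p3": p3, "p4": p4}


def _alt_base(rng: np.random.Generator, ref: str) -> str:
    # 2:1 transition bias, loosely matching germline spectra
    if rng.random() < 2 / 3:
        return TRANSITIONS[ref]
    choices = [b for b in "ACGT" if b not in (ref, TRANSITIONS[ref])]
    return choices[int(rng.integers(len(choices)))]


def _make_smallvar_pair(
    rng: np.random.Generator, idx: int, census: DesignCensus, context: VariantContext, vaf: float
) -> SmallVariantPair:
    pair_id = f"SV{idx:03d}"
    L = census.sequin_length
    template = list(random_dna(rng, L, gc=_CONTEXT_GC[context]))
    n = census.variants_per_pair
    step = (L - 120) // n
    positions = [60 + i * step for i in range(n)]
    if context is VariantContext.REPEAT:
        # short homopolymer immediately 5' of each variant site
        for p in positions:
            base = template[p]
            template[p - 8 : p - 2] = [base] * 6
    tmpl = "".join(template)
    variants: list[VariantRecord] = []
    for i, p in enumerate(positions):
        vclass = _VCLASS_CYCLE[i % len(_VCLASS_CYCLE)]
        if vclass is VariantClass.SNV:
            ref, alt = tmpl[p], _alt_base(rng, tmpl[p])
        elif vclass is VariantClass.INS:
            ref, alt = "", random_dna(rng, int(rng.integers(1, 4)))
        else:
            k = int(rng.integers(1, 4))
            ref, alt = tmpl[p : p + k], ""
        variants.append(
            VariantRecord(
                sequin_id=f"{pair_id}_R", pos=p + 1, ref=ref, alt=alt,
                vclass=vclass, context=context, designed_vaf=vaf,
            )
        )
    ref_s, var_s = build_variant_pair(tmpl, variants, pair_id, FeatureKind.SMALLVAR)
    return SmallVariantPair(pair_id, tmpl, variants, vaf, context, ref_s, var_s)


def _make_repeat_sequins(rng: np.random.Generator, census: DesignCensus) -> list[SequinDefinition]:
    """Unpaired controls carrying the designed homopolymer ladder, placed
    away from the edge-masked termini."""
    runs = census.designed_homopolymers
    L = census.sequin_length
    out = []
    for r in range(2):
        seq = list(random_dna(rng, L, gc=0.5))
        anns = []
        slot = census.edge_width + 40
        for base, length in runs:
            # pad run boundaries so it is maximal
            if seq[slot - 1] == base:
                seq[slot - 1] = "C" if base != "C" else "G"
            if seq[slot + length] == base:
                seq[slot + length] = "C" if base != "C" else "G"
            seq[slot : slot + length] = [base] * length
            anns.append(FeatureAnnotation(f"homopolymer_{base}x{length}", slot, slot + length))
            slot += length + 130
        out.append(
            SequinDefinition(
                id=f"REP{r:02d}", feature_kind=FeatureKind.REPEAT,
                natural_seq="".join(seq), annotations=anns,
            )
        )
    return out


def _make_microsatellite(
    rng: np.random.Generator, name: str, census: DesignCensus
) -> MicrosatellitePair:
    motif, copies, stable, shift = BETHESDA_PANEL[name]
    L = census.sequin_length
    tract_len = len(motif) * copies
    fl_len = (L - tract_len) // 2
    flank_left = random_dna(rng, fl_len, gc=0.45)
    flank_right = random_dna(rng, L - tract_len - fl_len, gc=0.45)
    # keep the tract maximal: flanks must not extend the repeat
    if flank_left.endswith(motif[-1]):
        flank_left = flank_left[:-1] + ("C" if motif[-1] != "C" else "G")
    if flank_right.startswith(motif[0]):
        flank_right = ("C" if motif[0] != "C" else "G") + flank_right[1:]
    d = MicrosatelliteDesign(name, motif, copies, stable, flank_left, flank_right)
    s, e = d.tract_interval
    ann = [FeatureAnnotation(f"microsat_{name}", s, e)]
    safe = name.replace("-", "")
    if stable:
        ref = SequinDefinition(
            id=f"MS_{safe}", feature_kind=FeatureKind.MICROSATELLITE,
            natural_seq=d.natural_seq, annotations=ann,
        )
        return MicrosatellitePair(d, ref, None, copies)
    var_copies = copies + shift
    var_seq = flank_left + motif * var_copies + flank_right
    pid = f"MS_{safe}"
    ref = SequinDefinition(
        id=f"{pid}_R", feature_kind=FeatureKind.MICROSATELLITE,
        natural_seq=d.natural_seq, pair_id=pid, role="reference", annotations=ann,
    )
    var = SequinDefinition(
        id=f"{pid}_V", feature_kind=FeatureKind.MICROSATELLITE,
        natural_seq=var_seq, pair_id=pid, role="variant",
    )
    return MicrosatellitePair(d, ref, var, var_copies)


def _haplotype_lengths(census: DesignCensus) -> list[int]:
    """Block lengths symmetric about the designed mean, so the build's
    average equals the designed 5.9 kb exactly."""
    n = census.haplotype_pairs
    half = n // 2
    spread = np.linspace(census.haplotype_len_spread / half, census.haplotype_len_spread, half)
    offsets = np.concatenate([-spread[::-1], spread]).round().astype(int)
    if n % 2:
        offsets = np.concatenate([offsets, [0]])
    return [census.haplotype_mean_len + int(o) for o in offsets]


_CHROM_LABELS = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]


def _make_haplotype(
    rng: np.random.Generator, idx: int, length: int, census: DesignCensus
) -> HaplotypeBuild:
    label = _CHROM_LABELS[idx % len(_CHROM_LABELS)]
    maternal = random_dna(rng, length, gc=0.45)
    sites = []
    pos = 150
    while pos < length - 150:
        jitter = int(rng.integers(-60, 61))
        p = pos + jitter
        am = maternal[p]
        sites.append((p, am, _alt_base(rng, am)))
        pos += census.het_spacing
    paternal = list(maternal)
    for p, _, ap in sites:
        paternal[p] = ap
    pair = HaplotypeBlockPair(
        block_id=f"HP{idx:02d}", source_label=label,
        maternal_seq=maternal, paternal_seq="".join(paternal), het_sites=sites,
    )
    mat = SequinDefinition(
        id=f"HP{idx:02d}_M", feature_kind=FeatureKind.HAPLOTYPE,
        natural_seq=maternal, pair_id=pair.block_id, role="reference",
    )
    pat = SequinDefinition(
        id=f"HP{idx:02d}_P", feature_kind=FeatureKind.HAPLOTYPE,
        natural_seq=pair.paternal_seq, pair_id=pair.block_id, role="variant",
    )
    return HaplotypeBuild(pair, mat, pat)


def _make_svs(rng: np.random.Generator, census: DesignCensus) -> list[SVBuild]:
    out: list[SVBuild] = []
    L = census.sequin_length
    sizes = {"DEL": (60, 800), "DUP": (60, 400), "INV": (100, 600),
             "INS": (60, 400), "VIR": (300, 500)}
    for svtype, count in census.sv_counts.items():
        for i in range(count):
            sv_id = f"{svtype}{i:02d}"
            if svtype == "TRA":
                ctx_a = random_dna(rng, L)
                ctx_b = random_dna(rng, L)
                jx = int(rng.integers(700, 1300))
                jy = int(rng.integers(700, 1300))
                design = StructuralVariantDesign(
                    sv_id=sv_id, svtype=SVType.TRA, breakpoints=[jx, jy],
                    size=abs(jx - jy) + 1, partner_sequin=f"{sv_id}_B_R",
                )
                out.append(build_structural_variant(ctx_a, design, ctx_b))
                continue
            ctx = random_dna(rng, L)
            lo, hi = sizes[svtype]
            size = int(rng.integers(lo, hi + 1))
            if svtype in ("INS", "VIR"):
                b1 = int(rng.integers(600, L - 600))
                design = StructuralVariantDesign(
                    sv_id=sv_id, svtype=SVType(svtype), breakpoints=[b1], size=size,
                    payload=random_dna(rng, size, gc=0.4 if svtype == "VIR" else 0.5),
                )
            else:
                b1 = int(rng.integers(census.edge_width + 50, L - census.edge_width - 50 - size))
                design = StructuralVariantDesign(
                    sv_id=sv_id, svtype=SVType(svtype), breakpoints=[b1, b1 + size], size=size,
                )
            out.append(build_structural_variant(ctx, design))
    return out


def _make_hla(rng: np.random.Generator, census: DesignCensus) -> list[HLABuild]:
    out = []
    L = census.sequin_length
    exon2 = (400, 670)
    exon3 = (900, 1170)
    for gene in census.hla_genes:
        base = random_dna(rng, L, gc=0.55)
        for a in range(1, census.alleles_per_gene + 1):
            seq = list(base)
            if a > 1:
                # alternative alleles differ at a handful of exonic SNVs
                for interval in (exon2, exon3):
                    for p in rng.choice(np.arange(*interval), size=3, replace=False):
                        seq[p] = _alt_base(rng, seq[p])
            allele_name = f"{gene}*{a:02d}:01"
            design = HLAAlleleDesign(gene, allele_name, exon2, exon3)
            sequin = SequinDefinition(
                id=f"{gene.replace('-', '_')}_{a:02d}", feature_kind=FeatureKind.HLA,
                natural_seq="".join(seq),
                annotations=[
                    FeatureAnnotation("exon2", *exon2),
                    FeatureAnnotation("exon3", *exon3),
                ],
            )
            out.append(HLABuild(design, sequin))
    return out


def _make_immune(rng: np.random.Generator, census: DesignCensus) -> ImmuneBuild:
    segments: dict[str, Segment] = {}
    clonotypes = []
    nonrearranged = []
    n_rear = census.rearranged_per_locus * len(IMMUNE_LOCI)
    # abundance ladder spanning two orders of magnitude, largest first
    raw = np.logspace(2, 0, n_rear)
    freqs = raw / raw.sum()
    k = 0
    L = census.sequin_length
    for locus in IMMUNE_LOCI:
        for kind, n in (("V", 2), ("J", 2), ("D", 1 if locus in D_LOCI else 0)):
            for i in range(1, n + 1):
                seg = make_segment(rng, locus, kind, i)
                segments[seg.seg_id] = seg
        for c in range(census.rearranged_per_locus):
            v = segments[f"{locus}V{c + 1}"]
            j = segments[f"{locus}J{c + 1}"]
            d = segments.get(f"{locus}D1") if locus in D_LOCI else None
            junction = random_dna(rng, int(rng.integers(21, 34)))
            core_len = len(v.seq) + len(junction) + len(j.seq)
            fl_left = random_dna(rng, (L - core_len) // 2, gc=0.45)
            fl_right = random_dna(rng, L - core_len - len(fl_left), gc=0.45)
            design, sequin = build_clonotype(
                clono_id=f"{locus}_C{c + 1}", v=v, j=j, junction=junction, locus=locus,
                d=d, trim_v=int(rng.integers(0, 4)), trim_j=int(rng.integers(0, 4)),
                expected_freq=float(freqs[k]), flank_left=fl_left, flank_right=fl_right,
            )
            s, e = design.cdr3_interval
            sequin.annotations.append(FeatureAnnotation(f"cdr3_{design.clono_id}", s, e))
            clonotypes.append((design, sequin))
            k += 1
        for c in range(census.nonrearranged_per_locus):
            kind = ("V", "J")[c % 2]
            seg = segments[f"{locus}{kind}{c // 2 + 1}"]
            flank = random_dna(rng, (L - len(seg.seq)) // 2, gc=0.45)
            nonrearranged.append(nonrearranged_sequin(seg, flank=flank))
    return ImmuneBuild(segments, clonotypes, nonrearranged)


def build_default_design(seed: int, census: DesignCensus | None = None) -> DesignBundle:
    """Generate the complete default design from a single seed."""
    census = census or DesignCensus()
    rng = np.random.default_rng(seed)
    bundle = DesignBundle(census=census, seed=seed)
    for i in range(census.smallvar_pairs):
        context = _CONTEXT_CYCLE[i % len(_CONTEXT_CYCLE)]
        bundle.smallvar_pairs.append(
            _make_smallvar_pair(rng, i, census, context, census.pair_vafs[i])
        )
    bundle.repeat_sequins = _make_repeat_sequins(rng, census)
    bundle.microsatellites = [
        _make_microsatellite(rng, name, census) for name in census.microsatellites
    ]
    for i, length in enumerate(_haplotype_lengths(census)):
        bundle.haplotypes.append(_make_haplotype(rng, i, length, census))
    bundle.svs = _make_svs(rng, census)
    bundle.hla = _make_hla(rng, census)
    bundle.immune = _make_immune(rng, census)
    return bundle
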