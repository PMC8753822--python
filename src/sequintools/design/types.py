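"""Domain types for synthetic-control design.

Coordinate conventions
----------------------
* ``FeatureAnnotation`` / BED-style intervals: 0-based half-open, on the
  *natural-orientation* template unless the field name says otherwise.
* ``VariantRecord.pos``: 1-based on the natural-orientation template
  (VCF-style anchor comes later, at write time).
* Decoy-chromosome coordinates: 0-based half-open internally; VCF writers
  convert to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from ..sequence import mirror_sequence, validate_dna


class FeatureKind(str, Enum):
    SMALLVAR = "smallvar"
    REPEAT = "repeat"
    MICROSATELLITE = "microsatellite"
    SV = "sv"
    HAPLOTYPE = "haplotype"
    HLA = "hla"
    IMMUNE = "immune"


class VariantClass(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"


class VariantContext(str, Enum):
    REPEAT = "repeat"
    GC_RICH = "gc_rich"
    GC_POOR = "gc_poor"
    NEUTRAL = "neutral"


class SVType(str, Enum):
    DEL = "DEL"
    INS = "INS"
    DUP = "DUP"
    INV = "INV"
    VIR = "VIR"
    TRA = "TRA"


@dataclass
class FeatureAnnotation:
    """A labelled interval on the natural-orientation template."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")


@dataclass
class SequinDefinition:
    """One synthetic control molecule.

    ``natural_seq`` is the template in natural (genome-like) orientation;
    ``mirrored_seq`` is the sequence actually synthesized/placed, i.e. the
    character-reversal of the template.  Pair members (reference/variant
    alleles) share a ``pair_id``.
    """

    id: str
    feature_kind: FeatureKind
    natural_seq: str
    pair_id: Optional[str] = None
    role: str = "single"  # "reference" | "variant" | "single"
    annotations: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_dna(self.natural_seq)

    @property
    def mirrored_seq(self) -> str:
        return mirror_sequence(self.natural_seq)

    def __len__(self) -> int:
        return len(self.natural_seq)


@dataclass
class VariantRecord:
    """A designed small variant on a sequin pair, in natural orientation.

    ``pos`` is 1-based.  ``ref``/``alt`` are plain allele strings; for pure
    insertions ``ref`` is empty and for pure deletions ``alt`` is empty
    (anchor bases are added only when serializing to VCF).
    """

    sequin_id: str
    pos: int
    ref: str
    alt: str
    vclass: VariantClass
    context: VariantContext = VariantContext.NEUTRAL
    designed_vaf: float = 0.5

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if not 0.0 < self.designed_vaf <= 1.0:
            raise ValueError(f"designed VAF {self.designed_vaf} outside (0, 1]")

    @property
    def start0(self) -> int:
        """0-based start of the replaced reference span."""
        return self.pos - 1

    @property
    def end0(self) -> int:
        return self.start0 + len(self.ref)


@dataclass
class StructuralVariantDesign:
    sv_id: str
    svtype: SVType
    breakpoints: list[int]  # 1-based positions on the affected context(s)
    size: int
    partner_sequin: Optional[str] = None  # TRA only
    payload: Optional[str] = None  # INS/VIR inserted sequence

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("SV size must be positive")
        if self.svtype is SVType.TRA and self.partner_sequin is None:
            raise ValueError("TRA requires a partner context")


@dataclass
class MicrosatelliteDesign:
    name: str
    motif: str
    copies: int
    stable: bool
    flank_left: str
    flank_right: str

    def __post_init__(self) -> None:
        if not 1 <= len(self.motif) <= 2:
            raise ValueError("motif must be 1-2 nt")
        if self.copies < 5:
            raise ValueError("microsatellites need >= 5 motif copies")

    @property
    def tract(self) -> str:
        return self.motif * self.copies

    @property
    def tract_interval(self) -> tuple[int, int]:
        """0-based half-open tract coordinates on the natural sequence."""
        s = len(self.flank_left)
        return s, s + len(self.tract)

    @property
    def natural_seq(self) -> str:
        return self.flank_left + self.tract + self.flank_right


@dataclass
class HaplotypeBlockPair:
    """Maternal/paternal alleles of one broad haplotype block.

    The maternal sequence is the 'reference' member placed on the decoy;
    sequences are identical outside ``het_sites`` (SNVs only), given as
    (0-based position, maternal allele, paternal allele).
    """

    block_id: str
    source_label: str
    maternal_seq: str
    paternal_seq: str
    het_sites: list[tuple[int, str, str]]

    def __post_init__(self) -> None:
        if len(self.maternal_seq) != len(self.paternal_seq):
            raise ValueError("haplotype members must have equal length (SNV het sites only)")
        for pos, am, ap in self.het_sites:
            if self.maternal_seq[pos] != am or self.paternal_seq[pos] != ap:
                raise ValueError(f"het site at {pos} inconsistent with sequences")


@dataclass
class ClonotypeDesign:
    clono_id: str
    locus: str  # IGL | IGK | TRG | TRD | TRB
    v_id: str
    j_id: str
    junction_seq: str
    cdr3_interval: tuple[int, int]  # 0-based half-open on the rearranged seq
    rearranged: bool
    expected_freq: float
    d_id: Optional[str] = None


@dataclass
class HLAAlleleDesign:
    gene: str  # HLA-A | HLA-B | HLA-C | HLA-DQB1
    allele_name: str
    exon2_interval: tuple[int, int]
    exon3_interval: tuple[int, int]

    def __post_init__(self) -> None:
        e2, e3 = self.exon2_interval, self.exon3_interval
        if not (e2[0] < e2[1] <= e3[0] < e3[1]):
            raise ValueError("exon intervals must be ordered and non-overlapping")


@dataclass
class Placement:
    sequin_id: str
    start: int
    end: int
    region_id: str


@dataclass
class DecoyChromosome:
    """The assembled decoy contig plus machine-readable truth sets."""

    name: str
    seq: str
    regions: list[tuple[str, int, int]]  # (region_id, start, end)
    placements: dict[str, Placement]
    edge_mask: list[tuple[str, int, int]]  # (sequin_id, start, end) decoy coords
    truth_small_variants: list[dict] = field(default_factory=list)
    truth_svs: list[dict] = field(default_factory=list)
    truth_phasing: list[dict] = field(default_factory=list)
    feature_intervals: list[dict] = field(default_factory=list)

    def placement_of(self, sequin_id: str) -> Placement:
        return self.placements[sequin_id]

    def to_decoy(self, sequin_id: str, natural_pos: int, natural_len: int) -> int:
        """Map a 0-based natural-orientation position to a decoy coordinate.

        Placement stores the *mirrored* sequence, so natural index ``i``
        lands at mirrored index ``L - 1 - i`` within the placement.
        """
        pl = self.placements[sequin_id]
        return pl.start + (natural_len - 1 - natural_pos)

    def to_natural(self, sequin_id: str, decoy_pos: int, natural_len: int) -> int:
        pl = self.placements[sequin_id]
        return natural_len - 1 - (decoy_pos - pl.start)
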