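"""Default design census: how many of each control the standard build makes.

Every count is overridable through :class:`DesignCensus`; the defaults
reproduce the published composition of the reference mixture this toolkit
emulates (1353 small variants, 12 Bethesda-panel microsatellites, 24
haplotype block pairs averaging 5.9 kb, 54 structural variants by type,
8 HLA alleles, 20 immune loci).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Bethesda-panel microsatellite designs: name -> (motif, copies, stable,
#: designed length shift of the unstable variant member, in motif copies).
#: Mononucleotide tract lengths follow the markers' names (e.g. BAT-25 is a
#: 25-nt poly-T run); dinucleotide loci are CA repeats.
BETHESDA_PANEL: dict[str, tuple[str, int, bool, int]] = {
    "NR27": ("A", 27, True, 0),
    "NR24": ("A", 24, True, 0),
    "NR22": ("A", 22, True, 0),
    "NR21": ("A", 21, True, 0),
    "MONO27": ("A", 27, True, 0),
    "D18S55": ("CA", 14, True, 0),
    "CAT25": ("T", 25, True, 0),
    "BAT-25": ("T", 25, False, -3),
    "BAT-26": ("A", 26, False, -4),
    "D2S123": ("CA", 13, False, -2),
    "D5S346": ("CA", 12, False, -1),
    "D17S250": ("CA", 15, False, -2),
}

STABLE_PANEL = tuple(n for n, v in BETHESDA_PANEL.items() if v[2])
UNSTABLE_PANEL = tuple(n for n, v in BETHESDA_PANEL.items() if not v[2])

#: per-pair designed VAFs for the small-variant section: 30 germline het,
#: 3 germline hom-alt, and a somatic dilution series (two pairs per level)
DEFAULT_PAIR_VAFS: tuple[float, ...] = (
    *([0.5] * 30),
    *([1.0] * 3),
    0.1, 0.1, 0.05, 0.05, 0.02, 0.02, 0.01, 0.01,
)


@dataclass
class DesignCensus:
    """Counts and sizes driving the default decoy build."""

    # small-variant section (p1)
    smallvar_pairs: int = 41
    variants_per_pair: int = 33
    pair_vafs: tuple[float, ...] = DEFAULT_PAIR_VAFS
    microsatellites: tuple[str, ...] = tuple(BETHESDA_PANEL)
    haplotype_pairs: int = 24
    haplotype_mean_len: int = 5900
    haplotype_len_spread: int = 1500
    het_spacing: int = 300

    # structural-variant section (p2), counts per type
    sv_del: int = 10
    sv_ins: int = 6
    sv_dup: int = 11
    sv_inv: int = 10
    sv_vir: int = 9
    sv_tra: int = 8

    # HLA section (p3)
    hla_genes: tuple[str, ...] = ("HLA-A", "HLA-B", "HLA-C", "HLA-DQB1")
    alleles_per_gene: int = 2

    # immune section (p4)
    rearranged_per_locus: int = 2
    nonrearranged_per_locus: int = 2

    # geometry
    sequin_length: int = 2000
    edge_width: int = 400
    decoy_name: str = "chrQ"

    #: designed large/medium homopolymer runs embedded in repeat-context
    #: templates (base, run length); spans the three published size classes
    designed_homopolymers: tuple[tuple[str, int], ...] = (
        ("A", 8), ("T", 10), ("G", 12), ("C", 14), ("A", 18), ("T", 22), ("G", 27),
    )

    def __post_init__(self) -> None:
        if len(self.pair_vafs) != self.smallvar_pairs:
            raise ValueError("pair_vafs must list one VAF per small-variant pair")

    @property
    def n_small_variants(self) -> int:
        return self.smallvar_pairs * self.variants_per_pair

    @property
    def sv_counts(self) -> dict[str, int]:
        return {
            "DEL": self.sv_del,
            "INS": self.sv_ins,
            "DUP": self.sv_dup,
            "INV": self.sv_inv,
            "VIR": self.sv_vir,
            "TRA": self.sv_tra,
        }

    @property
    def n_svs(self) -> int:
        return sum(self.sv_counts.values())

    @property
    def n_hla_alleles(self) -> int:
        return len(self.hla_genes) * self.alleles_per_gene

    @property
    def n_immune_loci(self) -> int:
        return 5 * (self.rearranged_per_locus + self.nonrearranged_per_locus)
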