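"""Synthetic immune-receptor (TCR/BCR) locus construction.

Rearranged clonotypes are built as V' + junction + J' with the CDR3 region
anchored by the conserved cysteine codon near the V 3' end and the
conserved tryptophan codon near the J 5' end (IMGT-style numbering:
Cys-104 ... Trp-118).  Segment libraries here are fully synthetic; no real
IMGT sequences are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..sequence import random_dna
from .types import ClonotypeDesign, FeatureKind, SequinDefinition

CYS_CODON = "TGT"
TRP_CODON = "TGG"

#: nt of trimmable sequence distal to each anchor codon
V_TAIL = 6
J_HEAD = 6

IMMUNE_LOCI = ("IGL", "IGK", "TRG", "TRD", "TRB")
#: loci whose rearrangement includes a D segment
D_LOCI = ("TRB", "TRD")


@dataclass
class Segment:
    seg_id: str
    locus: str
    kind: str  # V | D | J
    seq: str


def make_segment(rng: np.random.Generator, locus: str, kind: str, index: int) -> Segment:
    """Generate one synthetic germline segment with its anchor codon.

    V segments end ``... CYS tail(6)``; J segments start ``head(6) TRP ...``.
    D segments are short and anchor-free.
    """
    seg_id = f"{locus}{kind}{index}"
    if kind == "V":
        core = random_dna(rng, 291 - V_TAIL - 3)
        seq = core + CYS_CODON + random_dna(rng, V_TAIL)
    elif kind == "J":
        seq = random_dna(rng, J_HEAD) + TRP_CODON + random_dna(rng, 150 - J_HEAD - 3)
    elif kind == "D":
        seq = random_dna(rng, 16)
    else:
        raise ValueError(f"unknown segment kind {kind}")
    return Segment(seg_id, locus, kind, seq)


def _require_anchor(seg: Segment) -> None:
    if seg.kind == "V" and seg.seq[-V_TAIL - 3 : -V_TAIL] != CYS_CODON:
        raise ValueError(f"V segment {seg.seg_id} lacks the conserved cysteine anchor codon")
    if seg.kind == "J" and seg.seq[J_HEAD : J_HEAD + 3] != TRP_CODON:
        raise ValueError(f"J segment {seg.seg_id} lacks the conserved tryptophan anchor codon")


def build_clonotype(
    clono_id: str,
    v: Segment,
    j: Segment,
    junction: str,
    locus: str,
    d: Segment | None = None,
    trim_v: int = 0,
    trim_j: int = 0,
    expected_freq: float = 0.0,
    flank_left: str = "",
    flank_right: str = "",
) -> tuple[ClonotypeDesign, SequinDefinition]:
    """Assemble one rearranged clonotype sequin.

    ``junction`` is the designed inter-anchor insert (it already contains
    any D-derived bases; ``d`` is recorded for the truth table only).
    Trimming removes up to ``V_TAIL``/``J_HEAD`` nt distal to the anchors,
    which the anchors must survive.  The genomic-context flanks pad the
    locus so the CDR3 sits away from molecule termini.
    """
    if locus in D_LOCI and d is None:
        raise ValueError(f"{locus} rearrangements require a D segment")
    _require_anchor(v)
    _require_anchor(j)
    if not 0 <= trim_v <= V_TAIL or not 0 <= trim_j <= J_HEAD:
        raise ValueError("trimming would remove an anchor codon")
    v_part = v.seq[: len(v.seq) - trim_v]
    j_part = j.seq[trim_j:]
    rearranged = v_part + junction + j_part
    cys_start = len(v.seq) - V_TAIL - 3
    trp_start = len(v_part) + len(junction) + (J_HEAD - trim_j)
    cdr3 = (len(flank_left) + cys_start, len(flank_left) + trp_start + 3)

    natural = flank_left + rearranged + flank_right
    design = ClonotypeDesign(
        clono_id=clono_id,
        locus=locus,
        v_id=v.seg_id,
        j_id=j.seg_id,
        d_id=d.seg_id if d else None,
        junction_seq=junction,
        cdr3_interval=cdr3,
        rearranged=True,
        expected_freq=expected_freq,
    )
    sequin = SequinDefinition(
        id=clono_id, feature_kind=FeatureKind.IMMUNE, natural_seq=natural, role="single"
    )
    return design, sequin


def nonrearranged_sequin(seg: Segment, flank: str = "") -> SequinDefinition:
    """A germline (un-joined) segment shipped as its own control molecule."""
    return SequinDefinition(
        id=f"{seg.seg_id}_germline",
        feature_kind=FeatureKind.IMMUNE,
        natural_seq=flank + seg.seq + flank,
        role="single",
    )
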