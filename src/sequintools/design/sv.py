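"""Structural-variant sequin construction by direct string surgery.

Breakpoints are 0-based gap coordinates on the natural-orientation context:
an interval SV affects ``context[b1:b2]`` and a point insertion happens at
gap ``b1``.  Each builder returns the reference member(s), the variant
member(s) realizing the rearrangement, and the natural-coordinate
breakpoints that constitute the truth set.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..sequence import reverse_complement
from .types import FeatureKind, SVType, SequinDefinition, StructuralVariantDesign


@dataclass
class SVBuild:
    design: StructuralVariantDesign
    refs: list[SequinDefinition]
    variants: list[SequinDefinition]
    #: (context_sequin_id, 0-based gap position on the natural context)
    truth_breakpoints: list[tuple[str, int]]


def realize_sv(context: str, design: StructuralVariantDesign, partner: str | None = None) -> list[str]:
    """Apply the rearrangement and return the variant sequence(s)."""
    t = design.svtype
    bps = design.breakpoints
    if t is SVType.TRA:
        if partner is None:
            raise ValueError("TRA needs two contexts")
        jx, jy = bps
        if not (0 < jx < len(context) and 0 < jy < len(partner)):
            raise ValueError("TRA junctions outside contexts")
        return [context[:jx] + partner[jy:], partner[:jy] + context[jx:]]
    if t in (SVType.INS, SVType.VIR):
        (b1,) = bps if len(bps) == 1 else (bps[0],)
        if design.payload is None or len(design.payload) != design.size:
            raise ValueError("INS/VIR requires a payload of the designed size")
        if not 0 < b1 < len(context):
            raise ValueError("insertion point outside context")
        return [context[:b1] + design.payload + context[b1:]]
    b1, b2 = bps
    if not 0 <= b1 < b2 <= len(context):
        raise ValueError(f"breakpoints [{b1}, {b2}) outside context of {len(context)} nt")
    if b2 - b1 != design.size:
        raise ValueError("breakpoint span disagrees with designed size")
    if t is SVType.DEL:
        return [context[:b1] + context[b2:]]
    if t is SVType.DUP:
        return [context[:b2] + context[b1:b2] + context[b2:]]
    if t is SVType.INV:
        return [context[:b1] + reverse_complement(context[b1:b2]) + context[b2:]]
    raise ValueError(f"unhandled SV type {t}")


def build_structural_variant(
    context: str,
    design: StructuralVariantDesign,
    partner_context: str | None = None,
) -> SVBuild:
    """Build reference and variant sequin members for one SV design.

    TRA is reciprocal: two reference contexts and two derivative products,
    one junction on each context.  All other types have a single context.
    """
    variants_seqs = realize_sv(context, design, partner_context)
    sid = design.sv_id
    if design.svtype is SVType.TRA:
        refs = [
            SequinDefinition(f"{sid}_A_R", FeatureKind.SV, context, pair_id=sid, role="reference"),
            SequinDefinition(f"{sid}_B_R", FeatureKind.SV, partner_context, pair_id=sid, role="reference"),
        ]
        variants = [
            SequinDefinition(f"{sid}_A_V", FeatureKind.SV, variants_seqs[0], pair_id=sid, role="variant"),
            SequinDefinition(f"{sid}_B_V", FeatureKind.SV, variants_seqs[1], pair_id=sid, role="variant"),
        ]
        truth = [(refs[0].id, design.breakpoints[0]), (refs[1].id, design.breakpoints[1])]
    else:
        refs = [SequinDefinition(f"{sid}_R", FeatureKind.SV, context, pair_id=sid, role="reference")]
        variants = [SequinDefinition(f"{sid}_V", FeatureKind.SV, variants_seqs[0], pair_id=sid, role="variant")]
        if design.svtype in (SVType.INS, SVType.VIR):
            truth = [(refs[0].id, design.breakpoints[0])]
        else:
            truth = [(refs[0].id, design.breakpoints[0]), (refs[0].id, design.breakpoints[1])]
    return SVBuild(design=design, refs=refs, variants=variants, truth_breakpoints=truth)
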