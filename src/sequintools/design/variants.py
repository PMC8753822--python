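"""Construction of reference/variant sequin pairs from small-variant specs.

A pair consists of two overlapping molecules that are identical except at
the designed variant sites, so their reads co-locate on the decoy (where
only the reference member is placed) and the variant reads present the
alternate alleles at known positions and frequencies.
"""

from __future__ import annotations

import numpy as np

from .types import FeatureKind, SequinDefinition, VariantRecord


def _check_variants(template: str, variants: list[VariantRecord]) -> list[VariantRecord]:
    """Validate ref-allele identity and non-overlap; return sorted copies."""
    svs = sorted(variants, key=lambda v: (v.start0, v.end0))
    prev_end = -1
    for v in svs:
        if v.end0 > len(template):
            raise ValueError(f"variant at pos {v.pos} extends past template end")
        observed = template[v.start0 : v.end0]
        if observed != v.ref:
            raise ValueError(
                f"ref-allele mismatch at pos {v.pos}: template has "
                f"{observed!r}, spec says {v.ref!r}"
            )
        # insertions at the same gap as a preceding edit are also overlaps
        if v.start0 < prev_end or (v.start0 == prev_end and not v.ref):
            raise ValueError(f"overlapping variant specs near pos {v.pos}")
        prev_end = max(prev_end, v.end0) if v.ref else max(prev_end, v.start0 + 1)
    return svs


def apply_variants(template: str, variants: list[VariantRecord]) -> str:
    """Return the variant-allele sequence (natural orientation)."""
    svs = _check_variants(template, variants)
    out: list[str] = []
    cursor = 0
    for v in svs:
        out.append(template[cursor : v.start0])
        out.append(v.alt)
        cursor = v.end0
    out.append(template[cursor:])
    return "".join(out)


def variant_alignment_map(template: str, variants: list[VariantRecord]) -> np.ndarray:
    """Per-base alignment of the variant molecule onto its template.

    Returns an int array of length ``len(variant_seq)`` whose entry is the
    0-based template position a molecule base aligns to, or -1 for bases
    inside an inserted allele.  Substituted bases stay aligned; deleted
    template bases simply do not appear.  This colinear map is what lets the
    read simulator emit pre-aligned records for variant-member reads.
    """
    svs = _check_variants(template, variants)
    out: list[int] = []
    cursor = 0
    for v in svs:
        out.extend(range(cursor, v.start0))
        if len(v.ref) == len(v.alt):  # substitution block stays aligned
            out.extend(range(v.start0, v.end0))
        else:
            out.extend([-1] * len(v.alt))
        cursor = v.end0
    out.extend(range(cursor, len(template)))
    return np.asarray(out, dtype=np.int64)


def build_variant_pair(
    template: str,
    variants: list[VariantRecord],
    pair_id: str,
    feature_kind: FeatureKind = FeatureKind.SMALLVAR,
) -> tuple[SequinDefinition, SequinDefinition]:
    """Build the reference and variant members of a sequin pair.

    Both members carry the same ``pair_id``; variant coordinates are
    recorded on the natural orientation via the ``VariantRecord`` list the
    caller retains.  An empty variant list yields identical members.
    """
    var_seq = apply_variants(template, variants)
    ref = SequinDefinition(
        id=f"{pair_id}_R",
        feature_kind=feature_kind,
        natural_seq=template,
        pair_id=pair_id,
        role="reference",
    )
    var = SequinDefinition(
        id=f"{pair_id}_V",
        feature_kind=feature_kind,
        natural_seq=var_seq,
        pair_id=pair_id,
        role="variant",
    )
    return ref, var


def mirror_variant(
    v: VariantRecord, natural_len: int
) -> tuple[int, str, str]:
    """Express a natural-orientation variant in mirrored-molecule coordinates.

    Returns ``(start0, ref, alt)`` on the mirrored sequence: the replaced
    span ``[start0, start0+len(ref))`` with allele strings reversed (mirror
    reverses, never complements).  For a pure insertion the start is the
    mirrored gap position.
    """
    start0 = natural_len - v.end0
    return start0, v.ref[::-1], v.alt[::-1]
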