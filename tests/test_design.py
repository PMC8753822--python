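"""Design module: variant pairs, structural variants, clonotypes,
assembly, and the truth-set consistency contracts."""

import numpy as np
import edlib
import pysam
import pytest
from pyfaidx import Fasta

from sequintools.design import (
    DesignCensus,
    FeatureKind,
    SequinDefinition,
    StructuralVariantDesign,
    SVType,
    VariantClass,
    VariantRecord,
    apply_variants,
    assemble_decoy_chromosome,
    build_structural_variant,
    build_variant_pair,
    realize_sv,
    variant_alignment_map,
)
from sequintools.design.builder import DesignBundle
from sequintools.design.immune import Segment, build_clonotype
from sequintools.sequence import reverse_complement


def _snv(pos, ref, alt, sid="T_R"):
    return VariantRecord(sequin_id=sid, pos=pos, ref=ref, alt=alt, vclass=VariantClass.SNV)


class TestVariantPairs:
    def test_single_base_edit(self):
        ref, var = build_variant_pair("ACGTACGT", [_snv(3, "G", "T")], "T")
        assert var.natural_seq == "ACTTACGT"
        assert ref.natural_seq == "ACGTACGT"
        assert ref.pair_id == var.pair_id == "T"

    def test_empty_variant_list_gives_identical_members(self):
        ref, var = build_variant_pair("ACGTACGT", [], "T")
        assert ref.natural_seq == var.natural_seq

    def test_deletion_length_arithmetic(self):
        tmpl = "AACGTACGTA"
        v = VariantRecord(sequin_id="T_R", pos=2, ref=tmpl[1:4], alt="",
                          vclass=VariantClass.DEL)
        ref, var = build_variant_pair(tmpl, [v], "T")
        assert len(var.natural_seq) == len(tmpl) - 3

    def test_ref_mismatch_rejected_naming_position(self):
        with pytest.raises(ValueError, match="pos 3"):
            build_variant_pair("ACGTACGT", [_snv(3, "C", "T")], "T")

    def test_overlapping_specs_rejected(self):
        tmpl = "ACGTACGT"
        v1 = VariantRecord(sequin_id="x", pos=2, ref="CGT", alt="", vclass=VariantClass.DEL)
        v2 = _snv(3, "G", "A")
        with pytest.raises(ValueError, match="overlap"):
            apply_variants(tmpl, [v1, v2])

    def test_alignment_map_tracks_indels(self):
        tmpl = "ACGTACGT"
        ins = VariantRecord(sequin_id="x", pos=3, ref="", alt="TT", vclass=VariantClass.INS)
        amap = variant_alignment_map(tmpl, [ins])
        # A C [T T] G T A C G T : inserted bases unaligned (-1)
        assert amap.tolist() == [0, 1, -1, -1, 2, 3, 4, 5, 6, 7]

    def test_pair_members_differ_only_at_designed_sites(self, bundle):
        p = bundle.smallvar_pairs[0]
        n_edits = sum(max(len(v.ref), len(v.alt)) for v in p.variants)
        d = edlib.align(p.ref.natural_seq, p.var.natural_seq, task="distance")
        assert 0 < d["editDistance"] <= n_edits


class TestStructuralVariants:
    def test_deletion_shortens_by_size(self):
        ctx = "A" * 40 + "C" * 10 + "G" * 50
        d = StructuralVariantDesign("d", SVType.DEL, [40, 50], 10)
        build = build_structural_variant(ctx, d)
        assert len(build.variants[0].natural_seq) == 90
        assert build.variants[0].natural_seq == "A" * 40 + "G" * 50

    def test_duplication_doubles_interval(self):
        ctx = "ACGTACGTAC" * 10
        d = StructuralVariantDesign("d", SVType.DUP, [10, 20], 10)
        var = build_structural_variant(ctx, d).variants[0].natural_seq
        assert var[10:30] == ctx[10:20] * 2
        assert len(var) == 110

    def test_inversion_reverse_complements_in_place(self):
        ctx = "AAAACCCCGGGGTTTT"
        d = StructuralVariantDesign("d", SVType.INV, [4, 12], 8)
        var = build_structural_variant(ctx, d).variants[0].natural_seq
        assert var == ctx[:4] + reverse_complement(ctx[4:12]) + ctx[12:]

    def test_translocation_product_lengths(self):
        # junctions at prefix lengths 40 and 60: products 40+40 and 60+60
        x, y = "A" * 100, "C" * 100
        d = StructuralVariantDesign("t", SVType.TRA, [40, 60], 21, partner_sequin="p")
        prods = realize_sv(x, d, partner=y)
        assert sorted(len(p) for p in prods) == [80, 120]
        assert prods[0] == x[:40] + y[60:]
        assert prods[1] == y[:60] + x[40:]

    def test_oversized_sv_rejected(self):
        with pytest.raises(ValueError):
            d = StructuralVariantDesign("d", SVType.DEL, [90, 120], 30)
            realize_sv("A" * 100, d)

    def test_sv_realizability_oracle(self, bundle):
        """Re-applying each designed SV to its reference member by
        independent string surgery reproduces the variant member."""
        for build in bundle.svs:
            d = build.design
            if d.svtype is SVType.TRA:
                a = build.refs[0].natural_seq
                b = build.refs[1].natural_seq
                jx, jy = d.breakpoints
                assert build.variants[0].natural_seq == a[:jx] + b[jy:]
                assert build.variants[1].natural_seq == b[:jy] + a[jx:]
                continue
            ctx = build.refs[0].natural_seq
            var = build.variants[0].natural_seq
            if d.svtype is SVType.DEL:
                b1, b2 = d.breakpoints
                assert var == ctx[:b1] + ctx[b2:]
            elif d.svtype in (SVType.INS, SVType.VIR):
                b1 = d.breakpoints[0]
                assert var == ctx[:b1] + d.payload + ctx[b1:]
            elif d.svtype is SVType.DUP:
                b1, b2 = d.breakpoints
                assert var == ctx[:b2] + ctx[b1:b2] + ctx[b2:]
            elif d.svtype is SVType.INV:
                b1, b2 = d.breakpoints
                assert var == ctx[:b1] + reverse_complement(ctx[b1:b2]) + ctx[b2:]


class TestClonotypes:
    def _segments(self):
        v = Segment("V1", "IGL", "V", "A" * 21 + "TGT" + "G" * 6)  # 30 nt
        j = Segment("J1", "IGL", "J", "C" * 6 + "TGG" + "T" * 11)  # 20 nt
        return v, j

    def test_untrimmed_length(self):
        v, j = self._segments()
        _, seq = build_clonotype("c", v, j, "A" * 12, "IGL")
        assert len(seq.natural_seq) == 62

    def test_trimmed_length(self):
        v, j = self._segments()
        _, seq = build_clonotype("c", v, j, "A" * 12, "IGL", trim_v=3, trim_j=2)
        assert len(seq.natural_seq) == 57

    def test_cdr3_interval_by_manual_codon_count(self):
        v, j = self._segments()
        design, seq = build_clonotype("c", v, j, "A" * 12, "IGL")
        s, e = design.cdr3_interval
        # interval runs from the Cys codon start to the Trp codon end
        assert seq.natural_seq[s : s + 3] == "TGT"
        assert seq.natural_seq[e - 3 : e] == "TGG"
        # manual count: Cys codon at 21 (21 nt of V core), Trp codon at
        # 30 (V) + 12 (junction) + 6 (J head) = 48; interval = [21, 51)
        assert (s, e) == (21, 51)
        assert e - s == (48 - 21) + 3  # anchor-start distance + one codon

    def test_missing_anchor_rejected(self):
        bad_v = Segment("V1", "IGL", "V", "A" * 30)
        _, j = self._segments()
        with pytest.raises(ValueError, match="cysteine"):
            build_clonotype("c", bad_v, j, "AAA", "IGL")

    def test_d_segment_required_for_trb(self):
        v = Segment("V1", "TRB", "V", "A" * 21 + "TGT" + "G" * 6)
        j = Segment("J1", "TRB", "J", "C" * 6 + "TGG" + "T" * 11)
        with pytest.raises(ValueError, match="D segment"):
            build_clonotype("c", v, j, "AAA", "TRB")


class TestAssembly:
    def test_spacer_free_concatenation(self, bundle, decoy):
        total = sum(p.end - p.start for p in decoy.placements.values())
        assert total == len(decoy.seq)
        starts = sorted(p.start for p in decoy.placements.values())
        ends = sorted(p.end for p in decoy.placements.values())
        assert starts[0] == 0 and ends[-1] == len(decoy.seq)
        assert all(e == s for e, s in zip(ends[:-1], starts[1:]))

    def test_decoy_slice_equals_mirrored_sequence(self, bundle, decoy):
        placed = {s.id: s for region in bundle.placed_sequins().values() for s in region}
        for sid, p in decoy.placements.items():
            assert decoy.seq[p.start : p.end] == placed[sid].mirrored_seq

    def test_only_reference_members_placed(self, bundle, decoy):
        for region in bundle.placed_sequins().values():
            for s in region:
                assert s.role in ("reference", "single")
        for p in bundle.smallvar_pairs:
            assert p.var.id not in decoy.placements

    def test_coordinate_round_trip(self, decoy):
        p = decoy.placements["SV000_R"]
        L = p.end - p.start
        for natural_pos in (0, 1, L // 2, L - 1):
            dpos = decoy.to_decoy("SV000_R", natural_pos, L)
            assert p.start <= dpos < p.end
            assert decoy.to_natural("SV000_R", dpos, L) == natural_pos

    def test_truth_vcf_ref_matches_decoy_fasta(self, design_outdir):
        fa = Fasta(str(design_outdir["decoy_fasta"]))
        with pysam.VariantFile(str(design_outdir["truth_smallvar_vcf"])) as vf:
            n = 0
            for rec in vf:
                assert str(fa["chrQ"][rec.start : rec.start + len(rec.ref)]) == rec.ref
                n += 1
        assert n == DesignCensus().n_small_variants

    def test_feature_intervals_inside_placements(self, decoy):
        for f in decoy.feature_intervals:
            p = decoy.placements[f["sequin_id"]]
            assert p.start <= f["start"] < f["end"] <= p.end

    def test_edge_mask_covers_each_terminus(self, decoy):
        by_sequin = {}
        for sid, s, e in decoy.edge_mask:
            by_sequin.setdefault(sid, []).append((s, e))
        for sid, p in decoy.placements.items():
            ivals = sorted(by_sequin[sid])
            assert ivals[0][0] == p.start
            assert ivals[-1][1] == p.end

    def test_truth_sv_vcf_round_trip(self, design_outdir, decoy):
        from sequintools.sv_eval import truth_from_decoy, truth_svs_from_vcf

        loaded = {sv.sv_id: sv for sv in truth_svs_from_vcf(design_outdir["truth_sv_vcf"])}
        for sv in truth_from_decoy(decoy):
            got = loaded[sv.sv_id]
            assert got.svtype == sv.svtype
            assert sorted(got.breakpoints) == sorted(sv.breakpoints)

    def test_duplicate_placement_rejected(self):
        census = DesignCensus()
        from sequintools.design.builder import build_default_design

        bundle = build_default_design(3, census)
        # force a duplicate by placing the same sequin object twice
        bundle.repeat_sequins.append(bundle.repeat_sequins[0])
        with pytest.raises(ValueError, match="duplicate|placed twice"):
            assemble_decoy_chromosome(bundle)


class TestCensusDefaults:
    def test_haplotype_blocks_average_designed_length(self, bundle):
        lengths = [len(h.pair.maternal_seq) for h in bundle.haplotypes]
        assert len(lengths) == 24
        assert np.mean(lengths) == pytest.approx(5900.0)

    def test_microsatellite_panel(self, bundle):
        from sequintools.design import STABLE_PANEL, UNSTABLE_PANEL

        assert set(STABLE_PANEL) == {"NR27", "NR24", "NR22", "NR21", "MONO27", "D18S55", "CAT25"}
        assert set(UNSTABLE_PANEL) == {"BAT-25", "BAT-26", "D2S123", "D5S346", "D17S250"}
        assert len(bundle.microsatellites) == 12
        unstable = [m for m in bundle.microsatellites if m.var is not None]
        assert len(unstable) == 5

    def test_build_is_seed_deterministic(self):
        from sequintools.design import build_default_design

        a = assemble_decoy_chromosome(build_default_design(5))
        b = assemble_decoy_chromosome(build_default_design(5))
        c = assemble_decoy_chromosome(build_default_design(6))
        assert a.seq == b.seq
        assert a.seq != c.seq
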