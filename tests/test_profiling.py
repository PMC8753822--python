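"""Pileup profiling: oracle equivalence, normalization, spectra, and the
permissive caller with FP-by-AF curves."""

import numpy as np
import pandas as pd
import pysam
import pytest

from sequintools import readsim
from sequintools.profiling import (
    PerBaseProfile,
    PermissiveThresholds,
    coverage_by_gc,
    error_summary,
    fp_rate_by_af,
    gc_strata_summary,
    normalized_coverage,
    permissive_pileup_call,
    pileup_profile,
    truth_key_set,
)

from conftest import simulate_bam


def _hand_bam(tmp_path, records, ref_len=300, name="chrQ"):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": name, "LN": ref_len}]}
    path = tmp_path / "hand.bam"
    with pysam.AlignmentFile(str(path.with_suffix(".un.bam")), "wb", header=header) as out:
        for i, (start, seq, cigar) in enumerate(records):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i}"
            a.query_sequence = seq
            a.reference_id = 0
            a.reference_start = start
            a.cigarstring = cigar
            a.mapping_quality = 60
            out.write(a)
    pysam.sort("-o", str(path), str(path.with_suffix(".un.bam")))
    pysam.index(str(path))
    return path


def _naive_recount(bam, region, ref_seq):
    """Independent per-read recount via pysam aligned pairs."""
    chrom, start, end = region
    n = end - start
    depth = np.zeros(n, int)
    matches = np.zeros(n, int)
    mismatches = np.zeros(n, int)
    ins = np.zeros(n, int)
    dels = np.zeros(n, int)
    with pysam.AlignmentFile(str(bam)) as af:
        for rec in af.fetch(chrom, start, end):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            # soft-clipped query positions (excluded: they are unaligned)
            soft: set[int] = set()
            q = 0
            for op, ln in rec.cigartuples:
                if op == 4:
                    soft.update(range(q, q + ln))
                if op in (0, 1, 4, 7, 8):
                    q += ln
            prev_r = None
            prev_was_aligned = False
            for qpos, rpos in rec.get_aligned_pairs():
                if rpos is not None and qpos is not None:
                    if start <= rpos < end:
                        depth[rpos - start] += 1
                        if rec.query_sequence[qpos] == ref_seq[rpos - start]:
                            matches[rpos - start] += 1
                        else:
                            mismatches[rpos - start] += 1
                    prev_r = rpos
                    prev_was_aligned = True
                elif rpos is None and qpos is not None:
                    if qpos not in soft:
                        # first inserted base after an aligned base: one event
                        if prev_was_aligned and prev_r is not None and start <= prev_r < end:
                            ins[prev_r - start] += 1
                        prev_was_aligned = False
                elif rpos is not None and qpos is None:
                    if start <= rpos < end:
                        dels[rpos - start] += 1
                    prev_r = rpos
                    prev_was_aligned = False
    return depth, matches, mismatches, ins, dels


class TestPileup:
    def test_single_perfect_read_depth(self, tmp_path):
        ref = "ACGT" * 75
        bam = _hand_bam(tmp_path, [(50, ref[50:150], "100M")])
        prof = pileup_profile(bam, ("chrQ", 0, 300), ref)
        assert prof.depth[50:150].tolist() == [1] * 100
        assert prof.depth[:50].sum() == 0 and prof.depth[150:].sum() == 0
        assert prof.matches[50:150].tolist() == [1] * 100
        assert prof.mismatches.sum() == 0

    def test_cigar_walk_handles_indels(self, tmp_path):
        ref = "A" * 300
        # 10M 2I 10M: insertion anchored after ref position 59
        # 10M 3D 10M: deletion spanning 70..73
        bam = _hand_bam(
            tmp_path,
            [(50, "A" * 22, "10M2I10M"), (60, "A" * 20, "10M3D10M")],
        )
        prof = pileup_profile(bam, ("chrQ", 0, 300), ref)
        assert prof.insertion_starts[59] == 1
        assert prof.deletion_spans[70:73].tolist() == [1, 1, 1]
        assert prof.deletion_spans.sum() == 3

    def test_matches_plus_mismatches_bounded_by_depth(self, tmp_path):
        ref = "ACGT" * 75
        bam = _hand_bam(tmp_path, [(0, "T" * 50 + ref[50:100], "100M")])
        prof = pileup_profile(bam, ("chrQ", 0, 300), ref)
        assert ((prof.matches + prof.mismatches) <= prof.depth).all()

    def test_unindexed_input_rejected(self, tmp_path):
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrQ", "LN": 100}]}
        p = tmp_path / "noidx.sam"
        with pysam.AlignmentFile(str(p), "w", header=header):
            pass
        with pytest.raises(ValueError, match="indexed"):
            pileup_profile(p, ("chrQ", 0, 100), "A" * 100)

    def test_equals_naive_recount_oracle(self, bundle, decoy, manifest, molecules,
                                         decoy_maps, tmp_path):
        """Pileup equals an independent aligned-pairs recount on a <=50-read
        instance with substitution and indel errors."""
        cfg = readsim.ReadSimConfig(
            read_length=100, fragment_mean=250, fragment_sd=30,
            substitution_rate=0.02, insertion_rate=2e-3, deletion_rate=2e-3,
        )
        bam, _ = simulate_bam(manifest, molecules, cfg, decoy_maps, decoy,
                              tmp_path / "oracle.bam", seed=21,
                              ids=["REP00"], n_fragments=25)
        pl = decoy.placements["REP00"]
        region = (decoy.name, pl.start, pl.end)
        ref = decoy.seq[pl.start : pl.end]
        prof = pileup_profile(bam, region, ref)
        depth, matches, mismatches, ins, dels = _naive_recount(bam, region, ref)
        assert (prof.depth == depth).all()
        assert (prof.matches == matches).all()
        assert (prof.mismatches == mismatches).all()
        assert (prof.insertion_starts == ins).all()
        assert (prof.deletion_spans == dels).all()

    def test_mismatch_positions_equal_injected_error_log(self, bundle, decoy,
                                                         manifest, molecules,
                                                         decoy_maps, tmp_path):
        """Per-position mismatch counts equal the simulator's own injected
        substitution log exactly (reference molecule, subs only)."""
        cfg = readsim.ReadSimConfig(
            read_length=100, fragment_mean=250, fragment_sd=30, substitution_rate=0.01
        )
        bam, res = simulate_bam(manifest, molecules, cfg, decoy_maps, decoy,
                                tmp_path / "log.bam", seed=22,
                                ids=["REP01"], n_fragments=300)
        pl = decoy.placements["REP01"]
        prof = pileup_profile(bam, (decoy.name, pl.start, pl.end),
                              decoy.seq[pl.start : pl.end])
        expected = np.zeros(pl.end - pl.start, int)
        dmap = decoy_maps["REP01"]
        for r in res.reads:
            for e in r.events:
                if e.kind == "sub":
                    decoy_pos = dmap[r.slice_start + e.mol_offset]
                    expected[decoy_pos - pl.start] += 1
        assert (prof.mismatches == expected).all()

    def test_edge_mask_excluded_from_summaries(self, tmp_path):
        ref = "ACGT" * 100
        bam = _hand_bam(tmp_path, [(0, ref[0:100], "100M")], ref_len=400)
        prof = pileup_profile(bam, ("chrQ", 0, 400), ref,
                              edge_mask=[("x", 0, 50)])
        assert prof.mask[:50].all() and not prof.mask[50:].any()
        norm = normalized_coverage(prof)
        # masked positions do not enter the normalization mean
        ok = prof.unmasked()
        assert norm[ok].mean() == pytest.approx(norm[ok].mean())
        gc = coverage_by_gc(prof, window=100)
        assert (gc["window_start"] >= 0).all()


class TestCoverageByGC:
    def _uniform_profile(self, ref, depth_value=7):
        n = len(ref)
        return PerBaseProfile(
            region=("chrQ", 0, n), ref_seq=ref,
            depth=np.full(n, depth_value, dtype=np.int64),
            matches=np.full(n, depth_value, dtype=np.int64),
            mismatch_by_base={b: np.zeros(n, dtype=np.int64) for b in "ACGT"},
            insertion_starts=np.zeros(n, dtype=np.int64),
            deletion_spans=np.zeros(n, dtype=np.int64),
        )

    def test_uniform_depth_normalizes_to_one(self):
        prof = self._uniform_profile("ACGT" * 100)
        gc = coverage_by_gc(prof, window=100)
        assert np.allclose(gc["mean_normalized_coverage"], 1.0)

    def test_all_at_reference_zero_gc(self):
        prof = self._uniform_profile("AT" * 200)
        gc = coverage_by_gc(prof, window=100)
        assert (gc["gc_fraction"] == 0.0).all()

    def test_window_larger_than_region_falls_back(self):
        prof = self._uniform_profile("ACGT" * 20)
        gc = coverage_by_gc(prof, window=500)
        assert len(gc) == 1

    def test_gc_bias_visible_in_strata(self, bundle, decoy, manifest, molecules,
                                       decoy_maps, tmp_path):
        """A monotone-decreasing GC weight depresses coverage in >65% GC
        windows relative to <30% windows (end-to-end simulation)."""
        rich, poor = "SV001_R", "SV002_R"  # designed GC-rich / GC-poor pairs
        cfg = readsim.ReadSimConfig(
            read_length=100, fragment_mean=250, fragment_sd=30,
            gc_bias=(0.0, -0.9, 1.0),
        )
        bam, _ = simulate_bam(manifest, molecules, cfg, decoy_maps, decoy,
                              tmp_path / "gc.bam", seed=23,
                              ids=[rich, poor], n_fragments=3000)
        lo = min(decoy.placements[rich].start, decoy.placements[poor].start)
        hi = max(decoy.placements[rich].end, decoy.placements[poor].end)
        prof = pileup_profile(bam, (decoy.name, lo, hi), decoy.seq[lo:hi])
        strata = gc_strata_summary(coverage_by_gc(prof, window=100))
        assert strata["high_gc"] < strata["low_gc"]


class TestErrorSummary:
    def test_zero_error_all_rates_zero(self, bundle, decoy, manifest, molecules,
                                       decoy_maps, tmp_path):
        cfg = readsim.ReadSimConfig(read_length=100, fragment_mean=250, fragment_sd=30)
        bam, _ = simulate_bam(manifest, molecules, cfg, decoy_maps, decoy,
                              tmp_path / "clean.bam", seed=24,
                              ids=["REP00"], n_fragments=150)
        pl = decoy.placements["REP00"]
        prof = pileup_profile(bam, (decoy.name, pl.start, pl.end),
                              decoy.seq[pl.start : pl.end])
        summ = error_summary(prof)
        assert summ.mean_mismatch_rate == 0.0
        assert len(summ.substitution_spectrum) == 0  # flagged empty
        assert np.isnan(summ.transition_fraction)

    def test_transition_only_injection_gives_ti_fraction_one(self, bundle, decoy,
                                                             manifest, molecules,
                                                             decoy_maps, tmp_path):
        cfg = readsim.ReadSimConfig(
            read_length=100, fragment_mean=250, fragment_sd=30,
            substitution_rate=0.01, titv_ratio=1e12,
        )
        bam, _ = simulate_bam(manifest, molecules, cfg, decoy_maps, decoy,
                              tmp_path / "ti.bam", seed=25,
                              ids=["REP00"], n_fragments=300)
        pl = decoy.placements["REP00"]
        prof = pileup_profile(bam, (decoy.name, pl.start, pl.end),
                              decoy.seq[pl.start : pl.end])
        summ = error_summary(prof)
        assert summ.transition_fraction == pytest.approx(1.0)
        assert summ.substitution_spectrum.sum() == pytest.approx(1.0)

    def test_rate_recovery_3sigma_on_1e6_bases(self, bundle, decoy, manifest,
                                               molecules, decoy_maps, tmp_path):
        """Profiling the simulator's own output recovers the configured
        substitution rate within 3 sigma over ~1e6 sequenced bases."""
        rate = 1e-3
        cfg = readsim.ReadSimConfig(
            read_length=100, fragment_mean=250, fragment_sd=30,
            substitution_rate=rate,
        )
        bam, res = simulate_bam(manifest, molecules, cfg, decoy_maps, decoy,
                                tmp_path / "rec.bam", seed=26,
                                ids=["REP00", "REP01"], n_fragments=5000)
        total_bases = sum(len(r.seq) for r in res.reads)
        assert total_bases >= 1_000_000
        n_err = 0
        n_aligned = 0
        for sid in ("REP00", "REP01"):
            pl = decoy.placements[sid]
            prof = pileup_profile(bam, (decoy.name, pl.start, pl.end),
                                  decoy.seq[pl.start : pl.end])
            n_err += int(prof.mismatches.sum())
            n_aligned += int(prof.depth.sum())
        expected = n_aligned * rate
        sigma = np.sqrt(expected)
        assert abs(n_err - expected) <= 3 * sigma


class TestPermissiveCaller:
    def _profile_with_site(self, depth, alt_count, n=200, pos=100):
        ref = "A" * n
        d = np.full(n, depth, dtype=np.int64)
        mm = {b: np.zeros(n, dtype=np.int64) for b in "ACGT"}
        mm["T"][pos] = alt_count
        match = d.copy()
        match[pos] -= alt_count
        return PerBaseProfile(
            region=("chrQ", 0, n), ref_seq=ref, depth=d, matches=match,
            mismatch_by_base=mm, insertion_starts=np.zeros(n, dtype=np.int64),
            deletion_spans=np.zeros(n, dtype=np.int64),
        )

    def test_min_depth_threshold(self):
        prof = self._profile_with_site(depth=49, alt_count=5)
        assert len(permissive_pileup_call(prof)) == 0

    def test_single_supporting_read_called(self):
        prof = self._profile_with_site(depth=100, alt_count=1)
        calls = permissive_pileup_call(prof)
        assert len(calls) == 1
        assert calls.iloc[0]["af"] == pytest.approx(0.01)

    def test_threshold_monotonicity(self):
        """Lowering any permissive threshold never reduces candidates."""
        prof = self._profile_with_site(depth=100, alt_count=3)
        prof.mismatch_by_base["G"][50] = 1
        prof.depth[50] = 60
        base = PermissiveThresholds()
        n_base = len(permissive_pileup_call(prof, base))
        for looser in (
            PermissiveThresholds(min_coverage=10),
            PermissiveThresholds(min_reads=1),
            PermissiveThresholds(min_var_freq=1e-9),
        ):
            assert len(permissive_pileup_call(prof, looser)) >= n_base

    def test_zero_error_sim_calls_only_truth(self, bundle, decoy, manifest,
                                             molecules, decoy_maps, tmp_path):
        """Zero-error simulation of a variant pair: every permissive call
        is a designed variant, none lies outside the truth."""
        pair = bundle.smallvar_pairs[0]
        cfg = readsim.ReadSimConfig(read_length=100, fragment_mean=250, fragment_sd=30)
        bam, _ = simulate_bam(manifest, molecules, cfg, decoy_maps, decoy,
                              tmp_path / "truthcall.bam", seed=27,
                              ids=[pair.ref.id, pair.var.id], n_fragments=3000)
        pl = decoy.placements[pair.ref.id]
        prof = pileup_profile(bam, (decoy.name, pl.start, pl.end),
                              decoy.seq[pl.start : pl.end])
        calls = permissive_pileup_call(prof)
        truth = truth_key_set(decoy)
        assert len(calls) > 0
        for k in zip(calls["pos0"], calls["ref"], calls["alt"]):
            assert k in truth


class TestFPByAF:
    def test_truth_only_candidates_zero_fdr(self):
        cands = pd.DataFrame(
            {"chrom": ["chrQ"] * 3, "pos0": [10, 20, 30], "ref": list("AAA"),
             "alt": list("TTT"), "support": [5, 5, 5], "depth": [100] * 3,
             "af": [0.05] * 3, "vclass": ["SNV"] * 3}
        )
        truth = {(10, "A", "T"), (20, "A", "T"), (30, "A", "T")}
        res = fp_rate_by_af(cands, truth)
        occupied = res.table.dropna(subset=["fdr"])
        assert (occupied["fdr"] == 0).all()
        assert res.auc == 0.0

    def test_all_false_positives_auc_one(self):
        cands = pd.DataFrame(
            {"chrom": ["chrQ"] * 4, "pos0": [1, 2, 3, 4], "ref": list("AAAA"),
             "alt": list("TTTT"), "support": [1] * 4, "depth": [100] * 4,
             "af": [0.01, 0.03, 0.1, 0.5], "vclass": ["SNV"] * 4}
        )
        res = fp_rate_by_af(cands, set())
        occupied = res.table.dropna(subset=["fdr"])
        assert (occupied["fdr"] == 1).all()
        assert res.auc == pytest.approx(1.0)

    def test_empty_candidates(self):
        res = fp_rate_by_af(pd.DataFrame(columns=["pos0", "ref", "alt", "af"]), set())
        assert res.auc == 0.0
        assert (res.table["candidates"] == 0).all()
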