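"""Per-base coverage/error profiling and allele-frequency-resolved
false-positive statistics.

The profile is a CIGAR walk over sorted alignments: per reference position
it tallies depth, matching reads, mismatches by substituted base,
insertion starts (anchored at the aligned base preceding the insert) and
deletion spans (each spanned position counts one event per read).  Edge
intervals — the terminal ~400 nt of each control where linear-molecule
coverage decays — are excluded from all summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .sequence import TRANSITIONS

SUBSTITUTION_TYPES = [
    f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b
]


@dataclass
class PerBaseProfile:
    """Positional counts over a reference region (0-based half-open)."""

    region: tuple[str, int, int]
    ref_seq: str  # reference bases over the region
    depth: np.ndarray
    matches: np.ndarray
    mismatch_by_base: dict[str, np.ndarray]  # substituted-to base -> counts
    insertion_starts: np.ndarray
    deletion_spans: np.ndarray
    insertion_seqs: dict[int, dict[str, int]] = field(default_factory=dict)
    deletion_lens: dict[int, dict[int, int]] = field(default_factory=dict)
    mask: np.ndarray | None = None  # True where excluded
    library_id: str = ""

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(len(self.depth), dtype=bool)

    @property
    def mismatches(self) -> np.ndarray:
        out = np.zeros_like(self.depth)
        for arr in self.mismatch_by_base.values():
            out = out + arr
        return out

    def unmasked(self) -> np.ndarray:
        return ~self.mask


def _region_mask(region: tuple[str, int, int], edge_mask) -> np.ndarray:
    chrom, start, end = region
    mask = np.zeros(end - start, dtype=bool)
    if edge_mask:
        for item in edge_mask:
            s, e = (item[1], item[2]) if len(item) >= 3 else item
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                mask[lo - start : hi - start] = True
    return mask


def pileup_profile(
    alignments: str | Path,
    region: tuple[str, int, int],
    ref_seq: str,
    edge_mask=None,
    min_mapq: int = 0,
    library_id: str = "",
) -> PerBaseProfile:
    """CIGAR-walked per-position counts over *region*.

    *ref_seq* is the reference sequence of the region.  *edge_mask* is a
    list of excluded intervals, ``(id, start, end)`` or ``(start, end)``,
    in reference coordinates; masked positions are flagged and dropped from
    all downstream summaries.  Input must be sorted and indexed.
    """
    chrom, start, end = region
    n = end - start
    if len(ref_seq) != n:
        raise ValueError("ref_seq length disagrees with region span")
    depth = np.zeros(n, dtype=np.int64)
    matches = np.zeros(n, dtype=np.int64)
    mismatch_by_base = {b: np.zeros(n, dtype=np.int64) for b in "ACGT"}
    ins_starts = np.zeros(n, dtype=np.int64)
    del_spans = np.zeros(n, dtype=np.int64)
    ins_seqs: dict[int, dict[str, int]] = {}
    del_lens: dict[int, dict[int, int]] = {}

    with pysam.AlignmentFile(str(alignments)) as af:
        if not af.has_index():
            raise ValueError("alignments must be coordinate-sorted and indexed")
        ref_arr = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
        base_codes = {b: ord(b) for b in "ACGT"}
        for rec in af.fetch(chrom, start, end):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            qseq = rec.query_sequence
            qarr = np.frombuffer(qseq.encode(), dtype=np.uint8)
            rpos = rec.reference_start
            qpos = 0
            last_aligned_local = None
            for op, ln in rec.cigartuples:
                if op in (0, 7, 8):  # M/=/X — vectorized over the block
                    lo = max(rpos, start)
                    hi = min(rpos + ln, end)
                    if hi > lo:
                        locals_ = np.arange(lo - start, hi - start)
                        qslice = qarr[qpos + (lo - rpos) : qpos + (hi - rpos)]
                        depth[locals_] += 1
                        is_match = qslice == ref_arr[locals_]
                        matches[locals_[is_match]] += 1
                        mm = ~is_match
                        if mm.any():
                            for b, code in base_codes.items():
                                sel = locals_[mm & (qslice == code)]
                                if len(sel):
                                    np.add.at(mismatch_by_base[b], sel, 1)
                        last_aligned_local = int(locals_[-1])
                    rpos += ln
                    qpos += ln
                elif op == 1:  # insertion anchored at preceding aligned base
                    if last_aligned_local is not None:
                        ins_starts[last_aligned_local] += 1
                        seq = qseq[qpos : qpos + ln]
                        ins_seqs.setdefault(last_aligned_local, {}).setdefault(seq, 0)
                        ins_seqs[last_aligned_local][seq] += 1
                    qpos += ln
                elif op == 2:  # deletion: one event at every spanned position
                    first_local = None
                    for k in range(ln):
                        r = rpos + k
                        if start <= r < end:
                            local = r - start
                            del_spans[local] += 1
                            if first_local is None:
                                first_local = local
                    if first_local is not None:
                        del_lens.setdefault(first_local, {}).setdefault(ln, 0)
                        del_lens[first_local][ln] += 1
                    rpos += ln
                elif op == 3:  # N
                    rpos += ln
                elif op in (4,):  # soft clip
                    qpos += ln
                # hard clip (5) and pad (6) consume nothing we track
    return PerBaseProfile(
        region=region,
        ref_seq=ref_seq,
        depth=depth,
        matches=matches,
        mismatch_by_base=mismatch_by_base,
        insertion_starts=ins_starts,
        deletion_spans=del_spans,
        insertion_seqs=ins_seqs,
        deletion_lens=del_lens,
        mask=_region_mask(region, edge_mask),
        library_id=library_id,
    )


def normalized_coverage(profile: PerBaseProfile) -> np.ndarray:
    """Per-base depth divided by the library mean depth over unmasked
    positions (so the unmasked mean is 1 by construction)."""
    ok = profile.unmasked()
    mean = profile.depth[ok].mean() if ok.any() and profile.depth[ok].sum() else 0.0
    if mean == 0:
        return np.zeros_like(profile.depth, dtype=float)
    return profile.depth / mean


def coverage_by_gc(
    profile: PerBaseProfile, window: int = 100, step: int | None = None
) -> pd.DataFrame:
    """Windowed GC content vs mean normalized coverage.

    Windows tile the region (non-overlapping by default; pass *step* for
    sliding windows).  Windows that are entirely masked are dropped.  The
    published low/high GC strata are <30% and >65%.
    """
    if window < 10:
        raise ValueError("window must be >= 10 nt")
    chrom, start, end = profile.region
    n = end - start
    if window > n:
        window = n  # single-window fallback
    step = step or window
    norm = normalized_coverage(profile)
    ok = profile.unmasked()
    rows = []
    for w0 in range(0, n - window + 1, step):
        sel = ok[w0 : w0 + window]
        if not sel.any():
            continue
        seq = profile.ref_seq[w0 : w0 + window]
        gc = (seq.count("G") + seq.count("C")) / window
        rows.append(
            {
                "window_start": start + w0,
                "gc_fraction": gc,
                "mean_normalized_coverage": float(norm[w0 : w0 + window][sel].mean()),
            }
        )
    return pd.DataFrame(rows, columns=["window_start", "gc_fraction", "mean_normalized_coverage"])


def gc_strata_summary(gc_table: pd.DataFrame, low: float = 0.30, high: float = 0.65) -> dict:
    out = {}
    for name, sel in (
        ("low_gc", gc_table["gc_fraction"] < low),
        ("mid_gc", (gc_table["gc_fraction"] >= low) & (gc_table["gc_fraction"] <= high)),
        ("high_gc", gc_table["gc_fraction"] > high),
    ):
        sub = gc_table.loc[sel, "mean_normalized_coverage"]
        out[name] = float(sub.mean()) if len(sub) else float("nan")
    return out


@dataclass
class ErrorSummary:
    window_rates: pd.DataFrame  # per w_err window: mismatch/ins/del rates
    substitution_spectrum: pd.Series  # 12 relative frequencies (sum 1) or empty
    transition_fraction: float
    transversion_fraction: float
    coverage_iqr: float
    mean_mismatch_rate: float
    mean_insertion_rate: float
    mean_deletion_rate: float
    n_zero_depth: int


def error_summary(
    profile: PerBaseProfile,
    variant_mask: np.ndarray | None = None,
    w_err: int = 1000,
) -> ErrorSummary:
    """Windowed error rates and the substitution spectrum.

    *variant_mask* flags designed-variant positions (region-local), which
    are excluded from rate and spectrum computation so designed alleles are
    not counted as errors.  Zero-depth positions are excluded from rate
    denominators and tallied as coverage gaps.
    """
    n = len(profile.depth)
    excluded = profile.mask.copy()
    if variant_mask is not None:
        excluded |= variant_mask
    ok = ~excluded
    depth = profile.depth
    zero = ok & (depth == 0)
    use = ok & (depth > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        mm_rate = np.where(use, profile.mismatches / np.maximum(depth, 1), np.nan)
        ins_rate = np.where(use, profile.insertion_starts / np.maximum(depth, 1), np.nan)
        del_rate = np.where(use, profile.deletion_spans / np.maximum(depth, 1), np.nan)

    rows = []
    chrom, start, end = profile.region
    for w0 in range(0, n, w_err):
        sl = slice(w0, min(w0 + w_err, n))
        if not use[sl].any():
            continue
        rows.append(
            {
                "window_start": start + w0,
                "mismatch_rate": float(np.nanmean(mm_rate[sl])),
                "insertion_rate": float(np.nanmean(ins_rate[sl])),
                "deletion_rate": float(np.nanmean(del_rate[sl])),
            }
        )
    window_rates = pd.DataFrame(
        rows, columns=["window_start", "mismatch_rate", "insertion_rate", "deletion_rate"]
    )

    spectrum_counts = {}
    for alt, arr in profile.mismatch_by_base.items():
        for local in np.nonzero(arr * use)[0]:
            ref = profile.ref_seq[local]
            if ref in "ACGT" and ref != alt:
                key = f"{ref}>{alt}"
                spectrum_counts[key] = spectrum_counts.get(key, 0) + int(arr[local])
    total_subs = sum(spectrum_counts.values())
    if total_subs:
        spectrum = pd.Series(
            {k: spectrum_counts.get(k, 0) / total_subs for k in SUBSTITUTION_TYPES}
        )
        ti = sum(
            spectrum[f"{a}>{b}"] for a, b in TRANSITIONS.items()
        )
        tv = 1.0 - ti
    else:
        spectrum = pd.Series(dtype=float)
        ti = tv = float("nan")

    norm = normalized_coverage(profile)[use]
    iqr = float(np.percentile(norm, 75) - np.percentile(norm, 25)) if len(norm) else float("nan")
    return ErrorSummary(
        window_rates=window_rates,
        substitution_spectrum=spectrum,
        transition_fraction=ti,
        transversion_fraction=tv,
        coverage_iqr=iqr,
        mean_mismatch_rate=float(np.nanmean(mm_rate)) if use.any() else float("nan"),
        mean_insertion_rate=float(np.nanmean(ins_rate)) if use.any() else float("nan"),
        mean_deletion_rate=float(np.nanmean(del_rate)) if use.any() else float("nan"),
        n_zero_depth=int(zero.sum()),
    )


# ---------------------------------------------------------------------------
# permissive candidate generation and FP-by-AF
# ---------------------------------------------------------------------------


@dataclass
class PermissiveThresholds:
    """Sensitivity-maximizing thresholds for candidate generation
    (minimum depth 50, a single supporting read, AF down to 1e-5,
    no strand filtering)."""

    min_coverage: int = 50
    min_reads: int = 1
    min_var_freq: float = 1e-5


def permissive_pileup_call(
    profile: PerBaseProfile, thresholds: PermissiveThresholds | None = None
) -> pd.DataFrame:
    """Emit every non-reference allele meeting the permissive thresholds.

    Returns a table of candidates with observed AF = supporting/depth.
    This is a candidate generator for error-floor measurement, not a
    production caller.  Indels are reported with empty-side alleles
    (``ref=''`` for insertions), matching the design truth convention.
    """
    th = thresholds or PermissiveThresholds()
    chrom, start, end = profile.region
    ok = profile.unmasked()
    rows = []
    depth = profile.depth
    for local in np.nonzero(ok & (depth >= th.min_coverage))[0]:
        d = int(depth[local])
        ref = profile.ref_seq[local]
        for alt, arr in profile.mismatch_by_base.items():
            c = int(arr[local])
            if alt != ref and c >= th.min_reads and c / d >= th.min_var_freq:
                rows.append({"chrom": chrom, "pos0": start + local, "ref": ref,
                             "alt": alt, "support": c, "depth": d, "af": c / d,
                             "vclass": "SNV"})
        for seq, c in profile.insertion_seqs.get(local, {}).items():
            # anchored after this base: insertion gap position is local+1
            if c >= th.min_reads and c / d >= th.min_var_freq:
                rows.append({"chrom": chrom, "pos0": start + local + 1, "ref": "",
                             "alt": seq, "support": c, "depth": d, "af": c / d,
                             "vclass": "INS"})
        for ln, c in profile.deletion_lens.get(local, {}).items():
            if c >= th.min_reads and c / d >= th.min_var_freq:
                rows.append({"chrom": chrom, "pos0": start + local,
                             "ref": profile.ref_seq[local : local + ln], "alt": "",
                             "support": c, "depth": d, "af": c / d, "vclass": "DEL"})
    return pd.DataFrame(
        rows, columns=["chrom", "pos0", "ref", "alt", "support", "depth", "af", "vclass"]
    )


@dataclass
class FPRateByAF:
    table: pd.DataFrame  # per AF bin: candidates, false positives, fdr
    auc: float


def fp_rate_by_af(
    candidates: pd.DataFrame,
    truth: set[tuple[int, str, str]],
    af_bins: np.ndarray | None = None,
) -> FPRateByAF:
    """False-discovery rate per allele-frequency bin, with a trapezoidal
    area summary over the log-AF axis (normalized to the axis span).

    *truth* is a set of ``(pos0, ref, alt)`` keys from the design stage; a
    candidate is a false positive iff its key is absent.
    """
    if af_bins is None:
        af_bins = np.logspace(-4, 0, 13)
    rows = []
    if len(candidates):
        keys = list(zip(candidates["pos0"], candidates["ref"], candidates["alt"]))
        is_fp = np.array([k not in truth for k in keys])
        afs = candidates["af"].to_numpy()
    else:
        is_fp = np.array([], dtype=bool)
        afs = np.array([])
    for lo, hi in zip(af_bins[:-1], af_bins[1:]):
        sel = (afs >= lo) & (afs < hi)
        n = int(sel.sum())
        fp = int(is_fp[sel].sum())
        rows.append({"af_low": lo, "af_high": hi, "candidates": n,
                     "false_positives": fp, "fdr": fp / n if n else np.nan})
    table = pd.DataFrame(rows)
    mids = np.log10(np.sqrt(table["af_low"] * table["af_high"]).to_numpy())
    fdr = table["fdr"].to_numpy(dtype=float)
    occupied = ~np.isnan(fdr)
    if occupied.sum() >= 2:
        x, y = mids[occupied], fdr[occupied]
        auc = float(np.trapezoid(y, x) / (x[-1] - x[0]))
    elif occupied.sum() == 1:
        auc = float(fdr[occupied][0])
    else:
        auc = 0.0
    return FPRateByAF(table=table, auc=auc)


def truth_key_set(decoy) -> set[tuple[int, str, str]]:
    """Candidate-comparison keys from a decoy truth set."""
    return {(r["pos0"], r["ref"], r["alt"]) for r in decoy.truth_small_variants}
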