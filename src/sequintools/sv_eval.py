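"""Structural-variant benchmarking at breakpoint and whole-SV resolution.

A called breakpoint within the tolerance (default |offset| <= 10 nt,
inclusive) of an unmatched, type-compatible truth breakpoint is a true
positive; matching is greedy one-to-one by ascending |offset| with ties
broken by position.  Callers that report duplications as insertions are
accommodated: an insertion call positioned within a truth duplication's
span whose length equals the duplication size (within tolerance) counts
as a true positive and satisfies both duplication breakpoints.  An SV is
recovered only if *all* of its breakpoints were matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

#: truth type -> acceptable call types (beyond DUP-as-INS, handled apart)
_COMPAT: dict[str, tuple[str, ...]] = {
    "DEL": ("DEL",),
    "INS": ("INS",),
    "DUP": ("DUP",),
    "INV": ("INV",),
    "VIR": ("INS", "VIR"),
    "TRA": ("BND", "TRA"),
}


@dataclass
class TruthBreakpoint:
    sv_id: str
    svtype: str
    pos: int
    matched_by: str | None = None
    offset: int | None = None


@dataclass
class CallBreakpoint:
    call_id: str
    svtype: str
    pos: int
    svlen: int | None = None
    status: str = "FP"


@dataclass
class TruthSV:
    sv_id: str
    svtype: str
    breakpoints: list[int]
    size: int
    span: tuple[int, int] | None = None


@dataclass
class BreakpointMatchResult:
    truth_breakpoints: list[TruthBreakpoint]
    call_breakpoints: list[CallBreakpoint]
    truth_svs: list[TruthSV]
    tol: int

    @property
    def tp(self) -> int:
        return sum(t.matched_by is not None for t in self.truth_breakpoints)

    @property
    def fn(self) -> int:
        return sum(t.matched_by is None for t in self.truth_breakpoints)

    @property
    def fp(self) -> int:
        return sum(c.status == "FP" for c in self.call_breakpoints)

    @property
    def tp_calls(self) -> int:
        return sum(c.status == "TP" for c in self.call_breakpoints)

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def precision(self) -> float:
        denom = self.tp_calls + self.fp
        return self.tp_calls / denom if denom else float("nan")

    def sv_status(self) -> dict[str, bool]:
        """SV-level recovery: true iff every breakpoint of the SV matched."""
        by_sv: dict[str, list[TruthBreakpoint]] = {}
        for t in self.truth_breakpoints:
            by_sv.setdefault(t.sv_id, []).append(t)
        return {
            sv.sv_id: all(t.matched_by is not None for t in by_sv.get(sv.sv_id, []))
            for sv in self.truth_svs
        }


def truth_from_decoy(decoy) -> list[TruthSV]:
    out = []
    for sv in decoy.truth_svs:
        out.append(
            TruthSV(
                sv_id=sv["sv_id"], svtype=sv["svtype"],
                breakpoints=list(sv["breakpoints"]), size=sv["size"],
                span=sv.get("span"),
            )
        )
    return out


def truth_svs_from_vcf(path: str | Path) -> list[TruthSV]:
    """Reconstruct the truth-SV set from a design-stage truth VCF
    (symbolic records with SVID/SVLEN; translocations as BND pairs)."""
    by_id: dict[str, TruthSV] = {}
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            svid = rec.info.get("SVID") or rec.id
            svtype = rec.info.get("SVTYPE")
            svlen = rec.info.get("SVLEN")
            size = abs(int(svlen)) if svlen is not None else 0
            # undo VCF anchoring: breakpoint gap = start0 + 1; END = far gap
            if svtype == "BND":
                sv = by_id.setdefault(svid, TruthSV(svid, "TRA", [], 0))
                sv.breakpoints.append(rec.start + 1)
                sv.size = max(sv.size, 1)
            elif svtype in ("INS", "VIR"):
                by_id[svid] = TruthSV(svid, svtype, [rec.start + 1], size)
            else:
                sv = TruthSV(svid, svtype, [rec.start + 1, rec.stop], size,
                             span=(rec.start + 1, rec.stop))
                by_id[svid] = sv
    return list(by_id.values())


def read_sv_vcf(path: str | Path) -> list[CallBreakpoint]:
    """Extract call breakpoints from an SV VCF (SVTYPE/END/SVLEN symbolic
    records; BND records contribute one breakpoint each)."""
    calls: list[CallBreakpoint] = []
    with pysam.VariantFile(str(path)) as vf:
        for i, rec in enumerate(vf):
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                alt = rec.alts[0] if rec.alts else ""
                svtype = alt.strip("<>") if alt.startswith("<") else "BND"
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            svlen = abs(int(svlen)) if svlen is not None else None
            cid = rec.id or f"call{i}"
            if svtype in ("BND", "TRA"):
                calls.append(CallBreakpoint(cid, "BND", rec.start + 1, svlen))
            elif svtype in ("INS", "VIR"):
                calls.append(CallBreakpoint(cid, svtype, rec.start + 1, svlen))
            else:
                calls.append(CallBreakpoint(f"{cid}_l", svtype, rec.start + 1, svlen))
                calls.append(CallBreakpoint(f"{cid}_r", svtype, rec.stop, svlen))
    return calls


def match_breakpoints(
    calls: list[CallBreakpoint],
    truth_svs: list[TruthSV],
    tol: int = 10,
) -> BreakpointMatchResult:
    """Greedy one-to-one breakpoint matching within *tol* (inclusive)."""
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    truth_bps: list[TruthBreakpoint] = []
    for sv in truth_svs:
        for bp in sv.breakpoints:
            truth_bps.append(TruthBreakpoint(sv.sv_id, sv.svtype, bp))

    # candidate pairs: type-compatible and within tolerance
    pairs = []
    for ci, c in enumerate(calls):
        for ti, t in enumerate(truth_bps):
            if c.svtype not in _COMPAT.get(t.svtype, (t.svtype,)):
                continue
            off = abs(c.pos - t.pos)
            if off <= tol:
                pairs.append((off, c.pos, t.pos, ci, ti))
    used_calls: set[int] = set()
    used_truth: set[int] = set()
    for off, cpos, tpos, ci, ti in sorted(pairs):
        if ci in used_calls or ti in used_truth:
            continue
        used_calls.add(ci)
        used_truth.add(ti)
        calls[ci].status = "TP"
        truth_bps[ti].matched_by = calls[ci].call_id
        truth_bps[ti].offset = calls[ci].pos - truth_bps[ti].pos

    # DUP-as-INS: an unmatched INS call inside a truth DUP span with the
    # expected size satisfies the whole duplication
    bp_index: dict[str, list[int]] = {}
    for ti, t in enumerate(truth_bps):
        bp_index.setdefault(t.sv_id, []).append(ti)
    for ci, c in enumerate(calls):
        if ci in used_calls or c.svtype != "INS" or c.svlen is None:
            continue
        for sv in truth_svs:
            if sv.svtype != "DUP" or sv.span is None:
                continue
            tis = [ti for ti in bp_index[sv.sv_id] if ti not in used_truth]
            if not tis:
                continue
            lo, hi = sv.span
            if lo <= c.pos <= hi and abs(c.svlen - sv.size) <= tol:
                used_calls.add(ci)
                calls[ci].status = "TP"
                for ti in bp_index[sv.sv_id]:
                    if ti not in used_truth:
                        used_truth.add(ti)
                        truth_bps[ti].matched_by = c.call_id
                        truth_bps[ti].offset = None
                break
    return BreakpointMatchResult(
        truth_breakpoints=truth_bps, call_breakpoints=calls,
        truth_svs=truth_svs, tol=tol,
    )


def sv_performance(
    result: BreakpointMatchResult,
    size_bins: tuple[int, ...] = (100, 250, 500),
) -> pd.DataFrame:
    """Per-type and per-size-bin sensitivity/precision summary."""
    status = result.sv_status()
    by_sv_type: dict[str, str] = {sv.sv_id: sv.svtype for sv in result.truth_svs}

    def size_bin(size: int) -> str:
        prev = 0
        for edge in size_bins:
            if size <= edge:
                return f"{prev + 1}-{edge}"
            prev = edge
        return f">{size_bins[-1]}"

    rows = []
    groups: dict[tuple[str, str], list] = {}
    for sv in result.truth_svs:
        for key in (("type", sv.svtype), ("size", size_bin(sv.size))):
            groups.setdefault(key, []).append(sv)
    # call-side grouping for precision uses the matched truth's type where
    # known, otherwise the call's own declared type
    call_type: dict[str, str] = {}
    for t in result.truth_breakpoints:
        if t.matched_by is not None:
            call_type[t.matched_by] = by_sv_type[t.sv_id]
    for (axis, label), svs in sorted(groups.items()):
        sv_ids = {s.sv_id for s in svs}
        t_bps = [t for t in result.truth_breakpoints if t.sv_id in sv_ids]
        tp = sum(t.matched_by is not None for t in t_bps)
        fn = len(t_bps) - tp
        if axis == "type":
            fp = sum(
                1 for c in result.call_breakpoints
                if c.status == "FP" and c.svtype in _COMPAT.get(label, (label,))
            )
            tp_calls = sum(
                1 for c in result.call_breakpoints
                if c.status == "TP" and call_type.get(c.call_id) == label
            )
            precision = tp_calls / (tp_calls + fp) if tp_calls + fp else float("nan")
        else:
            precision = float("nan")
        rows.append(
            {
                "axis": axis,
                "group": label,
                "n_svs": len(svs),
                "svs_recovered": sum(status[s.sv_id] for s in svs),
                "sv_sensitivity": sum(status[s.sv_id] for s in svs) / len(svs),
                "bp_sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
                "bp_precision": precision,
            }
        )
    return pd.DataFrame(rows)
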