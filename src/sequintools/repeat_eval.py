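"""Per-read repeat-length accuracy at homopolymers and microsatellites.

For every repeat site, the observed repeat length in each spanning read is
``reference interval length + inserted bases within - deleted bases
within``, computed from the alignment's CIGAR.  Exact-match fraction is the
proportion of spanning reads whose observed length equals the designed
length.  Homopolymers are classified small (<=5 nt), medium (6-15 nt) and
large (>15 nt).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam


def classify_run(length: int) -> str:
    if length <= 5:
        return "small"
    if length <= 15:
        return "medium"
    return "large"


@dataclass
class HomopolymerSite:
    sequin_id: str
    start: int
    end: int
    base: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def size_class(self) -> str:
        return classify_run(self.length)


def find_homopolymers(seq: str, min_len: int = 2, sequin_id: str = "") -> list[HomopolymerSite]:
    """Maximal single-base runs of length >= *min_len* (exhaustive,
    non-overlapping), via run-length grouping."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    sites = []
    pos = 0
    for base, group in itertools.groupby(seq):
        ln = sum(1 for _ in group)
        if ln >= min_len and base in "ACGT":
            sites.append(HomopolymerSite(sequin_id, pos, pos + ln, base))
        pos += ln
    return sites


@dataclass
class SiteObservation:
    site_id: str
    truth_length: int
    size_class: str
    observed: list[int] = field(default_factory=list)
    n_soft_clipped: int = 0
    n_insertions: int = 0  # insertion events within the interval
    n_deletions: int = 0  # deletion events overlapping the interval

    @property
    def n_reads(self) -> int:
        return len(self.observed)

    @property
    def exact_fraction(self) -> float:
        if not self.observed:
            return float("nan")
        return sum(o == self.truth_length for o in self.observed) / len(self.observed)

    def histogram(self) -> Counter:
        return Counter(self.observed)


def observed_repeat_lengths(
    alignments: str | Path,
    chrom: str,
    start: int,
    end: int,
    flank: int = 5,
    site_id: str = "",
    size_class: str | None = None,
) -> SiteObservation:
    """Per-read observed lengths of the repeat interval ``[start, end)``.

    Only reads whose alignment fully spans the interval plus *flank* nt on
    both sides are used; reads soft-clipped within the flanked interval are
    excluded and counted.  The observed length is a net CIGAR accounting of
    insertions and deletions inside the interval.
    """
    obs = SiteObservation(
        site_id=site_id or f"{chrom}:{start}-{end}",
        truth_length=end - start,
        size_class=size_class or classify_run(end - start),
    )
    lo, hi = start - flank, end + flank
    with pysam.AlignmentFile(str(alignments)) as af:
        for rec in af.fetch(chrom, max(lo, 0), hi):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_start > lo or rec.reference_end < hi:
                continue
            net = 0
            rpos = rec.reference_start
            clipped = False
            n_ins = n_del = 0
            # walk: count inserted bases anchored strictly inside the
            # interval and deleted reference bases within it
            last_ref_before_gap = rec.reference_start - 1
            for op, ln in rec.cigartuples:
                if op in (0, 7, 8):
                    rpos += ln
                    last_ref_before_gap = rpos - 1
                elif op == 1:
                    # insertion anchored at a base inside the run extends it
                    if start <= last_ref_before_gap <= end - 1:
                        net += ln
                        n_ins += 1
                elif op in (2, 3):
                    del_lo, del_hi = max(rpos, start), min(rpos + ln, end)
                    if del_hi > del_lo:
                        net -= del_hi - del_lo
                        if op == 2:
                            n_del += 1
                    rpos += ln
                elif op == 4:
                    # soft clip inside the flanked window disqualifies
                    clip_at = rpos if rpos > rec.reference_start else rec.reference_start
                    if lo <= clip_at <= hi:
                        clipped = True
            if clipped:
                obs.n_soft_clipped += 1
                continue
            obs.observed.append((end - start) + net)
            obs.n_insertions += n_ins
            obs.n_deletions += n_del
    return obs


@dataclass
class RepeatAccuracy:
    per_site: pd.DataFrame
    per_class: pd.DataFrame
    panel_report: pd.DataFrame | None = None


def repeat_accuracy_summary(
    observations: list[SiteObservation],
    panel: dict[str, bool] | None = None,
    site_panel_names: dict[str, str] | None = None,
) -> RepeatAccuracy:
    """Aggregate per-site observations into per-site and per-class tables.

    *panel* maps microsatellite names to their designed stability (True =
    stable); *site_panel_names* maps observation ids to panel names so the
    panel report can list the designed stable and unstable sets.
    """
    site_rows = []
    for o in observations:
        site_rows.append(
            {
                "site_id": o.site_id,
                "truth_length": o.truth_length,
                "size_class": o.size_class,
                "n_reads": o.n_reads,
                "n_soft_clipped": o.n_soft_clipped,
                "exact_fraction": o.exact_fraction,
                "insertion_events": o.n_insertions,
                "deletion_events": o.n_deletions,
                "mode_length": (o.histogram().most_common(1)[0][0] if o.observed else None),
            }
        )
    per_site = pd.DataFrame(site_rows)

    class_rows = []
    for cls in ("small", "medium", "large"):
        sub = [o for o in observations if o.size_class == cls]
        n_reads = sum(o.n_reads for o in sub)
        if not sub:
            continue
        exact = sum(sum(x == o.truth_length for x in o.observed) for o in sub)
        ins = sum(o.n_insertions for o in sub)
        dele = sum(o.n_deletions for o in sub)
        class_rows.append(
            {
                "size_class": cls,
                "n_sites": len(sub),
                "n_reads": n_reads,
                "exact_fraction": exact / n_reads if n_reads else float("nan"),
                "insertion_rate": ins / n_reads if n_reads else float("nan"),
                "deletion_rate": dele / n_reads if n_reads else float("nan"),
            }
        )
    per_class = pd.DataFrame(class_rows)

    panel_report = None
    if panel is not None and site_panel_names is not None:
        rows = []
        by_site = {r["site_id"]: r for r in site_rows}
        for site_id, name in site_panel_names.items():
            r = by_site.get(site_id)
            if r is None:
                continue
            rows.append(
                {
                    "marker": name,
                    "designed_stable": panel[name],
                    "exact_fraction": r["exact_fraction"],
                    "mode_length": r["mode_length"],
                    "truth_length": r["truth_length"],
                    "n_reads": r["n_reads"],
                }
            )
        panel_report = pd.DataFrame(rows).sort_values("marker").reset_index(drop=True)
    return RepeatAccuracy(per_site=per_site, per_class=per_class, panel_report=panel_report)
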