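"""Partitioning control reads from host reads and flipping to natural
orientation.

In a combined-reference alignment (host genome + decoy contig), a read
derives from the controls iff its primary alignment lands on the decoy.
Because controls are mirror images, control reads are restored to natural
orientation by *flipping* — reversing the read and its quality string
without complementing — after which they can be re-aligned to the
natural-orientation templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam


def flip_read(seq: str, qual: str) -> tuple[str, str]:
    """Reverse sequence and qualities without complementing (involution)."""
    if len(seq) != len(qual):
        raise ValueError(f"seq length {len(seq)} != qual length {len(qual)}")
    return seq[::-1], qual[::-1]


@dataclass
class PartitionReport:
    n_total: int = 0
    n_sequin: int = 0
    n_host: int = 0
    n_unmapped: int = 0
    n_discordant_pairs: int = 0  # mates on different contig classes
    per_sequin_counts: dict[str, int] = field(default_factory=dict)
    achieved_spike_fraction: float = 0.0

    def finalize(self) -> None:
        mapped = self.n_sequin + self.n_host
        self.achieved_spike_fraction = self.n_sequin / mapped if mapped else 0.0
        assert self.n_total == self.n_sequin + self.n_host + self.n_unmapped


def partition_alignments(
    alignments: str | Path,
    decoy_name: str,
    region_of: dict[tuple[int, int], str] | None = None,
) -> tuple[list[pysam.AlignedSegment], list[pysam.AlignedSegment], PartitionReport]:
    """Split primary records into decoy-derived and host-derived sets.

    Pairs with mates on discordant contig classes follow the first mate and
    are counted separately.  Secondary and supplementary records are
    ignored; the primary record decides.
    """
    report = PartitionReport()
    sequin_reads: list[pysam.AlignedSegment] = []
    host_reads: list[pysam.AlignedSegment] = []
    with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
        if decoy_name not in af.references:
            raise ValueError(f"decoy contig {decoy_name!r} absent from header")
        first_mate_class: dict[str, bool] = {}
        for rec in af.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            report.n_total += 1
            if rec.is_unmapped:
                report.n_unmapped += 1
                continue
            on_decoy = rec.reference_name == decoy_name
            if rec.is_paired:
                prev = first_mate_class.get(rec.query_name)
                if prev is None:
                    first_mate_class[rec.query_name] = on_decoy
                elif prev != on_decoy:
                    report.n_discordant_pairs += 1
                    on_decoy = prev  # assign by the first mate
            if on_decoy:
                report.n_sequin += 1
                sequin_reads.append(rec)
            else:
                report.n_host += 1
                host_reads.append(rec)
    report.finalize()
    return sequin_reads, host_reads, report


def flip_reads_to_fastq(
    reads: list[pysam.AlignedSegment], prefix: Path, paired: bool = True
) -> list[Path]:
    """Write flipped (natural-orientation) control reads as FASTQ.

    Flipping reverses the sequenced read; for pairs this also swaps the
    R1/R2 roles so downstream aligners still see a canonical FR pair.
    Alignment SEQ is reference-orientation, so reverse-strand records are
    first restored to read orientation before flipping.
    """
    prefix = Path(prefix)

    def flipped(rec: pysam.AlignedSegment) -> tuple[str, str]:
        seq = rec.query_sequence or ""
        qual = (
            pysam.qualities_to_qualitystring(rec.query_qualities)
            if rec.query_qualities is not None
            else "I" * len(seq)
        )
        if rec.is_reverse:
            from .sequence import reverse_complement

            seq = reverse_complement(seq)
            qual = qual[::-1]
        return flip_read(seq, qual)

    if not paired:
        p = Path(f"{prefix}.flipped.fastq")
        with open(p, "w") as fh:
            for rec in reads:
                seq, qual = flipped(rec)
                fh.write(f"@{rec.query_name}\n{seq}\n+\n{qual}\n")
        return [p]
    p1, p2 = Path(f"{prefix}.flipped_R1.fastq"), Path(f"{prefix}.flipped_R2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for rec in reads:
            seq, qual = flipped(rec)
            # flip swaps fragment read order: former read2 becomes read1
            fh = f1 if rec.is_read2 else f2
            fh.write(f"@{rec.query_name}\n{seq}\n+\n{qual}\n")
    return [p1, p2]


def downsample_to_coverage(
    reads: list,
    target_coverage: float,
    total_span: int,
    seed: int,
    achieved_coverage: float | None = None,
) -> list:
    """Seeded Bernoulli thinning of *reads* to a target mean coverage.

    Retention probability is target/achieved; fragments (read pairs) are
    kept or dropped together, keyed by read name.
    """
    if achieved_coverage is None:
        total_bases = sum(
            (r.query_length or len(r.query_sequence or "")) for r in reads
        )
        achieved_coverage = total_bases / total_span if total_span else 0.0
    if target_coverage > achieved_coverage:
        raise ValueError(
            f"target coverage {target_coverage} exceeds achieved {achieved_coverage:.2f}"
        )
    if achieved_coverage == 0:
        return []
    p = target_coverage / achieved_coverage
    rng = np.random.default_rng(seed)
    names = sorted({getattr(r, "query_name", None) or r.name for r in reads})
    keep = {n for n in names if rng.random() < p}
    return [r for r in reads if (getattr(r, "query_name", None) or r.name) in keep]
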