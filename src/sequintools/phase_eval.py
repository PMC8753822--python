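"""Phasing evaluation against designed maternal/paternal haplotypes.

Each phase-set block reported by a phaser is compared with the truth under
both global orientations; the better orientation is scored.  A variant is
correctly phased iff its allele-to-haplotype assignment matches the truth
under that orientation.  Switch errors are transitions in the per-site
agree/disagree sequence ordered by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam


@dataclass
class TruthHetSite:
    block_id: str
    pos0: int
    maternal: str  # allele on the placed (reference) haplotype
    paternal: str


@dataclass
class PhasedSite:
    pos0: int
    hap1: str
    hap2: str
    phase_set: str


def truth_sites_from_decoy(decoy) -> list[TruthHetSite]:
    return [
        TruthHetSite(r["block_id"], r["pos0"], r["ref"], r["alt"])
        for r in decoy.truth_phasing
    ]


def read_phased_vcf(path: str | Path) -> tuple[list[PhasedSite], int]:
    """Phased sites (pipe-separated genotypes with a PS identifier) and the
    count of unphased records skipped."""
    sites: list[PhasedSite] = []
    n_unphased = 0
    with pysam.VariantFile(str(path)) as vf:
        sample = list(vf.header.samples)[0]
        for rec in vf:
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or None in gt or len(gt) != 2 or not call.phased:
                n_unphased += 1
                continue
            ps = call.get("PS")
            alleles = (rec.ref,) + tuple(rec.alts or ())
            sites.append(
                PhasedSite(
                    pos0=rec.start,
                    hap1=alleles[gt[0]],
                    hap2=alleles[gt[1]],
                    phase_set=str(ps) if ps is not None else "default",
                )
            )
    return sites, n_unphased


@dataclass
class BlockScore:
    phase_set: str
    n_phased: int  # truth sites phased in this block
    n_correct: int  # under the better orientation
    switch_errors: int
    span: int  # first to last phased site
    n_fp_sites: int


@dataclass
class PhasingResult:
    blocks: list[BlockScore]
    n_unphased: int
    total_fp_sites: int

    @property
    def correctly_phased_fraction(self) -> float:
        phased = sum(b.n_phased for b in self.blocks)
        correct = sum(b.n_correct for b in self.blocks)
        return correct / phased if phased else float("nan")

    @property
    def total_switch_errors(self) -> int:
        return sum(b.switch_errors for b in self.blocks)

    def block_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "phase_set": b.phase_set, "n_phased": b.n_phased,
                    "n_correct": b.n_correct, "switch_errors": b.switch_errors,
                    "span": b.span, "fp_sites": b.n_fp_sites,
                }
                for b in self.blocks
            ]
        )


def evaluate_phasing(
    phased_sites: list[PhasedSite],
    truth_sites: list[TruthHetSite],
    n_unphased: int = 0,
) -> PhasingResult:
    """Score phaser output blocks against the designed haplotypes.

    Sites absent from the truth are counted as false-positive variants and
    excluded from the correctly-phased denominator.  Blocks with a single
    truth site contribute to the phased fraction (trivially correct under
    the best orientation) but not to switch-error accounting.
    """
    truth_by_pos = {t.pos0: t for t in truth_sites}
    by_ps: dict[str, list[PhasedSite]] = {}
    for s in phased_sites:
        by_ps.setdefault(s.phase_set, []).append(s)

    blocks: list[BlockScore] = []
    total_fp = 0
    for ps, sites in sorted(by_ps.items()):
        sites = sorted(sites, key=lambda s: s.pos0)
        agree: list[bool] = []
        n_fp = 0
        positions: list[int] = []
        for s in sites:
            t = truth_by_pos.get(s.pos0)
            if t is None or {s.hap1, s.hap2} != {t.maternal, t.paternal}:
                n_fp += 1
                continue
            agree.append(s.hap1 == t.maternal)
            positions.append(s.pos0)
        total_fp += n_fp
        n_phased = len(agree)
        if n_phased == 0:
            blocks.append(BlockScore(ps, 0, 0, 0, 0, n_fp))
            continue
        n_true = sum(agree)
        n_correct = max(n_true, n_phased - n_true)  # best of two orientations
        switches = sum(a != b for a, b in zip(agree, agree[1:])) if n_phased >= 2 else 0
        span = positions[-1] - positions[0] if n_phased >= 2 else 0
        blocks.append(BlockScore(ps, n_phased, n_correct, switches, span, n_fp))
    return PhasingResult(blocks=blocks, n_unphased=n_unphased, total_fp_sites=total_fp)


def phased_fraction_by_distance(
    phased_sites: list[PhasedSite],
    truth_sites: list[TruthHetSite],
    bins: tuple[int, ...] = (100, 200, 400, 800, 1600),
) -> pd.DataFrame:
    """Fraction of adjacent truth het pairs co-phased correctly, by
    pairwise distance bin.  A pair is co-phased iff both sites share a
    phase set and their relative orientation matches the truth.  Empty
    bins are absent from the table, not reported as zero.
    """
    by_pos = {s.pos0: s for s in phased_sites}
    by_block: dict[str, list[TruthHetSite]] = {}
    for t in truth_sites:
        by_block.setdefault(t.block_id, []).append(t)

    def bin_label(d: int) -> str:
        prev = 0
        for edge in bins:
            if d <= edge:
                return f"{prev + 1}-{edge}"
            prev = edge
        return f">{bins[-1]}"

    counts: dict[str, list[int]] = {}
    for block_sites in by_block.values():
        block_sites = sorted(block_sites, key=lambda t: t.pos0)
        for t1, t2 in zip(block_sites, block_sites[1:]):
            d = t2.pos0 - t1.pos0
            s1, s2 = by_pos.get(t1.pos0), by_pos.get(t2.pos0)
            ok = False
            if (
                s1 is not None and s2 is not None
                and s1.phase_set == s2.phase_set
                and {s1.hap1, s1.hap2} == {t1.maternal, t1.paternal}
                and {s2.hap1, s2.hap2} == {t2.maternal, t2.paternal}
            ):
                ok = (s1.hap1 == t1.maternal) == (s2.hap1 == t2.maternal)
            lab = bin_label(d)
            counts.setdefault(lab, [0, 0])
            counts[lab][0] += ok
            counts[lab][1] += 1
    order = [f"1-{bins[0]}"] + [
        f"{a + 1}-{b}" for a, b in zip(bins, bins[1:])
    ] + [f">{bins[-1]}"]
    rows = [
        {"distance_bin": lab, "n_pairs": counts[lab][1],
         "co_phased_fraction": counts[lab][0] / counts[lab][1]}
        for lab in order if lab in counts
    ]
    return pd.DataFrame(rows, columns=["distance_bin", "n_pairs", "co_phased_fraction"])


# ---------------------------------------------------------------------------
# bundled phasers for harness self-tests
# ---------------------------------------------------------------------------


def write_phased_vcf(
    path: str | Path,
    decoy_name: str,
    decoy_length: int,
    records: list[tuple[int, str, str, tuple[int, int], str]],
) -> None:
    """Write records (pos0, ref, alt, phased GT, phase-set id) to VCF."""
    h = pysam.VariantHeader()
    h.contigs.add(decoy_name, length=decoy_length)
    h.formats.add("GT", 1, "String", "Genotype")
    h.formats.add("PS", 1, "Integer", "Phase set")
    h.add_sample("SAMPLE")
    with pysam.VariantFile(str(path), "w", header=h) as vf:
        for pos0, ref, alt, gt, ps in sorted(records):
            r = vf.new_record(contig=decoy_name, start=pos0, alleles=(ref, alt))
            r.samples["SAMPLE"]["GT"] = gt
            r.samples["SAMPLE"].phased = True
            r.samples["SAMPLE"]["PS"] = int(ps)
            vf.write(r)


def truth_aware_phaser(truth_sites: list[TruthHetSite]) -> list[PhasedSite]:
    """Assigns the truth phase to every site — scores exactly 1.0 by
    construction (harness self-test)."""
    by_block: dict[str, list[TruthHetSite]] = {}
    for t in truth_sites:
        by_block.setdefault(t.block_id, []).append(t)
    out = []
    for block_id, sites in by_block.items():
        for t in sites:
            out.append(PhasedSite(t.pos0, t.maternal, t.paternal, block_id))
    return out


def random_phaser(truth_sites: list[TruthHetSite], seed: int) -> list[PhasedSite]:
    """Random orientation per site within truth blocks (expected
    correctly-phased fraction 0.5 for large blocks)."""
    rng = np.random.default_rng(seed)
    out = []
    for t in truth_sites:
        if rng.integers(2):
            out.append(PhasedSite(t.pos0, t.maternal, t.paternal, t.block_id))
        else:
            out.append(PhasedSite(t.pos0, t.paternal, t.maternal, t.block_id))
    return out
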