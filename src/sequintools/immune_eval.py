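"""CDR3 sequencing fidelity, clonotype-ladder quantification and HLA
consensus accuracy.

All three analyses consume per-base profiles over designed intervals:
CDR3 error rate counts mismatch/indel events per 100 aligned bases;
clonotype abundance is the mean CDR3 depth share relative to the ladder's
expected frequencies (RMSE and squared correlation on the frequency
scale); HLA accuracy is the Levenshtein distance between the majority-vote
consensus over exons 2/3 and the designed allele sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .profiling import PerBaseProfile


def cdr3_error_rate(profile: PerBaseProfile, interval: tuple[int, int]) -> float | None:
    """Errors per 100 aligned bases within a CDR3 interval (decoy coords).

    Errors are mismatching read bases plus insertion and deletion events
    anchored/spanning within the interval.  Returns None when the interval
    has no coverage.
    """
    chrom, start, end = profile.region
    lo, hi = interval[0] - start, interval[1] - start
    if lo < 0 or hi > len(profile.depth):
        raise ValueError("interval outside profiled region")
    sl = slice(lo, hi)
    aligned = int(profile.depth[sl].sum())
    if aligned == 0:
        return None
    errors = (
        int(profile.mismatches[sl].sum())
        + int(profile.insertion_starts[sl].sum())
        + int(profile.deletion_spans[sl].sum())
    )
    return 100.0 * errors / aligned


@dataclass
class ClonotypeQuant:
    table: pd.DataFrame  # per clonotype: expected_freq, observed_freq, ...
    rmse: float
    r_squared: float
    rmse_log: float | None  # on log10 frequencies over detected clonotypes

    @property
    def spearman(self) -> float:
        t = self.table
        return float(stats.spearmanr(t["expected_freq"], t["observed_freq"]).statistic)


def quantify_clonotypes(
    mean_depths: dict[str, float],
    expected_freqs: dict[str, float],
    error_rates: dict[str, float | None] | None = None,
) -> ClonotypeQuant:
    """Observed vs expected clonotype frequencies over the ladder.

    ``mean_depths`` maps clonotype id -> mean coverage over its CDR3;
    observed frequency is that depth relative to the total over all
    clonotypes.  Undetected clonotypes observe 0, stay in the RMSE, and
    are flagged.  RMSE/R^2 are computed on the linear frequency scale (a
    log-scale RMSE over detected clonotypes is reported alongside).
    """
    ids = list(expected_freqs)
    exp = np.array([expected_freqs[i] for i in ids], dtype=float)
    exp = exp / exp.sum()
    depth = np.array([mean_depths.get(i, 0.0) for i in ids], dtype=float)
    total = depth.sum()
    obs = depth / total if total > 0 else np.zeros_like(depth)
    rows = []
    for i, cid in enumerate(ids):
        rows.append(
            {
                "clonotype": cid,
                "expected_freq": float(exp[i]),
                "observed_freq": float(obs[i]),
                "mean_depth": float(depth[i]),
                "detected": bool(depth[i] > 0),
                "cdr3_errors_per_100nt": (
                    (error_rates or {}).get(cid) if error_rates else None
                ),
            }
        )
    table = pd.DataFrame(rows)
    rmse = float(np.sqrt(np.mean((obs - exp) ** 2)))
    if len(ids) >= 2 and obs.std() > 0 and exp.std() > 0:
        r = float(stats.pearsonr(exp, obs).statistic)
        r2 = r * r
    else:
        r2 = float("nan")
    det = obs > 0
    if det.sum() >= 2:
        rmse_log = float(np.sqrt(np.mean((np.log10(obs[det]) - np.log10(exp[det])) ** 2)))
    else:
        rmse_log = None
    return ClonotypeQuant(table=table, rmse=rmse, r_squared=r2, rmse_log=rmse_log)


@dataclass
class HLAConsensusResult:
    gene: str
    exon: str
    consensus: str
    edit_distance: int
    low_confidence: bool  # any exon position below the coverage floor
    n_ties: int


def consensus_sequence(
    profile: PerBaseProfile, interval: tuple[int, int], min_depth: int = 5
) -> tuple[str, bool, int]:
    """Per-position majority-vote consensus over an interval.

    Base support at each position is the matching-read count for the
    reference base plus the mismatch counts for the alternatives; ties go
    to the reference base and are flagged.  Positions under *min_depth*
    mark the consensus low-confidence.
    """
    chrom, start, end = profile.region
    lo, hi = interval[0] - start, interval[1] - start
    out = []
    low = False
    ties = 0
    for local in range(lo, hi):
        ref = profile.ref_seq[local]
        support = {b: int(profile.mismatch_by_base[b][local]) for b in "ACGT"}
        support[ref] = int(profile.matches[local])
        if profile.depth[local] < min_depth:
            low = True
        best = max(support.values())
        winners = [b for b, c in support.items() if c == best]
        if len(winners) > 1:
            ties += 1
            out.append(ref if ref in winners else sorted(winners)[0])
        else:
            out.append(winners[0])
    return "".join(out), low, ties


def hla_consensus_distance(
    profile: PerBaseProfile,
    gene: str,
    exon_intervals: dict[str, tuple[int, int]],
    references: dict[str, str],
    min_depth: int = 5,
) -> list[HLAConsensusResult]:
    """Consensus-vs-designed-allele edit distance per exon.

    *references* maps exon name to the designed sequence in the same
    (decoy) orientation as the profile.  Distance is plain Levenshtein with
    unit costs.
    """
    out = []
    for exon, interval in exon_intervals.items():
        cons, low, ties = consensus_sequence(profile, interval, min_depth)
        ref = references[exon]
        dist = edlib.align(cons, ref, task="distance")["editDistance"]
        out.append(
            HLAConsensusResult(
                gene=gene, exon=exon, consensus=cons,
                edit_distance=int(dist), low_confidence=low, n_ties=ties,
            )
        )
    return out
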