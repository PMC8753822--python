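"""Mixture design: genotypes, somatic VAFs and abundance ladders as shares.

A mixture manifest assigns every control molecule a relative concentration
(molar share).  Genotypes and somatic allele frequencies are encoded purely
by the ratio between pair members: a heterozygote mixes reference and
variant 1:1, a 1% somatic VAF mixes them 99:1, and a homozygous-alt design
contains only the variant member.  Shares are molar over molecules of
near-equal length; the read simulator weights fragment sampling by
share x length so that *coverage* tracks the designed share.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: default fraction of total library mass assigned to the controls
DEFAULT_SPIKE_FRACTION = 0.02


def genotype_to_concentration(designed_vaf: float) -> tuple[float, float]:
    """Pair-local (reference share, variant share) for a designed VAF.

    The variant member's share of the pair equals the VAF: het (0.5) gives
    1:1, a 1% somatic design gives ref:var = 99:1, hom-alt (1.0) gives
    (0, 1).  Shares are later scaled by the pair's overall abundance.
    """
    if not 0.0 < designed_vaf <= 1.0:
        raise ValueError(f"designed VAF must be in (0, 1], got {designed_vaf}")
    return 1.0 - designed_vaf, designed_vaf


def required_spike_fraction(total_control_span: float, genome_size: float) -> float:
    """Mass fraction at which mean control coverage equals genome coverage.

    Under uniform fragment sampling, coverage is proportional to mass per
    nucleotide of target, so equal mean coverage needs the controls to make
    up ``control_span / genome_size`` of the library (~0.05% for a ~1.7 Mb
    control span against a ~3.2 Gb genome).
    """
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if total_control_span <= 0:
        raise ValueError("control span must be positive")
    return total_control_span / genome_size


@dataclass
class MixtureManifest:
    """Normalized per-sequin relative concentrations."""

    table: pd.DataFrame  # columns: sequin_id, pair_id, role, share
    spike_fraction: float = DEFAULT_SPIKE_FRACTION

    def __post_init__(self) -> None:
        total = float(self.table["share"].sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"manifest shares sum to {total}, expected 1")
        if (self.table["share"] < 0).any():
            raise ValueError("negative share in manifest")
        if self.table["sequin_id"].duplicated().any():
            raise ValueError("duplicate sequin assignment in manifest")

    def share_of(self, sequin_id: str) -> float:
        sel = self.table.loc[self.table["sequin_id"] == sequin_id, "share"]
        return float(sel.iloc[0]) if len(sel) else 0.0

    def pair_vaf(self, pair_id: str) -> float:
        """Recover var/(var+ref) for a pair from the manifest shares."""
        sub = self.table[self.table["pair_id"] == pair_id]
        ref = float(sub.loc[sub["role"] == "reference", "share"].sum())
        var = float(sub.loc[sub["role"] == "variant", "share"].sum())
        if ref + var == 0:
            raise KeyError(f"pair {pair_id} absent from manifest")
        return var / (var + ref)

    def to_tsv(self, path: Path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write(f"#spike_fraction={self.spike_fraction}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Path) -> "MixtureManifest":
        spike = DEFAULT_SPIKE_FRACTION
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#spike_fraction="):
                spike = float(first.split("=", 1)[1])
                table = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                table = pd.read_csv(fh, sep="\t")
        table["pair_id"] = table["pair_id"].where(table["pair_id"].notna(), None)
        return cls(table=table, spike_fraction=spike)


def build_mixture_manifest(
    pair_abundances: dict[str, tuple[float, float]],
    single_abundances: dict[str, float],
    roles: dict[str, dict[str, str]] | None = None,
    spike_fraction: float = DEFAULT_SPIKE_FRACTION,
) -> MixtureManifest:
    """Combine per-pair (abundance, VAF) and per-singleton abundances.

    ``pair_abundances`` maps pair_id -> (pair weight, designed VAF); the
    pair weight is split between members by :func:`genotype_to_concentration`.
    ``roles`` optionally maps pair_id -> {role: sequin_id}; by default
    members are named ``<pair>_R`` / ``<pair>_V``.  All raw weights are
    normalized to sum to 1.
    """
    rows: list[dict] = []
    seen: set[str] = set()

    def add(sequin_id: str, pair_id: str | None, role: str, weight: float) -> None:
        if sequin_id in seen:
            raise ValueError(f"duplicate abundance assignment for {sequin_id}")
        if weight < 0:
            raise ValueError(f"negative abundance for {sequin_id}")
        seen.add(sequin_id)
        rows.append({"sequin_id": sequin_id, "pair_id": pair_id, "role": role, "share": weight})

    for pair_id, (weight, vaf) in pair_abundances.items():
        ref_share, var_share = genotype_to_concentration(vaf)
        member = (roles or {}).get(pair_id, {})
        add(member.get("reference", f"{pair_id}_R"), pair_id, "reference", weight * ref_share)
        add(member.get("variant", f"{pair_id}_V"), pair_id, "variant", weight * var_share)
    for sequin_id, weight in single_abundances.items():
        add(sequin_id, None, "single", weight)

    table = pd.DataFrame(rows, columns=["sequin_id", "pair_id", "role", "share"])
    total = float(table["share"].sum())
    if total <= 0:
        raise ValueError("all abundances are zero")
    table["share"] = table["share"] / total
    return MixtureManifest(table=table, spike_fraction=spike_fraction)


def default_manifest(bundle, spike_fraction: float = DEFAULT_SPIKE_FRACTION) -> MixtureManifest:
    """Manifest for the default design: unit pair weights, designed VAFs,
    and the clonotype abundance ladder from the immune section."""
    pair_abundances: dict[str, tuple[float, float]] = {}
    roles: dict[str, dict[str, str]] = {}
    singles: dict[str, float] = {}

    for p in bundle.smallvar_pairs:
        pair_abundances[p.pair_id] = (1.0, p.vaf)
        roles[p.pair_id] = {"reference": p.ref.id, "variant": p.var.id}
    for m in bundle.microsatellites:
        if m.var is None:
            singles[m.ref.id] = 1.0
        else:
            pid = m.ref.pair_id
            pair_abundances[pid] = (1.0, 0.5)
            roles[pid] = {"reference": m.ref.id, "variant": m.var.id}
    for s in bundle.repeat_sequins:
        singles[s.id] = 1.0
    for h in bundle.haplotypes:
        pid = h.pair.block_id
        pair_abundances[pid] = (1.0, 0.5)
        roles[pid] = {"reference": h.maternal.id, "variant": h.paternal.id}
    for build in bundle.svs:
        # SV pairs are heterozygous; TRA splits its weight across both
        # reciprocal contexts/products
        w = 1.0 / len(build.refs)
        for ref, var in zip(build.refs, build.variants):
            singles[ref.id] = 0.5 * w
            singles[var.id] = 0.5 * w
    for h in bundle.hla:
        singles[h.sequin.id] = 0.5  # two alleles per gene ~ one diploid locus
    n_clono = len(bundle.immune.clonotypes)
    for design, sequin in bundle.immune.clonotypes:
        # the ladder spans the designed dynamic range; scale so the immune
        # section keeps a comparable total mass to other sections
        singles[sequin.id] = design.expected_freq * n_clono * 0.5
    for s in bundle.immune.nonrearranged:
        singles[s.id] = 0.25

    return build_mixture_manifest(pair_abundances, singles, roles, spike_fraction)


def clonotype_ladder(manifest: MixtureManifest, clonotype_ids: list[str]) -> pd.Series:
    """Expected clonotype frequencies implied by the manifest (renormalized
    over the rearranged clonotype set)."""
    sub = manifest.table.set_index("sequin_id").loc[clonotype_ids, "share"]
    return sub / sub.sum()
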