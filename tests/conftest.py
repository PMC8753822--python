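"""Shared fixtures: the default design build and helpers for simulating
small aligned libraries against it.  Everything is generated at test time
from fixed seeds."""

from __future__ import annotations

from pathlib import Path

import pytest

from sequintools.design import assemble_decoy_chromosome, build_default_design
from sequintools.mixture import MixtureManifest, default_manifest
from sequintools import readsim

BUILD_SEED = 11


@pytest.fixture(scope="session")
def bundle():
    return build_default_design(BUILD_SEED)


@pytest.fixture(scope="session")
def decoy(bundle):
    return assemble_decoy_chromosome(bundle)


@pytest.fixture(scope="session")
def manifest(bundle):
    return default_manifest(bundle)


@pytest.fixture(scope="session")
def molecules(bundle):
    """Mirrored (as-synthesized) sequences for every designed molecule."""
    return {s.id: s.mirrored_seq for s in bundle.all_sequins()}


@pytest.fixture(scope="session")
def decoy_maps(bundle, decoy):
    return readsim.decoy_alignment_maps(bundle, decoy)


@pytest.fixture(scope="session")
def design_outdir(tmp_path_factory, bundle, decoy):
    from sequintools.design import write_design_outputs

    out = tmp_path_factory.mktemp("design")
    paths = write_design_outputs(bundle, decoy, out)
    return paths


def subset_manifest(manifest: MixtureManifest, ids: list[str]) -> MixtureManifest:
    sub = manifest.table[manifest.table.sequin_id.isin(ids)].copy()
    sub["share"] = sub["share"] / sub["share"].sum()
    return MixtureManifest(table=sub.reset_index(drop=True),
                           spike_fraction=manifest.spike_fraction)


def simulate_bam(
    manifest,
    molecules: dict[str, str],
    config: readsim.ReadSimConfig,
    decoy_maps,
    decoy,
    path: Path,
    seed: int,
    ids: list[str] | None = None,
    **sim_kwargs,
):
    """Simulate a library (optionally restricted to *ids*) and return the
    (sorted+indexed BAM path, SimResult)."""
    m = subset_manifest(manifest, ids) if ids else manifest
    mols = {k: molecules[k] for k in (ids or molecules)}
    result = readsim.simulate_reads(m, mols, config, seed=seed, **sim_kwargs)
    bam = readsim.write_alignments(result, decoy_maps, decoy.name, len(decoy.seq), path)
    return bam, result
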