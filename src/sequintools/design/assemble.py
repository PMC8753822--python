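"""Decoy-chromosome assembly and truth-set serialization.

Placed sequins are concatenated spacer-free into four functional regions:

* ``p1`` — small variants, simple repeats, microsatellites, haplotype blocks
* ``p2`` — structural variants
* ``p3`` — HLA alleles
* ``p4`` — immune-receptor loci

Only the *reference* member of each pair is placed; variant-member truth is
expressed at the reference member's decoy coordinates.  The decoy carries
the **mirrored** sequence of each sequin, so natural-orientation feature
coordinates are reflected during mapping.

Coordinates: decoy/BED intervals are 0-based half-open; VCF output is
1-based (pysam handles the conversion from the 0-based ``start`` we pass).
"""

from __future__ import annotations

import csv
from pathlib import Path

import pysam

from .builder import DesignBundle
from .types import DecoyChromosome, Placement, SVType, VariantClass
from .variants import mirror_variant

REGION_ORDER = ("p1", "p2", "p3", "p4")


def _mirror_interval(start: int, end: int, natural_len: int) -> tuple[int, int]:
    """Natural-orientation [start, end) -> mirrored-molecule coordinates."""
    return natural_len - end, natural_len - start


def assemble_decoy_chromosome(bundle: DesignBundle) -> DecoyChromosome:
    """Concatenate placed sequins and derive all decoy-coordinate truth sets."""
    census = bundle.census
    by_region = bundle.placed_sequins()
    seq_parts: list[str] = []
    placements: dict[str, Placement] = {}
    regions: list[tuple[str, int, int]] = []
    edge_mask: list[tuple[str, int, int]] = []
    cursor = 0
    for region_id in REGION_ORDER:
        region_start = cursor
        for s in by_region[region_id]:
            if s.id in placements:
                raise ValueError(f"sequin {s.id} placed twice")
            L = len(s)
            placements[s.id] = Placement(s.id, cursor, cursor + L, region_id)
            seq_parts.append(s.mirrored_seq)
            e = min(census.edge_width, L // 2)
            edge_mask.append((s.id, cursor, cursor + e))
            edge_mask.append((s.id, cursor + L - e, cursor + L))
            cursor += L
        regions.append((region_id, region_start, cursor))

    decoy = DecoyChromosome(
        name=census.decoy_name,
        seq="".join(seq_parts),
        regions=regions,
        placements=placements,
        edge_mask=edge_mask,
    )

    # --- small-variant truth (decoy coordinates, mirrored alleles) ---
    for pair in bundle.smallvar_pairs:
        pl = placements[pair.ref.id]
        L = len(pair.template)
        for v in pair.variants:
            mstart, mref, malt = mirror_variant(v, L)
            decoy.truth_small_variants.append(
                {
                    "chrom": decoy.name,
                    "pos0": pl.start + mstart,
                    "ref": mref,
                    "alt": malt,
                    "vclass": v.vclass.value,
                    "context": v.context.value,
                    "vaf": v.designed_vaf,
                    "pair_id": pair.pair_id,
                }
            )
    assert len(decoy.truth_small_variants) == census.n_small_variants

    # --- phasing truth ---
    for h in bundle.haplotypes:
        pl = placements[h.maternal.id]
        L = len(h.pair.maternal_seq)
        for pos, am, ap in h.pair.het_sites:
            decoy.truth_phasing.append(
                {
                    "block_id": h.pair.block_id,
                    "source_label": h.pair.source_label,
                    "chrom": decoy.name,
                    "pos0": pl.start + (L - 1 - pos),
                    "ref": am,  # maternal member is the placed reference
                    "alt": ap,
                    "block_start": pl.start,
                    "block_end": pl.end,
                }
            )

    # --- SV truth ---
    for build in bundle.svs:
        d = build.design
        bps = []
        for ctx_id, gap in build.truth_breakpoints:
            pl = placements[ctx_id]
            L = pl.end - pl.start
            bps.append(pl.start + (L - gap))
        rec = {
            "sv_id": d.sv_id,
            "svtype": d.svtype.value,
            "size": d.size,
            "breakpoints": sorted(bps) if d.svtype is not SVType.TRA else bps,
            "chrom": decoy.name,
        }
        if d.svtype in (SVType.DEL, SVType.DUP, SVType.INV):
            rec["span"] = (min(bps), max(bps))
        decoy.truth_svs.append(rec)

    # --- feature intervals (BED-ready, decoy coordinates) ---
    def add_interval(kind: str, label: str, sequin_id: str, s: int, e: int) -> None:
        pl = placements[sequin_id]
        L = pl.end - pl.start
        ms, me = _mirror_interval(s, e, L)
        decoy.feature_intervals.append(
            {"kind": kind, "label": label, "sequin_id": sequin_id,
             "start": pl.start + ms, "end": pl.start + me}
        )

    for s in bundle.repeat_sequins:
        for ann in s.annotations:
            add_interval("homopolymer", ann.label, s.id, ann.start, ann.end)
    for m in bundle.microsatellites:
        s, e = m.design.tract_interval
        add_interval("microsatellite", m.design.name, m.ref.id, s, e)
    for h in bundle.hla:
        add_interval("hla_exon2", h.design.allele_name, h.sequin.id, *h.design.exon2_interval)
        add_interval("hla_exon3", h.design.allele_name, h.sequin.id, *h.design.exon3_interval)
    for design, sequin in bundle.immune.clonotypes:
        add_interval("cdr3", design.clono_id, sequin.id, *design.cdr3_interval)

    # truth REF alleles must match the assembled sequence
    for rec in decoy.truth_small_variants:
        sl = decoy.seq[rec["pos0"] : rec["pos0"] + len(rec["ref"])]
        if sl != rec["ref"]:
            raise AssertionError(f"truth/decoy mismatch at {rec['pos0']}")
    return decoy


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(path: Path, entries: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _vcf_header(decoy: DecoyChromosome) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    h.contigs.add(decoy.name, length=len(decoy.seq))
    return h


def write_truth_small_variant_vcf(path: Path, decoy: DecoyChromosome) -> None:
    """Truth VCF (v4.2).  Indels are left-anchored on the preceding base so
    every REF field matches the decoy FASTA slice at POS."""
    h = _vcf_header(decoy)
    h.info.add("VAF", 1, "Float", "Designed variant allele frequency")
    h.info.add("PAIR", 1, "String", "Sequin pair identifier")
    h.info.add("VCLASS", 1, "String", "Designed variant class (SNV/INS/DEL)")
    h.info.add("CONTEXT", 1, "String", "Designed sequence context")
    with pysam.VariantFile(str(path), "w", header=h) as vf:
        for rec in sorted(decoy.truth_small_variants, key=lambda r: r["pos0"]):
            pos0, ref, alt = rec["pos0"], rec["ref"], rec["alt"]
            if not ref or not alt:  # anchor indels on the previous base
                anchor = decoy.seq[pos0 - 1]
                pos0, ref, alt = pos0 - 1, anchor + ref, anchor + alt
            r = vf.new_record(contig=decoy.name, start=pos0, alleles=(ref, alt))
            r.stop = pos0 + len(ref)
            r.info["VAF"] = rec["vaf"]
            r.info["PAIR"] = rec["pair_id"]
            r.info["VCLASS"] = rec["vclass"]
            r.info["CONTEXT"] = rec["context"]
            vf.write(r)


def write_truth_sv_vcf(path: Path, decoy: DecoyChromosome) -> None:
    """Symbolic-allele SV truth; reciprocal translocations as BND pairs."""
    h = _vcf_header(decoy)
    h.info.add("SVTYPE", 1, "String", "Structural variant type")
    h.info.add("END", 1, "Integer", "End of the variant on the decoy")
    h.info.add("SVLEN", 1, "Integer", "Designed SV length")
    h.info.add("MATEID", 1, "String", "Breakend mate record")
    h.info.add("SVID", 1, "String", "Design identifier")
    # VCF anchoring: POS is the base preceding the event, so a breakpoint
    # at 0-based gap g anchors at start0 = g - 1 and END = far gap
    recs = []
    for sv in decoy.truth_svs:
        if sv["svtype"] == "TRA":
            p1, p2 = sv["breakpoints"]
            for tag, pa, pb in ((("a", p1, p2)), (("b", p2, p1))):
                alt = f"N]{decoy.name}:{pb}]"
                recs.append((pa - 1, sv, f"{sv['sv_id']}_{tag}", alt, None))
        else:
            bps = sv["breakpoints"]
            recs.append((bps[0] - 1, sv, sv["sv_id"], f"<{sv['svtype']}>", bps[-1]))
    with pysam.VariantFile(str(path), "w", header=h) as vf:
        for pos0, sv, rid, alt, end in sorted(recs, key=lambda t: t[0]):
            ref = decoy.seq[pos0] if pos0 < len(decoy.seq) else "N"
            if sv["svtype"] in ("INS", "VIR", "TRA"):
                stop = pos0 + 1
            else:
                stop = end
            r = vf.new_record(
                contig=decoy.name, start=pos0, stop=stop, alleles=(ref, alt), id=rid
            )
            if sv["svtype"] == "TRA":
                r.info["SVTYPE"] = "BND"
                mate = f"{sv['sv_id']}_b" if rid.endswith("_a") else f"{sv['sv_id']}_a"
                r.info["MATEID"] = mate
            else:
                r.info["SVTYPE"] = sv["svtype"]
                svlen = -sv["size"] if sv["svtype"] == "DEL" else sv["size"]
                r.info["SVLEN"] = svlen
            r.info["SVID"] = sv["sv_id"]
            vf.write(r)


def write_bed(path: Path, rows: list[tuple], header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("#" + header + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_phasing_truth(path: Path, decoy: DecoyChromosome) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["block_id", "source_label", "chrom", "pos", "ref", "alt",
                    "block_start", "block_end"])
        for rec in sorted(decoy.truth_phasing, key=lambda r: r["pos0"]):
            w.writerow([rec["block_id"], rec["source_label"], rec["chrom"],
                        rec["pos0"] + 1, rec["ref"], rec["alt"],
                        rec["block_start"], rec["block_end"]])


def write_census_tsv(path: Path, bundle: DesignBundle) -> None:
    c = bundle.census
    rows = [
        ("small_variants", c.n_small_variants),
        ("smallvar_pairs", c.smallvar_pairs),
        ("microsatellites", len(c.microsatellites)),
        ("haplotype_pairs", c.haplotype_pairs),
        ("hla_alleles", c.n_hla_alleles),
        ("immune_loci", c.n_immune_loci),
        *[(f"sv_{t.lower()}", n) for t, n in c.sv_counts.items()],
        ("sv_total", c.n_svs),
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["feature", "count"])
        w.writerows(rows)


def write_design_outputs(bundle: DesignBundle, decoy: DecoyChromosome, outdir: Path) -> dict[str, Path]:
    """Emit the full design file set; returns a name->path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "decoy_fasta": outdir / "decoy.fa",
        "sequin_fasta": outdir / "sequins_natural.fa",
        "sequin_mirrored_fasta": outdir / "sequins_mirrored.fa",
        "cytoband_bed": outdir / "decoy_cytoband.bed",
        "placement_bed": outdir / "sequin_placements.bed",
        "edge_bed": outdir / "edge_mask.bed",
        "feature_bed": outdir / "feature_intervals.bed",
        "truth_smallvar_vcf": outdir / "truth_small_variants.vcf",
        "truth_sv_vcf": outdir / "truth_svs.vcf",
        "phasing_truth": outdir / "truth_phasing.tsv",
        "census_tsv": outdir / "design_census.tsv",
    }
    write_fasta(paths["decoy_fasta"], [(decoy.name, decoy.seq)])
    all_sequins = bundle.all_sequins()
    write_fasta(paths["sequin_fasta"], [(s.id, s.natural_seq) for s in all_sequins])
    write_fasta(
        paths["sequin_mirrored_fasta"], [(s.id, s.mirrored_seq) for s in all_sequins]
    )
    write_bed(paths["cytoband_bed"],
              [(decoy.name, s, e, rid) for rid, s, e in decoy.regions],
              header="chrom\tstart\tend\tregion (0-based half-open)")
    write_bed(paths["placement_bed"],
              [(decoy.name, p.start, p.end, p.sequin_id, p.region_id)
               for p in sorted(decoy.placements.values(), key=lambda p: p.start)],
              header="chrom\tstart\tend\tsequin\tregion (0-based half-open)")
    write_bed(paths["edge_bed"],
              [(decoy.name, s, e, sid) for sid, s, e in decoy.edge_mask],
              header="chrom\tstart\tend\tsequin (0-based half-open)")
    write_bed(paths["feature_bed"],
              [(decoy.name, f["start"], f["end"], f"{f['kind']}:{f['label']}", f["sequin_id"])
               for f in sorted(decoy.feature_intervals, key=lambda f: f["start"])],
              header="chrom\tstart\tend\tfeature\tsequin (0-based half-open)")
    write_truth_small_variant_vcf(paths["truth_smallvar_vcf"], decoy)
    write_truth_sv_vcf(paths["truth_sv_vcf"], decoy)
    write_phasing_truth(paths["phasing_truth"], decoy)
    write_census_tsv(paths["census_tsv"], bundle)
    return paths
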