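"""Seeded read simulator for control mixtures.

Simulates paired short-read or single long-read libraries from a mixture
manifest: fragments are sampled per molecule proportional to
``share x length``, placed uniformly, optionally reweighted by a quadratic
GC-bias curve, and mutated by an error model with transition/transversion
structure and homopolymer-scaled indel rates (plateauing at run length 15).
Every injected event is logged, which lets the simulator emit pre-aligned
records against the decoy chromosome and gives downstream evaluation
modules an exact per-read truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .sequence import (
    TRANSITIONS,
    TRANSVERSIONS,
    gc_fraction,
    homopolymer_run_lengths,
    reverse_complement,
)

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def default_homopolymer_curve(
    max_run: int = 15, ins_scale: float = 1.0, del_scale: float = 1.0
) -> dict[int, tuple[float, float]]:
    """Linear growth of indel-rate multipliers with run length, plateauing
    at ``max_run`` (error rates in repeats rise with repeat length up to
    ~15 nt and flatten beyond)."""
    curve = {}
    for run in range(1, max_run + 1):
        mult = 1.0 + (run - 1)
        curve[run] = (ins_scale * mult, del_scale * mult)
    return curve


@dataclass
class ReadSimConfig:
    mode: str = "paired_short"  # "paired_short" | "long"
    read_length: int = 100
    fragment_mean: float = 300.0
    fragment_sd: float = 60.0
    substitution_rate: float = 0.0
    titv_ratio: float = 2.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    homopolymer_error_curve: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (1.0, 1.0)}
    )
    gc_bias: tuple[float, float, float] = (0.0, 0.0, 1.0)  # a*g^2 + b*g + c
    depth: float = 30.0
    quality_char: str = "I"  # constant Q40; evaluation never weights by quality

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError(f"rate {r} outside [0, 1)")
        if self.mode not in ("paired_short", "long"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "paired_short" and self.fragment_mean <= self.read_length:
            raise ValueError("fragment_mean must exceed read_length in short mode")

    def curve_multipliers(self, run_length: int) -> tuple[float, float]:
        if not self.homopolymer_error_curve:
            return 1.0, 1.0
        run = min(run_length, max(self.homopolymer_error_curve))
        return self.homopolymer_error_curve.get(run, (1.0, 1.0))


#: qualitative instrument-like presets; orderings (long-read error >>
#: short-read; PCR adds indel/GC bias) are illustrative, not calibrated
PROFILES: dict[str, ReadSimConfig] = {
    "pcrfree_like": ReadSimConfig(
        mode="paired_short", read_length=150, fragment_mean=320, fragment_sd=80,
        substitution_rate=1e-3, titv_ratio=2.0,
        insertion_rate=2e-6, deletion_rate=1e-5,
        homopolymer_error_curve=default_homopolymer_curve(),
    ),
    "pcr_like": ReadSimConfig(
        mode="paired_short", read_length=125, fragment_mean=180, fragment_sd=40,
        substitution_rate=2e-3, titv_ratio=2.0,
        insertion_rate=1e-5, deletion_rate=4e-5,
        homopolymer_error_curve=default_homopolymer_curve(ins_scale=2.0, del_scale=3.0),
        gc_bias=(-4.0, 4.0, 0.2),
    ),
    "nanopore_like": ReadSimConfig(
        mode="long", read_length=100, fragment_mean=800, fragment_sd=700,
        substitution_rate=3e-2, titv_ratio=1.7,
        insertion_rate=1e-2, deletion_rate=2e-2,
        homopolymer_error_curve=default_homopolymer_curve(ins_scale=1.0, del_scale=2.0),
    ),
}


def gc_bias_weight(gc: float, coefficients: tuple[float, float, float]) -> float:
    """Quadratic fragment weight in GC fraction, clipped at zero."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc fraction outside [0, 1]")
    a, b, c = coefficients
    return max(0.0, a * gc * gc + b * gc + c)


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------


@dataclass
class ErrorEvent:
    kind: str  # "sub" | "ins" | "del"
    mol_offset: int  # position within the input slice (input coordinates)
    base: str  # substituted-to base, inserted payload, or deleted base


def inject_errors(
    seq: str, config: ReadSimConfig, rng: np.random.Generator
) -> tuple[str, list[ErrorEvent]]:
    """Mutate *seq* under the configured error model.

    Substitutions pick a transition with probability titv/(titv+1);
    insertion/deletion probabilities at each base are the baseline rates
    times the homopolymer-curve multiplier for the run containing the base.
    Insertions duplicate the current base (slippage-like) after it.
    Returns the mutated sequence and a log of events in input coordinates.
    """
    n = len(seq)
    if n == 0:
        return seq, []
    any_indel = config.insertion_rate > 0 or config.deletion_rate > 0
    if not any_indel and config.substitution_rate == 0:
        return seq, []
    events: list[ErrorEvent] = []
    sub_draw = rng.random(n)
    indel_draw = rng.random(n)
    p_ti = config.titv_ratio / (config.titv_ratio + 1.0)
    if not any_indel:
        # substitution-only fast path: mutate just the drawn positions
        chars = list(seq)
        for i in np.nonzero(sub_draw < config.substitution_rate)[0]:
            base = chars[i]
            if base not in TRANSITIONS:
                continue
            if rng.random() < p_ti:
                new_base = TRANSITIONS[base]
            else:
                new_base = TRANSVERSIONS[base][int(rng.integers(2))]
            chars[i] = new_base
            events.append(ErrorEvent("sub", int(i), new_base))
        return "".join(chars), events
    runs = homopolymer_run_lengths(seq)
    out: list[str] = []
    for i, base in enumerate(seq):
        ins_rate = del_rate = 0.0
        if any_indel:
            ins_m, del_m = config.curve_multipliers(int(runs[i]))
            ins_rate = min(config.insertion_rate * ins_m, 0.5)
            del_rate = min(config.deletion_rate * del_m, 0.5)
        if indel_draw[i] < del_rate:
            events.append(ErrorEvent("del", i, base))
            continue
        new_base = base
        if sub_draw[i] < config.substitution_rate and base in TRANSITIONS:
            if rng.random() < p_ti:
                new_base = TRANSITIONS[base]
            else:
                new_base = TRANSVERSIONS[base][int(rng.integers(2))]
            events.append(ErrorEvent("sub", i, new_base))
        out.append(new_base)
        if indel_draw[i] >= del_rate and indel_draw[i] < del_rate + ins_rate:
            out.append(base)  # slippage copy
            events.append(ErrorEvent("ins", i, base))
    return "".join(out), events


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclass
class SimRead:
    name: str
    seq: str  # molecule-forward orientation (pre-flip for FASTQ output)
    qual: str
    mol_id: str
    slice_start: int  # fragment-slice coordinates on the molecule
    slice_end: int
    is_read2: bool
    fastq_revcomp: bool  # emit as reverse complement in FASTQ
    events: list[ErrorEvent] = field(default_factory=list)


@dataclass
class SimResult:
    reads: list[SimRead]
    config: ReadSimConfig
    seed: int
    n_fragments: int
    n_resampled: int  # fragments longer than their molecule, redrawn

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "read": r.name, "mate": 2 if r.is_read2 else 1, "sequin_id": r.mol_id,
                "mol_start": r.slice_start, "mol_end": r.slice_end,
                "strand": "-" if r.fastq_revcomp else "+",
                "n_sub": sum(e.kind == "sub" for e in r.events),
                "n_ins": sum(e.kind == "ins" for e in r.events),
                "n_del": sum(e.kind == "del" for e in r.events),
            }
            for r in self.reads
        ]
        return pd.DataFrame(rows)


def _sample_fragment_length(
    rng: np.random.Generator, config: ReadSimConfig, mol_len: int
) -> tuple[int, int]:
    """Truncated-normal fragment length within [min_len, mol_len]; returns
    (length, number of redraws)."""
    min_len = config.read_length if config.mode == "paired_short" else 50
    min_len = min(min_len, mol_len)
    redraws = 0
    for _ in range(100):
        ln = int(round(rng.normal(config.fragment_mean, config.fragment_sd)))
        if min_len <= ln <= mol_len:
            return ln, redraws
        redraws += 1
    return min(mol_len, max(min_len, int(config.fragment_mean))), redraws


def simulate_reads(
    manifest,
    molecules: dict[str, str],
    config: ReadSimConfig,
    seed: int,
    n_fragments: int | None = None,
    reference_span: int | None = None,
) -> SimResult:
    """Simulate a library from *manifest* shares over *molecules*.

    Fragment counts follow a multinomial over share x length weights.  With
    ``n_fragments`` unset, the count targets ``config.depth`` mean coverage
    over ``reference_span`` (default: total molecule span).  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    table = manifest.table
    ids = [i for i in table["sequin_id"] if i in molecules]
    if not ids:
        raise ValueError("no manifest entries match the supplied molecules")
    shares = np.array([manifest.share_of(i) for i in ids], dtype=float)
    lengths = np.array([len(molecules[i]) for i in ids], dtype=float)
    weights = shares * lengths
    if weights.sum() == 0:
        raise ValueError("manifest shares for supplied molecules are all zero")
    weights = weights / weights.sum()

    if n_fragments is None:
        span = reference_span or int(lengths.sum())
        bases_per_frag = (
            2 * config.read_length if config.mode == "paired_short"
            else min(config.fragment_mean, float(np.mean(lengths)))
        )
        n_fragments = max(0, math.ceil(config.depth * span / bases_per_frag))
    if n_fragments == 0:
        return SimResult([], config, seed, 0, 0)

    wmax = max(
        gc_bias_weight(g, config.gc_bias) for g in np.linspace(0, 1, 101)
    )
    reads: list[SimRead] = []
    n_resampled = 0
    choices = rng.choice(len(ids), size=n_fragments * 2, p=weights)
    ci = 0
    made = 0
    frag_idx = 0
    while made < n_fragments:
        if ci >= len(choices):
            choices = rng.choice(len(ids), size=n_fragments, p=weights)
            ci = 0
        mol_id = ids[choices[ci]]
        ci += 1
        mol = molecules[mol_id]
        frag_len, redraws = _sample_fragment_length(rng, config, len(mol))
        n_resampled += redraws
        start = int(rng.integers(0, len(mol) - frag_len + 1))
        frag = mol[start : start + frag_len]
        if wmax > 0:
            w = gc_bias_weight(gc_fraction(frag), config.gc_bias) / wmax
            if rng.random() >= w:
                continue  # rejected by GC bias; not counted as a fragment
        made += 1
        frag_idx += 1
        name = f"sim{frag_idx:07d}"
        if config.mode == "paired_short":
            rl = min(config.read_length, frag_len)
            for is_r2 in (False, True):
                if is_r2:
                    s0, s1 = start + frag_len - rl, start + frag_len
                else:
                    s0, s1 = start, start + rl
                raw = mol[s0:s1]
                mutated, events = inject_errors(raw, config, rng)
                reads.append(
                    SimRead(
                        name=name, seq=mutated, qual=config.quality_char * len(mutated),
                        mol_id=mol_id, slice_start=s0, slice_end=s1,
                        is_read2=is_r2, fastq_revcomp=is_r2, events=events,
                    )
                )
        else:
            mutated, events = inject_errors(frag, config, rng)
            flip = bool(rng.integers(2))
            reads.append(
                SimRead(
                    name=name, seq=mutated, qual=config.quality_char * len(mutated),
                    mol_id=mol_id, slice_start=start, slice_end=start + frag_len,
                    is_read2=False, fastq_revcomp=flip, events=events,
                )
            )
    return SimResult(reads, config, seed, n_fragments, n_resampled)


# ---------------------------------------------------------------------------
# output: FASTQ and pre-aligned SAM/BAM
# ---------------------------------------------------------------------------


def write_fastq(result: SimResult, prefix: Path) -> list[Path]:
    """Write the library as FASTQ (paired mode: ``_R1``/``_R2`` files)."""
    prefix = Path(prefix)

    def emit(read: SimRead, fh) -> None:
        seq = reverse_complement(read.seq) if read.fastq_revcomp else read.seq
        fh.write(f"@{read.name}\n{seq}\n+\n{read.qual}\n")

    if result.config.mode == "paired_short":
        p1, p2 = Path(f"{prefix}_R1.fastq"), Path(f"{prefix}_R2.fastq")
        with open(p1, "w") as f1, open(p2, "w") as f2:
            for r in result.reads:
                emit(r, f2 if r.is_read2 else f1)
        return [p1, p2]
    p = Path(f"{prefix}.fastq")
    with open(p, "w") as fh:
        for r in result.reads:
            emit(r, fh)
    return [p]


def aligned_tokens(read: SimRead) -> list[int | None]:
    """Per-output-base molecule position (None for inserted bases)."""
    tokens: list[int | None] = []
    dels = {e.mol_offset for e in read.events if e.kind == "del"}
    ins_after = {}
    for e in read.events:
        if e.kind == "ins":
            ins_after.setdefault(e.mol_offset, 0)
            ins_after[e.mol_offset] += len(e.base)
    for i in range(read.slice_start, read.slice_end):
        off = i - read.slice_start
        if off not in dels:
            tokens.append(i)
        if off in ins_after:
            tokens.extend([None] * ins_after[off])
    return tokens


def decoy_alignment_maps(bundle, decoy) -> dict[str, np.ndarray]:
    """Molecule-base -> decoy-coordinate maps for every mappable molecule.

    Placed (reference) members map by identity to their placement.  Variant
    members of colinear pairs (small variants, haplotypes, unstable
    microsatellites, DEL/INS/VIR structural variants) map through the
    designed variant alignment, reflected into mirror space.  Variant
    members of non-colinear rearrangements (INV/DUP/TRA) are unmappable as
    single linear segments and are omitted (their reads are emitted
    unmapped).
    """
    from .design.types import SVType
    from .design.variants import variant_alignment_map
    from .design.types import VariantClass, VariantRecord

    maps: dict[str, np.ndarray] = {}
    for pl in decoy.placements.values():
        maps[pl.sequin_id] = np.arange(pl.start, pl.end, dtype=np.int64)

    def add_variant_map(var_id: str, ref_id: str, template: str, variants) -> None:
        pl = decoy.placements[ref_id]
        amap = variant_alignment_map(template, variants)  # natural var -> natural ref
        Lt = len(template)
        Lv = len(amap)
        out = np.empty(Lv, dtype=np.int64)
        for i in range(Lv):
            t = amap[Lv - 1 - i]  # mirrored molecule index -> natural index
            out[i] = pl.start + (Lt - 1 - t) if t >= 0 else -1
        maps[var_id] = out

    for p in bundle.smallvar_pairs:
        add_variant_map(p.var.id, p.ref.id, p.template, p.variants)
    for h in bundle.haplotypes:
        recs = [
            VariantRecord(sequin_id=h.maternal.id, pos=pos + 1, ref=am, alt=ap,
                          vclass=VariantClass.SNV)
            for pos, am, ap in h.pair.het_sites
        ]
        add_variant_map(h.paternal.id, h.maternal.id, h.pair.maternal_seq, recs)
    for m in bundle.microsatellites:
        if m.var is None:
            continue
        d = m.design
        shift = (m.variant_copies - d.copies) * len(d.motif)
        if shift >= 0:
            continue  # expansions would need an insertion record; panel uses contractions
        s, e = d.tract_interval
        rec = VariantRecord(sequin_id=m.ref.id, pos=e + shift + 1,
                            ref=d.natural_seq[e + shift : e], alt="",
                            vclass=VariantClass.DEL)
        add_variant_map(m.var.id, m.ref.id, d.natural_seq, rec and [rec])
    for build in bundle.svs:
        d = build.design
        if d.svtype is SVType.DEL:
            b1, b2 = d.breakpoints
            ctx = build.refs[0].natural_seq
            rec = VariantRecord(sequin_id=build.refs[0].id, pos=b1 + 1,
                                ref=ctx[b1:b2], alt="", vclass=VariantClass.DEL)
            add_variant_map(build.variants[0].id, build.refs[0].id, ctx, [rec])
        elif d.svtype in (SVType.INS, SVType.VIR):
            b1 = d.breakpoints[0]
            ctx = build.refs[0].natural_seq
            rec = VariantRecord(sequin_id=build.refs[0].id, pos=b1 + 1,
                                ref="", alt=d.payload, vclass=VariantClass.INS)
            add_variant_map(build.variants[0].id, build.refs[0].id, ctx, [rec])
    return maps


def _cigar_and_pos(tokens: list[int | None], decoy_map: np.ndarray) -> tuple[int, list[tuple[int, int]]] | None:
    """Build (POS, cigartuples) from aligned tokens; None if unmappable."""
    ref_pos: list[int | None] = []
    for t in tokens:
        if t is None:
            ref_pos.append(None)
        else:
            r = int(decoy_map[t])
            ref_pos.append(r if r >= 0 else None)
    mapped = [r for r in ref_pos if r is not None]
    if not mapped:
        return None
    if any(b <= a for a, b in zip(mapped, mapped[1:])):
        return None  # non-colinear
    cig: list[tuple[int, int]] = []

    def push(op: int, n: int = 1) -> None:
        if cig and cig[-1][0] == op:
            cig[-1] = (op, cig[-1][1] + n)
        else:
            cig.append((op, n))

    # leading unmapped bases are soft-clipped
    i = 0
    while i < len(ref_pos) and ref_pos[i] is None:
        push(4)
        i += 1
    pos = ref_pos[i]
    prev = None
    for r in ref_pos[i:]:
        if r is None:
            push(1)
        else:
            if prev is not None and r > prev + 1:
                push(2, r - prev - 1)
            push(0)
            prev = r
    # trailing insertions become soft-clips
    if cig and cig[-1][0] == 1:
        cig[-1] = (4, cig[-1][1])
    return pos, cig


def write_alignments(
    result: SimResult,
    decoy_maps: dict[str, np.ndarray],
    decoy_name: str,
    decoy_length: int,
    path: Path,
    sort_and_index: bool = True,
) -> Path:
    """Emit the simulated library as alignments against the decoy.

    Reads whose molecule has no colinear decoy map (or that cross a
    non-colinear junction) are written unmapped.  Returns the path of the
    coordinate-sorted, indexed BAM (or the plain SAM if not sorting).
    """
    path = Path(path)
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": decoy_name, "LN": decoy_length}]}
    tmp = path.with_suffix(".unsorted.bam") if sort_and_index else path
    mode = "wb" if str(tmp).endswith(".bam") else "w"
    pairs: dict[str, list[SimRead]] = {}
    for r in result.reads:
        pairs.setdefault(r.name, []).append(r)
    with pysam.AlignmentFile(str(tmp), mode, header=header) as out:
        for name, group in pairs.items():
            placed = []
            for r in group:
                dm = decoy_maps.get(r.mol_id)
                pc = _cigar_and_pos(aligned_tokens(r), dm) if dm is not None else None
                placed.append(pc)
            for r, pc in zip(group, placed):
                a = pysam.AlignedSegment()
                a.query_name = name
                a.query_sequence = r.seq
                a.query_qualities = pysam.qualitystring_to_array(r.qual)
                flag = 0
                paired = result.config.mode == "paired_short"
                if paired:
                    flag |= 0x1
                    flag |= 0x80 if r.is_read2 else 0x40
                    if r.fastq_revcomp:
                        flag |= 0x10
                    else:
                        flag |= 0x20  # mate on the reverse strand
                if pc is None:
                    flag |= 0x4
                    a.flag = flag
                    out.write(a)
                    continue
                pos, cig = pc
                a.reference_id = 0
                a.reference_start = pos
                a.cigartuples = cig
                a.mapping_quality = 60
                mate = next((q for q, qc in zip(group, placed) if q is not r), None)
                mate_pc = next((qc for q, qc in zip(group, placed) if q is not r), None)
                if paired and mate is not None and mate_pc is not None:
                    a.next_reference_id = 0
                    a.next_reference_start = mate_pc[0]
                    flag |= 0x2
                a.flag = flag
                out.write(a)
    if not sort_and_index:
        return path
    sorted_path = path if str(path).endswith(".bam") else path.with_suffix(".bam")
    pysam.sort("-o", str(sorted_path), str(tmp))
    pysam.index(str(sorted_path))
    Path(tmp).unlink(missing_ok=True)
    return sorted_path


def profile_config(name: str, **overrides) -> ReadSimConfig:
    """A copy of a named profile with field overrides applied."""
    base = PROFILES[name]
    return replace(base, **overrides)
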