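"""Primitive DNA-string operations shared across the toolkit.

The central transform is *mirroring*: character-by-character reversal of a
DNA string **without** complementation.  Because DNA has 5'-3' directionality,
a mirrored sequence is distinct from both strands of the natural sequence, so
reads derived from mirrored controls can be partitioned unambiguously from
reads derived from the natural genome.
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: transition partner for each base (A<->G, C<->T)
TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: the two transversion partners for each base
TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


def validate_dna(seq: str, allow_n: bool = True) -> None:
    """Raise ``ValueError`` naming the first offending position if *seq*
    contains a character outside the DNA alphabet (optionally excluding N)."""
    alphabet = DNA_ALPHABET if allow_n else DNA_ALPHABET - {"N"}
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(f"non-DNA character {ch!r} at position {i}")


def mirror_sequence(seq: str) -> str:
    """Reverse *seq* character by character without complementing.

    This is the design transform for synthetic controls: the mirrored
    sequence has the same base composition as the natural template but is
    distinct from both the template and its reverse complement (except for
    palindromic-by-reversal edge cases).  The transform is an involution.
    """
    if not seq:
        raise ValueError("cannot mirror an empty sequence")
    validate_dna(seq)
    return seq[::-1]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC fraction of *seq*; N bases count toward length."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Draw a random sequence of *length* nt with expected GC content *gc*
    from an i.i.d. nucleotide model."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.array(list("ACGT")), size=length, p=p)
    return "".join(bases)


def homopolymer_run_lengths(seq: str) -> np.ndarray:
    """For every position, the length of the maximal single-base run that
    contains it.  Used by the error model to scale indel rates in repeats."""
    n = len(seq)
    out = np.empty(n, dtype=np.int64)
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        out[i:j] = j - i
        i = j
    return out
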