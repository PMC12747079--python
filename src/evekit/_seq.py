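"""Low-level DNA sequence helpers shared across modules.

Sequences are plain uppercase strings over A/C/G/T/N. Coordinates are
0-based half-open throughout the library; conversion to 1-based closed
happens only at the GFF3 boundary.
"""
from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    """I.i.d. random DNA with P(G)+P(C) = ``gc``.

    Per-base independent composition; no higher-order structure.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0,1), got {gc}")
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]  # A, C, G, T
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def gc_fraction(seq: str) -> float:
    """GC fraction with N excluded from the denominator.

    Returns nan for sequences with no unambiguous bases.
    """
    a = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    gc = int(np.count_nonzero((a == ord("G")) | (a == ord("C"))))
    n = int(np.count_nonzero(a == ord("N")))
    denom = len(seq) - n
    return gc / denom if denom > 0 else float("nan")


def check_dna(seq: str, allow_n: bool = True) -> None:
    """Raise ValueError on characters outside the DNA alphabet."""
    allowed = set("ACGT" + ("N" if allow_n else ""))
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
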