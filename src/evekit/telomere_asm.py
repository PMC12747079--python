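"""Telomere-based chromosome accounting and assembly statistics.

A contig carrying tandem telomeric motif runs at both ends is interpreted
as a complete, telomere-to-telomere chromosome. Contigs with one telomere
pair up at best, so ``n_both + ceil(n_one / 2)`` is a lower bound on the
chromosome number of the organism.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._seq import check_dna, gc_fraction, revcomp


@dataclass
class TelomereCall:
    contig_id: str
    left_end: str       # telomere | none
    right_end: str
    left_copies: int
    right_copies: int
    status: str         # both | one | none


@dataclass
class AsmStats:
    n_contigs: int
    total_bp: int
    gc: float
    min_len: int
    max_len: int
    mean_len: float
    n50: int


def _count_tandem_copies(window: str, motif: str) -> int:
    """Longest tandem motif run starting at position 0 of ``window``.

    Copy counting tolerates 1 mismatched base per 3 copies (cumulative);
    a copy with more than one mismatch terminates the run.
    """
    m = len(motif)
    copies = 0
    mismatches = 0
    pos = 0
    while pos + m <= len(window):
        mm = sum(a != b for a, b in zip(window[pos : pos + m], motif))
        if mm > 1 or mismatches + mm > (copies + 1) / 3:
            break
        mismatches += mm
        copies += 1
        pos += m
    return copies


def _scan_one_end(end_seq: str, motif: str, max_offset: int, min_copies: int) -> int:
    """Best tandem copy count over run starts within ``max_offset`` of the
    terminus, testing the motif and its reverse complement."""
    best = 0
    for mot in (motif, revcomp(motif)):
        for start in range(0, min(max_offset, len(end_seq)) + 1):
            c = _count_tandem_copies(end_seq[start:], mot)
            if c > best:
                best = c
    return best


def scan_telomeres(
    contig: tuple[str, str] | str,
    motif: str,
    terminal_window: int = 2000,
    min_copies: int = 6,
    max_offset: int = 100,
) -> TelomereCall:
    """Classify one contig's ends by telomeric repeat content.

    An end is called when a tandem run of at least ``min_copies`` motif
    copies (either orientation) starts within ``max_offset`` bp of the
    terminus. The defaults operationalise a "high-quality" telomere as >= 6
    tandem copies within 100 bp of the terminus; relax ``min_copies``/
    ``max_offset`` (e.g. 4 copies within 1 kb) for a "recognizable" call.
    """
    cid, seq = contig if isinstance(contig, tuple) else ("contig", contig)
    motif = motif.upper()
    check_dna(motif, allow_n=False)
    if not 4 <= len(motif) <= 10:
        raise ValueError("motif must be 4-10 bp")
    if len(seq) < 2 * terminal_window:
        raise ValueError("contig shorter than twice the terminal window")
    seq = seq.upper()
    left_copies = _scan_one_end(seq[:terminal_window], motif, max_offset, min_copies)
    right_copies = _scan_one_end(
        revcomp(seq[-terminal_window:]), motif, max_offset, min_copies
    )
    left = "telomere" if left_copies >= min_copies else "none"
    right = "telomere" if right_copies >= min_copies else "none"
    n = (left == "telomere") + (right == "telomere")
    status = {2: "both", 1: "one", 0: "none"}[n]
    return TelomereCall(cid, left, right, left_copies, right_copies, status)


def min_chromosomes(n_both: int, n_one: int) -> int:
    """Lower bound on chromosome number from telomere-contig counts.

    Each chromosome has two telomeres: every both-end contig is a complete
    chromosome, and one-end contigs pair up at best, so the bound is
    ``n_both + ceil(n_one / 2)``.
    """
    if n_both < 0 or n_one < 0:
        raise ValueError("counts must be non-negative")
    return n_both + math.ceil(n_one / 2)


def asm_stats(genome: dict[str, str]) -> AsmStats:
    """Assembly summary statistics.

    N50 is the standard definition: sort contigs descending; N50 is the
    length at which the running sum first reaches half the total. GC
    excludes N bases from the denominator.
    """
    if not genome:
        raise ValueError("empty assembly")
    lengths = np.array([len(s) for s in genome.values()], dtype=int)
    total = int(lengths.sum())
    desc = np.sort(lengths)[::-1]
    csum = np.cumsum(desc)
    n50 = int(desc[np.searchsorted(csum, total / 2)])
    return AsmStats(
        n_contigs=len(lengths),
        total_bp=total,
        gc=gc_fraction("".join(genome.values())),
        min_len=int(lengths.min()),
        max_len=int(lengths.max()),
        mean_len=float(lengths.mean()),
        n50=n50,
    )
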