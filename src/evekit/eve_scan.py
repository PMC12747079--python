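"""Detection and classification of endogenous polinton-like viral elements.

The detection strategy mirrors how endogenous PLVs are found in practice:
candidate loci are regions of depressed GC content relative to the host
baseline, required to contain at least one hallmark-gene anchor (major
capsid protein or integrase evidence — anchor evidence is mandatory);
element boundaries are refined to terminal inverted/direct repeat (TIR/TDR)
coordinates found by seed-and-extend comparison of the candidate's ends,
and the 20-bp flanks are checked for a target-site duplication (TSD).
Elements are classified by the co-occurrence of repeat kind and integrase
type: TIR + retroviral-type integrase (rve-INT) is the canonical
polinton-like configuration; TDR + tyrosine recombinase (YREC) marks the
distinct YREC/TDR integration strategy, which typically leaves no TSD.
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np

from ._seq import check_dna, gc_fraction, revcomp

_TRANSLATE_TABLES = None  # lazily imported Biopython machinery


@dataclass
class GCTrack:
    contig_id: str
    window: int
    step: int
    values: np.ndarray          # GC fraction per window; nan = too ambiguous
    n_excluded: np.ndarray      # ambiguous (N) bases per window


@dataclass
class TerminalRepeat:
    kind: str                   # TIR | TDR
    length: int
    identity: float
    left_span: tuple[int, int]
    right_span: tuple[int, int]


@dataclass
class TSD:
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class EVECall:
    contig_id: str
    start: int
    end: int
    gc: float
    repeat: TerminalRepeat | None
    tsd: TSD | None
    anchors: list[tuple[str, int, int]]   # (name, frame, offset)
    integrase: str                        # rve-INT | YREC | rve-other | none
    class_label: str = "unclassified"
    warnings: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ScanParams:
    """Tunable knobs of the scanner; defaults bracket reported PLV features."""

    window: int = 1000
    step: int = 200
    min_delta: float = 8.0        # percentage points below host baseline
    min_len: int = 5_000
    max_len: int = 60_000
    repeat_min_len: int = 100
    repeat_max_len: int = 150_000
    max_mismatch_frac: float = 0.05
    search_margin: int = 2_000    # 150 kb for giant-virus-scale TIRs
    tsd_kmin: int = 4
    tsd_kmax: int = 8


# ---------------------------------------------------------------------------
# GC landscape
# ---------------------------------------------------------------------------

def gc_track(seq: str, window: int, step: int, contig_id: str = "") -> GCTrack:
    """Sliding-window GC fractions.

    N bases are excluded from each window's denominator; windows with more
    than 50% ambiguous bases yield nan.
    """
    if not seq:
        raise ValueError("empty sequence")
    if not window >= step >= 1:
        raise ValueError("need window >= step >= 1")
    if len(seq) < window:
        raise ValueError("sequence shorter than window")
    a = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    gc_cum = np.concatenate([[0], np.cumsum((a == ord("G")) | (a == ord("C")))])
    n_cum = np.concatenate([[0], np.cumsum(a == ord("N"))])
    starts = np.arange(0, len(seq) - window + 1, step)
    gc = gc_cum[starts + window] - gc_cum[starts]
    nn = n_cum[starts + window] - n_cum[starts]
    denom = window - nn
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(nn > window // 2, np.nan, gc / np.where(denom > 0, denom, 1))
    vals = np.where(denom == 0, np.nan, vals)
    return GCTrack(contig_id, window, step, vals.astype(float), nn.astype(int))


def segment_low_gc(
    track: GCTrack,
    baseline: float,
    min_delta: float,
    min_len: int,
    max_len: int,
) -> list[tuple[int, int]]:
    """Maximal low-GC runs as base intervals, length-filtered.

    Windows at or below ``baseline - min_delta/100`` are "low"; runs are
    merged across gaps of at most one window, converted to base coordinates
    (run of windows i..j -> [i*step, j*step + window)), and filtered to
    [min_len, max_len].
    """
    if not 0.0 < baseline < 1.0:
        raise ValueError("baseline must be in (0,1)")
    thresh = baseline - min_delta / 100.0
    low = np.where(np.isnan(track.values), False, track.values <= thresh)
    runs: list[list[int]] = []
    for i in np.flatnonzero(low):
        if runs and i - runs[-1][1] <= 2:   # gap of <= 1 window
            runs[-1][1] = i
        else:
            runs.append([int(i), int(i)])
    out = []
    for i, j in runs:
        s, e = i * track.step, j * track.step + track.window
        if min_len <= e - s <= max_len:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# Terminal repeats
# ---------------------------------------------------------------------------

def _best_diagonal_match(
    left: str, right: str, max_mm_frac: float, k: int = 12
) -> tuple[int, int, int, int] | None:
    """Longest seeded ungapped match between two strings.

    Returns (i, j, length, mismatches) with left[i:i+L] ~ right[j:j+L], or
    None. Seeds are exact shared k-mers; each seeded diagonal is scanned with
    a sliding window keeping mismatches <= max_mm_frac * window length
    (greedy; exact when max_mm_frac = 0). N never matches anything.
    """
    if len(left) < k or len(right) < k:
        return None
    la = np.frombuffer(left.encode("ascii"), dtype=np.uint8)
    ra = np.frombuffer(right.encode("ascii"), dtype=np.uint8)
    seeds: dict[str, list[int]] = {}
    for i in range(len(left) - k + 1):
        kmer = left[i : i + k]
        if "N" not in kmer:
            seeds.setdefault(kmer, []).append(i)
    diagonals: set[int] = set()
    for j in range(len(right) - k + 1):
        for i in seeds.get(right[j : j + k], ()):
            diagonals.add(j - i)
    best = None
    n_mask = (la == ord("N"))
    for d in diagonals:
        i0, j0 = (0, d) if d >= 0 else (-d, 0)
        n = min(len(left) - i0, len(right) - j0)
        match = (la[i0 : i0 + n] == ra[j0 : j0 + n]) & ~n_mask[i0 : i0 + n] \
            & (ra[j0 : j0 + n] != ord("N"))
        mism = ~match
        lo = 0
        mm = 0
        for hi in range(n):
            mm += int(mism[hi])
            while mm > max_mm_frac * (hi - lo + 1):
                mm -= int(mism[lo])
                lo += 1
            length = hi - lo + 1
            if best is None or length > best[2]:
                best = (i0 + lo, j0 + lo, length, mm)
    return best


def find_terminal_repeats(
    seq: str,
    min_len: int = 100,
    max_len: int = 150_000,
    max_mismatch_frac: float = 0.05,
    search_margin: int = 2_000,
) -> TerminalRepeat | None:
    """Find the longest terminal repeat of an element sequence.

    Compares the first ``search_margin`` bp against the last ``search_margin``
    bp in direct orientation (TDR) and against their reverse complement
    (TIR). Returns the longest repeat whose mismatch fraction is within
    ``max_mismatch_frac``; a TIR is preferred over a TDR on an exact length
    tie; None when nothing reaches ``min_len``.
    """
    if min_len > search_margin:
        raise ValueError("min_len exceeds search_margin")
    if len(seq) <= 2 * min_len:
        raise ValueError("sequence too short for terminal repeat search")
    m = min(search_margin, len(seq) // 2)
    left = seq[:m].upper()
    right = seq[-m:].upper()
    L = len(seq)

    results = []
    hit = _best_diagonal_match(left, revcomp(right), max_mismatch_frac)
    if hit:
        i, j, length, mm = hit
        # position j in revcomp(right) maps to right[m-j-length : m-j]
        results.append(
            ("TIR", length, mm, (i, i + length), (L - j - length, L - j))
        )
    hit = _best_diagonal_match(left, right, max_mismatch_frac)
    if hit:
        i, j, length, mm = hit
        results.append(
            ("TDR", length, mm, (i, i + length), (L - m + j, L - m + j + length))
        )
    results = [
        r for r in results
        if min_len <= r[1] <= max_len and r[3][1] <= r[4][0]
    ]
    if not results:
        return None
    # longest wins; TIR preferred on exact tie
    results.sort(key=lambda r: (-r[1], 0 if r[0] == "TIR" else 1))
    kind, length, mm, lspan, rspan = results[0]
    return TerminalRepeat(kind, length, 1.0 - mm / length, lspan, rspan)


# ---------------------------------------------------------------------------
# Target-site duplications
# ---------------------------------------------------------------------------

def find_tsd(
    left_flank: str, right_flank: str, k_min: int = 4, k_max: int = 8
) -> TSD | None:
    """Longest exact TSD between the element-adjacent flank positions.

    Tests k in [k_min, k_max]: the k-mer ending at the last position of the
    left flank against the k-mer starting the right flank. Exact match only;
    N inside a compared k-mer disqualifies that k.
    """
    left = left_flank.upper()
    right = right_flank.upper()
    check_dna(left)
    check_dna(right)
    for k in range(min(k_max, len(left), len(right)), k_min - 1, -1):
        a, b = left[-k:], right[:k]
        if "N" not in a and a == b:
            return TSD(a)
    return None


# ---------------------------------------------------------------------------
# Anchors
# ---------------------------------------------------------------------------

def six_frame_anchor_scan(
    seq: str, motifs: list[tuple[str, str]]
) -> list[tuple[str, int, int]]:
    """Locate exact peptide motifs in all six reading frames.

    Returns (name, frame, nucleotide offset); frames 0-2 forward, 3-5 on the
    reverse complement.
    """
    from Bio.Seq import Seq

    hits = []
    for strand, s in enumerate((seq, revcomp(seq))):
        for frame in range(3):
            sub = s[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate())
            for name, pep in motifs:
                pos = aa.find(pep.upper())
                while pos != -1:
                    nt = frame + 3 * pos
                    if strand:
                        nt = len(seq) - nt - 3 * len(pep)
                    hits.append((name, 3 * strand + frame, nt))
                    pos = aa.find(pep.upper(), pos + 1)
    return hits


def _anchors_in_interval(
    contig_id: str,
    seq_slice: str,
    slice_start: int,
    anchors: list[dict] | list[tuple[str, str]],
) -> list[tuple[str, int, int]]:
    """Anchors overlapping [slice_start, slice_start+len) on a contig.

    ``anchors`` is either GFF3-derived feature dicts (interval evidence) or
    peptide motifs to be located by six-frame scan of the slice itself.
    """
    if anchors and isinstance(anchors[0], dict):
        out = []
        for f in anchors:
            if f["seqid"] != contig_id:
                continue
            if f["start"] < slice_start + len(seq_slice) and f["end"] > slice_start:
                name = f.get("attributes", {}).get("Name", f.get("type", "anchor"))
                out.append((name, -1, f["start"] - slice_start))
        return out
    return six_frame_anchor_scan(seq_slice, list(anchors))


# ---------------------------------------------------------------------------
# Calling and classification
# ---------------------------------------------------------------------------

def _genome_baseline_gc(genome: dict[str, str], exclude: dict[str, list[tuple[int, int]]]) -> float:
    gc = tot = 0
    for cid, seq in genome.items():
        mask = np.zeros(len(seq), dtype=bool)
        for s, e in exclude.get(cid, ()):
            mask[s:e] = True
        a = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        keep = ~mask & (a != ord("N"))
        gc += int(np.count_nonzero(((a == ord("G")) | (a == ord("C"))) & keep))
        tot += int(np.count_nonzero(keep))
    return gc / tot if tot else float("nan")


def call_eves(
    genome: dict[str, str],
    anchors: list[dict] | list[tuple[str, str]],
    params: ScanParams | None = None,
) -> list[EVECall]:
    """Call endogenous viral elements across a genome.

    Pipeline per contig: GC track -> low-GC candidate segments against a
    host baseline (estimated genome-wide, then re-estimated once with
    candidate intervals excluded) -> anchor requirement -> boundary
    refinement to terminal-repeat coordinates when found (element = the
    outermost repeat positions), else the GC-segment ends -> TSD on the
    refined 20-bp flanks -> GC recomputed over the final span.

    ``anchors`` is mandatory: either GFF3-derived hallmark-gene features or
    a list of (name, peptide) motifs for six-frame exact search.
    """
    if not anchors:
        raise ValueError(
            "anchor evidence is mandatory: supply hallmark-gene annotations "
            "(GFF3 features) or peptide motifs"
        )
    p = params or ScanParams()

    tracks = {
        cid: gc_track(seq, p.window, p.step, cid)
        for cid, seq in genome.items()
        if len(seq) >= p.window
    }
    baseline = _genome_baseline_gc(genome, {})
    candidates = {
        cid: segment_low_gc(tr, baseline, p.min_delta, p.min_len, p.max_len)
        for cid, tr in tracks.items()
    }
    # one refinement: low-GC elements bias a naive genome-wide baseline
    baseline = _genome_baseline_gc(genome, candidates)
    candidates = {
        cid: segment_low_gc(tr, baseline, p.min_delta, p.min_len, p.max_len)
        for cid, tr in tracks.items()
    }

    calls: list[EVECall] = []
    pad = p.window
    for cid, intervals in candidates.items():
        seq = genome[cid]
        for cs, ce in intervals:
            lo = max(0, cs - pad)
            hi = min(len(seq), ce + pad)
            sub = seq[lo:hi]
            found = _anchors_in_interval(cid, sub, lo, anchors)
            if not found:
                continue
            repeat = None
            if len(sub) > 2 * p.repeat_min_len:
                # margin covers the configured search depth plus the boundary
                # slop of GC segmentation (up to ~pad + window on each side),
                # so a repeat near the true boundary is never truncated
                margin = p.search_margin + pad + p.window
                repeat = find_terminal_repeats(
                    sub, p.repeat_min_len, p.repeat_max_len,
                    p.max_mismatch_frac, margin,
                )
            if repeat is not None:
                start = lo + repeat.left_span[0]
                end = lo + repeat.right_span[1]
                repeat = TerminalRepeat(
                    repeat.kind, repeat.length, repeat.identity,
                    (lo + repeat.left_span[0], lo + repeat.left_span[1]),
                    (lo + repeat.right_span[0], lo + repeat.right_span[1]),
                )
            else:
                start, end = cs, ce
            left_flank = seq[max(0, start - 20) : start]
            right_flank = seq[end : end + 20]
            tsd = find_tsd(left_flank, right_flank, p.tsd_kmin, p.tsd_kmax)
            integrase = "none"
            for name, _f, _o in found:
                low = name.lower()
                if "yrec" in low:
                    integrase = "YREC"
                elif "rve-int" in low or "rve_int" in low:
                    integrase = "rve-INT"
                elif "rve" in low and integrase == "none":
                    integrase = "rve-other"
            call = EVECall(
                contig_id=cid,
                start=start,
                end=end,
                gc=gc_fraction(seq[start:end]),
                repeat=repeat,
                tsd=tsd,
                anchors=found,
                integrase=integrase,
            )
            call.class_label = classify_eve(call)
            calls.append(call)
    calls.sort(key=lambda c: (c.contig_id, c.start))
    return calls


def classify_eve(call: EVECall, gene_annotations: dict | None = None) -> str:
    """Classify an element by repeat kind and integrase type.

    TDR + YREC -> ``yrec-TDR-type`` (tyrosine-recombinase integration via a
    circular intermediate, which typically leaves no TSD — a warning is
    attached if a TSD is nonetheless present); TIR + rve-INT ->
    ``canonical-polinton-like``; anything else ``unclassified``.
    ``gene_annotations`` may override the integrase type per element.
    """
    integrase = call.integrase
    if gene_annotations:
        key = (call.contig_id, call.start, call.end)
        integrase = gene_annotations.get(key, integrase)
    kind = call.repeat.kind if call.repeat else None
    if kind == "TDR" and integrase == "YREC":
        if call.tsd is not None:
            call.warnings.append(
                "TSD co-occurs with a TDR/YREC element; YREC integration "
                "typically does not generate TSDs"
            )
        return "yrec-TDR-type"
    if kind == "TIR" and integrase == "rve-INT":
        return "canonical-polinton-like"
    return "unclassified"


def _median_low(values: list[float]) -> float | None:
    return statistics.median_low(sorted(values)) if values else None


def summarize_eves(calls: list[EVECall]) -> dict:
    """Cohort summary: n, lower-median length, mean GC, median TIR/TDR
    lengths, per-class counts. Empty input gives n=0 and missing medians."""
    tir = [c.repeat.length for c in calls if c.repeat and c.repeat.kind == "TIR"]
    tdr = [c.repeat.length for c in calls if c.repeat and c.repeat.kind == "TDR"]
    classes: dict[str, int] = {}
    for c in calls:
        classes[c.class_label] = classes.get(c.class_label, 0) + 1
    return {
        "n": len(calls),
        "median_length": _median_low([c.length for c in calls]),
        "mean_gc": float(np.mean([c.gc for c in calls])) if calls else None,
        "median_tir_len": _median_low(tir),
        "n_tir": len(tir),
        "median_tdr_len": _median_low(tdr),
        "n_tdr": len(tdr),
        "class_counts": classes,
    }


def calls_to_gff3_features(calls: list[EVECall]) -> list[dict]:
    """GFF3 feature dicts for a call set: one parent feature per element
    with child features for its repeat arms, TSD and anchors."""
    feats = []
    for i, c in enumerate(calls):
        eid = f"EVE_{i + 1}"
        attrs = {"ID": eid, "class": c.class_label, "gc": f"{c.gc:.4f}",
                 "integrase": c.integrase}
        if c.warnings:
            attrs["note"] = "; ".join(c.warnings)
        feats.append({"seqid": c.contig_id, "type": "mobile_genetic_element",
                      "start": c.start, "end": c.end, "strand": "+",
                      "attributes": attrs})
        if c.repeat:
            for span, side in ((c.repeat.left_span, "left"), (c.repeat.right_span, "right")):
                feats.append({
                    "seqid": c.contig_id, "type": "repeat_region",
                    "start": span[0], "end": span[1], "strand": "+",
                    "attributes": {"ID": f"{eid}_{c.repeat.kind}_{side}",
                                   "Parent": eid, "repeat_kind": c.repeat.kind},
                })
        if c.tsd:
            feats.append({
                "seqid": c.contig_id, "type": "target_site_duplication",
                "start": max(0, c.start - c.tsd.length), "end": c.start,
                "strand": "+",
                "attributes": {"ID": f"{eid}_TSD", "Parent": eid,
                               "sequence": c.tsd.sequence},
            })
        for j, (name, frame, offset) in enumerate(c.anchors):
            feats.append({
                "seqid": c.contig_id, "type": "protein_match",
                "start": c.start, "end": c.end, "strand": "+",
                "attributes": {"ID": f"{eid}_anchor_{j}", "Parent": eid,
                               "Name": name, "frame": frame},
            })
    return feats
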