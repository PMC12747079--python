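"""Ground-truth-labelled synthetic data generators.

Every generator is deterministic given its seed and returns (or updates) a
:class:`TruthSet` so that downstream detectors can be scored against known
answers without any external download. The defaults emulate the study
system: a ~52% GC nuclear genome of a heterotrophic cryptomonad carrying
telomeric tracts at contig ends, implanted low-GC (~35%) polinton-like
viral elements (PLVs) of 14-40 kb flanked by terminal inverted or direct
repeats with 5-6 bp target-site duplications, giant-virus-like references
with a contiguous uncovered "metagenomic island", CARD-FISH survey tables,
and flagellate growth curves with lag, exponential growth, and collapse.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import check_dna, gc_fraction, random_seq, revcomp

# Fixed codon per amino acid for embedding anchor peptides as exact ORFs.
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

TELOMERE_TRACT_COPIES = 12  # tandem motif copies written at a flagged end


@dataclass
class ElementSpec:
    """Descriptor of one endogenous viral element to implant.

    Defaults follow the PLV profile reported for *Tyrannomonas regina*:
    ~20 kb elements at 35% GC flanked by ~488 bp TIRs with 5-bp TSDs.
    """

    length: int = 20290
    gc: float = 0.35
    repeat_kind: str = "TIR"          # TIR | TDR | none
    repeat_len: int = 488
    tsd_len: int = 5                  # 0 = no target-site duplication
    anchor_peptides: list[tuple[str, str]] = field(
        default_factory=lambda: [("MCP", "MAVHKELTRFGWDQN"), ("rve-INT", "MKDLRHEWAVYSTQG")]
    )

    def __post_init__(self) -> None:
        if self.repeat_kind not in ("TIR", "TDR", "none"):
            raise ValueError(f"repeat_kind must be TIR/TDR/none, got {self.repeat_kind!r}")
        if self.repeat_kind != "none" and 2 * self.repeat_len >= self.length:
            raise ValueError("2*repeat_len must be < length")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0,1]")
        if self.tsd_len != 0 and not 4 <= self.tsd_len <= 8:
            raise ValueError("tsd_len must be 0 or in 4..8")


@dataclass
class EveTruth:
    """Ground truth for one implanted element (final coordinates)."""

    contig_id: str
    start: int
    end: int
    gc: float
    repeat_kind: str
    repeat_len: int
    tsd: str
    anchors: list[str]
    integrase: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    """Everything a scorer needs about a generated dataset."""

    eves: list[EveTruth] = field(default_factory=list)
    telomeres: list[dict] = field(default_factory=list)   # {contig_id, status}
    islands: list[tuple[str, int, int]] = field(default_factory=list)
    growth_params: dict | None = None

    def to_dict(self) -> dict:
        return {
            "eves": [dataclasses.asdict(e) for e in self.eves],
            "telomeres": list(self.telomeres),
            "islands": [list(i) for i in self.islands],
            "growth_params": self.growth_params,
        }


# ---------------------------------------------------------------------------
# Host genome with telomeres
# ---------------------------------------------------------------------------

def gen_host_genome(
    n_contigs: int,
    length_range: tuple[int, int],
    gc: float,
    telomere_motif: str,
    end_plan: Sequence[str],
    seed: int,
    tract_copies: int = TELOMERE_TRACT_COPIES,
) -> tuple[dict[str, str], TruthSet]:
    """Generate a multi-contig host genome with planned telomeric ends.

    ``end_plan`` gives one of ``both``/``one``/``none`` per contig; flagged
    ends receive ``tract_copies`` tandem copies of the motif starting at the
    terminus (motif on the left end, its reverse complement on the right end,
    following chromosome-strand convention). ``one`` places a left telomere.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    motif = telomere_motif.upper()
    check_dna(motif, allow_n=False)
    if not 4 <= len(motif) <= 10:
        raise ValueError("telomere motif must be 4-10 bp")
    if len(end_plan) != n_contigs:
        raise ValueError("end_plan length must equal n_contigs")
    bad = set(end_plan) - {"both", "one", "none"}
    if bad:
        raise ValueError(f"invalid end_plan labels: {sorted(bad)}")
    tract_len = tract_copies * len(motif)
    if length_range[0] < 2 * tract_len:
        raise ValueError("length_range minimum is below twice the telomere tract length")

    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    truth = TruthSet()
    tract = motif * tract_copies
    for i, status in enumerate(end_plan):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = random_seq(length, gc, rng)
        if status in ("both", "one"):
            seq = tract + seq[tract_len:]
        if status == "both":
            seq = seq[:-tract_len] + revcomp(tract)
        cid = f"contig_{i + 1}"
        genome[cid] = seq
        truth.telomeres.append({"contig_id": cid, "status": status})
    return genome, truth


# ---------------------------------------------------------------------------
# Element implantation
# ---------------------------------------------------------------------------

def _element_sequence(spec: ElementSpec, rng: np.random.Generator) -> tuple[str, list[str]]:
    """Build the element: terminal repeats, anchor ORFs, random core."""
    rlen = spec.repeat_len if spec.repeat_kind != "none" else 0
    left = random_seq(rlen, spec.gc, rng) if rlen else ""
    if spec.repeat_kind == "TIR":
        right = revcomp(left)
    elif spec.repeat_kind == "TDR":
        right = left
    else:
        right = ""
    core_len = spec.length - len(left) - len(right)
    core = list(random_seq(core_len, spec.gc, rng))

    # Embed each anchor peptide as an exact forward-strand ORF in the core,
    # spaced so ORFs never overlap each other or the repeats.
    offset = min(500, max(0, core_len // 10))
    names = []
    for name, peptide in spec.anchor_peptides:
        orf = "ATG" + "".join(_CODON[aa] for aa in peptide.upper()) + "TAA"
        if offset + len(orf) > core_len:
            raise ValueError("element too short for its anchor ORFs")
        core[offset : offset + len(orf)] = orf
        offset += len(orf) + 120
        names.append(name)
    return left + "".join(core) + right, names


def implant_eve(
    genome: dict[str, str],
    contig_id: str,
    pos: int,
    spec: ElementSpec,
    seed: int,
    truth: TruthSet | None = None,
) -> tuple[dict[str, str], EveTruth]:
    """Insert one element at ``pos`` (0-based, coordinates of the current
    genome), duplicating the ``tsd_len`` bases left of the insertion point
    to the right of the element.

    Host bases outside the insertion are unchanged; total contig length grows
    by exactly ``spec.length + spec.tsd_len``. Rejects positions closer than
    1 kb to a contig end or overlapping a previously implanted element.
    """
    if contig_id not in genome:
        raise KeyError(contig_id)
    host = genome[contig_id]
    if not 1000 <= pos <= len(host) - 1000:
        raise ValueError(f"pos {pos} closer than 1 kb to a contig end")
    if truth is not None:
        for e in truth.eves:
            if e.contig_id == contig_id and e.start - spec.tsd_len <= pos < e.end + 20:
                raise ValueError("insertion overlaps a previously implanted element")

    rng = np.random.default_rng(seed)
    element, anchor_names = _element_sequence(spec, rng)
    tsd = host[pos - spec.tsd_len : pos] if spec.tsd_len else ""
    new_host = host[:pos] + element + tsd + host[pos:]

    integrase = "none"
    for name in anchor_names:
        low = name.lower()
        if "yrec" in low:
            integrase = "YREC"
        elif "rve-int" in low or "rve_int" in low:
            integrase = "rve-INT"
    record = EveTruth(
        contig_id=contig_id,
        start=pos,
        end=pos + spec.length,
        gc=gc_fraction(element),
        repeat_kind=spec.repeat_kind,
        repeat_len=spec.repeat_len if spec.repeat_kind != "none" else 0,
        tsd=tsd,
        anchors=anchor_names,
        integrase=integrase,
    )
    out = dict(genome)
    out[contig_id] = new_host
    if truth is not None:
        # Shift truth records downstream of the insertion point.
        for e in truth.eves:
            if e.contig_id == contig_id and e.start >= pos:
                e.start += spec.length + spec.tsd_len
                e.end += spec.length + spec.tsd_len
        truth.eves.append(record)
        truth.eves.sort(key=lambda e: (e.contig_id, e.start))
    return out, record


def anchor_features_from_truth(truth: TruthSet) -> list[dict]:
    """GFF3-writable anchor features (one per anchor name per element).

    Anchors are positioned inside the element span; the scanner only needs
    an overlapping interval plus the Name attribute.
    """
    feats = []
    for i, e in enumerate(truth.eves):
        for j, name in enumerate(e.anchors):
            mid = (e.start + e.end) // 2
            feats.append(
                {
                    "seqid": e.contig_id,
                    "type": "protein_match",
                    "start": mid + 100 * j,
                    "end": mid + 100 * j + 60,
                    "strand": "+",
                    "attributes": {"ID": f"anchor_{i}_{j}", "Name": name},
                }
            )
    return feats


def gen_eve_genome(
    n_implants: int,
    seed: int,
    n_contigs: int = 2,
    contig_len: int = 220_000,
    host_gc: float = 0.52,
    element_gc: float = 0.35,
    telomere_motif: str = "TTAGGG",
) -> tuple[dict[str, str], TruthSet]:
    """Host genome with ``n_implants`` randomly drawn, non-overlapping PLVs.

    Element lengths are uniform over 14-40 kb, TIR-flanked elements (with
    5-6 bp TSDs and an rve-INT anchor) and TDR-flanked ones (no TSD, YREC
    anchor) drawn 4:1, repeat lengths 250-800 bp — the parameter ranges of
    the endogenous PLV complement this generator emulates.
    """
    rng = np.random.default_rng(seed)
    genome, truth = gen_host_genome(
        n_contigs, (contig_len, contig_len), host_gc, telomere_motif,
        ["both"] * n_contigs, seed=seed,
    )
    contigs = list(genome)
    # place implants in original coordinates, well separated, then apply
    # right-to-left so earlier positions stay valid
    placements: list[tuple[str, int]] = []
    margin, gap = 6_000, 4_000
    for k in range(n_implants):
        cid = contigs[k % n_contigs]
        for _attempt in range(200):
            pos = int(rng.integers(margin, contig_len - margin))
            if all(c != cid or abs(p - pos) >= gap for c, p in placements):
                placements.append((cid, pos))
                break
        else:
            raise RuntimeError("could not place implants without overlap")
    placements.sort(key=lambda cp: (cp[0], -cp[1]))
    for k, (cid, pos) in enumerate(placements):
        if rng.random() < 0.8:
            spec = ElementSpec(
                length=int(rng.integers(14_000, 40_001)),
                gc=element_gc,
                repeat_kind="TIR",
                repeat_len=int(rng.integers(250, 801)),
                tsd_len=int(rng.integers(5, 7)),
                anchor_peptides=[("MCP", "MAVHKELTRFGWDQN"), ("rve-INT", "MKDLRHEWAVYSTQG")],
            )
        else:
            spec = ElementSpec(
                length=int(rng.integers(14_000, 40_001)),
                gc=element_gc,
                repeat_kind="TDR",
                repeat_len=int(rng.integers(200, 351)),
                tsd_len=0,
                anchor_peptides=[("MCP", "MAVHKELTRFGWDQN"), ("YREC", "MHYRECLAVKWGDST")],
            )
        genome, _ = implant_eve(genome, cid, pos, spec, seed=seed + 100 + k, truth=truth)
    return genome, truth


DEFAULT_ANCHOR_MOTIFS: list[tuple[str, str]] = [
    ("MCP", "MAVHKELTRFGWDQN"),
    ("rve-INT", "MKDLRHEWAVYSTQG"),
    ("YREC", "MHYRECLAVKWGDST"),
]


# ---------------------------------------------------------------------------
# Read alignments with excluded islands
# ---------------------------------------------------------------------------

def gen_alignments(
    reference: tuple[str, int] | tuple[str, str],
    n_reads: int,
    read_len: int,
    excluded: Sequence[tuple[int, int]] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate perfect-identity read placements on one reference.

    ``reference`` is ``(ref_id, length)`` or ``(ref_id, sequence)``. Read
    start positions are uniform over positions whose full read interval
    avoids every excluded interval, emulating a metagenomic island that
    recruits no reads. No sequencing errors or quality strings are modelled.
    """
    ref_id, second = reference
    ref_len = second if isinstance(second, int) else len(second)
    if read_len > ref_len:
        raise ValueError("read_len exceeds reference length")
    for s, e in excluded:
        if not 0 <= s < e <= ref_len:
            raise ValueError(f"excluded interval ({s},{e}) outside reference")

    allowed = np.ones(ref_len - read_len + 1, dtype=bool)
    for s, e in excluded:
        lo = max(0, s - read_len + 1)
        allowed[lo : min(e, len(allowed))] = False
    positions = np.flatnonzero(allowed)
    if positions.size == 0:
        raise ValueError("excluded intervals cover the whole reference")

    rng = np.random.default_rng(seed)
    starts = rng.choice(positions, size=n_reads, replace=True) if n_reads else np.array([], dtype=int)
    starts = np.sort(starts)
    return pd.DataFrame(
        {
            "read_id": [f"read_{i + 1}" for i in range(n_reads)],
            "ref_id": ref_id,
            "start": starts.astype(int),
            "end": (starts + read_len).astype(int),
            "identity": 1.0,
        }
    )


def mutate(seq: str, sub_rate: float, seed: int = 0) -> str:
    """Apply i.i.d. substitutions at ``sub_rate`` (each hit base is replaced
    by one of the three other bases, uniformly). Used to build genome pairs
    of known expected nucleotide identity."""
    rng = np.random.default_rng(seed)
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(a.size) < sub_rate)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = alphabet[alphabet != a[i]]
        a[i] = choices[rng.integers(3)]
    return a.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# CARD-FISH survey tables
# ---------------------------------------------------------------------------

def gen_survey(
    n_samples: int,
    hnf_mean: float = 1500.0,
    cry1a_beta: tuple[float, float] = (1.02, 5.17),
    env_vars: Sequence[dict] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a CARD-FISH survey table.

    HNF densities (cells/ml) are log-normal around ``hnf_mean``; the CRY1a
    fraction of HNF is Beta(a, b). The default Beta(1.02, 5.17) gives mean
    fraction a/(a+b) ~= 0.165, the survey-wide average relative abundance.
    ``env_vars`` entries are ``{"name", "mean", "sd", "coupling"}`` where
    coupling is the target correlation with the CRY1a percentage (0 =
    independent covariate).
    """
    a, b = cry1a_beta
    if a <= 0 or b <= 0:
        raise ValueError("Beta parameters must be > 0")
    rng = np.random.default_rng(seed)
    sigma = 0.5
    hnf = rng.lognormal(np.log(hnf_mean) - sigma**2 / 2, sigma, n_samples)
    frac = np.clip(rng.beta(a, b, n_samples), 0.0, 1.0)
    cry = frac * hnf
    depth_classes = rng.choice(["epilimnion", "mid", "hypolimnion"], n_samples)
    table = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(n_samples)],
            "site": [f"lake_{i % 87 + 1}" for i in range(n_samples)],
            "date": "2024-05-01",
            "depth_class": depth_classes,
            "hnf_count": hnf,
            "cry1a_count": cry,
        }
    )
    pct = 100.0 * frac
    z_pct = (pct - pct.mean()) / pct.std() if pct.std() > 0 else np.zeros(n_samples)
    for spec in env_vars or []:
        c = float(spec.get("coupling", 0.0))
        noise = rng.standard_normal(n_samples)
        z = c * z_pct + np.sqrt(max(0.0, 1.0 - c * c)) * noise
        table[f"env_{spec['name']}"] = spec.get("mean", 0.0) + spec.get("sd", 1.0) * z
    return table


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

def gen_growth(
    inoculum: float,
    lag: float,
    mu: float,
    t_collapse: float,
    collapse_frac: float,
    cv: float,
    timepoints: Sequence[float],
    seed: int = 0,
    replicate_id: str = "rep_1",
) -> pd.DataFrame:
    """Simulate one growth-curve replicate.

    N(t) = inoculum for t < lag; exponential at rate ``mu`` from the end of
    lag; multiplied by (1 - collapse_frac) from ``t_collapse`` on (a sudden
    culture collapse). Multiplicative log-normal noise with coefficient of
    variation ``cv`` (mean-corrected so E[noise] = 1).
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if not 0.0 <= collapse_frac < 1.0:
        raise ValueError("collapse_frac must be in [0,1)")
    t = np.asarray(timepoints, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")

    n = np.where(t < lag, inoculum, inoculum * np.exp(mu * np.maximum(t - lag, 0.0)))
    n = np.where(t >= t_collapse, n * (1.0 - collapse_frac), n)
    if cv > 0:
        rng = np.random.default_rng(seed)
        s = np.sqrt(np.log1p(cv * cv))
        n = n * rng.lognormal(-s * s / 2, s, t.size)
    return pd.DataFrame({"replicate_id": replicate_id, "time_h": t, "count": n})


# ---------------------------------------------------------------------------
# Synthetic stand-ins reconstructed from published summary marginals
# ---------------------------------------------------------------------------

def synthetic_pct_from_marginals(
    n: int = 263,
    mean: float = 16.47,
    median: float = 12.08,
    sd: float = 15.95,
    vmin: float = 0.0,
    vmax: float = 96.5,
    n_above_10: int = 154,
    n_below_1: int = 39,
) -> np.ndarray:
    """SYNTHETIC stand-in: a percentage vector matching published marginals.

    The raw survey table is not redistributable here, so this constructs a
    deterministic vector of ``n`` percentages whose mean, median (lower
    median), sample SD, range and strict category counts (>10%, <1%) equal
    the published summary values. Used to exercise the survey summariser at
    the reported operating point; it carries no information about the real
    per-sample data beyond those marginals.
    """
    from scipy.optimize import brentq

    n_mid = n - n_above_10 - n_below_1            # values in [1, 10]
    n_low_band = (n - 1) // 2 - n_below_1 - n_mid  # >10 but <= median, below median rank
    if n_mid < 0 or n_low_band < 0:
        raise ValueError("inconsistent marginals")
    fixed = np.concatenate(
        [
            [vmin],
            np.full(n_below_1 - 1, 0.9),
            np.full(n_mid, 5.5),
            np.full(n_low_band, 11.0),
            [median],
            [vmax],
        ]
    )
    n_free = n - fixed.size
    target_sum = mean * n
    target_ss = sd * sd * (n - 1) + n * mean * mean
    rem_sum = target_sum - fixed.sum()
    rem_ss = target_ss - np.square(fixed).sum()
    lo = median + 0.02
    base = np.linspace(0.0, 1.0, n_free)

    def ss_at(p: float) -> float:
        g = base**p
        c = (rem_sum - n_free * lo) / g.sum()
        v = lo + c * g
        return float(np.square(v).sum() - rem_ss)

    p = brentq(ss_at, 0.05, 12.0, xtol=1e-12)
    g = base**p
    c = (rem_sum - n_free * lo) / g.sum()
    free = lo + c * g
    if free.max() > vmax or free.min() < lo:
        raise RuntimeError("stand-in construction left the allowed range")
    return np.sort(np.concatenate([fixed, free]))


def synthetic_survey_from_marginals(**kwargs) -> pd.DataFrame:
    """SYNTHETIC stand-in survey table built from published marginals.

    HNF counts are fixed at 1e4 cells/ml so the derived CRY1a percentage is
    exact; see :func:`synthetic_pct_from_marginals`.
    """
    pct = synthetic_pct_from_marginals(**kwargs)
    n = pct.size
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(n)],
            "site": "synthetic",
            "date": "2024-01-01",
            "depth_class": "epilimnion",
            "hnf_count": 1e4,
            "cry1a_count": pct * 100.0,   # pct/100 * 1e4
        }
    )


# Element descriptors matching the published PLV complement: 13 elements,
# median length 20.29 kb; 11 TIR-flanked (median TIR 488 bp, rve-INT, 5-6 bp
# TSDs) and 2 TDR-flanked (median TDR 266 bp, YREC, no TSD). SYNTHETIC
# stand-in: individual values are chosen to reproduce published medians, not
# taken from the per-element table, which is not redistributable here.
SYNTHETIC_PLV_SPECS: list[ElementSpec] = [
    ElementSpec(length, 0.35, "TIR", tir, tsd,
                [("MCP", "MAVHKELTRFGWDQN"), ("rve-INT", "MKDLRHEWAVYSTQG")])
    for length, tir, tsd in [
        (14200, 320, 5), (15800, 355, 5), (17300, 410, 6), (18600, 440, 5),
        (19500, 470, 6), (20290, 488, 5), (21800, 510, 5), (24300, 560, 6),
        (27600, 620, 5), (31900, 700, 6), (36400, 780, 5),
    ]
] + [
    ElementSpec(19100, 0.35, "TDR", 266, 0,
                [("MCP", "MAVHKELTRFGWDQN"), ("YREC", "MHYRECLAVKWGDST")]),
    ElementSpec(22700, 0.35, "TDR", 300, 0,
                [("MCP", "MAVHKELTRFGWDQN"), ("YREC", "MHYRECLAVKWGDST")]),
]
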