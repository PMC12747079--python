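"""EVE scanner: oracle agreement, recovery, classification, invariants."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evekit._seq import random_seq, revcomp
from evekit.eve_scan import (
    EVECall,
    ScanParams,
    TerminalRepeat,
    TSD,
    call_eves,
    classify_eve,
    find_terminal_repeats,
    find_tsd,
    gc_track,
    segment_low_gc,
    summarize_eves,
)
from evekit.synthetic_data import DEFAULT_ANCHOR_MOTIFS, ElementSpec, gen_eve_genome, implant_eve

from conftest import random_dna


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def lcs_oracle(left: str, right: str) -> int:
    """Longest common substring length by dense dynamic programming."""
    la = np.frombuffer(left.encode(), dtype=np.uint8)
    ra = np.frombuffer(right.encode(), dtype=np.uint8)
    best = 0
    prev = np.zeros(ra.size, dtype=np.int32)
    for i in range(la.size):
        cur = np.where(la[i] == ra, 1, 0).astype(np.int32)
        cur[1:] += np.where(la[i] == ra[1:], prev[:-1], 0)
        best = max(best, int(cur.max()))
        prev = cur
    return best


def terminal_repeat_oracle(seq: str, margin: int) -> tuple[int, int]:
    """(longest exact TDR, longest exact TIR) between the end margins."""
    m = min(margin, len(seq) // 2)
    left, right = seq[:m], seq[-m:]
    return lcs_oracle(left, right), lcs_oracle(left, revcomp(right))


def tsd_oracle(left: str, right: str, k_min=4, k_max=8):
    hits = [
        k for k in range(k_min, k_max + 1)
        if len(left) >= k and len(right) >= k
        and "N" not in left[-k:] and left[-k:] == right[:k]
    ]
    return max(hits) if hits else None


# ---------------------------------------------------------------------------
# GC track and segmentation
# ---------------------------------------------------------------------------

class TestGCTrack:
    @pytest.mark.parametrize("seq,expected", [("GGGG", [1.0]), ("ATGC", [0.5])])
    def test_single_window(self, seq, expected):
        assert gc_track(seq, 4, 4).values.tolist() == expected

    def test_matches_naive_recount(self):
        seq = random_dna(10_000, seed=1, gc=0.45)
        track = gc_track(seq, 1000, 200)
        naive = [
            (seq[i : i + 1000].count("G") + seq[i : i + 1000].count("C")) / 1000
            for i in range(0, len(seq) - 1000 + 1, 200)
        ]
        assert np.allclose(track.values, naive)
        assert len(track.values) == (10_000 - 1000) // 200 + 1

    def test_ambiguous_bases_excluded_from_denominator(self):
        track = gc_track("GGNN" * 2, 8, 8)
        assert track.values[0] == pytest.approx(4 / 4)
        assert track.n_excluded[0] == 4

    def test_mostly_ambiguous_window_is_missing(self):
        assert np.isnan(gc_track("N" * 7 + "GCA", 10, 10).values[0])

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            gc_track("", 4, 4)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        seq=st.text(alphabet="ACGT", min_size=20, max_size=300),
        window=st.integers(5, 20),
        step=st.integers(1, 5),
    )
    def test_property_window_count_and_bounds(self, seq, window, step):
        track = gc_track(seq, window, step)
        assert len(track.values) == (len(seq) - window) // step + 1
        assert np.all((track.values >= 0) & (track.values <= 1))


class TestSegmentLowGC:
    def test_flat_track_yields_nothing(self):
        track = gc_track(random_dna(50_000, seed=2, gc=0.52), 1000, 200)
        assert segment_low_gc(track, 0.52, 8.0, 5_000, 60_000) == []

    def test_implant_recovered_with_reciprocal_overlap(self, small_host, tir_spec):
        genome, truth = small_host
        for seed in range(5):
            g2, rec = implant_eve(dict(genome), "contig_3", 25_000, tir_spec, seed=seed)
            track = gc_track(g2["contig_3"], 1000, 200)
            segs = segment_low_gc(track, 0.52, 8.0, 5_000, 60_000)
            assert len(segs) == 1
            s, e = segs[0]
            ov = min(e, rec.end) - max(s, rec.start)
            assert ov >= 0.9 * (rec.end - rec.start)
            assert ov >= 0.9 * (e - s)

    def test_nearby_implants_not_merged(self, small_host):
        genome, truth = small_host
        spec = ElementSpec(14_000, 0.35, "TIR", 300, 5)
        g2, r1 = implant_eve(genome, "contig_3", 20_000, spec, seed=0, truth=truth)
        # 2 kb downstream of the first element's end in current coordinates
        g2, r2 = implant_eve(g2, "contig_3", r1.end + spec.tsd_len + 2_000, spec, seed=1, truth=truth)
        track = gc_track(g2["contig_3"], 1000, 200)
        segs = segment_low_gc(track, 0.52, 8.0, 5_000, 60_000)
        assert len(segs) == 2


# ---------------------------------------------------------------------------
# terminal repeats
# ---------------------------------------------------------------------------

class TestFindTerminalRepeats:
    def test_exact_tir_forced(self):
        r = random_dna(500, seed=3, gc=0.35)
        seq = r + random_dna(19_000, seed=4, gc=0.35) + revcomp(r)
        hit = find_terminal_repeats(seq, max_mismatch_frac=0.0)
        assert hit.kind == "TIR" and hit.length == 500 and hit.identity == 1.0
        assert hit.left_span == (0, 500)
        assert hit.right_span == (len(seq) - 500, len(seq))

    def test_exact_tdr_forced(self):
        r = random_dna(266, seed=5, gc=0.35)
        seq = r + random_dna(18_000, seed=6, gc=0.35) + r
        hit = find_terminal_repeats(seq, max_mismatch_frac=0.0)
        assert hit.kind == "TDR" and hit.length == 266

    def test_mismatch_tolerant_detection(self):
        r = random_dna(500, seed=7, gc=0.4)
        rc = list(revcomp(r))
        for i in range(0, 500, 60):   # 9 substitutions = 1.8%
            rc[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[rc[i]]
        seq = r + random_dna(10_000, seed=8) + "".join(rc)
        hit = find_terminal_repeats(seq, max_mismatch_frac=0.05)
        assert hit is not None and hit.kind == "TIR"
        assert hit.length >= 490 and hit.identity >= 0.95

    def test_agrees_with_exhaustive_oracle_on_random_sequences(self):
        """No false repeats: on 60 random sequences the finder at zero
        mismatch tolerance agrees with the DP longest-common-substring
        oracle about whether a >= min_len terminal repeat exists."""
        for seed in range(60):
            n = int(np.random.default_rng(seed).integers(1_000, 5_001))
            seq = random_dna(n, seed=1000 + seed)
            margin = 400
            tdr, tir = terminal_repeat_oracle(seq, margin)
            hit = find_terminal_repeats(
                seq, min_len=25, max_mismatch_frac=0.0, search_margin=margin
            )
            if max(tdr, tir) < 25:
                assert hit is None
            else:
                assert hit is not None
                assert hit.length == max(tdr, tir)

    def test_min_len_above_margin_rejected(self):
        with pytest.raises(ValueError):
            find_terminal_repeats("ACGT" * 1000, min_len=300, search_margin=200)


# ---------------------------------------------------------------------------
# TSDs
# ---------------------------------------------------------------------------

class TestFindTSD:
    def test_forced_five_mer(self):
        left = random_dna(15, seed=9) + "AACGT"
        right = "AACGT" + random_dna(15, seed=10)
        tsd = find_tsd(left, right)
        assert tsd.sequence == "AACGT" and tsd.length == 5

    def test_longest_k_wins(self):
        # flanks share a 6-mer (which contains the 5- and 4-mer matches)
        left = random_dna(14, seed=11) + "TAACGT"
        right = "TAACGT" + random_dna(14, seed=12)
        assert find_tsd(left, right).length == 6

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        n_hits = 0
        for i in range(300):
            left = random_dna(20, seed=2000 + i)
            right = random_dna(20, seed=3000 + i)
            got = find_tsd(left, right)
            want = tsd_oracle(left, right)
            assert (got.length if got else None) == want
            n_hits += want is not None
        # chance of a >=4-mer TSD between random flanks ~ 4^-4
        assert n_hits <= 10

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        left=st.text(alphabet="ACGTN", min_size=8, max_size=20),
        right=st.text(alphabet="ACGTN", min_size=8, max_size=20),
    )
    def test_property_matches_oracle_on_arbitrary_flanks(self, left, right):
        got = find_tsd(left, right)
        assert (got.length if got else None) == tsd_oracle(left, right)

    def test_n_breaks_match_and_bad_chars_reject(self):
        assert find_tsd("A" * 15 + "AANGT", "AANGT" + "C" * 15) is None
        with pytest.raises(ValueError):
            find_tsd("A" * 19 + "X", "ACGTA" + "C" * 15)


# ---------------------------------------------------------------------------
# calling, classification, summaries
# ---------------------------------------------------------------------------

class TestCallEves:
    def test_synthetic_genome_fully_recovered(self, anchor_motifs):
        genome, truth = gen_eve_genome(4, seed=21)
        calls = call_eves(genome, anchor_motifs)
        assert len(calls) == len(truth.eves)
        for t, c in zip(truth.eves, calls):
            assert c.contig_id == t.contig_id
            assert abs(c.start - t.start) <= 50 and abs(c.end - t.end) <= 50
            assert c.repeat is not None and c.repeat.kind == t.repeat_kind

    def test_low_gc_without_anchor_not_called(self, small_host):
        genome, _ = small_host
        spec = ElementSpec(20_000, 0.35, "TIR", 400, 5, anchor_peptides=[])
        g2, _ = implant_eve(genome, "contig_1", 30_000, spec, seed=1)
        assert call_eves(g2, DEFAULT_ANCHOR_MOTIFS) == []

    def test_no_anchor_evidence_rejected(self, small_host):
        with pytest.raises(ValueError, match="anchor"):
            call_eves(small_host[0], [])

    def test_monotone_in_min_delta(self):
        genome, _ = gen_eve_genome(4, seed=22)
        n_calls = [
            len(call_eves(genome, DEFAULT_ANCHOR_MOTIFS, ScanParams(min_delta=d)))
            for d in (6.0, 8.0, 12.0)
        ]
        assert n_calls == sorted(n_calls, reverse=True)

    def test_idempotent_after_hard_masking(self, anchor_motifs):
        genome, _ = gen_eve_genome(3, seed=23)
        calls = call_eves(genome, anchor_motifs)
        assert calls
        masked = dict(genome)
        for c in calls:
            s = masked[c.contig_id]
            masked[c.contig_id] = s[: c.start] + "N" * (c.end - c.start) + s[c.end :]
        assert call_eves(masked, anchor_motifs) == []


class TestClassifyAndSummarize:
    def _call(self, kind, integrase, tsd=None):
        repeat = TerminalRepeat(kind, 400, 1.0, (0, 400), (19_600, 20_000)) if kind else None
        return EVECall("c", 0, 20_000, 0.35, repeat, tsd, [("MCP", 0, 0)], integrase)

    @pytest.mark.parametrize(
        "kind,integrase,expected",
        [
            ("TDR", "YREC", "yrec-TDR-type"),
            ("TIR", "rve-INT", "canonical-polinton-like"),
            ("TIR", "none", "unclassified"),
            (None, "rve-INT", "unclassified"),
        ],
    )
    def test_classification_rules(self, kind, integrase, expected):
        assert classify_eve(self._call(kind, integrase)) == expected

    def test_tdr_with_tsd_warns(self):
        call = self._call("TDR", "YREC", tsd=TSD("AACGT"))
        assert classify_eve(call) == "yrec-TDR-type"
        assert call.warnings

    def test_median_is_lower_median(self):
        calls = [self._call("TIR", "rve-INT") for _ in range(3)]
        for c, ln in zip(calls, (10_000, 20_000, 30_000)):
            c.end = ln
        assert summarize_eves(calls)["median_length"] == 20_000

    def test_empty_summary(self):
        s = summarize_eves([])
        assert s["n"] == 0 and s["median_length"] is None
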