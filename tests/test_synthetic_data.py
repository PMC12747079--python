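"""Generator correctness: determinism, truth consistency, conservation."""
import numpy as np
import pytest

from evekit._seq import gc_fraction, revcomp
from evekit.synthetic_data import (
    ElementSpec,
    gen_alignments,
    gen_growth,
    gen_host_genome,
    gen_survey,
    implant_eve,
)


class TestGenHostGenome:
    def test_telomere_plan_is_realized(self, small_host):
        genome, truth = small_host
        motif = "TTAGGG"
        for (cid, seq), t in zip(genome.items(), truth.telomeres):
            left = seq.startswith(motif * 8)
            right = seq.endswith(revcomp(motif * 8))
            got = {2: "both", 1: "one", 0: "none"}[left + right]
            assert got == t["status"] == {0: "both", 1: "one", 2: "none"}[int(cid[-1]) - 1]

    def test_gc_within_two_points(self):
        genome, _ = gen_host_genome(1, (100_000, 100_000), 0.52, "TTAGGG", ["none"], seed=3)
        assert 0.50 <= gc_fraction(next(iter(genome.values()))) <= 0.54

    def test_same_seed_is_byte_identical(self):
        a, _ = gen_host_genome(2, (60_000, 70_000), 0.5, "TTAGGG", ["both", "none"], seed=7)
        b, _ = gen_host_genome(2, (60_000, 70_000), 0.5, "TTAGGG", ["both", "none"], seed=7)
        assert a == b

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(length_range=(100, 200)),                 # below 2x telomere tract
            dict(end_plan=["both", "left", "none"]),       # invalid label
        ],
    )
    def test_rejects_bad_inputs(self, kwargs):
        base = dict(
            n_contigs=3, length_range=(60_000, 70_000), gc=0.5,
            telomere_motif="TTAGGG", end_plan=["both", "one", "none"], seed=0,
        )
        with pytest.raises(ValueError):
            gen_host_genome(**{**base, **kwargs})


class TestImplantEve:
    def test_tir_and_tsd_structure(self, small_host):
        genome, truth = small_host
        spec = ElementSpec(20_000, 0.35, "TIR", 500, 5)
        g2, rec = implant_eve(genome, "contig_1", 30_000, spec, seed=1, truth=truth)
        element = g2["contig_1"][rec.start : rec.end]
        assert element[:500] == revcomp(element[-500:])
        left = g2["contig_1"][rec.start - 5 : rec.start]
        right = g2["contig_1"][rec.end : rec.end + 5]
        assert left == right == rec.tsd

    def test_tdr_no_flank_duplication(self, small_host):
        genome, truth = small_host
        spec = ElementSpec(19_000, 0.35, "TDR", 266, 0)
        g2, rec = implant_eve(genome, "contig_2", 20_000, spec, seed=2, truth=truth)
        element = g2["contig_2"][rec.start : rec.end]
        assert element[:266] == element[-266:]
        assert rec.tsd == ""

    def test_length_conservation_and_flanks_unchanged(self, small_host, tir_spec):
        genome, truth = small_host
        before = genome["contig_1"]
        g2, rec = implant_eve(genome, "contig_1", 30_000, tir_spec, seed=3, truth=truth)
        after = g2["contig_1"]
        assert len(after) == len(before) + tir_spec.length + tir_spec.tsd_len
        assert after[:30_000] == before[:30_000]
        assert after[rec.end + tir_spec.tsd_len :] == before[30_000:]

    def test_element_gc_near_spec(self, small_host, tir_spec):
        genome, truth = small_host
        _, rec = implant_eve(genome, "contig_1", 30_000, tir_spec, seed=4, truth=truth)
        assert abs(rec.gc - 0.35) < 0.03

    def test_rejects_positions_near_ends_and_overlaps(self, small_host, tir_spec):
        genome, truth = small_host
        with pytest.raises(ValueError):
            implant_eve(genome, "contig_1", 500, tir_spec, seed=0, truth=truth)
        g2, _ = implant_eve(genome, "contig_1", 30_000, tir_spec, seed=0, truth=truth)
        with pytest.raises(ValueError):
            implant_eve(g2, "contig_1", 31_000, tir_spec, seed=0, truth=truth)


class TestGenAlignments:
    def test_excluded_region_has_zero_coverage(self):
        aln = gen_alignments(("GV1", 100_000), 2_000, 150, [(40_000, 60_000)], seed=5)
        assert not ((aln["end"] > 40_000) & (aln["start"] < 60_000)).any()

    def test_zero_reads_is_valid_empty_table(self):
        aln = gen_alignments(("GV1", 10_000), 0, 150)
        assert len(aln) == 0
        assert list(aln.columns) == ["read_id", "ref_id", "start", "end", "identity"]

    def test_mean_coverage_matches_closed_form(self):
        """Empirical mean depth over the covered region ~= n*L/usable."""
        ref_len, n_reads, read_len = 200_000, 5_000, 100
        depths = []
        for seed in range(10):
            aln = gen_alignments(("r", ref_len), n_reads, read_len, seed=seed)
            depths.append((aln["end"] - aln["start"]).sum() / ref_len)
        expected = n_reads * read_len / ref_len
        assert np.mean(depths) == pytest.approx(expected, rel=1e-9)

    def test_rejects_fully_excluded_reference(self):
        with pytest.raises(ValueError):
            gen_alignments(("r", 1_000), 10, 100, [(0, 1_000)], seed=0)


class TestGenSurvey:
    def test_mean_fraction_matches_beta_mean(self):
        # Beta(a,b) mean a/(a+b) = 0.165 -> mean percentage within 2 pp
        table = gen_survey(1_000, cry1a_beta=(1.02, 5.17), seed=9)
        pct = 100 * table["cry1a_count"] / table["hnf_count"]
        assert abs(pct.mean() - 16.5) < 2.0

    def test_uncoupled_covariate_is_uncorrelated(self):
        table = gen_survey(
            1_000, env_vars=[{"name": "temp", "mean": 15, "sd": 5, "coupling": 0.0}],
            seed=10,
        )
        pct = 100 * table["cry1a_count"] / table["hnf_count"]
        assert abs(np.corrcoef(pct, table["env_temp"])[0, 1]) < 0.2

    def test_row_count(self):
        assert len(gen_survey(263, seed=0)) == 263


class TestGenGrowth:
    def test_noiseless_curve_follows_model(self):
        t = list(range(0, 200, 12))
        g = gen_growth(200, lag=48, mu=0.03, t_collapse=150, collapse_frac=0.8,
                       cv=0.0, timepoints=t, seed=0)
        n = g["count"].to_numpy()
        tt = g["time_h"].to_numpy()
        model = np.where(tt < 48, 200.0, 200.0 * np.exp(0.03 * (tt - 48)))
        model = np.where(tt >= 150, model * 0.2, model)
        assert np.allclose(n, model)

    def test_unsorted_timepoints_rejected(self):
        with pytest.raises(ValueError):
            gen_growth(200, 0, 0.02, 1e9, 0.0, 0.0, [0, 10, 5], seed=0)
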