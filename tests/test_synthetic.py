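"""Generator properties: determinism, distribution matching, analytic limits."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tailtop.enrichment import classify_top_motif
from tailtop.io_formats import write_polya_table
from tailtop.synthetic import (
    SimulationConfig,
    simulate_count_matrices,
    simulate_slam_course,
    simulate_tail_reads,
    simulate_transcriptome,
    simulate_utr_sequences,
)


class TestSimulateTranscriptome:
    def test_top_count_matches_configuration_exactly(self):
        truth = simulate_transcriptome(SimulationConfig(n_transcripts=1000, top_fraction=0.1), 7)
        assert len(truth.top_ids) == 100

    def test_zero_top_fraction_gives_no_top_transcripts(self):
        truth = simulate_transcriptome(SimulationConfig(n_transcripts=500, top_fraction=0.0), 7)
        assert truth.top_ids == set()

    def test_same_config_and_seed_reproduce_identical_truth(self):
        cfg = SimulationConfig(n_transcripts=200)
        a = simulate_transcriptome(cfg, 3).to_frame()
        b = simulate_transcriptome(cfg, 3).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_transcripts=0)

    def test_mixture_weights_sum_to_one_everywhere(self, tiny_truth):
        for t in tiny_truth.transcripts:
            for mix in t.tail_mixtures.values():
                assert math.isclose(sum(mix.weights), 1.0, abs_tol=1e-9)
                assert min(mix.weights) >= 0


class TestSimulateTailReads:
    def test_pure_60nt_component_recovers_its_mean(self):
        cfg = SimulationConfig(
            n_transcripts=5,
            top_fraction=0.0,
            excluded_fraction=0.0,
            base_weights=(0.0, 1.0, 0.0),
            mixture_sds=(8.0, 8.0, 8.0),
            tail_noise_sd=0.0,
            depth=500.0,
            scale_depth_with_expression=False,
            n_replicates=1,
        )
        truth = simulate_transcriptome(cfg, 1)
        df = simulate_tail_reads(truth, cfg.conditions[0], seed=2, as_frame=True)
        assert abs(df["polya_length"].mean() - 60.0) < 1.0

    def test_qc_failure_count_is_binomially_consistent(self):
        cfg = SimulationConfig(n_transcripts=100, depth=100.0, qc_fail_fraction=0.05)
        truth = simulate_transcriptome(cfg, 1)
        df = simulate_tail_reads(truth, "D0", seed=3, as_frame=True)
        n = len(df)
        fails = (df["qc_tag"] != "PASS").sum()
        sd = math.sqrt(n * 0.05 * 0.95)
        assert abs(fails - 0.05 * n) < 3 * sd

    def test_fixed_seed_gives_byte_identical_table(self, tiny_truth, tmp_path):
        a = simulate_tail_reads(tiny_truth, "D0", seed=11, as_frame=True)
        b = simulate_tail_reads(tiny_truth, "D0", seed=11, as_frame=True)
        write_polya_table(a, tmp_path / "a.tsv")
        write_polya_table(b, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_unknown_condition_rejected(self, tiny_truth):
        with pytest.raises(ValueError, match="condition"):
            simulate_tail_reads(tiny_truth, "D99", seed=1)

    def test_empirical_distribution_matches_configured_mixture(self):
        """Kolmogorov distance to the (truncated) mixture CDF < 0.02 at 1e5 reads."""
        cfg = SimulationConfig(
            n_transcripts=1,
            top_fraction=0.0,
            excluded_fraction=0.0,
            tail_noise_sd=0.0,
            depth=1e5,
            n_replicates=1,
            scale_depth_with_expression=False,
        )
        truth = simulate_transcriptome(cfg, 5)
        lengths = np.sort(
            simulate_tail_reads(truth, "D0", seed=6, as_frame=True)["polya_length"].to_numpy()
        )

        w = np.array(cfg.base_weights)
        mu = np.array(cfg.mixture_means)
        sd = np.array(cfg.mixture_sds)
        trunc = stats.norm.sf(0.0, loc=mu, scale=sd)  # resampling renormalizes above 0

        def mix_cdf(x):
            comp = (stats.norm.cdf(x[:, None], mu, sd) - stats.norm.cdf(0.0, mu, sd)) / trunc
            return comp @ w

        ecdf = np.arange(1, lengths.size + 1) / lengths.size
        d = np.max(np.abs(ecdf - mix_cdf(lengths)))
        assert d < 0.02


class TestSimulateSlamCourse:
    def test_noiseless_catabolic_halves_at_the_half_life(self, tiny_truth):
        t360 = tiny_truth.transcripts[0]
        t360.k_d = math.log(2) / 360.0
        table = simulate_slam_course(tiny_truth, "catabolic", coverage=None, seed=0)
        sub = table[table["transcript_id"] == t360.transcript_id]
        f0 = sub.loc[sub["time_h"] == 0.0, "conversion_rate"].iloc[0]
        f6 = sub.loc[sub["time_h"] == 6.0, "conversion_rate"].iloc[0]
        assert math.isclose(f6 / f0, 0.5, rel_tol=1e-12)

    def test_high_coverage_approaches_analytic_curve(self, tiny_truth):
        exact = simulate_slam_course(tiny_truth, "anabolic", coverage=None, seed=0)
        noisy = simulate_slam_course(tiny_truth, "anabolic", coverage=10**5, seed=1)
        dev = (noisy["conversion_rate"] - exact["conversion_rate"]).abs()
        assert dev.max() < 0.01  # binomial concentration on the conversion scale

    def test_background_only_transcript_stays_flat(self, tiny_truth):
        tiny_truth.transcripts[0].saturation_conversion = 0.0
        table = simulate_slam_course(
            tiny_truth, "catabolic", coverage=None, seed=0, background=0.001
        )
        sub = table[table["transcript_id"] == tiny_truth.transcripts[0].transcript_id]
        assert np.allclose(sub["conversion_rate"], 0.001)

    def test_missing_time_zero_rejected(self, tiny_truth):
        with pytest.raises(ValueError, match="0"):
            simulate_slam_course(tiny_truth, "catabolic", timepoints_h=(3.0, 6.0))

    def test_unknown_design_rejected(self, tiny_truth):
        with pytest.raises(ValueError, match="design"):
            simulate_slam_course(tiny_truth, "sideways")


class TestSimulateCountMatrices:
    def test_te_effect_doubles_rfp_rna_ratio(self):
        cfg = SimulationConfig(
            n_transcripts=50,
            top_fraction=1.0,
            excluded_fraction=0.0,
            top_delta_log2_te=1.0,
            top_log2fc=0.0,
            dispersion=0.0,
            library_size_log_sd=0.0,
            baseline_mean=50000.0,
            baseline_log_sd=0.0,
        )
        truth = simulate_transcriptome(cfg, 1)
        rna, rfp = simulate_count_matrices(truth, seed=2)
        cond = rna.sample_meta["condition"]
        ratio = {
            c: rfp.counts[:, (cond == c).to_numpy()].sum()
            / rna.counts[:, (cond == c).to_numpy()].sum()
            for c in ("D0", "D6")
        }
        assert ratio["D6"] / ratio["D0"] == pytest.approx(2.0, rel=0.01)

    def test_replicate_minimum_enforced(self, tiny_truth):
        with pytest.raises(ValueError, match="replicates"):
            simulate_count_matrices(tiny_truth, n_replicates=1)

    def test_fixed_seed_determinism(self, tiny_truth):
        a, _ = simulate_count_matrices(tiny_truth, seed=9)
        b, _ = simulate_count_matrices(tiny_truth, seed=9)
        assert np.array_equal(a.counts, b.counts)


class TestSimulateUtrSequences:
    def test_classifier_recovers_truth_labels_exactly(self, tiny_truth):
        for rec in simulate_utr_sequences(tiny_truth, seed=4):
            call = classify_top_motif(str(rec.seq))
            assert call.is_top == (rec.id in tiny_truth.top_ids)

    def test_top_run_lengths_span_4_to_15(self):
        cfg = SimulationConfig(n_transcripts=1000, top_fraction=1.0, excluded_fraction=0.0)
        truth = simulate_transcriptome(cfg, 2)
        runs = {
            classify_top_motif(str(r.seq)).run_length
            for r in simulate_utr_sequences(truth, seed=5)
        }
        assert runs == set(range(4, 16))
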