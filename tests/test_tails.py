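"""Tail profiling: bin fractions, filters, and the per-transcript shift test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from tailtop.io_formats import GeneSets, TailRead
from tailtop import tails


def _reads(spec):
    """spec: list of (transcript, sample, condition, [lengths])."""
    out = []
    i = 0
    for tx, sample, cond, lengths in spec:
        for l in lengths:
            out.append(TailRead(f"r{i}", tx, sample, cond, float(l)))
            i += 1
    return out


class TestBinFractions:
    @pytest.mark.parametrize(
        "lengths,expected",
        [
            ([10, 45, 60, 100], (0.25, 0.50, 0.25)),
            ([30, 90], (0.0, 1.0, 0.0)),  # boundaries belong to the ~60 band
            ([5, 10, 29.9], (1.0, 0.0, 0.0)),
            ([100, 200], (0.0, 0.0, 1.0)),
        ],
    )
    def test_known_partitions(self, lengths, expected):
        assert tails.bin_fractions(lengths) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tails.bin_fractions([])

    @given(
        lengths=st.lists(
            st.floats(min_value=0, max_value=300, allow_nan=False), min_size=1, max_size=50
        )
    )
    def test_matches_bruteforce_counting_and_sums_to_one(self, lengths):
        lt, mid, gt = tails.bin_fractions(lengths)
        n = len(lengths)
        assert lt == sum(1 for l in lengths if l < 30) / n
        assert mid == sum(1 for l in lengths if 30 <= l <= 90) / n
        assert gt == sum(1 for l in lengths if l > 90) / n
        assert math.isclose(lt + mid + gt, 1.0, abs_tol=1e-12)


class TestBuildTailProfiles:
    def test_transcript_below_min_reads_dropped(self):
        reads = _reads([("tx1", "s1", "D0", [50] * 29), ("tx2", "s1", "D0", [50] * 30)])
        prof = tails.build_tail_profiles(reads, min_reads=30)
        assert set(prof["transcript_id"]) == {"tx2"}

    def test_excluded_transcript_dropped_despite_depth(self):
        reads = _reads([("mt-tx", "s1", "D0", [50] * 500), ("tx2", "s1", "D0", [50] * 40)])
        gs = GeneSets(universe={"mt-tx", "tx2"}, top_genes=set(), exclusions={"mt-tx"})
        prof = tails.build_tail_profiles(reads, gs, min_reads=30)
        assert set(prof["transcript_id"]) == {"tx2"}

    def test_min_reads_pools_across_samples(self):
        reads = _reads([("tx1", s, "D0", [55] * 15) for s in ("s1", "s2", "s3")])
        prof = tails.build_tail_profiles(reads, min_reads=30)
        assert len(prof) == 3
        assert (prof["n_reads"] == 15).all()

    def test_empty_input_gives_empty_table(self):
        assert tails.build_tail_profiles([]).empty

    def test_histogram_total_equals_read_count(self):
        reads = _reads([("tx1", "s1", "D0", list(range(40)))])
        prof = tails.build_tail_profiles(reads, min_reads=30)
        assert prof["histogram"].iloc[0].sum() == prof["n_reads"].iloc[0]


class TestRelativeFrequencyHistogram:
    def _profiles(self):
        reads = _reads([("tx1", "s1", "D0", [60, 60, 90, 120] * 10)])
        return tails.build_tail_profiles(reads, min_reads=30)

    def test_width_30_bins_match_counting(self):
        hist = tails.relative_frequency_histogram(self._profiles(), "D0", bin_width=30)
        freq = dict(zip(hist["length"], hist["s1"]))
        assert freq[60] == 0.5 and freq[90] == 0.25 and freq[120] == 0.25

    def test_each_replicate_normalized(self):
        reads = _reads(
            [("tx1", "s1", "D0", [55] * 30), ("tx1", "s2", "D0", [65] * 40)]
        )
        prof = tails.build_tail_profiles(reads, min_reads=30)
        hist = tails.relative_frequency_histogram(prof, "D0")
        assert hist["s1"].sum() == pytest.approx(1.0)
        assert hist["s2"].sum() == pytest.approx(1.0)

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="D6"):
            tails.relative_frequency_histogram(self._profiles(), "D6")


def _profiles_from_fractions(per_sample):
    """per_sample: dict sample -> (condition, frac_60). Builds a profile table."""
    rows = []
    for sample, (cond, frac) in per_sample.items():
        rows.append(
            {
                "transcript_id": "tx1",
                "sample_id": sample,
                "condition": cond,
                "n_reads": 100,
                "frac_lt30": (1 - frac) / 2,
                "frac_60": frac,
                "frac_gt90": (1 - frac) / 2,
                "histogram": np.zeros(1),
            }
        )
    return pd.DataFrame(rows)


class TestBinFractionChange:
    def test_strong_shift_matches_pooled_t_oracle(self):
        a, b = [0.10, 0.12, 0.11], [0.30, 0.31, 0.29]
        prof = _profiles_from_fractions(
            {f"a{i}": ("D0", v) for i, v in enumerate(a)}
            | {f"b{i}": ("D6", v) for i, v in enumerate(b)}
        )
        res, _ = tails.test_bin_fraction_change(prof, "D0", "D6", bin="about60")
        # independent pooled-variance arithmetic
        ma, mb = np.mean(a), np.mean(b)
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t = (mb - ma) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        p = 2 * stats.t.sf(abs(t), df=4)
        row = res.iloc[0]
        assert row["t_statistic"] == pytest.approx(t)
        assert row["p_value"] == pytest.approx(p)
        assert row["p_value"] < 0.001 and row["significant"]
        assert row["delta"] == pytest.approx(mb - ma)

    def test_identical_constant_replicates_degenerate_p_one(self):
        prof = _profiles_from_fractions(
            {f"a{i}": ("D0", 0.2) for i in range(3)} | {f"b{i}": ("D6", 0.2) for i in range(3)}
        )
        res, _ = tails.test_bin_fraction_change(prof, "D0", "D6")
        assert res.iloc[0]["p_value"] == 1.0
        assert not res.iloc[0]["significant"]
        assert res.iloc[0]["degenerate"]

    def test_constant_but_different_degenerate_p_zero(self):
        prof = _profiles_from_fractions(
            {f"a{i}": ("D0", 0.2) for i in range(3)} | {f"b{i}": ("D6", 0.4) for i in range(3)}
        )
        res, _ = tails.test_bin_fraction_change(prof, "D0", "D6")
        assert res.iloc[0]["p_value"] == 0.0 and res.iloc[0]["degenerate"]

    def test_single_replicate_skipped_with_reason(self):
        prof = _profiles_from_fractions(
            {"a0": ("D0", 0.2)} | {f"b{i}": ("D6", 0.3 + 0.01 * i) for i in range(3)}
        )
        res, skipped = tails.test_bin_fraction_change(prof, "D0", "D6")
        assert res.empty
        assert len(skipped) == 1 and "replicates" in skipped.iloc[0]["reason"]

    def test_unknown_bin_rejected(self):
        with pytest.raises(ValueError, match="bin"):
            tails.test_bin_fraction_change(_profiles_from_fractions({}), "D0", "D6", bin="gt90x")

    def test_monotone_response_to_weight_transfer(self):
        """A larger simulated w120->w60 transfer gives a larger median delta."""
        from tailtop.synthetic import SimulationConfig, simulate_tail_reads, simulate_transcriptome

        medians = []
        for transfer in (0.1, 0.3):
            cfg = SimulationConfig(
                n_transcripts=60,
                top_fraction=1.0,
                excluded_fraction=0.0,
                conditions=("D0", "D2"),
                top_w120_to_w60=transfer,
                top_w60_to_short=0.0,
                depth=200.0,
            )
            truth = simulate_transcriptome(cfg, 1)
            reads = pd.concat(
                [
                    simulate_tail_reads(truth, c, seed=i, as_frame=True)
                    for i, c in enumerate(("D0", "D2"))
                ]
            )
            prof = tails.build_tail_profiles(reads, min_reads=30)
            res, _ = tails.test_bin_fraction_change(prof, "D0", "D2", bin="about60")
            medians.append(res["delta"].median())
        assert medians[1] > medians[0] > 0
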