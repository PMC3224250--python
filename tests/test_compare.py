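"""Paired statistics oracles and the end-to-end cohort pipeline."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from coldcore import compare, experiments, synthetic


def oracle_paired_t(d):
    """Textbook formula, evaluated independently."""
    d = np.asarray(d, dtype=float)
    n = d.size
    mean = d.sum() / n
    var = ((d - mean) ** 2).sum() / (n - 1)
    t = mean / math.sqrt(var / n)
    p = 2 * (1 - sps.t.cdf(abs(t), n - 1))
    return t, p


def oracle_binomial_two_sided(k, n):
    """Exact two-sided binomial p at p0 = 1/2 by direct enumeration."""
    pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
    return sum(p for p in pmf if p <= pmf[k] * (1 + 1e-12))


class TestPairedT:
    def test_matches_oracle_on_random_inputs(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 25))
            d = rng.normal(0, 2, n).round(4)
            if np.std(d, ddof=1) == 0:
                continue
            res = compare.paired_t(d)
            t, p = oracle_paired_t(d)
            assert res.t == pytest.approx(t, rel=1e-10)
            assert res.p == pytest.approx(p, rel=1e-8, abs=1e-12)
            assert res.df == n - 1

    def test_hand_example(self):
        res = compare.paired_t([2, -1, 3, 0, 1])
        t, p = oracle_paired_t([2, -1, 3, 0, 1])
        assert res.t == pytest.approx(t) and res.p == pytest.approx(p)

    def test_zero_variance_is_degenerate(self):
        res = compare.paired_t([1.0] * 5)
        assert res.degenerate and res.p is None and res.mean_diff == 1.0

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            compare.paired_t([1.0, 2.0])


class TestSignBinomial:
    def test_eleven_of_fourteen(self):
        d = [1] * 11 + [-1] * 3
        res = compare.sign_binomial(d)
        # One-sided: P(X >= 11 | 14, ½) = 470/16384 ≈ 0.0287
        assert res.p_one_sided == pytest.approx(470 / 16384)
        assert res.p_two_sided == pytest.approx(oracle_binomial_two_sided(11, 14))

    def test_balanced_split_gives_one(self):
        res = compare.sign_binomial([1] * 7 + [-1] * 7)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_unanimous_gives_closed_form(self):
        res = compare.sign_binomial([1] * 14)
        assert res.p_two_sided == pytest.approx(2 * 0.5**14)
        assert res.p_one_sided == pytest.approx(0.5**14)

    def test_ties_dropped_and_all_ties_flagged(self):
        res = compare.sign_binomial([0.0, 0.0, 1.0])
        assert res.n_informative == 1
        allt = compare.sign_binomial([0.0, 0.0])
        assert allt.all_ties and allt.p_two_sided is None

    def test_matches_scipy_on_random_inputs(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 30))
            d = rng.choice([-1.0, 1.0], n)
            res = compare.sign_binomial(d)
            k = int((d > 0).sum())
            assert res.p_two_sided == pytest.approx(
                oracle_binomial_two_sided(k, n), rel=1e-10
            )


class TestPearsonR2:
    def test_perfect_line(self):
        x = np.arange(10.0)
        assert compare.pearson_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_hand_table_matches_formula(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        sx, sy = x - x.mean(), y - y.mean()
        r = (sx * sy).sum() / math.sqrt((sx**2).sum() * (sy**2).sum())
        assert compare.pearson_r2(x, y) == pytest.approx(r * r, rel=1e-12)

    def test_independent_samples_near_zero(self, rng):
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        assert compare.pearson_r2(x, y) < 0.01

    def test_zero_variance_absent(self):
        assert compare.pearson_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) is None


class TestTypeIControl:
    def test_rate_close_to_alpha(self):
        res = experiments.null_type1_rate(n_seeds=600, alpha=0.05, seed=3)
        assert abs(res["rate"] - 0.05) < 3 * math.sqrt(0.05 * 0.95 / 600)


class TestRunCohort:
    @pytest.fixture(scope="class")
    @staticmethod
    def cohort_result():
        spec = synthetic.CohortSpec(n_pairs=20, seed=42)
        pairs, _ = synthetic.make_cohort(spec)
        config = compare.CohortConfig(probes=(0.6, 1.4), include_pockets=True)
        return compare.run_cohort(experiments.cohort_entries(pairs), config)

    def test_all_pairs_survive(self, cohort_result):
        assert len(cohort_result.pair_table) == 20
        assert cohort_result.rejected == [] and cohort_result.skipped == []

    def test_cavity_effect_flagged_at_water_probe_only(self, cohort_result):
        stats_ = cohort_result.stats_table.set_index("metric")
        assert bool(stats_.loc["d_vol_per_cav_1.4", "significant"])
        assert stats_.loc["d_vol_per_cav_1.4", "mean_diff"] > 0
        assert not bool(stats_.loc["d_vol_per_cav_0.6", "significant"])

    def test_acidic_wall_bias_detected(self, cohort_result):
        stats_ = cohort_result.stats_table.set_index("metric")
        assert bool(stats_.loc["d_freq_acidic", "significant"])
        assert stats_.loc["d_freq_acidic", "mean_diff"] > 0
        # the bias is taken from the hydrophobic share
        assert stats_.loc["d_freq_hydrophobic", "mean_diff"] < 0

    def test_buried_water_excess_detected(self, cohort_result):
        stats_ = cohort_result.stats_table.set_index("metric")
        assert bool(stats_.loc["d_buried_waters", "significant"])
        assert stats_.loc["d_buried_waters", "mean_diff"] > 0

    def test_flexible_classes_positive_in_ss_table(self, cohort_result):
        ss = cohort_result.ss_table.set_index("ss_class")
        for cls in ("E", "I"):
            assert ss.loc[cls, "mean_delta"] > 0
            assert ss.loc[cls, "p"] < 0.01

    def test_buried_r2_reflects_shared_pair_base(self, cohort_result):
        assert 0.3 < cohort_result.buried_r2 <= 1.0

    def test_report_roundtrips_through_csv(self, cohort_result, tmp_path):
        cohort_result.write(tmp_path)
        import pandas as pd

        back = pd.read_csv(tmp_path / "pairs.csv")
        d = back["d_buried_waters"].to_numpy(dtype=float)
        res = compare.paired_t(d)
        stats_ = cohort_result.stats_table.set_index("metric")
        assert res.p == pytest.approx(stats_.loc["d_buried_waters", "p_t"])
        assert res.mean_diff == pytest.approx(
            stats_.loc["d_buried_waters", "mean_diff"]
        )

    def test_run_is_deterministic(self):
        spec = synthetic.CohortSpec(n_pairs=2, seed=8)
        config = compare.CohortConfig(probes=(1.4,), include_pockets=False)
        results = []
        for _ in range(2):
            pairs, _ = synthetic.make_cohort(spec)
            results.append(
                compare.run_cohort(experiments.cohort_entries(pairs), config)
            )
        assert results[0].pair_table.equals(results[1].pair_table)
        assert results[0].structure_table.equals(results[1].structure_table)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            compare.run_cohort([])

    def test_unacceptable_pair_is_logged(self):
        spec = synthetic.CohortSpec(n_pairs=2, seed=5)
        pairs, _ = synthetic.make_cohort(spec)
        pairs[0].psy.resolution = 3.2  # fails the resolution gate
        config = compare.CohortConfig(probes=(1.4,), include_pockets=False)
        result = compare.run_cohort(experiments.cohort_entries(pairs), config)
        assert len(result.pair_table) == 1
        assert result.rejected[0][0] == pairs[0].pair_id


class TestConfig:
    def test_from_yaml(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text("probes: [0.6, 1.4]\nalpha: 0.05\ngrid_spacing: 0.4\n")
        cfg = compare.CohortConfig.from_yaml(path)
        assert cfg.probes == (0.6, 1.4)
        assert cfg.alpha == 0.05
        assert cfg.grid_spacing == 0.4
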