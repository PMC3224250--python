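"""B-value outlier filter, normalization, ΔB′, and per-class stratification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldcore import bflex, synthetic
from coldcore.pairing import PairAlignment
from coldcore.structure_io import SSAnnotation


def brute_force_outliers(values):
    """Independent re-evaluation of the modified z-score rule, scalar by scalar."""
    values = list(values)
    srt = sorted(values)
    n = len(srt)
    med = (srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2.0)
    devs = sorted(abs(v - med) for v in values)
    mad = (devs[n // 2] if n % 2 else (devs[n // 2 - 1] + devs[n // 2]) / 2.0)
    if mad == 0:
        return [False] * n, True
    return [0.6745 * abs(v - med) / mad > 3.5 for v in values], False


def identity_alignment(n):
    return PairAlignment("", "", [(i, i) for i in range(n)], 100.0)


def keyed(profile):
    profile.residue_keys = [("A", i + 1, "") for i in range(len(profile))]
    return profile


class TestDetectOutliers:
    def test_worked_example_flags_only_the_extreme_value(self):
        # median 12, MAD 2 -> M(100) = 0.6745*88/2 ≈ 29.7 > 3.5, all others <= 1.35
        mask, degenerate = bflex.detect_outliers([8, 10, 12, 14, 100])
        assert not degenerate
        assert mask.tolist() == [False, False, False, False, True]

    @pytest.mark.parametrize("values", [[7, 7, 7, 7, 7], [10, 10, 10, 11]])
    def test_mad_zero_is_degenerate_and_flags_nothing(self, values):
        mask, degenerate = bflex.detect_outliers(values)
        assert degenerate
        assert not mask.any()

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError):
            bflex.detect_outliers([1, 2, 3])

    def test_matches_brute_force_on_random_profiles(self, rng):
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            x = rng.gamma(2.0, 10.0, n).round(3)
            if rng.random() < 0.2:  # salt with gross outliers
                x[rng.integers(n)] *= 8
            mask, degenerate = bflex.detect_outliers(x)
            exp_mask, exp_degenerate = brute_force_outliers(x)
            assert degenerate == exp_degenerate
            assert mask.tolist() == exp_mask

    @given(st.permutations(list(range(8))))
    @settings(deadline=None, max_examples=50)
    def test_permutation_equivariance(self, perm):
        base = np.array([8.0, 9.0, 11.0, 12.0, 13.0, 15.0, 16.0, 90.0])
        mask, _ = bflex.detect_outliers(base)
        pmask, _ = bflex.detect_outliers(base[perm])
        assert pmask.tolist() == mask[perm].tolist()


class TestNormalizeB:
    def test_printed_form_divides_by_mean_square(self):
        prof = bflex.normalize_b([1.0, 2.0, 3.0], np.zeros(3, dtype=bool))
        assert prof.norm_constant == pytest.approx(14.0 / 3.0)
        np.testing.assert_allclose(prof.normalized, [3 / 14, 6 / 14, 9 / 14])

    def test_outlier_excluded_from_constant_but_still_scored(self):
        mask = np.array([False, False, False, True])
        prof = bflex.normalize_b([2.0, 2.0, 2.0, 100.0], mask)
        assert prof.norm_constant == pytest.approx(4.0)
        assert prof.normalized[3] == pytest.approx(25.0)
        assert prof.outlier_mask[3]

    def test_printed_form_is_not_scale_invariant(self):
        a = bflex.normalize_b([5.0, 10.0, 15.0], np.zeros(3, dtype=bool))
        b = bflex.normalize_b([10.0, 20.0, 30.0], np.zeros(3, dtype=bool))
        # Doubling B halves B' under the printed equation.
        np.testing.assert_allclose(b.normalized, a.normalized / 2.0)

    def test_zscore_mode_centers_and_scales(self):
        prof = bflex.normalize_b(
            [10.0, 20.0, 30.0, 40.0], np.zeros(4, dtype=bool), mode="zscore"
        )
        assert prof.normalized.mean() == pytest.approx(0.0, abs=1e-12)
        assert prof.normalized.std(ddof=1) == pytest.approx(1.0)

    def test_all_outliers_rejected(self):
        with pytest.raises(bflex.DegenerateProfileError):
            bflex.normalize_b([1.0, 2.0], np.ones(2, dtype=bool))


class TestDeltaB:
    def test_identical_profiles_give_zero(self):
        prof = keyed(bflex.normalize_b([10.0, 12.0, 14.0, 16.0]))
        delta = bflex.delta_b(prof, prof, identity_alignment(4))
        np.testing.assert_array_equal(delta.delta, np.zeros(4))

    def test_uniform_shift_propagates(self):
        psy = keyed(bflex.normalize_b([10.0, 12.0, 14.0, 16.0]))
        mes = keyed(bflex.normalize_b([10.0, 12.0, 14.0, 16.0]))
        psy.normalized = psy.normalized + 0.25
        delta = bflex.delta_b(psy, mes, identity_alignment(4))
        np.testing.assert_allclose(delta.delta, 0.25)

    def test_gap_positions_are_absent(self):
        psy = keyed(bflex.normalize_b([10.0, 12.0, 14.0, 16.0, 18.0]))
        mes = keyed(bflex.normalize_b([10.0, 12.0, 14.0, 16.0]))
        aln = PairAlignment("", "", [(0, 0), (1, 1), (3, 2), (4, 3)], 80.0)
        delta = bflex.delta_b(psy, mes, aln)
        assert len(delta) == 4

    def test_outlier_positions_are_dropped(self):
        psy = keyed(bflex.normalize_b([10.0, 12.0, 14.0, 16.0, 500.0]))
        mes = keyed(bflex.normalize_b([10.0, 12.0, 14.0, 16.0, 18.0]))
        assert psy.outlier_mask[4]
        delta = bflex.delta_b(psy, mes, identity_alignment(5))
        assert len(delta) == 4

    def test_antisymmetry(self, rng):
        a = keyed(bflex.normalize_b(rng.gamma(2.0, 10.0, 30)))
        b = keyed(bflex.normalize_b(rng.gamma(2.0, 10.0, 30)))
        aln = identity_alignment(30)
        fwd = bflex.delta_b(a, b, aln)
        rev = bflex.delta_b(b, a, aln)
        np.testing.assert_allclose(fwd.delta, -rev.delta)


class TestStratifyBySS:
    def _delta_with_ss(self, ss_string, deltas):
        n = len(ss_string)
        delta = bflex.DeltaBProfile(
            delta=np.asarray(deltas, dtype=float),
            psy_keys=[("A", i + 1, "") for i in range(n)],
            mes_keys=[("A", i + 1, "") for i in range(n)],
        )
        ss = SSAnnotation({("A", i + 1, ""): ss_string[i] for i in range(n)})
        return delta, ss

    def test_counts_conserve_scored_positions(self):
        delta, ss = self._delta_with_ss("HHHEEETT-", np.arange(9) * 0.01)
        table = bflex.stratify_by_ss(delta, ss)
        assert table["n"].sum() == 9
        assert set(table["ss_class"]) == {"H", "E", "T", "-"}

    def test_all_zero_deltas_show_no_effect(self):
        delta, ss = self._delta_with_ss("HHHHEEEE", np.zeros(8))
        table = bflex.stratify_by_ss(delta, ss)
        assert (table["mean_delta"] == 0).all()
        assert table["p"].isna().all()  # zero variance -> test suppressed

    def test_sparse_class_suppresses_test(self):
        delta, ss = self._delta_with_ss("HHHHHHI", [0.1, 0.2, 0.1, 0.3, 0.2, 0.1, 0.5])
        table = bflex.stratify_by_ss(delta, ss).set_index("ss_class")
        assert np.isnan(table.loc["I", "p"])
        assert not np.isnan(table.loc["H", "p"])

    def test_planted_strand_shift_detected_across_seeds(self):
        """Strand-shifted members show class E above class H in ΔB′, and a
        significantly positive strand mean at cohort scale."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ss_string = synthetic.random_ss_string(200, rng)
            b_mes, _ = synthetic.plant_b_profile(ss_string, None, 2.0, 0.0, seed=seed)
            b_psy, _ = synthetic.plant_b_profile(
                ss_string, {"E": 4.0}, 2.0, 0.0, seed=seed + 10_000
            )
            psy = keyed(bflex.normalize_b(b_psy))
            mes = keyed(bflex.normalize_b(b_mes))
            delta = bflex.delta_b(psy, mes, identity_alignment(200))
            ss = SSAnnotation(
                {("A", i + 1, ""): ss_string[i] for i in range(200)}
            )
            table = bflex.stratify_by_ss(delta, ss).set_index("ss_class")
            if "E" in table.index and "H" in table.index:
                if table.loc["E", "mean_delta"] > table.loc["H", "mean_delta"]:
                    wins += 1
        assert wins >= 95

    def test_delta_table_has_one_row_per_position(self):
        delta, ss = self._delta_with_ss("HHEE", [0.1, -0.1, 0.2, 0.3])
        table = bflex.delta_table(delta, ss)
        assert len(table) == 4
        assert table["ss"].tolist() == ["H", "H", "E", "E"]
        assert table["delta_b"].tolist() == [0.1, -0.1, 0.2, 0.3]

    def test_ss_mismatch_rate(self):
        delta, ss_psy = self._delta_with_ss("HHEE", np.zeros(4))
        ss_mes = SSAnnotation({("A", i + 1, ""): "H" for i in range(4)})
        assert bflex.ss_mismatch_rate(delta, ss_psy, ss_mes) == pytest.approx(0.5)
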