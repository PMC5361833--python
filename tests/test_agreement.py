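"""Agreement statistics: Bland-Altman, Pitman, 4-quadrant, polar,
zero-zone, AAMI verdict, and the model/results surface."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnibp.agreement import (MethodComparison, aami_verdict, bland_altman,
                             consecutive_changes, four_quadrant,
                             pearson_and_normality, pitman_test, polar_trend,
                             zero_zone_aami)


class TestBlandAltman:
    def test_identical_series(self):
        r = bland_altman([100, 110, 120], [100, 110, 120])
        assert r.bias_mmhg == 0.0 and r.sd_mmhg == 0.0

    def test_hand_computed_two_pairs(self):
        """(100,102),(110,108): differences +2,-2 -> bias 0, SD sqrt(8)."""
        r = bland_altman([100, 110], [102, 108])
        assert r.bias_mmhg == pytest.approx(0.0)
        assert r.sd_mmhg == pytest.approx(np.sqrt(8.0))
        assert r.loa_upper_mmhg == pytest.approx(1.96 * np.sqrt(8.0))

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([100], [101])

    @given(st.lists(st.tuples(st.floats(60, 200), st.floats(-30, 30)),
                    min_size=2, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_oracle(self, pairs):
        ref = np.array([p[0] for p in pairs])
        test = ref + np.array([p[1] for p in pairs])
        r = bland_altman(ref, test)
        d = test - ref
        mean = sum(d) / len(d)  # one-pass brute force
        var = sum((x - mean) ** 2 for x in d) / (len(d) - 1)
        assert r.bias_mmhg == pytest.approx(mean, abs=1e-9)
        assert r.sd_mmhg == pytest.approx(np.sqrt(var), abs=1e-9)

    def test_monte_carlo_recovery(self):
        """Differences ~ N(mu, sigma) at the study's n: estimated bias and
        SD recover the generator values within 3 standard errors."""
        mu, sigma, n = -0.57, 7.34, 3870
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ref = rng.normal(120, 15, n)
            r = bland_altman(ref, ref + rng.normal(mu, sigma, n))
            se_bias = sigma / np.sqrt(n)
            se_sd = sigma / np.sqrt(2 * (n - 1))
            assert abs(r.bias_mmhg - mu) < 3 * se_bias
            assert abs(r.sd_mmhg - sigma) < 3 * se_sd


class TestPearsonAndPitman:
    def test_perfect_correlation(self):
        out = pearson_and_normality([1, 2, 3, 4.0], [1, 2, 3, 4.0])
        assert out["r"] == pytest.approx(1.0)
        out = pearson_and_normality([1, 2, 3, 4.0], [-1, -2, -3, -4.0])
        assert out["r"] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        out = pearson_and_normality([1, 1, 1.0], [1, 2, 3.0])
        assert out["degenerate"] and np.isnan(out["r"])

    def test_attenuation_matches_closed_form(self):
        """test = ref + N(0, sd(ref)/3): r -> 1/sqrt(1 + 1/9)."""
        target = 1.0 / np.sqrt(1 + 1 / 9)
        rs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            ref = rng.normal(120, 15, 2000)
            rs.append(pearson_and_normality(ref, ref + rng.normal(0, 5, 2000))["r"])
        assert abs(np.mean(rs) - target) < 0.01

    def test_pitman_equal_variance_shift(self):
        ref = np.array([100, 105, 111, 120, 130.0])
        out = pitman_test(ref, ref + 7.0)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_pitman_detects_variance_inflation(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(100, 10, 100)
        out = pitman_test(ref, 2 * ref)
        assert out["statistic"] > 0.5
        assert out["p"] < 1e-6

    def test_pitman_type_one_error(self):
        """Under equal variances the rejection rate at alpha=0.05 is ~5%."""
        rej = 0
        reps = 1000
        rng = np.random.default_rng(7)
        for _ in range(reps):
            x = rng.normal(0, 1, (2, 50))
            x[1] = 0.5 * x[0] + np.sqrt(1 - 0.25) * x[1]  # correlated pairs
            if pitman_test(x[0], x[1])["p"] < 0.05:
                rej += 1
        assert abs(rej / reps - 0.05) < 0.02


def _ch(pairs):
    return pd.DataFrame(pairs, columns=["d_ref", "d_test"])


class TestFourQuadrant:
    def test_perfect_concordance(self):
        ch = _ch([(5, 5), (-4, -4), (2, 2), (8, 8)])
        assert four_quadrant(ch, zone_mmhg=1.0)["concordance"] == 1.0

    def test_enumerated_example_zone_1(self):
        ch = _ch([(5, 6), (-4, -3), (2, -2)])
        out = four_quadrant(ch, zone_mmhg=1.0)
        assert out["concordance"] == pytest.approx(2 / 3)

    def test_enumerated_example_zone_3(self):
        ch = _ch([(5, 6), (-4, -3), (2, -2)])
        out = four_quadrant(ch, zone_mmhg=3.0)
        assert out["concordance"] == 1.0
        assert out["n_excluded"] == 1

    def test_all_excluded_flagged(self):
        out = four_quadrant(_ch([(0.1, 0.1)]), zone_mmhg=5.0)
        assert out["undefined"] and np.isnan(out["concordance"])

    def test_device_swap_invariance(self):
        rng = np.random.default_rng(3)
        ch = _ch(list(zip(rng.normal(0, 8, 50), rng.normal(0, 8, 50))))
        sw = _ch(list(zip(ch["d_test"], ch["d_ref"])))
        a, b = four_quadrant(ch, 5.0), four_quadrant(sw, 5.0)
        assert a["concordance"] == b["concordance"]
        pa, pb = polar_trend(ch, 5.0), polar_trend(sw, 5.0)
        assert pa.mean_polar_bias_deg == pytest.approx(-pb.mean_polar_bias_deg)
        assert pa.boundary_95_deg == pytest.approx(pb.boundary_95_deg)

    def test_cap_mode(self):
        ch = _ch([(5, 6), (2, 1)])
        assert four_quadrant(ch, 3.0, mode="cap")["n_excluded"] == 1

    @given(st.lists(st.tuples(st.floats(-20, 20), st.floats(-20, 20)),
                    min_size=1, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_enumeration(self, pairs):
        ch = _ch(pairs)
        out = four_quadrant(ch, zone_mmhg=4.0)
        kept = [(a, b) for a, b in pairs if (abs(a) + abs(b)) / 2 >= 4.0]
        if not kept:
            assert out["undefined"]
        else:
            expect = sum(np.sign(a) == np.sign(b) for a, b in kept) / len(kept)
            assert out["concordance"] == pytest.approx(expect)


class TestPolarTrend:
    def test_identity_line_angle(self):
        out = polar_trend(_ch([(10, 10)]), zone_mmhg=1.0)
        assert out.mean_polar_bias_deg == pytest.approx(0.0)

    def test_pure_reference_change_angle(self):
        out = polar_trend(_ch([(10, 0)]), zone_mmhg=1.0)
        assert out.mean_polar_bias_deg == pytest.approx(-45.0)

    def test_enumerated_boundaries(self):
        """Angles {-10, 0, +10} degrees: zero bias, 95% boundary 10 deg."""
        d = np.array([10.0, 10.0, 10.0])
        t = d * np.tan(np.radians(np.array([-10.0, 0.0, 10.0]) + 45.0))
        out = polar_trend(_ch(list(zip(d, t))), zone_mmhg=1.0)
        assert out.mean_polar_bias_deg == pytest.approx(0.0, abs=1e-9)
        assert out.boundary_95_deg == pytest.approx(10.0, abs=1e-6)
        assert out.boundary_90_deg <= out.boundary_95_deg

    def test_exclusion_zone(self):
        out = polar_trend(_ch([(10, 10), (0.5, 0.5)]), zone_mmhg=2.0)
        assert out.n_retained == 1 and out.n_excluded == 1


class TestZeroZone:
    def test_reading_inside_zone_scores_zero(self):
        """Reference window mean 120, SD 4 -> zone [116, 124]; 118 -> 0."""
        ref_t = np.arange(-30, 31, 10.0)
        # mean 120, sample SD exactly 4 -> zone [116, 124]
        ref_v = np.array([124.0, 116, 124, 116, 124, 116, 120])
        assert np.mean(ref_v) == 120.0 and np.std(ref_v, ddof=1) == 4.0
        out = zero_zone_aami([0.0], [118.0], ref_t, ref_v, quantity="sbp")
        assert out.diffs_mmhg[0] == 0.0
        out = zero_zone_aami([0.0], [130.0], ref_t, ref_v, quantity="sbp")
        assert out.diffs_mmhg[0] == pytest.approx(130.0 - 124.0)
        out = zero_zone_aami([0.0], [110.0], ref_t, ref_v, quantity="sbp")
        assert out.diffs_mmhg[0] == pytest.approx(110.0 - 116.0)

    def test_wide_reference_range_excluded(self):
        """Systolic reference window spanning 25 mmHg (> 20) is excluded."""
        ref_t = np.arange(-30, 31, 10.0)
        ref_v = np.linspace(110, 135, len(ref_t))
        out = zero_zone_aami([0.0], [120.0], ref_t, ref_v, quantity="sbp")
        assert out.n_excluded_reference == 1 and out.n_readings == 0

    def test_diastolic_threshold_12(self):
        ref_t = np.arange(-30, 31, 10.0)
        ref_v = np.linspace(70, 83, len(ref_t))  # range 13 > 12
        out = zero_zone_aami([0.0], [75.0], ref_t, ref_v, quantity="dbp")
        assert out.n_excluded_reference == 1
        ref_v = np.linspace(70, 81, len(ref_t))  # range 11 <= 12
        out = zero_zone_aami([0.0], [75.0], ref_t, ref_v, quantity="dbp")
        assert out.n_readings == 1

    def test_adjusted_never_exceeds_raw_difference(self):
        rng = np.random.default_rng(2)
        ref_t = np.arange(0, 600, 10.0)
        ref_v = 120 + rng.normal(0, 3, len(ref_t))
        times = np.arange(40, 560, 10.0)
        readings = 120 + rng.normal(0, 6, len(times))
        out = zero_zone_aami(times, readings, ref_t, ref_v, quantity="sbp")
        for t, x, d in zip(times, readings, out.diffs_mmhg):
            sel = (ref_t >= t - 30) & (ref_t <= t + 30)
            assert abs(d) <= abs(x - ref_v[sel].mean()) + 1e-9

    def test_unknown_quantity_rejected(self):
        with pytest.raises(ValueError):
            zero_zone_aami([0.0], [90.0], [0.0], [90.0], quantity="map")


class TestAamiVerdict:
    @pytest.mark.parametrize("bias,sd,passed", [
        (-0.57, 7.34, True),   # reported systolic values vs 5/8 limits
        (-2.52, 6.47, True),
        (1.01, 5.33, True),
        (5.1, 4.0, False),     # bias just over
        (0.0, 8.0, True),      # inclusive boundary
        (5.0, 8.0, True),
        (0.0, 8.01, False),
    ])
    def test_limits(self, bias, sd, passed):
        assert aami_verdict(bias, sd).passed is passed

    def test_margins(self):
        v = aami_verdict(-0.57, 7.34)
        assert v.bias_margin_mmhg == pytest.approx(5 - 0.57)
        assert v.sd_margin_mmhg == pytest.approx(8 - 7.34)


class TestConsecutiveChanges:
    def test_gaps_not_bridged(self):
        ch = consecutive_changes([100, 105, 111], [100, 104, 112],
                                 times=[0, 10, 30], interval_s=10.0)
        assert len(ch) == 1  # the 10->30 jump is a gap


@pytest.fixture(scope="module")
def results():
    rng = np.random.default_rng(0)
    n = 120
    t = np.arange(n) * 10.0
    sbp = 120 + np.cumsum(rng.normal(0, 2, n))
    data = pd.DataFrame({
        "interval_start_s": t,
        "ref_sbp": sbp, "ref_dbp": sbp - 40, "ref_map": sbp - 40 + 40 / 3,
        "test_sbp": sbp + rng.normal(0.5, 2, n),
        "test_dbp": sbp - 40 + rng.normal(0, 2, n),
        "test_map": sbp - 40 + 40 / 3 + rng.normal(0, 2, n),
    })
    return MethodComparison(data).fit()


class TestModelResults:
    def test_quantities_present(self, results):
        for q in ("sbp", "dbp", "map"):
            e = results[q]
            assert e["bland_altman"].n == 120
            assert "r" in e["pearson"] and e["pitman"] is not None
            assert e["aami"].passed in (True, False)

    def test_summary_renders(self, results):
        s = results.summary()
        assert "SBP" in s and "AAMI" in s and "bias" in s

    def test_json_round_trip(self, results, tmp_path):
        import json
        p = tmp_path / "r.json"
        results.to_json(p)
        raw = json.loads(p.read_text())
        assert set(raw["quantities"]) == {"sbp", "dbp", "map"}

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            MethodComparison(pd.DataFrame({"interval_start_s": [0.0]}))
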