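"""5PL standard curves, censoring, fold changes and the D statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microperm.cooperativity import (
    FivePLFitError,
    StandardCurve,
    compute_cooperativity_D,
    compute_log2fc,
    fit_five_pl,
    five_pl,
    impute_censoring,
    invert_five_pl,
    log2fc_matrix,
)

CURVE = StandardCurve(a=0.0, b=1.0, c=100.0, d=10000.0, g=1.0, lloq_pg_ml=1.0, uloq_pg_ml=5000.0)


def _table(rows):
    return pd.DataFrame(
        rows, columns=["analyte", "condition", "concentration_pg_ml", "censor", "replicate"]
    )


def three_condition_table(analyte, mvn, sph, co, censor="none"):
    return _table(
        [
            (analyte, "MVN", mvn, "none", 1),
            (analyte, "Spheroids", sph, censor, 1),
            (analyte, "MVN_plus_Spheroids", co, "none", 1),
        ]
    )


class TestFivePL:
    def test_midpoint_at_inflection_when_symmetric(self):
        assert five_pl(CURVE.c, CURVE) == pytest.approx((CURVE.a + CURVE.d) / 2)

    def test_lower_asymptote(self):
        assert five_pl(0.0, CURVE) == pytest.approx(CURVE.a)

    def test_hand_evaluation(self):
        assert five_pl(100.0, CURVE) == pytest.approx(5000.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            five_pl(-1.0, CURVE)

    def test_strictly_monotone_on_range(self):
        x = np.geomspace(0.1, 10000.0, 200)
        y = five_pl(x, CURVE)
        assert (np.diff(y) > 0).all()


class TestInversion:
    def test_hand_inversion(self):
        x, flag = invert_five_pl(5000.0, CURVE)
        assert x == pytest.approx(100.0, rel=1e-12)
        assert flag == "none"

    @pytest.mark.parametrize("x", np.geomspace(1.0, 5000.0, 9).tolist())
    def test_round_trip_on_dynamic_range(self, x):
        back, flag = invert_five_pl(five_pl(x, CURVE), CURVE)
        assert back == pytest.approx(x, rel=1e-9)
        if CURVE.lloq_pg_ml < x < CURVE.uloq_pg_ml:
            assert flag == "none"  # range endpoints themselves carry the bound flag

    def test_low_response_censored_at_lloq(self):
        y_low = five_pl(CURVE.lloq_pg_ml, CURVE) * 0.5
        x, flag = invert_five_pl(y_low, CURVE)
        assert (x, flag) == (CURVE.lloq_pg_ml, "below_lloq")

    def test_response_at_upper_asymptote_censored_not_nan(self):
        x, flag = invert_five_pl(CURVE.d, CURVE)
        assert (x, flag) == (CURVE.uloq_pg_ml, "above_uloq")

    def test_decreasing_curve_orientation(self):
        dec = StandardCurve(a=10000.0, b=1.0, c=100.0, d=0.0, g=1.0,
                            lloq_pg_ml=1.0, uloq_pg_ml=5000.0)
        x, flag = invert_five_pl(five_pl(50.0, dec), dec)
        assert x == pytest.approx(50.0, rel=1e-9)
        assert flag == "none"


class TestFitFivePL:
    GEN = StandardCurve(a=0.0, b=1.2, c=80.0, d=10000.0, g=0.9,
                        lloq_pg_ml=1.0, uloq_pg_ml=5000.0)

    def _assert_recovers(self, fit, rel=1e-4):
        span = abs(self.GEN.d - self.GEN.a)
        for p in "abcdg":
            true, est = getattr(self.GEN, p), getattr(fit, p)
            assert est == pytest.approx(true, rel=rel, abs=rel * span if true == 0 else 0)

    def test_noiseless_parameter_recovery(self):
        x = np.geomspace(1.0, 5000.0, 8)
        fit = fit_five_pl(x, five_pl(x, self.GEN))
        self._assert_recovers(fit)

    def test_replication_invariance(self):
        x = np.geomspace(1.0, 5000.0, 8)
        y = five_pl(x, self.GEN)
        single = fit_five_pl(x, y)
        dup = fit_five_pl(np.repeat(x, 2), np.repeat(y, 2))
        for p in "abcdg":
            assert getattr(dup, p) == pytest.approx(getattr(single, p), rel=1e-6)

    def test_noisy_midpoint_recovery(self):
        # 5% CV response noise over 20 seeds: the midpoint EC50 is the
        # identifiable location parameter (b/c/g trade off individually)
        x = np.geomspace(1.0, 5000.0, 8)
        y = five_pl(x, self.GEN)
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = y * (1.0 + 0.05 * rng.standard_normal(len(y)))
            try:
                fit = fit_five_pl(x, noisy)
            except FivePLFitError:
                continue
            errs.append(abs(fit.ec50_pg_ml - self.GEN.ec50_pg_ml) / self.GEN.ec50_pg_ml)
        assert np.median(errs) < 0.10

    def test_too_few_levels_rejected(self):
        x = np.geomspace(1.0, 5000.0, 5)
        with pytest.raises(FivePLFitError, match="6 calibrator"):
            fit_five_pl(x, five_pl(x, self.GEN))

    def test_non_monotone_calibrators_rejected(self):
        x = np.geomspace(1.0, 5000.0, 8)
        y = five_pl(x, self.GEN)
        y[3], y[4] = y[4] * 2, y[3]
        with pytest.raises(FivePLFitError, match="monotone"):
            fit_five_pl(x, y)

    def test_lloq_uloq_default_to_calibrator_range(self):
        x = np.geomspace(2.0, 4000.0, 8)
        fit = fit_five_pl(x, five_pl(x, self.GEN))
        assert fit.lloq_pg_ml == pytest.approx(2.0)
        assert fit.uloq_pg_ml == pytest.approx(4000.0)


class TestImputation:
    def test_bound_substitution(self):
        t = _table([("A", "MVN", 1.2, "below_lloq", 1), ("A", "MVN", 9999.0, "above_uloq", 2)])
        out = impute_censoring(t, lloq_pg_ml=3.2, uloq_pg_ml=5000.0)
        assert out["concentration_pg_ml"].tolist() == [3.2, 5000.0]

    def test_half_lloq_option(self):
        t = _table([("A", "MVN", 1.2, "below_lloq", 1)])
        out = impute_censoring(t, lloq_pg_ml=3.2, method="half_lloq")
        assert out["concentration_pg_ml"].iloc[0] == pytest.approx(1.6)

    def test_uncensored_rows_untouched(self):
        t = _table([("A", "MVN", 42.0, "none", 1)])
        out = impute_censoring(t, lloq_pg_ml=3.2, uloq_pg_ml=5000.0)
        assert out["concentration_pg_ml"].iloc[0] == 42.0


class TestLog2FC:
    def test_identity_when_equal(self):
        t = _table([("A", "MVN", 100.0, "none", 1), ("A", "Spheroids", 100.0, "none", 1)])
        fc = compute_log2fc(t, "Spheroids", "MVN")
        assert fc["log2fc"].iloc[0] == 0.0

    def test_hand_arithmetic(self):
        t = _table([("A", "MVN", 100.0, "none", 1), ("A", "Spheroids", 400.0, "none", 1)])
        assert compute_log2fc(t, "Spheroids", "MVN")["log2fc"].iloc[0] == pytest.approx(2.0)

    def test_censored_control_imputed_and_flagged(self):
        t = _table(
            [("A", "MVN", 1.0, "below_lloq", 1), ("A", "Spheroids", 320.0, "none", 1)]
        )
        t = impute_censoring(t, lloq_pg_ml=3.2)
        fc = compute_log2fc(t, "Spheroids", "MVN")
        assert fc["log2fc"].iloc[0] == pytest.approx(np.log2(100.0))
        assert bool(fc["censored"].iloc[0])

    def test_zero_control_is_error(self):
        t = _table([("A", "MVN", 0.0, "none", 1), ("A", "Spheroids", 10.0, "none", 1)])
        with pytest.raises(ValueError, match="pseudo-count"):
            compute_log2fc(t, "Spheroids", "MVN")

    def test_matrix_layout(self):
        t = _table(
            [
                ("A", "MVN", 100.0, "none", 1),
                ("A", "Spheroids", 50.0, "none", 1),
                ("A", "MVN_plus_Spheroids", 400.0, "none", 1),
            ]
        )
        m = log2fc_matrix(t, [("MVN_plus_Spheroids", "MVN"), ("MVN_plus_Spheroids", "Spheroids")])
        assert m.loc["A", "MVN_plus_Spheroids_vs_MVN"] == pytest.approx(2.0)
        assert m.shape == (1, 2)


class TestCooperativityD:
    def test_additive_case(self):
        res = compute_cooperativity_D(three_condition_table("A", 100.0, 50.0, 150.0))
        assert res[0].D == 1.0 and res[0].classification == "additive"

    def test_suppressed_case_is_antagonistic(self):
        res = compute_cooperativity_D(three_condition_table("A", 100.0, 50.0, 100.0))
        assert res[0].D == 0.0 and res[0].classification == "antagonistic"

    def test_supra_additive_case(self):
        res = compute_cooperativity_D(three_condition_table("A", 100.0, 50.0, 250.0))
        assert res[0].D == 3.0 and res[0].classification == "supra_additive"

    def test_missing_condition_undefined_but_pipeline_continues(self):
        t = pd.concat(
            [
                three_condition_table("A", 100.0, 50.0, 150.0),
                _table([("B", "MVN", 10.0, "none", 1), ("B", "MVN_plus_Spheroids", 30.0, "none", 1)]),
            ]
        )
        res = {r.analyte: r for r in compute_cooperativity_D(t)}
        assert res["A"].classification == "additive"
        assert res["B"].classification == "undefined"
        assert "Spheroids" in res["B"].reason

    def test_zero_spheroid_mean_undefined(self):
        res = compute_cooperativity_D(three_condition_table("A", 100.0, 0.0, 150.0))
        assert res[0].classification == "undefined"

    def test_fully_censored_spheroids_undefined(self):
        res = compute_cooperativity_D(
            three_condition_table("A", 100.0, 3.2, 150.0, censor="below_lloq")
        )
        assert res[0].classification == "undefined"

    def test_per_replicate_mode_matches_on_balanced_data(self):
        rows = []
        for rep, (m, s, c) in enumerate([(90, 45, 140), (110, 55, 160)], start=1):
            rows += [
                ("A", "MVN", float(m), "none", rep),
                ("A", "Spheroids", float(s), "none", rep),
                ("A", "MVN_plus_Spheroids", float(c), "none", rep),
            ]
        t = _table(rows)
        means_mode = compute_cooperativity_D(t, mode="condition_means")[0].D
        rep_mode = compute_cooperativity_D(t, mode="per_replicate")[0].D
        assert means_mode == pytest.approx(1.0)
        assert rep_mode == pytest.approx(np.mean([(140 - 90) / 45, (160 - 110) / 55]))

    @settings(derandomize=True, max_examples=50)
    @given(
        c=st.floats(min_value=1e-3, max_value=1e3),
        mvn=st.floats(min_value=1.0, max_value=1e4),
        sph=st.floats(min_value=1.0, max_value=1e4),
        co=st.floats(min_value=0.0, max_value=1e5),
    )
    def test_scale_invariance(self, c, mvn, sph, co):
        base = compute_cooperativity_D(three_condition_table("A", mvn, sph, co))[0].D
        scaled = compute_cooperativity_D(
            three_condition_table("A", c * mvn, c * sph, c * co)
        )[0].D
        assert scaled == pytest.approx(base, rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(
        delta=st.floats(min_value=-50.0, max_value=50.0),
        sph=st.floats(min_value=1.0, max_value=1e3),
    )
    def test_affine_in_coculture_value(self, delta, sph):
        # D(co + δ) − D(co) = δ / Spheroids, exactly
        co = 150.0
        d0 = compute_cooperativity_D(three_condition_table("A", 100.0, sph, co))[0].D
        d1 = compute_cooperativity_D(three_condition_table("A", 100.0, sph, co + delta))[0].D
        assert d1 - d0 == pytest.approx(delta / sph, rel=1e-9, abs=1e-12)
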