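"""Preferendum estimation, uniformity testing, and AICc model comparison."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermoshred.records import ControlTrace, PositionTrace
from thermoshred.specs import DesignSpec, GradientSpec
from thermoshred.synthetic_data import (
    generate_control_traces,
    generate_position_traces,
)
from thermoshred.thermal_preference import (
    AcutePreferendum,
    acute_preferenda,
    aicc,
    akaike_weights_and_average,
    chi_squared_p,
    control_uniformity_test,
    final_preferendum,
    fit_preference_models,
    individual_medians,
    median_selected_temperature,
)


def _trace(temps, ind="x1", acc=15.0):
    return PositionTrace(
        individual_id=ind,
        species="G. pulex",
        sex="M",
        acclimation_c=acc,
        track_id="track1",
        run_time="run001",
        records=[(3.0 * (i + 1), t) for i, t in enumerate(temps)],
    )


class TestMedian:
    @pytest.mark.parametrize(
        "temps, expected",
        [
            ([13.0, 13.0, 13.0], 13.0),
            ([12.0, 13.0, 20.0], 13.0),
            ([10.0, 12.0, 14.0, 30.0], 13.0),  # even n: mean of central pair
        ],
    )
    def test_median_selected_temperature(self, temps, expected):
        assert median_selected_temperature(_trace(temps)) == expected

    @given(st.floats(min_value=4.0, max_value=24.0), st.integers(2, 30))
    def test_constant_trace_median_is_the_constant(self, value, n):
        assert median_selected_temperature(_trace([value] * n)) == value


class TestAcutePreferenda:
    def test_group_mean_and_se(self):
        med = pd.DataFrame(
            {
                "individual_id": ["a", "b", "c"],
                "species": ["G. pulex"] * 3,
                "sex": ["M", "F", "M"],
                "acclimation_c": [15.0] * 3,
                "median_c": [13.0, 14.0, 15.0],
            }
        )
        (ap,) = acute_preferenda(med)
        assert ap.mean_c == 14.0
        assert ap.se_c == pytest.approx(1.0 / np.sqrt(3), abs=1e-9)
        assert ap.n == 3

    def test_singleton_group_has_undefined_se(self):
        med = pd.DataFrame(
            {
                "individual_id": ["a"],
                "species": ["G. pulex"],
                "sex": ["M"],
                "acclimation_c": [15.0],
                "median_c": [14.3],
            }
        )
        (ap,) = acute_preferenda(med)
        assert ap.mean_c == 14.3
        assert ap.se_c is None


class TestFinalPreferendum:
    def _acutes(self, a, b, temps=(5.0, 15.0, 20.0), species="G. pulex"):
        return [
            AcutePreferendum(species, t, a + b * t, 0.3, 30) for t in temps
        ]

    def test_exact_line_intersection(self):
        fp = final_preferendum(self._acutes(12.06, 0.1))
        assert fp.value_c == pytest.approx(12.06 / 0.9, abs=1e-9)
        assert fp.slope == pytest.approx(0.1, abs=1e-9)

    def test_flat_preference_returns_the_intercept(self):
        fp = final_preferendum(self._acutes(14.3, 0.0))
        assert fp.value_c == pytest.approx(14.3, abs=1e-9)

    def test_slope_of_one_diverges(self):
        with pytest.raises(ValueError, match="parallel"):
            final_preferendum(self._acutes(2.0, 1.0))

    def test_shift_equivariance(self):
        base = final_preferendum(self._acutes(12.0, 0.2))
        shifted = [
            AcutePreferendum("G. pulex", ac.acclimation_c + 3.0, ac.mean_c + 3.0, 0.3, 30)
            for ac in self._acutes(12.0, 0.2)
        ]
        fp = final_preferendum(shifted)
        assert fp.slope == pytest.approx(base.slope, abs=1e-9)
        assert fp.value_c == pytest.approx(base.value_c + 3.0, abs=1e-9)


class TestUniformity:
    def test_flat_counts_give_zero_chi2(self, gradient):
        # 15 positions dead-centre in each of the 12 bins
        traces = [
            ControlTrace("c1", "G. pulex", [b * 10.0 + 5.0 for b in range(12)] * 15)
        ]
        res = control_uniformity_test(traces, gradient)
        assert res.chi2 == 0.0 and res.p == 1.0
        assert res.df == 11

    @pytest.mark.parametrize("chi2, p", [(6.93, 0.805), (15.13, 0.176)])
    def test_chi_squared_tail_matches_printed_values(self, chi2, p):
        # inputs are rounded to 2 dp, so match the printed p to ~1e-3
        assert chi_squared_p(chi2, 11) == pytest.approx(p, abs=1e-3)

    def test_single_bin_track_is_trivially_uniform(self):
        g = GradientSpec(bin_width_cm=120.0)
        traces = generate_control_traces(6, 30, g, 0)
        res = control_uniformity_test(traces, g)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_bin_label_invariance_of_chi2(self, gradient, rng):
        traces = generate_control_traces(6, 30, gradient, 17)
        res = control_uniformity_test(traces, gradient)
        counts = res.counts
        perm = rng.permutation(counts)
        expected = counts.sum() / counts.size
        chi2_perm = float(np.sum((perm - expected) ** 2) / expected)
        assert chi2_perm == pytest.approx(res.chi2, rel=1e-12)

    def test_type_i_error_rate_near_nominal(self, gradient):
        rejections = 0
        n_seeds = 400
        for seed in range(n_seeds):
            traces = generate_control_traces(6, 30, gradient, seed)
            if control_uniformity_test(traces, gradient).p < 0.05 :
                rejections += 1
        # binomial(400, 0.05): 3 sigma band around the nominal rate
        assert 0.017 <= rejections / n_seeds <= 0.083

    def test_chi2_tail_matches_incomplete_gamma_oracle(self):
        # regularised upper incomplete gamma via series / continued fraction
        def gammq(a, x, itmax=200, eps=1e-14):
            import math

            gln = math.lgamma(a)
            if x < a + 1.0:  # series for P(a,x), complement
                ap, summ, delta = a, 1.0 / a, 1.0 / a
                for _ in range(itmax):
                    ap += 1.0
                    delta *= x / ap
                    summ += delta
                    if abs(delta) < abs(summ) * eps:
                        break
                return 1.0 - summ * math.exp(-x + a * math.log(x) - gln)
            # Lentz continued fraction for Q(a,x)
            tiny = 1e-300
            b, c, d = x + 1.0 - a, 1.0 / tiny, 1.0 / (x + 1.0 - a)
            h = d
            for i in range(1, itmax):
                an = -i * (i - a)
                b += 2.0
                d = an * d + b
                d = tiny if abs(d) < tiny else d
                c = b + an / c
                c = tiny if abs(c) < tiny else c
                d = 1.0 / d
                delta = d * c
                h *= delta
                if abs(delta - 1.0) < eps:
                    break
            return h * math.exp(-x + a * math.log(x) - gln)

        for chi2 in (0.5, 3.2, 6.93, 11.0, 15.13, 40.0):
            for df in (1, 5, 11, 20):
                oracle = gammq(df / 2.0, chi2 / 2.0)
                assert chi_squared_p(chi2, df) == pytest.approx(oracle, abs=1e-10)


class TestAicc:
    def test_small_sample_correction(self):
        assert aicc(100.0, 2, 10) == pytest.approx(104 + 12 / 7, abs=1e-9)

    def test_limits_to_aic_for_large_n(self):
        assert aicc(100.0, 2, 10**7) == pytest.approx(104.0, abs=1e-4)

    def test_penalty_monotone_in_k(self):
        assert aicc(100.0, 2, 30) < aicc(100.0, 3, 30)

    def test_undefined_below_minimum_n(self):
        with pytest.raises(ValueError):
            aicc(100.0, 4, 5)


class TestAkaikeWeights:
    def test_printed_delta_set_reproduces_top_weight(self):
        models = [
            ("Species x Acc.Temp", 7, 555.9, {"b": 1.0}),
            ("Species", 5, 557.88, {"b": 0.5}),
            ("Species + Sex x Acc.Temp", 8, 559.79, {}),
        ]
        out = akaike_weights_and_average(models)
        w = out.table["weight"].to_numpy()
        assert round(w[0], 3) == 0.660
        # remaining weights were printed from unrounded AICc values
        assert w[1] == pytest.approx(0.246, abs=1e-3)
        assert w[2] == pytest.approx(0.094, abs=1e-3)
        assert np.nansum(w) == pytest.approx(1.0, abs=1e-12)

    def test_single_model_gets_unit_weight(self):
        out = akaike_weights_and_average([("only", 2, 10.0, {"a": 1.0})])
        assert out.table["weight"].iloc[0] == 1.0
        assert out.averaged_coefficients == {"a": 1.0}

    def test_tied_models_split_evenly(self):
        out = akaike_weights_and_average(
            [("m1", 2, 10.0, {"a": 2.0}), ("m2", 2, 10.0, {})]
        )
        assert np.allclose(out.table["weight"], 0.5)
        # zero substitution: absent coefficient averaged as zero
        assert out.averaged_coefficients["a"] == pytest.approx(1.0)

    @given(st.floats(min_value=-50, max_value=50))
    def test_weights_invariant_to_aicc_shift(self, shift):
        base = [("a", 2, 100.0, {}), ("b", 3, 101.5, {}), ("c", 4, 103.0, {})]
        shifted = [(m, k, a + shift, c) for m, k, a, c in base]
        w0 = akaike_weights_and_average(base).table["weight"].to_numpy()
        w1 = akaike_weights_and_average(shifted).table["weight"].to_numpy()
        assert np.allclose(w0, w1, equal_nan=True)

    def test_cutoff_excludes_distant_models_but_keeps_best(self):
        out = akaike_weights_and_average(
            [("good", 2, 0.0, {}), ("bad", 2, 10.0, {})]
        )
        tab = out.table
        assert tab.loc[tab["model"] == "good", "retained"].item()
        assert not tab.loc[tab["model"] == "bad", "retained"].item()
        assert tab.loc[tab["model"] == "good", "weight"].item() == 1.0


class TestModelComparison:
    def _medians(self, seed, gpulex, dvillosus, gradient, n=20):
        design = DesignSpec(n_per_acclimation=n)
        traces = generate_position_traces(gpulex, design, gradient, seed)
        traces += generate_position_traces(dvillosus, design, gradient, seed + 10_000)
        return individual_medians(traces)

    def test_interaction_recovered_with_correct_sign(self, gpulex, dvillosus, gradient):
        # generating slopes +0.1 (G. pulex) and -0.1 (D. villosus): the
        # species x acclimation interaction is real and positive under
        # alphabetical (D. villosus baseline) coding
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            out = fit_preference_models(
                self._medians(seed, gpulex, dvillosus, gradient)
            )
            top_has_interaction = "Species x Acc.Temp" in out.top_model
            sign_ok = (
                out.averaged_coefficients.get("species[T.G. pulex]:acclimation_c", 0.0)
                > 0
            )
            hits += top_has_interaction and sign_ok
        assert hits / n_seeds >= 0.95

    def test_null_generator_keeps_intercept_model_competitive(
        self, gpulex, gradient
    ):
        null = dataclasses.replace(gpulex, pref_slope=0.0)
        other = dataclasses.replace(
            null, name="D. villosus", pref_intercept_c=null.pref_intercept_c
        )
        close = 0
        n_seeds = 20
        for seed in range(n_seeds):
            out = fit_preference_models(self._medians(seed, null, other, gradient))
            tab = out.table
            delta = tab.loc[tab["model"] == "Intercept only", "delta_aicc"].item()
            close += delta < 4.0
        assert close / n_seeds >= 0.7

    def test_zero_noise_generator_gives_perfect_top_model(
        self, gpulex, dvillosus, gradient
    ):
        a = dataclasses.replace(gpulex, pref_sd_c=0.0)
        b = dataclasses.replace(dvillosus, pref_sd_c=0.0)
        out = fit_preference_models(self._medians(0, a, b, gradient, n=6))
        coefs = out.top_model_coefficients
        # exact fit: estimated line reproduces each species' medians exactly
        assert "Species x Acc.Temp" in out.top_model
        assert coefs.loc["acclimation_c", "estimate"] == pytest.approx(
            b.pref_slope, abs=1e-8
        )

    def test_single_species_drops_species_terms_with_warning(self, gpulex, gradient):
        design = DesignSpec(n_per_acclimation=8)
        med = individual_medians(
            generate_position_traces(gpulex, design, gradient, 3)
        )
        with pytest.warns(UserWarning, match="single species"):
            out = fit_preference_models(med)
        assert all("Species" not in m for m in out.table["model"])
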