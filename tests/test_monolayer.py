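import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from terpord import monolayer as ml
from terpord import synth
from terpord.errors import DegeneracyError, FormatError, RangeError, TerpordError

MIX_2_1 = ml.MixtureSpec(("pc", "terpenoid"), (2 / 3, 1 / 3))


def make_iso(pressures, areas, **kw):
    return ml.Isotherm(np.asarray(pressures, float), np.asarray(areas, float), **kw)


# ---------------------------------------------------------------------- I/O


class TestReadIsotherm:
    def test_parses_sorted_table(self, tmp_path):
        f = tmp_path / "iso.csv"
        f.write_text("pressure_mN_per_m,area_A2_per_molecule\n15,67\n5,70\n30,64\n")
        iso = ml.read_isotherm(f)
        assert len(iso) == 3
        assert iso.pressures.tolist() == [5, 15, 30]
        assert iso.areas.tolist() == [70, 67, 64]

    def test_duplicate_pressures_averaged_with_warning(self, tmp_path):
        f = tmp_path / "iso.csv"
        f.write_text(
            "pressure_mN_per_m,area_A2_per_molecule\n5,70\n15,66\n15,68\n30,64\n"
        )
        with pytest.warns(UserWarning, match="duplicated"):
            iso = ml.read_isotherm(f)
        assert iso.areas[iso.pressures == 15][0] == pytest.approx(67.0)

    @pytest.mark.parametrize(
        "content,match",
        [
            ("pressure_mN_per_m,other\n5,70\n15,67\n30,64\n", "area"),
            ("pressure_mN_per_m,area_A2_per_molecule\n5,70\n15,abc\n30,64\n", "row 2"),
            ("pressure_mN_per_m,area_A2_per_molecule\n5,70\n30,64\n", "3 numeric rows"),
        ],
    )
    def test_format_errors(self, tmp_path, content, match):
        f = tmp_path / "bad.csv"
        f.write_text(content)
        with pytest.raises(FormatError, match=match):
            ml.read_isotherm(f)

    def test_write_read_round_trip(self, tmp_path):
        iso = make_iso([5, 15, 30], [70, 67, 64])
        f = tmp_path / "rt.csv"
        ml.write_isotherm(iso, f)
        back = ml.read_isotherm(f)
        np.testing.assert_allclose(back.areas, iso.areas)


class TestIsothermValidation:
    def test_rejects_short_unsorted_or_negative(self):
        with pytest.raises(TerpordError):
            make_iso([5, 15], [70, 67])
        with pytest.raises(TerpordError):
            make_iso([5, 5, 30], [70, 67, 64])
        with pytest.raises(TerpordError):
            make_iso([5, 15, 30], [70, -1, 64])

    def test_warns_on_non_monotone_area(self):
        with pytest.warns(UserWarning, match="monotone"):
            make_iso([5, 15, 30], [70, 71, 64])


# ------------------------------------------------------------- mean + MMA


class TestMeanIsotherm:
    def test_identical_replicates_zero_sd(self):
        reps = [make_iso([5, 15, 30], [70, 67, 64]) for _ in range(3)]
        mean = ml.mean_isotherm(reps)
        np.testing.assert_allclose(mean.areas, [70, 67, 64])
        np.testing.assert_allclose(mean.area_sd, 0.0)

    def test_two_point_sample_sd(self):
        reps = [
            make_iso([5, 15, 30], [70, 67, 64]),
            make_iso([5, 15, 30], [70, 67, 66]),
        ]
        mean = ml.mean_isotherm(reps)
        assert mean.areas[-1] == pytest.approx(65.0)
        assert mean.area_sd[-1] == pytest.approx(np.sqrt(2.0), abs=1e-9)

    def test_generator_replicates_have_positive_sd(self):
        model = synth.reference_isotherm_models(noise_sd=0.3, seed=1)["d9pc"]
        with pytest.warns(UserWarning):
            reps = synth.gen_isotherms(model)
        mean = ml.mean_isotherm(reps)
        assert np.all(mean.area_sd > 0)

    def test_disjoint_ranges_error(self):
        reps = [make_iso([5, 10, 15], [70, 68, 67]), make_iso([20, 25, 30], [66, 65, 64])]
        with pytest.raises(TerpordError, match="disjoint"):
            ml.mean_isotherm(reps)


class TestMmaAtPressure:
    def test_linear_midpoint_and_exact_sample(self):
        iso = make_iso([10, 20, 40], [70, 68, 60])
        assert ml.mma_at_pressure(iso, 30).value == pytest.approx(64.0)
        assert ml.mma_at_pressure(iso, 20).value == pytest.approx(68.0)

    def test_extrapolation_refused(self):
        iso = make_iso([10, 20, 40], [70, 68, 60])
        with pytest.raises(RangeError, match="outside"):
            ml.mma_at_pressure(iso, 45)

    def test_round_down_mode_snaps_to_lower_sample(self):
        iso = make_iso([10, 20, 40], [70, 68, 60])
        a = ml.mma_at_pressure(iso, 30, round_down=True)
        assert a.value == pytest.approx(68.0)
        assert a.pressure == pytest.approx(20.0)

    def test_monotone_consistency(self):
        iso = make_iso(np.linspace(1, 40, 40), np.linspace(90, 55, 40))
        queries = np.linspace(1, 40, 117)
        areas = [ml.mma_at_pressure(iso, q).value for q in queries]
        assert np.all(np.diff(areas) <= 1e-12)


# ---------------------------------------------------- condensation effect


class TestCondensation:
    def test_worked_example(self):
        a0 = ml.MeasuredArea(50.0, 0.0, 30.0)
        a1 = ml.MeasuredArea(66.0, 0.0, 30.0)
        a2 = ml.MeasuredArea(40.0, 0.0, 30.0)
        res = ml.condensation_effect(a0, a1, a2, MIX_2_1)
        assert res.c == pytest.approx(12.79, abs=0.005)

    def test_ideal_mixture_gives_zero(self):
        a1 = ml.MeasuredArea(66.0, 0.0, 30.0)
        a2 = ml.MeasuredArea(40.0, 0.0, 30.0)
        ideal = ml.ideal_mixing_area(a1, a2, MIX_2_1)
        res = ml.condensation_effect(ideal, a1, a2, MIX_2_1)
        assert abs(res.c) < 1e-12

    def test_expansion_is_negative(self):
        # mixture larger than ideal -> negative condensing effect
        a1 = ml.MeasuredArea(66.0, 0.0, 30.0)
        a2 = ml.MeasuredArea(40.0, 0.0, 30.0)
        ideal = ml.ideal_mixing_area(a1, a2, MIX_2_1)
        a0 = ml.MeasuredArea(ideal.value + 2.0, 0.0, 30.0)
        assert ml.condensation_effect(a0, a1, a2, MIX_2_1).c < 0

    def test_error_propagation_is_first_order_linear(self):
        a0 = ml.MeasuredArea(50.0, 0.4, 30.0)
        a1 = ml.MeasuredArea(66.0, 0.3, 30.0)
        a2 = ml.MeasuredArea(40.0, 0.2, 30.0)
        sd1 = ml.condensation_effect(a0, a1, a2, MIX_2_1).sd
        a0d = ml.MeasuredArea(50.0, 0.8, 30.0)
        a1d = ml.MeasuredArea(66.0, 0.6, 30.0)
        a2d = ml.MeasuredArea(40.0, 0.4, 30.0)
        sd2 = ml.condensation_effect(a0d, a1d, a2d, MIX_2_1).sd
        assert sd2 == pytest.approx(2.0 * sd1, rel=1e-12)

    def test_mismatched_pressures_rejected(self):
        a0 = ml.MeasuredArea(50.0, 0.0, 30.0)
        a1 = ml.MeasuredArea(66.0, 0.0, 25.0)
        a2 = ml.MeasuredArea(40.0, 0.0, 30.0)
        with pytest.raises(TerpordError):
            ml.condensation_effect(a0, a1, a2, MIX_2_1)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        x1=st.floats(0.05, 0.95),
        a1=st.floats(40.0, 90.0),
        a2=st.floats(30.0, 60.0),
    )
    def test_ideal_construction_always_zero(self, x1, a1, a2):
        mix = ml.MixtureSpec(("a", "b"), (x1, 1.0 - x1))
        m1 = ml.MeasuredArea(a1, 0.0, 30.0)
        m2 = ml.MeasuredArea(a2, 0.0, 30.0)
        ideal = ml.ideal_mixing_area(m1, m2, mix)
        assert abs(ml.condensation_effect(ideal, m1, m2, mix).c) < 1e-12


class TestIdealMixingArea:
    def test_arithmetic(self):
        half = ml.MixtureSpec(("a", "b"), (0.5, 0.5))
        a = ml.ideal_mixing_area(
            ml.MeasuredArea(60.0, 0.0, 30.0), ml.MeasuredArea(40.0, 0.0, 30.0), half
        )
        assert a.value == pytest.approx(50.0)
        b = ml.ideal_mixing_area(
            ml.MeasuredArea(66.0, 0.0, 30.0), ml.MeasuredArea(40.0, 0.0, 30.0), MIX_2_1
        )
        assert b.value == pytest.approx(57.333, abs=5e-4)
        assert b.sd == 0.0


# ----------------------------------------------- excess area + free energy


def _linear_iso(c0, slope, pressures=None):
    p = np.asarray(pressures if pressures is not None else np.arange(0.0, 31.0, 1.0))
    return make_iso(p, c0 + slope * p)


class TestExcessArea:
    def test_exact_weighted_mean_gives_zero(self):
        p1 = _linear_iso(80.0, -0.5)
        p2 = _linear_iso(50.0, -0.3)
        mix_areas = MIX_2_1.x1 * p1.areas + MIX_2_1.x2 * p2.areas
        mix_iso = make_iso(p1.pressures, mix_areas)
        tab = ml.excess_area_curve(mix_iso, p1, p2, MIX_2_1, [5, 10, 15, 20, 25])
        np.testing.assert_allclose(tab["excess_area"], 0.0, atol=1e-9)

    def test_injected_constant_excess_recovered(self):
        p1 = _linear_iso(80.0, -0.5)
        p2 = _linear_iso(50.0, -0.3)
        mix_iso = make_iso(
            p1.pressures, MIX_2_1.x1 * p1.areas + MIX_2_1.x2 * p2.areas - 1.0
        )
        tab = ml.excess_area_curve(mix_iso, p1, p2, MIX_2_1, [5, 10, 15, 20, 25])
        np.testing.assert_allclose(tab["excess_area"], -1.0, atol=1e-9)

    def test_single_component_mixture_degenerate(self):
        p1 = _linear_iso(80.0, -0.5)
        pure = ml.MixtureSpec(("a",), (1.0,))
        tab = ml.excess_area_curve(p1, p1, p1, pure, [5, 15, 25])
        np.testing.assert_allclose(tab["excess_area"], 0.0, atol=1e-9)

    def test_grid_out_of_range_error(self):
        p1 = _linear_iso(80.0, -0.5)
        with pytest.raises(RangeError, match="35"):
            ml.excess_area_curve(p1, p1, p1, ml.MixtureSpec(("a",), (1.0,)), [5, 35])


class TestExcessFreeEnergy:
    def test_zero_curve_gives_zero_everywhere(self):
        tab = pd.DataFrame(
            {"pressure": np.linspace(0.5, 30, 60), "excess_area": 0.0, "sd": 0.0}
        )
        dg = ml.excess_free_energy(tab)
        assert dg.values == (0.0,) * 5
        assert dg.lower_bound == pytest.approx(0.5)

    def test_constant_excess_closed_form(self):
        tab = pd.DataFrame(
            {"pressure": np.linspace(0.0, 25.0, 51), "excess_area": -1.0, "sd": 0.0}
        )
        dg = ml.excess_free_energy(tab, [25.0])
        expected = -25.0 * ml.MNM_A2_TO_J_PER_MOL  # rectangle, exact
        assert dg.values[0] == pytest.approx(expected, rel=1e-3)
        assert expected == pytest.approx(-150.6, abs=0.1)

    def test_piecewise_linear_matches_closed_form(self):
        # ΔA = 0.2·Π: integral from p0 to Π* is 0.1(Π*² − p0²)
        p = np.linspace(1.0, 30.0, 30)
        tab = pd.DataFrame({"pressure": p, "excess_area": 0.2 * p, "sd": 0.0})
        dg = ml.excess_free_energy(tab, [10.0, 25.0])
        for target, got in zip(dg.target_pressures, dg.values):
            want = 0.1 * (target**2 - 1.0) * ml.MNM_A2_TO_J_PER_MOL
            assert got == pytest.approx(want, rel=1e-10)

    def test_nonnegative_excess_monotone_in_target(self):
        p = np.linspace(0.5, 30.0, 60)
        tab = pd.DataFrame(
            {"pressure": p, "excess_area": 0.5 + 0.01 * p, "sd": 0.0}
        )
        dg = ml.excess_free_energy(tab)
        assert np.all(np.diff(dg.values) >= 0)

    def test_ideal_entropy_term(self):
        tab = pd.DataFrame(
            {"pressure": np.linspace(0.5, 30, 60), "excess_area": 0.0, "sd": 0.0}
        )
        dg = ml.excess_free_energy(tab, include_ideal=True, mix=MIX_2_1, temperature=20.0)
        rt = ml.GAS_CONSTANT * 293.15
        want = rt * (MIX_2_1.x1 * np.log(MIX_2_1.x1) + MIX_2_1.x2 * np.log(MIX_2_1.x2))
        assert want < 0
        assert dg.values[0] == pytest.approx(want, rel=1e-12)

    def test_sd_scales_linearly(self):
        p = np.linspace(0.5, 30.0, 60)
        tab1 = pd.DataFrame({"pressure": p, "excess_area": -1.0, "sd": 0.2})
        tab2 = pd.DataFrame({"pressure": p, "excess_area": -1.0, "sd": 0.4})
        dg1 = ml.excess_free_energy(tab1)
        dg2 = ml.excess_free_energy(tab2)
        np.testing.assert_allclose(dg2.sds, 2.0 * np.asarray(dg1.sds), rtol=1e-12)

    def test_target_below_table_error(self):
        tab = pd.DataFrame(
            {"pressure": np.linspace(10.0, 30.0, 21), "excess_area": -1.0, "sd": 0.0}
        )
        with pytest.raises(RangeError, match="below"):
            ml.excess_free_energy(tab, [5.0])


# ------------------------------------------------------- regression/MANOVA


class TestRegression:
    def test_exact_line(self):
        iso = _linear_iso(70.0, -0.2)
        fit = ml.fit_isotherm_regression(iso)
        assert fit.coefficients[0] == pytest.approx(70.0)
        assert fit.coefficients[1] == pytest.approx(-0.2)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_data_zero_slope(self):
        iso = make_iso([10, 20, 30], [65, 65, 65])
        fit = ml.fit_isotherm_regression(iso)
        assert fit.coefficients[1] == pytest.approx(0.0)

    def test_too_few_points_in_window(self):
        iso = make_iso([1, 2, 35], [80, 79, 60])
        with pytest.raises(TerpordError, match="3 points"):
            ml.fit_isotherm_regression(iso, (10, 30))

    def test_generator_slope_recovered_within_3_sd(self):
        model = synth.reference_isotherm_models(noise_sd=0.3, seed=1)["d9pc"]
        with pytest.warns(UserWarning):
            iso = synth.gen_isotherms(model)[0]
        fit = ml.fit_isotherm_regression(iso, (10.0, 30.0))
        # true mean slope of the quadratic over the window: c1 + 2 c2 <Π>
        p = iso.pressures[(iso.pressures >= 10) & (iso.pressures <= 30)]
        truth = model.c1 + 2 * model.c2 * p.mean()
        res_sd = 3 * 0.3 / np.sqrt(np.sum((p - p.mean()) ** 2))
        assert abs(fit.coefficients[1] - truth) < 3 * max(res_sd, 1e-6) + 3e-3


class TestManova:
    def _fits(self, intercepts, noise, n, seed):
        rng = np.random.default_rng(seed)
        out = []
        for b0 in intercepts:
            out.append(
                ml.IsothermFitCoefficients(
                    (b0 + rng.normal(0, noise), -0.5 + rng.normal(0, noise)),
                    (10.0, 30.0),
                    0.99,
                )
            )
        return out

    def test_strong_separation_tiny_p(self):
        groups = {
            "a": self._fits([60.0] * 6, 0.01, 6, 1),
            "b": self._fits([90.0] * 6, 0.01, 6, 2),
        }
        res = ml.manova_isotherm_groups(groups)
        assert res.p < 1e-6
        assert res.F > 0

    def test_single_group_rejected(self):
        with pytest.raises(TerpordError, match="2 groups"):
            ml.manova_isotherm_groups({"a": self._fits([60, 60, 60], 0.1, 3, 1)})

    def test_identical_replicates_degenerate(self):
        fit = ml.IsothermFitCoefficients((70.0, -0.2), (10.0, 30.0), 1.0)
        with pytest.raises(DegeneracyError):
            ml.manova_isotherm_groups({"a": [fit, fit], "b": [fit, fit]})

    def test_wilks_variant_available(self):
        groups = {
            "a": self._fits([60.0] * 4, 0.5, 4, 3),
            "b": self._fits([61.0] * 4, 0.5, 4, 4),
        }
        res = ml.manova_isotherm_groups(groups, statistic="wilks")
        assert res.statistic_name == "Wilks' lambda"
        assert 0.0 <= res.p <= 1.0
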