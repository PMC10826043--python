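"""Mixture design, combination index, DRI, fa-CI curves and isobolograms."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from combindex import (
    MedianEffectFit,
    MixtureObservation,
    classify,
    combination_index,
    combination_median_effect,
    design_effect_matched_mixtures,
    dose_for_effect,
    dose_reduction_index,
    effect_at_dose,
    fa_ci_curve,
    isobologram,
)

fa_st = st.floats(min_value=0.01, max_value=0.99)
dose_st = st.floats(min_value=1e-3, max_value=1e3)


def nominal_mixture(fit_a, fit_b, level, fa):
    """Design-dose mixture at one nominal level with an observed effect."""
    return MixtureObservation(
        c_a=dose_for_effect(fit_a, level), c_b=dose_for_effect(fit_b, level), fa=fa
    )


class TestDesign:
    def test_lowest_level_doses(self, acarbose, propolis):
        (mix,) = design_effect_matched_mixtures(acarbose, propolis, [0.10])
        assert round(mix.c_a, 3) == 0.012  # mM acarbose
        assert round(mix.c_b, 3) == 0.015  # mg/mL propolis
        assert mix.fa is None
        assert mix.level_label == "IC10-matched"

    def test_median_level_returns_dm_pair(self, acarbose, kaempferol):
        (mix,) = design_effect_matched_mixtures(acarbose, kaempferol, [0.50])
        assert mix.c_a == pytest.approx(acarbose.dm, rel=1e-12)
        assert mix.c_b == pytest.approx(kaempferol.dm, rel=1e-12)

    def test_kaempferol_low_level_dose(self, acarbose, kaempferol):
        (mix,) = design_effect_matched_mixtures(acarbose, kaempferol, [0.10])
        assert mix.c_b == pytest.approx(0.752, abs=1e-3)

    def test_default_five_levels(self, acarbose, propolis):
        mixtures = design_effect_matched_mixtures(acarbose, propolis)
        assert [m.level_label for m in mixtures] == [
            "IC10-matched", "IC30-matched", "IC50-matched",
            "IC70-matched", "IC90-matched",
        ]

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 1.2])
    def test_level_out_of_range(self, bad, acarbose, propolis):
        with pytest.raises(ValueError, match="effect level"):
            design_effect_matched_mixtures(acarbose, propolis, [bad])


class TestCombinationIndex:
    def test_acarbose_propolis_low_level(self, acarbose, propolis):
        obs = nominal_mixture(acarbose, propolis, 0.10, fa=0.235)
        metrics = combination_index(obs, acarbose, propolis)
        assert metrics.ci == pytest.approx(0.601, abs=0.01)
        assert metrics.interaction_class == "synergism"

    def test_acarbose_kaempferol_low_level(self, acarbose, kaempferol):
        obs = nominal_mixture(acarbose, kaempferol, 0.10, fa=0.26)
        metrics = combination_index(obs, acarbose, kaempferol)
        assert metrics.ci == pytest.approx(0.795, abs=0.01)

    def test_single_agent_at_own_equieffective_dose(self, acarbose, kaempferol):
        fa = 0.42
        obs = MixtureObservation(c_a=dose_for_effect(acarbose, fa), c_b=0.0, fa=fa)
        metrics = combination_index(obs, acarbose, kaempferol)
        assert metrics.ci == pytest.approx(1.0, rel=1e-12)
        assert math.isinf(metrics.dri_b)

    @given(fa=fa_st, ca=dose_st, cb=dose_st)
    def test_ci_equals_reciprocal_dri_sum(self, fa, ca, cb, acarbose, propolis):
        metrics = combination_index(
            MixtureObservation(c_a=ca, c_b=cb, fa=fa), acarbose, propolis
        )
        assert metrics.ci == pytest.approx(
            1.0 / metrics.dri_a + 1.0 / metrics.dri_b, rel=1e-12
        )

    @given(fa=fa_st, ca=dose_st, cb=dose_st,
           ka=st.floats(min_value=1e-3, max_value=1e3),
           kb=st.floats(min_value=1e-3, max_value=1e3))
    def test_ci_invariant_under_unit_rescaling(self, fa, ca, cb, ka, kb):
        """Rescaling either component's dose unit (doses and the matching fit's
        Dm by the same factor) leaves CI unchanged."""
        fit_a = MedianEffectFit(dm=0.061, m=1.32)
        fit_b = MedianEffectFit(dm=1.07, m=0.512)
        base = combination_index(
            MixtureObservation(c_a=ca, c_b=cb, fa=fa), fit_a, fit_b
        ).ci
        scaled = combination_index(
            MixtureObservation(c_a=ca * ka, c_b=cb * kb, fa=fa),
            MedianEffectFit(dm=0.061 * ka, m=1.32),
            MedianEffectFit(dm=1.07 * kb, m=0.512),
        ).ci
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_unmeasured_observation_rejected(self, acarbose, propolis):
        obs = MixtureObservation(c_a=0.01, c_b=0.01, fa=None)
        with pytest.raises(ValueError, match="no measured fa"):
            combination_index(obs, acarbose, propolis)

    def test_out_of_range_fa_rejected_at_construction(self):
        with pytest.raises(ValueError):
            MixtureObservation(c_a=0.01, c_b=0.01, fa=1.0)
        with pytest.raises(ValueError):
            MixtureObservation(c_a=0.0, c_b=0.0, fa=0.5)


class TestDoseReductionIndex:
    def test_propolis_fold_reduction(self, acarbose, propolis):
        obs = nominal_mixture(acarbose, propolis, 0.10, fa=0.235)
        assert dose_reduction_index(obs, propolis, "B") == pytest.approx(7.28, abs=0.02)

    def test_acarbose_fold_reduction(self, acarbose, kaempferol):
        obs = nominal_mixture(acarbose, kaempferol, 0.10, fa=0.26)
        assert dose_reduction_index(obs, acarbose, "A") == pytest.approx(2.39, abs=0.02)

    @given(fa=fa_st)
    def test_component_at_solitary_dose_gives_unity(self, fa, acarbose, kaempferol):
        obs = MixtureObservation(
            c_a=dose_for_effect(acarbose, fa), c_b=1.0, fa=fa
        )
        assert dose_reduction_index(obs, acarbose, "A") == pytest.approx(1.0, rel=1e-12)

    def test_zero_component_dose_rejected(self, acarbose, propolis):
        obs = MixtureObservation(c_a=0.0, c_b=0.5, fa=0.4)
        with pytest.raises(ValueError, match="infinite"):
            dose_reduction_index(obs, acarbose, "A")

    def test_unknown_component_rejected(self, acarbose):
        obs = MixtureObservation(c_a=0.1, c_b=0.5, fa=0.4)
        with pytest.raises(ValueError, match="component"):
            dose_reduction_index(obs, acarbose, "C")


class TestClassify:
    @pytest.mark.parametrize(
        "ci, expected",
        [(0.601, "synergism"), (1.71, "antagonism"), (1.0, "additivity")],
    )
    def test_strict_thresholds(self, ci, expected):
        assert classify(ci) == expected

    def test_tolerance_band(self):
        assert classify(0.95, tolerance=0.1) == "additivity"
        assert classify(0.85, tolerance=0.1) == "synergism"
        assert classify(1.15, tolerance=0.1) == "antagonism"

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_invalid_ci_rejected(self, bad):
        with pytest.raises(ValueError):
            classify(bad)


class TestFaCiCurve:
    def test_observation_mode_reproduces_published_series(
        self, acarbose, propolis, ap_rows
    ):
        observations = [
            nominal_mixture(acarbose, propolis, row.level, row.fa)
            for row in ap_rows.itertuples()
        ]
        curve = fa_ci_curve(acarbose, propolis, observations=observations)
        np.testing.assert_allclose(
            [ci for _, ci in curve], ap_rows["ci"], atol=0.01
        )

    def test_sham_constant_ratio_is_additive(self, acarbose):
        curve = fa_ci_curve(
            acarbose, acarbose, combo_fit=acarbose, ratio=0.3,
            fa_grid=[0.1, 0.5, 0.9],
        )
        for fa, ci in curve:
            assert ci == pytest.approx(1.0, rel=1e-10)

    def test_single_observation_consistent_with_combination_index(
        self, acarbose, kaempferol
    ):
        obs = nominal_mixture(acarbose, kaempferol, 0.30, fa=0.537)
        ((fa, ci),) = fa_ci_curve(acarbose, kaempferol, observations=[obs])
        assert fa == obs.fa
        assert ci == combination_index(obs, acarbose, kaempferol).ci

    def test_mode_selection_errors(self, acarbose, kaempferol):
        with pytest.raises(ValueError, match="mode"):
            fa_ci_curve(acarbose, kaempferol)
        with pytest.raises(ValueError, match="mode"):
            fa_ci_curve(
                acarbose, kaempferol, combo_fit=acarbose, ratio=0.5,
                observations=[nominal_mixture(acarbose, kaempferol, 0.5, 0.5)],
            )


class TestIsobologram:
    def test_normalized_coordinates_sum_to_ci(self, acarbose, propolis, ap_rows):
        observations = [
            nominal_mixture(acarbose, propolis, row.level, row.fa)
            for row in ap_rows.itertuples()
        ]
        iso = isobologram(acarbose, propolis, observations)
        for point in iso.points:
            assert point.x + point.y == pytest.approx(point.ci, rel=1e-12)

    def test_position_labels_match_interaction(self, acarbose, propolis):
        below = nominal_mixture(acarbose, propolis, 0.10, fa=0.235)  # CI ~ 0.60
        above = nominal_mixture(acarbose, propolis, 0.90, fa=0.91)   # CI ~ 1.71
        iso = isobologram(acarbose, propolis, [below, above])
        assert iso.points[0].position == "below"
        assert iso.points[1].position == "above"

    def test_additive_line_endpoints_are_equieffective_doses(
        self, acarbose, propolis
    ):
        iso = isobologram(acarbose, propolis, [], effect_levels=[0.3, 0.7])
        for level in iso.levels:
            assert level.ic_a == pytest.approx(
                dose_for_effect(acarbose, level.effect_level), rel=1e-12
            )
            assert level.ic_b == pytest.approx(
                dose_for_effect(propolis, level.effect_level), rel=1e-12
            )


class TestCombinationMedianEffect:
    def test_published_acarbose_kaempferol_row(self, acarbose, kaempferol, ak_rows):
        observations = [
            nominal_mixture(acarbose, kaempferol, row.level, row.fa)
            for row in ak_rows.itertuples()
        ]
        fit = combination_median_effect(observations)
        assert fit.m == pytest.approx(0.935, rel=0.02)
        assert fit.dm == pytest.approx(2.01, rel=0.02)
        assert fit.r >= 0.98

    def test_self_mixture_reproduces_single_agent(self, acarbose):
        observations = []
        for level in (0.2, 0.4, 0.6, 0.8):
            total = dose_for_effect(acarbose, level)
            observations.append(
                MixtureObservation(c_a=0.3 * total, c_b=0.7 * total, fa=level)
            )
        fit = combination_median_effect(observations)
        assert fit.dm == pytest.approx(acarbose.dm, rel=1e-9)
        assert fit.m == pytest.approx(acarbose.m, rel=1e-9)

    def test_two_observations_exact(self, acarbose, kaempferol):
        obs = [
            MixtureObservation(c_a=0.5, c_b=0.5, fa=0.25),
            MixtureObservation(c_a=2.0, c_b=2.0, fa=0.75),
        ]
        with pytest.warns(Warning):
            fit = combination_median_effect(obs)
        assert fit.r == 1.0
        assert fit.dm == pytest.approx(2.0, rel=1e-12)

    def test_heterogeneous_units_warn_and_compose(self, acarbose, propolis, ap_rows):
        observations = [
            nominal_mixture(acarbose, propolis, row.level, row.fa)
            for row in ap_rows.itertuples()
        ]
        with pytest.warns(UserWarning, match="heterogeneous units"):
            fit = combination_median_effect(
                observations, dose_unit_a="mM", dose_unit_b="mg/mL"
            )
        assert fit.dose_unit == "mM+mg/mL"

    def test_too_few_observations(self, acarbose):
        with pytest.raises(ValueError, match="at least 2"):
            combination_median_effect(
                [MixtureObservation(c_a=1.0, c_b=1.0, fa=0.5)]
            )
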