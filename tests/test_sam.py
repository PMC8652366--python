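"""Social accuracy model: identifiability, probing, effect sizes, EB slopes."""

import numpy as np
import pandas as pd
import pytest

from coordsam.sam import (
    SAMSpec,
    design_columns,
    effect_size_d,
    empirical_bayes_accuracy,
    fit_sam,
    simple_slopes,
)
from coordsam.simulate import StudyGenConfig

from conftest import make_frame

SPEC = SAMSpec(moderators=("ibc_variability",))


class TestNoiselessIdentifiability:
    def test_generator_and_fitter_are_algebraic_inverses(self):
        cfg = StudyGenConfig(
            seed=5, n_targets=30, n_perceivers=12, n_subsets=2, n_items=12,
            target_sds=(0, 0, 0), perceiver_sds=(0, 0, 0), residual_sd=0.0,
        )
        frame, study = make_frame(cfg)
        fit = fit_sam(frame, SPEC)
        for name, true_val in study["truth"]["gamma"].items():
            assert fit.coefficient(name) == pytest.approx(true_val, abs=1e-6)
        assert fit.result.sigma2 < 1e-10

    def test_report_contains_every_design_coefficient_exactly_once(self, small_fit):
        assert list(small_fit.fixed_effects.index) == design_columns(SPEC)


class TestSimpleSlopes:
    def test_linear_combination_arithmetic(self, small_fit):
        """Probed slope = base + interaction x probe, exactly."""
        s = small_fit.observability_sd
        probe = simple_slopes(small_fit, "distinctive", observability_level=1.0)
        expected = (
            small_fit.coefficient("distinctive")
            + small_fit.coefficient("distinctive:observability") * s
        )
        assert probe["estimate"] == pytest.approx(expected, abs=1e-12)

    def test_probe_at_mean_returns_base_coefficient(self, small_fit):
        probe = simple_slopes(
            small_fit, "distinctive",
            observability_level=0.0, moderator_levels={"ibc_variability": 0.0},
        )
        assert probe["estimate"] == small_fit.coefficient("distinctive")
        assert probe["se"] == pytest.approx(
            small_fit.fixed_effects.loc["distinctive", "se"], abs=1e-12
        )

    @pytest.mark.parametrize("obs_level,mod_level", [(1.0, 1.0), (-1.0, 0.5), (0.5, -1.0)])
    def test_probe_equals_recentered_refit(self, small_study, small_fit, obs_level, mod_level):
        """The probed slope equals the base coefficient after recentering the
        moderator and observability at the probe values (variance parameters
        are invariant under recentering, so they are carried over exactly)."""
        frame, _ = small_study
        probe = simple_slopes(
            small_fit, "distinctive",
            observability_level=obs_level,
            moderator_levels={"ibc_variability": mod_level},
        )
        shifted = frame.copy()
        shifted.attrs = dict(frame.attrs)
        shifted["observability"] = frame["observability"] - obs_level * small_fit.observability_sd
        shifted["ibc_variability"] = frame["ibc_variability"] - mod_level
        refit = fit_sam(shifted, SPEC, start_theta=small_fit.result.theta, reuse_theta=True)
        assert probe["estimate"] == pytest.approx(
            refit.coefficient("distinctive"), abs=1e-8
        )

    def test_probes_bracket_the_mean_slope_under_nonzero_moderation(self, small_fit):
        mid = simple_slopes(small_fit, "distinctive")["estimate"]
        lo = simple_slopes(small_fit, "distinctive", observability_level=-1.0)["estimate"]
        hi = simple_slopes(small_fit, "distinctive", observability_level=1.0)["estimate"]
        assert min(lo, hi) < mid < max(lo, hi)

    def test_probing_zero_sd_moderator_rejected(self, small_fit):
        # construct a fit whose observability profile SD is zero
        from coordsam.sam import SAMFit

        zero = SAMFit(
            result=small_fit.result, spec=small_fit.spec,
            observability_sd=0.0, moderator_scales=small_fit.moderator_scales,
        )
        with pytest.raises(ValueError, match="zero SD"):
            simple_slopes(zero, "distinctive", observability_level=1.0)


class TestEffectSize:
    def test_two_sd_change_over_target_slope_sd(self, small_fit):
        """d = 2 b / SD(target distinctive slopes), the published convention
        pair (b=.07, SD=.23) giving d ~ .61."""
        out = effect_size_d(small_fit, "ibc_variability")
        expected = 2.0 * small_fit.coefficient("ibc_variability:distinctive") / \
            small_fit.target_distinctive_slope_sd
        assert out["d"] == pytest.approx(expected, abs=1e-12)
        assert 2.0 * 0.07 / 0.23 == pytest.approx(0.6087, abs=1e-4)

    def test_wald_interval_is_symmetric(self, small_fit):
        out = effect_size_d(small_fit, "ibc_variability", observability_level=1.0)
        assert out["ci_high"] - out["d"] == pytest.approx(out["d"] - out["ci_low"], abs=1e-10)

    def test_null_moderation_gives_zero_d_with_symmetric_ci(self, small_fit):
        import dataclasses

        from coordsam.sam import SAMFit

        params = small_fit.result.fe_params.copy()
        params["ibc_variability:distinctive"] = 0.0
        params["ibc_variability:distinctive:observability"] = 0.0
        res = dataclasses.replace(small_fit.result, fe_params=params)
        nulled = SAMFit(
            result=res, spec=small_fit.spec,
            observability_sd=small_fit.observability_sd,
            moderator_scales=small_fit.moderator_scales,
        )
        out = effect_size_d(nulled, "ibc_variability")
        assert out["d"] == 0.0
        assert out["ci_low"] == pytest.approx(-out["ci_high"])

    def test_zero_slope_variance_reported_undefined(self):
        cfg = StudyGenConfig(
            seed=17, n_targets=24, n_perceivers=12, n_subsets=2, n_items=8,
            target_sds=(0.3, 0.0, 0.2),
        )
        frame, _ = make_frame(cfg)
        fit = fit_sam(frame, SPEC)
        out = effect_size_d(fit, "ibc_variability")
        if np.isnan(out["d"]):
            assert "zero" in out["reason"]
        else:  # estimated slope variance may be small but nonzero
            assert out["slope_sd"] < 0.1


class TestEmpiricalBayes:
    def test_zero_target_slope_variance_fully_shrinks(self):
        """Generator matched to the EB model (no observability or moderation
        terms) with zero target slope variance: every EB slope collapses to
        the fixed effect."""
        g = {k: 0.0 for k in StudyGenConfig().gamma}
        g.update({"intercept": 4.0, "distinctive": 0.12, "normative": 0.64})
        cfg = StudyGenConfig(
            seed=23, n_targets=24, n_perceivers=12, n_subsets=2, n_items=8,
            gamma=g, target_sds=(0.3, 0.0, 0.2), residual_sd=0.3,
        )
        frame, _ = make_frame(cfg)
        eb = empirical_bayes_accuracy(frame, SPEC, "all")
        assert eb["eb_distinctive_slope"].std() < 0.02
        assert eb["eb_distinctive_slope"].mean() == pytest.approx(0.12, abs=0.05)

    def test_eb_mean_close_to_fixed_effect(self, small_study):
        frame, _ = small_study
        eb = empirical_bayes_accuracy(frame, SPEC, "all")
        base = fit_sam(frame, SAMSpec(include_observability=False))
        assert eb["eb_distinctive_slope"].mean() == pytest.approx(
            base.coefficient("distinctive"), abs=0.02
        )

    def test_eb_slopes_recover_generating_random_slopes(self):
        cfg = StudyGenConfig(seed=31)  # study scale: 105 targets
        frame, study = make_frame(cfg)
        eb = empirical_bayes_accuracy(frame, SPEC, "all").set_index("target_id")
        true_u = pd.Series(
            {t: v[1] for t, v in study["truth"]["target_random_effects"].items()}
        )
        r = np.corrcoef(eb["eb_distinctive_slope"].loc[true_u.index], true_u)[0, 1]
        assert r > 0.5

    def test_small_item_subset_rejected(self, small_study):
        frame, _ = small_study
        tiny = frame[frame["item_id"].isin(frame["item_id"].unique()[:2])]
        tiny.attrs = dict(frame.attrs)
        with pytest.raises(ValueError, match="items"):
            empirical_bayes_accuracy(tiny, SPEC, "all")


class TestModerationDetection:
    def test_three_way_z_grows_with_generating_coefficient(self):
        """Average fitted three-way z increases with the generating term."""
        zs = []
        for coef in (0.0, 0.05, 0.10):
            vals = []
            for rep in range(3):
                g = StudyGenConfig().gamma
                g["ibc_variability:distinctive:observability"] = coef
                cfg = StudyGenConfig(
                    seed=700 + rep, gamma=g,
                    n_targets=60, n_perceivers=32, n_subsets=4, n_items=16,
                )
                frame, _ = make_frame(cfg)
                fit = fit_sam(frame, SPEC)
                vals.append(
                    fit.fixed_effects.loc["ibc_variability:distinctive:observability", "z"]
                )
            zs.append(np.mean(vals))
        assert zs[0] < zs[1] < zs[2]


def test_unknown_moderator_rejected(small_study):
    frame, _ = small_study
    with pytest.raises(ValueError, match="not present"):
        fit_sam(frame, SAMSpec(moderators=("nope",)))
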