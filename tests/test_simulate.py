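"""Synthetic-data generators: determinism, coupling, rendering, study draws."""

import numpy as np
import pandas as pd
import pytest

from coordsam.coordination import CMAConfig, instantaneous_correlation, summarize_ibc
from coordsam.criteria import build_accuracy_criterion
from coordsam.motion import compute_motion_magnitude, extract_roi_motion
from coordsam.simulate import (
    BlobGeometry,
    CouplingProfile,
    StudyGenConfig,
    render_synthetic_video,
    simulate_coupled_signals,
    simulate_personality_study,
)


class TestCoupledSignals:
    def test_perfect_coupling_duplicates_head(self):
        profile = CouplingProfile.constant(1.0, 400, noise_sd=0.0)
        head, body = simulate_coupled_signals(400, profile, seed=1)
        assert np.array_equal(head.values, body.values)
        series = instantaneous_correlation(head, body, CMAConfig())
        assert np.allclose(series.valid_r, 1.0)

    def test_same_seed_is_bit_identical(self):
        profile = CouplingProfile.constant(0.6, 300)
        a = simulate_coupled_signals(300, profile, seed=11)
        b = simulate_coupled_signals(300, profile, seed=11)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)
        c = simulate_coupled_signals(300, profile, seed=12)
        assert not np.array_equal(a[1].values, c[1].values)

    def test_coupling_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            CouplingProfile(rho=np.array([0.5, 1.2]))

    def test_profile_length_must_match(self):
        with pytest.raises(ValueError, match="n_frames"):
            simulate_coupled_signals(100, CouplingProfile.constant(0.5, 99), seed=0)

    def test_block_coupling_inflates_ibc_variability(self):
        """Alternating coupling produces a more variable coordination trace
        than constant coupling matched on the mean, in nearly every paired
        replicate."""
        cma = CMAConfig()
        wins = 0
        for seed in range(50):
            block = CouplingProfile.blocks(0.9, 0.1, 1200, block_len=3 * cma.window_frames)
            const = CouplingProfile.constant(0.5, 1200)
            vb = summarize_ibc(
                instantaneous_correlation(*simulate_coupled_signals(1200, block, seed), cma), "b"
            ).variability
            vc = summarize_ibc(
                instantaneous_correlation(*simulate_coupled_signals(1200, const, seed), cma), "c"
            ).variability
            wins += vb > vc
        assert wins >= 45


class TestRenderedVideo:
    def test_zero_signals_give_static_video(self):
        from coordsam.motion import MotionSeries, ROISpec

        zero = MotionSeries(np.zeros(50), ROISpec("head", 0, 0, 64, 64), 30.0)
        zero_b = MotionSeries(np.zeros(50), ROISpec("body", 0, 64, 64, 128), 30.0)
        stack, roi_h, roi_b = render_synthetic_video(zero, zero_b)
        grids = compute_motion_magnitude(stack)
        assert extract_roi_motion(grids, roi_h, 30.0).values.sum() == 0.0
        assert extract_roi_motion(grids, roi_b, 30.0).values.sum() == 0.0

    def test_blob_escape_rejected(self):
        head, body = simulate_coupled_signals(
            50, CouplingProfile.constant(0.5, 50), seed=2
        )
        with pytest.raises(ValueError, match="escapes"):
            render_synthetic_video(head, body, BlobGeometry(travel=40.0))

    def test_motion_response_is_linear_in_amplitude(self):
        """Total framediff ROI motion scales (approximately linearly) with
        signal amplitude for sub-pixel displacements: doubling the amplitude
        doubles the summed motion to within 2.5%."""
        head, body = simulate_coupled_signals(
            200, CouplingProfile.constant(0.8, 200), seed=9
        )
        totals = []
        for step in (0.5, 1.0):
            stack, roi_h, _ = render_synthetic_video(head, body, BlobGeometry(max_step=step))
            totals.append(
                extract_roi_motion(compute_motion_magnitude(stack), roi_h, 30.0).values.sum()
            )
        assert totals[1] / totals[0] == pytest.approx(2.0, rel=0.025)

    def test_end_to_end_trace_recovery(self):
        """The coordination trace recovered from the rendered video matches
        the trace computed directly on the generating signals."""
        cma = CMAConfig()
        profile = CouplingProfile.blocks(0.9, 0.2, 599, block_len=4 * cma.window_frames)
        head, body = simulate_coupled_signals(599, profile, seed=4)
        stack, roi_h, roi_b = render_synthetic_video(head, body)
        grids = compute_motion_magnitude(stack)
        mh = extract_roi_motion(grids, roi_h, 30.0)
        mb = extract_roi_motion(grids, roi_b, 30.0)
        tv = instantaneous_correlation(mh, mb, cma)
        td = instantaneous_correlation(head, body, cma)
        mask = tv.valid_mask & td.valid_mask
        assert np.corrcoef(tv.r[mask], td.r[mask])[0, 1] > 0.8


class TestStudyGenerator:
    def test_same_seed_identical_tables_different_seed_differs(self):
        cfg = dict(n_targets=12, n_perceivers=8, n_subsets=2, n_items=6)
        a = simulate_personality_study(StudyGenConfig(seed=3, **cfg))
        b = simulate_personality_study(StudyGenConfig(seed=3, **cfg))
        c = simulate_personality_study(StudyGenConfig(seed=4, **cfg))
        for key in ("self_reports", "other_reports", "perceptions", "observability", "moderators"):
            pd.testing.assert_frame_equal(a[key], b[key])
        assert not a["perceptions"]["value"].equals(c["perceptions"]["value"])

    def test_noiseless_ratings_equal_linear_predictor(self):
        """With all random effects and residual noise at zero, each rating is
        exactly the gamma-weighted combination of its predictors."""
        cfg = StudyGenConfig(
            seed=6, n_targets=10, n_perceivers=4, n_subsets=2, n_items=5,
            target_sds=(0, 0, 0), perceiver_sds=(0, 0, 0), residual_sd=0.0,
        )
        study = simulate_personality_study(cfg)
        truth, g = study["truth"], study["truth"]["gamma"]
        crit = build_accuracy_criterion(study["self_reports"], study["other_reports"])
        m_raw = pd.Series(truth["moderator_raw"])
        m_std = (m_raw - m_raw.mean()) / m_raw.std(ddof=1)
        obs = pd.Series(truth["observability_centered"])
        for _, row in study["perceptions"].head(40).iterrows():
            t, k = row["target_id"], row["item_id"]
            D = crit.distinctive.loc[t, k]
            N = crit.normative[k]
            O = obs[k]
            M = m_std[t]
            lp = (
                g["intercept"] + g["distinctive"] * D + g["normative"] * N
                + g["observability"] * O
                + g["distinctive:observability"] * D * O
                + g["normative:observability"] * N * O
                + g["ibc_variability"] * M
                + g["ibc_variability:distinctive"] * M * D
                + g["ibc_variability:normative"] * M * N
                + g["ibc_variability:observability"] * M * O
                + g["ibc_variability:distinctive:observability"] * M * D * O
                + g["ibc_variability:normative:observability"] * M * N * O
            )
            assert row["value"] == pytest.approx(lp, abs=1e-10)

    def test_zero_other_error_makes_criterion_equal_true_profile(self):
        cfg = StudyGenConfig(
            seed=8, n_targets=10, n_perceivers=4, n_subsets=2, n_items=5,
            other_report_sd=0.0, self_report_sd=0.0,
        )
        study = simulate_personality_study(cfg)
        crit = build_accuracy_criterion(study["self_reports"], study["other_reports"])
        for t, profile in study["truth"]["true_profiles"].items():
            assert np.allclose(crit.criterion.loc[t].to_numpy(), profile, atol=1e-10)

    def test_clipping_flag_bounds_ratings(self):
        cfg = dict(n_targets=10, n_perceivers=4, n_subsets=2, n_items=5, residual_sd=3.0)
        unclipped = simulate_personality_study(StudyGenConfig(seed=9, **cfg))
        clipped = simulate_personality_study(StudyGenConfig(seed=9, clip_ratings=True, **cfg))
        assert unclipped["perceptions"]["value"].max() > 7.0
        assert clipped["perceptions"]["value"].between(1.0, 7.0).all()

    def test_viewing_design_gives_each_target_several_perceivers(self):
        study = simulate_personality_study(StudyGenConfig(seed=10))
        per_target = study["perceptions"].groupby("target_id")["perceiver_id"].nunique()
        assert per_target.between(10, 16).all()

    def test_moderator_moments_match_cohort_scale(self):
        """Drawn IBC variability matches the target cohort's published
        moments (M = .19, SD = .06) within Monte-Carlo error."""
        vals = np.concatenate(
            [
                simulate_personality_study(StudyGenConfig(seed=s))["moderators"]["value"]
                for s in (1, 2, 3)
            ]
        )
        assert np.mean(vals) == pytest.approx(0.19, abs=0.01)
        assert np.std(vals, ddof=1) == pytest.approx(0.06, abs=0.01)
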