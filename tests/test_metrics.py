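import math

import numpy as np
import pytest

import gazesteer as gs
from gazesteer.controllers import ControllerParams
from gazesteer.metrics import fisher_mean
from gazesteer.sim import SimulationResult, Trial, centerline_trial
from gazesteer.tracks import Pose


def as_result(trial, model="test"):
    """Wrap a trial's own poses as a model result (identity model)."""
    pos = np.array([[p.x, p.z] for p in trial.poses])
    s = gs.closest_track_indices(pos, trial.track)
    off = np.array([gs.offtrack(p, trial.track) for p in pos])
    return SimulationResult(list(trial.poses), [], s, off, trial, model)


def shifted_trial(trial, dx):
    poses = [Pose(p.x + dx, p.z, p.heading, p.yaw_rate) for p in trial.poses]
    return Trial(
        trial.participant_id, trial.trial_id, trial.experiment,
        poses, trial.gaze, trial.track, trial.v,
    )


class TestTrajectoryError:
    def test_identity_zero(self, slalom):
        trial = centerline_trial(slalom, v=8.0)
        assert gs.trajectory_error(as_result(trial), trial) == pytest.approx(0.0)

    def test_constant_lateral_offset(self, slalom):
        trial = centerline_trial(slalom, v=8.0)
        model = as_result(shifted_trial(trial, 0.2))
        # nearest-sample resampling at 60 Hz leaves sub-mm tie-break noise
        assert gs.trajectory_error(model, trial) == pytest.approx(0.2, abs=1e-3)

    def test_symmetry(self, slalom, noisy_trials):
        a, b = noisy_trials[0], noisy_trials[1]
        err_ab = gs.trajectory_error(as_result(a), b)
        err_ba = gs.trajectory_error(as_result(b), a)
        assert err_ab == pytest.approx(err_ba, rel=1e-9)

    def test_matches_bruteforce_resampling(self, slalom):
        rng = np.random.default_rng(5)
        trial = centerline_trial(slalom, v=8.0)
        model = as_result(shifted_trial(trial, 0.0))
        # perturb model poses smoothly
        wob = 0.3 * np.sin(np.linspace(0, 4 * np.pi, len(model.poses)))
        poses = [
            Pose(p.x + w, p.z, p.heading, p.yaw_rate)
            for p, w in zip(model.poses, wob)
        ]
        wtrial = Trial("p", "0", "exp1", poses, [], slalom, 8.0)
        wmodel = as_result(wtrial)
        got = gs.trajectory_error(wmodel, trial)
        # oracle: per-station nearest point on each polyline, averaged
        m_pos = wmodel.positions
        h_pos = np.array([[p.x, p.z] for p in trial.poses])
        dists = []
        for st in slalom.reference_xy:
            m = m_pos[np.argmin(np.hypot(*(m_pos - st).T))]
            h = h_pos[np.argmin(np.hypot(*(h_pos - st).T))]
            dists.append(np.hypot(*(m - h)))
        assert got == pytest.approx(np.mean(dists), abs=1e-3)

    def test_rigid_transform_invariance(self, slalom):
        trial = centerline_trial(slalom, v=8.0)
        model = as_result(shifted_trial(trial, 0.25))
        base = gs.trajectory_error(model, trial)

        theta = 0.7
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        shift = np.array([5.0, -3.0])

        def xform_pose(p):
            xy = rot @ np.array([p.x, p.z]) + shift
            return Pose(xy[0], xy[1], p.heading - theta, p.yaw_rate)

        track2 = gs.TrackGeometry(
            reference_xy=slalom.reference_xy @ rot.T + shift,
            s=slalom.s,
            half_width=slalom.half_width,
            waypoints=slalom.waypoints @ rot.T + shift,
            waypoint_s=slalom.waypoint_s,
            curve_signs=slalom.curve_signs,
            analysis_window=slalom.analysis_window,
        )
        t2 = Trial("p", "0", "exp1", [xform_pose(p) for p in trial.poses], [], track2, 8.0)
        m2_src = Trial("p", "0", "exp1", [xform_pose(p) for p in model.poses], [], track2, 8.0)
        # rotation perturbs nearest-sample tie-breaks at isolated stations
        assert gs.trajectory_error(as_result(m2_src), t2) == pytest.approx(base, abs=2e-3)


class TestOfftrackPercentage:
    def test_all_inside_zero(self, slalom):
        trial = centerline_trial(slalom, v=8.0)
        assert gs.offtrack_percentage(as_result(trial)) == 0.0

    def test_three_of_six_hundred(self, slalom):
        n = 600
        poses = [Pose(0.0, 0.05 * i, 0.0) for i in range(n)]
        for i in (10, 20, 30):
            poses[i] = Pose(2.0, 0.05 * i, 0.0)  # beyond the 1.5 m half-width
        trial = Trial("p", "0", "exp1", poses, [], slalom, 8.0)
        assert gs.offtrack_percentage(as_result(trial)) == pytest.approx(0.5)

    def test_matches_corridor_oracle(self, sbend_small, noisy_trials):
        trial = centerline_trial(sbend_small, v=10.5, experiment="exp2")
        rng = np.random.default_rng(9)
        poses = [
            Pose(p.x + rng.normal(0, 1.0), p.z + rng.normal(0, 1.0), p.heading)
            for p in trial.poses
        ]
        wtrial = Trial("p", "0", "exp2", poses, [], sbend_small, 10.5)
        res = as_result(wtrial)
        lo, hi = sbend_small.analysis_window
        mask = (res.s_track >= lo) & (res.s_track <= hi)
        oracle = 100.0 * np.mean(
            [gs.offtrack(p, sbend_small) for p, m in zip(poses, mask) if m]
        )
        assert gs.offtrack_percentage(res) == pytest.approx(oracle)


class TestYawrateCorrelation:
    def _trial_with_yaw(self, slalom, yaws):
        poses = [Pose(0.0, 0.1 * i, 0.0, y) for i, y in enumerate(yaws)]
        return Trial("p", "0", "exp1", poses, [], slalom, 8.0)

    def test_identical_series(self, slalom):
        yaws = np.sin(np.linspace(0, 3, 50))
        t = self._trial_with_yaw(slalom, yaws)
        assert gs.yawrate_correlation(as_result(t), t) == pytest.approx(1.0)

    def test_mirrored_series(self, slalom):
        yaws = np.sin(np.linspace(0, 3, 50))
        t = self._trial_with_yaw(slalom, yaws)
        m = self._trial_with_yaw(slalom, -yaws)
        assert gs.yawrate_correlation(as_result(m), t) == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self, slalom):
        h = np.array([0.1, 0.3, -0.2, 0.0, 0.5, -0.1, 0.2, 0.4, -0.3, 0.1])
        m = np.array([0.2, 0.2, -0.1, 0.1, 0.4, -0.2, 0.3, 0.3, -0.2, 0.0])
        num = np.sum((h - h.mean()) * (m - m.mean()))
        den = math.sqrt(np.sum((h - h.mean()) ** 2) * np.sum((m - m.mean()) ** 2))
        t = self._trial_with_yaw(slalom, h)
        mt = self._trial_with_yaw(slalom, m)
        assert gs.yawrate_correlation(as_result(mt), t) == pytest.approx(num / den)

    def test_zero_variance_flagged(self, slalom):
        t = self._trial_with_yaw(slalom, np.zeros(20))
        m = self._trial_with_yaw(slalom, np.sin(np.linspace(0, 3, 20)))
        with pytest.warns(UserWarning):
            assert math.isnan(gs.yawrate_correlation(as_result(m), t))


class TestFisherAveraging:
    def test_identical_correlations_fixed_point(self):
        assert fisher_mean([0.4, 0.4, 0.4]) == pytest.approx(0.4)

    def test_handles_perfect_correlation(self):
        out = fisher_mean([1.0, 0.5])
        assert 0.5 < out <= 1.0 and np.isfinite(out)

    def test_nan_excluded(self):
        assert fisher_mean([0.3, math.nan]) == pytest.approx(0.3)

    def test_differs_from_arithmetic_mean(self):
        rs = [0.1, 0.9]
        assert fisher_mean(rs) > np.mean(rs)


class TestLandmarkCorrelations:
    def _dataset(self, slalom, rho_noise=0.0, n_trials=6, seed=0):
        """Participants whose model lane positions equal (or perturb) the
        human lane positions at each waypoint."""
        rng = np.random.default_rng(seed)
        humans, models = [], []
        for pid in ("pa", "pb"):
            for t in range(n_trials):
                offset = float(rng.uniform(-0.5, 0.5))
                trial = centerline_trial(slalom, v=8.0, participant_id=pid, trial_id=str(t))
                human = shifted_trial(trial, offset)
                human.participant_id = pid
                model_off = offset + rng.normal(0, rho_noise)
                model = as_result(shifted_trial(trial, model_off))
                humans.append(human)
                models.append(model)
        return models, humans

    def test_identical_lane_positions_r_one(self, slalom):
        models, humans = self._dataset(slalom, rho_noise=0.0)
        lms = {f"WP{i+1}": float(s) for i, s in enumerate(slalom.waypoint_s)}
        out = gs.landmark_trajectory_correlation(models, humans, lms, slalom)
        for r in out.values():
            assert r == pytest.approx(1.0, abs=1e-6)

    def test_zero_variance_participant_dropped(self, slalom):
        models, humans = self._dataset(slalom, rho_noise=0.0)
        # overwrite one participant's model results with constant lane position
        const = as_result(centerline_trial(slalom, v=8.0))
        models = [
            const if h.participant_id == "pa" else m
            for m, h in zip(models, humans)
        ]
        lms = {"WP1": float(slalom.waypoint_s[0])}
        with pytest.warns(UserWarning, match="zero variance"):
            out = gs.landmark_trajectory_correlation(models, humans, lms, slalom)
        assert out["WP1"] == pytest.approx(1.0, abs=1e-6)  # only pb remains

    def test_noisy_common_correlation_recovered(self, slalom):
        models, humans = self._dataset(slalom, rho_noise=0.15, n_trials=40, seed=3)
        lms = {"WP2": float(slalom.waypoint_s[1])}
        out = gs.landmark_trajectory_correlation(models, humans, lms, slalom)
        # expected rho = sd_signal / sqrt(sd_signal^2 + sd_noise^2)
        sd_signal = 1.0 / math.sqrt(12.0)
        rho = sd_signal / math.sqrt(sd_signal**2 + 0.15**2)
        assert out["WP2"] == pytest.approx(rho, abs=0.1)


class TestSummarize:
    def test_grand_mean_unweighted_by_trial_count(self, slalom):
        base = centerline_trial(slalom, v=8.0)
        # participant A: 3 trials at error 0.1; participant B: 1 trial at 0.5
        humans, models = [], []
        for pid, errs in (("A", [0.1] * 3), ("B", [0.5])):
            for i, e in enumerate(errs):
                h = shifted_trial(base, 0.0)
                h.participant_id, h.trial_id = pid, str(i)
                humans.append(h)
                models.append(as_result(shifted_trial(base, e)))
        summary = gs.summarize(models, humans)
        assert summary.grand_mean_error == pytest.approx(0.3, abs=1e-6)
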