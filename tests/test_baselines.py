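"""Baselines: known-weight Kalman, RLS variants, the augmented-state oracle,
and the two ad-hoc filter/learner couplings."""

import numpy as np
import pytest

from piaf import (
    JointBelief,
    KalmanBelief,
    RlsState,
    SystemParams,
    Trajectory,
    classical_rls_step,
    joint_kalman_step,
    kalman_step,
    rls_modified_piaf_step,
    run_kalman_rls_loop,
    run_rls_to_kalman,
)
from piaf.baselines import VARIANCE_SENTINEL

from conftest import random_belief


class TestKalmanStep:
    def test_null_command_zero_residual_closed_form(self):
        b = kalman_step(KalmanBelief(mu_z=1.0, Sigma_zz=3.0), np.zeros(1),
                        x=1.0, w_true=np.ones(1), sigma_p=0.5, sigma_s=2.0)
        P = 3.0 + 0.25
        assert b.mu_z == pytest.approx(1.0)
        assert b.Sigma_zz == pytest.approx(4.0 * P / (4.0 + P))

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            kalman_step(KalmanBelief(0.0, 0.0), np.zeros(1), 0.0,
                        np.ones(1), 0.0, 0.0)


class TestRlsModifiedPiafStep:
    def test_discards_incoming_cross_covariance(self, rng):
        b = random_belief(rng, 2)
        b_zeroed = JointBelief(mu_z=b.mu_z, mu_w=b.mu_w, Sigma_zz=b.Sigma_zz,
                               Sigma_ww=b.Sigma_ww, Sigma_zw=np.zeros(2))
        q, x = rng.normal(size=2), 0.4
        out = rls_modified_piaf_step(b, q, x, 0.1, 2.0)
        ref = rls_modified_piaf_step(b_zeroed, q, x, 0.1, 2.0)
        np.testing.assert_allclose(out.joint_mean(), ref.joint_mean())
        np.testing.assert_allclose(out.joint_cov(), ref.joint_cov())

    def test_null_command_gives_zero_cross_covariance(self, rng):
        out = rls_modified_piaf_step(random_belief(rng, 2), np.zeros(2),
                                     0.1, 0.0, 2.0)
        np.testing.assert_array_equal(out.Sigma_zw, np.zeros(2))

    def test_uses_inflated_noise_variance(self, rng):
        # the update must behave as if the sensor noise variance were doubled
        from piaf.core import measure_update, predict

        b = random_belief(rng, 1)
        b = JointBelief(mu_z=b.mu_z, mu_w=b.mu_w, Sigma_zz=b.Sigma_zz,
                        Sigma_ww=b.Sigma_ww, Sigma_zw=np.zeros(1))
        q, x, ss = np.array([0.5]), 1.1, 2.0
        out = rls_modified_piaf_step(b, q, x, 0.0, ss)
        ref = measure_update(predict(b, q, 0.0), x, ss, sigma_s_sq=2 * ss**2)
        np.testing.assert_allclose(out.joint_cov(), ref.joint_cov())


class TestClassicalRls:
    def test_exact_fit_noiseless(self):
        s = RlsState(D_q=1)
        for _ in range(5):
            s = classical_rls_step(s, np.array([1.0]), 1.0)
        assert s.mu_w[0] == pytest.approx(1.0, rel=1e-7)
        assert s.rss == pytest.approx(0.0, abs=1e-6)  # ridge-limited

    @pytest.mark.parametrize("D", [1, 2])
    def test_matches_batch_ols_every_step(self, rng, D):
        qs = rng.normal(size=(50, D))
        ys = qs @ np.arange(1, D + 1) + rng.normal(size=50)
        s = RlsState(D_q=D)
        for n in range(50):
            s = classical_rls_step(s, qs[n], ys[n])
            if n + 1 >= D:
                w_ols, rss, *_ = np.linalg.lstsq(qs[: n + 1], ys[: n + 1],
                                                 rcond=None)
                np.testing.assert_allclose(s.mu_w, w_ols, rtol=1e-6, atol=1e-8)
                if n + 1 > D:
                    # OLS standard-error covariance from the batch fit
                    resid = ys[: n + 1] - qs[: n + 1] @ w_ols
                    s2 = resid @ resid / (n + 1 - D)
                    cov = s2 * np.linalg.inv(qs[: n + 1].T @ qs[: n + 1])
                    np.testing.assert_allclose(s.sigma_w2, cov, rtol=1e-4,
                                               atol=1e-8)

    def test_variance_sentinel_before_identifiability(self):
        s = RlsState(D_q=1)
        assert s.sigma_w2[0, 0] == VARIANCE_SENTINEL
        s = classical_rls_step(s, np.array([2.0]), 1.0)
        assert s.sigma_w2[0, 0] == VARIANCE_SENTINEL  # exact fit, 0 dof
        s = classical_rls_step(s, np.array([1.0]), 1.0)
        assert np.isfinite(s.sigma_w2[0, 0])


class TestJointKalmanStep:
    def test_static_weight_mean_under_zero_residual(self, rng):
        b = random_belief(rng, 2)
        m, P = b.joint_mean(), b.joint_cov()
        q = rng.normal(size=2)
        F = np.eye(3)
        F[0, 1:] = q
        x = float((F @ m)[0])  # zero innovation
        m2, _ = joint_kalman_step(m, P, q, x, 0.2, 1.0)
        np.testing.assert_allclose(m2[1:], m[1:], rtol=1e-12)

    def test_zero_weight_covariance_reduces_to_known_w_kalman(self, rng):
        w = np.array([1.5, -0.3])
        P = np.zeros((3, 3))
        P[0, 0] = 2.0
        m = np.array([0.4, *w])
        q, x = rng.normal(size=2), 0.9
        m2, P2 = joint_kalman_step(m, P, q, x, 0.3, 2.0)
        kb = kalman_step(KalmanBelief(0.4, 2.0), q, x, w, 0.3, 2.0)
        assert m2[0] == pytest.approx(kb.mu_z, rel=1e-12)
        assert P2[0, 0] == pytest.approx(kb.Sigma_zz, rel=1e-12)
        np.testing.assert_allclose(m2[1:], w)


def _noiseless_traj(n=30, w=1.0, z0=0.0, seed=0):
    rng = np.random.default_rng(seed)
    q = rng.normal(size=n)
    params = SystemParams(w=np.array([w]), sigma_s=0.0, sigma_p=0.0)
    from piaf import simulate_trajectory

    return params, simulate_trajectory(params, q, z0, rng)


class TestCoupledRunners:
    def test_rls_to_kalman_noiseless_recovers_weight_immediately(self):
        params, traj = _noiseless_traj()
        out = run_rls_to_kalman(params, traj)
        # first differenced pair arrives at step 2 and fits exactly
        np.testing.assert_allclose(out.mu_w[1:, 0], 1.0, rtol=1e-6)
        np.testing.assert_allclose(out.mu_z_post[2:], traj.z[3:], atol=1e-6)

    def test_rls_to_kalman_three_step_hand_trace(self):
        # hand-rolled trace of the wiring on fixed numbers: Kalman predicts
        # with the learner's current estimate, updates on x, then RLS
        # consumes (qdot_n, x_n - x_{n-1}) from step 2 on
        params = SystemParams(w=np.array([1.0]), sigma_s=2.0, sigma_p=0.1)
        traj = Trajectory(z=np.array([0.0, 1.0, 1.5, 2.5]),
                          x=np.array([1.2, 1.4, 2.9]),
                          qdot=np.array([[1.0], [0.5], [1.0]]))
        priors = JointBelief.default_prior(1)
        out = run_rls_to_kalman(params, traj, priors)
        ss2 = 4.0
        # step 1: RLS prior mu_w=0, var_w=1
        mu, P = 0.0 + 1.0 * 0.0, 1e4 + 0.01 + 1.0**2 * 1.0
        S = ss2 + P
        mu, P = mu + P / S * (1.2 - mu), ss2 * P / S
        assert out.mu_z_post[0] == pytest.approx(mu, rel=1e-12)
        assert out.mu_w[0, 0] == 0.0
        # RLS pair at step 2: (0.5, 1.4 - 1.2) -> exact fit w = 0.4
        A, b = 0.25, 0.5 * 0.2
        w1 = b / (A + 1e-8)
        mu, P = mu + 0.5 * 0.0, P + 0.01 + 0.25 * 1.0  # predict before RLS
        S = ss2 + P
        mu, P = mu + P / S * (1.4 - mu), ss2 * P / S
        assert out.mu_z_post[1] == pytest.approx(mu, rel=1e-10)
        assert out.mu_w[1, 0] == pytest.approx(w1, rel=1e-6)
        assert out.var_w[1, 0] == VARIANCE_SENTINEL  # one pair, no dof
        # step 3: Kalman predicts with w1 and sentinel variance
        mu, P = mu + 1.0 * w1, P + 0.01 + 1.0 * VARIANCE_SENTINEL
        S = ss2 + P
        mu = mu + P / S * (2.9 - mu)
        assert out.mu_z_post[2] == pytest.approx(mu, rel=1e-10)

    def test_loop_with_zero_sensor_noise_tracks_truth(self):
        params, traj = _noiseless_traj(n=40, seed=2)
        out = run_kalman_rls_loop(params, traj)
        np.testing.assert_allclose(out.mu_z_post[2:], traj.z[3:], atol=1e-6)
        np.testing.assert_allclose(out.mu_w[5:, 0], 1.0, rtol=1e-6)

    def test_records_are_exportable(self):
        params, traj = _noiseless_traj(n=10)
        df = run_rls_to_kalman(params, traj).to_frame("rls_to_kalman")
        assert list(df["method"].unique()) == ["rls_to_kalman"]
        assert {"mu_z_prior", "mu_z_post", "var_z", "mu_w_0", "var_w_0"} <= set(
            df.columns
        )


@pytest.fixture(scope="module")
def batch():
    from piaf import _engine

    params = SystemParams(w=np.array([1.0]), sigma_s=2.0, sigma_p=0.05)
    return params, _engine.simulate_batch(params, "sinusoidal", 200, 3, 42)


class TestEngineMatchesReference:
    """The vectorized Monte-Carlo kernels agree step-for-step with the
    per-step reference implementations."""

    def _reference_se_z(self, method, params, traj):
        from piaf.core import run_filter

        priors = JointBelief.default_prior(1)
        if method == "piaf":
            run = run_filter(params, traj, priors)
            return (run.mu_z_post - traj.z[1:]) ** 2, (run.mu_w[:, 0] - 1) ** 2
        if method == "rls":
            b = priors
            se_z, se_w = [], []
            for n in range(traj.N):
                b = rls_modified_piaf_step(b, traj.qdot[n], traj.x[n],
                                           params.sigma_p, params.sigma_s)
                se_z.append((b.mu_z - traj.z[n + 1]) ** 2)
                se_w.append((b.mu_w[0] - 1) ** 2)
            return np.array(se_z), np.array(se_w)
        if method == "kalman":
            kb = KalmanBelief(priors.mu_z, priors.Sigma_zz)
            se_z = []
            for n in range(traj.N):
                kb = kalman_step(kb, traj.qdot[n], traj.x[n], params.w,
                                 params.sigma_p, params.sigma_s)
                se_z.append((kb.mu_z - traj.z[n + 1]) ** 2)
            return np.array(se_z), np.zeros(traj.N)
        runner = {"rls_to_kalman": run_rls_to_kalman,
                  "kalman_rls_loop": run_kalman_rls_loop}[method]
        out = runner(params, traj, priors)
        return ((out.mu_z_post - traj.z[1:]) ** 2,
                (out.mu_w[:, 0] - 1) ** 2)

    @pytest.mark.parametrize(
        "method", ["piaf", "rls", "kalman", "rls_to_kalman", "kalman_rls_loop"]
    )
    def test_squared_errors_match(self, batch, method):
        from piaf import _engine

        params, b = batch
        run = _engine.run_batch(method, b, params)
        for k in range(b.n_runs):
            traj = _engine.trajectory_of(b, k)
            se_z, se_w = self._reference_se_z(method, params, traj)
            np.testing.assert_allclose(run.se_z[:, k], se_z, rtol=1e-9,
                                       atol=1e-12)
            np.testing.assert_allclose(run.se_w[:, k], se_w, rtol=1e-9,
                                       atol=1e-12)
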