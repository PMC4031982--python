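"""Unit and property tests for the swimmer model core."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rheotaxis import (
    FlowProtocol,
    ModelParams,
    SwimmerState,
    angle_drift,
    fixed_points,
    orientation_drift,
    predicted_mean_velocities,
    simulate_ensemble,
    simulate_trajectory,
    stationary_angle_density,
    step,
)
from rheotaxis.model import (
    TWO_PI,
    max_stable_dt,
    orientation_moments,
    sample_stationary_angles,
)

from conftest import combined_se


def state_at(psi: float) -> SwimmerState:
    return SwimmerState(0.0, 0.0, psi)


# ---------------------------------------------------------------------------
# deterministic drift

class TestOrientationDrift:
    @pytest.mark.parametrize(
        "psi, chi, alpha, beta, gamma_dot, expected",
        [
            # antiparallel heading is a fixed point of the alpha term
            (math.pi, 0, 0.3, 0.075, 1.7, (0.0, 0.0)),
            # N = (1, 0): pure alpha rotation toward upstream
            (math.pi / 2, 0, 0.3, 0.075, 1.0, (0.0, -0.3)),
            # N = (0, -1): chirality term alone drives a transverse kick
            (math.pi, +1, 0.3, 0.075, 1.0, (-0.075, 0.0)),
        ],
    )
    def test_hand_evaluated_examples(self, psi, chi, alpha, beta, gamma_dot, expected):
        p = ModelParams(alpha=alpha, beta=beta, chi=chi)
        d = orientation_drift(state_at(psi), p, +1, gamma_dot)
        assert d == pytest.approx(expected, abs=1e-12)

    def test_tangency_on_random_states(self):
        """drift . N = 0 to <= 1e-12 for 1000 random states and parameters."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = ModelParams(
                alpha=rng.uniform(0.05, 1.0),
                beta=rng.uniform(0.0, 0.5),
                chi=int(rng.integers(-1, 2)),
            )
            s = state_at(rng.uniform(0, TWO_PI))
            d = orientation_drift(s, p, int(rng.choice([-1, 1])),
                                  rng.uniform(0.0, 9.0))
            assert abs(float(d @ s.orientation)) <= 1e-12


class TestAngleDrift:
    def test_downstream_is_equilibrium_without_chirality(self, achiral_params):
        assert angle_drift(0.0, achiral_params, +1, 3.0) == 0.0

    def test_hand_evaluated_value(self):
        p = ModelParams(alpha=0.3, beta=0.075, chi=0)
        assert angle_drift(math.pi / 2, p, +1, 2.0) == pytest.approx(0.6)

    @given(
        psi=st.floats(0, TWO_PI),
        alpha=st.floats(0.05, 1.0),
        beta=st.floats(0.0, 0.5),
        chi=st.sampled_from([-1, 0, 1]),
        sigma=st.sampled_from([-1, 1]),
        gamma_dot=st.floats(0.0, 9.0),
    )
    def test_equals_projected_vector_drift(self, psi, alpha, beta, chi, sigma,
                                           gamma_dot):
        """Scalar drift is the tangential projection of the 2-vector drift."""
        p = ModelParams(alpha=alpha, beta=beta, chi=chi)
        tangent = np.array([math.cos(psi), -math.sin(psi)])
        proj = float(orientation_drift(state_at(psi), p, sigma, gamma_dot) @ tangent)
        assert angle_drift(psi, p, sigma, gamma_dot) == pytest.approx(proj, abs=1e-12)

    def test_projection_on_fine_grid(self, params):
        psis = np.linspace(0, TWO_PI, 100, endpoint=False)
        for psi in psis:
            tangent = np.array([math.cos(psi), -math.sin(psi)])
            proj = float(orientation_drift(state_at(psi), params, +1, 2.5) @ tangent)
            assert angle_drift(psi, params, +1, 2.5) == pytest.approx(proj, abs=1e-12)


class TestFixedPoints:
    def test_achiral_pure_upstream(self, achiral_params):
        fps = dict((lab, psi) for psi, lab in fixed_points(achiral_params, +1, 2.0))
        assert math.sin(fps["stable"]) == pytest.approx(0.0, abs=1e-12)
        assert math.cos(fps["stable"]) == pytest.approx(-1.0)
        assert math.cos(fps["unstable"]) == pytest.approx(+1.0)

    def test_chiral_stable_heading(self, params):
        """Stable heading N* = (-chi beta, -alpha)/|(alpha, beta)|, checked
        against direct root-finding on the drift with a numerical Jacobian."""
        fps = fixed_points(params, +1, 2.5)
        stable = [psi for psi, lab in fps if lab == "stable"]
        assert len(stable) == 1
        n = np.array([math.sin(stable[0]), math.cos(stable[0])])
        assert n == pytest.approx([-0.2425, -0.9701], abs=1e-4)
        # every reported root annihilates the drift; stability matches the
        # sign of a centred finite-difference Jacobian
        for psi, lab in fps:
            assert angle_drift(psi, params, +1, 2.5) == pytest.approx(0.0, abs=1e-12)
            h = 1e-6
            jac = (angle_drift(psi + h, params, +1, 2.5)
                   - angle_drift(psi - h, params, +1, 2.5)) / (2 * h)
            assert (jac < 0) == (lab == "stable")

    def test_sigma_flip_maps_to_antipode(self, params):
        plus = dict((lab, psi) for psi, lab in fixed_points(params, +1, 2.5))
        minus = dict((lab, psi) for psi, lab in fixed_points(params, -1, 2.5))
        assert (plus["stable"] + math.pi) % TWO_PI == pytest.approx(
            minus["stable"], abs=1e-12
        )

    def test_zero_shear_raises(self, params):
        with pytest.raises(ValueError):
            fixed_points(params, +1, 0.0)


# ---------------------------------------------------------------------------
# stepping

class TestStep:
    def test_fixed_point_gives_straight_line(self, achiral_params):
        p = ModelParams(**{**achiral_params.__dict__, "D": 0.0})
        prot = FlowProtocol(gamma_dot=2.0)
        s = state_at(math.pi)  # stable upstream heading
        for _ in range(50):
            s = step(s, p, prot, 0.01, 0.0)
        assert s.psi == pytest.approx(math.pi)
        assert s.x == pytest.approx(0.0, abs=1e-12)
        # straight-line speed: -V (swimming) + U_bar (advection), along y
        assert s.y == pytest.approx(0.5 * (-p.V + prot.advection(p)))

    def test_determinism(self, params, steady_flow):
        a = step(state_at(0.3), params, steady_flow, 0.01, 1.234, t=2.0)
        b = step(state_at(0.3), params, steady_flow, 0.01, 1.234, t=2.0)
        assert (a.x, a.y, a.psi) == (b.x, b.y, b.psi)

    def test_nonfinite_state_raises(self, params, steady_flow):
        with pytest.raises(ValueError):
            step(SwimmerState(np.nan, 0.0, 0.0), params, steady_flow, 0.01, 0.0)

    def test_agrees_with_stratonovich_heun_vector_step(self, params):
        """One noise-free angle step matches a Stratonovich Euler-Heun step of
        the constrained 2-vector form to O(dt^2)."""
        prot = FlowProtocol(gamma_dot=2.5)
        psi0 = 0.9

        def heun_vector(dt):
            n = np.array([math.sin(psi0), math.cos(psi0)])

            def f(n):
                nx, ny = n
                g = prot.gamma_dot
                return g * params.alpha * np.array([nx * ny, ny**2 - 1]) + (
                    g * params.chi * params.beta
                ) * np.array([nx**2 - 1, nx * ny])

            pred = n + dt * f(n)
            return n + 0.5 * dt * (f(n) + f(pred))

        p0 = ModelParams(**{**params.__dict__, "D": 0.0})
        errs = []
        for dt in (1e-2, 1e-3, 1e-4):
            s = step(state_at(psi0), p0, prot, dt, 0.0)
            n_angle = np.array([math.sin(s.psi), math.cos(s.psi)])
            errs.append(np.linalg.norm(n_angle - heun_vector(dt)))
        # error shrinks like dt^2 (both schemes are first order with the same
        # leading term): each decade in dt gains ~two decades in error
        assert errs[0] / errs[1] == pytest.approx(100, rel=0.3)
        assert errs[1] / errs[2] == pytest.approx(100, rel=0.3)

    def test_unit_norm_conserved_exactly(self, params, steady_flow):
        rng = np.random.default_rng(1)
        s = state_at(0.2)
        for _ in range(200):
            s = step(s, params, steady_flow, 0.01, rng.standard_normal())
            n = s.orientation
            assert abs(float(n @ n) - 1.0) < 1e-15


class TestSimulateTrajectory:
    def test_zero_shear_zero_noise_straight_line(self):
        p = ModelParams(D=0.0)
        tr = simulate_trajectory(state_at(0.7), p, FlowProtocol(gamma_dot=0.0),
                                 duration=4.0, dt=0.01, seed=0)
        v = np.hypot(np.diff(tr.xs), np.diff(tr.ys)) / np.diff(tr.times)
        assert v == pytest.approx(np.full(v.size, 50.0))
        assert np.ptp(tr.psis) == 0.0

    def test_converges_to_stable_heading(self, params):
        p = ModelParams(**{**params.__dict__, "D": 0.0})
        stable = [psi for psi, lab in fixed_points(p, +1, 2.5) if lab == "stable"][0]
        tr = simulate_trajectory(state_at(0.35), p, FlowProtocol(gamma_dot=2.5),
                                 duration=40.0, dt=0.01, seed=0)
        assert abs(math.remainder(tr.psis[-1] - stable, TWO_PI)) < 1e-3

    def test_seed_reproducibility(self, params, steady_flow):
        a = simulate_trajectory(state_at(0.0), params, steady_flow, 5.0, seed=42)
        b = simulate_trajectory(state_at(0.0), params, steady_flow, 5.0, seed=42)
        assert np.array_equal(a.xs, b.xs) and np.array_equal(a.psis, b.psis)

    def test_stability_guard(self, params):
        prot = FlowProtocol(gamma_dot=9.0)
        limit = max_stable_dt(params, 9.0)
        with pytest.raises(ValueError, match="stability"):
            simulate_trajectory(state_at(0.0), params, prot, 1.0,
                                dt=limit * 1.5, seed=0)


class TestSimulateEnsemble:
    def test_n1_reduces_to_simulate_trajectory(self, params, steady_flow):
        child = np.random.SeedSequence(7).spawn(1)[0]
        tr = simulate_trajectory(state_at(1.234), params, steady_flow, 5.0,
                                 seed=child)
        ens = simulate_ensemble(1, params, steady_flow, 5.0, seed=7,
                                initial=np.array([1.234]))
        e = ens.tracks[0]
        assert np.array_equal(tr.xs, e.xs)
        assert np.array_equal(tr.ys, e.ys)
        assert np.array_equal(tr.psis, e.psis)

    def test_master_seed_reproducibility(self, params, steady_flow):
        a = simulate_ensemble(5, params, steady_flow, 3.0, seed=11)
        b = simulate_ensemble(5, params, steady_flow, 3.0, seed=11)
        for ta, tb in zip(a.tracks, b.tracks):
            assert np.array_equal(ta.xs, tb.xs)

    def test_zero_shear_ensemble_mean_velocity_isotropic(self, params):
        """At zero shear the model is isotropic: ensemble-mean velocity is 0
        within 3 standard errors."""
        ts = simulate_ensemble(400, params, FlowProtocol(gamma_dot=0.0),
                               duration=30.0, seed=3, frame_rate=25.0)
        vmx, vmy = [], []
        for tr in ts:
            vmx.append(np.gradient(tr.xs, tr.times).mean())
            vmy.append(np.gradient(tr.ys, tr.times).mean())
        for comp in (np.array(vmx), np.array(vmy)):
            se = comp.std(ddof=1) / math.sqrt(comp.size)
            assert abs(comp.mean()) < 3 * se


# ---------------------------------------------------------------------------
# stationary Fokker-Planck quadrature

class TestStationaryDensity:
    def test_uniform_at_zero_shear(self, params):
        _, p = stationary_angle_density(params, +1, 0.0, n_grid=512)
        assert p == pytest.approx(np.full(512, 1.0 / TWO_PI))

    def test_normalized_nonneg_mode_at_stable_point(self, params):
        psi, p = stationary_angle_density(params, +1, 2.5, n_grid=4096)
        assert np.all(p >= 0)
        assert (p.sum() * TWO_PI / 4096) == pytest.approx(1.0, abs=1e-8)
        stable = [s for s, lab in fixed_points(params, +1, 2.5) if lab == "stable"][0]
        assert abs(psi[np.argmax(p)] - stable) < TWO_PI / 4096 * 1.5

    def test_achiral_density_symmetric_no_transverse_drift(self, achiral_params):
        nx, _ = orientation_moments(achiral_params, +1, 2.5)
        assert abs(nx) < 1e-12

    def test_zero_noise_raises(self, params):
        with pytest.raises(ValueError):
            stationary_angle_density(
                ModelParams(**{**params.__dict__, "D": 0.0}), +1, 2.5
            )

    def test_small_noise_limit_recovers_fixed_point(self, params):
        p = ModelParams(**{**params.__dict__, "D": 1e-4})
        stable = [s for s, lab in fixed_points(p, +1, 2.5) if lab == "stable"][0]
        nx, ny = orientation_moments(p, +1, 2.5, n_grid=1 << 16)
        assert nx == pytest.approx(math.sin(stable), abs=1e-2)
        assert ny == pytest.approx(math.cos(stable), abs=1e-2)

    def test_stationary_sampler_matches_density_moments(self, params):
        rng = np.random.default_rng(5)
        draws = sample_stationary_angles(params, +1, 2.5, 20000, rng)
        nx, ny = orientation_moments(params, +1, 2.5)
        assert np.sin(draws).mean() == pytest.approx(nx, abs=0.02)
        assert np.cos(draws).mean() == pytest.approx(ny, abs=0.02)


class TestPredictedMeanVelocities:
    def test_zero_shear_is_zero(self, params):
        assert predicted_mean_velocities(params, +1, 0.0) == pytest.approx((0, 0))

    def test_no_chirality_no_transverse(self, achiral_params):
        vx, _ = predicted_mean_velocities(achiral_params, +1, 2.5)
        assert abs(vx) < 1e-12

    def test_matches_monte_carlo_time_average(self, params):
        """Quadrature moments agree with a long ensemble time average within
        3 clustered standard errors (stationary initial headings)."""
        ts = simulate_ensemble(300, params, FlowProtocol(gamma_dot=2.5),
                               duration=60.0, seed=9, frame_rate=25.0,
                               initial="stationary")
        vx_pred, vy_pred = predicted_mean_velocities(params, +1, 2.5)
        mx = np.array([np.gradient(t.xs, t.times).mean() for t in ts])
        my = np.array([np.gradient(t.ys, t.times).mean() for t in ts])
        for sample, pred in ((mx, vx_pred), (my, vy_pred)):
            se = sample.std(ddof=1) / math.sqrt(sample.size)
            assert abs(sample.mean() - pred) < 3 * se


class TestFlowProtocol:
    def test_sigma_steps_at_reversal(self):
        prot = FlowProtocol(gamma_dot=1.0, reversal_times=(10.0,))
        assert prot.sigma(10.0 - 1e-9) == 1
        assert prot.sigma(10.0 + 1e-9) == -1

    def test_ramp_midpoint_has_zero_amplitude(self):
        prot = FlowProtocol(gamma_dot=1.0, reversal_times=(10.0,),
                            switching_time=0.8)
        assert prot.signed_amplitude(10.4) == pytest.approx(0.0, abs=1e-12)
        assert prot.signed_amplitude(9.999) == 1.0
        assert prot.signed_amplitude(10.8) == -1.0

    @given(t=st.floats(-50, 50))
    def test_amplitude_bounded(self, t):
        prot = FlowProtocol(gamma_dot=1.0, reversal_times=(0.0, 20.0),
                            switching_time=0.5)
        assert -1.0 <= prot.signed_amplitude(t) <= 1.0

    def test_switching_time_below_one_second(self):
        with pytest.raises(ValueError):
            FlowProtocol(gamma_dot=1.0, switching_time=1.0)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(alpha=0.0), dict(beta=-0.1), dict(chi=2),
                   dict(D=-0.1), dict(A=0.0), dict(h_adv=0.0), dict(V=-1.0)]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)
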