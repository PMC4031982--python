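"""Minimal stochastic model of sperm rheotaxis near a channel wall.

A sperm cell swimming in the effective 2-D plane of a wall, exposed to a
linear shear flow of rate ``gamma_dot`` along the y axis, is described by its
position ``R = (X, Y)`` and unit orientation ``N = (N_x, N_y)``:

    dR/dt = V N + sigma * U_bar * e_y
    dN/dt = sigma*gamma_dot*alpha * (N_x N_y, N_y^2 - 1)
          + sigma*gamma_dot*chi*beta * (N_x^2 - 1, N_x N_y)
          + sqrt(2 D) (I - N N) . xi(t)        (Stratonovich)

where ``sigma = +-1`` is the flow direction, ``V`` the swimming speed,
``alpha`` the shear-alignment shape factor, ``beta`` the chirality shape
factor with handedness ``chi in {-1, 0, +1}``, ``D`` the orientational noise
amplitude and ``U_bar`` the mean advection speed experienced by the cell.
The alpha term aligns the cell against the flow; the chirality term tilts
the stable heading sideways (sign -chi); the projected white noise keeps
``|N| = 1``.

Internally the orientation is a single angle ``psi`` with
``N = (sin psi, cos psi)`` (psi = 0 points along +y, the sigma=+1 flow
direction), which conserves the unit norm exactly.  On the circle the model
reduces to

    dpsi/dt = sigma*gamma_dot*(alpha sin psi - chi beta cos psi) + sqrt(2D) eta(t)

with scalar white noise eta; the noise is additive in psi, so the Ito and
Stratonovich readings coincide and a plain Euler-Maruyama step is used.  The
deterministic part derives from a potential
``Phi(psi) = sigma*gamma_dot*(alpha cos psi + chi beta sin psi)``, giving the
closed-form stationary angle density ``p(psi) ~ exp(-Phi(psi)/D)`` used for
quadrature predictions of the ensemble-mean velocities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "FlowProtocol",
    "SwimmerState",
    "Track",
    "orientation_drift",
    "angle_drift",
    "fixed_points",
    "step",
    "max_stable_dt",
    "simulate_trajectory",
    "simulate_ensemble",
    "stationary_angle_density",
    "orientation_moments",
    "sample_stationary_angles",
    "predicted_mean_velocities",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of one swimmer.

    Parameters
    ----------
    V : swimming speed, um/s.
    alpha : shear-alignment shape factor (dimensionless, > 0).
    beta : chirality shape factor (dimensionless, >= 0).
    chi : chirality sign, one of {-1, 0, +1}; +1 for human sperm at low
        viscosity, 0 for weakly chiral bull sperm.
    D : orientational noise amplitude, rad^2/s (configs accept the printed
        rad/s figures unchanged).
    A : flagellar beat amplitude, um; 2A is the beat-envelope height.
    ell : sperm length, um (metadata only, not used by the dynamics).
    h_adv : effective advection height above the wall, um; the default mean
        advection speed is ``gamma_dot * h_adv``.
    """

    V: float = 50.0
    alpha: float = 0.3
    beta: float = 0.075
    chi: int = +1
    D: float = 0.25
    A: float = 10.0
    ell: float = 60.0
    h_adv: float = 10.0

    def __post_init__(self) -> None:
        if not (self.V >= 0):
            raise ValueError(f"V must be >= 0, got {self.V}")
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not (self.beta >= 0):
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.chi not in (-1, 0, 1):
            raise ValueError(f"chi must be one of -1, 0, +1, got {self.chi}")
        if not (self.D >= 0):
            raise ValueError(f"D must be >= 0, got {self.D}")
        if not (self.A > 0):
            raise ValueError(f"A must be > 0, got {self.A}")
        if not (self.h_adv > 0):
            raise ValueError(f"h_adv must be > 0, got {self.h_adv}")


@dataclass(frozen=True)
class FlowProtocol:
    """Time course of the imposed near-wall flow.

    The flow points along +-y.  ``sigma0`` is the initial direction; at each
    time in ``reversal_times`` the direction reverses, either instantaneously
    (``switching_time = 0``) or through a linear ramp of the signed amplitude
    over ``switching_time`` seconds.  ``signed_amplitude(t)`` in [-1, 1]
    multiplies both the shear rate and the advection speed in the dynamics;
    ``sigma(t)`` is its sign (the ramp midpoint switches the sign).

    U_bar is the mean advection speed (um/s) of the cell body; when None it
    defaults to ``gamma_dot * params.h_adv`` at simulation time.
    """

    gamma_dot: float
    U_bar: float | None = None
    reversal_times: tuple[float, ...] = ()
    switching_time: float = 0.0
    sigma0: int = +1

    def __post_init__(self) -> None:
        if not (self.gamma_dot >= 0):
            raise ValueError(f"gamma_dot must be >= 0, got {self.gamma_dot}")
        if self.U_bar is not None and not (self.U_bar >= 0):
            raise ValueError(f"U_bar must be >= 0, got {self.U_bar}")
        if not (0.0 <= self.switching_time < 1.0):
            raise ValueError(
                f"switching_time must be in [0, 1) s, got {self.switching_time}"
            )
        if self.sigma0 not in (-1, 1):
            raise ValueError(f"sigma0 must be +-1, got {self.sigma0}")
        rt = tuple(float(t) for t in self.reversal_times)
        if any(b <= a for a, b in zip(rt, rt[1:])):
            raise ValueError("reversal_times must be strictly increasing")
        object.__setattr__(self, "reversal_times", rt)

    def advection(self, params: ModelParams | None = None) -> float:
        """Mean advection speed U_bar, um/s."""
        if self.U_bar is not None:
            return self.U_bar
        if params is None:
            raise ValueError("U_bar not set and no ModelParams given")
        return self.gamma_dot * params.h_adv

    def signed_amplitude(self, t):
        """Signed flow amplitude in [-1, 1] at time(s) t (ramped at reversals)."""
        t = np.asarray(t, dtype=float)
        s = np.full(t.shape, float(self.sigma0))
        for r in self.reversal_times:
            if self.switching_time > 0:
                f = np.clip(1.0 - 2.0 * (t - r) / self.switching_time, -1.0, 1.0)
                f = np.where(t < r, 1.0, f)
            else:
                f = np.where(t < r, 1.0, -1.0)
            s = s * f
        return s if s.shape else float(s)

    def sigma(self, t):
        """Flow direction sign at time(s) t; flips at each ramp midpoint."""
        t = np.asarray(t, dtype=float)
        s = np.full(t.shape, self.sigma0, dtype=int)
        for r in self.reversal_times:
            mid = r + 0.5 * self.switching_time
            s = s * np.where(t < mid, 1, -1)
        return s if s.shape else int(s)


@dataclass(frozen=True)
class SwimmerState:
    """Instantaneous position (um) and heading angle (rad) of one cell."""

    x: float
    y: float
    psi: float

    @property
    def orientation(self) -> np.ndarray:
        """Unit orientation vector N = (sin psi, cos psi)."""
        return np.array([math.sin(self.psi), math.cos(self.psi)])


@dataclass
class Track:
    """Time-stamped positions (and optionally headings) of one cell."""

    cell_id: str
    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    psis: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        if self.psis is not None:
            self.psis = np.asarray(self.psis, dtype=float)
        n = self.times.size
        if self.xs.size != n or self.ys.size != n or (
            self.psis is not None and self.psis.size != n
        ):
            raise ValueError("times, xs, ys (and psis) must have equal length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"track {self.cell_id}: times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0


# ---------------------------------------------------------------------------
# deterministic structure

def orientation_drift(
    state: SwimmerState, params: ModelParams, sigma: int, gamma_dot: float
) -> np.ndarray:
    """Deterministic rate of change of the orientation vector N.

    Returns the alpha (shear alignment) plus chi*beta (chirality turning)
    terms evaluated at the state's orientation; the result is tangent to the
    unit circle (orthogonal to N).
    """
    nx, ny = math.sin(state.psi), math.cos(state.psi)
    g = sigma * gamma_dot
    return g * params.alpha * np.array([nx * ny, ny * ny - 1.0]) + (
        g * params.chi * params.beta
    ) * np.array([nx * nx - 1.0, nx * ny])


def angle_drift(psi, params: ModelParams, sigma: int, gamma_dot: float):
    """Scalar angular drift dpsi/dt = sigma*gamma_dot*(alpha sin psi - chi beta cos psi).

    Exact reduction of :func:`orientation_drift` to the circle; equals its
    projection on the tangent (cos psi, -sin psi).
    """
    return (
        sigma
        * gamma_dot
        * (params.alpha * np.sin(psi) - params.chi * params.beta * np.cos(psi))
    )


def fixed_points(
    params: ModelParams, sigma: int, gamma_dot: float
) -> list[tuple[float, str]]:
    """Equilibria of the deterministic angle dynamics with stability labels.

    The drift vanishes where tan psi = chi*beta/alpha, giving two antipodal
    roots; stability follows the sign of the linearised drift
    sigma*gamma_dot*(alpha cos psi + chi beta sin psi).  For sigma=+1 the
    stable heading is N* = (-chi beta, -alpha)/sqrt(alpha^2 + beta^2):
    upstream with a transverse tilt of sign -chi.
    """
    if gamma_dot <= 0:
        raise ValueError("fixed_points requires gamma_dot > 0 "
                         "(at zero shear every heading is neutrally stable)")
    b = params.chi * params.beta
    roots = [math.atan2(b, params.alpha) % TWO_PI]
    roots.append((roots[0] + math.pi) % TWO_PI)
    out = []
    for psi in roots:
        deriv = sigma * gamma_dot * (
            params.alpha * math.cos(psi) + b * math.sin(psi)
        )
        out.append((psi, "stable" if deriv < 0 else "unstable"))
    return out


def max_stable_dt(params: ModelParams, gamma_dot: float) -> float:
    """Largest time step accepted by the explicit integrator, s."""
    return 0.1 / max(1.0, gamma_dot * max(params.alpha, params.beta))


# ---------------------------------------------------------------------------
# stochastic stepping

def step(
    state: SwimmerState,
    params: ModelParams,
    protocol: FlowProtocol,
    dt: float,
    noise_increment: float,
    t: float = 0.0,
) -> SwimmerState:
    """One Euler-Maruyama step of the angle dynamics plus the position update.

    ``noise_increment`` is a standard-normal draw; the angular kick is
    ``sqrt(2 D dt) * noise_increment``.  The orientation norm is conserved
    exactly because only the angle is advanced.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not (
        math.isfinite(state.x) and math.isfinite(state.y) and math.isfinite(state.psi)
    ):
        raise ValueError(f"non-finite swimmer state: {state}")
    s = protocol.signed_amplitude(t)
    u_bar = protocol.advection(params)
    sin_p, cos_p = math.sin(state.psi), math.cos(state.psi)
    x = state.x + dt * params.V * sin_p
    y = state.y + dt * (params.V * cos_p + s * u_bar)
    psi = (
        state.psi
        + dt * s * protocol.gamma_dot
        * (params.alpha * sin_p - params.chi * params.beta * cos_p)
        + math.sqrt(2.0 * params.D * dt) * noise_increment
    )
    return SwimmerState(x, y, psi)


def _integrate(
    psi0: np.ndarray,
    x0: np.ndarray,
    y0: np.ndarray,
    noise: np.ndarray,
    params: ModelParams,
    protocol: FlowProtocol,
    dt: float,
    t0: float = 0.0,
    omega0: float = 0.0,
):
    """Vectorised Euler-Maruyama integration of n swimmers over noise.shape[0] steps.

    ``noise`` holds standard normals, shape (n_steps, n).  ``omega0`` is an
    optional constant intrinsic turning rate (rad/s) used only by the
    synthetic-track generator; the model proper has omega0 = 0.  Returns
    (times, xs, ys, psis) with shape (n_steps + 1, n); the per-column math is
    identical to :func:`step`, so a single column reproduces a scalar run
    bit for bit.
    """
    n_steps, n = noise.shape
    times = t0 + dt * np.arange(n_steps + 1)
    xs = np.empty((n_steps + 1, n))
    ys = np.empty((n_steps + 1, n))
    psis = np.empty((n_steps + 1, n))
    x = np.array(x0, dtype=float, copy=True)
    y = np.array(y0, dtype=float, copy=True)
    psi = np.array(psi0, dtype=float, copy=True)
    xs[0], ys[0], psis[0] = x, y, psi

    amp = np.atleast_1d(protocol.signed_amplitude(times[:-1]))
    u_bar = protocol.advection(params)
    gd = protocol.gamma_dot
    a = params.alpha
    b = params.chi * params.beta
    V = params.V
    kick = math.sqrt(2.0 * params.D * dt)
    for k in range(n_steps):
        s = amp[k]
        sin_p = np.sin(psi)
        cos_p = np.cos(psi)
        x = x + dt * V * sin_p
        y = y + dt * (V * cos_p + s * u_bar)
        psi = psi + dt * (s * gd * (a * sin_p - b * cos_p) + omega0) + kick * noise[k]
        xs[k + 1], ys[k + 1], psis[k + 1] = x, y, psi
    return times, xs, ys, psis


def _frame_stride(frame_rate: float | None, dt: float) -> int:
    if frame_rate is None:
        return 1
    stride = 1.0 / (frame_rate * dt)
    if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
        raise ValueError(
            f"frame rate {frame_rate}/s is not a whole multiple of the step 1/dt"
        )
    return int(round(stride))


def _check_dt(params: ModelParams, protocol: FlowProtocol, dt: float) -> None:
    if dt <= 0:
        raise ValueError("dt must be > 0")
    lim = max_stable_dt(params, protocol.gamma_dot)
    if dt > lim * (1 + 1e-12):
        raise ValueError(
            f"dt = {dt} s exceeds the stability guard {lim:.4g} s "
            f"for gamma_dot = {protocol.gamma_dot}/s"
        )


def simulate_trajectory(
    initial: SwimmerState,
    params: ModelParams,
    protocol: FlowProtocol,
    duration: float,
    dt: float = 0.01,
    seed=None,
    t0: float = 0.0,
    frame_rate: float | None = None,
    cell_id: str = "c00000",
) -> Track:
    """Integrate one swimmer for ``duration`` seconds; reproducible given seed.

    The track is optionally decimated to ``frame_rate`` samples per second
    (1/(frame_rate*dt) must be a whole number).  ``seed`` may be an int or a
    numpy SeedSequence.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    _check_dt(params, protocol, dt)
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_steps, 1))
    times, xs, ys, psis = _integrate(
        np.array([initial.psi]),
        np.array([initial.x]),
        np.array([initial.y]),
        noise,
        params,
        protocol,
        dt,
        t0=t0,
    )
    k = _frame_stride(frame_rate, dt)
    return Track(cell_id, times[::k], xs[::k, 0], ys[::k, 0], psis[::k, 0])


def simulate_ensemble(
    n: int,
    params: ModelParams,
    protocol: FlowProtocol,
    duration: float,
    dt: float = 0.01,
    seed=None,
    initial="uniform",
    t0: float = 0.0,
    frame_rate: float | None = None,
    x0: np.ndarray | None = None,
    y0: np.ndarray | None = None,
    omega0: float = 0.0,
    species: str = "model",
):
    """Simulate n independent swimmers; returns a :class:`~rheotaxis.tracks.TrackSet`.

    Per-track seeds are spawned deterministically from the master ``seed``
    via ``numpy.random.SeedSequence``; track i matches
    ``simulate_trajectory(..., seed=SeedSequence(seed).spawn(n)[i])`` exactly
    when the initial angle is supplied explicitly.

    ``initial`` selects the initial-heading policy: ``"uniform"`` (default;
    each track's angle is the first draw of its own stream), ``"stationary"``
    (inverse-CDF sample of the stationary angle density under the protocol's
    initial flow sign), or an array of n angles.
    """
    from .tracks import Condition, TrackSet  # deferred: tracks imports model

    if n < 1:
        raise ValueError("n must be >= 1")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    _check_dt(params, protocol, dt)
    n_steps = int(round(duration / dt))

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n)

    psi0 = np.empty(n)
    noise = np.empty((n_steps, n))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        if isinstance(initial, str) and initial == "uniform":
            psi0[i] = rng.uniform(0.0, TWO_PI)
        elif isinstance(initial, str) and initial == "stationary":
            psi0[i] = sample_stationary_angles(
                params, protocol.sigma(t0), protocol.gamma_dot, 1, rng
            )[0]
        else:
            psi0[i] = np.asarray(initial, dtype=float)[i]
        noise[:, i] = rng.standard_normal(n_steps)

    x0 = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float)
    y0 = np.zeros(n) if y0 is None else np.asarray(y0, dtype=float)
    times, xs, ys, psis = _integrate(
        psi0, x0, y0, noise, params, protocol, dt, t0=t0, omega0=omega0
    )
    k = _frame_stride(frame_rate, dt)
    tracks = [
        Track(f"c{i:05d}", times[::k], xs[::k, i], ys[::k, i], psis[::k, i])
        for i in range(n)
    ]
    condition = Condition(
        viscosity_mpas=None, gamma_dot=protocol.gamma_dot, species=species
    )
    provenance = {
        "generator": "simulate_ensemble",
        "seed": None if seed is None else repr(seed),
        "dt_s": dt,
        "omega0_rad_per_s": omega0,
    }
    return TrackSet(tracks=tracks, condition=condition, provenance=provenance)


# ---------------------------------------------------------------------------
# stationary Fokker-Planck quadrature

def stationary_angle_density(
    params: ModelParams, sigma: int, gamma_dot: float, n_grid: int = 2048
):
    """Stationary density of the heading angle on a uniform grid over [0, 2pi).

    Closed form of the periodic Fokker-Planck equation for the angle SDE:
    p(psi) ~ exp(-Phi(psi)/D) with
    Phi(psi) = sigma*gamma_dot*(alpha cos psi + chi beta sin psi).
    Returns (psi_grid, density); the Riemann sum over the grid is exactly 1.
    """
    if params.D <= 0:
        raise ValueError(
            "stationary density requires D > 0 (D = 0 collapses to a point "
            "mass at the stable fixed point; use fixed_points)"
        )
    psi = np.linspace(0.0, TWO_PI, n_grid, endpoint=False)
    phi = sigma * gamma_dot * (
        params.alpha * np.cos(psi) + params.chi * params.beta * np.sin(psi)
    )
    w = np.exp(-(phi - phi.min()) / params.D)
    p = w / (w.sum() * (TWO_PI / n_grid))
    return psi, p


def orientation_moments(
    params: ModelParams, sigma: int, gamma_dot: float, n_grid: int = 2048
) -> tuple[float, float]:
    """Stationary means (<N_x>, <N_y>) by quadrature over the angle density."""
    psi, p = stationary_angle_density(params, sigma, gamma_dot, n_grid)
    d = TWO_PI / n_grid
    return float((p * np.sin(psi)).sum() * d), float((p * np.cos(psi)).sum() * d)


def sample_stationary_angles(
    params: ModelParams,
    sigma: int,
    gamma_dot: float,
    n: int,
    rng: np.random.Generator,
    n_grid: int = 4096,
) -> np.ndarray:
    """Draw n angles from the stationary density by inverse-CDF on a fine grid."""
    psi, p = stationary_angle_density(params, sigma, gamma_dot, n_grid)
    cdf = np.cumsum(p) * (TWO_PI / n_grid)
    cdf /= cdf[-1]
    return np.interp(rng.uniform(0.0, 1.0, n), cdf, psi + TWO_PI / n_grid)


def predicted_mean_velocities(
    params: ModelParams,
    sigma: int,
    gamma_dot: float,
    U_bar: float | None = None,
    n_grid: int = 2048,
) -> tuple[float, float]:
    """Stationary ensemble-mean velocity (<v_x>, <v_y>) in um/s.

    (V <N_x>, V <N_y> + sigma U_bar) with the orientation moments taken under
    the stationary angle density; U_bar defaults to gamma_dot * h_adv.
    """
    nx, ny = orientation_moments(params, sigma, gamma_dot, n_grid)
    u = gamma_dot * params.h_adv if U_bar is None else U_bar
    return params.V * nx, params.V * ny + sigma * u
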