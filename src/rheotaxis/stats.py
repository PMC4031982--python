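"""Trajectory kinematics statistics: velocities, curvature, reversal response.

This is the analysis layer applied identically to synthetic and (in
principle) experimental PTV tracks: finite-difference velocities per track,
per-condition normalized mean upstream/transverse velocities with
track-clustered standard errors and histograms, the zero-shear sample mean
speed used as the normalization constant, signed trajectory curvature from
local quadratic (Savitzky-Golay) fits, and time-resolved ensemble response
to a flow reversal with a 90%-recovery response time.

Sign conventions: the flow points along sigma * e_y; the "upstream" velocity
component is -sigma * v_y (positive = progress against the flow) and the
transverse component is v_x.  Positive curvature is counterclockwise turning
in the (x, y) plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .model import FlowProtocol, Track
from .tracks import TrackSet

__all__ = [
    "VelocityStats",
    "ResponseCurve",
    "track_velocities",
    "zero_shear_mean_speed",
    "ensemble_velocity_stats",
    "signed_curvature",
    "response_curve",
]


@dataclass
class VelocityStats:
    """Normalized ensemble velocity statistics for one (gamma_dot, mu) condition.

    Means are over pooled samples, normalized by the zero-shear speed v0;
    standard errors cluster by track (per-sample velocities within a track
    are autocorrelated), se = sd(track means)/sqrt(n_tracks); ``sd_*`` keep
    the raw spread of the track means for experiment-level error bars.
    """

    mean_upstream: float
    mean_transverse: float
    se_upstream: float
    se_transverse: float
    sd_upstream: float
    sd_transverse: float
    hist_upstream: tuple[np.ndarray, np.ndarray] | None
    hist_transverse: tuple[np.ndarray, np.ndarray] | None
    n_samples: int
    n_tracks: int
    v0: float


@dataclass
class ResponseCurve:
    """Time-binned ensemble response to a flow reversal at t = 0 (relative).

    ``mean_upstream_series`` is the mean velocity along the *instantaneous*
    upstream direction, -sigma(t) <v_y>(t), in um/s; the transient peak right
    after reversal (cells momentarily carried with the new flow) appears as
    a negative excursion.  ``flow_reference_series`` is the signed flow speed
    5 um above the wall.  ``tau`` is the recovery time: the first time after
    the reversal at which the upstream mean reaches ``recovery_fraction`` of
    its post-reversal long-time mean.
    """

    times: np.ndarray
    mean_upstream_series: np.ndarray
    mean_transverse_series: np.ndarray
    flow_reference_series: np.ndarray
    tau: float
    tail_mean: float
    recovery_fraction: float


def track_velocities(track: Track, frame_rate: float | None = None) -> np.ndarray:
    """Per-sample velocity vectors (um/s), shape (n, 2).

    Central differences at interior samples, one-sided at the ends
    (``numpy.gradient`` on the sample times).  ``frame_rate`` is accepted for
    interface symmetry but the track's own time stamps are authoritative.
    """
    if len(track) < 3:
        raise ValueError("velocity estimation needs at least 3 samples")
    vx = np.gradient(track.xs, track.times)
    vy = np.gradient(track.ys, track.times)
    return np.column_stack([vx, vy])


def zero_shear_mean_speed(ts: TrackSet) -> float:
    """Sample mean speed v0 (um/s) pooled over all tracks of a zero-shear set."""
    if ts.condition is not None and ts.condition.gamma_dot != 0:
        raise ValueError(
            f"zero-shear speed requires gamma_dot = 0, got {ts.condition.gamma_dot}"
        )
    if len(ts) == 0:
        raise ValueError("empty TrackSet")
    speeds = [np.hypot(*track_velocities(t).T) for t in ts]
    return float(np.concatenate(speeds).mean())


def _check_constant_sigma(protocol: FlowProtocol, ts: TrackSet) -> int:
    sigmas = set()
    for t in ts:
        s = np.atleast_1d(protocol.sigma(t.times))
        sigmas.update(np.unique(s).tolist())
    if len(sigmas) != 1:
        raise ValueError(
            "mixed flow directions within the averaging window; "
            "split the data at the reversal(s) or use response_curve"
        )
    return int(sigmas.pop())


def ensemble_velocity_stats(
    ts: TrackSet,
    v0: float,
    sigma: int = +1,
    protocol: FlowProtocol | None = None,
    bins: int = 40,
    bin_range: tuple[float, float] | None = None,
) -> VelocityStats:
    """Normalized mean upstream/transverse velocities of a track ensemble.

    Velocities are normalized by the zero-shear mean speed ``v0``; upstream
    is -sigma*v_y/v0.  If a ``protocol`` is given, sigma is taken from it and
    an error is raised if the flow direction changes within the data span.
    Histogram bin edges default to the pooled data range so that the counts
    sum exactly to ``n_samples``.
    """
    if v0 <= 0:
        raise ValueError(f"v0 must be > 0, got {v0}")
    if len(ts) == 0:
        raise ValueError("empty TrackSet")
    if protocol is not None:
        sigma = _check_constant_sigma(protocol, ts)

    ups, trs, up_means, tr_means = [], [], [], []
    for t in ts:
        v = track_velocities(t)
        up = -sigma * v[:, 1] / v0
        tr = v[:, 0] / v0
        ups.append(up)
        trs.append(tr)
        up_means.append(up.mean())
        tr_means.append(tr.mean())
    up = np.concatenate(ups)
    tr = np.concatenate(trs)
    up_means = np.asarray(up_means)
    tr_means = np.asarray(tr_means)
    n_tracks = len(ts)

    def _se_sd(track_means: np.ndarray) -> tuple[float, float]:
        if n_tracks < 2:
            return float("nan"), float("nan")
        sd = float(track_means.std(ddof=1))
        return sd / np.sqrt(n_tracks), sd

    se_up, sd_up = _se_sd(up_means)
    se_tr, sd_tr = _se_sd(tr_means)

    def _hist(x: np.ndarray):
        if bin_range is not None:
            edges = np.linspace(bin_range[0], bin_range[1], bins + 1)
        else:
            lo, hi = float(x.min()), float(x.max())
            if lo == hi:
                lo, hi = lo - 0.5, hi + 0.5
            edges = np.linspace(lo, hi, bins + 1)
        counts, edges = np.histogram(x, bins=edges)
        return counts, edges

    return VelocityStats(
        mean_upstream=float(up.mean()),
        mean_transverse=float(tr.mean()),
        se_upstream=se_up,
        se_transverse=se_tr,
        sd_upstream=sd_up,
        sd_transverse=sd_tr,
        hist_upstream=_hist(up),
        hist_transverse=_hist(tr),
        n_samples=int(up.size),
        n_tracks=n_tracks,
        v0=float(v0),
    )


def signed_curvature(
    track: Track,
    window: int = 7,
    speed_floor: float = 5.0,
) -> tuple[np.ndarray, float]:
    """Per-sample signed trajectory curvature (1/um) and its mean.

    kappa = (x' y'' - y' x'') / (x'^2 + y'^2)^(3/2) with derivatives from a
    sliding local quadratic fit (Savitzky-Golay, odd window >= 5) over
    uniformly sampled positions; positive = counterclockwise turning.
    Samples slower than ``speed_floor`` (um/s), where curvature is ill
    defined, are returned as NaN and excluded from the mean; an error is
    raised if no sample survives.
    """
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be odd and >= 5")
    if len(track) < window:
        raise ValueError(f"need at least window={window} samples")
    dts = np.diff(track.times)
    dt = dts.mean()
    if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
        raise ValueError("curvature estimation requires uniform sampling")

    xd = savgol_filter(track.xs, window, 2, deriv=1, delta=dt)
    yd = savgol_filter(track.ys, window, 2, deriv=1, delta=dt)
    xdd = savgol_filter(track.xs, window, 2, deriv=2, delta=dt)
    ydd = savgol_filter(track.ys, window, 2, deriv=2, delta=dt)
    speed = np.hypot(xd, yd)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (xd * ydd - yd * xdd) / speed**3
    kappa = np.where(speed < speed_floor, np.nan, kappa)
    if np.all(np.isnan(kappa)):
        raise ValueError(
            f"all samples are slower than the {speed_floor} um/s speed floor"
        )
    return kappa, float(np.nanmean(kappa))


def response_curve(
    ts: TrackSet,
    protocol: FlowProtocol,
    bin_width: float = 0.5,
    recovery_fraction: float = 0.9,
    tail_window: tuple[float, float] | None = None,
    flow_offset: float = 5.0,
) -> ResponseCurve:
    """Ensemble velocity response to the protocol's single flow reversal.

    Per-sample velocities of all tracks are pooled into time bins of
    ``bin_width`` seconds relative to the reversal.  The response time tau is
    the first post-reversal time (linear interpolation between bin centres)
    at which the mean velocity along the new upstream direction reaches
    ``recovery_fraction`` of its long-time mean, taken over ``tail_window``
    (relative seconds; default: the second half of the post-reversal span).
    Raises if the post-reversal span is shorter than 3 tau.
    """
    if len(protocol.reversal_times) != 1:
        raise ValueError("protocol must contain exactly one reversal")
    if len(ts) == 0:
        raise ValueError("empty TrackSet")
    t_rev = protocol.reversal_times[0]

    rel_all, vx_all, vy_all = [], [], []
    for t in ts:
        v = track_velocities(t)
        rel_all.append(t.times - t_rev)
        vx_all.append(v[:, 0])
        vy_all.append(v[:, 1])
    rel = np.concatenate(rel_all)
    vx = np.concatenate(vx_all)
    vy = np.concatenate(vy_all)
    if rel.min() >= 0 or rel.max() <= 0:
        raise ValueError("data must span both sides of the reversal")

    lo = np.floor(rel.min() / bin_width) * bin_width
    hi = np.ceil(rel.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    idx = np.digitize(rel, edges) - 1
    nbins = edges.size - 1
    counts = np.bincount(idx, minlength=nbins)[:nbins]
    keep = counts > 0
    centers = (edges[:-1] + 0.5 * bin_width)[keep]
    mean_vy = (np.bincount(idx, weights=vy, minlength=nbins)[:nbins][keep]
               / counts[keep])
    mean_vx = (np.bincount(idx, weights=vx, minlength=nbins)[:nbins][keep]
               / counts[keep])

    sig = np.atleast_1d(protocol.sigma(centers + t_rev)).astype(float)
    up_series = -sig * mean_vy
    flow_series = (
        np.atleast_1d(protocol.signed_amplitude(centers + t_rev))
        * protocol.gamma_dot
        * flow_offset
    )

    post = centers > 0
    post_span = centers[post].max()
    if tail_window is None:
        tail_window = (post_span / 2.0, post_span)
    in_tail = (centers >= tail_window[0]) & (centers <= tail_window[1])
    if not in_tail.any():
        raise ValueError("empty tail window for the post-reversal mean")
    tail_mean = float(up_series[in_tail].mean())

    threshold = recovery_fraction * tail_mean
    tau = float("nan")
    pc, pu = centers[post], up_series[post]
    above = pu >= threshold
    if above.any():
        i = int(np.argmax(above))
        if i == 0:
            tau = float(pc[0])
        else:
            t0, t1 = pc[i - 1], pc[i]
            u0, u1 = pu[i - 1], pu[i]
            tau = float(t0 + (threshold - u0) / (u1 - u0) * (t1 - t0))
    if not np.isfinite(tau):
        raise ValueError("mean upstream velocity never recovered in the data span")
    if post_span < 3.0 * tau:
        raise ValueError(
            f"post-reversal span {post_span:.1f} s is shorter than 3*tau "
            f"({tau:.1f} s): long-time mean unreliable"
        )
    return ResponseCurve(
        times=centers,
        mean_upstream_series=up_series,
        mean_transverse_series=mean_vx,
        flow_reference_series=flow_series,
        tau=tau,
        tail_mean=tail_mean,
        recovery_fraction=recovery_fraction,
    )
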