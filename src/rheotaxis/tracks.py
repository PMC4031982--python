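"""Synthetic particle-tracking datasets and the delimited track format.

The generator emulates what a particle-tracking-velocimetry (PTV) pipeline
would deliver for the swimmer model: trajectories sampled at the camera
frame rate (25 fps by default) inside a finite field of view (800 x 800 um),
with per-frame Gaussian localization noise, random per-frame detection
dropout that fragments tracks, and a minimum kept track length.  In the
noise-free, unbounded limit the acquisition layer is the identity on the
decimated simulation output.

Track files are plain CSV with unit-bearing column names
(cell_id, time_s, x_um, y_um[, psi_rad]) plus a YAML metadata sidecar
(<basename>.meta.yaml) holding the condition, acquisition settings and
generator provenance, so a dataset round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .model import (
    FlowProtocol,
    ModelParams,
    Track,
    simulate_ensemble,
)

__all__ = [
    "AcquisitionModel",
    "Condition",
    "TrackSet",
    "generate_dataset",
    "write_tracks",
    "read_tracks",
    "tracks_equal",
    "tracksets_equal",
]

TRACK_COLUMNS = ["cell_id", "time_s", "x_um", "y_um"]
PSI_COLUMN = "psi_rad"
FORMAT_VERSION = 1


@dataclass(frozen=True)
class AcquisitionModel:
    """Camera/tracking characteristics of a (synthetic) PTV acquisition.

    frame_rate : frames per second (default 25).
    field_of_view : (Lx, Ly) in um, or None for an unbounded view; cells are
        lost (track truncated) when their observed position leaves the view.
    localization_noise_sd : per-coordinate Gaussian localization error, um.
    min_track_length : shortest kept track/fragment duration, s.
    dropout_prob_per_frame : probability that a detection is missed in a
        frame, splitting the track into fragments.
    """

    frame_rate: float = 25.0
    field_of_view: tuple[float, float] | None = (800.0, 800.0)
    localization_noise_sd: float = 0.5
    min_track_length: float = 1.0
    dropout_prob_per_frame: float = 0.0

    def __post_init__(self) -> None:
        if not (self.frame_rate > 0):
            raise ValueError("frame_rate must be > 0")
        if self.localization_noise_sd < 0:
            raise ValueError("localization_noise_sd must be >= 0")
        if not (0 <= self.dropout_prob_per_frame < 1):
            raise ValueError("dropout_prob_per_frame must be in [0, 1)")
        if self.min_track_length < 0:
            raise ValueError("min_track_length must be >= 0")
        if self.field_of_view is not None:
            fov = tuple(float(v) for v in self.field_of_view)
            if len(fov) != 2 or any(v <= 0 for v in fov):
                raise ValueError("field_of_view must be two positive lengths")
            object.__setattr__(self, "field_of_view", fov)


@dataclass(frozen=True)
class Condition:
    """Experimental condition labels shared by all tracks of a set."""

    viscosity_mpas: float | None
    gamma_dot: float
    species: str = "model"


@dataclass
class TrackSet:
    """A collection of tracks sharing one acquisition and condition."""

    tracks: list[Track]
    condition: Condition
    acquisition: AcquisitionModel | None = None
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    @property
    def n_samples(self) -> int:
        return sum(len(t) for t in self.tracks)


def tracks_equal(a: Track, b: Track) -> bool:
    """Field-for-field equality of two tracks (exact array comparison)."""
    if a.cell_id != b.cell_id:
        return False
    if (a.psis is None) != (b.psis is None):
        return False
    same = (
        np.array_equal(a.times, b.times)
        and np.array_equal(a.xs, b.xs)
        and np.array_equal(a.ys, b.ys)
    )
    if same and a.psis is not None:
        same = np.array_equal(a.psis, b.psis)
    return same


def tracksets_equal(a: TrackSet, b: TrackSet, metadata: bool = True) -> bool:
    """Exact equality of two track sets, optionally including metadata."""
    if len(a) != len(b) or not all(
        tracks_equal(s, t) for s, t in zip(a.tracks, b.tracks)
    ):
        return False
    if metadata:
        return (
            a.condition == b.condition
            and a.acquisition == b.acquisition
            and a.provenance == b.provenance
        )
    return True


# ---------------------------------------------------------------------------
# generation

def _fragment(keep: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges [start, stop) of consecutive True runs."""
    runs = []
    start = None
    for i, k in enumerate(keep):
        if k and start is None:
            start = i
        elif not k and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, keep.size))
    return runs


def generate_dataset(
    params: ModelParams,
    protocol: FlowProtocol,
    acq: AcquisitionModel,
    n_cells: int,
    duration: float,
    seed,
    dt: float = 0.01,
    omega0: float = 0.0,
    viscosity_mpas: float | None = None,
    species: str = "synthetic",
) -> TrackSet:
    """Generate a PTV-like synthetic dataset of ``n_cells`` model swimmers.

    The master seed is split into a simulation stream and an acquisition
    stream (``SeedSequence(seed).spawn(2)``); the simulation half drives
    :func:`~rheotaxis.model.simulate_ensemble` (per-track substreams), the
    acquisition half draws, in order, initial positions (uniform over the
    field of view), localization noise and dropout.  Cells whose observed
    position leaves the field of view are truncated there; dropped frames
    split tracks into fragments (ids ``c00012.1`` etc.); tracks or fragments
    shorter than ``min_track_length`` are discarded.  ``omega0`` adds a
    constant intrinsic turning rate (rad/s) inside the generator only, to
    emulate the small mean trajectory curvature real cells show at zero
    shear.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if duration < acq.min_track_length:
        raise ValueError(
            f"duration {duration} s is shorter than min_track_length "
            f"{acq.min_track_length} s: no track could be kept"
        )
    # choose a simulation step that divides the frame interval exactly
    stride = max(1, round(1.0 / (acq.frame_rate * dt)))
    dt = 1.0 / (acq.frame_rate * stride)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sim_ss, acq_ss = ss.spawn(2)
    arng = np.random.default_rng(acq_ss)

    if acq.field_of_view is not None:
        lx, ly = acq.field_of_view
        x0 = arng.uniform(0.0, lx, n_cells)
        y0 = arng.uniform(0.0, ly, n_cells)
    else:
        x0 = np.zeros(n_cells)
        y0 = np.zeros(n_cells)

    ens = simulate_ensemble(
        n_cells,
        params,
        protocol,
        duration,
        dt=dt,
        seed=sim_ss,
        frame_rate=acq.frame_rate,
        x0=x0,
        y0=y0,
        omega0=omega0,
    )
    n_frames = len(ens.tracks[0])

    if acq.localization_noise_sd > 0:
        eps = arng.standard_normal((n_frames, n_cells, 2)) * acq.localization_noise_sd
    else:
        eps = np.zeros((n_frames, n_cells, 2))
    if acq.dropout_prob_per_frame > 0:
        present = arng.random((n_frames, n_cells)) >= acq.dropout_prob_per_frame
    else:
        present = np.ones((n_frames, n_cells), dtype=bool)

    min_frames = acq.min_track_length * acq.frame_rate  # kept if (len-1) >= this
    out: list[Track] = []
    for i, tr in enumerate(ens.tracks):
        xs = tr.xs + eps[:, i, 0]
        ys = tr.ys + eps[:, i, 1]
        if acq.field_of_view is not None:
            inside = (xs >= 0) & (xs <= lx) & (ys >= 0) & (ys <= ly)
            n_keep = int(np.argmin(inside)) if not inside.all() else n_frames
            if n_keep == 0 and not inside[0]:
                continue
        else:
            n_keep = n_frames
        runs = _fragment(present[:n_keep, i])
        frags = [
            (a, b) for a, b in runs if (b - 1 - a) >= min_frames - 1e-9
        ]
        for j, (a, b) in enumerate(frags):
            cid = tr.cell_id if len(frags) == 1 and (a, b) == (0, n_keep) else (
                f"{tr.cell_id}.{j}"
            )
            out.append(Track(cid, tr.times[a:b], xs[a:b], ys[a:b], tr.psis[a:b]))

    return TrackSet(
        tracks=out,
        condition=Condition(viscosity_mpas, protocol.gamma_dot, species),
        acquisition=acq,
        provenance=_to_plain({
            "generator": "generate_dataset",
            "seed": None if isinstance(seed, np.random.SeedSequence) else int(seed),
            "dt_s": dt,
            "omega0_rad_per_s": omega0,
            "n_cells": int(n_cells),
            "duration_s": float(duration),
            "params": dataclasses.asdict(params),
            "protocol": dataclasses.asdict(protocol),
        }),
    )


# ---------------------------------------------------------------------------
# file format

def _sidecar_path(path) -> str:
    base, _ = os.path.splitext(os.fspath(path))
    return base + ".meta.yaml"


def _to_plain(obj):
    """Recursively convert numpy scalars/arrays into YAML-safe builtins."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_tracks(ts: TrackSet, path) -> None:
    """Write a TrackSet as CSV plus a YAML metadata sidecar."""
    has_psi = any(t.psis is not None for t in ts.tracks)
    if has_psi and not all(t.psis is not None for t in ts.tracks):
        raise ValueError("either all tracks or none must carry psi")
    frames = []
    for t in ts.tracks:
        d = {
            "cell_id": t.cell_id,
            "time_s": t.times,
            "x_um": t.xs,
            "y_um": t.ys,
        }
        if has_psi:
            d[PSI_COLUMN] = t.psis
        frames.append(pd.DataFrame(d))
    cols = TRACK_COLUMNS + ([PSI_COLUMN] if has_psi else [])
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=cols)
    )
    df.to_csv(path, index=False, float_format="%.17g")

    meta = {
        "format": "rheotaxis-tracks",
        "format_version": FORMAT_VERSION,
        "condition": None
        if ts.condition is None
        else dataclasses.asdict(ts.condition),
        "acquisition": None
        if ts.acquisition is None
        else dataclasses.asdict(ts.acquisition),
        "provenance": ts.provenance,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(_to_plain(meta), fh, sort_keys=False)


def read_tracks(path) -> TrackSet:
    """Read a TrackSet written by :func:`write_tracks` (round-trip identity).

    Raises on missing required columns or non-monotone times within a cell.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track file {path} is missing required columns {missing}")
    has_psi = PSI_COLUMN in df.columns

    tracks = []
    for cid, g in df.groupby("cell_id", sort=False):
        times = g["time_s"].to_numpy(dtype=float)
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError(
                f"track file {path}: non-monotone times for cell {cid!r}"
            )
        tracks.append(
            Track(
                str(cid),
                times,
                g["x_um"].to_numpy(dtype=float),
                g["y_um"].to_numpy(dtype=float),
                g[PSI_COLUMN].to_numpy(dtype=float) if has_psi else None,
            )
        )

    condition = None
    acquisition = None
    provenance: dict = {}
    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        c = meta.get("condition")
        if c is not None:
            condition = Condition(**c)
        a = meta.get("acquisition")
        if a is not None:
            if a.get("field_of_view") is not None:
                a["field_of_view"] = tuple(a["field_of_view"])
            acquisition = AcquisitionModel(**a)
        provenance = meta.get("provenance") or {}
    return TrackSet(
        tracks=tracks,
        condition=condition,
        acquisition=acquisition,
        provenance=provenance,
    )
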