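"""Trajectory data model, synthetic path generators, normalization and I/O.

A trajectory is an ordered sequence of planar points sampled at a constant
frame rate: point ``i`` is the position at time ``i * dt``.  All dimension
estimators in this package consume this representation.  Synthetic
generators provide the validation fixtures used throughout: the Koch curve
(known dimension log4/log3), planar Brownian motion (graph dimension 2,
displacement exponent 1/2), and a correlated random walk emulating larval
centroid tracks recorded at 30 frames per second.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

DEFAULT_DT = 1.0 / 30.0  # 30 fps video acquisition


@dataclass
class Trajectory:
    """Uniformly time-sampled planar path.

    Parameters
    ----------
    points : ndarray of shape (n, 2)
        Ordered coordinates; point ``i`` is at time ``i * dt``.
    dt : float, default 1/30
        Sampling interval in seconds.
    meta : dict
        Free-form labels (genotype, animal id, ...).
    """

    points: np.ndarray
    dt: float = DEFAULT_DT
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass
class NormalizationRecord:
    """Record of the affine normalization applied to a trajectory.

    ``eta`` is the scale factor: the bounding-box extent in ``extent`` mode,
    or the mean consecutive-frame distance in ``mean_step`` mode.  The
    inverse transform ``p * eta + offset`` recovers the original coordinates.
    """

    eta: float
    offset: tuple[float, float]
    mode: str

    def invert(self, traj: Trajectory) -> Trajectory:
        """Map a normalized trajectory back to original coordinates."""
        pts = traj.points * self.eta + np.asarray(self.offset)
        return Trajectory(pts, dt=traj.dt, meta=dict(traj.meta))


def as_points(traj) -> np.ndarray:
    """Coerce a Trajectory or array-like into an (n, 2) float array."""
    if isinstance(traj, Trajectory):
        return traj.points
    pts = np.asarray(traj, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) point array")
    return pts


# ---------------------------------------------------------------------------
# Synthetic generators
# ---------------------------------------------------------------------------

_ROT60 = np.array([[0.5, -np.sqrt(3.0) / 2.0], [np.sqrt(3.0) / 2.0, 0.5]])


def generate_koch(level: int, dt: float = DEFAULT_DT) -> Trajectory:
    """Vertices of the standard Koch curve, base (0,0)-(1,0), bumps upward.

    Returns the ``4**level + 1`` construction-order vertices; every segment
    has length ``3**-level``.  The polyline visits the vertices at uniform
    arc-length spacing, so index order doubles as a constant-speed time
    parameterization.
    """
    level = int(level)
    if level < 0:
        raise ValueError("level must be non-negative")
    pts = np.array([[0.0, 0.0], [1.0, 0.0]])
    for _ in range(level):
        p, q = pts[:-1], pts[1:]
        v = (q - p) / 3.0
        a = p + v
        b = a + v @ _ROT60.T  # apex of the upward bump
        c = p + 2.0 * v
        new = np.empty((4 * len(p) + 1, 2))
        new[0::4] = pts
        new[1::4] = a
        new[2::4] = b
        new[3::4] = c
        pts = new
    return Trajectory(pts, dt=dt, meta={"kind": "koch", "level": level})


def generate_brownian(
    n: int, dt: float = DEFAULT_DT, sigma: float = 1.0, seed: int = 0
) -> Trajectory:
    """Planar Brownian path: cumulative sum of N(0, sigma^2 dt) increments.

    The root-mean-square displacement over lag ``delta`` grows as
    ``sqrt(delta)``, so the temporal-sampling exponent is 1/2 and the graph
    dimension is 2.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, sigma * np.sqrt(dt), size=(n - 1, 2))
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return Trajectory(pts, dt=dt, meta={"kind": "brownian", "seed": seed})


def generate_crw(
    n: int,
    dt: float = DEFAULT_DT,
    speed_mean: float = 1.0,
    speed_cv: float = 0.3,
    turn_concentration: float = 10.0,
    seed: int = 0,
) -> Trajectory:
    """Correlated random walk emulating a crawling-larva centroid track.

    Step lengths are lognormal with mean ``speed_mean * dt`` and coefficient
    of variation ``speed_cv``; heading increments are wrapped normal with
    standard deviation ``1 / sqrt(turn_concentration)``.  Higher
    concentration gives straighter, lower-dimension paths;
    ``turn_concentration = 0`` gives an isotropic random walk (uniform
    headings).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if speed_mean <= 0:
        raise ValueError("speed_mean must be positive")
    if speed_cv < 0:
        raise ValueError("speed_cv must be non-negative")
    if turn_concentration < 0:
        raise ValueError("turn_concentration must be non-negative")
    rng = np.random.default_rng(seed)
    step_mean = speed_mean * dt
    if speed_cv == 0:
        steps = np.full(n - 1, step_mean)
    else:
        # lognormal with prescribed arithmetic mean and CV
        s2 = np.log1p(speed_cv**2)
        mu = np.log(step_mean) - s2 / 2.0
        steps = rng.lognormal(mu, np.sqrt(s2), size=n - 1)
    if turn_concentration == 0:
        headings = rng.uniform(-np.pi, np.pi, size=n - 1)
    else:
        turns = rng.normal(0.0, 1.0 / np.sqrt(turn_concentration), size=n - 1)
        turns[0] = rng.uniform(-np.pi, np.pi)  # random initial heading
        headings = np.cumsum(turns)
    inc = steps[:, None] * np.column_stack([np.cos(headings), np.sin(headings)])
    pts = np.vstack([[0.0, 0.0], np.cumsum(inc, axis=0)])
    return Trajectory(pts, dt=dt, meta={"kind": "crw", "seed": seed})


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_trace(
    traj: Trajectory, mode: str = "extent"
) -> tuple[Trajectory, NormalizationRecord]:
    """Normalize a trajectory so dimension estimates are speed/size aligned.

    ``extent`` mode translates the bounding-box corner to the origin and
    divides by eta = max(x-extent, y-extent), placing the path in the unit
    square with the wider dimension spanning [0, 1].  ``mean_step`` mode
    divides by the mean consecutive-frame distance (proportional to average
    speed).  Scaling shifts log N(eps) curves without changing their slope,
    so the dimension itself is unaffected.
    """
    pts = traj.points
    if traj.n < 2:
        raise ValueError("need at least 2 points")
    mins = pts.min(axis=0)
    if mode == "extent":
        extent = pts.max(axis=0) - mins
        eta = float(extent.max())
        if eta <= 0:
            raise ValueError("degenerate trajectory: zero spatial extent")
    elif mode == "mean_step":
        eta = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).mean())
        if eta <= 0:
            raise ValueError("degenerate trajectory: zero mean step")
    else:
        raise ValueError(f"unknown normalization mode: {mode!r}")
    out = Trajectory((pts - mins) / eta, dt=traj.dt, meta=dict(traj.meta))
    return out, NormalizationRecord(eta=eta, offset=tuple(mins), mode=mode)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_trajectory_csv(path, dt: float = DEFAULT_DT, meta: dict | None = None) -> Trajectory:
    """Read a ``frame,x,y`` CSV; frames must be consecutive integers."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
    frames = df["frame"].to_numpy()
    if len(frames) and not np.array_equal(frames, frames[0] + np.arange(len(frames))):
        raise ValueError("frame column must be consecutive integers")
    pts = df[["x", "y"]].to_numpy(dtype=float)
    return Trajectory(pts, dt=dt, meta=meta or {})


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Write a trajectory as ``frame,x,y`` at full float precision."""
    df = pd.DataFrame(
        {"frame": np.arange(traj.n), "x": traj.x, "y": traj.y}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def load_config(path) -> dict:
    """Load a YAML or JSON configuration mapping (fps, gamma, xi, ...)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg
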