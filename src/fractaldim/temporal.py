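"""Temporal-sampling dimension estimator.

Constant-frame-rate tracking makes the frame lag ``delta`` a natural ruler:
``U(delta)`` is the mean distance between points ``delta`` frames apart,
measured over the non-overlapping downsampled path.  If ``U ~ C delta^alpha``
the exponent ``alpha`` plays the role of a Hölder exponent of the motion and
the graph-dimension bound gives

    D_T = 1 + (1 - alpha) * min(d, 1/alpha),

which for planar paths with ``alpha > 1/2`` reduces to ``D_T = 1/alpha``.
Straight motion has ``alpha = 1`` (D_T = 1); diffusive motion has
``alpha = 1/2`` (D_T = 2).  Unlike box-counting, U is invariant to rigid
rotation and translation of the path, and the whole computation is a
streaming O(n/delta) pass per lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .boxcount import FDEstimate
from .curves import as_points


@dataclass
class TemporalCurve:
    """Mean lag distances U(delta) with their pair counts.

    ``m[k] = floor((n - offset) / deltas[k])`` is the number of
    non-overlapping steps averaged at that lag; ``offset`` is the 1-based
    starting frame (offset 1 starts at the first point).
    """

    deltas: np.ndarray
    U: np.ndarray
    m: np.ndarray
    offset: int = 1

    def __post_init__(self) -> None:
        self.deltas = np.asarray(self.deltas, dtype=int)
        self.U = np.asarray(self.U, dtype=float)
        self.m = np.asarray(self.m, dtype=int)
        if not (len(self.deltas) == len(self.U) == len(self.m)):
            raise ValueError("deltas, U, m must have equal length")

    def __len__(self) -> int:
        return len(self.deltas)


def avg_step_distance(traj, delta: int, offset: int = 1) -> tuple[float, int]:
    """Mean distance between points ``delta`` frames apart, from ``offset``.

    Averages ``||x[i*delta + o] - x[(i-1)*delta + o]||`` (1-based indexing,
    ``o = offset``) over ``m = floor((n - o) / delta)`` non-overlapping
    steps.  Requires ``1 <= offset <= delta <= n - 1`` and at least one
    step.
    """
    pts = as_points(traj)
    n = len(pts)
    delta = int(delta)
    offset = int(offset)
    if not 1 <= delta <= n - 1:
        raise ValueError(f"delta must be in [1, {n - 1}]")
    if not 1 <= offset <= delta:
        raise ValueError("offset must be in [1, delta]")
    m = (n - offset) // delta
    if m < 1:
        raise ValueError("no complete step at this lag/offset")
    sub = pts[offset - 1 :: delta][: m + 1]
    U = float(np.linalg.norm(np.diff(sub, axis=0), axis=1).mean())
    return U, m


def temporal_curve(traj, deltas=None, offset: int = 1) -> TemporalCurve:
    """U(delta) across a lag set (default 1..min(100, n-1))."""
    pts = as_points(traj)
    n = len(pts)
    if deltas is None:
        deltas = np.arange(1, min(100, n - 1) + 1)
    deltas = np.asarray(deltas, dtype=int)
    U = np.empty(len(deltas))
    m = np.empty(len(deltas), dtype=int)
    for k, d in enumerate(deltas):
        U[k], m[k] = avg_step_distance(pts, int(d), offset)
    return TemporalCurve(deltas, U, m, offset=offset)


def alpha_from_temporal(curve: TemporalCurve, delta_subset=None):
    """OLS slope alpha of log10 U(delta) on log10 delta.

    Returns ``(alpha, diagnostics)`` where diagnostics carries the
    intercept, r^2 and the lag set used.
    """
    deltas, U = curve.deltas, curve.U
    if delta_subset is not None:
        mask = np.isin(deltas, np.asarray(delta_subset, dtype=int))
        deltas, U = deltas[mask], U[mask]
    if len(deltas) < 2:
        raise ValueError("need at least 2 lags")
    if np.any(U <= 0):
        raise ValueError("U must be positive for log fitting")
    lx, ly = np.log10(deltas.astype(float)), np.log10(U)
    if np.ptp(ly) == 0:
        alpha, intercept, r2 = 0.0, float(ly[0]), 1.0
    else:
        fit = stats.linregress(lx, ly)
        alpha, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    diagnostics = {
        "intercept": intercept,
        "r2": r2,
        "deltas": deltas.copy(),
        "lag_range": (int(deltas.min()), int(deltas.max())),
    }
    return alpha, diagnostics


def dt_from_alpha(alpha: float, d: int = 2) -> float:
    """Graph dimension from the displacement exponent.

    ``D_T = 1 + (1 - alpha) * min(d, 1/alpha)``; alpha >= 1 (possible with
    noise) is clipped to dimension 1.  For planar paths with alpha > 1/2
    this is simply 1/alpha.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if alpha >= 1.0:
        return 1.0
    return float(1.0 + (1.0 - alpha) * min(d, 1.0 / alpha))


def estimate_dt(curve: TemporalCurve, delta_subset=None, d: int = 2) -> FDEstimate:
    """Convenience wrapper: alpha fit plus conversion to a dimension."""
    alpha, diag = alpha_from_temporal(curve, delta_subset)
    flags = []
    if alpha >= 1.0:
        flags.append("alpha_clipped")
    D = dt_from_alpha(alpha, d=d) if alpha > 0 else float("nan")
    lo, hi = diag["lag_range"]
    return FDEstimate(
        D=D,
        method="temporal",
        scale_range=(float(lo), float(hi)),
        slope=alpha,
        intercept=diag["intercept"],
        r2=diag["r2"],
        flags=flags,
        provenance={"alpha": alpha, "deltas": diag["deltas"]},
    )


def rolling_dt(traj, k_max: int = 40, d: int = 2):
    """Local temporal dimension over log-uniform lag windows k..3k.

    For each ``k`` in 1..k_max the exponent is fitted over lags
    ``k..3k`` (uniform width in the log domain) and converted to a
    dimension.  Returns ``(k_values, local_DT)``.
    """
    pts = as_points(traj)
    n = len(pts)
    if 3 * k_max > n - 1:
        raise ValueError("path too short for k_max (need 3*k_max <= n-1)")
    ks = np.arange(1, k_max + 1)
    dims = np.empty(len(ks))
    for i, k in enumerate(ks):
        curve = temporal_curve(pts, deltas=np.arange(k, 3 * k + 1))
        alpha, _ = alpha_from_temporal(curve)
        dims[i] = dt_from_alpha(alpha, d=d) if alpha > 0 else np.nan
    return ks, dims


def takens_fd(traj, eps_max: float) -> FDEstimate:
    """Correlation-sum maximum-likelihood dimension (Takens' estimator).

    ``D = -1 / mean(log(r_ij / eps_max))`` over all pairwise distances
    below ``eps_max``.  Experimental: sensitive to the cutoff and excluded
    from the main comparison pipeline; provided for cross-method checks.
    """
    pts = as_points(traj)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    if eps_max <= 0:
        raise ValueError("eps_max must be positive")
    diff = pts[:, None, :] - pts[None, :, :]
    r = np.linalg.norm(diff, axis=-1)[np.triu_indices(len(pts), k=1)]
    r = r[r < eps_max]
    flags = ["experimental"]
    nz = r[r > 0]
    if len(nz) == 0:
        raise ValueError("no positive pairwise distances below eps_max")
    if len(nz) < len(r):
        flags.append("zero_distance_pairs_dropped")
    D = float(-1.0 / np.mean(np.log(nz / eps_max)))
    return FDEstimate(
        D=D,
        method="takens",
        scale_range=(float(nz.min()), float(eps_max)),
        slope=np.nan,
        intercept=np.nan,
        r2=np.nan,
        flags=flags,
        provenance={"n_pairs": int(len(nz))},
    )
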