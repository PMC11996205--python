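"""Automatic scale selection for dimension estimation.

A box-counting curve on a finite path has three regimes: a flat large-scale
tail (one box covers everything), a power-law mid-range, and a saturated
small-scale tail (every sample point in its own box).  Only the mid-range
carries the dimension, and its location tracks the animal's speed, so
comparisons across animals need an automatic, per-path choice of scales.

The procedure: start from a dense log-spaced scale set, trim the tails
either by a count threshold (Method 1) or by a regression criterion
(Method 2), then locate the elbow of the remaining log-log curve by dual
total least squares — for every two-way split of the retained scales, fit
an orthogonal-distance line to each part and take the split minimizing the
summed squared perpendicular error.  The elbow scale ``eps*`` (times a
multiplier ``xi``, default 3) anchors the scale sets used for the final
dimension fits; the matching temporal lag ``delta*`` is the first lag whose
mean displacement reaches ``xi * eps*``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .boxcount import ScalingCurve
from .temporal import TemporalCurve


def initial_scale_set(k_max: int = 400, step: float = 0.025) -> np.ndarray:
    """Dense initial scales 10**(-step*k), k = 0..k_max, decreasing from 1."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    return 10.0 ** (-step * np.arange(k_max + 1))


def _largest_run(mask: np.ndarray) -> slice:
    """Longest consecutive True run; ties favor the earliest (largest scales)."""
    best_len, best_start = 0, None
    start = None
    for i, flag in enumerate(np.append(mask, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best_len:
                best_len, best_start = i - start, start
            start = None
    if best_start is None:
        raise ValueError("no scales satisfy the selection criterion")
    return slice(best_start, best_start + best_len)


def refine_scales_threshold(curve: ScalingCurve, gamma: float = 0.01) -> ScalingCurve:
    """Method 1: keep scales with gamma*Nmax <= N(eps) <= (1-gamma)*Nmax.

    Returns the largest consecutive run of qualifying scales, dropping
    spurious scales that fluctuate across the threshold band.
    """
    if not 0.0 < gamma < 0.5:
        raise ValueError("gamma must be in (0, 0.5)")
    nmax = curve.values.max()
    mask = (curve.values >= gamma * nmax) & (curve.values <= (1.0 - gamma) * nmax)
    return curve.restrict(_largest_run(mask))


def refine_scales_regression(curve: ScalingCurve) -> ScalingCurve:
    """Method 2: keep scales whose counts lie strictly above a global fit.

    The fit is OLS of log10 N on -log10 eps over the span from scale 1 down
    to the largest scale attaining the maximum count; the retained set is
    the largest consecutive run above the fitted line.
    """
    scales, values = curve.scales, curve.values
    nmax = values.max()
    at_max = np.nonzero(values == nmax)[0]
    first_max = at_max[np.argmax(scales[at_max])]  # largest scale reaching Nmax
    span = (scales <= 1.0 + 1e-12) & (scales >= scales[first_max])
    if span.sum() < 2:
        raise ValueError("regression span has fewer than 2 scales")
    x = -np.log10(scales[span])
    y = np.log10(values[span])
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression span")
    fit = stats.linregress(x, y)
    predicted = fit.slope * (-np.log10(scales)) + fit.intercept
    # strictly above the line by more than round-off: an exactly linear
    # curve must yield an empty run, not a float-noise selection
    tol = 1e-9 * np.maximum(1.0, np.abs(predicted))
    mask = np.log10(values) > predicted + tol
    return curve.restrict(_largest_run(mask))


@dataclass
class TlsFit:
    """Orthogonal-distance (total least squares) line fit."""

    direction: np.ndarray  # unit vector along the fitted line
    centroid: np.ndarray
    sse: float  # summed squared perpendicular distances


def tls_fit(xs, ys) -> TlsFit:
    """Fit a line minimizing perpendicular squared error via SVD.

    The direction is the principal axis of the centered point cloud and the
    SSE is the total squared distance along the minor axis; zero iff the
    points are exactly collinear.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1 or len(xs) < 2:
        raise ValueError("need >= 2 paired points")
    pts = np.column_stack([xs, ys])
    centroid = pts.mean(axis=0)
    _, svals, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    sse = float(svals[1] ** 2) if len(svals) > 1 else 0.0
    return TlsFit(direction=vt[0], centroid=centroid, sse=sse)


def _tls_sse_prefix(x: np.ndarray, y: np.ndarray):
    """Closed-form TLS SSE of every prefix (and via reversal, suffix).

    The SSE of an orthogonal line fit equals the smallest eigenvalue of the
    2x2 scatter matrix of the centered points; cumulative moments give all
    prefixes in O(K).
    """
    k = np.arange(1, len(x) + 1, dtype=float)
    sx, sy = np.cumsum(x), np.cumsum(y)
    sxx, syy, sxy = np.cumsum(x * x), np.cumsum(y * y), np.cumsum(x * y)
    cxx = sxx - sx * sx / k
    cyy = syy - sy * sy / k
    cxy = sxy - sx * sy / k
    tr = cxx + cyy
    det = cxx * cyy - cxy * cxy
    lam_min = 0.5 * (tr - np.sqrt(np.maximum(tr * tr - 4.0 * det, 0.0)))
    return np.maximum(lam_min, 0.0)


@dataclass
class ElbowResult:
    """Outcome of the dual-TLS elbow search on a refined scale set."""

    s1: np.ndarray  # retained scales (K of them)
    sse_profile: np.ndarray  # SSE_i for i = 2..K-2
    i_star: int  # 1-based split index minimizing SSE
    eps_star: float  # scale at the elbow
    method_used: str


def dual_tls_elbow(curve: ScalingCurve, method_used: str = "threshold") -> ElbowResult:
    """Locate the elbow of log10 N vs -log10 eps by a two-piece TLS fit.

    For each split ``i`` in {2..K-2} the first ``i`` points and the
    remaining ``K - i`` points each get an orthogonal line fit; the elbow is
    the split with minimal summed SSE (ties broken toward the smallest
    ``i``, i.e. the coarse-scale side).  Needs K >= 4.
    """
    K = len(curve)
    if K < 4:
        raise ValueError("need at least 4 scales for elbow detection")
    x = -np.log10(curve.scales)
    y = np.log10(curve.values)
    pre = _tls_sse_prefix(x, y)
    suf = _tls_sse_prefix(x[::-1], y[::-1])[::-1]
    splits = np.arange(2, K - 1)  # i = 2..K-2 (1-based prefix size)
    sse = pre[splits - 1] + suf[splits]
    # ties (within round-off of the closed form) break to the smallest i
    tol = 1e-9 * max(1.0, float(sse.max()))
    i_star = int(splits[np.nonzero(sse <= sse.min() + tol)[0][0]])
    return ElbowResult(
        s1=curve.scales.copy(),
        sse_profile=sse,
        i_star=i_star,
        eps_star=float(curve.scales[i_star - 1]),
        method_used=method_used,
    )


def scaled_elbow(eps_star: float, xi: float = 3.0) -> float:
    """Multiply the elbow scale by the calibration factor xi."""
    if eps_star <= 0 or xi <= 0:
        raise ValueError("eps_star and xi must be positive")
    return xi * eps_star


def delta_star(tcurve: TemporalCurve, threshold: float) -> int:
    """Smallest lag whose mean displacement reaches the threshold.

    ``delta* = inf{delta : U(delta) >= threshold}``; raises if no lag in
    the curve qualifies.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    hits = np.nonzero(tcurve.U >= threshold)[0]
    if len(hits) == 0:
        raise ValueError("no lag satisfies U(delta) >= threshold")
    return int(tcurve.deltas[hits[0]])


def dyadic_scales(base: float, K: int, lam: int = 2) -> np.ndarray:
    """Geometric scale set {base * lam**k : k = 0..K-1} with integer lam >= 2.

    With a common grid origin, lam**2 boxes of one scale tile one box of the
    next, so box counts are guaranteed monotone along the set.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if int(lam) != lam or lam < 2:
        raise ValueError("lam must be an integer >= 2")
    if base <= 0:
        raise ValueError("base must be positive")
    return base * float(lam) ** np.arange(K)
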