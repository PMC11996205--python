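"""End-to-end dimension estimation and multi-group comparison.

``estimate_fd`` chains the full per-trajectory procedure: extent
normalization, a dense original box-count, threshold-based scale
refinement, the dual-TLS elbow, and a final dimension fit with the chosen
estimator on elbow-anchored scales.  ``compare_groups`` then applies the
statistical protocol used for genotype contrasts: Shapiro-Wilk on the
ANOVA residuals gates the choice between parametric (t-test/ANOVA) and
nonparametric (Mann-Whitney U) tests at alpha = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import boxcount as bc
from . import scaleselect as ss
from . import temporal as tp
from .curves import Trajectory, normalize_trace

logger = logging.getLogger("fractaldim")


@dataclass
class PipelineConfig:
    """Tunable parameters of the estimation chain.

    ``gamma`` is the Method-1 count-threshold fraction, ``xi`` the elbow
    multiplier transferring the original-count elbow to the exact counter,
    ``k_max``/``step`` define the dense initial scale set
    10**(-step*k), k=0..k_max.  ``preset='fine'`` fits box dimensions over
    {3, 4.5, 6} * eps* and temporal over delta*..2*delta*; ``'coarse'``
    uses 4*eps*..10**-1.5 and delta*..60.
    """

    fps: float = 30.0
    gamma: float = 0.01
    xi: float = 3.0
    k_max: int = 400
    step: float = 0.025
    d: int = 2
    preset: str = "fine"
    normalization: str = "extent"

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in cfg.items() if k in known})


class PipelineError(RuntimeError):
    """Stage-tagged failure of the estimation chain."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _run_stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc


def select_scales(traj_norm: Trajectory, config: PipelineConfig):
    """Shared front half of the chain: dense count, refinement, elbow.

    Runs on the normalized path with the original (point) counter — the
    cheap counter whose smooth saturation makes the elbow robust — and
    returns the elbow result plus the dense curve.
    """
    s0 = ss.initial_scale_set(config.k_max, config.step)
    curve = _run_stage(
        "boxcount_s0", bc.boxcount_curve, traj_norm.points, s0, "original"
    )
    refined = _run_stage("refine_scales", ss.refine_scales_threshold, curve, config.gamma)
    elbow = _run_stage("dual_tls_elbow", ss.dual_tls_elbow, refined)
    logger.info(
        "scale selection: K=%d retained, eps*=%.4g (split %d)",
        len(refined), elbow.eps_star, elbow.i_star,
    )
    return elbow, curve


def estimate_fd(
    traj: Trajectory, method: str = "exact", config: PipelineConfig | None = None
) -> bc.FDEstimate:
    """Full-chain dimension estimate for one trajectory.

    ``method`` chooses the final estimator: ``original`` or ``exact``
    box-counting over elbow-anchored scales, or ``temporal`` over
    elbow-anchored lags.  The returned estimate carries the provenance of
    every intermediate (eta, eps*, scale sets, counts or U values).
    """
    config = config or PipelineConfig()
    if traj.n < 4:
        raise PipelineError("validate", f"trajectory too short (n={traj.n})")
    traj_norm, record = _run_stage(
        "normalize", normalize_trace, traj, config.normalization
    )
    elbow, _ = select_scales(traj_norm, config)
    anchor = ss.scaled_elbow(elbow.eps_star, config.xi)
    provenance = {
        "eta": record.eta,
        "normalization": record.mode,
        "eps_star": elbow.eps_star,
        "anchor": anchor,
        "n_retained_scales": len(elbow.s1),
        "preset": config.preset,
    }

    if method in ("original", "exact"):
        if config.preset == "fine":
            scales = anchor * np.array([1.0, 1.5, 2.0])
        elif config.preset == "coarse":
            lo = np.log10(4.0 * elbow.eps_star)
            hi = -1.5
            if lo >= hi:
                raise PipelineError(
                    "scales", "coarse preset needs 4*eps* below 10^-1.5"
                )
            scales = 10.0 ** np.arange(lo, hi + 1e-12, config.step)
        else:
            raise PipelineError("scales", f"unknown preset {config.preset!r}")
        curve = _run_stage(
            "boxcount_final", bc.boxcount_curve, traj_norm.points, scales, method
        )
        est = _run_stage("fd_fit", bc.fd_from_curve, curve, None, method)
        provenance["scales"] = scales
        provenance["counts"] = curve.values
    elif method == "temporal":
        n = traj_norm.n
        tcurve = _run_stage(
            "temporal_curve", tp.temporal_curve, traj_norm,
            np.arange(1, min(2000, n - 1) + 1),
        )
        dstar = _run_stage("delta_star", ss.delta_star, tcurve, anchor)
        if config.preset == "fine":
            lags = np.arange(dstar, 2 * dstar + 1)
        elif config.preset == "coarse":
            if dstar >= 60:
                raise PipelineError("lags", "coarse preset needs delta* < 60")
            lags = np.arange(dstar, 61)
        else:
            raise PipelineError("lags", f"unknown preset {config.preset!r}")
        est = _run_stage("dt_fit", tp.estimate_dt, tcurve, lags, config.d)
        provenance["delta_star"] = dstar
        provenance["lags"] = lags
        provenance["U"] = tcurve.U[np.isin(tcurve.deltas, lags)]
    else:
        raise PipelineError("method", f"unknown method {method!r}")

    est = replace(est, provenance={**est.provenance, **provenance})
    logger.info("estimate_fd(%s): D=%.4f r2=%.4f", method, est.D, est.r2)
    return est


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """Outcome of the normality-gated multi-group test protocol."""

    groups: dict  # label -> np.ndarray of FD samples
    control: str
    shapiro_p: float
    residuals_normal: bool
    test_used: str  # 't-test' or 'mannwhitneyu'
    anova_p: float
    p_values: dict  # label -> p vs control (raw)
    p_adjusted: dict | None  # Bonferroni, when requested
    means: dict  # label -> mean
    ci95: dict  # label -> (lo, hi)


def compare_groups(
    samples: dict,
    control: str | None = None,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> GroupComparison:
    """Compare per-group dimension samples against a control group.

    The gate: one-way ANOVA residuals (each value minus its group mean) are
    tested for normality by Shapiro-Wilk at ``alpha``.  Normal residuals
    select Student's t-test for the pairwise contrasts; non-normal
    residuals select the two-sided Mann-Whitney U test (tie-corrected
    normal approximation).  Pairwise p-values are reported raw; Bonferroni
    adjustment is optional.  Group means come with t-based 95% CIs.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    for label, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {label!r} has fewer than 3 samples")
    labels = list(groups)
    control = control if control is not None else labels[0]
    if control not in groups:
        raise ValueError(f"control group {control!r} not found")

    residuals = np.concatenate([v - v.mean() for v in groups.values()])
    shapiro_p = float(stats.shapiro(residuals).pvalue)
    normal = shapiro_p >= alpha
    anova_p = float(stats.f_oneway(*groups.values()).pvalue)

    p_values = {}
    for label in labels:
        if label == control:
            continue
        a, b = groups[label], groups[control]
        if normal:
            p = stats.ttest_ind(a, b).pvalue
        else:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        p_values[label] = float(p)
    p_adjusted = (
        {k: min(1.0, v * len(p_values)) for k, v in p_values.items()}
        if bonferroni
        else None
    )

    means, ci95 = {}, {}
    for label, vals in groups.items():
        m = float(vals.mean())
        half = (
            stats.t.ppf(0.975, len(vals) - 1) * vals.std(ddof=1) / np.sqrt(len(vals))
            if len(vals) > 1 and vals.std(ddof=1) > 0
            else 0.0
        )
        means[label] = m
        ci95[label] = (m - half, m + half)

    test_used = "t-test" if normal else "mannwhitneyu"
    logger.info(
        "compare_groups: shapiro_p=%.3g -> %s; anova_p=%.3g", shapiro_p, test_used, anova_p
    )
    return GroupComparison(
        groups=groups,
        control=control,
        shapiro_p=shapiro_p,
        residuals_normal=normal,
        test_used=test_used,
        anova_p=anova_p,
        p_values=p_values,
        p_adjusted=p_adjusted,
        means=means,
        ci95=ci95,
    )
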