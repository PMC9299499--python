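"""Covariate-structure selection, benchmark-dose computation and profile CIs.

The covariate approach fits all subgroups (e.g. sexes) jointly with the shape
parameters c and d shared; background a, potency b and log-scale variance are
promoted to level-specific only when a likelihood-ratio test at ``alpha``
justifies the extra parameters.  The benchmark dose at critical effect size
CES is the dose where the fitted curve reaches ``a * (1 + CES)``; its
confidence bounds (BMDL/BMDU) come from the profile log-likelihood, with the
BMD made an explicit model parameter and all nuisance parameters profiled out.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .models import (
    ConfigurationError,
    ConvergenceError,
    CovariateStructure,
    DoseResponseDataset,
    FitOptions,
    FitResult,
    ModelParams,
    COVARIATE_PARAMS,
    _Layout,
    _minimize_multistart,
    fit_single_structure,
)

__all__ = [
    "BmdEstimate",
    "CombinedPoD",
    "loglik_ratio_threshold",
    "select_covariate_structure",
    "compute_bmd",
    "profile_bmd_ci",
    "combine_families",
    "ci_ratio_report",
]


@dataclass
class BmdEstimate:
    """BMD point estimate and profile-likelihood CI for one level and family."""

    family: str
    covariate_level: str
    ces: float
    bmd: float
    bmdl: float
    bmdu: float  # may be +inf when the profile is unbounded above
    ci_level: float = 0.90
    diagnostics: dict = field(default_factory=dict)

    @property
    def ci_ratio(self) -> float:
        return self.bmdu / self.bmdl

    def __post_init__(self) -> None:
        if math.isfinite(self.bmd) and not (self.bmdl <= self.bmd * (1 + 1e-9) and self.bmd <= self.bmdu * (1 + 1e-9)):
            raise ValueError(
                f"CI must contain the MLE: bmdl={self.bmdl}, bmd={self.bmd}, bmdu={self.bmdu}"
            )


@dataclass
class CombinedPoD:
    """Cross-family combination: lowest BMDL and highest BMDU per level."""

    covariate_level: str
    pod_bmdl: float
    pod_bmdu: float
    contributing_families: tuple


def loglik_ratio_threshold(alpha: float, df: int) -> float:
    """Required log-likelihood gain: half the chi-square critical value."""
    return 0.5 * float(chi2.ppf(1.0 - alpha, df))


def select_covariate_structure(
    dataset: DoseResponseDataset,
    family: str,
    alpha: float = 0.05,
    opts: FitOptions | None = None,
) -> tuple[CovariateStructure, FitResult]:
    """Forward stepwise selection of level-specific parameters by likelihood ratio.

    Starting from the all-shared structure, the candidate in the fixed order
    (a, b, var) giving the largest log-likelihood gain is added, but only when
    2*dLL exceeds the chi-square critical value at ``alpha`` with one degree
    of freedom per additional level.  Non-convergent candidate fits are
    skipped and recorded.
    """
    if not (0.0 < alpha < 1.0):
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha!r}")
    structure = CovariateStructure()
    current = fit_single_structure(dataset, family, structure, opts=opts)
    n_levels = len(dataset.levels)
    history: list[dict] = []
    skipped: list[str] = []
    if n_levels < 2:
        current.diagnostics["selection"] = {"history": [], "skipped": [], "note": "single level"}
        return structure, current

    df_per_param = n_levels - 1
    while True:
        best_name, best_fit = None, None
        for name in COVARIATE_PARAMS:  # fixed order is the deterministic tie-break
            if structure.is_specific(name):
                continue
            cand = structure.with_param(name)
            try:
                fit = fit_single_structure(
                    dataset, family, cand, opts=opts, init_params=current.params
                )
            except ConvergenceError:
                skipped.append(f"{name}: non-convergent")
                continue
            if not fit.converged:
                skipped.append(f"{name}: converged=False")
                continue
            if best_fit is None or fit.loglik > best_fit.loglik:
                best_name, best_fit = name, fit
        if best_fit is None:
            break
        gain = best_fit.loglik - current.loglik
        crit = loglik_ratio_threshold(alpha, df_per_param)
        accepted = gain > crit
        history.append(
            {"param": best_name, "gain": gain, "critical": crit, "accepted": accepted}
        )
        if not accepted:
            break
        structure = structure.with_param(best_name)
        current = best_fit
        if len(structure.level_specific) == len(COVARIATE_PARAMS):
            break
    current.diagnostics["selection"] = {"history": history, "skipped": skipped}
    return structure, current


def compute_bmd(params: ModelParams, level: str, ces: float) -> float:
    """Dose where the level's curve reaches a*(1+CES); +inf when CES >= c-1.

    Closed forms:
      exponential: BMD = [-ln((c-1-ces)/(c-1)) / b]^(1/d)
      Hill:        BMD = b * (t/(1-t))^(1/d),  t = ces/(c-1)
    """
    params.require_level(level)
    if not (ces > 0):
        raise ConfigurationError(f"ces must be > 0, got {ces!r}")
    c, d, b = params.c, params.d, params.b[level]
    if ces >= c - 1.0:
        return math.inf
    if params.family == "exponential":
        return (-math.log((c - 1.0 - ces) / (c - 1.0)) / b) ** (1.0 / d)
    t = ces / (c - 1.0)
    return b * (t / (1.0 - t)) ** (1.0 / d)


# ---------------------------------------------------------------------------
# profile-likelihood confidence interval
# ---------------------------------------------------------------------------

def _profiled_loglik(
    stats,
    family: str,
    structure: CovariateStructure,
    opts: FitOptions,
    level: str,
    ces: float,
    log_bmd: float,
    warm: list[np.ndarray],
) -> float:
    """Maximized log-likelihood with the level's BMD fixed at exp(log_bmd)."""
    layout = _Layout(stats, family, structure, opts, profile_bmd=(level, ces, log_bmd))
    starts = []
    for w in warm:
        lo = np.array([b[0] for b in layout.bounds])
        hi = np.array([b[1] for b in layout.bounds])
        starts.append(np.clip(w, lo, hi))
    best = None
    for theta0 in starts:
        res = minimize(
            layout.nll, theta0, method="L-BFGS-B", bounds=layout.bounds,
            options={"maxiter": opts.maxiter, "ftol": opts.ftol},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e12:
        # fall back to the full lattice
        best, _ = _minimize_multistart(layout, starts)
    # keep the anchor (MLE-mapped) start plus the latest solution
    del warm[1:]
    warm.append(best.x.copy())
    return -float(best.fun)


def profile_bmd_ci(
    dataset: DoseResponseDataset,
    family: str,
    structure: CovariateStructure | None = None,
    level: str | None = None,
    ces: float = 0.50,
    ci_level: float = 0.90,
    fit: FitResult | None = None,
    opts: FitOptions | None = None,
    bracket_decades: float = 3.0,
    log_tol: float = 1e-4,
) -> BmdEstimate:
    """Two-sided profile-likelihood CI for the BMD of one covariate level.

    The curve is reparameterized so the level's BMD is explicit; all nuisance
    parameters (including the variances, profiled in closed form) are
    maximized out at each trial BMD.  The bounds are where the profile
    log-likelihood drops by chi2(ci_level, 1)/2 below its maximum (1.3528 for
    a 90% interval), located by bisection to ``log_tol`` in log-dose within a
    bracket of ``bracket_decades`` decades each side of the MLE.
    """
    structure = structure or CovariateStructure()
    opts = opts or FitOptions()
    if level is None:
        if len(dataset.levels) != 1:
            raise ConfigurationError("level must be given for multi-level data")
        level = dataset.levels[0]
    if fit is None:
        fit = fit_single_structure(dataset, family, structure, opts=opts)
    if not fit.converged:
        raise ConvergenceError("profile CI requires a converged full fit")
    diagnostics: dict = {"boundary_warning": bool(fit.diagnostics.get("at_bounds"))}
    bmd_hat = compute_bmd(fit.params, level, ces)
    if not math.isfinite(bmd_hat):
        return BmdEstimate(
            family=family, covariate_level=level, ces=ces,
            bmd=math.inf, bmdl=math.nan, bmdu=math.inf, ci_level=ci_level,
            diagnostics={**diagnostics, "ces_unreachable": True},
        )
    drop = 0.5 * float(chi2.ppf(ci_level, 1))
    target = fit.loglik - drop
    stats = dataset.group_stats()
    log_hat = math.log(bmd_hat)
    span = bracket_decades * math.log(10.0)

    def profile(log_bmd: float, warm: list[np.ndarray]) -> float:
        return _profiled_loglik(stats, family, structure, opts, level, ces, log_bmd, warm)

    # warm start at the MLE, mapped into the profile layout
    layout0 = _Layout(stats, family, structure, opts, profile_bmd=(level, ces, log_hat))
    # drop the focal b coordinate from the packed full-layout vector
    full_layout = _Layout(stats, family, structure, opts)
    theta_full = full_layout.pack(fit.params)
    if full_layout.n_b > layout0.n_b:
        keep = [j for j, slot in enumerate(full_layout.free_b_slots) if slot in layout0.free_b_slots]
        theta0 = np.concatenate(
            [
                theta_full[: full_layout.n_a],
                theta_full[full_layout.n_a : full_layout.n_a + full_layout.n_b][keep],
                theta_full[full_layout.n_a + full_layout.n_b :],
            ]
        )
    else:
        theta0 = theta_full

    n_evals = 0

    def bound(direction: int) -> float:
        """direction -1 for the lower bound, +1 for the upper."""
        nonlocal n_evals
        warm = [theta0.copy()]
        step = 0.35
        inside = log_hat  # profile >= target here
        outside = None    # first point with profile < target
        t = step
        while t <= span + 1e-12:
            cur = log_hat + direction * t
            ll = profile(cur, warm)
            n_evals += 1
            if ll < target:
                outside = cur
                break
            inside = cur
            t += step
        if outside is None:
            return math.inf if direction > 0 else math.exp(log_hat - span)
        # bisection; robust to small warm-start noise in the inner maximization
        while abs(outside - inside) > log_tol:
            mid = 0.5 * (inside + outside)
            ll = profile(mid, warm)
            n_evals += 1
            if ll >= target:
                inside = mid
            else:
                outside = mid
        return math.exp(0.5 * (inside + outside))

    bmdu = bound(+1)
    bmdl = bound(-1)
    if not math.isfinite(bmdu):
        diagnostics["bmdu_unbounded"] = True
    if bmdl <= math.exp(log_hat - span) * (1 + 1e-9):
        diagnostics["bmdl_at_bracket_edge"] = True
    diagnostics["n_profile_evals"] = n_evals
    return BmdEstimate(
        family=family, covariate_level=level, ces=ces,
        bmd=bmd_hat, bmdl=min(bmdl, bmd_hat), bmdu=max(bmdu, bmd_hat),
        ci_level=ci_level, diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# cross-family combination and reporting
# ---------------------------------------------------------------------------

def combine_families(estimates: Iterable[BmdEstimate]) -> list[CombinedPoD]:
    """Per level, the lowest BMDL and the highest BMDU across model families.

    An infinite BMDU dominates the maximum.  All inputs must share the same
    CES and CI level.
    """
    estimates = list(estimates)
    if not estimates:
        raise ConfigurationError("no estimates to combine")
    if len({e.ces for e in estimates}) > 1:
        raise ConfigurationError(f"mixed CES values: {sorted({e.ces for e in estimates})}")
    if len({e.ci_level for e in estimates}) > 1:
        raise ConfigurationError(f"mixed CI levels: {sorted({e.ci_level for e in estimates})}")
    out = []
    levels = list(dict.fromkeys(e.covariate_level for e in estimates))
    for lvl in levels:
        es = [e for e in estimates if e.covariate_level == lvl]
        out.append(
            CombinedPoD(
                covariate_level=lvl,
                pod_bmdl=min(e.bmdl for e in es),
                pod_bmdu=max(e.bmdu for e in es),
                contributing_families=tuple(dict.fromkeys(e.family for e in es)),
            )
        )
    return out


def ci_ratio_report(estimates: Iterable[BmdEstimate]) -> pd.DataFrame:
    """BMDU/BMDL precision ratios per level and family, plus the combined rows.

    A wider ratio flags a less informative study design; infinite BMDU yields
    an infinite ratio.
    """
    estimates = list(estimates)
    rows = [
        {
            "covariate_level": e.covariate_level,
            "family": e.family,
            "bmdl": e.bmdl,
            "bmdu": e.bmdu,
            "ci_ratio": e.ci_ratio,
        }
        for e in estimates
    ]
    for pod in combine_families(estimates):
        rows.append(
            {
                "covariate_level": pod.covariate_level,
                "family": "combined",
                "bmdl": pod.pod_bmdl,
                "bmdu": pod.pod_bmdu,
                "ci_ratio": pod.pod_bmdu / pod.pod_bmdl,
            }
        )
    return pd.DataFrame(rows)
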