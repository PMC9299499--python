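"""Continuous dose-response model families and lognormal maximum-likelihood fitting.

Implements the two standard continuous benchmark-dose families for increasing
responses,

    exponential:  m(x) = a * [c - (c - 1) * exp(-b * x**d)]
    Hill:         m(x) = a * [1 + (c - 1) * x**d / (b**d + x**d)]

with a lognormal error model: log-responses are normal with mean ``log m(x)``
and a per-covariate-level variance ``var``.  In the covariate approach the two
shape parameters — maximum fold-change ``c`` and log-steepness ``d`` — are
always shared across covariate levels (e.g. sexes), while background ``a``,
potency ``b`` and ``var`` may be level-specific when the data warrant it.

Fitting maximizes the lognormal log-likelihood over the curve parameters with
the variance(s) profiled out in closed form, using a deterministic multi-start
bounded quasi-Newton strategy (no RNG in the fit path).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

__all__ = [
    "FAMILIES",
    "COVARIATE_PARAMS",
    "DoseResponseRecord",
    "GroupSummary",
    "DoseResponseDataset",
    "CovariateStructure",
    "ModelParams",
    "FitResult",
    "FitOptions",
    "predict_response",
    "log_likelihood",
    "fit_single_structure",
    "DataSupportError",
    "DeclaredLevelError",
    "ConfigurationError",
    "IdentifiabilityError",
    "ConvergenceError",
]

FAMILIES = ("exponential", "hill")
#: parameters that may be made covariate-level-specific; c and d never are
COVARIATE_PARAMS = ("a", "b", "var")

#: floor applied to the profiled variance (guards noise-free data)
_VAR_FLOOR = 1e-12


class DataSupportError(ValueError):
    """A response lies outside the lognormal support (must be > 0)."""


class DeclaredLevelError(KeyError):
    """A covariate level was requested that the object does not declare."""


class ConfigurationError(ValueError):
    """Invalid analysis configuration (unknown family, bad structure, ...)."""


class IdentifiabilityError(ValueError):
    """Too few distinct dose levels for the requested model structure."""


class ConvergenceError(RuntimeError):
    """All optimizer starts failed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseRecord:
    """One animal's observation: dose (mg/kg/day) and response (e.g. MN-PCE %)."""

    dataset_id: str
    covariate_level: str
    dose: float
    response: float
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if not (self.dose >= 0):
            raise ValueError(f"dose must be >= 0, got {self.dose!r}")
        if not (self.response > 0):
            raise DataSupportError(
                f"response must be > 0 (lognormal support), got {self.response!r} "
                f"for record {self.dataset_id}/{self.covariate_level} at dose {self.dose}"
            )


@dataclass(frozen=True)
class GroupSummary:
    """Published group summary: arithmetic mean/SD of the response per dose group."""

    dose: float
    n: int
    mean: float
    sd: float
    covariate_level: str
    dataset_id: str = "summary"

    def __post_init__(self) -> None:
        if not (self.dose >= 0):
            raise ValueError(f"dose must be >= 0, got {self.dose!r}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n!r}")
        if not (self.mean > 0):
            raise DataSupportError(f"group mean must be > 0, got {self.mean!r}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd!r}")
        if self.n == 1 and self.sd != 0:
            raise ValueError("a single-animal group cannot carry a nonzero sd")

    def log_scale_stats(self) -> tuple[float, float]:
        """Lognormal moment map: arithmetic (mean, sd) -> (log-mean, log-variance).

        log-variance = ln(1 + CV^2);  log-mean = ln(mean) - log-variance / 2.
        """
        cv2 = (self.sd / self.mean) ** 2
        logvar = math.log1p(cv2)
        logmean = math.log(self.mean) - logvar / 2.0
        return logmean, logvar


@dataclass(frozen=True)
class _GroupStats:
    """Per (level, dose) sufficient statistics of log-responses."""

    levels: tuple[str, ...]
    level_idx: np.ndarray  # int, shape (G,)
    dose: np.ndarray       # float, shape (G,)
    n: np.ndarray          # int, shape (G,)
    mean_log: np.ndarray   # float, shape (G,)
    ss_log: np.ndarray     # sum of squared deviations of log-responses, shape (G,)

    @property
    def n_total(self) -> int:
        return int(self.n.sum())


class DoseResponseDataset:
    """Continuous dose-response data, individual-animal or group-summary form.

    Parameters
    ----------
    records
        Individual observations (mutually exclusive with ``summaries``).
    summaries
        Published per-group arithmetic summaries.
    endpoint, units
        Labels carried through to reports.
    levels
        Declared covariate levels; defaults to the sorted levels present.
    """

    def __init__(
        self,
        records: Iterable[DoseResponseRecord] | None = None,
        summaries: Iterable[GroupSummary] | None = None,
        endpoint: str = "MN-PCE%",
        units: str = "mg/kg/day",
        levels: Sequence[str] | None = None,
    ) -> None:
        records = tuple(records) if records is not None else ()
        summaries = tuple(summaries) if summaries is not None else ()
        if bool(records) == bool(summaries):
            raise ValueError("provide exactly one of records or summaries (non-empty)")
        self.records = records
        self.summaries = summaries
        self.endpoint = endpoint
        self.units = units
        present = sorted({r.covariate_level for r in records} | {s.covariate_level for s in summaries})
        if levels is None:
            self.levels: tuple[str, ...] = tuple(present)
        else:
            self.levels = tuple(levels)
            undeclared = set(present) - set(self.levels)
            if undeclared:
                raise DeclaredLevelError(
                    f"data contain undeclared covariate level(s) {sorted(undeclared)}; "
                    f"declared: {list(self.levels)}"
                )

    # -- basic views --------------------------------------------------------

    @property
    def is_summary(self) -> bool:
        return bool(self.summaries)

    @property
    def doses(self) -> tuple[float, ...]:
        if self.records:
            return tuple(sorted({r.dose for r in self.records}))
        return tuple(sorted({s.dose for s in self.summaries}))

    @property
    def n_obs(self) -> int:
        if self.records:
            return len(self.records)
        return int(sum(s.n for s in self.summaries))

    def to_frame(self) -> pd.DataFrame:
        if self.records:
            return pd.DataFrame(
                [
                    {
                        "dataset_id": r.dataset_id,
                        "covariate_level": r.covariate_level,
                        "dose": r.dose,
                        "response": r.response,
                    }
                    for r in self.records
                ]
            )
        return pd.DataFrame(
            [
                {
                    "dataset_id": s.dataset_id,
                    "covariate_level": s.covariate_level,
                    "dose": s.dose,
                    "n": s.n,
                    "mean": s.mean,
                    "sd": s.sd,
                }
                for s in self.summaries
            ]
        )

    def subset(self, level: str) -> "DoseResponseDataset":
        if level not in self.levels:
            raise DeclaredLevelError(f"unknown covariate level {level!r}; declared: {list(self.levels)}")
        if self.records:
            return DoseResponseDataset(
                records=[r for r in self.records if r.covariate_level == level],
                endpoint=self.endpoint, units=self.units, levels=(level,),
            )
        return DoseResponseDataset(
            summaries=[s for s in self.summaries if s.covariate_level == level],
            endpoint=self.endpoint, units=self.units, levels=(level,),
        )

    def relabel(self, level: str) -> "DoseResponseDataset":
        """Pool all observations under a single covariate level label."""
        if self.records:
            return DoseResponseDataset(
                records=[replace(r, covariate_level=level) for r in self.records],
                endpoint=self.endpoint, units=self.units, levels=(level,),
            )
        return DoseResponseDataset(
            summaries=[replace(s, covariate_level=level) for s in self.summaries],
            endpoint=self.endpoint, units=self.units, levels=(level,),
        )

    # -- sufficient statistics ----------------------------------------------

    def group_stats(self) -> _GroupStats:
        """Per (level, dose) log-scale sufficient statistics for the likelihood."""
        keys: list[tuple[int, float]] = []
        n_l: list[int] = []
        ml: list[float] = []
        ss: list[float] = []
        if self.records:
            groups: dict[tuple[int, float], list[float]] = {}
            for r in self.records:
                groups.setdefault((self.levels.index(r.covariate_level), r.dose), []).append(
                    math.log(r.response)
                )
            for key in sorted(groups):
                logs = np.asarray(groups[key])
                keys.append(key)
                n_l.append(logs.size)
                mu = float(logs.mean())
                ml.append(mu)
                ss.append(float(((logs - mu) ** 2).sum()))
        else:
            for s in sorted(self.summaries, key=lambda s: (self.levels.index(s.covariate_level), s.dose)):
                logmean, logvar = s.log_scale_stats()
                keys.append((self.levels.index(s.covariate_level), s.dose))
                n_l.append(s.n)
                ml.append(logmean)
                ss.append((s.n - 1) * logvar)
        return _GroupStats(
            levels=self.levels,
            level_idx=np.asarray([k[0] for k in keys], dtype=int),
            dose=np.asarray([k[1] for k in keys], dtype=float),
            n=np.asarray(n_l, dtype=int),
            mean_log=np.asarray(ml, dtype=float),
            ss_log=np.asarray(ss, dtype=float),
        )


@dataclass(frozen=True)
class CovariateStructure:
    """Which of {a, b, var} are estimated per covariate level; c and d are always shared."""

    level_specific: frozenset = frozenset()

    def __post_init__(self) -> None:
        ls = frozenset(self.level_specific)
        bad = ls - set(COVARIATE_PARAMS)
        if bad:
            raise ConfigurationError(
                f"only {COVARIATE_PARAMS} may be level-specific (c and d are always shared); got {sorted(bad)}"
            )
        object.__setattr__(self, "level_specific", ls)

    def with_param(self, name: str) -> "CovariateStructure":
        return CovariateStructure(self.level_specific | {name})

    def is_specific(self, name: str) -> bool:
        return name in self.level_specific

    def n_free_params(self, n_levels: int) -> int:
        n = 2  # c, d
        for p in COVARIATE_PARAMS:
            n += n_levels if p in self.level_specific else 1
        return n

    def describe(self) -> str:
        ls = sorted(self.level_specific)
        return "all-shared" if not ls else "level-specific: " + ", ".join(ls)


@dataclass
class ModelParams:
    """One fitted (or true) curve-family instance with per-level parameter maps."""

    family: str
    a: dict  # level -> background response, response units, > 0
    b: dict  # level -> potency; dose^(-d) (exponential) or dose (Hill), > 0
    c: float  # shared maximum fold-change, > 1 for increasing responses
    d: float  # shared log-steepness
    var: dict  # level -> variance of log-responses, > 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if set(self.a) != set(self.b) or set(self.a) != set(self.var):
            raise ConfigurationError("a, b and var must cover the same covariate levels")
        for name, m in (("a", self.a), ("b", self.b), ("var", self.var)):
            for lvl, v in m.items():
                if not (v > 0):
                    raise ConfigurationError(f"{name}[{lvl!r}] must be > 0, got {v!r}")
        if not (self.c > 1):
            raise ConfigurationError(f"c must be > 1 for increasing responses, got {self.c!r}")
        if not (self.d > 0):
            raise ConfigurationError(f"d must be > 0, got {self.d!r}")

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(self.a)

    def require_level(self, level: str) -> None:
        if level not in self.a:
            raise DeclaredLevelError(f"unknown covariate level {level!r}; declared: {list(self.a)}")


@dataclass
class FitResult:
    params: ModelParams
    loglik: float
    n_free_params: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# curve evaluation and likelihood
# ---------------------------------------------------------------------------

def _curve(family: str, x, a, b, c: float, d: float):
    """Vectorized mean response; a, b broadcast against x."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore", under="ignore"):
        if family == "exponential":
            return a * (c - (c - 1.0) * np.exp(-b * np.power(x, d)))
        if family == "hill":
            xd = np.power(x, d)
            return a * (1.0 + (c - 1.0) * xd / (np.power(b, d) + xd))
    raise ConfigurationError(f"unknown family {family!r}; choose from {FAMILIES}")


def predict_response(params: ModelParams, level: str, dose):
    """Mean response m(dose) for one covariate level; m(0) = a, sup m = a*c."""
    params.require_level(level)
    doses = np.asarray(dose, dtype=float)
    if np.any(doses < 0):
        raise ValueError("dose must be >= 0")
    out = _curve(params.family, doses, params.a[level], params.b[level], params.c, params.d)
    return float(out) if np.isscalar(dose) or np.ndim(dose) == 0 else out


def _loglik_from_stats(stats: _GroupStats, family: str, a_by, b_by, c: float, d: float, var_by) -> float:
    """Lognormal log-likelihood from per-group sufficient statistics.

    Per group g in level l:  -n_g/2 * ln(2*pi*var_l)
                             - [ss_g + n_g*(mean_log_g - ln m(x_g))^2] / (2*var_l)
    """
    a = a_by[stats.level_idx]
    b = b_by[stats.level_idx]
    v = var_by[stats.level_idx]
    m = _curve(family, stats.dose, a, b, c, d)
    q = stats.ss_log + stats.n * (stats.mean_log - np.log(m)) ** 2
    return float(np.sum(-0.5 * stats.n * np.log(2.0 * math.pi * v) - q / (2.0 * v)))


def log_likelihood(dataset: DoseResponseDataset, params: ModelParams) -> float:
    """Lognormal log-likelihood of the dataset under ``params``.

    Log-responses are modelled as normal with mean ``log m(x)`` and the
    level's ``var``; summary-form data enter through log-scale sufficient
    statistics (lognormal moment map). Additive over independent observations
    and invariant to record order.
    """
    for lvl in dataset.levels:
        params.require_level(lvl)
    stats = dataset.group_stats()
    a = np.asarray([params.a[l] for l in stats.levels])
    b = np.asarray([params.b[l] for l in stats.levels])
    v = np.asarray([params.var[l] for l in stats.levels])
    return _loglik_from_stats(stats, params.family, a, b, params.c, params.d, v)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings.

    d_bounds regularize the shared log-steepness (default [0.25, 4], the usual
    continuous-BMD practice: avoids infinite-slope and flat-shape degeneracy).
    c_max caps the maximum fold-change.  n_local_starts local searches are run
    from the best points of a fixed, seed-free lattice.
    """

    d_bounds: tuple[float, float] = (0.25, 4.0)
    c_min_excess: float = 1e-6   # lower bound on c - 1
    c_max: float = 1e4
    n_local_starts: int = 10
    maxiter: int = 400
    ftol: float = 1e-12


class _Layout:
    """Maps a flat optimizer vector to curve parameters for one structure.

    Internal coordinates: log a (per level or shared), a potency coordinate
    (exponential: eta = ln(b) + d*ln(x_scale), the log exponent at the top
    dose, which decouples b's scale from d; Hill: ln b), log(c-1), and d.
    When ``profile_bmd`` is set, the focal potency coordinate is dropped and b
    is recovered from the fixed BMD and the current (c, d) at the given CES.
    """

    def __init__(
        self,
        stats: _GroupStats,
        family: str,
        structure: CovariateStructure,
        opts: FitOptions,
        profile_bmd: tuple[str, float, float] | None = None,  # (level, ces, log_bmd)
    ) -> None:
        self.stats = stats
        self.family = family
        self.structure = structure
        self.opts = opts
        self.levels = stats.levels
        self.L = len(self.levels)
        self.x_scale = float(stats.dose[stats.dose > 0].max())
        self.profile = profile_bmd
        if profile_bmd is not None and profile_bmd[0] not in self.levels:
            raise DeclaredLevelError(f"unknown covariate level {profile_bmd[0]!r}")

        self.n_a = self.L if structure.is_specific("a") else 1
        b_specific = structure.is_specific("b")
        self.n_b_full = self.L if b_specific else 1
        # which b slots are free (the focal one is derived during profiling)
        if profile_bmd is None:
            self.free_b_slots = list(range(self.n_b_full))
        elif b_specific:
            focal = self.levels.index(profile_bmd[0])
            self.free_b_slots = [i for i in range(self.L) if i != focal]
            self.focal_b_slot = focal
        else:
            self.free_b_slots = []
            self.focal_b_slot = 0
        self.n_b = len(self.free_b_slots)
        self.n_theta = self.n_a + self.n_b + 2

        # bounds: a from the data's per-level geometric-mean range
        gm = np.exp(stats.mean_log)
        lo_a, hi_a = [], []
        for i in range(self.n_a):
            sel = stats.level_idx == i if self.n_a > 1 else np.ones_like(stats.level_idx, dtype=bool)
            g = gm[sel]
            lo_a.append(math.log(g.min() / 50.0))
            hi_a.append(math.log(g.max() * 50.0))
        if family == "exponential":
            b_lo, b_hi = math.log(1e-5), math.log(1e3)
        else:
            b_lo, b_hi = math.log(self.x_scale) - 10.0, math.log(self.x_scale) + 10.0
        c_lo = math.log(opts.c_min_excess)
        if profile_bmd is not None:
            # BMD at this CES exists only when c - 1 > ces
            c_lo = max(c_lo, math.log(profile_bmd[1]) + 1e-9)
        self.bounds = (
            list(zip(lo_a, hi_a))
            + [(b_lo, b_hi)] * self.n_b
            + [(c_lo, math.log(self.opts.c_max - 1.0))]
            + [opts.d_bounds]
        )

    # -- coordinate transforms ----------------------------------------------

    def _b_from_coord(self, coord: float, d: float) -> float:
        if self.family == "exponential":
            return math.exp(coord - d * math.log(self.x_scale))
        return math.exp(coord)

    def _coord_from_b(self, b: float, d: float) -> float:
        if self.family == "exponential":
            return math.log(b) + d * math.log(self.x_scale)
        return math.log(b)

    def _focal_b(self, c: float, d: float) -> float:
        """Potency implied by the fixed BMD at the profiled CES (needs c-1 > ces)."""
        level, ces, log_bmd = self.profile
        bmd = math.exp(log_bmd)
        if self.family == "exponential":
            return -math.log((c - 1.0 - ces) / (c - 1.0)) / bmd ** d
        t = ces / (c - 1.0)
        return bmd * ((1.0 - t) / t) ** (1.0 / d)

    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
        a = np.exp(theta[: self.n_a])
        if self.n_a == 1:
            a = np.repeat(a, self.L)
        c = 1.0 + math.exp(theta[self.n_a + self.n_b])
        d = float(theta[self.n_a + self.n_b + 1])
        b_full = np.empty(self.n_b_full)
        for j, slot in enumerate(self.free_b_slots):
            b_full[slot] = self._b_from_coord(theta[self.n_a + j], d)
        if self.profile is not None:
            b_full[self.focal_b_slot] = self._focal_b(c, d)
        b = b_full if self.n_b_full > 1 else np.repeat(b_full, self.L)
        return a, b, c, d

    def pack(self, params: ModelParams) -> np.ndarray:
        """Map a ModelParams (levels matching) into a start vector, clipped to bounds."""
        theta = np.empty(self.n_theta)
        if self.n_a == 1:
            theta[0] = float(np.mean([math.log(params.a[l]) for l in self.levels]))
        else:
            theta[: self.n_a] = [math.log(params.a[l]) for l in self.levels]
        for j, slot in enumerate(self.free_b_slots):
            lvl = self.levels[slot] if self.n_b_full > 1 else self.levels[0]
            theta[self.n_a + j] = self._coord_from_b(params.b[lvl], params.d)
        theta[self.n_a + self.n_b] = math.log(max(params.c - 1.0, self.opts.c_min_excess))
        theta[self.n_a + self.n_b + 1] = params.d
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip(theta, lo, hi)

    # -- objective -----------------------------------------------------------

    def _profiled_var(self, q: np.ndarray) -> np.ndarray:
        """ML variance(s) given curve residual mass q per group -> per-group var array."""
        stats = self.stats
        if self.structure.is_specific("var"):
            v = np.empty(self.L)
            for i in range(self.L):
                sel = stats.level_idx == i
                v[i] = max(q[sel].sum() / stats.n[sel].sum(), _VAR_FLOOR)
            return v[stats.level_idx]
        v = max(q.sum() / stats.n.sum(), _VAR_FLOOR)
        return np.full(len(q), v)

    def nll(self, theta: np.ndarray) -> float:
        """Negative log-likelihood with var profiled out in closed form."""
        try:
            a, b, c, d = self.unpack(theta)
        except (OverflowError, ValueError):
            return 1e12
        stats = self.stats
        m = _curve(self.family, stats.dose, a[stats.level_idx], b[stats.level_idx], c, d)
        if not np.all(np.isfinite(m)) or np.any(m <= 0):
            return 1e12
        q = stats.ss_log + stats.n * (stats.mean_log - np.log(m)) ** 2
        v = self._profiled_var(q)
        ll = np.sum(-0.5 * stats.n * np.log(2.0 * math.pi * v) - q / (2.0 * v))
        return -float(ll) if np.isfinite(ll) else 1e12

    def lattice(self) -> list[np.ndarray]:
        """Fixed seed-free start lattice over (d, c, potency); a at the control level."""
        stats = self.stats
        starts = []
        a0 = np.empty(self.n_a)
        gm = np.exp(stats.mean_log)
        for i in range(self.n_a):
            sel = stats.level_idx == i if self.n_a > 1 else np.ones_like(stats.level_idx, dtype=bool)
            dsel = stats.dose[sel]
            a0[i] = math.log(gm[sel][np.argmin(dsel)])
        if self.family == "exponential":
            pot_coords = [math.log(0.1), math.log(1.0), math.log(5.0)]
        else:
            pot_coords = [math.log(self.x_scale * f) for f in (0.1, 0.5, 2.0)]
        for d0 in (0.5, 1.0, 2.0, 3.5):
            for cm1 in (1.0, 9.0, 99.0):
                for pc in pot_coords:
                    theta = np.empty(self.n_theta)
                    theta[: self.n_a] = a0
                    theta[self.n_a : self.n_a + self.n_b] = pc
                    theta[self.n_a + self.n_b] = math.log(cm1)
                    theta[self.n_a + self.n_b + 1] = d0
                    lo = np.array([b[0] for b in self.bounds])
                    hi = np.array([b[1] for b in self.bounds])
                    starts.append(np.clip(theta, lo, hi))
        return starts

    def result_params(self, theta: np.ndarray) -> ModelParams:
        a, b, c, d = self.unpack(theta)
        stats = self.stats
        m = _curve(self.family, stats.dose, a[stats.level_idx], b[stats.level_idx], c, d)
        q = stats.ss_log + stats.n * (stats.mean_log - np.log(m)) ** 2
        if self.structure.is_specific("var"):
            var = {}
            for i, lvl in enumerate(self.levels):
                sel = stats.level_idx == i
                var[lvl] = max(float(q[sel].sum() / stats.n[sel].sum()), _VAR_FLOOR)
        else:
            v = max(float(q.sum() / stats.n.sum()), _VAR_FLOOR)
            var = {lvl: v for lvl in self.levels}
        return ModelParams(
            family=self.family,
            a={lvl: float(a[i]) for i, lvl in enumerate(self.levels)},
            b={lvl: float(b[i]) for i, lvl in enumerate(self.levels)},
            c=float(c),
            d=float(d),
            var=var,
        )

    def at_bounds(self, theta: np.ndarray, tol: float = 1e-6) -> list[str]:
        names = (
            [f"a[{self.levels[i]}]" if self.n_a > 1 else "a" for i in range(self.n_a)]
            + [
                f"b[{self.levels[s]}]" if self.n_b_full > 1 else "b"
                for s in self.free_b_slots
            ]
            + ["c", "d"]
        )
        hits = []
        for name, t, (lo, hi) in zip(names, theta, self.bounds):
            if t - lo <= tol * max(1.0, abs(lo)):
                hits.append(f"{name}@lower")
            elif hi - t <= tol * max(1.0, abs(hi)):
                hits.append(f"{name}@upper")
        return hits


def _constant_model_loglik(stats: _GroupStats, structure: CovariateStructure) -> float:
    """ML log-likelihood of the dose-independent model (per-level constant mean
    when a is level-specific, one global constant otherwise; var per structure)."""
    n_levels = len(stats.levels)
    if structure.is_specific("a") and n_levels > 1:
        mean_groups = [stats.level_idx == i for i in range(n_levels)]
    else:
        mean_groups = [np.ones(len(stats.dose), dtype=bool)]
    q = np.empty(len(stats.dose))
    for sel in mean_groups:
        mu = float(np.sum(stats.n[sel] * stats.mean_log[sel]) / np.sum(stats.n[sel]))
        q[sel] = stats.ss_log[sel] + stats.n[sel] * (stats.mean_log[sel] - mu) ** 2
    if structure.is_specific("var") and n_levels > 1:
        var_groups = [stats.level_idx == i for i in range(n_levels)]
    else:
        var_groups = [np.ones(len(stats.dose), dtype=bool)]
    ll = 0.0
    for sel in var_groups:
        n = float(np.sum(stats.n[sel]))
        v = max(float(q[sel].sum()) / n, _VAR_FLOOR)
        ll += -0.5 * n * (math.log(2.0 * math.pi * v) + 1.0)
    return ll


def _minimize_multistart(layout: _Layout, extra_starts: Sequence[np.ndarray] = ()):
    """Rank the fixed lattice by objective value, polish the best points."""
    opts = layout.opts
    cands = list(extra_starts) + layout.lattice()
    ranked = sorted(cands, key=layout.nll)
    n_extra = len(extra_starts)
    n_polish = max(opts.n_local_starts, n_extra)
    best = None
    trace = []
    for theta0 in ranked[:n_polish]:
        res = minimize(
            layout.nll,
            theta0,
            method="L-BFGS-B",
            bounds=layout.bounds,
            options={"maxiter": opts.maxiter, "ftol": opts.ftol},
        )
        trace.append((float(res.fun), bool(res.success)))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise ConvergenceError(f"all {n_polish} optimizer starts failed; trace={trace}")
    return best, trace


def fit_single_structure(
    dataset: DoseResponseDataset,
    family: str,
    structure: CovariateStructure | None = None,
    opts: FitOptions | None = None,
    init_params: ModelParams | None = None,
) -> FitResult:
    """Maximize the lognormal log-likelihood for one covariate structure.

    ``init_params`` (e.g. the fit of a nested structure) is added as an extra
    warm start, which guarantees nested-model log-likelihood dominance up to
    optimizer tolerance.
    """
    if family not in FAMILIES:
        raise ConfigurationError(f"unknown family {family!r}; choose from {FAMILIES}")
    structure = structure or CovariateStructure()
    opts = opts or FitOptions()
    stats = dataset.group_stats()
    distinct = np.unique(stats.dose)
    if len(distinct) < 3 or 0.0 not in distinct:
        raise IdentifiabilityError(
            f"model fitting needs >= 3 distinct dose levels including 0; got {list(distinct)}"
        )
    layout = _Layout(stats, family, structure, opts)
    n_curve = layout.n_theta
    if len(stats.dose) < n_curve:
        raise IdentifiabilityError(
            f"{len(stats.dose)} (level, dose) groups cannot identify {n_curve} free curve parameters"
        )
    extra = []
    if init_params is not None:
        extra.append(layout.pack(init_params))
    best, trace = _minimize_multistart(layout, extra)
    params = layout.result_params(best.x)
    hits = layout.at_bounds(best.x)
    flat_gain = -float(best.fun) - _constant_model_loglik(stats, structure)
    return FitResult(
        params=params,
        loglik=-float(best.fun),
        n_free_params=structure.n_free_params(len(dataset.levels)),
        converged=bool(best.success),
        diagnostics={
            "n_starts": len(trace),
            "start_values": trace,
            "at_bounds": hits,
            # no-effect degeneracy: the dose-response terms add (almost) nothing
            # over the nested constant model, or c collapsed to its lower bound
            "flat_model": bool(
                flat_gain < 0.5 * float(chi2.ppf(0.95, 2))
                or any(h.startswith("c@lower") for h in hits)
            ),
            "gain_over_constant": flat_gain,
            "message": str(best.message),
            "nit": int(best.nit),
        },
    )
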