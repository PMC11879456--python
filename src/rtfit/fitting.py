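"""Maximum-likelihood fitting of the RTF by multi-start bounded optimization.

The objective is twice the negative Gaussian log-likelihood,

    -2 ln L = sum_i [ ln(2 pi sigma_i^2) + Delta_i^2 / sigma_i^2 ],

where ``Delta_i = y_i - R(t_i)`` are the residuals.  When the data table
carries a known per-point standard error (``sigmaExp``) it is used as
``sigma_i``; otherwise a single noise parameter ``sigma`` is estimated
jointly with the kinetic parameters.

Each local search is an L-BFGS-B run with the analytic objective gradient,
on a parameter vector where positive scale-spanning parameters (rates,
sigma, Hill h and K, the M of rate parameters) live on a log10 axis.
Multi-start initial points are Latin-hypercube draws inside the bounds,
seeded for reproducibility; when the component signs are left to ``auto``,
the four (signSus, signTrans) combinations split the start budget.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.stats import qmc

from .model import (
    DOSE_PARAM_NAMES,
    SINGLE_DOSE_PARAM_NAMES,
    DoseRTFParams,
    RTFParams,
    TimeScale,
    dose_gradient,
    dose_rtf_evaluate,
    dose_expand,
    rtf_evaluate,
    rtf_gradient,
)

__all__ = [
    "TimeCourseTable",
    "OptimProblem",
    "StartResult",
    "FitResult",
    "FitError",
    "neg2_log_likelihood",
    "objective_gradient",
    "build_problem",
    "default_initial_guess",
    "initial_guesses",
    "fit",
    "predict",
    "derive_seed",
]

_LN10 = np.log(10.0)

SINGLE_DOSE = "singleDose"
DOSE_DEPENDENT = "doseDependent"


class FitError(RuntimeError):
    """Raised when every optimization start fails."""


def derive_seed(seed: int, *tags) -> int:
    """Derive a reproducible child seed (< 2^31) from a master seed and tags."""
    text = repr((int(seed),) + tuple(tags)).encode()
    return zlib.crc32(text) % (2**31 - 1)


@dataclass(frozen=True)
class TimeCourseTable:
    """Observed time course: times ``t``, values ``y``, optional dose ``d``
    and optional known per-point standard error ``sigma_exp``."""

    t: np.ndarray
    y: np.ndarray
    d: np.ndarray | None = None
    sigma_exp: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if self.t.size < 3:
            raise ValueError("need at least 3 data points")
        if np.unique(self.t).size < 2:
            raise ValueError("need at least 2 distinct time points")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.y))):
            raise ValueError("t and y must be finite")
        for name in ("d", "sigma_exp"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                object.__setattr__(self, name, v)
                if v.shape != self.t.shape:
                    raise ValueError(f"{name} must match the length of t")
        if self.sigma_exp is not None and not np.all(self.sigma_exp > 0):
            raise ValueError("sigma_exp values must all be > 0")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def time_range(self) -> float:
        return float(self.t.max() - self.t.min())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TimeCourseTable":
        for col in ("t", "y"):
            if col not in df.columns:
                raise ValueError(f"missing required column '{col}'")
        return cls(
            t=df["t"].to_numpy(dtype=float),
            y=df["y"].to_numpy(dtype=float),
            d=df["d"].to_numpy(dtype=float) if "d" in df.columns else None,
            sigma_exp=(
                df["sigmaExp"].to_numpy(dtype=float) if "sigmaExp" in df.columns else None
            ),
        )

    def to_frame(self) -> pd.DataFrame:
        out = {"t": self.t, "y": self.y}
        if self.d is not None:
            out["d"] = self.d
        if self.sigma_exp is not None:
            out["sigmaExp"] = self.sigma_exp
        return pd.DataFrame(out)


@dataclass
class OptimProblem:
    """Fitting task: data, parameter layout, bounds, fixings, transforms.

    ``param_names`` fixes the serialization order; ``fixed`` maps a
    parameter name to an imposed value (absent = free); ``take_log10``
    marks parameters optimized on a log10 axis; signs may be +1, -1 or
    ``"auto"`` (enumerated during fitting).
    """

    data: TimeCourseTable
    mode: str
    param_names: tuple[str, ...]
    lb: np.ndarray
    ub: np.ndarray
    take_log10: np.ndarray
    initial_guess: np.ndarray
    fixed: dict[str, float] = field(default_factory=dict)
    sign_sus: int | str = "auto"
    sign_trans: int | str = "auto"
    sigma_free: bool = False
    T: float = 0.0

    def __post_init__(self) -> None:
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.take_log10 = np.asarray(self.take_log10, dtype=bool)
        self.initial_guess = np.asarray(self.initial_guess, dtype=float)
        p = len(self.param_names)
        if not (self.lb.size == self.ub.size == self.take_log10.size == p):
            raise ValueError("bounds/mask lengths must match param_names")
        free = self.free_mask
        if np.any(self.lb[free] >= self.ub[free]):
            raise ValueError("lb < ub required for free parameters")
        if np.any(self.take_log10 & free & (self.lb <= 0)):
            raise ValueError("log10-transformed free parameters need lb > 0")
        unknown = set(self.fixed) - set(self.param_names)
        if unknown:
            raise ValueError(f"fixed refers to unknown parameters: {sorted(unknown)}")
        if self.mode == DOSE_DEPENDENT:
            if self.data.d is None or np.unique(self.data.d).size < 2:
                raise ValueError("doseDependent mode needs a dose column with >= 2 doses")
        elif self.mode != SINGLE_DOSE:
            raise ValueError(f"unknown mode {self.mode!r}")

    # -- parameter-space plumbing ------------------------------------------

    @property
    def free_mask(self) -> np.ndarray:
        return np.array([n not in self.fixed for n in self.param_names])

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.param_names if n not in self.fixed)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def index_of(self, name: str) -> int:
        return self.param_names.index(name)

    def full_from_free(self, free_vec: np.ndarray) -> np.ndarray:
        """Insert fixed values into a natural-scale free vector."""
        out = np.empty(len(self.param_names))
        out[self.free_mask] = free_vec
        for name, val in self.fixed.items():
            out[self.index_of(name)] = val
        return out

    def to_internal(self, full: np.ndarray) -> np.ndarray:
        """Natural-scale full vector -> transformed free vector."""
        free = np.asarray(full, dtype=float)[self.free_mask]
        logmask = self.take_log10[self.free_mask]
        out = free.copy()
        out[logmask] = np.log10(free[logmask])
        return out

    def from_internal(self, z: np.ndarray) -> np.ndarray:
        """Transformed free vector -> natural-scale full vector."""
        logmask = self.take_log10[self.free_mask]
        free = np.asarray(z, dtype=float).copy()
        free[logmask] = 10.0 ** free[logmask]
        return self.full_from_free(free)

    def internal_bounds(self) -> list[tuple[float, float]]:
        lo, hi = self.lb[self.free_mask].copy(), self.ub[self.free_mask].copy()
        logmask = self.take_log10[self.free_mask]
        lo[logmask] = np.log10(lo[logmask])
        hi[logmask] = np.log10(hi[logmask])
        return list(zip(lo, hi))

    def with_signs(self, sign_sus: int, sign_trans: int) -> "OptimProblem":
        return replace(self, sign_sus=sign_sus, sign_trans=sign_trans)

    def with_fixed(self, extra: dict[str, float]) -> "OptimProblem":
        merged = dict(self.fixed)
        merged.update(extra)
        guess = self.initial_guess.copy()
        for name, val in merged.items():
            guess[self.index_of(name)] = val
        return replace(self, fixed=merged, initial_guess=guess)

    def params_from_vector(self, theta: np.ndarray):
        """Build the validated parameter object from a full natural vector."""
        sigma = float(theta[-1]) if self.sigma_free else None
        ss = self.sign_sus if self.sign_sus in (1, -1) else +1
        st = self.sign_trans if self.sign_trans in (1, -1) else +1
        if self.mode == SINGLE_DOSE:
            return RTFParams.from_vector(theta[:7], ss, st, sigma)
        return DoseRTFParams.from_vector(theta[:19], ss, st, sigma)


# -- objective ----------------------------------------------------------------


def _model_values(theta: np.ndarray, problem: OptimProblem) -> np.ndarray:
    params = problem.params_from_vector(theta)
    scale = TimeScale(problem.T)
    if problem.mode == SINGLE_DOSE:
        return rtf_evaluate(params, problem.data.t, scale)
    return dose_rtf_evaluate(params, problem.data.t, problem.data.d, scale)


def _resolve_sigma(theta: np.ndarray, problem: OptimProblem) -> np.ndarray:
    if problem.sigma_free:
        sigma = float(theta[-1])
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        return np.full(problem.data.n, sigma)
    if problem.data.sigma_exp is None:
        raise ValueError("no sigmaExp column and sigma is not a free parameter")
    return problem.data.sigma_exp


def neg2_log_likelihood(theta: np.ndarray, problem: OptimProblem) -> float:
    """-2 ln L = sum[ ln(2 pi sigma_i^2) + Delta_i^2 / sigma_i^2 ]."""
    theta = np.asarray(theta, dtype=float)
    sigma = _resolve_sigma(theta, problem)
    delta = problem.data.y - _model_values(theta, problem)
    return float(np.sum(np.log(2.0 * np.pi * sigma**2) + delta**2 / sigma**2))


def objective_gradient(theta: np.ndarray, problem: OptimProblem) -> np.ndarray:
    """Natural-scale gradient of the -2 ln L objective over all parameters.

    The model part is the chain rule through the analytic RTF Jacobian;
    with sigma free the extra component is ``2n/sigma - 2 sum(Delta^2)/sigma^3``.
    """
    theta = np.asarray(theta, dtype=float)
    sigma = _resolve_sigma(theta, problem)
    delta = problem.data.y - _model_values(theta, problem)
    params = problem.params_from_vector(theta)
    scale = TimeScale(problem.T)
    if problem.mode == SINGLE_DOSE:
        jac = rtf_gradient(params, problem.data.t, scale)
    else:
        jac = dose_gradient(params, problem.data.t, problem.data.d, scale)
    grad_model = (-2.0 * delta / sigma**2) @ jac
    if problem.sigma_free:
        s = float(theta[-1])
        grad_sigma = 2.0 * problem.data.n / s - 2.0 * np.sum(delta**2) / s**3
        return np.append(grad_model, grad_sigma)
    return grad_model


def _internal_objective(problem: OptimProblem):
    """Objective + gradient on the transformed free-parameter vector."""
    free_theta_mask = problem.free_mask
    logmask = problem.take_log10[free_theta_mask]

    def fun(z: np.ndarray):
        theta = problem.from_internal(z)
        f = neg2_log_likelihood(theta, problem)
        g = objective_gradient(theta, problem)[free_theta_mask]
        g = g.copy()
        g[logmask] *= theta[free_theta_mask][logmask] * _LN10  # d theta / d log10(theta)
        return f, g

    return fun


# -- problem construction -----------------------------------------------------


def build_problem(
    data: TimeCourseTable,
    mode: str = SINGLE_DOSE,
    sign_sus: int | str = "auto",
    sign_trans: int | str = "auto",
    fixed: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> OptimProblem:
    """Derive a fitting task from a data table.

    Default bounds are scale-free in the data's units: with
    ``ry = max(y) - min(y)`` and the transformed time axis spanning about
    [0, 10], amplitudes live in [0, 2 ry], rates in [1e-2, 1e2] (log10),
    tau in [-2, max(t) * 10 / T], the offset in [min(y) - ry, max(y) + ry]
    and sigma (when free) in [1e-4 ry, ry] (log10).  Hill maxima inherit
    the bounds of the parameter they modulate, h lives in [0.1, 10] and K
    spans the observed dose range, both on log10 axes.  ``bounds`` and
    ``fixed`` override these per parameter.
    """
    y, t = data.y, data.t
    ry = float(y.max() - y.min())
    if ry == 0:
        import warnings

        warnings.warn("all y values are identical; fit will be degenerate", stacklevel=2)
        ry = max(abs(float(y[0])), 1.0)
    T = data.time_range
    tau_hi = float(t.max()) * 10.0 / T
    sigma_free = data.sigma_exp is None

    lo: dict[str, float] = {}
    hi: dict[str, float] = {}
    log10: dict[str, bool] = {}

    def set_bound(name, lo_v, hi_v, is_log):
        lo[name], hi[name], log10[name] = lo_v, hi_v, is_log

    if mode == SINGLE_DOSE:
        names = list(SINGLE_DOSE_PARAM_NAMES)
        set_bound("A", 0.0, 2.0 * ry, False)
        set_bound("B", 0.0, 2.0 * ry, False)
        for r in ("alpha", "beta", "gamma"):
            set_bound(r, 1e-2, 1e2, True)
        set_bound("tau", -2.0, tau_hi, False)
        set_bound("b", float(y.min()) - ry, float(y.max()) + ry, False)
    elif mode == DOSE_DEPENDENT:
        if data.d is None:
            raise ValueError("doseDependent mode needs a dose column")
        doses = np.unique(data.d)
        if doses.size < 2:
            raise ValueError("doseDependent mode needs >= 2 distinct doses")
        pos = doses[doses > 0]
        if pos.size == 0:
            raise ValueError("doseDependent mode needs at least one positive dose")
        k_lo, k_hi = float(pos.min()) / 10.0, float(doses.max()) * 10.0
        names = list(DOSE_PARAM_NAMES)
        for target in ("A", "B"):
            set_bound(f"M_{target}", 0.0, 2.0 * ry, False)
        for target in ("alpha", "beta", "gamma"):
            set_bound(f"M_{target}", 1e-2, 1e2, True)
        set_bound("M_tau", 0.0, tau_hi, False)
        for target in ("A", "B", "alpha", "beta", "gamma", "tau"):
            set_bound(f"h_{target}", 0.1, 10.0, True)
            set_bound(f"K_{target}", k_lo, k_hi, True)
        set_bound("b", float(y.min()) - ry, float(y.max()) + ry, False)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if sigma_free:
        names.append("sigma")
        set_bound("sigma", 1e-4 * ry, ry, True)

    if bounds:
        for name, (lo_v, hi_v) in bounds.items():
            if name not in names:
                raise ValueError(f"bounds override for unknown parameter {name!r}")
            lo[name], hi[name] = float(lo_v), float(hi_v)

    problem = OptimProblem(
        data=data,
        mode=mode,
        param_names=tuple(names),
        lb=np.array([lo[n] for n in names]),
        ub=np.array([hi[n] for n in names]),
        take_log10=np.array([log10[n] for n in names]),
        initial_guess=np.zeros(len(names)),
        fixed=dict(fixed) if fixed else {},
        sign_sus=sign_sus,
        sign_trans=sign_trans,
        sigma_free=sigma_free,
        T=T,
    )
    guess_sign = sign_sus if sign_sus in (1, -1) else +1
    problem.initial_guess = default_initial_guess(problem, guess_sign)
    return problem


def default_initial_guess(problem: OptimProblem, sign_sus: int = +1) -> np.ndarray:
    """Cheap data-driven starting point, clipped into the bounds.

    Offset from the data floor (median when the sustained sign is
    negative), amplitudes from the net and peak excursion relative to the
    first observation, unit rates on the transformed axis, no retardation,
    sigma at 10% of the data range.
    """
    y = problem.data.y
    ry = float(y.max() - y.min()) or 1.0
    b0 = float(np.median(y)) if sign_sus == -1 else float(y.min())
    a0 = abs(float(y[-1] - y[0]))
    b_amp = float(np.max(np.abs(y - y[0])))
    guess: dict[str, float] = {}
    if problem.mode == SINGLE_DOSE:
        guess.update(
            A=a0, B=b_amp, alpha=1.0, beta=1.0, gamma=1.0, tau=0.0, b=b0
        )
    else:
        doses = np.unique(problem.data.d)
        k0 = float(np.median(doses[doses > 0]))
        for target, m0 in (
            ("A", a0 if a0 > 0 else ry),
            ("B", b_amp if b_amp > 0 else ry),
            ("alpha", 1.0),
            ("beta", 1.0),
            ("gamma", 1.0),
            ("tau", 1.0),
        ):
            guess[f"M_{target}"] = m0
            guess[f"h_{target}"] = 1.0
            guess[f"K_{target}"] = k0
        guess["b"] = b0
    if problem.sigma_free:
        guess["sigma"] = 0.1 * ry

    vec = np.array([guess[n] for n in problem.param_names])
    vec = np.clip(vec, problem.lb, problem.ub)
    for name, val in problem.fixed.items():
        vec[problem.index_of(name)] = val
    return vec


def initial_guesses(
    problem: OptimProblem, n_starts: int, seed: int = 1
) -> list[np.ndarray]:
    """Default guess plus seeded Latin-hypercube draws within the bounds.

    Draws are uniform on the transformed axis (so log10-uniform for
    log-scale parameters); the list is deterministic given the seed.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    sign = problem.sign_sus if problem.sign_sus in (1, -1) else +1
    guesses = [default_initial_guess(problem, sign)]
    n_random = n_starts - 1
    if n_random > 0:
        bounds = np.array(problem.internal_bounds())
        sampler = qmc.LatinHypercube(d=bounds.shape[0], seed=derive_seed(seed, "lhs"))
        unit = sampler.random(n_random)
        z = bounds[:, 0] + unit * (bounds[:, 1] - bounds[:, 0])
        guesses.extend(problem.from_internal(zi) for zi in z)
    return guesses


# -- multi-start fitting ------------------------------------------------------


@dataclass(frozen=True, eq=False)
class StartResult:
    """Outcome of one local optimization start."""

    x0: np.ndarray
    x: np.ndarray
    value: float
    converged: bool
    sign_sus: int
    sign_trans: int
    message: str = ""


@dataclass
class FitResult:
    """Multi-start fit outcome; ``best`` is the natural-scale minimizer."""

    problem: OptimProblem
    starts: list[StartResult]
    best: np.ndarray
    value: float
    residuals: np.ndarray

    @property
    def best_params(self):
        return self.problem.params_from_vector(self.best)

    @property
    def sorted_values(self) -> np.ndarray:
        """Finite per-start objectives sorted ascending (waterfall plot data)."""
        vals = np.array([s.value for s in self.starts])
        return np.sort(vals[np.isfinite(vals)])

    @property
    def sigma_hat(self) -> float:
        """Best-fit noise level: estimated sigma, or RMS of sigmaExp."""
        if self.problem.sigma_free:
            return float(self.best[-1])
        return float(np.sqrt(np.mean(self.problem.data.sigma_exp**2)))

    def predict(self, times, doses=None):
        return predict(self, times, doses)


def _model_jacobian(theta: np.ndarray, problem: OptimProblem) -> np.ndarray:
    params = problem.params_from_vector(theta)
    scale = TimeScale(problem.T)
    if problem.mode == SINGLE_DOSE:
        return rtf_gradient(params, problem.data.t, scale)
    return dose_gradient(params, problem.data.t, problem.data.d, scale)


def _free_model_layout(problem: OptimProblem):
    """Indices of the free non-sigma parameters in the free vector and in
    the full parameter vector."""
    free_names = problem.free_names
    in_free = [i for i, n in enumerate(free_names) if n != "sigma"]
    in_full = [problem.index_of(free_names[i]) for i in in_free]
    return np.array(in_free, dtype=int), np.array(in_full, dtype=int)


def _run_start(problem: OptimProblem, x0_full: np.ndarray, callback=None):
    """One local search: trust-region least squares on the kinetic
    parameters (sigma, when free, is profiled analytically -- the joint
    -2 ln L optimum satisfies sigma^2 = mean(Delta^2)), followed by a
    short joint quasi-Newton refinement with the analytic gradient."""
    z0 = problem.to_internal(x0_full)
    if z0.size == 0:  # fully pinned model: nothing to optimize
        x = problem.full_from_free(z0)
        return StartResult(
            x0=np.asarray(x0_full, float),
            x=x,
            value=neg2_log_likelihood(x, problem),
            converged=True,
            sign_sus=problem.sign_sus,
            sign_trans=problem.sign_trans,
            message="no free parameters",
        )

    in_free, in_full = _free_model_layout(problem)
    logmask_full = problem.take_log10
    z_work = z0.copy()
    converged = True
    message = ""

    if in_free.size > 0:
        weights = (
            problem.data.sigma_exp
            if problem.data.sigma_exp is not None
            else np.ones(problem.data.n)
        )
        if "sigma" in problem.fixed:
            weights = np.full(problem.data.n, problem.fixed["sigma"])

        def theta_of(zm: np.ndarray) -> np.ndarray:
            z = z_work.copy()
            z[in_free] = zm
            return problem.from_internal(z)

        def resid(zm: np.ndarray) -> np.ndarray:
            return (problem.data.y - _model_values(theta_of(zm), problem)) / weights

        def jac(zm: np.ndarray) -> np.ndarray:
            theta = theta_of(zm)
            J = _model_jacobian(theta, problem)[:, : len(problem.param_names)]
            cols = J[:, in_full] * np.where(
                logmask_full[in_full], theta[in_full] * _LN10, 1.0
            )
            return -cols / weights[:, None]

        bounds = np.array(problem.internal_bounds())
        lo, hi = bounds[in_free, 0], bounds[in_free, 1]
        zm0 = np.clip(z0[in_free], lo, hi)
        try:
            ls = least_squares(
                resid, zm0, jac=jac, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-10, max_nfev=400,
            )
            z_work[in_free] = ls.x
            converged = bool(ls.status > 0)
            message = str(ls.message)
        except Exception as err:  # noqa: BLE001 - a failed start is reported, not fatal
            converged = False
            message = f"least-squares stage failed: {err}"

    if problem.sigma_free:
        # profile optimum of the joint likelihood, clamped into the bounds
        theta = problem.from_internal(z_work)
        delta = problem.data.y - _model_values(theta, problem)
        i_sigma = problem.index_of("sigma")
        s_hat = float(np.sqrt(np.mean(delta**2)))
        s_hat = float(np.clip(s_hat, problem.lb[i_sigma], problem.ub[i_sigma]))
        z_work[list(problem.free_names).index("sigma")] = np.log10(s_hat)

    # joint refinement (a no-op when the profiled point is already optimal)
    obj = _internal_objective(problem)
    res = minimize(
        obj,
        z_work,
        jac=True,
        method="L-BFGS-B",
        bounds=problem.internal_bounds(),
        callback=callback,
        options={"maxiter": 200, "ftol": 1e-13, "gtol": 1e-9},
    )
    x = problem.from_internal(res.x)
    return StartResult(
        x0=np.asarray(x0_full, float),
        x=x,
        value=float(res.fun),
        converged=converged and np.isfinite(res.fun),
        sign_sus=problem.sign_sus,
        sign_trans=problem.sign_trans,
        message=message or str(res.message),
    )


def _sign_combos(problem: OptimProblem) -> list[tuple[int, int]]:
    sus = [problem.sign_sus] if problem.sign_sus in (1, -1) else [+1, -1]
    trans = [problem.sign_trans] if problem.sign_trans in (1, -1) else [+1, -1]
    return [(s, t) for s in sus for t in trans]


def fit(
    problem: OptimProblem,
    n_starts: int = 50,
    seed: int = 1,
    res_old: FitResult | None = None,
    extra_starts: Sequence[np.ndarray] = (),
    callback=None,
) -> FitResult:
    """Multi-start maximum-likelihood fit.

    Runs a bounded L-BFGS-B search from the data-driven default guess and
    seeded Latin-hypercube starts; with ``auto`` signs the four sign
    combinations split the budget.  ``res_old`` starts (a previous
    FitResult on the same problem layout) and ``extra_starts`` (warm-start
    vectors) join the comparison, so continuation never worsens the best
    value.  The winning start is polished with tighter tolerances.
    """
    combos = _sign_combos(problem)
    starts: list[StartResult] = []
    if n_starts > 0:
        per_combo = max(1, n_starts // len(combos))
        for k, (ss, st) in enumerate(combos):
            prob_c = problem.with_signs(ss, st)
            for x0 in initial_guesses(prob_c, per_combo, derive_seed(seed, "signs", k)):
                starts.append(_run_start(prob_c, x0, callback=callback))
    for x0 in extra_starts:
        prob_c = problem if problem.sign_sus in (1, -1) else problem.with_signs(+1, +1)
        starts.append(_run_start(prob_c, np.asarray(x0, float), callback=callback))
    if res_old is not None:
        starts.extend(res_old.starts)

    finite = [s for s in starts if np.isfinite(s.value)]
    if not finite:
        msgs = "; ".join(s.message for s in starts[:5])
        raise FitError(f"all {len(starts)} optimization starts failed: {msgs}")

    best_start = min(finite, key=lambda s: s.value)
    best_problem = problem.with_signs(best_start.sign_sus, best_start.sign_trans)

    # polish the winner with tighter tolerances (sharpens the sigma
    # stationarity condition without re-running the whole multistart)
    if best_problem.n_free > 0:
        best_start = _polish(best_problem, best_start)

    best = best_start.x
    value = neg2_log_likelihood(best, best_problem)
    residuals = best_problem.data.y - _model_values(best, best_problem)
    if best_start not in starts:
        starts.append(best_start)
    return FitResult(
        problem=best_problem, starts=starts, best=best, value=value, residuals=residuals
    )


def _polish(best_problem: OptimProblem, best_start: StartResult) -> StartResult:
    obj = _internal_objective(best_problem)
    res = minimize(
        obj,
        best_problem.to_internal(best_start.x),
        jac=True,
        method="L-BFGS-B",
        bounds=best_problem.internal_bounds(),
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    if np.isfinite(res.fun) and res.fun <= best_start.value:
        return StartResult(
            x0=best_start.x,
            x=best_problem.from_internal(res.x),
            value=float(res.fun),
            converged=bool(res.success),
            sign_sus=best_problem.sign_sus,
            sign_trans=best_problem.sign_trans,
            message="polish: " + str(res.message),
        )
    return best_start


def parameter_standard_errors(fitted: FitResult) -> dict[str, float]:
    """Asymptotic standard errors of the free parameters at the best fit.

    From the observed Fisher information of the Gaussian likelihood,
    ``F = J^T J / sigma^2`` with the analytic model Jacobian J (pseudo-
    inverse for near-singular fits).  Pinned parameters get se = 0; the
    noise parameter sigma is excluded (its error is independent of the
    kinetic block).
    """
    problem = fitted.problem
    theta = fitted.best
    sigma = _resolve_sigma(theta, problem)
    J = _model_jacobian(theta, problem)[:, : len(problem.param_names) - int(problem.sigma_free)]
    in_free, in_full = _free_model_layout(problem)
    out = {name: 0.0 for name in problem.param_names if name != "sigma"}
    if in_full.size:
        Jf = J[:, in_full] / sigma[:, None]
        cov = np.linalg.pinv(Jf.T @ Jf)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        for idx, s in zip(in_full, se):
            out[problem.param_names[idx]] = float(s)
    return out


def predict(fitted: FitResult, times, doses=None):
    """Evaluate the fitted RTF at new times (and doses in dose mode).

    Single-dose fits return a vector over ``times``; dose-dependent fits
    return a (len(times), len(doses)) matrix over the cartesian grid.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    scale = TimeScale(fitted.problem.T)
    params = fitted.best_params
    if fitted.problem.mode == SINGLE_DOSE:
        if doses is not None:
            raise ValueError("doses are not accepted for a singleDose fit")
        return rtf_evaluate(params, times, scale)
    if doses is None:
        raise ValueError("doses are required for a doseDependent fit")
    doses = np.atleast_1d(np.asarray(doses, dtype=float))
    out = np.empty((times.size, doses.size))
    for j, d in enumerate(doses):
        out[:, j] = rtf_evaluate(dose_expand(params, float(d)), times, scale)
    return out
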