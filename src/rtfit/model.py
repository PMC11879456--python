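"""Core retarded transient function (RTF) model.

The RTF describes a signalling time course as the sum of a *sustained*
component, ``signSus * A * (1 - exp(-alpha * t))``, and a *transient*
component, ``signTrans * B * (1 - exp(-beta * t)) * exp(-gamma * t)``, plus
an offset ``b``.  The argument ``t`` is not the experimental time but a
nonlinear, log-domain transform of it with a time-shift parameter ``tau``
that produces a delayed onset of the response (the "retardation").

For dose-resolved data the parameters ``A, B, alpha, beta, gamma, tau``
each become functions of the dose ``d`` through a Hill equation
``H(d) = M d^h / (K^h + d^h)``, with ``tau`` using a reversed (decreasing)
Hill so that the delay shrinks with increasing dose.

Everything in this module is pure, vectorized math with hand-derived
analytic partial derivatives; it carries no fitting or I/O state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.special import expit

__all__ = [
    "RTFParams",
    "TimeScale",
    "HillTriple",
    "DoseRTFParams",
    "RATE_FLOOR",
    "SINGLE_DOSE_PARAM_NAMES",
    "DOSE_PARAM_NAMES",
    "time_transform",
    "time_transform_dtau",
    "rtf_evaluate",
    "rtf_components",
    "rtf_gradient",
    "hill",
    "hill_gradient",
    "dose_expand",
    "dose_gradient",
]

_LN10 = np.log(10.0)

#: Floor applied to rate constants that degenerate to 0 under the Hill
#: expansion at dose 0 (amplitudes vanish there, so the response is
#: unaffected; the floor only preserves the rate-positivity invariant).
RATE_FLOOR = 1e-10

#: Canonical ordering of the single-dose parameters (without sigma).
SINGLE_DOSE_PARAM_NAMES = ("A", "B", "alpha", "beta", "gamma", "tau", "b")

#: Canonical ordering of the dose-dependent parameters (without sigma):
#: (M, h, K) per Hill triple in the order A, B, alpha, beta, gamma, tau,
#: followed by the offset.
DOSE_PARAM_NAMES = tuple(
    f"{p}_{t}" for t in ("A", "B", "alpha", "beta", "gamma", "tau") for p in ("M", "h", "K")
) + ("b",)


def _check_sign(value: int, name: str) -> int:
    if value not in (+1, -1):
        raise ValueError(f"{name} must be +1 or -1, got {value!r}")
    return int(value)


@dataclass(frozen=True)
class RTFParams:
    """Parameter set of the single-dose RTF.

    Amplitudes ``A`` (sustained) and ``B`` (transient) are in signal units
    and non-negative; rates ``alpha`` (sustained), ``beta`` (transient
    rise) and ``gamma`` (transient decay) are positive and act on the
    transformed time axis (range roughly [0, 10]); ``tau`` shifts the time
    transform; ``b`` is the signal offset.  ``sigma`` is the Gaussian noise
    standard deviation and is present only when it is estimated from the
    data rather than supplied per point.
    """

    A: float
    B: float
    alpha: float
    beta: float
    gamma: float
    tau: float
    b: float
    signSus: int = +1
    signTrans: int = +1
    sigma: float | None = None

    def __post_init__(self) -> None:
        _check_sign(self.signSus, "signSus")
        _check_sign(self.signTrans, "signTrans")
        if not (self.A >= 0 and self.B >= 0):
            raise ValueError("amplitudes A, B must be >= 0")
        if not (self.alpha > 0 and self.beta > 0 and self.gamma > 0):
            raise ValueError("rates alpha, beta, gamma must be > 0")
        if not np.isfinite(self.tau):
            raise ValueError("tau must be finite")
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError("sigma must be > 0 when present")

    def to_vector(self) -> np.ndarray:
        """Return (A, B, alpha, beta, gamma, tau, b) as an array."""
        return np.array(
            [self.A, self.B, self.alpha, self.beta, self.gamma, self.tau, self.b]
        )

    @classmethod
    def from_vector(
        cls,
        vec: Iterable[float],
        signSus: int = +1,
        signTrans: int = +1,
        sigma: float | None = None,
    ) -> "RTFParams":
        A, B, alpha, beta, gamma, tau, b = (float(v) for v in vec)
        return cls(A, B, alpha, beta, gamma, tau, b, signSus, signTrans, sigma)


@dataclass(frozen=True)
class TimeScale:
    """Range ``T = max(treal) - min(treal)`` of the measurement times."""

    T: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.T) and self.T > 0):
            raise ValueError(f"T must be finite and > 0, got {self.T!r}")

    @classmethod
    def from_times(cls, treal: np.ndarray) -> "TimeScale":
        treal = np.asarray(treal, dtype=float)
        return cls(float(treal.max() - treal.min()))


@dataclass(frozen=True)
class HillTriple:
    """(M, h, K): maximum, Hill coefficient, half-maximal dose (EC50).

    ``M = 0`` is admitted so that reduced models with an eliminated
    component (amplitude pinned to zero) remain representable.
    """

    M: float
    h: float
    K: float

    def __post_init__(self) -> None:
        if not (self.M >= 0 and self.h > 0 and self.K > 0):
            raise ValueError("Hill parameters require M >= 0 and h, K > 0")


@dataclass(frozen=True)
class DoseRTFParams:
    """Dose-dependent RTF parameters: one Hill triple per kinetic parameter.

    ``A, B, alpha, beta, gamma`` follow increasing Hill curves; ``tau``
    follows the reversed Hill ``tau(d) = M_tau * K^h / (K^h + d^h)`` so it
    decreases from ``M_tau`` at dose 0 towards 0 at saturating dose.
    """

    hillA: HillTriple
    hillB: HillTriple
    hillAlpha: HillTriple
    hillBeta: HillTriple
    hillGamma: HillTriple
    hillTau: HillTriple
    b: float
    signSus: int = +1
    signTrans: int = +1
    sigma: float | None = None

    def __post_init__(self) -> None:
        _check_sign(self.signSus, "signSus")
        _check_sign(self.signTrans, "signTrans")
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError("sigma must be > 0 when present")

    @property
    def triples(self) -> tuple[HillTriple, ...]:
        return (
            self.hillA,
            self.hillB,
            self.hillAlpha,
            self.hillBeta,
            self.hillGamma,
            self.hillTau,
        )

    def to_vector(self) -> np.ndarray:
        out = []
        for tr in self.triples:
            out.extend([tr.M, tr.h, tr.K])
        out.append(self.b)
        return np.array(out)

    @classmethod
    def from_vector(
        cls,
        vec: Iterable[float],
        signSus: int = +1,
        signTrans: int = +1,
        sigma: float | None = None,
    ) -> "DoseRTFParams":
        v = [float(x) for x in vec]
        if len(v) != 19:
            raise ValueError(f"expected 19 values (6 triples + b), got {len(v)}")
        triples = [HillTriple(*v[3 * i : 3 * i + 3]) for i in range(6)]
        return cls(*triples, b=v[18], signSus=signSus, signTrans=signTrans, sigma=sigma)


def _validate_times(treal: np.ndarray) -> np.ndarray:
    treal = np.asarray(treal, dtype=float)
    if not np.all(np.isfinite(treal)):
        raise ValueError("times must be finite")
    return treal


def time_transform(treal, tau: float, T: float):
    """Nonlinear, delayed transform of the experimental time axis.

    ``t = log10(10^(treal*10/T) + 10^tau) - log10(1 + 10^tau)``

    Evaluated in log-sum-exp form so large ``treal*10/T`` cannot overflow.
    The transform is strictly increasing in ``treal``, maps 0 to 0 exactly,
    and approaches the linear rescaling ``treal*10/T`` as ``tau -> -inf``.
    """
    if not (np.isfinite(T) and T > 0):
        raise ValueError(f"T must be finite and > 0, got {T!r}")
    if not np.isfinite(tau):
        raise ValueError("tau must be finite")
    treal = _validate_times(np.asarray(treal, dtype=float))
    a = treal * (10.0 / T)
    # log10(10^a + 10^tau) = logaddexp(a ln10, tau ln10) / ln10
    return (np.logaddexp(a * _LN10, tau * _LN10) - np.logaddexp(0.0, tau * _LN10)) / _LN10


def time_transform_dtau(treal, tau: float, T: float):
    """Partial derivative of :func:`time_transform` with respect to ``tau``.

    ``dt/dtau = 10^tau/(10^a + 10^tau) - 10^tau/(1 + 10^tau)`` with
    ``a = treal*10/T``, computed through logistic sigmoids for stability.
    """
    treal = _validate_times(np.asarray(treal, dtype=float))
    a = treal * (10.0 / T)
    return expit((tau - a) * _LN10) - expit(tau * _LN10)


def _components_at_t(params: RTFParams, t: np.ndarray):
    sus = params.signSus * params.A * (1.0 - np.exp(-params.alpha * t))
    trans = (
        params.signTrans
        * params.B
        * (1.0 - np.exp(-params.beta * t))
        * np.exp(-params.gamma * t)
    )
    return sus, trans


def _transform_raw(treal: np.ndarray, tau, T: float):
    """Time transform allowing an array-valued tau (per-point dose expansion)."""
    a = np.asarray(treal, dtype=float) * (10.0 / T)
    tau = np.asarray(tau, dtype=float)
    return (np.logaddexp(a * _LN10, tau * _LN10) - np.logaddexp(0.0, tau * _LN10)) / _LN10


def _transform_dtau_raw(treal: np.ndarray, tau, T: float):
    a = np.asarray(treal, dtype=float) * (10.0 / T)
    tau = np.asarray(tau, dtype=float)
    return expit((tau - a) * _LN10) - expit(tau * _LN10)


def _rtf_eval_raw(A, B, alpha, beta, gamma, tau, b, sS, sT, treal, T):
    """RTF evaluation with scalar or per-point array parameters."""
    t = _transform_raw(treal, tau, T)
    sus = sS * A * (1.0 - np.exp(-alpha * t))
    trans = sT * B * (1.0 - np.exp(-beta * t)) * np.exp(-gamma * t)
    return sus + trans + b


def _rtf_grad_raw(A, B, alpha, beta, gamma, tau, sS, sT, treal, T):
    """Columns (dA, dB, dalpha, dbeta, dgamma, dtau, db) with scalar or
    per-point array parameters."""
    t = _transform_raw(treal, tau, T)
    ea, eb, eg = np.exp(-alpha * t), np.exp(-beta * t), np.exp(-gamma * t)
    dA = sS * (1.0 - ea)
    dB = sT * (1.0 - eb) * eg
    dalpha = sS * A * t * ea
    dbeta = sT * B * t * eb * eg
    dgamma = -sT * B * (1.0 - eb) * t * eg
    dR_dt = sS * A * alpha * ea + sT * B * (beta * eb * eg - gamma * (1.0 - eb) * eg)
    dtau = dR_dt * _transform_dtau_raw(treal, tau, T)
    db = np.ones_like(t)
    return np.column_stack([
        np.broadcast_to(c, t.shape) for c in (dA, dB, dalpha, dbeta, dgamma, dtau, db)
    ])


def rtf_evaluate(params: RTFParams, treal, scale: TimeScale):
    """Evaluate the RTF at experimental times ``treal``."""
    t = time_transform(treal, params.tau, scale.T)
    sus, trans = _components_at_t(params, t)
    return sus + trans + params.b


def rtf_components(params: RTFParams, treal, scale: TimeScale):
    """Return ``(sustained, transient, offset)``; they sum to the full RTF."""
    t = time_transform(treal, params.tau, scale.T)
    sus, trans = _components_at_t(params, t)
    return sus, trans, params.b


def rtf_gradient(params: RTFParams, treal, scale: TimeScale) -> np.ndarray:
    """Analytic Jacobian dR/dtheta, columns ordered (A, B, alpha, beta, gamma, tau, b).

    tau enters through the chain rule via the time transform; the offset
    column is identically 1.
    """
    treal = np.asarray(treal, dtype=float)
    t = time_transform(treal, params.tau, scale.T)
    ea = np.exp(-params.alpha * t)
    eb = np.exp(-params.beta * t)
    eg = np.exp(-params.gamma * t)
    sS, sT = params.signSus, params.signTrans

    dA = sS * (1.0 - ea)
    dB = sT * (1.0 - eb) * eg
    dalpha = sS * params.A * t * ea
    dbeta = sT * params.B * t * eb * eg
    dgamma = -sT * params.B * (1.0 - eb) * t * eg
    # dR/dt, then chain rule through the time transform for tau
    dR_dt = sS * params.A * params.alpha * ea + sT * params.B * (
        params.beta * eb * eg - params.gamma * (1.0 - eb) * eg
    )
    dtau = dR_dt * time_transform_dtau(treal, params.tau, scale.T)
    db = np.ones_like(t)
    return np.column_stack([dA, dB, dalpha, dbeta, dgamma, dtau, db])


def hill(d, triple: HillTriple):
    """Hill dose-response ``H(d) = M d^h / (K^h + d^h)``; 0 at d=0, M/2 at d=K."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("doses must be >= 0")
    # work with u = (d/K)^h to avoid overflow of d^h at large doses
    with np.errstate(divide="ignore"):
        log_u = triple.h * (np.log(np.where(d > 0, d, 1.0)) - np.log(triple.K))
    u = np.where(d > 0, np.exp(log_u), 0.0)
    return triple.M * np.where(np.isinf(u), 1.0, u / (1.0 + u))


def hill_gradient(d, triple: HillTriple) -> np.ndarray:
    """Jacobian of the Hill equation, columns (dH/dM, dH/dh, dH/dK)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("doses must be >= 0")
    pos = d > 0
    with np.errstate(divide="ignore"):
        log_ratio = np.where(pos, np.log(np.where(pos, d, 1.0)) - np.log(triple.K), 0.0)
    u = np.where(pos, np.exp(triple.h * log_ratio), 0.0)
    finite = ~np.isinf(u)
    frac = np.where(finite, u / (1.0 + u), 1.0)          # H / M
    denom2 = np.where(finite, (1.0 + u) ** 2, np.inf)
    dM = frac
    dh = np.where(finite, triple.M * u * log_ratio / denom2, 0.0)
    dK = np.where(finite, -triple.M * triple.h * u / (triple.K * denom2), 0.0)
    return np.column_stack([dM, dh, dK])


def _expanded_values(params: DoseRTFParams, d: float) -> np.ndarray:
    """(A, B, alpha, beta, gamma, tau) at dose d, before rate flooring."""
    vals = np.array([float(hill(d, tr)) for tr in params.triples[:5]])
    # reversed Hill: tau(d) = M_tau - H(d; M_tau, h, K), so tau(0) = M_tau
    tau = params.hillTau.M - float(hill(d, params.hillTau))
    return np.append(vals, tau)


def dose_expand(params: DoseRTFParams, d: float) -> RTFParams:
    """Collapse dose-dependent parameters to a single-dose :class:`RTFParams` at dose ``d``.

    Rates that vanish at d=0 are clamped to :data:`RATE_FLOOR`; the
    response is unaffected there because the amplitudes are 0 too.
    """
    if d < 0:
        raise ValueError("dose must be >= 0")
    A, B, alpha, beta, gamma, tau = _expanded_values(params, d)
    return RTFParams(
        A=A,
        B=B,
        alpha=max(alpha, RATE_FLOOR),
        beta=max(beta, RATE_FLOOR),
        gamma=max(gamma, RATE_FLOOR),
        tau=tau,
        b=params.b,
        signSus=params.signSus,
        signTrans=params.signTrans,
        sigma=params.sigma,
    )


def _expand_vectors(params: DoseRTFParams, doses: np.ndarray):
    """Per-point (A, B, alpha, beta, gamma, tau) arrays over a dose vector."""
    A, B, alpha, beta, gamma = (hill(doses, tr) for tr in params.triples[:5])
    tau = params.hillTau.M - hill(doses, params.hillTau)
    floor = np.maximum
    return A, B, floor(alpha, RATE_FLOOR), floor(beta, RATE_FLOOR), floor(
        gamma, RATE_FLOOR
    ), tau


def dose_rtf_evaluate(params: DoseRTFParams, treal, doses, scale: TimeScale):
    """Evaluate the dose-dependent RTF at paired ``(treal, dose)`` points."""
    treal = np.asarray(treal, dtype=float)
    doses = np.asarray(doses, dtype=float)
    if treal.shape != doses.shape:
        raise ValueError("treal and doses must have the same shape")
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    A, B, alpha, beta, gamma, tau = _expand_vectors(params, doses)
    return _rtf_eval_raw(
        A, B, alpha, beta, gamma, tau, params.b,
        params.signSus, params.signTrans, treal, scale.T,
    )


def dose_gradient(params: DoseRTFParams, treal, doses, scale: TimeScale) -> np.ndarray:
    """Analytic Jacobian of the dose-dependent RTF.

    Columns follow :data:`DOSE_PARAM_NAMES`: (M, h, K) per triple in the
    order A, B, alpha, beta, gamma, tau, then the offset b.  Obtained by
    the chain rule: dR/d(M,h,K) = dR/dtheta * dtheta/d(M,h,K), with the
    tau triple picking up a sign flip from the reversed Hill
    (dtau/dM = 1 - H/M, dtau/dh = -dH/dh, dtau/dK = -dH/dK).
    """
    treal = np.asarray(treal, dtype=float)
    doses = np.asarray(doses, dtype=float)
    if treal.shape != doses.shape:
        raise ValueError("treal and doses must have the same shape")
    A, B, alpha, beta, gamma, tau = _expand_vectors(params, doses)
    grad_single = _rtf_grad_raw(
        A, B, alpha, beta, gamma, tau,
        params.signSus, params.signTrans, treal, scale.T,
    )
    n = treal.size
    out = np.empty((n, 19))
    for j, tr in enumerate(params.triples):
        hg = hill_gradient(doses, tr)  # (n, 3): dH/dM, dH/dh, dH/dK
        if j == 5:  # tau: reversed Hill
            hg = np.column_stack([1.0 - hg[:, 0], -hg[:, 1], -hg[:, 2]])
        out[:, 3 * j : 3 * j + 3] = grad_single[:, [j]] * hg
    out[:, 18] = 1.0
    return out
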