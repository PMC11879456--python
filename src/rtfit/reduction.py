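"""Stepwise model reduction by likelihood-ratio tests.

Backward elimination on a fitted RTF: at each round every candidate
simplification (a nested model with some parameters pinned) is refit and
compared with the current model by a chi-squared likelihood-ratio test.
If any candidate is *not* rejected at level alpha, the one with the
largest p-value is accepted and the loop continues; the result is a model
with a minimal number of free parameters.

Candidates remove whole components together with the rates they make
unidentifiable: dropping the transient amplitude B alone would leave beta
and gamma unconstrained, so they are pinned jointly and the test degrees
of freedom count every pinned parameter.  sigma (or a supplied sigmaExp)
is never a reduction candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .fitting import (
    DOSE_DEPENDENT,
    SINGLE_DOSE,
    FitError,
    FitResult,
    OptimProblem,
    derive_seed,
    fit,
)

__all__ = [
    "Candidate",
    "ReductionStep",
    "ReducedFit",
    "candidate_eliminations",
    "lrt_pvalue",
    "reduce_model",
]

#: Sentinel: pin a parameter at its current best-fit value (it is removed
#: from the optimization but does not define a simpler mechanism itself).
CURRENT = "current"


@dataclass(frozen=True)
class Candidate:
    """One candidate simplification: parameters to pin and the LRT df."""

    name: str
    fixes: tuple[tuple[str, float | str], ...]  # (param, value or CURRENT)
    df: int


@dataclass(frozen=True)
class ReductionStep:
    """Outcome of testing one candidate against the current model."""

    eliminated: str
    fixes: dict[str, float]
    df: int
    neg2ll_before: float
    neg2ll_after: float
    p_value: float
    accepted: bool


@dataclass
class ReducedFit:
    """Final reduced model plus the ordered trail of tested steps."""

    final_fit: FitResult
    trail: list[ReductionStep]
    alpha: float

    @property
    def accepted_steps(self) -> list[ReductionStep]:
        return [s for s in self.trail if s.accepted]


def candidate_eliminations(problem: OptimProblem) -> list[Candidate]:
    """Enumerate nested simplifications still available for this problem.

    Single-dose: remove the transient component (B -> 0 with beta, gamma
    pinned, df 3), the sustained component (A -> 0 with alpha pinned,
    df 2), the retardation (tau -> 0, df 1) or the offset (b -> 0, df 1).
    Dose-dependent: the analogous whole-component removals pin every Hill
    triple the component owns, plus per-triple Hill-coefficient
    simplifications h -> 1 (df 1 each).
    """
    fixed = set(problem.fixed)
    cands: list[Candidate] = []

    def add(name: str, fixes: list[tuple[str, float | str]]):
        params = [p for p, _ in fixes]
        if any(p in fixed for p in params):
            return
        cands.append(Candidate(name=name, fixes=tuple(fixes), df=len(params)))

    if problem.mode == SINGLE_DOSE:
        # rates made unidentifiable by a removed amplitude are pinned at the
        # neutral value 1 so reduced parameter vectors are canonical
        add("transient", [("B", 0.0), ("beta", 1.0), ("gamma", 1.0)])
        add("sustained", [("A", 0.0), ("alpha", 1.0)])
        add("retardation", [("tau", 0.0)])
        add("offset", [("b", 0.0)])
    elif problem.mode == DOSE_DEPENDENT:
        add(
            "transient",
            [("M_B", 0.0)]
            + [(f"{p}_{t}", CURRENT) for t in ("B", "beta", "gamma") for p in ("h", "K")]
            + [(f"M_{t}", CURRENT) for t in ("beta", "gamma")],
        )
        add(
            "sustained",
            [("M_A", 0.0)]
            + [(f"{p}_{t}", CURRENT) for t in ("A", "alpha") for p in ("h", "K")]
            + [("M_alpha", CURRENT)],
        )
        add("retardation", [("M_tau", 0.0), ("h_tau", CURRENT), ("K_tau", CURRENT)])
        add("offset", [("b", 0.0)])
        for t in ("A", "B", "alpha", "beta", "gamma", "tau"):
            add(f"hill_h_{t}", [(f"h_{t}", 1.0)])
    else:  # pragma: no cover - guarded by OptimProblem
        raise ValueError(f"unknown mode {problem.mode!r}")
    return cands


def lrt_pvalue(neg2ll_reduced: float, neg2ll_full: float, df: int) -> float:
    """Upper-tail chi-squared probability of the likelihood-ratio statistic.

    The statistic ``neg2ll_reduced - neg2ll_full`` is clamped at 0 (a
    negative value only arises from optimizer noise in nested fits).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = max(0.0, float(neg2ll_reduced) - float(neg2ll_full))
    return float(chi2.sf(stat, df))


def _resolve_fixes(candidate: Candidate, best: np.ndarray, problem: OptimProblem):
    out = {}
    for name, value in candidate.fixes:
        if value == CURRENT:
            out[name] = float(best[problem.index_of(name)])
        else:
            out[name] = float(value)
    return out


def _warm_start(problem: OptimProblem, best: np.ndarray, fixes: dict[str, float]):
    x = best.copy()
    for name, value in fixes.items():
        x[problem.index_of(name)] = value
    return x


def fit_candidate(
    current: FitResult, candidate: Candidate, n_starts: int, seed: int
) -> tuple[FitResult, dict[str, float]]:
    """Refit one nested candidate, warm-started from the current best fit."""
    problem = current.problem
    fixes = _resolve_fixes(candidate, current.best, problem)
    reduced_problem = problem.with_fixed(fixes)
    warm = _warm_start(problem, current.best, fixes)
    refit = fit(
        reduced_problem,
        n_starts=n_starts,
        seed=derive_seed(seed, "reduce", candidate.name),
        extra_starts=[warm],
    )
    return refit, fixes


def reduce_model(
    fit_result: FitResult,
    alpha: float = 0.05,
    n_starts_per_refit: int = 20,
    seed: int = 1,
) -> ReducedFit:
    """Greedy backward elimination of unnecessary RTF parameters.

    Each round refits every available candidate simplification and tests
    it against the current model; if the least significant candidate has
    p >= alpha it is accepted (ties broken by fewest pinned parameters,
    then candidate order) and the loop repeats.  Candidate fits that fail
    outright are recorded as skipped, never silently accepted.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    current = fit_result
    trail: list[ReductionStep] = []
    round_idx = 0
    while True:
        candidates = candidate_eliminations(current.problem)
        if not candidates:
            break
        tested: list[tuple[ReductionStep, FitResult]] = []
        for cand in candidates:
            try:
                refit, fixes = fit_candidate(
                    current, cand, n_starts_per_refit, derive_seed(seed, round_idx)
                )
            except FitError as err:
                trail.append(
                    ReductionStep(
                        eliminated=cand.name + " (skipped: fit failed)",
                        fixes={},
                        df=cand.df,
                        neg2ll_before=current.value,
                        neg2ll_after=float("nan"),
                        p_value=float("nan"),
                        accepted=False,
                    )
                )
                continue
            p = lrt_pvalue(refit.value, current.value, cand.df)
            step = ReductionStep(
                eliminated=cand.name,
                fixes=fixes,
                df=cand.df,
                neg2ll_before=current.value,
                neg2ll_after=refit.value,
                p_value=p,
                accepted=False,
            )
            tested.append((step, refit))
        # alpha = 1 is the limiting "always eliminate" setting: every
        # candidate is eligible regardless of its p-value
        keepable = [
            (step, refit)
            for step, refit in tested
            if alpha >= 1.0 or step.p_value >= alpha
        ]
        if not keepable:
            trail.extend(step for step, _ in tested)
            break
        # largest p wins; ties -> fewest df, then enumeration order
        order = {id(step): i for i, (step, _) in enumerate(tested)}
        best_step, best_refit = max(
            keepable, key=lambda sr: (sr[0].p_value, -sr[0].df, -order[id(sr[0])])
        )
        for step, _ in tested:
            accepted = step is best_step
            trail.append(
                ReductionStep(
                    eliminated=step.eliminated,
                    fixes=step.fixes,
                    df=step.df,
                    neg2ll_before=step.neg2ll_before,
                    neg2ll_after=step.neg2ll_after,
                    p_value=step.p_value,
                    accepted=accepted,
                )
            )
        current = best_refit
        round_idx += 1
    return ReducedFit(final_fit=current, trail=trail, alpha=alpha)
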