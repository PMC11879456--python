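"""Synthetic RTF time courses with Gaussian noise.

Used both as example data and as ground truth for recovery tests: every
simulation records the generating parameters next to the noisy table, and
is fully reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    DoseRTFParams,
    HillTriple,
    RTFParams,
    TimeScale,
    dose_expand,
    rtf_evaluate,
)
from .fitting import SINGLE_DOSE, DOSE_DEPENDENT, TimeCourseTable, derive_seed

__all__ = [
    "SimSpec",
    "Course",
    "CourseCollection",
    "ConditionEffect",
    "default_single_dose_truth",
    "default_dose_dependent_truth",
    "DEFAULT_DOSES",
    "simulate",
    "simulate_collection",
]

#: Dose grid of the default dose-dependent simulation (geometric, spanning
#: either side of the default EC50 of 5).
DEFAULT_DOSES = (1.25, 2.5, 5.0, 10.0, 20.0)


def default_single_dose_truth() -> RTFParams:
    """Default ground truth: visible sustained and transient structure,
    moderate retardation, non-zero offset."""
    return RTFParams(A=1.0, B=1.0, alpha=1.0, beta=2.0, gamma=0.5, tau=0.5, b=0.2)


def default_dose_dependent_truth() -> DoseRTFParams:
    """Dose-dependent default: Hill maxima matching the single-dose truth,
    Hill coefficient 2, EC50 at the middle of the default dose grid."""
    k = 5.0
    return DoseRTFParams(
        hillA=HillTriple(1.0, 2.0, k),
        hillB=HillTriple(1.0, 2.0, k),
        hillAlpha=HillTriple(1.0, 2.0, k),
        hillBeta=HillTriple(2.0, 2.0, k),
        hillGamma=HillTriple(0.5, 2.0, k),
        hillTau=HillTriple(0.5, 2.0, k),
        b=0.2,
    )


@dataclass(frozen=True)
class SimSpec:
    """Specification of one simulated time course (or dose family)."""

    mode: str = SINGLE_DOSE
    truth: RTFParams | DoseRTFParams | None = None
    times: np.ndarray | tuple[int, float] = (21, 10.0)
    doses: tuple[float, ...] | None = None
    noise_sd: float | str = 0.02
    seed: int = 0

    def resolved_truth(self):
        if self.truth is not None:
            return self.truth
        if self.mode == SINGLE_DOSE:
            return default_single_dose_truth()
        return default_dose_dependent_truth()

    def resolved_times(self) -> np.ndarray:
        if isinstance(self.times, tuple) and len(self.times) == 2:
            n, tmax = self.times
            if int(n) < 3:
                raise ValueError("need at least 3 time points")
            return np.linspace(0.0, float(tmax), int(n))
        times = np.asarray(self.times, dtype=float)
        if times.size < 3:
            raise ValueError("need at least 3 time points")
        return times

    def resolved_doses(self) -> np.ndarray:
        doses = np.asarray(
            self.doses if self.doses is not None else DEFAULT_DOSES, dtype=float
        )
        if doses.size < 2:
            raise ValueError("doseDependent mode needs >= 2 doses")
        return doses


def _noise_level(noise_sd: float | str, model_values: np.ndarray) -> float:
    """Absolute noise sd; ``"relative:f"`` means f times the model's range."""
    if isinstance(noise_sd, str):
        if not noise_sd.startswith("relative:"):
            raise ValueError(f"unrecognised noise spec {noise_sd!r}")
        frac = float(noise_sd.split(":", 1)[1])
        span = float(model_values.max() - model_values.min()) or 1.0
        sd = frac * span
    else:
        sd = float(noise_sd)
    if sd <= 0:
        raise ValueError("noise sd must be > 0")
    return sd


def simulate(spec: SimSpec) -> tuple[TimeCourseTable, dict]:
    """Draw one noisy table from the spec; returns (table, truth record)."""
    times = spec.resolved_times()
    truth = spec.resolved_truth()
    rng = np.random.default_rng(derive_seed(spec.seed, "simulate"))

    if spec.mode == SINGLE_DOSE:
        scale = TimeScale.from_times(times)
        model = rtf_evaluate(truth, times, scale)
        sd = _noise_level(spec.noise_sd, model)
        y = model + rng.normal(0.0, sd, size=model.shape)
        table = TimeCourseTable(t=times, y=y)
    elif spec.mode == DOSE_DEPENDENT:
        doses = spec.resolved_doses()
        scale = TimeScale.from_times(times)
        t_all = np.tile(times, doses.size)
        d_all = np.repeat(doses, times.size)
        model = np.concatenate(
            [rtf_evaluate(dose_expand(truth, float(d)), times, scale) for d in doses]
        )
        sd = _noise_level(spec.noise_sd, model)
        y = model + rng.normal(0.0, sd, size=model.shape)
        table = TimeCourseTable(t=t_all, y=y, d=d_all)
    else:
        raise ValueError(f"unknown mode {spec.mode!r}")

    record = {"mode": spec.mode, "truth": truth, "noise_sd": sd, "seed": spec.seed}
    return table, record


# -- multi-course collections -------------------------------------------------


@dataclass(frozen=True)
class Course:
    id: str
    metadata: dict
    table: TimeCourseTable


@dataclass(frozen=True)
class CourseCollection:
    courses: tuple[Course, ...]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.courses]
        if len(set(ids)) != len(ids):
            raise ValueError("course ids must be unique")

    def __len__(self) -> int:
        return len(self.courses)

    def ids(self) -> list[str]:
        return [c.id for c in self.courses]

    def get(self, course_id: str) -> Course:
        for c in self.courses:
            if c.id == course_id:
                return c
        raise KeyError(course_id)


@dataclass(frozen=True)
class ConditionEffect:
    """Parameter perturbation applied to a subset of classes in the second
    condition: multiplicative factors per parameter name (e.g. {"B": 2.0})."""

    factors: dict[str, float]
    classes: tuple[str, ...] | None = None  # None = all classes

    def applies_to(self, class_name: str) -> bool:
        return self.classes is None or class_name in self.classes

    def apply(self, truth: RTFParams) -> RTFParams:
        return replace(
            truth, **{k: getattr(truth, k) * f for k, f in self.factors.items()}
        )


def simulate_collection(
    class_specs: list[tuple[str, RTFParams, int]],
    condition_effect: ConditionEffect | None = None,
    times: np.ndarray | tuple[int, float] = (101, 10.0),
    noise_sd: float | str = 0.002,
    seed: int = 0,
) -> CourseCollection:
    """Simulate a labelled multi-course collection, optionally paired across
    two conditions.

    Defaults (101 time points, 0.2% noise) emulate densely sampled,
    essentially noise-free ODE-model trajectories, the typical input of
    the embedding workflow.  ``class_specs`` is a list of
    (class name, single-dose truth, count).
    Without ``condition_effect`` one condition ("control") is produced;
    with it, each entity also gets a paired "perturbed" course whose truth
    is transformed for the affected classes (identity otherwise, so those
    pairs differ only by noise).  Metadata records class, condition and
    the pairing entity id.
    """
    courses: list[Course] = []
    conditions = ["control"] if condition_effect is None else ["control", "perturbed"]
    for class_name, truth, count in class_specs:
        if count < 1:
            raise ValueError("class counts must be >= 1")
        for i in range(count):
            entity = f"{class_name}_{i}"
            for cond in conditions:
                t = truth
                if cond == "perturbed" and condition_effect.applies_to(class_name):
                    t = condition_effect.apply(truth)
                spec = SimSpec(
                    mode=SINGLE_DOSE,
                    truth=t,
                    times=times,
                    noise_sd=noise_sd,
                    seed=derive_seed(seed, "collection", entity, cond),
                )
                table, _ = simulate(spec)
                courses.append(
                    Course(
                        id=f"{entity}_{cond}",
                        metadata={
                            "class": class_name,
                            "condition": cond,
                            "entity": entity,
                        },
                        table=table,
                    )
                )
    return CourseCollection(tuple(courses))
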