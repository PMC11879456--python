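"""Reading time-course tables and (de)serializing fits.

Tables are delimited text (comma or tab, auto-detected) with a header row
naming ``t`` and ``y``, plus optional ``d`` and ``sigmaExp`` columns.
Fits are stored as a documented JSON schema that round-trips the full
fit result -- data, bounds, transforms, every start and the best vector --
in full double precision, so a stored fit can be reloaded for prediction,
reduction or plotting without refitting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult, OptimProblem, StartResult, TimeCourseTable
from .reduction import ReducedFit, ReductionStep

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "read_collection",
    "write_fit",
    "read_fit",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1


def _sniff_delimiter(path: Path, override: str | None) -> str:
    if override:
        return override
    header = path.open("r").readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_timecourse(path, delimiter: str | None = None) -> TimeCourseTable:
    """Read a delimited time-course table, validating columns and cells."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path, delimiter))
    for col in ("t", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    use = [c for c in ("t", "y", "d", "sigmaExp") if c in df.columns]
    numeric = df[use].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df[use].notna()
    if bad.to_numpy().any():
        rows = sorted(set(bad.index[bad.any(axis=1)] + 2))  # +2: header + 1-based
        raise ValueError(f"{path}: non-numeric cells in file rows {rows}")
    if numeric.isna().to_numpy().any():
        rows = sorted(set(numeric.index[numeric.isna().any(axis=1)] + 2))
        raise ValueError(f"{path}: missing values in file rows {rows}")
    return TimeCourseTable.from_frame(numeric)


def write_timecourse(table: TimeCourseTable, path, delimiter: str = ",") -> None:
    table.to_frame().to_csv(path, sep=delimiter, index=False)


def read_collection(manifest_path=None, long_path=None, delimiter: str | None = None):
    """Load a course collection from a manifest or a long-format table.

    Manifest mode: a table with columns ``id`` and ``file`` (paths
    relative to the manifest) plus arbitrary metadata columns.  Long mode:
    one table with an ``id`` column and per-row ``t``/``y`` values.
    """
    from .simulate import Course, CourseCollection

    courses = []
    if manifest_path is not None:
        manifest_path = Path(manifest_path)
        manifest = pd.read_csv(manifest_path, sep=_sniff_delimiter(manifest_path, delimiter))
        for col in ("id", "file"):
            if col not in manifest.columns:
                raise ValueError(f"manifest is missing required column '{col}'")
        meta_cols = [c for c in manifest.columns if c not in ("id", "file")]
        for _, row in manifest.iterrows():
            table = read_timecourse(manifest_path.parent / row["file"], delimiter)
            courses.append(
                Course(
                    id=str(row["id"]),
                    metadata={c: row[c] for c in meta_cols},
                    table=table,
                )
            )
    elif long_path is not None:
        long_path = Path(long_path)
        df = pd.read_csv(long_path, sep=_sniff_delimiter(long_path, delimiter))
        for col in ("id", "t", "y"):
            if col not in df.columns:
                raise ValueError(f"long-format table is missing column '{col}'")
        for cid, sub in df.groupby("id", sort=False):
            courses.append(
                Course(
                    id=str(cid),
                    metadata={},
                    table=TimeCourseTable.from_frame(sub[["t", "y"]]),
                )
            )
    else:
        raise ValueError("provide either a manifest or a long-format table")
    return CourseCollection(tuple(courses))


# -- fit serialization --------------------------------------------------------


def _arr(x):
    return None if x is None else np.asarray(x).tolist()


def write_fit(
    result: FitResult,
    path,
    seed: int | None = None,
    n_starts: int | None = None,
    reduction: ReducedFit | None = None,
) -> None:
    """Serialize a fit (optionally with its reduction trail) to JSON."""
    p = result.problem
    doc = {
        "schemaVersion": SCHEMA_VERSION,
        "mode": p.mode,
        "paramNames": list(p.param_names),
        "best": _arr(result.best),
        "value": float(result.value),
        "bounds": {"lb": _arr(p.lb), "ub": _arr(p.ub)},
        "fixed": {k: float(v) for k, v in p.fixed.items()},
        "takeLog10": [bool(v) for v in p.take_log10],
        "signs": {"sus": p.sign_sus, "trans": p.sign_trans},
        "sigmaFree": bool(p.sigma_free),
        "T": float(p.T),
        "seed": seed,
        "nStarts": n_starts,
        "data": {
            "t": _arr(p.data.t),
            "y": _arr(p.data.y),
            "d": _arr(p.data.d),
            "sigmaExp": _arr(p.data.sigma_exp),
        },
        "starts": [
            {
                "x0": _arr(s.x0),
                "x": _arr(s.x),
                "value": float(s.value),
                "converged": bool(s.converged),
                "signSus": s.sign_sus,
                "signTrans": s.sign_trans,
            }
            for s in result.starts
        ],
    }
    if reduction is not None:
        doc["reduction"] = {
            "alpha": reduction.alpha,
            "trail": [
                {
                    "eliminated": st.eliminated,
                    "fixes": st.fixes,
                    "df": st.df,
                    "neg2llBefore": st.neg2ll_before,
                    "neg2llAfter": st.neg2ll_after,
                    "pValue": st.p_value,
                    "accepted": st.accepted,
                }
                for st in reduction.trail
            ],
        }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_fit(path) -> FitResult:
    """Reconstruct a FitResult from a fit file (bit-exact round trip)."""
    doc = json.loads(Path(path).read_text())
    version = doc.get("schemaVersion")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported fit-file schema version {version!r}")
    d = doc["data"]
    data = TimeCourseTable(
        t=np.array(d["t"], float),
        y=np.array(d["y"], float),
        d=None if d["d"] is None else np.array(d["d"], float),
        sigma_exp=None if d["sigmaExp"] is None else np.array(d["sigmaExp"], float),
    )
    problem = OptimProblem(
        data=data,
        mode=doc["mode"],
        param_names=tuple(doc["paramNames"]),
        lb=np.array(doc["bounds"]["lb"], float),
        ub=np.array(doc["bounds"]["ub"], float),
        take_log10=np.array(doc["takeLog10"], bool),
        initial_guess=np.array(doc["best"], float),
        fixed={k: float(v) for k, v in doc["fixed"].items()},
        sign_sus=doc["signs"]["sus"],
        sign_trans=doc["signs"]["trans"],
        sigma_free=bool(doc["sigmaFree"]),
        T=float(doc["T"]),
    )
    starts = [
        StartResult(
            x0=np.array(s["x0"], float),
            x=np.array(s["x"], float),
            value=float(s["value"]),
            converged=bool(s["converged"]),
            sign_sus=s["signSus"],
            sign_trans=s["signTrans"],
        )
        for s in doc["starts"]
    ]
    best = np.array(doc["best"], float)
    from .fitting import _model_values  # residuals recomputed, not stored

    residuals = data.y - _model_values(best, problem)
    return FitResult(
        problem=problem,
        starts=starts,
        best=best,
        value=float(doc["value"]),
        residuals=residuals,
    )


def read_reduction_trail(path) -> list[ReductionStep]:
    """Load the reduction trail stored in a reduced-fit file, if any."""
    doc = json.loads(Path(path).read_text())
    trail = doc.get("reduction", {}).get("trail", [])
    return [
        ReductionStep(
            eliminated=st["eliminated"],
            fixes=st["fixes"],
            df=st["df"],
            neg2ll_before=st["neg2llBefore"],
            neg2ll_after=st["neg2llAfter"],
            p_value=st["pValue"],
            accepted=st["accepted"],
        )
        for st in trail
    ]
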