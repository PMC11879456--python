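"""Low-dimensional representation of many fitted RTFs.

Each time course in a collection is fit independently by the single-dose
RTF; the fitted kinetic parameters form a courses x parameters matrix.
After per-parameter standardization (log10 first for the rate constants)
the matrix is embedded in 2-D with UMAP for display, and k-means on the
standardized matrix groups courses with similar dynamics.  Displacements
of paired points between two conditions rank the molecular entities whose
dynamics changed most.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .fitting import FitResult, TimeCourseTable, build_problem, derive_seed, fit
from .model import RTFParams, TimeScale, rtf_evaluate
from .simulate import CourseCollection

__all__ = [
    "EmbeddingResult",
    "PARAM_COLUMNS",
    "fit_collection",
    "standardize",
    "embed",
    "cluster",
    "summarize_clusters",
    "condition_shift",
    "lowdimensional_rtf",
]

#: Columns of the parameter matrix: the kinetic parameters plus the two
#: resolved signs (so direction flips contribute to shifts).  sigma is a
#: noise property, not a dynamic one, and is excluded.
PARAM_COLUMNS = ("A", "B", "alpha", "beta", "gamma", "tau", "b", "signSus", "signTrans")

#: Parameter-matrix columns standardized on a log10 axis.
_LOG_COLUMNS = ("alpha", "beta", "gamma")


@dataclass
class EmbeddingResult:
    """Parameter matrix, 2-D coordinates, clusters and their summaries."""

    param_matrix: pd.DataFrame          # courses x parameters, natural scale
    scaled_matrix: pd.DataFrame         # standardized matrix used downstream
    coords: np.ndarray                  # courses x 2
    cluster_labels: np.ndarray          # int labels in 1..k
    k: int
    cluster_summaries: pd.DataFrame     # (cluster, parameter) -> q25/median/q75
    metadata: pd.DataFrame | None = None
    fits: dict[str, FitResult] | None = None

    @property
    def ids(self) -> list[str]:
        return list(self.param_matrix.index)


def fit_collection(
    collection: CourseCollection,
    fit_options: dict | None = None,
    seed: int = 0,
    reduce: bool = True,
    reduce_alpha: float = 0.05,
    reduce_starts: int = 1,
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Independent single-dose fits for every course in the collection.

    Every course is fit from the same seeded start set, so identical data
    always yields identical rows.  With ``reduce=True`` (default) each fit
    is then simplified by likelihood-ratio reduction: components that
    merely overfit noise are pinned to canonical null values, which makes
    parameter vectors comparable across courses -- without it, the
    practically unidentifiable parameters of e.g. a sustained-only course
    (its transient amplitude and rates) take arbitrary values and swamp
    the embedding distances.  Signs of zeroed amplitudes are canonicalized
    to +1 for the same reason.

    Returns the parameter matrix (rows in input order, indexed by course
    id) and the per-course fit results.  Courses whose fit fails are
    excluded with a warning; if all fail, an error is raised.
    """
    from .reduction import reduce_model  # deferred: circular import

    options = {"n_starts": 12, "sign_sus": "auto", "sign_trans": "auto"}
    options.update(fit_options or {})
    n_starts = options.pop("n_starts")

    rows, fits = [], {}
    for course in collection.courses:
        try:
            problem = build_problem(course.table, mode="singleDose", **options)
            result = fit(problem, n_starts=n_starts, seed=derive_seed(seed, "collection"))
            if reduce:
                result = reduce_model(
                    result,
                    alpha=reduce_alpha,
                    n_starts_per_refit=reduce_starts,
                    seed=derive_seed(seed, "collection-reduce"),
                ).final_fit
        except Exception as err:  # noqa: BLE001 - report and continue
            warnings.warn(f"fit failed for course {course.id!r}: {err}", stacklevel=2)
            continue
        fits[course.id] = result
        vec = dict(zip(result.problem.param_names, result.best))
        vec["signSus"] = result.problem.sign_sus
        vec["signTrans"] = result.problem.sign_trans
        if vec["A"] == 0.0:
            vec["signSus"] = 1
        if vec["B"] == 0.0:
            vec["signTrans"] = 1
        rows.append(pd.Series({c: vec[c] for c in PARAM_COLUMNS}, name=course.id))
    if not rows:
        raise RuntimeError("every course fit failed; nothing to embed")
    return pd.DataFrame(rows), fits


def standardize(
    param_matrix: pd.DataFrame, uncertainties: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Standardize the parameter matrix for embedding and clustering.

    Rate constants are log10-transformed first; each column is then
    centred and scaled.  Without ``uncertainties``, plain z-scores are
    used (constant columns map to 0).  With per-course parameter standard
    errors supplied, columns are scaled by the between-course standard
    deviation *in excess of* the mean fit uncertainty, and columns whose
    spread is indistinguishable from fit noise are zeroed -- otherwise
    pure estimation noise would be inflated to unit variance and swamp
    the real differences in dynamics.
    """
    out = param_matrix.astype(float).copy()
    if uncertainties is not None:
        unc = uncertainties.astype(float).copy()
    for col in _LOG_COLUMNS:
        if col in out.columns:
            if uncertainties is not None:
                # delta method: se on the log10 axis
                unc[col] = unc[col] / (param_matrix[col].astype(float) * np.log(10.0))
            out[col] = np.log10(out[col])
    mean = out.mean(axis=0)
    var = out.var(axis=0, ddof=0)
    if uncertainties is None:
        sd = np.sqrt(var)
        scale = sd.where(sd > 0, 1.0)
        z = (out - mean) / scale
        z.loc[:, sd == 0] = 0.0
        return z
    # median across courses: robust to the occasional near-singular fit
    # whose standard errors explode along a sloppy direction
    noise_var = (unc**2).median(axis=0).reindex(out.columns).fillna(0.0)
    sd = np.sqrt(var)
    scale = sd.where(sd > 0, 1.0)
    # reliability weight: the fraction of a column's variance that is real
    # between-course variation rather than fit uncertainty
    weight = (1.0 - noise_var / var.where(var > 0, np.inf)).clip(lower=0.0)
    z = weight * (out - mean) / scale
    z.loc[:, sd == 0] = 0.0
    return z


def uncertainty_matrix(
    fits: dict[str, FitResult], index: pd.Index
) -> pd.DataFrame:
    """Per-course parameter standard errors aligned with the parameter
    matrix (sign columns get 0: they are discrete)."""
    from .fitting import parameter_standard_errors

    rows = []
    for cid in index:
        se = parameter_standard_errors(fits[cid])
        se["signSus"] = 0.0
        se["signTrans"] = 0.0
        rows.append(pd.Series({c: se[c] for c in PARAM_COLUMNS}, name=cid))
    return pd.DataFrame(rows)


def embed(
    param_matrix: pd.DataFrame,
    seed: int = 0,
    n_neighbors: int | None = None,
    min_dist: float = 0.1,
    uncertainties: pd.DataFrame | None = None,
) -> np.ndarray:
    """2-D UMAP of the standardized parameter matrix, deterministic per seed."""
    n = len(param_matrix)
    if n < 4:
        raise ValueError(
            "need at least 4 courses to embed; plot the parameter matrix directly"
        )
    import umap  # deferred: numba compilation is slow at import time

    scaled = standardize(param_matrix, uncertainties).to_numpy()
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors or min(15, n - 1),
        min_dist=min_dist,
        random_state=derive_seed(seed, "umap"),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that a seed disables parallelism
        coords = reducer.fit_transform(scaled)
    return np.asarray(coords, dtype=float)


def cluster(
    scaled_matrix: pd.DataFrame, k: int | None = None, seed: int = 0
) -> tuple[np.ndarray, int]:
    """k-means on the standardized parameter matrix; labels are 1-based.

    When k is not given it is chosen in 2..min(10, n-1) by the mean
    silhouette.  Rows are processed in a canonical (lexicographic) order
    with a content-derived seed, so the partition is invariant to row
    permutations of the input.
    """
    X = scaled_matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to cluster")
    if k is not None and k == 1:
        return np.ones(n, dtype=int), 1

    order = np.lexsort(np.round(X, 12).T[::-1])
    Xs = X[order]
    content_seed = (zlib.crc32(np.ascontiguousarray(Xs).tobytes()) ^ seed) % (2**31 - 1)

    def run(k_try: int) -> np.ndarray:
        km = KMeans(n_clusters=k_try, n_init=10, random_state=content_seed)
        return km.fit_predict(Xs)

    if k is None:
        best_k, best_labels, best_score = None, None, -np.inf
        for k_try in range(2, min(10, n - 1) + 1):
            labels_try = run(k_try)
            if np.unique(labels_try).size < 2:
                continue
            score = silhouette_score(Xs, labels_try)
            if score > best_score:
                best_k, best_labels, best_score = k_try, labels_try, score
        if best_labels is None:
            raise ValueError("could not find a valid clustering")
        k, sorted_labels = best_k, best_labels
    else:
        sorted_labels = run(k)

    # map back to input order and renumber 1..k by first appearance
    labels = np.empty(n, dtype=int)
    labels[order] = sorted_labels
    renumber: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in renumber:
            renumber[lab] = len(renumber) + 1
        out[i] = renumber[lab]
    return out, int(k)


def summarize_clusters(
    param_matrix: pd.DataFrame,
    labels: np.ndarray,
    times: np.ndarray | None = None,
    T: float | None = None,
) -> tuple[pd.DataFrame, dict[int, dict[str, np.ndarray]]]:
    """Quantile summaries and fitted-curve bundles per cluster.

    Returns a tidy frame of (cluster, parameter) -> (q25, median, q75)
    using linear-interpolation quantiles, plus per-cluster dynamics: the
    RTF curve of every member evaluated on a common time grid, both
    unscaled and min-max scaled to [0, 1] (constant curves map to 0.5).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != len(param_matrix):
        raise ValueError("labels must match the parameter matrix rows")
    if times is None:
        times = np.linspace(0.0, 10.0, 101)
    scale = TimeScale(T if T is not None else float(times.max() - times.min()))

    records = []
    numeric = param_matrix.astype(float)
    for lab in np.unique(labels):
        sub = numeric.loc[labels == lab]
        for col in numeric.columns:
            q25, med, q75 = np.percentile(sub[col], [25, 50, 75])
            records.append(
                {"cluster": int(lab), "parameter": col, "q25": q25, "median": med, "q75": q75}
            )
    summaries = pd.DataFrame(records)

    bundles: dict[int, dict[str, np.ndarray]] = {}
    for lab in np.unique(labels):
        sub = numeric.loc[labels == lab]
        curves = []
        for _, row in sub.iterrows():
            params = RTFParams(
                A=row["A"], B=row["B"], alpha=row["alpha"], beta=row["beta"],
                gamma=row["gamma"], tau=row["tau"], b=row["b"],
                signSus=int(row.get("signSus", 1)), signTrans=int(row.get("signTrans", 1)),
            )
            curves.append(rtf_evaluate(params, times, scale))
        unscaled = np.vstack(curves)
        span = unscaled.max(axis=1, keepdims=True) - unscaled.min(axis=1, keepdims=True)
        scaled = np.where(
            span > 0,
            (unscaled - unscaled.min(axis=1, keepdims=True)) / np.where(span > 0, span, 1.0),
            0.5,
        )
        bundles[int(lab)] = {
            "times": times,
            "ids": list(sub.index),
            "unscaled": unscaled,
            "scaled": scaled,
        }
    return summaries, bundles


def condition_shift(
    embedding: EmbeddingResult, pairing: dict[str, str]
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Embedding displacement per paired entity across two conditions.

    Returns a table (id_a, id_b, dx, dy, distance) sorted by descending
    distance -- the ranked list of entities whose dynamics changed most --
    plus the list of pairs with ids missing from the embedding.
    """
    index = {cid: i for i, cid in enumerate(embedding.ids)}
    rows, unmatched = [], []
    for id_a, id_b in pairing.items():
        if id_a not in index or id_b not in index:
            unmatched.append((id_a, id_b))
            continue
        delta = embedding.coords[index[id_b]] - embedding.coords[index[id_a]]
        rows.append(
            {
                "id_a": id_a,
                "id_b": id_b,
                "dx": float(delta[0]),
                "dy": float(delta[1]),
                "distance": float(np.hypot(*delta)),
            }
        )
    table = pd.DataFrame(rows, columns=["id_a", "id_b", "dx", "dy", "distance"])
    if len(table):
        table = table.sort_values("distance", ascending=False).reset_index(drop=True)
    return table, unmatched


def lowdimensional_rtf(
    collection: CourseCollection,
    k: int | None = None,
    seed: int = 0,
    fit_options: dict | None = None,
    reduce: bool = True,
) -> EmbeddingResult:
    """Full pipeline: per-course (reduced) fits -> parameter matrix -> UMAP
    -> k-means -> cluster summaries."""
    param_matrix, fits = fit_collection(
        collection, fit_options=fit_options, seed=seed, reduce=reduce
    )
    unc = uncertainty_matrix(fits, param_matrix.index)
    scaled = standardize(param_matrix, unc)
    coords = embed(param_matrix, seed=seed, uncertainties=unc)
    labels, k_used = cluster(scaled, k=k, seed=seed)
    summaries, _ = summarize_clusters(param_matrix, labels)
    meta_rows = [
        {"id": c.id, **c.metadata}
        for c in collection.courses
        if c.id in set(param_matrix.index)
    ]
    metadata = pd.DataFrame(meta_rows).set_index("id") if meta_rows else None
    return EmbeddingResult(
        param_matrix=param_matrix,
        scaled_matrix=scaled,
        coords=coords,
        cluster_labels=labels,
        k=k_used,
        cluster_summaries=summaries,
        metadata=metadata,
        fits=fits,
    )
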