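"""Static diagnostic plots: data, fits with component decomposition,
waterfall of multi-start objectives, parameter histograms, dose-response
curves of the fitted Hill parameters, and embedding/cluster figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .fitting import DOSE_DEPENDENT, SINGLE_DOSE, FitResult, TimeCourseTable
from .lowdim import EmbeddingResult, summarize_clusters
from .model import TimeScale, dose_expand, rtf_components, rtf_evaluate

__all__ = [
    "plot_data",
    "plot_fit",
    "plot_waterfall",
    "plot_param_histograms",
    "plot_dose_params",
    "plot_embedding",
    "plot_cluster_quantiles",
    "plot_cluster_dynamics",
    "make_plots",
]


def plot_data(table: TimeCourseTable):
    """Scatter of the observations; dose-resolved data is colour-coded."""
    fig, ax = plt.subplots()
    if table.d is not None:
        sc = ax.scatter(table.t, table.y, c=table.d, cmap="viridis")
        fig.colorbar(sc, ax=ax, label="dose")
    else:
        ax.scatter(table.t, table.y)
    if table.sigma_exp is not None:
        ax.errorbar(table.t, table.y, yerr=table.sigma_exp, fmt="none", alpha=0.5)
    ax.set_xlabel("time")
    ax.set_ylabel("y")
    return fig


def plot_fit(result: FitResult, n_points: int = 201):
    """Best fit over the data; single-dose fits also show the sustained and
    transient components (offset added for context)."""
    fig, ax = plt.subplots()
    data = result.problem.data
    scale = TimeScale(result.problem.T)
    grid = np.linspace(data.t.min(), data.t.max(), n_points)
    params = result.best_params
    if result.problem.mode == SINGLE_DOSE:
        ax.scatter(data.t, data.y, label="data", zorder=3)
        sus, trans, b = rtf_components(params, grid, scale)
        ax.plot(grid, sus + trans + b, label="RTF fit")
        ax.plot(grid, sus + b, "--", label="sustained + b")
        ax.plot(grid, trans + b, ":", label="transient + b")
    else:
        doses = np.unique(data.d)
        cmap = plt.get_cmap("viridis")
        for i, d in enumerate(doses):
            color = cmap(i / max(1, doses.size - 1))
            mask = data.d == d
            ax.scatter(data.t[mask], data.y[mask], color=color, zorder=3)
            curve = rtf_evaluate(dose_expand(params, float(d)), grid, scale)
            ax.plot(grid, curve, color=color, label=f"d={d:g}")
    ax.set_xlabel("time")
    ax.set_ylabel("y")
    ax.legend()
    return fig


def plot_waterfall(result: FitResult):
    """Sorted final objectives of all starts; a plateau at the minimum
    suggests the global optimum was found."""
    fig, ax = plt.subplots()
    vals = result.sorted_values
    ax.plot(np.arange(1, vals.size + 1), vals, marker="o")
    ax.set_xlabel("start (sorted)")
    ax.set_ylabel("-2 ln L")
    return fig


def plot_param_histograms(result: FitResult, bins: int = 20):
    """Distribution of each free parameter's fitted value across starts."""
    names = result.problem.free_names
    finite = [s for s in result.starts if np.isfinite(s.value)]
    idx = [result.problem.index_of(n) for n in names]
    n = len(names)
    ncols = min(4, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.5 * nrows), squeeze=False)
    for ax, name, i in zip(axes.flat, names, idx):
        ax.hist([s.x[i] for s in finite], bins=bins)
        ax.set_title(name)
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    return fig


def plot_dose_params(result: FitResult, n_points: int = 101):
    """Dose dependence of each Hill-expanded parameter (6 panels)."""
    if result.problem.mode != DOSE_DEPENDENT:
        raise ValueError("dose-parameter plot requires a doseDependent fit")
    params = result.best_params
    doses_obs = np.unique(result.problem.data.d)
    grid = np.linspace(0, doses_obs.max() * 1.1, n_points)
    names = ("A", "B", "alpha", "beta", "gamma", "tau")
    fig, axes = plt.subplots(2, 3, figsize=(10, 6))
    for ax, name in zip(axes.flat, names):
        curve = [getattr(dose_expand(params, float(d)), name) for d in grid]
        at_obs = [getattr(dose_expand(params, float(d)), name) for d in doses_obs]
        ax.plot(grid, curve)
        ax.plot(doses_obs, at_obs, "o")
        ax.set_title(name)
        ax.set_xlabel("dose")
    fig.tight_layout()
    return fig


def plot_embedding(embedding: EmbeddingResult, color_by: str = "cluster"):
    """2-D embedding coloured by cluster label or a metadata column."""
    fig, ax = plt.subplots()
    x, y = embedding.coords[:, 0], embedding.coords[:, 1]
    if color_by == "cluster":
        values = embedding.cluster_labels
        sc = ax.scatter(x, y, c=values, cmap="tab10")
        fig.colorbar(sc, ax=ax, label="cluster")
    else:
        if embedding.metadata is None or color_by not in embedding.metadata.columns:
            raise ValueError(f"no metadata column {color_by!r}")
        cats = embedding.metadata.loc[embedding.ids, color_by].astype(str)
        for cat in sorted(cats.unique()):
            mask = (cats == cat).to_numpy()
            ax.scatter(x[mask], y[mask], label=cat)
        ax.legend(title=color_by)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    return fig


def plot_cluster_quantiles(embedding: EmbeddingResult):
    """Median with 25th-75th quantile band of each parameter per cluster."""
    summaries = embedding.cluster_summaries
    params = summaries["parameter"].unique()
    fig, ax = plt.subplots(figsize=(1.2 * len(params) + 2, 4))
    xs = np.arange(len(params))
    for lab, sub in summaries.groupby("cluster"):
        sub = sub.set_index("parameter").loc[params]
        ax.errorbar(
            xs,
            sub["median"],
            yerr=[sub["median"] - sub["q25"], sub["q75"] - sub["median"]],
            marker="o",
            capsize=3,
            label=f"cluster {lab}",
        )
    ax.set_xticks(xs, params, rotation=45)
    ax.legend()
    fig.tight_layout()
    return fig


def plot_cluster_dynamics(embedding: EmbeddingResult, scaled: bool = False):
    """Member time courses per cluster, unscaled or min-max scaled."""
    _, bundles = summarize_clusters(embedding.param_matrix, embedding.cluster_labels)
    n = len(bundles)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3), squeeze=False)
    key = "scaled" if scaled else "unscaled"
    for ax, (lab, bundle) in zip(axes.flat, sorted(bundles.items())):
        for curve in bundle[key]:
            ax.plot(bundle["times"], curve, alpha=0.6)
        ax.set_title(f"cluster {lab} ({key})")
        ax.set_xlabel("time")
    fig.tight_layout()
    return fig


_FIT_PLOTS = {
    "data": lambda fr: plot_data(fr.problem.data),
    "fit": plot_fit,
    "waterfall": plot_waterfall,
    "histograms": plot_param_histograms,
    "dose-params": plot_dose_params,
}

_EMBED_PLOTS = {
    "embedding": plot_embedding,
    "cluster-quantiles": plot_cluster_quantiles,
    "dynamics": plot_cluster_dynamics,
    "dynamics-scaled": lambda e: plot_cluster_dynamics(e, scaled=True),
}


def make_plots(obj, what: str, outdir, fmt: str = "png") -> Path:
    """Render one named figure for a fit or embedding result to a file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, FitResult) and what in _FIT_PLOTS:
        fig = _FIT_PLOTS[what](obj)
    elif isinstance(obj, EmbeddingResult) and what in _EMBED_PLOTS:
        fig = _EMBED_PLOTS[what](obj)
    else:
        valid = sorted(_FIT_PLOTS) + sorted(_EMBED_PLOTS)
        raise ValueError(f"unknown plot {what!r}; valid names: {valid}")
    path = outdir / f"{what}.{fmt}"
    fig.savefig(path)
    plt.close(fig)
    return path
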