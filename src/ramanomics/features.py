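"""PCA feature extraction from preprocessed spectra.

Spectra are mean-centered (not variance-scaled: after [0,1]
normalization all channels share units) and projected onto the leading
principal components.  Two uses mirror the study design: the first
three components for exploratory per-group distribution summaries, and
the first 100 as classifier inputs.  To avoid information leakage the
model is fitted on training-partition spectra only and then applied to
held-out spectra.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from ramanomics.spectra_io import Spectrum

logger = logging.getLogger(__name__)


class ShapeError(ValueError):
    """Input dimensionality does not match the fitted model."""


@dataclass
class PCAModel:
    """Fitted PCA: mean vector, orthonormal components, explained variances."""

    mean: np.ndarray                # (n_channels,)
    components: np.ndarray          # (n_components, n_channels), orthonormal rows
    explained_variance: np.ndarray  # (n_components,), non-increasing
    n_components: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "n_components": self.n_components,
        }))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["mean"]), np.asarray(d["components"]),
                   np.asarray(d["explained_variance"]), int(d["n_components"]))


def _as_matrix(batch) -> np.ndarray:
    if isinstance(batch, np.ndarray):
        return np.atleast_2d(batch)
    return np.vstack([s.intensities if isinstance(s, Spectrum) else np.asarray(s)
                      for s in batch])


def fit_pca(batch, n_components: int) -> PCAModel:
    """Fit mean-centered PCA on a batch of spectra (or a 2-D matrix).

    ``n_components`` beyond the data rank is clipped with a warning.
    Component signs follow a fixed convention — the largest-magnitude
    loading of each component is positive — so refits are reproducible.
    """
    X = _as_matrix(batch)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 spectra")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    k = n_components
    if k > max_rank:
        warnings.warn(f"n_components={k} exceeds data rank {max_rank}; clipped",
                      stacklevel=2)
        k = max_rank
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    components = pca.components_.copy()
    for i in range(components.shape[0]):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] = -components[i]
    return PCAModel(mean=pca.mean_.copy(), components=components,
                    explained_variance=pca.explained_variance_.copy(),
                    n_components=k)


def transform(model: PCAModel, batch) -> np.ndarray:
    """Project spectra onto the model's components: (x - mean) @ components.T."""
    X = _as_matrix(batch)
    if X.shape[1] != model.mean.size:
        raise ShapeError(f"{X.shape[1]} channels vs model's {model.mean.size}")
    return (X - model.mean) @ model.components.T


def inverse_transform(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Reconstruct spectra from scores."""
    scores = np.atleast_2d(scores)
    return scores @ model.components + model.mean


def summarize_components(model: PCAModel, batch, labels, k: int = 3,
                         bins: int = 20) -> pd.DataFrame:
    """Per-group histogram and kernel-density summaries of leading PC scores.

    Returns a long DataFrame with one row per (label, component) holding
    histogram counts/edges and a Gaussian KDE (Silverman bandwidth)
    evaluated on a common grid.
    """
    scores = transform(model, batch)
    labels = np.asarray(labels, dtype=object)
    if labels.size != scores.shape[0]:
        raise ValueError("labels length must match batch size")
    k = min(k, model.n_components)
    rows = []
    for pc in range(k):
        col = scores[:, pc]
        grid = np.linspace(col.min(), col.max(), 200)
        for lab in pd.unique(labels):
            vals = col[labels == lab]
            counts, edges = np.histogram(vals, bins=bins, range=(col.min(), col.max()))
            if vals.size > 1 and np.ptp(vals) > 0:
                density = stats.gaussian_kde(vals, bw_method="silverman")(grid)
            else:
                density = np.full(grid.size, np.nan)
            rows.append({"label": lab, "component": pc + 1,
                         "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                         "hist_counts": counts, "hist_edges": edges,
                         "kde_grid": grid, "kde_density": density})
    return pd.DataFrame(rows)


def plot_components(summary: pd.DataFrame, path: str | Path) -> Path:
    """Histogram + KDE panel per component, groups overlaid (QC figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comps = sorted(summary["component"].unique())
    fig, axes = plt.subplots(1, len(comps), figsize=(4 * len(comps), 3.2), squeeze=False)
    for ax, pc in zip(axes[0], comps):
        for _, row in summary[summary["component"] == pc].iterrows():
            width = np.diff(row["hist_edges"])
            total = row["hist_counts"].sum() or 1
            ax.bar(row["hist_edges"][:-1], row["hist_counts"] / (total * width),
                   width=width, align="edge", alpha=0.35, label=str(row["label"]))
            if np.isfinite(row["kde_density"]).all():
                ax.plot(row["kde_grid"], row["kde_density"])
        ax.set_title(f"PC{pc}")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
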