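"""PCA on the correlation matrix and convex-hull overlap diagnostics.

The ordination runs at nest-mean level on RAV-corrected ratio indices (size
trends removed first, see :mod:`ncmorph.allometry`). Working on the
correlation matrix -- equivalently z-scoring every index -- puts indices of
very different magnitude (e.g. groove depths ~0.02 vs head shape ~1.15) on an
equal footing, so eigenvalues sum to the number of variables. Group overlap is
quantified by counting each group's points inside (or on the boundary of) the
other group's convex hull in the plotted component plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point

#: The published reduced index set used for ordination.
PCA_INDICES = ["CL/CW", "HTL/CS", "MGr/CS", "NOL/CS", "PeSH/CS", "PreOc/CL", "PrGr/CS"]


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    loadings: pd.DataFrame   # variables x components
    scores: pd.DataFrame     # samples x components
    variance_fraction: np.ndarray

    def reconstruct(self) -> pd.DataFrame:
        """Back-project all components (returns the z-scored data)."""
        return self.scores @ self.loadings.T


def pca_correlation(nest_means: pd.DataFrame) -> PcaResult:
    """PCA of a samples x variables table on its correlation matrix.

    Variables are z-scored internally (ddof=1). Components are ordered by
    decreasing eigenvalue; each component's sign is fixed so its
    largest-magnitude loading is positive.
    """
    X = nest_means.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in PCA input")
    sd = X.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            f"constant variable(s): {list(nest_means.columns[constant])}"
        )
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    eigenvalues, vectors = np.linalg.eigh(corr)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    vectors = vectors[:, order]
    for j in range(vectors.shape[1]):
        if vectors[np.argmax(np.abs(vectors[:, j])), j] < 0:
            vectors[:, j] = -vectors[:, j]
    comps = [f"PC{i + 1}" for i in range(len(eigenvalues))]
    loadings = pd.DataFrame(vectors, index=nest_means.columns, columns=comps)
    scores = pd.DataFrame(Z @ vectors, index=nest_means.index, columns=comps)
    return PcaResult(eigenvalues=eigenvalues, loadings=loadings, scores=scores,
                     variance_fraction=eigenvalues / eigenvalues.sum())


def hull_overlap(scores: pd.DataFrame, labels: pd.Series,
                 components=("PC1", "PC2")) -> dict:
    """Count each group's points covered by the other group's convex hull.

    ``scores`` holds at least the two plotted components; ``labels`` names
    exactly two groups with >= 3 points each. Points on the hull boundary
    count as inside (a sample "at the margin of the polygon" overlaps).
    Degenerate (collinear) groups yield a zero-area hull; counts remain
    defined.
    """
    labels = pd.Series(labels, index=scores.index)
    groups = sorted(pd.unique(labels.dropna()), key=str)
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups, got {groups}")
    pts = {g: scores.loc[(labels == g).values, list(components)].to_numpy(float)
           for g in groups}
    for g, p in pts.items():
        if len(p) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 points")
    hulls = {g: MultiPoint([tuple(row) for row in p]).convex_hull
             for g, p in pts.items()}
    out = {}
    for g_in, g_hull in ((groups[0], groups[1]), (groups[1], groups[0])):
        hull = hulls[g_hull]
        out[g_in] = int(sum(hull.covers(Point(*row)) for row in pts[g_in]))
    return out


def plot_scores(result: PcaResult, labels: pd.Series, path,
                morphs: pd.Series | None = None,
                components=("PC1", "PC2")) -> None:
    """Scatter of two components: groups by marker, optional morphs by color."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = pd.Series(labels, index=result.scores.index)
    markers = ["^", "o", "s", "D"]
    morph_colors = {"truncata_like": "tab:blue", "red_headed": "tab:red",
                    "blackish": "black", "none": "tab:gray"}
    fig, ax = plt.subplots(figsize=(6, 5))
    for marker, group in zip(markers, sorted(pd.unique(labels.dropna()), key=str)):
        mask = (labels == group).values
        sub = result.scores.loc[mask, list(components)]
        if morphs is not None:
            colors = [morph_colors.get(m, "tab:gray")
                      for m in pd.Series(morphs, index=result.scores.index)[mask]]
        else:
            colors = None
        ax.scatter(sub[components[0]], sub[components[1]], marker=marker,
                   c=colors, label=str(group), edgecolors="k", linewidths=0.3)
    pc = {c: i for i, c in enumerate(result.scores.columns)}
    ax.set_xlabel(f"{components[0]} "
                  f"({100 * result.variance_fraction[pc[components[0]]]:.1f}%)")
    ax.set_ylabel(f"{components[1]} "
                  f"({100 * result.variance_fraction[pc[components[1]]]:.1f}%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
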