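"""Effect-profile comparison: correlations, distances, clustering, scaling.

Rows of an effect matrix are compounds/conditions, columns are curve (or
thrombus) parameters; values are log2 effects or raw means.  The tools
here mirror the downstream comparisons of a screening campaign: Pearson
parameter-parameter correlation matrices, Euclidean distance matrices
between compound profiles, k-means clustering with silhouette-chosen k,
PCA, and univariate 0-10 min-max scaling with subtraction panels for
treated-vs-control heatmaps.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .errors import AnalysisError


def parameter_correlation(matrix: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Pairwise column correlation, pairwise-complete over missing values."""
    if method not in ("pearson", "spearman"):
        raise AnalysisError(f"unsupported correlation method {method!r}")
    zero_var = [c for c in matrix.columns if matrix[c].dropna().nunique() <= 1]
    if zero_var:
        warnings.warn(f"zero-variance columns {zero_var}: correlations missing", stacklevel=2)
    corr = matrix.corr(method=method, min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    for c in zero_var:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = 1.0
    return corr


def _standardized(matrix: pd.DataFrame) -> pd.DataFrame:
    std = matrix.std(ddof=1)
    std = std.replace(0.0, np.nan)
    return (matrix - matrix.mean()) / std


def euclidean_distances(matrix: pd.DataFrame, standardize: bool = True) -> pd.DataFrame:
    """Row-by-row Euclidean distance matrix (optionally column-standardized)."""
    data = _standardized(matrix) if standardize else matrix
    incomplete = data.index[data.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(f"dropping incomplete rows {list(incomplete)}", stacklevel=2)
        data = data.drop(index=incomplete)
    x = data.to_numpy(dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=data.index, columns=data.index)


def kmeans_profiles(
    matrix: pd.DataFrame,
    k_range: range | list[int] = range(2, 6),
    seed: int = 0,
    standardize: bool = True,
) -> tuple[pd.Series, int, pd.DataFrame]:
    """Seeded k-means over a k range; k chosen by mean silhouette.

    Returns (assignments, chosen_k, diagnostics) where diagnostics has one
    row per k with its silhouette and within-cluster sum of squares.
    """
    data = _standardized(matrix) if standardize else matrix
    data = data.dropna(axis=0)
    n = len(data)
    if n < 3:
        raise AnalysisError("need >= 3 complete rows for clustering")
    if data.to_numpy().std() == 0:
        raise AnalysisError("zero variance across rows; clustering undefined")
    x = data.to_numpy(dtype=float)
    records = []
    best = None
    for k in k_range:
        if not (2 <= k < n):
            continue
        km = KMeans(n_clusters=k, n_init=50, random_state=seed)
        labels = km.fit_predict(x)
        if len(set(labels)) < 2:
            continue
        sil = float(silhouette_score(x, labels))
        records.append({"k": k, "silhouette": sil, "inertia": float(km.inertia_)})
        if best is None or sil > best[0]:
            best = (sil, k, labels)
    if best is None:
        raise AnalysisError("no valid k in k_range")
    _, chosen_k, labels = best
    return (
        pd.Series(labels, index=data.index, name="cluster"),
        chosen_k,
        pd.DataFrame(records),
    )


def pca_scores(
    matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA on column-standardized rows.

    Components are ordered by decreasing explained variance; the sign
    convention makes the largest-magnitude loading of each component
    positive.  Requesting more components than the rank truncates with a
    warning.
    """
    data = _standardized(matrix).dropna(axis=1, how="all").dropna(axis=0)
    x = data.to_numpy(dtype=float)
    rank = int(np.linalg.matrix_rank(x - x.mean(axis=0)))
    max_comp = min(rank, min(x.shape))
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} exceeds rank {max_comp}; truncated",
            stacklevel=2,
        )
        n_components = max_comp
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x)
    loadings = pca.components_
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=data.index, columns=comp_names),
        pd.DataFrame(loadings, index=comp_names, columns=data.columns),
        pca.explained_variance_ratio_,
    )


def univariate_scale(panel: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each column to [0, 10] across the scaling domain.

    Constant columns scale to all 0 with a warning.
    """
    out = panel.copy().astype(float)
    for col in out.columns:
        lo, hi = out[col].min(), out[col].max()
        if hi == lo:
            warnings.warn(f"constant column {col!r}: scaled to all 0", stacklevel=2)
            out[col] = 0.0
        else:
            out[col] = (out[col] - lo) / (hi - lo) * 10.0
    return out


def subtraction_matrix(treated: pd.DataFrame, control: pd.DataFrame) -> pd.DataFrame:
    """Elementwise treated - control after aligning rows/columns by label."""
    if set(treated.index) != set(control.index) or set(treated.columns) != set(
        control.columns
    ):
        raise AnalysisError("treated and control panels must share labels")
    control = control.reindex(index=treated.index, columns=treated.columns)
    return treated - control


def write_heatmap_inputs(matrix: pd.DataFrame, path: str) -> None:
    """Persist a matrix for external heatmap rendering; the matrix is the
    contract, figures are a courtesy."""
    matrix.to_csv(path, float_format="%.10g")
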