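"""Compare compound effect profiles: correlation, distances, clustering,
PCA, and 0-10 univariate scaling with a subtraction panel.

Effect matrices are compounds x parameters (log2 of percent-of-control /
100).  Compounds acting through the same pathway sit close in Euclidean
distance and cluster together.
"""

import numpy as np
import pandas as pd

from calscreen import (
    euclidean_distances,
    kmeans_profiles,
    parameter_correlation,
    pca_scores,
    subtraction_matrix,
    univariate_scale,
)

rng = np.random.default_rng(1)
params = ["P2", "P3", "P4", "P5", "P6", "P7"]
# two mechanism groups: strong broad inhibitors vs late-phase-only modulators
broad = rng.normal(-1.5, 0.15, size=(5, len(params)))
late = np.column_stack([rng.normal(0, 0.1, (4, 4)), rng.normal(-1.0, 0.1, (4, 2))])
matrix = pd.DataFrame(
    np.vstack([broad, late]),
    index=[f"broad{i}" for i in range(5)] + [f"late{i}" for i in range(4)],
    columns=params,
)

corr = parameter_correlation(matrix)
print("parameter correlation (P2 vs P4):", round(corr.loc["P2", "P4"], 2))

dist = euclidean_distances(matrix, standardize=True)
print("mean within-group distance :", round(dist.iloc[:5, :5].to_numpy().mean(), 2))
print("mean between-group distance:", round(dist.iloc[:5, 5:].to_numpy().mean(), 2))

labels, k, _ = kmeans_profiles(matrix, range(2, 5), seed=0)
print(f"k-means chose k = {k}; assignments:\n{labels.to_string()}")

scores, loadings, evr = pca_scores(matrix, n_components=2)
print(f"PCA explained variance fractions: {np.round(evr, 2).tolist()}")

panel = pd.DataFrame(
    {"size": [6.0, 4.5, 2.0], "contraction": [3.0, 2.5, 1.0]},
    index=["M1", "M2", "M3"],
)
treated = panel * 0.4
# the 0-10 scaling domain spans all conditions AND treatments, so scale
# the combined panel before splitting and subtracting
combined = univariate_scale(pd.concat([panel, treated], keys=["control", "treated"]))
print("\nsubtraction panel (treated - control, 0-10 scale):")
print(
    subtraction_matrix(combined.loc["treated"], combined.loc["control"])
    .round(1)
    .to_string()
)
print("Negative entries mark parameters reduced by treatment.")
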