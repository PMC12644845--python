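#!/usr/bin/env python
"""Characterize the diversity of regional growth trajectories.

K-means-clusters the fitted nodal ECS curves (with K-selection
diagnostics), computes the trajectory correlation matrix with
network-block averages, and extracts the first-principal-component
developmental gradient with network-averaged loadings.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from lifespan_ec.io import read_parcellation
from lifespan_ec.patterns import (
    TrajectoryMatrix,
    cluster_trajectories,
    pca_gradient,
    select_k,
    trajectory_correlation,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--out-dir", type=Path, default=Path("results/cohort"))
parser.add_argument("--k", type=int, default=5)
parser.add_argument("--seed", type=int, default=0)
args = parser.parse_args()

out = args.out_dir
parcellation = read_parcellation(out / "parcellation.tsv")
df = pd.read_csv(out / "trajectories.tsv", sep="\t", index_col=0)
tm = TrajectoryMatrix(df.to_numpy(dtype=float), tuple(df.index),
                      np.array([float(c) for c in df.columns]))

diag = select_k(tm, range(2, min(11, len(df) - 1)), seed=args.seed)
diag.to_csv(out / "select_k.tsv", sep="\t", index=False, float_format="%.6g")
best = diag.loc[diag["silhouette"].idxmax()]
print(f"K diagnostics written; silhouette favors K={int(best['k'])} "
      f"({best['silhouette']:.3f}); analysis K pinned at {args.k}")

res = cluster_trajectories(tm, k=args.k, seed=args.seed, parcellation=parcellation)
pd.DataFrame({"region": list(tm.region_ids), "cluster": res.labels}).to_csv(
    out / "clusters.tsv", sep="\t", index=False)
res.composition.to_csv(out / "cluster_composition.tsv", sep="\t", float_format="%.6g")
shares = pd.Series(res.labels).value_counts(normalize=True).sort_index() * 100
print("  cluster shares (%):",
      {int(c): round(float(s), 1) for c, s in shares.items()})

corr, blocks = trajectory_correlation(tm, parcellation)
corr.to_csv(out / "trajectory_correlation.tsv", sep="\t", float_format="%.6g")
blocks.to_csv(out / "correlation_blocks.tsv", sep="\t", float_format="%.6g")

grad = pca_gradient(tm, parcellation)
pd.DataFrame({"region": list(tm.region_ids), "loading": grad.loadings}).to_csv(
    out / "gradient.tsv", sep="\t", index=False, float_format="%.12g")
print(f"  PC1 explains {100 * grad.explained_variance_ratio:.1f}% of trajectory variance")
print("  network mean loadings:",
      {n: round(float(v), 3) for n, v in grad.network_summary["mean"].items()})
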