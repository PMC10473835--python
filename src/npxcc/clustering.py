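"""Two-layer unsupervised clustering and annotation enrichment.

Layer one groups samples by their food-derived metabolite profiles
(Ward-linkage hierarchical clustering on Euclidean distances, k = 2 by
default); layer two groups the same samples by their inflammatory-protein
profiles (k-means with 100 random restarts, keeping the lowest-inertia
run).  Annotations — including layer-one membership — are then tested for
enrichment across the layer-two clusters: chi-square (Fisher's exact test
when any expected cell is below 5) for categorical annotations and
Mann-Whitney U for continuous ones, with BH FDR across annotations.

Cluster labels are canonical so repeated runs compare equal: cluster 1 is
the cluster with the lower mean of the clustered data ("lower-expressed"),
ties broken by size (larger first) then by smallest member id.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .containers import ClusterAssignment
from .diffexp import bh_fdr
from .exceptions import IntegrityError


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1).replace(0.0, 1.0)
    return (df - df.mean()) / sd


def _canonical_labels(raw: np.ndarray, data: np.ndarray, index: pd.Index) -> pd.Series:
    """Relabel clusters 1..k by ascending cluster mean (ties: size desc, then
    smallest member id)."""
    uniq = np.unique(raw)
    stats_ = []
    for lab in uniq:
        mask = raw == lab
        stats_.append(
            (float(data[mask].mean()), -int(mask.sum()), str(min(index[mask])), lab)
        )
    order = [s[3] for s in sorted(stats_)]
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return pd.Series([remap[v] for v in raw], index=index, name="cluster")


def cluster_metabolome(
    metab: pd.DataFrame, k: int = 2, standardize: bool = True
) -> ClusterAssignment:
    """Ward hierarchical clustering of samples on (standardized) metabolite
    intensities; deterministic."""
    if k < 1:
        raise IntegrityError("k must be >= 1")
    if k > metab.shape[0] // 2 and k > 1:
        raise IntegrityError(f"k={k} too large for {metab.shape[0]} samples")
    data = _zscore(metab) if standardize else metab
    x = data.to_numpy(dtype=float)
    if k == 1:
        labels = pd.Series(1, index=metab.index, name="cluster")
    else:
        z = linkage(x, method="ward", metric="euclidean")
        raw = fcluster(z, t=k, criterion="maxclust")
        labels = _canonical_labels(raw, x, metab.index)
    return ClusterAssignment(labels=labels, k=k, method="hierarchical_ward")


def cluster_proteome(
    npx: pd.DataFrame,
    k: int = 2,
    restarts: int = 100,
    seed: int | None = 0,
    standardize: bool = True,
) -> ClusterAssignment:
    """k-means (Euclidean) with ``restarts`` random initializations, keeping
    the run with minimal within-cluster sum of squares; seed-reproducible.

    Cluster 1 is the "lower-expressed" cluster (lower mean of the clustered
    data), cluster k the "higher-expressed" one.
    """
    if k < 1:
        raise IntegrityError("k must be >= 1")
    if k > npx.shape[0] // 2 and k > 1:
        raise IntegrityError(f"k={k} too large for {npx.shape[0]} samples")
    data = _zscore(npx) if standardize else npx
    x = data.to_numpy(dtype=float)
    if k == 1:
        labels = pd.Series(1, index=npx.index, name="cluster")
        inertia = float(((x - x.mean(axis=0)) ** 2).sum())
    else:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
        raw = km.fit_predict(x)
        labels = _canonical_labels(raw, x, npx.index)
        inertia = float(km.inertia_)
    return ClusterAssignment(
        labels=labels, k=k, method="kmeans", inertia=inertia, seed=seed
    )


def _is_categorical(col: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(col) or pd.api.types.is_bool_dtype(col)


def cluster_enrichment(
    assign: ClusterAssignment, annotations: pd.DataFrame, min_join: float = 0.9
) -> pd.DataFrame:
    """Test every annotation column for association with cluster membership.

    Categorical columns: Pearson chi-square without continuity correction
    (Fisher's exact test on 2x2 tables when any expected count < 5); the
    effect is the odds ratio (ad/bc) for 2x2 tables.  Continuous columns:
    Mann-Whitney U between cluster 1 and 2 (Kruskal-Wallis for k > 2); the
    effect is the rank-biserial correlation.  BH FDR across annotations.
    """
    joined = annotations.reindex(assign.labels.index)
    join_rate = joined.notna().any(axis=1).mean() if annotations.shape[1] else 0.0
    if join_rate < min_join:
        raise IntegrityError(
            f"annotations join to only {join_rate:.0%} of clustered samples (need >= {min_join:.0%})"
        )
    rows = []
    for col in joined.columns:
        vals = joined[col]
        ok = vals.notna()
        labs = assign.labels[ok]
        vals = vals[ok]
        if vals.nunique() < 2:
            rows.append({"annotation": col, "test": "skipped", "reason": "single level",
                         "statistic": np.nan, "p": np.nan, "effect": np.nan, "n": int(ok.sum())})
            continue
        if _is_categorical(vals):
            table = pd.crosstab(labs, vals)
            expected = stats.contingency.expected_freq(table.to_numpy())
            if table.shape == (2, 2) and (expected < 5).any():
                orat, p = stats.fisher_exact(table.to_numpy())
                stat, test = np.nan, "fisher"
                effect = float(orat)
            else:
                stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
                test = "chi_square"
                if table.shape == (2, 2):
                    a_, b_ = table.iloc[0]
                    c_, d_ = table.iloc[1]
                    effect = (a_ * d_) / (b_ * c_) if b_ * c_ > 0 else np.inf
                else:
                    effect = np.nan
            rows.append({
                "annotation": col, "test": test, "statistic": float(stat) if np.isfinite(stat) else np.nan,
                "p": float(p), "effect": effect, "n": int(ok.sum()),
                "contingency": table.to_numpy().tolist(), "reason": "",
            })
        else:
            groups = [vals[labs == g].to_numpy(dtype=float) for g in sorted(labs.unique())]
            if len(groups) == 2:
                u, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
                n1, n2 = len(groups[0]), len(groups[1])
                effect = 1.0 - 2.0 * u / (n1 * n2)  # rank-biserial
                test, stat = "mann_whitney", float(u)
            else:
                stat, p = stats.kruskal(*groups)
                test, effect = "kruskal_wallis", np.nan
            rows.append({
                "annotation": col, "test": test, "statistic": float(stat),
                "p": float(p), "effect": float(effect) if np.isfinite(effect) else effect,
                "n": int(ok.sum()), "reason": "",
            })
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out
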