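"""Spatial and age-associated statistics on sterol concentration matrices.

The concentration matrix has one row per sterol and MultiIndex columns
(region, age, replicate), values in ng/mg tissue.  Downstream analyses:

* one-way ANOVA across brain regions (per age) to flag spatially altered
  sterols (raw p < 0.05 as the screening criterion; BH-adjusted variant
  behind a flag);
* Z-score standardization and WPGMC (median-linkage) hierarchical
  clustering of altered sterols on per-region mean profiles with a
  correlation distance;
* per-region two-sided two-sample t-tests between ages with
  Benjamini–Hochberg adjustment and log2 fold changes;
* the Pearson coregulation network over per-region fold-change profiles
  (|r| ≥ 0.85).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "make_concentration_matrix", "zscore_rows", "anova_screen",
    "cluster_regions", "age_contrast", "coregulation_network",
]

DEFAULT_REGIONS = (
    "olfactory_bulb", "anterior_cortex", "posterior_cortex", "hippocampus",
    "cerebral_nuclei", "interbrain", "midbrain", "pons", "medulla", "cerebellum",
)
AGES = ("6wk", "68wk")


def make_concentration_matrix(values: np.ndarray, sterols: Sequence[str],
                              regions: Sequence[str] = DEFAULT_REGIONS,
                              ages: Sequence[str] = AGES,
                              n_replicates: int = 6) -> pd.DataFrame:
    """Wrap a (sterol × sample) array with (region, age, replicate) columns;
    sample order is region-major, then age, then replicate."""
    cols = pd.MultiIndex.from_product(
        [list(regions), list(ages), range(1, n_replicates + 1)],
        names=["region", "age", "replicate"])
    values = np.asarray(values, dtype=float)
    if values.shape != (len(sterols), len(cols)):
        raise ValueError(f"values shape {values.shape} != ({len(sterols)}, {len(cols)})")
    return pd.DataFrame(values, index=pd.Index(sterols, name="sterol"), columns=cols)


def zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-scores; constant rows are dropped with a warning."""
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant rows (Z-score undefined)")
    out = df.loc[~constant]
    return out.sub(mu[~constant], axis=0).div(sd[~constant], axis=0)


def anova_screen(matrix: pd.DataFrame, age: str | None = "6wk",
                 alpha: float = 0.05, adjust: str = "none") -> pd.DataFrame:
    """One-way ANOVA of each sterol across regions within one age.

    ``age=None`` pools both ages.  Returns per-sterol F, p (optionally
    BH-adjusted when ``adjust="fdr_bh"``) and the ``altered`` flag
    (p < alpha).  Sterols with zero variance in every group are flagged
    ``degenerate`` with undefined p.
    """
    sub = matrix if age is None else matrix.xs(age, axis=1, level="age")
    regions = sub.columns.get_level_values("region").unique()
    if len(regions) < 2:
        raise ValueError("ANOVA needs at least 2 region groups")
    for r in regions:
        if sub.xs(r, axis=1, level="region").shape[1] < 2:
            raise ValueError(f"region {r!r} has fewer than 2 replicates")
    rows = []
    for sterol, row in sub.iterrows():
        groups = [row.xs(r, level="region").dropna().values for r in regions]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) < 2 or all(np.ptp(g) == 0 for g in groups):
            rows.append({"sterol": sterol, "F": np.nan, "p": np.nan, "degenerate": True})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(*groups)
        rows.append({"sterol": sterol, "F": float(f), "p": float(p), "degenerate": False})
    out = pd.DataFrame(rows).set_index("sterol")
    pcol = out["p"].copy()
    if adjust == "fdr_bh":
        ok = pcol.notna()
        adj = pcol.copy()
        adj[ok] = multipletests(pcol[ok], method="fdr_bh")[1]
        out["p_adj"] = adj
        pcol = adj
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["altered"] = pcol < alpha
    return out


def cluster_regions(matrix: pd.DataFrame, n_clusters: int = 5,
                    age: str | None = "6wk") -> tuple[pd.Series, np.ndarray]:
    """WPGMC hierarchical clustering of sterols on per-region mean Z-score
    profiles.

    Distance is 1 − Pearson correlation between sterol profiles; linkage is
    median (WPGMC).  Centroid-family linkage with a non-Euclidean distance
    is a heuristic, used deliberately to match field practice.  Returns
    (cluster labels, scipy linkage matrix).
    """
    sub = matrix if age is None else matrix.xs(age, axis=1, level="age")
    means = sub.T.groupby(level="region", sort=False).mean().T  # sterol × region
    z = zscore_rows(means)
    if len(z) < 2:
        raise ValueError("need at least 2 non-constant sterols to cluster")
    corr = np.corrcoef(z.values)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="median")
    labels = fcluster(Z, t=min(n_clusters, len(z)), criterion="maxclust")
    return pd.Series(labels, index=z.index, name="cluster"), Z


def age_contrast(matrix: pd.DataFrame, young: str = "6wk", old: str = "68wk",
                 alpha: float = 0.05) -> pd.DataFrame:
    """Per (sterol, region): log2 fold change (old/young), two-sided
    two-sample t-test p, and BH-adjusted p within each region."""
    regions = matrix.columns.get_level_values("region").unique()
    rows = []
    for region in regions:
        sub = matrix.xs(region, axis=1, level="region")
        for sterol, row in sub.iterrows():
            a = row.xs(old, level="age").dropna().values
            b = row.xs(young, level="age").dropna().values
            if a.size < 2 or b.size < 2:
                rows.append({"sterol": sterol, "region": region, "log2_fc": np.nan,
                             "p": np.nan, "skipped": True})
                continue
            with np.errstate(divide="ignore"):
                fc = np.log2(a.mean() / b.mean()) if b.mean() > 0 and a.mean() > 0 else np.nan
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                p = 1.0 if a.mean() == b.mean() else 0.0
            else:
                p = float(stats.ttest_ind(a, b).pvalue)
            rows.append({"sterol": sterol, "region": region, "log2_fc": float(fc),
                         "p": p, "skipped": False})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for region in regions:
        mask = (out.region == region) & out.p.notna()
        if mask.any():
            out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    out["significant"] = out.p_adj < alpha
    return out


def coregulation_network(fold_changes: pd.DataFrame, threshold: float = 0.85,
                         min_regions: int = 3) -> tuple[pd.DataFrame, nx.Graph]:
    """Pearson coregulation network over per-region fold-change profiles.

    ``fold_changes``: sterol × region matrix of log2 fold changes
    (dysregulated sterols only).  Edges connect unordered sterol pairs with
    |r| ≥ threshold computed over their ≥ ``min_regions`` shared regions;
    zero-variance profiles are excluded.  Returns (edge table, graph with
    per-region fold-change node attributes).
    """
    fc = fold_changes.astype(float)
    edges = []
    names = list(fc.index)
    vals = fc.values
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            both = np.isfinite(vals[i]) & np.isfinite(vals[j])
            if both.sum() < min_regions:
                continue
            a, b = vals[i][both], vals[j][both]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if abs(r) >= threshold:
                edges.append({"sterol_a": names[i], "sterol_b": names[j],
                              "r": r, "sign": "positive" if r > 0 else "negative"})
    edge_df = pd.DataFrame(edges, columns=["sterol_a", "sterol_b", "r", "sign"])
    g = nx.Graph()
    for _, e in edge_df.iterrows():
        g.add_edge(e.sterol_a, e.sterol_b, r=float(e.r), sign=e.sign)
    for node in g.nodes:
        for region in fc.columns:
            v = fc.loc[node, region]
            g.nodes[node][f"log2fc_{region}"] = float(v) if np.isfinite(v) else float("nan")
    return edge_df, g
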