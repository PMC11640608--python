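"""Hierarchical clustering of STP profiles and nonparametric group
characterization.

Cell-line profiles are clustered agglomeratively on their pathway-score
vectors (Ward linkage on Euclidean distance by default).  Groups — clusters
or histological subtypes — are characterized per pathway with a
Kruskal–Wallis omnibus test followed by pairwise two-sided Mann–Whitney
tests, and labeled High/Low when a group differs significantly from at least
three other groups in one consistent direction.  Profiles can also be
assigned to externally supplied reference-cluster centroids by least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import kruskal, mannwhitneyu

from .stp_model import STPProfile

__all__ = [
    "ClusterResult",
    "CharacterizationTable",
    "hierarchical_cluster",
    "characterize_clusters",
    "characterize_histology",
    "assign_to_reference_clusters",
    "linkage_to_newick",
]


@dataclass
class ClusterResult:
    """Flat cluster assignment plus the underlying merge tree."""

    labels: pd.Series          # sample id -> cluster id in 1..k
    linkage: np.ndarray        # scipy linkage matrix
    k: int
    method: str
    metric: str

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def to_newick(self) -> str:
        return linkage_to_newick(self.linkage, list(self.labels.index))


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string.

    Branch lengths are differences of merge heights (leaves sit at height 0).
    """
    safe = [str(n).replace(" ", "_").replace(",", "_").replace("(", "_")
            .replace(")", "_").replace(":", "_").replace(";", "_")
            for n in leaf_names]
    root = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{safe[node.id]}:{length:.6g}"
        inner = f"({render(node.left, node.dist)},{render(node.right, node.dist)})"
        return f"{inner}:{length:.6g}"

    if root.is_leaf():
        return f"({safe[root.id]}:0);"
    return (
        f"({render(root.left, root.dist)},{render(root.right, root.dist)});"
    )


def hierarchical_cluster(
    profile: STPProfile,
    k: int = 7,
    method: str = "ward",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomeratively cluster samples on their pathway-score vectors.

    Deterministic given the input order.  ``k`` flat clusters are cut with
    the ``maxclust`` criterion; a constant profile is valid (all merge
    heights zero) but warns because fewer than ``k`` distinct clusters can
    then be formed.
    """
    n = len(profile.sample_ids)
    if not (1 <= k <= n):
        raise ValueError(f"k must satisfy 1 <= k <= n_samples ({n}), got {k}")
    X = profile.scores.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("profile contains missing scores")
    if n == 1:
        Z = np.empty((0, 4))
        labels = pd.Series([1], index=profile.scores.index)
        return ClusterResult(labels, Z, k, method, metric)
    D = pdist(X, metric=metric)
    Z = hierarchy.linkage(D, method=method)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=profile.scores.index, name="cluster")
    if labels.nunique() < k:
        warnings.warn(
            f"requested k={k} but only {labels.nunique()} distinct clusters "
            "formed (degenerate merge heights)",
            stacklevel=2,
        )
    return ClusterResult(labels, Z, k, method, metric)


# ---------------------------------------------------------------------------
# group characterization


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (finite entries only)."""
    adj = np.array(pvals, dtype=float)
    ok = np.isfinite(adj)
    p = adj[ok]
    m = len(p)
    order = np.argsort(p)
    out = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        out[idx] = min(running, 1.0)
    adj[ok] = out
    return adj


@dataclass
class CharacterizationTable:
    """Per-group, per-pathway statistical characterization.

    ``omnibus`` holds the Kruskal–Wallis p-value per pathway; ``pairwise``
    is a long table of two-sided Mann–Whitney comparisons with direction and
    star notation; ``labels`` is groups × pathways with entries in
    {"High", "Low", "CNBD", ""}.
    """

    omnibus: pd.Series
    pairwise: pd.DataFrame
    labels: pd.DataFrame
    alpha: float = 0.05
    min_significant: int = 3
    correction: str | None = None

    def to_csv(self, path) -> None:
        """Long CSV: one row per pairwise comparison, with the group label."""
        out = self.pairwise.copy()
        out["label"] = [
            self.labels.loc[g, p] for g, p in zip(out["group"], out["pathway"])
        ]
        out["omnibus_p"] = [self.omnibus[p] for p in out["pathway"]]
        out.to_csv(path, index=False)


def characterize_groups(
    profile: STPProfile,
    groups: pd.Series,
    alpha: float = 0.05,
    min_significant: int = 3,
    correction: str | None = None,
) -> CharacterizationTable:
    """Kruskal–Wallis omnibus + pairwise Mann–Whitney characterization.

    For each (group, pathway): comparisons against every other group; a
    group is labeled High (Low) on a pathway when it is significantly
    higher (lower) than at least ``min_significant`` other groups with all
    significant differences in one direction; significant differences that
    fall short of that count, or point both ways, give "CNBD" (cannot be
    determined).  Comparisons involving a single-member group are not
    testable and are flagged CNBD; such groups receive no labels.

    ``correction="holm"`` adjusts the pairwise p-values per pathway
    (off by default).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    groups = groups.reindex(profile.sample_ids)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    names = sorted(groups.unique())
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    if len(names) < min_significant + 1:
        warnings.warn(
            f"only {len(names)} groups: High/Low labels need significance vs "
            f">= {min_significant} others and are unreachable",
            stacklevel=2,
        )
    members = {g: profile.scores.index[groups == g] for g in names}

    omnibus = {}
    rows = []
    for pathway in profile.pathways:
        col = profile.scores[pathway]
        arrays = [col.loc[members[g]].to_numpy() for g in names]
        if all(len(a) > 0 for a in arrays) and len(arrays) >= 2:
            pooled = np.concatenate(arrays)
            if np.all(pooled == pooled[0]):
                omnibus[pathway] = 1.0
            else:
                omnibus[pathway] = float(kruskal(*arrays).pvalue)
        else:
            omnibus[pathway] = np.nan
        for i, g in enumerate(names):
            a = col.loc[members[g]].to_numpy()
            for j, h in enumerate(names):
                if i == j:
                    continue
                b = col.loc[members[h]].to_numpy()
                if len(a) < 2 or len(b) < 2:
                    p, note = np.nan, "CNBD"
                elif np.all(np.concatenate([a, b]) == a[0]):
                    p, note = 1.0, ""
                else:
                    p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
                    note = ""
                direction = (
                    "higher" if np.median(a) > np.median(b)
                    else "lower" if np.median(a) < np.median(b)
                    else "equal"
                )
                rows.append(
                    {"group": g, "pathway": pathway, "other": h,
                     "p_value": p, "direction": direction, "note": note}
                )
    pairwise = pd.DataFrame(rows)
    if correction == "holm":
        for pathway in profile.pathways:
            mask = pairwise["pathway"] == pathway
            pairwise.loc[mask, "p_value"] = _holm(
                pairwise.loc[mask, "p_value"].to_numpy()
            )
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    pairwise["stars"] = pairwise["p_value"].map(_stars)

    labels = pd.DataFrame("", index=pd.Index(names, name="group"),
                          columns=profile.pathways)
    for g in names:
        if len(members[g]) < 2:
            continue  # single-sample groups cannot earn labels
        for pathway in profile.pathways:
            sub = pairwise[(pairwise["group"] == g) & (pairwise["pathway"] == pathway)]
            sig = sub[(sub["p_value"] < alpha) & sub["p_value"].notna()]
            if len(sig) == 0:
                continue
            directions = set(sig["direction"])
            if len(sig) >= min_significant and directions == {"higher"}:
                labels.loc[g, pathway] = "High"
            elif len(sig) >= min_significant and directions == {"lower"}:
                labels.loc[g, pathway] = "Low"
            else:
                labels.loc[g, pathway] = "CNBD"
    return CharacterizationTable(
        omnibus=pd.Series(omnibus, name="kruskal_wallis_p"),
        pairwise=pairwise,
        labels=labels,
        alpha=alpha,
        min_significant=min_significant,
        correction=correction,
    )


def characterize_clusters(
    profile: STPProfile,
    clusters: "pd.Series | ClusterResult",
    alpha: float = 0.05,
    correction: str | None = None,
) -> CharacterizationTable:
    """Characterize hierarchical clusters per pathway (see
    :func:`characterize_groups`)."""
    labels = clusters.labels if isinstance(clusters, ClusterResult) else clusters
    return characterize_groups(profile, labels, alpha=alpha, correction=correction)


def characterize_histology(
    profile: STPProfile,
    histology: pd.Series | None = None,
    alpha: float = 0.05,
    correction: str | None = None,
) -> CharacterizationTable:
    """Characterize histological subtypes per pathway.

    ``histology`` defaults to the profile metadata's ``histology_of_origin``
    column.  The High/Low rule requires consistent significance against at
    least three other subtypes.
    """
    if histology is None:
        if profile.metadata is None or "histology_of_origin" not in profile.metadata:
            raise ValueError(
                "no histology labels: pass a Series or attach metadata with "
                "a 'histology_of_origin' column"
            )
        histology = profile.metadata["histology_of_origin"]
    return characterize_groups(profile, histology, alpha=alpha, correction=correction)


# ---------------------------------------------------------------------------
# reference-cluster assignment


def assign_to_reference_clusters(
    profile: STPProfile, centroids: pd.DataFrame
) -> pd.DataFrame:
    """Assign each sample to the nearest reference-cluster centroid by
    least squares.

    ``centroids``: rows = reference clusters, columns = pathways (must cover
    the profile's pathway set).  Returns per sample the chosen cluster, the
    squared distance, and a tie flag; exact ties go to the lowest centroid
    index.
    """
    if len(centroids) == 0:
        raise ValueError("empty centroid list")
    missing = set(profile.pathways) - set(centroids.columns)
    if missing:
        raise ValueError(f"centroids lack pathways: {sorted(missing)}")
    C = centroids[profile.pathways].to_numpy(dtype=float)
    X = profile.scores.to_numpy(dtype=float)
    d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)
    tie = (d2 == d2.min(axis=1, keepdims=True)).sum(axis=1) > 1
    return pd.DataFrame(
        {
            "reference_cluster": centroids.index.to_numpy()[best],
            "sq_distance": d2[np.arange(len(X)), best],
            "tie": tie,
        },
        index=profile.scores.index,
    )
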