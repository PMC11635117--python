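"""Immune-metabolic subtyping: ssGSEA, consensus clustering and the 2-D index.

The subtyping pipeline crosses two unsupervised clusterings of a bulk
expression cohort:

1. samples are consensus-clustered (k=3) on an immunotherapy-associated
   lncRNA panel;
2. per-sample enrichment of 28 immune-cell signatures is scored by ssGSEA
   (single-sample gene set enrichment analysis) and the score matrix is
   consensus-clustered (k=2).

Raw cluster indices are arbitrary, so they are canonicalized — lncRNA
clusters renumbered 1..3 by descending mean panel expression, immune clusters
1..2 by descending mean enrichment — which pins the semantic labels
("cluster 1 = high"). The pair (lncRNA cluster, immune cluster) then maps
totally onto the four immune-metabolic subtypes:

    (1,1) -> iFA   immune-active        (fatty-acid metabolism)
    (2,1), (1,2) -> iAA   immune-exclusion     (amino-acid metabolism)
    (2,2), (3,1) -> iGlu  immune-dysfunctional (glucose metabolism)
    (3,2) -> iFolate  immune-desert     (folate/pterin metabolism)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "SSGSEAResult",
    "ConsensusResult",
    "SubtypeConfig",
    "ssgsea",
    "consensus_cluster",
    "assign_subtype",
    "subtype_cohort",
    "read_gmt",
    "write_gmt",
    "SUBTYPE_MAP",
]

SUBTYPE_MAP = {
    (1, 1): "iFA",
    (2, 1): "iAA",
    (1, 2): "iAA",
    (2, 2): "iGlu",
    (3, 1): "iGlu",
    (3, 2): "iFolate",
}


def read_gmt(path) -> dict:
    """Read a GMT gene-set file: name, description, then gene ids per line."""
    sets = {}
    with open(path) as f:
        for line in f:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as f:
        for name, genes in sets.items():
            f.write("\t".join([name, "na"] + list(genes)) + "\n")


@dataclass
class SSGSEAResult:
    scores: pd.DataFrame  # sets x samples
    alpha: float
    normalized: bool


def _ssgsea_sample(expr: np.ndarray, set_masks: dict, alpha: float) -> dict:
    """Enrichment scores of one sample for every gene set.

    Genes are ordered by decreasing expression; the gene at ordered position i
    (1-based) carries rank weight (N - i + 1)^alpha. The running sum gains the
    normalized rank weight at in-set genes and loses 1/(N - |S|) at out-set
    genes; the score integrates the running-sum deviation over all positions
    (so the walk, whose increments and decrements cancel by the end, is summed
    rather than maximized).
    """
    N = len(expr)
    order = np.argsort(-expr, kind="stable")
    weights = (N - np.arange(N)).astype(np.float64) ** alpha
    out = {}
    for name, mask in set_masks.items():
        in_ordered = mask[order]
        w = weights * in_ordered
        denom_in = w.sum()
        n_out = N - int(mask.sum())
        p_in = np.cumsum(w) / denom_in
        p_out = (np.cumsum(~in_ordered) / n_out) if n_out > 0 else np.zeros(N)
        out[name] = float(np.sum(p_in - p_out))
    return out


def ssgsea(expr: pd.DataFrame, sets: dict, alpha: float = 0.25,
           normalize: bool = True) -> SSGSEAResult:
    """Rank-based per-sample enrichment scores for each gene set.

    ``expr``: genes x samples DataFrame (any normalized expression scale —
    scores depend on each sample's ranks only, so they are invariant to
    per-sample monotone transforms). ``normalize`` rescales the whole score
    matrix by its global range (max - min), the usual cross-sample convention.
    """
    if expr.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    if len(expr) < 2:
        raise ValueError("need at least 2 genes")
    universe = expr.index
    set_masks = {}
    for name, genes in sets.items():
        mask = universe.isin(set(genes)).astype(bool)
        if not mask.any():
            raise ValueError(f"gene set '{name}' has no overlap with the expression matrix")
        set_masks[name] = np.asarray(mask)
    values = expr.to_numpy(dtype=np.float64)
    scores = np.empty((len(sets), expr.shape[1]))
    names = list(sets)
    for j in range(expr.shape[1]):
        s = _ssgsea_sample(values[:, j], set_masks, alpha)
        for i, name in enumerate(names):
            scores[i, j] = s[name]
    if normalize:
        span = scores.max() - scores.min()
        if span > 0:
            scores = scores / span
    return SSGSEAResult(
        scores=pd.DataFrame(scores, index=names, columns=expr.columns),
        alpha=alpha, normalized=normalize,
    )


@dataclass
class ConsensusResult:
    consensus: dict            # k -> n x n consensus matrix in [0,1] (NaN = never co-sampled)
    cdf: dict                  # k -> (grid, empirical CDF of consensus values)
    area: dict                 # k -> area under the consensus CDF
    chosen_k: int
    assignments: dict          # k -> integer labels 1..k per sample

    def labels(self, k: int | None = None) -> np.ndarray:
        return self.assignments[k or self.chosen_k]


def _hclust_labels(X: np.ndarray, k: int, method: str) -> np.ndarray:
    Z = linkage(X, method=method, metric="euclidean")
    return fcluster(Z, t=k, criterion="maxclust")


def consensus_cluster(X, k_range=(2, 3, 4, 5), n_iter: int = 1000,
                      resample_frac: float = 0.8, seed: int = 0,
                      method: str = "average", algorithm: str = "hierarchical",
                      ) -> ConsensusResult:
    """Resampling-based consensus clustering with CDF-based model selection.

    For each k, ``n_iter`` random subsamples of ``resample_frac`` of the
    samples are clustered (hierarchical, average linkage on Euclidean
    distance by default; ``algorithm='kmeans'`` available); the consensus
    matrix entry (i, j) is the fraction of co-clustered runs among runs where
    both were sampled. Final assignments cluster the 1 - consensus distance;
    the number of clusters is chosen by the largest relative increase of the
    area under the consensus CDF.
    """
    X = np.asarray(X, dtype=np.float64)
    n = len(X)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 < resample_frac <= 1:
        raise ValueError("resample_frac must be in (0, 1]")
    k_range = [k for k in k_range]
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ValueError(f"k={k} outside [2, n_samples-1]")
    rng = np.random.default_rng(seed)
    m = max(2, int(round(resample_frac * n)))

    co_count = np.zeros((n, n))
    co_cluster = {k: np.zeros((n, n)) for k in k_range}
    for _ in range(n_iter):
        idx = np.sort(rng.choice(n, size=m, replace=False)) if m < n else np.arange(n)
        co_count[np.ix_(idx, idx)] += 1.0
        sub = X[idx]
        if algorithm == "kmeans":
            from sklearn.cluster import KMeans

            for k in k_range:
                labels = KMeans(n_clusters=k, n_init=3,
                                random_state=int(rng.integers(2**31))).fit_predict(sub)
                eq = labels[:, None] == labels[None, :]
                co_cluster[k][np.ix_(idx, idx)] += eq
        else:
            Z = linkage(sub, method=method, metric="euclidean")
            for k in k_range:
                labels = fcluster(Z, t=k, criterion="maxclust")
                eq = labels[:, None] == labels[None, :]
                co_cluster[k][np.ix_(idx, idx)] += eq

    consensus, cdfs, areas, assignments = {}, {}, {}, {}
    never = co_count == 0
    if never.any():
        warnings.warn("some sample pairs were never co-sampled; their consensus "
                      "entries are missing (NaN)", stacklevel=2)
    grid = np.linspace(0, 1, 101)
    for k in k_range:
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(never, np.nan, co_cluster[k] / np.maximum(co_count, 1))
        np.fill_diagonal(M, np.where(np.diag(co_count) > 0, 1.0, np.nan))
        consensus[k] = M
        tri = M[np.triu_indices(n, k=1)]
        tri = tri[~np.isnan(tri)]
        cdf = np.array([(tri <= g).mean() for g in grid]) if len(tri) else grid * 0
        cdfs[k] = (grid, cdf)
        areas[k] = float(np.trapezoid(cdf, grid))
        D = 1.0 - np.nan_to_num(M, nan=0.5)
        np.fill_diagonal(D, 0.0)
        Zc = linkage(squareform(D, checks=False), method=method)
        assignments[k] = fcluster(Zc, t=k, criterion="maxclust")

    ks = sorted(k_range)
    rel_delta = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        rel_delta[k] = ((areas[k] - areas[prev]) / areas[prev]
                        if areas[prev] > 0 else areas[k])
    chosen_k = max(ks, key=lambda k: rel_delta[k])
    return ConsensusResult(consensus=consensus, cdf=cdfs, area=areas,
                           chosen_k=chosen_k, assignments=assignments)


def assign_subtype(lnc_cluster: int, imm_cluster: int) -> str:
    """Total mapping from (lncRNA cluster 1-3, immune cluster 1-2) to subtype."""
    key = (int(lnc_cluster), int(imm_cluster))
    if key not in SUBTYPE_MAP:
        raise ValueError(
            f"cluster pair {key} out of range: lncRNA cluster must be 1-3, "
            "immune cluster 1-2"
        )
    return SUBTYPE_MAP[key]


@dataclass
class SubtypeConfig:
    k_lnc: int = 3
    k_imm: int = 2
    n_iter: int = 1000
    resample_frac: float = 0.8
    seed: int = 0
    ssgsea_alpha: float = 0.25
    min_panel_coverage: float = 0.8
    linkage: str = "average"


def _canonicalize(labels: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Renumber raw cluster labels 1..k by descending cluster mean of ``means``."""
    uniq = np.unique(labels)
    cluster_means = {c: means[labels == c].mean() for c in uniq}
    order = sorted(uniq, key=lambda c: -cluster_means[c])
    remap = {c: i + 1 for i, c in enumerate(order)}
    return np.asarray([remap[c] for c in labels])


def subtype_cohort(expr: pd.DataFrame, lnc_panel: list, immune_sets: dict,
                   cfg: SubtypeConfig | None = None) -> pd.DataFrame:
    """Full subtyping pipeline for one cohort.

    Returns a DataFrame indexed by sample with columns ``lnc_cluster``
    (1..3, canonical: 1 = highest mean panel expression), ``imm_cluster``
    (1..2, canonical: 1 = highest mean immune enrichment) and ``subtype``.
    """
    cfg = cfg or SubtypeConfig()
    present = [g for g in lnc_panel if g in expr.index]
    coverage = len(present) / max(len(lnc_panel), 1)
    if coverage < cfg.min_panel_coverage:
        missing = sorted(set(lnc_panel) - set(present))
        raise ValueError(
            f"lncRNA panel coverage {coverage:.2f} below "
            f"{cfg.min_panel_coverage}; missing genes: {missing[:10]}..."
        )
    # samples x panel genes, z-scored per gene across samples
    X_lnc = expr.loc[present].to_numpy(dtype=np.float64).T
    X_lnc_z = (X_lnc - X_lnc.mean(0)) / (X_lnc.std(0) + 1e-12)
    lnc_res = consensus_cluster(X_lnc_z, k_range=[cfg.k_lnc], n_iter=cfg.n_iter,
                                resample_frac=cfg.resample_frac, seed=cfg.seed,
                                method=cfg.linkage)
    lnc_raw = lnc_res.assignments[cfg.k_lnc]
    lnc_cluster = _canonicalize(lnc_raw, X_lnc.mean(axis=1))

    scores = ssgsea(expr, immune_sets, alpha=cfg.ssgsea_alpha).scores
    X_imm = scores.to_numpy(dtype=np.float64).T  # samples x 28
    X_imm_z = (X_imm - X_imm.mean(0)) / (X_imm.std(0) + 1e-12)
    imm_res = consensus_cluster(X_imm_z, k_range=[cfg.k_imm], n_iter=cfg.n_iter,
                                resample_frac=cfg.resample_frac, seed=cfg.seed + 1,
                                method=cfg.linkage)
    imm_raw = imm_res.assignments[cfg.k_imm]
    imm_cluster = _canonicalize(imm_raw, X_imm.mean(axis=1))

    subtype = [assign_subtype(l, i) for l, i in zip(lnc_cluster, imm_cluster)]
    return pd.DataFrame(
        {"lnc_cluster": lnc_cluster, "imm_cluster": imm_cluster, "subtype": subtype},
        index=expr.columns,
    )
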