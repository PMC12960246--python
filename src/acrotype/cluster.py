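"""Consensus clustering with stability-based model selection, plus the
two-level signature analysis (cluster signature genes, gene modules,
over-representation analysis).

The consensus matrix records, for every sample pair, the fraction of
co-sampled subsample partitions in which the pair co-clusters. Stability
per k is summarized by 1-PAC (one minus the fraction of off-diagonal
entries in the ambiguous interval), mean silhouette on 1 - consensus,
pair-concordance of resample partitions with the final labels, and the
Jaccard similarity of the k vs k-1 partitions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .stats import bh_fdr

PAC_INTERVAL = (0.1, 0.9)
FEATURE_METHODS = ("sd", "mad", "cv")
BASE_METHODS = ("kmeans", "pam", "hclust")


# ------------------------------------------------------------------ sample QC

def qc_rnaseq_samples(metrics: pd.DataFrame,
                      min_total_reads: float = 25e6) -> pd.DataFrame:
    """Keep/drop per sample from read-level metrics.

    Drops samples with total read counts strictly below ``min_total_reads``
    or whose ambiguous + no-feature counts strictly exceed the summed gene
    counts. Needs columns sample, total_reads, ambiguous_reads,
    no_feature_reads, gene_reads.
    """
    need = {"sample", "total_reads", "ambiguous_reads",
            "no_feature_reads", "gene_reads"}
    missing = need - set(metrics.columns)
    if missing:
        raise ValueError(f"missing metric columns: {sorted(missing)}")
    num_cols = list(need - {"sample"})
    if (metrics[num_cols] < 0).any().any():
        raise ValueError("negative read counts")
    rows = []
    for _, r in metrics.iterrows():
        reasons = []
        if r.total_reads < min_total_reads:
            reasons.append("total reads below 25M")
        if r.ambiguous_reads + r.no_feature_reads > r.gene_reads:
            reasons.append("ambiguous + no-feature exceeds gene counts")
        rows.append({"sample": r["sample"], "keep": not reasons,
                     "reasons": "; ".join(reasons)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------- preprocessing

def preprocess_matrix(matrix: pd.DataFrame,
                      max_na_frac: float = 0.25,
                      winsor: tuple = (5.0, 95.0),
                      min_var_pct: float = 5.0) -> pd.DataFrame:
    """Five-step row filtering/stabilization before clustering.

    In order: (1) drop rows with more than ``max_na_frac`` missing values
    (boundary keeps); (2) impute remaining missing values with the row
    median; (3) winsorize each row at its own 5th/95th percentiles
    (linear-interpolation percentile rule); (4) drop zero-variance rows;
    (5) drop rows with variance below the cohort's 5th variance percentile.
    """
    m = matrix.astype(float).copy()
    na_frac = m.isna().mean(axis=1)
    m = m[na_frac <= max_na_frac]
    if m.empty:
        raise ValueError("empty matrix after preprocessing")
    med = m.median(axis=1)
    m = m.apply(lambda row: row.fillna(med[row.name]), axis=1)
    lo = np.nanpercentile(m, winsor[0], axis=1)
    hi = np.nanpercentile(m, winsor[1], axis=1)
    m = m.clip(lower=pd.Series(lo, index=m.index),
               upper=pd.Series(hi, index=m.index), axis=0)
    var = m.var(axis=1, ddof=1)
    m = m[var > 0]
    var = var[var > 0]
    if m.empty:
        raise ValueError("empty matrix after preprocessing")
    m = m[var >= np.percentile(var, min_var_pct)]
    if m.empty:
        raise ValueError("empty matrix after preprocessing")
    return m


# ------------------------------------------------------------------ utilities

def _feature_scores(matrix: pd.DataFrame, method: str) -> pd.Series:
    if method == "sd":
        return matrix.std(axis=1, ddof=1)
    if method == "mad":
        med = matrix.median(axis=1)
        return (matrix.sub(med, axis=0)).abs().median(axis=1)
    if method == "cv":
        mean = matrix.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = matrix.std(axis=1, ddof=1) / mean.abs()
        return cv.replace([np.inf, -np.inf], np.nan).fillna(0.0)
    raise ValueError(f"unknown feature method {method!r}")


def _pam(X: np.ndarray, k: int, rng: np.random.Generator,
         max_iter: int = 50) -> np.ndarray:
    """Partitioning around medoids by Voronoi iteration on Euclidean
    distances, greedy farthest-point initialization."""
    n = X.shape[0]
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        dist_to_near = d[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(dist_to_near)))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        labels = np.argmin(d[:, medoids], axis=1)
        new = medoids.copy()
        for j in range(k):
            members = np.flatnonzero(labels == j)
            if len(members) == 0:
                continue
            within = d[np.ix_(members, members)].sum(axis=1)
            new[j] = members[int(np.argmin(within))]
        if np.array_equal(np.sort(new), np.sort(medoids)):
            break
        medoids = new
    return np.argmin(d[:, medoids], axis=1)


def _base_partition(X: np.ndarray, k: int, method: str,
                    rng: np.random.Generator) -> np.ndarray:
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=5,
                    random_state=int(rng.integers(2 ** 31 - 1)))
        return km.fit_predict(X)
    if method == "pam":
        return _pam(X, k, rng)
    if method == "hclust":
        Z = linkage(X, method="ward")
        return fcluster(Z, t=k, criterion="maxclust") - 1
    raise ValueError(f"unknown base method {method!r}")


def pair_concordance(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of sample pairs on which two partitions agree
    (co-clustered in both or separated in both)."""
    n = len(a)
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, k=1)
    return float((same_a[iu] == same_b[iu]).mean())


def jaccard_partitions(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard similarity of the co-clustered pair sets of two partitions."""
    same_a = (a[:, None] == a[None, :])
    same_b = (b[:, None] == b[None, :])
    iu = np.triu_indices(len(a), k=1)
    inter = (same_a[iu] & same_b[iu]).sum()
    union = (same_a[iu] | same_b[iu]).sum()
    return float(inter / union) if union else 1.0


# --------------------------------------------------------- consensus pipeline

@dataclass
class ConsensusResult:
    """Consensus clustering over a k range for one method combination."""

    feature_method: str
    base_method: str
    consensus: dict               # k -> (n x n) consensus matrix
    metrics: pd.DataFrame         # per-k stability metrics
    labels: dict                  # k -> final labels (1..k)
    best_k: int
    samples: list

    def best_labels(self) -> np.ndarray:
        return self.labels[self.best_k]


def evaluate_stability(consensus: np.ndarray,
                       resample_partitions: Sequence[tuple],
                       final_labels: np.ndarray,
                       prev_labels: Optional[np.ndarray] = None,
                       pac_interval: tuple = PAC_INTERVAL) -> dict:
    """Stability metrics for one k.

    PAC is the fraction of off-diagonal consensus entries strictly inside
    ``pac_interval``; concordance averages pair-agreement of each resample
    partition (restricted to its co-sampled items) with the final labels;
    Jaccard compares the k and k-1 partitions; silhouette uses
    1 - consensus as the dissimilarity.
    """
    n = consensus.shape[0]
    iu = np.triu_indices(n, k=1)
    off = consensus[iu]
    lo, hi = pac_interval
    pac = float(((off > lo) & (off < hi)).mean())
    conc = float(np.mean([
        pair_concordance(lab, final_labels[idx])
        for idx, lab in resample_partitions
        if len(idx) > 1
    ])) if resample_partitions else np.nan
    jac = jaccard_partitions(final_labels, prev_labels) \
        if prev_labels is not None else np.nan
    k = len(np.unique(final_labels))
    if 1 < k < n:
        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        sil = float(silhouette_score(dist, final_labels,
                                     metric="precomputed"))
    else:
        sil = np.nan
    return {"one_minus_pac": 1.0 - pac, "pac": pac, "concordance": conc,
            "jaccard_vs_prev": jac, "mean_silhouette": sil}


def consensus_partition(matrix: pd.DataFrame,
                        feature_method: str = "sd",
                        base_method: str = "pam",
                        k_range: Sequence[int] = (2, 3, 4, 5, 6),
                        n_resamples: int = 50,
                        subsample_fraction: float = 0.8,
                        n_features: int = 2000,
                        seed: int = 0) -> ConsensusResult:
    """Subsampled consensus clustering for one method combination.

    Top ``n_features`` rows by the feature score are kept; for each k,
    ``n_resamples`` random subsamples of the samples are partitioned and
    consensus(i, j) = co-cluster count / co-sample count. Final labels cut
    the average-linkage tree of 1 - consensus at k.
    """
    if feature_method not in FEATURE_METHODS:
        raise ValueError(f"unknown feature method {feature_method!r}")
    if base_method not in BASE_METHODS:
        raise ValueError(f"unknown base method {base_method!r}")
    samples = list(matrix.columns)
    n = len(samples)
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("empty usable k range")
    m_sub = int(round(subsample_fraction * n))
    if m_sub < max(k_range) + 1:
        raise ValueError("subsample too small for the largest k")

    scores = _feature_scores(matrix, feature_method)
    keep = scores.sort_values(ascending=False).index[:n_features]
    X = matrix.loc[keep].to_numpy().T       # samples x features
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1)

    rng = np.random.default_rng(seed)
    consensus = {}
    labels = {}
    metric_rows = []
    prev = None
    for k in k_range:
        co = np.zeros((n, n))
        tog = np.zeros((n, n))
        parts = []
        for _ in range(n_resamples):
            idx = np.sort(rng.choice(n, size=m_sub, replace=False))
            lab = _base_partition(X[idx], k, base_method, rng)
            parts.append((idx, lab))
            co[np.ix_(idx, idx)] += 1
            same = lab[:, None] == lab[None, :]
            tog[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            cons = np.where(co > 0, tog / np.maximum(co, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2
        consensus[k] = cons
        dist = 1.0 - cons
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        lab_final = fcluster(Z, t=k, criterion="maxclust")
        labels[k] = lab_final
        metric_rows.append({
            "k": k, **evaluate_stability(cons, parts, lab_final, prev)})
        prev = lab_final
    metrics = pd.DataFrame(metric_rows).set_index("k")
    # best k: highest 1-PAC, ties broken by mean silhouette
    ranked = metrics.sort_values(["one_minus_pac", "mean_silhouette"],
                                 ascending=False, kind="stable")
    best_k = int(ranked.index[0])
    return ConsensusResult(
        feature_method=feature_method, base_method=base_method,
        consensus=consensus, metrics=metrics, labels=labels,
        best_k=best_k, samples=samples,
    )


def consensus_sweep(matrix: pd.DataFrame,
                    feature_methods: Sequence[str] = FEATURE_METHODS,
                    base_methods: Sequence[str] = BASE_METHODS,
                    **kw) -> tuple:
    """Run every method combination; return (best result, summary table).

    The best combination maximizes 1-PAC at its own best k, ties broken by
    mean silhouette.
    """
    results = {}
    rows = []
    for fm, bm in itertools.product(feature_methods, base_methods):
        res = consensus_partition(matrix, feature_method=fm,
                                  base_method=bm, **kw)
        results[(fm, bm)] = res
        row = res.metrics.loc[res.best_k]
        rows.append({"feature_method": fm, "base_method": bm,
                     "best_k": res.best_k,
                     "one_minus_pac": row["one_minus_pac"],
                     "mean_silhouette": row["mean_silhouette"]})
    summary = pd.DataFrame(rows).sort_values(
        ["one_minus_pac", "mean_silhouette"], ascending=False,
        kind="stable").reset_index(drop=True)
    best = results[(summary.loc[0, "feature_method"],
                    summary.loc[0, "base_method"])]
    return best, summary


# ---------------------------------------------------------- signature analysis

def signature_genes(matrix: pd.DataFrame, labels: Sequence[int],
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene one-way fixed-effects F test across sample clusters, BH
    corrected; significant genes are assigned to their argmax-mean cluster.
    """
    lab = np.asarray(labels)
    levels = np.unique(lab)
    if len(levels) < 2:
        raise ValueError("need at least 2 clusters")
    for lv in levels:
        if (lab == lv).sum() < 2:
            raise ValueError(f"cluster {lv} has fewer than 2 samples")
    X = matrix.to_numpy()
    n = X.shape[1]
    grand = X.mean(axis=1)
    ss_between = np.zeros(len(X))
    ss_within = np.zeros(len(X))
    means = {}
    for lv in levels:
        cols = lab == lv
        m = X[:, cols].mean(axis=1)
        means[lv] = m
        ss_between += cols.sum() * (m - grand) ** 2
        ss_within += ((X[:, cols] - m[:, None]) ** 2).sum(axis=1)
    df1 = len(levels) - 1
    df2 = n - len(levels)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(ss_within > 0,
                     (ss_between / df1) / (ss_within * (1 / df2)),
                     np.inf)
    p = _sps.f.sf(F, df1, df2)          # sf(inf) = 0: exact separation
    degenerate = ss_between <= 1e-300   # no between-group variation
    F = np.where(degenerate, 0.0, F)
    p = np.where(degenerate, 1.0, p)
    q = bh_fdr(p)
    mean_mat = np.column_stack([means[lv] for lv in levels])
    assigned = levels[np.argmax(mean_mat, axis=1)]
    out = pd.DataFrame({
        "F": F, "p": p, "q": q,
        "significant": q < alpha,
        "assigned_cluster": np.where(q < alpha, assigned, -1),
    }, index=matrix.index)
    for i, lv in enumerate(levels):
        out[f"mean_cluster_{lv}"] = mean_mat[:, i]
    return out


@dataclass
class GeneModuleSet:
    modules: dict                 # "M1" -> gene list
    profiles: pd.DataFrame        # module x cluster scaled mean profiles
    assignments: pd.Series        # gene -> module id


def gene_modules(matrix: pd.DataFrame, labels: Sequence[int], k: int = 3,
                 seed: int = 0, n_init: int = 25) -> GeneModuleSet:
    """k-means modules of signature genes on scaled cluster-mean profiles.

    Each gene's per-cluster mean profile is standardized (mean 0, sd 1
    across clusters) before k-means; modules are labelled M1..Mk by the
    sample cluster at which their centroid peaks.
    """
    if k > len(matrix):
        raise ValueError("k exceeds number of genes")
    lab = np.asarray(labels)
    levels = np.unique(lab)
    prof = np.column_stack([matrix.to_numpy()[:, lab == lv].mean(axis=1)
                            for lv in levels])
    mu = prof.mean(axis=1, keepdims=True)
    sd = prof.std(axis=1, ddof=0, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    z = (prof - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(z)
    # stable module ids: order by centroid peak cluster, then by centroid
    peak = km.cluster_centers_.argmax(axis=1)
    order = np.lexsort((km.cluster_centers_.max(axis=1), peak))
    remap = {int(old): i for i, old in enumerate(order)}
    ids = np.array([f"M{remap[int(r)] + 1}" for r in raw])
    assignments = pd.Series(ids, index=matrix.index, name="module")
    modules = {m: assignments.index[assignments == m].tolist()
               for m in sorted(set(ids))}
    prof_rows = []
    for m in sorted(modules):
        zm = z[assignments.to_numpy() == m].mean(axis=0)
        prof_rows.append(pd.Series(zm, index=[f"cluster_{lv}" for lv in
                                              levels], name=m))
    profiles = pd.DataFrame(prof_rows)
    return GeneModuleSet(modules=modules, profiles=profiles,
                         assignments=assignments)


def ora_enrichment(module_genes: Sequence[str], gene_sets: dict,
                   universe: Sequence[str], q_max: float = 0.05
                   ) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation analysis with BH FDR.

    For each set: p = P(overlap >= observed) with the module drawn from the
    universe without replacement.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    mod = set(module_genes) & uni
    rows = []
    for name, genes in gene_sets.items():
        s = set(genes) & uni
        ov = len(s & mod)
        # survival function at ov-1 includes the observed overlap
        p = float(_sps.hypergeom.sf(ov - 1, len(uni), len(s), len(mod)))
        rows.append({"set": name, "set_size": len(s), "overlap": ov,
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < q_max
    return out.sort_values("p", ignore_index=True)
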