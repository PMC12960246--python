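"""Melanocytic-origin (acral:cutaneous, A:C) gene-signature score.

Trains a 10+10-gene panel from the loadings of the class-separating
principal component of log2 normalized expression (panel-style counts are
normalized by the housekeeping geometric mean with a background floor of
20; RNA-seq counts by median-of-ratios size factors with a log2(x+1)
transform), then scores each sample as the ratio of the products of the
floored log2 expression values of the acral-side over the cutaneous-side
genes. Higher scores are more acral (volar-melanocyte) like.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stats import mann_whitney, TestResult

RNASEQ_FLOOR = 1.0 + 2.0 ** -10


@dataclass
class NormalizedExpression:
    """Log2 normalized matrix with its provenance."""

    values: pd.DataFrame          # genes x samples, log2 scale
    transform: str                # "log2-counts" | "log2-TPM+1"
    floor: float
    housekeeping: list = field(default_factory=list)

    def column(self, sample: str) -> pd.Series:
        return self.values[sample]


@dataclass
class ScorePanel:
    """Trained A:C panel: gene lists with their component loadings."""

    acral_genes: list
    cutaneous_genes: list
    loadings: dict                # gene -> loading on selected component
    component_index: int          # 1-based PC index
    training_n: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.acral_genes) & set(self.cutaneous_genes):
            raise ValueError("panel sides must be disjoint")
        signs_a = {np.sign(self.loadings[g]) for g in self.acral_genes}
        signs_c = {np.sign(self.loadings[g]) for g in self.cutaneous_genes}
        if len(signs_a) > 1 or len(signs_c) > 1 or signs_a == signs_c:
            raise ValueError("loadings must be sign-consistent per side")

    def to_dict(self) -> dict:
        return {
            "acral_genes": self.acral_genes,
            "cutaneous_genes": self.cutaneous_genes,
            "loadings": self.loadings,
            "component_index": self.component_index,
            "training_n": self.training_n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScorePanel":
        return cls(**d)


# -------------------------------------------------------------- normalization

def normalize_counts(raw: pd.DataFrame, housekeeping: Sequence[str],
                     background: float = 20.0) -> NormalizedExpression:
    """Housekeeping geometric-mean normalization for panel counts.

    Each sample is scaled by (cohort mean of housekeeping geometric means)
    / (sample housekeeping geometric mean); values are then floored at the
    background threshold and log2 transformed.
    """
    missing = [g for g in housekeeping if g not in raw.index]
    if missing:
        raise ValueError(f"housekeeping genes absent from matrix: {missing}")
    hk = raw.loc[list(housekeeping)]
    zero_cols = hk.columns[(hk <= 0).any(axis=0)]
    if len(zero_cols):
        bad_gene = hk.index[(hk <= 0).any(axis=1)][0]
        raise ValueError(
            f"housekeeping gene {bad_gene!r} has a zero count "
            f"(sample {zero_cols[0]!r}); geometric mean undefined")
    geomeans = np.exp(np.log(hk).mean(axis=0))
    factors = geomeans.mean() / geomeans
    scaled = raw * factors
    floored = scaled.clip(lower=background)
    return NormalizedExpression(values=np.log2(floored),
                                transform="log2-counts",
                                floor=background,
                                housekeeping=list(housekeeping))


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: per-sample median ratio to the row-wise
    geometric-mean reference, over genes expressed in every sample."""
    logc = np.log(counts.where(counts > 0))
    ref = logc.mean(axis=1)
    usable = np.isfinite(ref)
    if not usable.any():
        raise ValueError("no gene is expressed in every sample")
    ratios = logc.loc[usable].sub(ref[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def normalize_rnaseq(counts: pd.DataFrame,
                     batch: Optional[Sequence] = None,
                     floor: float = RNASEQ_FLOOR) -> NormalizedExpression:
    """Size-factor normalization, log2(x+1), optional per-batch centring.

    With more than one batch, each gene is mean-centred within batch and
    the global gene mean restored, removing additive batch offsets on the
    log scale. Values are floored just above 1 so downstream log2-of-log2
    panel scoring stays positive.
    """
    sf = median_of_ratios_size_factors(counts)
    normed = counts.div(sf, axis=1)
    logv = np.log2(normed + 1.0)
    if batch is not None:
        b = pd.Series(list(batch), index=counts.columns)
        if b.nunique() > 1:
            sizes = b.value_counts()
            if (sizes < 2).any():
                raise ValueError("each batch needs at least 2 samples "
                                 "for centring")
            grand = logv.mean(axis=1)
            for level in b.unique():
                cols = b.index[b == level]
                centred = logv[cols].sub(logv[cols].mean(axis=1), axis=0)
                logv[cols] = centred.add(grand, axis=0)
    logv = logv.clip(lower=floor)
    return NormalizedExpression(values=logv, transform="log2-TPM+1",
                                floor=floor)


# ------------------------------------------------------------------- training

def train_panel(expr: NormalizedExpression, labels: Sequence[str],
                n_genes: int = 10) -> ScorePanel:
    """Train the two-sided panel from the class-separating PC.

    PCA treats genes as variables and samples as observations
    (column-centred per gene, no scaling). The component whose sample
    scores have the largest |point-biserial correlation| with the
    acral/cutaneous label is selected; the top and bottom ``n_genes`` by
    loading become the two panel sides, oriented so acral samples score
    high.
    """
    X = expr.values.to_numpy().T           # samples x genes
    genes = expr.values.index.to_numpy()
    y = np.asarray([1 if l == "acral" else 0 for l in labels])
    if len(y) != X.shape[0]:
        raise ValueError("labels length must match sample count")
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need >= 2 samples per class")
    if len(genes) < 2 * n_genes:
        raise ValueError("fewer candidate genes than 2 * n_genes")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("zero-variance expression matrix")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = u * s                          # samples x components
    k = min(len(s), X.shape[0] - 1)
    corrs = np.zeros(k)
    for j in range(k):
        sc = scores[:, j]
        if np.std(sc) == 0:
            continue
        corrs[j] = abs(np.corrcoef(sc, y)[0, 1])
    comp = int(np.argmax(corrs))
    load = vt[comp]
    sc = scores[:, comp]
    # orient so acral samples have positive component scores
    if sc[y == 1].mean() < sc[y == 0].mean():
        load = -load
    order = np.argsort(load)
    top = genes[order[::-1][:n_genes]]      # highest loadings -> acral side
    bottom = genes[order[:n_genes]]
    return ScorePanel(
        acral_genes=[str(g) for g in top],
        cutaneous_genes=[str(g) for g in bottom],
        loadings={str(g): float(l) for g, l in zip(genes, load)},
        component_index=comp + 1,
        training_n={"acral": int(y.sum()), "cutaneous": int((1 - y).sum())},
    )


# -------------------------------------------------------------------- scoring

def panel_product(sample: pd.Series, genes: Sequence[str]) -> float:
    """Product of the (floored, log2) expression values over a gene list."""
    missing = [g for g in genes if g not in sample.index]
    if missing:
        raise ValueError(f"genes missing from sample: {missing}")
    if len(genes) == 0:
        return 1.0
    return float(np.prod([sample[g] for g in genes]))


def ac_score(sample: pd.Series, panel: ScorePanel) -> float:
    """A:C score: product of acral-side over cutaneous-side log2 values."""
    num = panel_product(sample, panel.acral_genes)
    den = panel_product(sample, panel.cutaneous_genes)
    assert den > 0, "cutaneous product must be positive under the floor"
    return num / den


def log_ac_score(sample: pd.Series, panel: ScorePanel) -> float:
    """Numerically stable log2 of the A:C score."""
    num = sum(math.log2(sample[g]) for g in panel.acral_genes)
    den = sum(math.log2(sample[g]) for g in panel.cutaneous_genes)
    return num - den


@dataclass
class OriginScoreResult:
    scores: pd.Series            # per-sample A:C score
    log_scores: pd.Series
    groups: Optional[pd.Series] = None

    def summary(self) -> str:
        lines = ["A:C origin scores",
                 f"  n = {len(self.scores)}  "
                 f"median = {self.scores.median():.4g}"]
        if self.groups is not None:
            for g, sub in self.scores.groupby(self.groups):
                lines.append(f"  {g}: n = {len(sub)}, "
                             f"median = {sub.median():.4g}")
        return "\n".join(lines)


def score_cohort(expr: NormalizedExpression, panel: ScorePanel,
                 groups: Optional[pd.Series] = None) -> OriginScoreResult:
    scores = {}
    logs = {}
    for sample in expr.values.columns:
        col = expr.column(sample)
        scores[sample] = ac_score(col, panel)
        logs[sample] = log_ac_score(col, panel)
    return OriginScoreResult(scores=pd.Series(scores, name="ac_score"),
                             log_scores=pd.Series(logs, name="log2_ac"),
                             groups=groups)


def compare_scores(result: OriginScoreResult, grouping: pd.Series,
                   alternative: str = "two-sided",
                   order: Optional[tuple] = None) -> TestResult:
    """Wilcoxon-Mann-Whitney comparison of A:C scores between two groups.

    ``order`` names (group_x, group_y); with ``alternative='less'`` the
    test is that group_x scores are stochastically smaller.
    """
    levels = order if order is not None else tuple(pd.unique(grouping))
    if len(levels) != 2:
        raise ValueError("grouping must have exactly 2 levels")
    x = result.scores[grouping == levels[0]]
    y = result.scores[grouping == levels[1]]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    return mann_whitney(x.to_numpy(), y.to_numpy(), alternative=alternative)
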