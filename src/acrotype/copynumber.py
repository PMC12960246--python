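"""Copy-number QC, burden scoring and homozygous-deletion calling.

Purity/ploidy-aware: segment means are log2(cn / ploidy), the expected
log2 ratio of a homozygous deletion follows the tumour-normal mixture
log2(2(1-rho) / (rho*psi + 2(1-rho))), and cohort burden combines a broad
(arm-level) and a focal (length-weighted) component, each min-max
normalized to [0, 50] across the cohort so the global score lies in
[0, 100]. The absolute scale of the burden is a package convention; only
orderings are comparable across tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

LOG2_FLOOR = -5.0

REGION_CLASSES = ("high-del", "low-del", "neutral", "low-amp", "high-amp")


# ------------------------------------------------------------------------- QC

@dataclass
class PurityQCResult:
    sample: str
    status: str          # "pass" | "fail" | "unassessable"
    reasons: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def purity_qc(sample: str, purity_a, purity_b, goodness_of_fit,
              max_discrepancy: float = 0.5,
              min_gof: float = 95.0) -> PurityQCResult:
    """Purity/ploidy quality control.

    Fails when the two independent purity estimates disagree by more than
    ``max_discrepancy``, when they show the extreme-disagreement pattern
    (one below 0.15 while the other is at or above 0.95), or when the
    goodness of fit is below ``min_gof`` (boundary keeps). A missing
    estimate yields status "unassessable", never a silent pass.
    """
    if purity_a is None or purity_b is None or \
            (isinstance(purity_a, float) and math.isnan(purity_a)) or \
            (isinstance(purity_b, float) and math.isnan(purity_b)):
        return PurityQCResult(sample, "unassessable",
                              ["missing purity estimate"])
    reasons = []
    lo, hi = min(purity_a, purity_b), max(purity_a, purity_b)
    if hi - lo > max_discrepancy:
        reasons.append(f"purity discrepancy {hi - lo:.3f} > {max_discrepancy}")
    if lo < 0.15 and hi >= 0.95:
        reasons.append("extreme purity disagreement (<0.15 vs >=0.95)")
    if goodness_of_fit is not None and goodness_of_fit < min_gof:
        reasons.append(f"goodness of fit {goodness_of_fit} < {min_gof}")
    return PurityQCResult(sample, "fail" if reasons else "pass", reasons)


def purity_qc_table(pp: pd.DataFrame, **kw) -> pd.DataFrame:
    """Vectorised QC over a purity/ploidy table."""
    rows = []
    for _, r in pp.iterrows():
        res = purity_qc(r["sample"], r.get("purity_a"), r.get("purity_b"),
                        r.get("goodness_of_fit"), **kw)
        rows.append({"sample": res.sample, "status": res.status,
                     "reasons": "; ".join(res.reasons)})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ seg means

def seg_mean(cn, psi: float):
    """log2(cn / ploidy); copy number 0 is capped at the documented floor."""
    if psi <= 0:
        raise ValueError("ploidy must be positive")
    cn = np.asarray(cn, dtype=float)
    if np.any(cn < 0):
        raise ValueError("copy number must be non-negative")
    with np.errstate(divide="ignore"):
        out = np.log2(cn / psi)
    out = np.where(np.isfinite(out), out, LOG2_FLOOR)
    out = np.maximum(out, LOG2_FLOOR)
    return float(out) if out.ndim == 0 else out


def classify_region(g: float) -> str:
    """GISTIC-value classification of a region copy-number value.

    Gains in (0.25, 0.9] are low-level and above 0.9 high-level
    amplifications; losses in [-1.3, -0.25) are low-level and below -1.3
    high-level deletions; [-0.25, 0.25] is neutral.
    """
    if not np.isfinite(g):
        raise ValueError("region value must be finite")
    if g > 0.9:
        return "high-amp"
    if g > 0.25:
        return "low-amp"
    if g >= -0.25:
        return "neutral"
    if g >= -1.3:
        return "low-del"
    return "high-del"


# --------------------------------------------------------------------- burden

@dataclass
class CopyNumberBurden:
    sample: str
    bcs: float
    fcs: float
    bcs_norm: float
    fcs_norm: float

    @property
    def gcs(self) -> float:
        return self.bcs_norm + self.fcs_norm


def _coalesce(segs: pd.DataFrame) -> pd.DataFrame:
    """Merge contiguous same-copy-number segments per chromosome, so the
    burden is invariant to how a constant region was split."""
    rows = []
    for chrom, sub in segs.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for _, r in sub.iterrows():
            cn = r["nMajor"] + r["nMinor"]
            if (cur is not None and cur["cn"] == cn
                    and r["start"] <= cur["end"] + 1):
                cur["end"] = max(cur["end"], r["end"])
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": chrom, "start": r["start"], "end": r["end"],
                       "cn": cn}
        if cur is not None:
            rows.append(cur)
    return pd.DataFrame(rows)


def _per_sample_components(segs: pd.DataFrame, arms: pd.DataFrame,
                           psi: float, broad_threshold: float):
    """Raw broad and focal burden components of one sample."""
    bcs = 0.0
    fcs = 0.0
    segs = _coalesce(segs)
    segs = segs.assign(_sm=seg_mean(segs["cn"].to_numpy(), psi))
    for _, arm in arms.iterrows():
        sel = ((segs["chrom"] == arm.chrom)
               & (segs["start"] <= arm.end) & (segs["end"] >= arm.start))
        sub = segs[sel]
        if not len(sub):
            continue
        arm_len = arm.end - arm.start + 1
        ov_start = np.maximum(sub["start"].to_numpy(), arm.start)
        ov_end = np.minimum(sub["end"].to_numpy(), arm.end)
        lengths = np.maximum(ov_end - ov_start + 1, 0)
        sm = sub["_sm"].to_numpy()
        arm_mean = float((sm * lengths).sum() / lengths.sum())
        if abs(arm_mean) > broad_threshold:
            bcs += abs(arm_mean)
        # focal: sub-arm segments weighted by amplitude and length fraction
        focal = lengths < arm_len
        fcs += float((np.abs(sm[focal]) * lengths[focal] / arm_len).sum())
    return bcs, fcs


def compute_burden(segments: pd.DataFrame, arm_model: pd.DataFrame,
                   purity_ploidy: pd.DataFrame,
                   broad_threshold: float = 0.2,
                   norm_max: float = 50.0) -> pd.DataFrame:
    """Cohort copy-number burden scores.

    BCS sums |arm-level length-weighted mean seg_mean| over arms exceeding
    the broad threshold; FCS sums |seg_mean| * (segment length / arm
    length) over sub-arm segments. Each component is min-max normalized to
    [0, ``norm_max``] across the cohort; GCS is their sum.
    """
    samples = sorted(set(segments["sample"]))
    if len(samples) < 2:
        raise ValueError("burden normalization needs a cohort of >= 2 samples")
    psi_map = dict(zip(purity_ploidy["sample"], purity_ploidy["ploidy"]))
    rows = []
    for sid in samples:
        segs = segments[segments["sample"] == sid]
        psi = float(psi_map.get(sid, 2.0))
        bcs, fcs = _per_sample_components(segs, arm_model, psi,
                                          broad_threshold)
        rows.append({"sample": sid, "bcs": bcs, "fcs": fcs})
    out = pd.DataFrame(rows)
    for col in ("bcs", "fcs"):
        v = out[col].to_numpy()
        rng = v.max() - v.min()
        out[col + "_norm"] = norm_max * (v - v.min()) / rng if rng > 0 \
            else np.zeros(len(v))
    out["gcs"] = out["bcs_norm"] + out["fcs_norm"]
    return out


# ------------------------------------------------------------------- hom-dels

def homdel_threshold(rho: float, psi: float) -> float:
    """Expected log2 ratio of total copy number 0 at purity rho, ploidy psi.

    log2(2(1-rho) / (rho*psi + 2(1-rho))); a pure tumour (rho = 1) has no
    contaminating normal signal, so the value is capped at the floor.
    """
    if not (0 < rho <= 1):
        raise ValueError("purity must lie in (0, 1]")
    if psi <= 0:
        raise ValueError("ploidy must be positive")
    num = 2 * (1 - rho)
    if num <= 0:
        return LOG2_FLOOR
    return max(math.log2(num / (rho * psi + num)), LOG2_FLOOR)


@dataclass
class HomdelCall:
    sample: str
    gene: str
    status: str            # "deleted" | "intact" | "unassessable"
    rule: str
    threshold: float
    evidence: dict = field(default_factory=dict)

    @property
    def deleted(self) -> bool:
        return self.status == "deleted"


def call_homozygous_deletion(bins: pd.DataFrame, threshold: float,
                             gene: str, rule: str,
                             near_margin: float = 0.3,
                             neighbour_margin: float = 0.5,
                             sample: str = "") -> HomdelCall:
    """Homozygous-deletion call from bin-level log2 ratios over one gene.

    large-gene rule: at least two contiguous in-gene bins at or below the
    threshold, or at least one full in-gene bin with zero read coverage.
    small-gene rule: at least one in-gene bin at or below the threshold,
    at least two further in-gene bins within ``near_margin`` of it, and an
    in-gene mean log2 ratio at least ``neighbour_margin`` below the mean of
    the flanking bins.
    """
    if rule not in ("large-gene", "small-gene"):
        raise ValueError("rule must be 'large-gene' or 'small-gene'")
    in_gene = bins[bins["gene"] == gene].sort_values("start")
    if not len(in_gene):
        return HomdelCall(sample, gene, "unassessable", rule, threshold,
                          {"reason": "no bins overlap gene"})
    l2 = in_gene["log2"].to_numpy()
    below = l2 <= threshold
    evidence = {"n_bins": int(len(l2)), "n_below": int(below.sum()),
                "min_log2": float(l2.min())}
    if rule == "large-gene":
        runs = np.flatnonzero(below[:-1] & below[1:])
        zero_cov = ("coverage" in in_gene
                    and bool((in_gene["coverage"].to_numpy() == 0).any()))
        deleted = len(runs) > 0 or zero_cov
        evidence["contiguous_pair"] = bool(len(runs) > 0)
        evidence["zero_coverage_bin"] = zero_cov
    else:
        # "further bins close to the threshold": any additional bin at or
        # below threshold + near_margin counts, including ones below it
        near = l2 <= threshold + near_margin
        flank = bins[bins["gene"] != gene]
        if len(flank):
            diff = float(flank["log2"].mean() - l2.mean())
        else:
            diff = math.inf
        deleted = (below.sum() >= 1 and near.sum() >= 3
                   and diff >= neighbour_margin)
        evidence.update({"n_near": int(near.sum()) - 1,
                         "flank_minus_gene_mean": diff})
    return HomdelCall(sample, gene, "deleted" if deleted else "intact",
                      rule, threshold, evidence)


def call_homdels_cohort(bins: pd.DataFrame, purity_ploidy: pd.DataFrame,
                        gene: str, rule: str, **kw) -> pd.DataFrame:
    """Per-sample hom-del calls for one gene across a cohort."""
    pp = purity_ploidy.set_index("sample")
    rows = []
    for sid, sub in bins[bins["window"] == gene].groupby("sample"):
        rho = float(pp.loc[sid, "purity_a"])
        psi = float(pp.loc[sid, "ploidy"])
        thr = homdel_threshold(rho, psi)
        call = call_homozygous_deletion(sub, thr, gene, rule,
                                        sample=sid, **kw)
        rows.append({"sample": sid, "gene": gene, "status": call.status,
                     "deleted": call.deleted, "threshold": thr,
                     **{f"ev_{k}": v for k, v in call.evidence.items()}})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- converters

def seg_to_bed(df: pd.DataFrame) -> pd.DataFrame:
    """1-based inclusive SEG intervals -> 0-based half-open BED."""
    out = df.copy()
    out["start"] = out["start"] - 1
    return out


def bed_to_seg(df: pd.DataFrame) -> pd.DataFrame:
    """0-based half-open BED intervals -> 1-based inclusive SEG."""
    out = df.copy()
    out["start"] = out["start"] + 1
    return out
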