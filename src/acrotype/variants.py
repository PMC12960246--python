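"""Somatic variant consensus and driver classification.

Merges per-caller somatic call sets under a 2-of-3 voting rule with a
protein-change rescue whitelist (by default BRAF p.V600E, whose
oncogenicity justifies keeping single-caller calls), applies base-quality
and strand-bias filters, selects one index sample per patient, classifies
driver status into {BRAF, NRAS, KIT, NF1, multi-hit, QWT} and computes the
tumour mutational burden (SNVs + indels per captured megabase).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import DRIVER_GENES

DEFAULT_CALLERS = ("caveman", "mutect2", "varscan2")
DEFAULT_RESCUE = (("BRAF", "p.V600E"),)


@dataclass(frozen=True)
class VariantCall:
    """One caller's record of one candidate somatic variant."""

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    caller: str
    baseq: Optional[float] = None
    strand_bias: bool = False
    gene: Optional[str] = None
    protein_change: Optional[str] = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos < 1:
            raise ValueError("pos must be 1-based positive")

    @property
    def site(self):
        return (self.sample, self.chrom, self.pos, self.ref, self.alt)


@dataclass
class DriverProfile:
    """Per-patient consensus profile."""

    patient: str
    index_sample: str
    variants: pd.DataFrame
    driver_category: str
    tmb: float


def _normalize_site(chrom, pos, ref, alt):
    """Left-align and trim an indel representation.

    Removes the shared suffix then the shared prefix (advancing pos), the
    usual VCF normalization so identical events from different callers
    compare equal. SNVs pass through unchanged.
    """
    ref, alt = str(ref), str(alt)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return str(chrom), int(pos), ref, alt


def _as_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        df = calls.copy()
    else:
        df = pd.DataFrame([c.__dict__ for c in calls])
    required = {"sample", "chrom", "pos", "ref", "alt", "caller"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"call table missing columns: {sorted(missing)}")
    for col, default in (("baseq", np.nan), ("strand_bias", False),
                         ("gene", None), ("protein_change", None)):
        if col not in df.columns:
            df[col] = default
    norm = [_normalize_site(c, p, r, a) for c, p, r, a in
            zip(df["chrom"], df["pos"], df["ref"], df["alt"])]
    df[["chrom", "pos", "ref", "alt"]] = pd.DataFrame(norm, index=df.index)
    return df


def merge_callers(calls, rescue_list: Sequence = DEFAULT_RESCUE,
                  callers: Sequence[str] = DEFAULT_CALLERS,
                  min_support: int = 2) -> pd.DataFrame:
    """Consensus call set under the 2-of-3 rule with rescue.

    A site (sample, chrom, pos, ref, alt after normalization) is kept iff
    called by at least ``min_support`` of the declared callers, or by at
    least one caller while matching a (gene, protein-change) rescue entry.
    The supporting caller set is retained as provenance.
    """
    df = _as_frame(calls)
    bad = set(df["caller"]) - set(callers)
    if bad:
        raise ValueError(f"undeclared callers: {sorted(bad)}")
    key_cols = ["sample", "chrom", "pos", "ref", "alt"]
    dup = df.duplicated(subset=key_cols + ["caller"])
    if dup.any():
        raise ValueError("duplicate (caller, site) records")

    rescue = {(g, p) for g, p in rescue_list}

    def agg(grp: pd.DataFrame) -> Optional[dict]:
        support = sorted(set(grp["caller"]))
        genes = grp["gene"].dropna()
        pchg = grp["protein_change"].dropna()
        gene = genes.iloc[0] if len(genes) else None
        pc = pchg.iloc[0] if len(pchg) else None
        rescued = (gene, pc) in rescue
        if len(support) >= min_support or rescued:
            return {
                "sample": grp["sample"].iloc[0], "chrom": grp["chrom"].iloc[0],
                "pos": grp["pos"].iloc[0], "ref": grp["ref"].iloc[0],
                "alt": grp["alt"].iloc[0],
                "gene": gene, "protein_change": pc,
                "baseq": float(np.nanmean(grp["baseq"].astype(float)))
                if grp["baseq"].notna().any() else np.nan,
                "strand_bias": bool(grp["strand_bias"].any()),
                "supporting_callers": ",".join(support),
                "n_callers": len(support),
                "rescued": rescued and len(support) < min_support,
            }
        return None

    rows = [r for _, grp in df.groupby(key_cols, sort=True)
            if (r := agg(grp)) is not None]
    cols = ["sample", "chrom", "pos", "ref", "alt", "gene", "protein_change",
            "baseq", "strand_bias", "supporting_callers", "n_callers",
            "rescued"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["sample", "chrom", "pos", "ref", "alt"],
                           ignore_index=True)


def filter_quality(calls: pd.DataFrame, min_baseq: float = 30.0,
                   drop_strand_bias: bool = True) -> pd.DataFrame:
    """Remove calls below the Phred base-quality floor (boundary keeps)
    and, optionally, strand-bias-flagged calls. Missing base qualities are
    retained. Filter counts are stored in ``df.attrs['filter_counts']``."""
    if min_baseq < 0:
        raise ValueError("min_baseq must be non-negative")
    df = calls.copy()
    bq = df["baseq"].astype(float)
    low = bq.notna() & (bq < min_baseq)
    sb = df["strand_bias"].astype(bool) if drop_strand_bias \
        else pd.Series(False, index=df.index)
    keep = ~(low | sb)
    out = df[keep].reset_index(drop=True)
    out.attrs["filter_counts"] = {
        "input": int(len(df)),
        "low_baseq": int(low.sum()),
        "strand_bias": int((sb & ~low).sum()),
        "kept": int(keep.sum()),
    }
    return out


_SAMPLE_TYPE_ORDER = {"primary": 0, "metastasis": 1, "recurrence": 2,
                      "other": 3}


def select_index_sample(samples: pd.DataFrame) -> pd.Series:
    """One sample per patient: primaries preferred; otherwise the first
    non-primary by (type order, collection date, sample id).

    ``samples`` needs columns patient, sample, sample_type and optionally
    collection_date.
    """
    df = samples.copy()
    unknown = set(df["sample_type"]) - set(_SAMPLE_TYPE_ORDER)
    if unknown:
        raise ValueError(f"unknown sample types: {sorted(unknown)}")
    df["_type_rank"] = df["sample_type"].map(_SAMPLE_TYPE_ORDER)
    if "collection_date" not in df.columns:
        df["collection_date"] = ""
    df = df.sort_values(["_type_rank", "collection_date", "sample"],
                        kind="stable")
    picked = df.groupby("patient", sort=True).first()["sample"]
    if picked.isna().any():
        raise ValueError("patient with zero samples")
    return picked


def classify_driver_status(variants: pd.DataFrame,
                           driver_genes: Sequence[str] = DRIVER_GENES,
                           require_annotation: bool = True) -> str:
    """Driver category of one patient's consensus variants."""
    if len(variants) and require_annotation and "gene" not in variants:
        raise ValueError("variants must be gene-annotated")
    genes = set(variants["gene"].dropna()) if len(variants) else set()
    hit = sorted(genes & set(driver_genes))
    if len(hit) == 0:
        return "QWT"
    if len(hit) > 1:
        return "multi-hit"
    return hit[0]


def compute_tmb(variants: pd.DataFrame, capture_size_mb: float) -> float:
    """Mutations (SNVs + indels) per captured megabase."""
    if capture_size_mb <= 0:
        raise ValueError("capture_size_mb must be positive")
    return len(variants) / capture_size_mb


def build_driver_profiles(consensus: pd.DataFrame,
                          capture_size_mb: float,
                          sample_to_patient: Optional[dict] = None,
                          ) -> pd.DataFrame:
    """Per-patient driver category and TMB from a consensus call table."""
    df = consensus.copy()
    df["patient"] = df["sample"].map(sample_to_patient) \
        if sample_to_patient else df["sample"]
    rows = []
    for patient, grp in df.groupby("patient", sort=True):
        rows.append({
            "patient": patient,
            "driver_category": classify_driver_status(grp),
            "tmb": compute_tmb(grp, capture_size_mb),
            "n_variants": len(grp),
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- VCF I/O


def read_caller_vcf(path, sample: str, caller: str,
                    pass_only: bool = True) -> pd.DataFrame:
    """Read one caller's VCF into the internal call-table layout."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if pass_only and "PASS" not in rec.filter and len(rec.filter):
                continue
            info = dict(rec.info)
            for alt in rec.alts or ():
                rows.append({
                    "sample": sample, "caller": caller,
                    "chrom": rec.chrom, "pos": rec.pos,
                    "ref": rec.ref, "alt": alt,
                    "baseq": float(info["BQ"]) if "BQ" in info else np.nan,
                    "strand_bias": bool(info.get("SB", False)),
                    "gene": info.get("GENE"),
                    "protein_change": info.get("AA"),
                })
    return pd.DataFrame(rows, columns=["sample", "caller", "chrom", "pos",
                                       "ref", "alt", "baseq", "strand_bias",
                                       "gene", "protein_change"])


def read_cohort_vcfs(vcf_dir, callers: Sequence[str] = DEFAULT_CALLERS,
                     pass_only: bool = True) -> pd.DataFrame:
    """Read every ``<sample>.<caller>.vcf`` under a directory."""
    frames = []
    for path in sorted(Path(vcf_dir).glob("*.vcf")):
        parts = path.stem.rsplit(".", 1)
        if len(parts) != 2 or parts[1] not in callers:
            continue
        frames.append(read_caller_vcf(path, parts[0], parts[1], pass_only))
    if not frames:
        return pd.DataFrame(columns=["sample", "caller", "chrom", "pos",
                                     "ref", "alt", "baseq", "strand_bias",
                                     "gene", "protein_change"])
    return pd.concat(frames, ignore_index=True)
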