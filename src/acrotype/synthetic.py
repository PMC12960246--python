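"""Synthetic acral-melanoma cohort generator.

Generates cohorts with the statistical structure the downstream analyses
assume: admixed ancestry fractions, ancestry- and sex-linked driver
mutations, negative-binomial expression with two melanocyte lineage
programs (volar "v-type" vs cutaneous "c-type") and three transcriptional
cluster modules, purity/ploidy-contaminated copy-number profiles with
planted homozygous deletions, and driver-dependent recurrence and survival.
Every planted parameter is recorded in the cohort's ``truth`` block so each
downstream stage can be tested as a recovery experiment.

Determinism contract: identical (config, seed) pairs reproduce identical
cohorts. One master seed is split into per-component child seeds with
``numpy.random.SeedSequence.spawn`` in a fixed documented order
(ancestry, clinical, drivers, variants, expression, copy number, outcomes).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special

from .genome import DRIVER_GENES, GENES, arm_model, gene_interval

# --------------------------------------------------------------------- config


@dataclass
class GeneUniverse:
    """Synthetic gene panel: disjoint functional gene sets.

    ``acral``/``cutaneous`` are the two lineage programs; ``modules`` are the
    three cluster-specific co-expression modules; ``oncogene`` is a
    BRAF-downstream program deliberately disjoint from the lineage panel.
    """

    housekeeping: list
    acral: list
    cutaneous: list
    modules: list  # list of 3 gene lists
    oncogene: list
    background: list

    @classmethod
    def default(cls, n_module: int = 100, n_background: int = 700):
        return cls(
            housekeeping=[f"HK{i:02d}" for i in range(1, 9)],
            acral=[f"VML{i:02d}" for i in range(1, 11)],
            cutaneous=[f"CML{i:02d}" for i in range(1, 11)],
            modules=[[f"M{k}G{i:03d}" for i in range(1, n_module + 1)]
                     for k in (1, 2, 3)],
            oncogene=[f"ONC{i:02d}" for i in range(1, 11)],
            background=[f"BG{i:04d}" for i in range(1, n_background + 1)],
        )

    @property
    def all_genes(self) -> list:
        out = (self.housekeeping + self.acral + self.cutaneous
               + [g for m in self.modules for g in m]
               + self.oncogene + self.background)
        if len(set(out)) != len(out):
            raise ValueError("gene sets must be pairwise disjoint")
        return out

    def validate(self) -> None:
        self.all_genes  # raises on overlap
        for m in self.modules:
            if not m:
                raise ValueError("empty cluster module")


@dataclass
class DriverModel:
    """Two-stage driver genotype model.

    Stage 1: carrier status is Bernoulli with a planted sex effect --
    ``sex_log_or`` is the female-vs-male log odds ratio of carrying any
    driver, with the marginal carrier rate held at ``any_driver_rate``.
    Stage 2: carriers are assigned a gene; the BRAF share among carriers
    follows a logistic curve in the European ancestry fraction with slope
    ``eur_braf_log_odds``, calibrated so the marginal gene frequencies match
    ``gene_frequencies``. A small ``multi_hit_rate`` adds a second distinct
    driver gene.
    """

    any_driver_rate: float = 42 / 85
    sex_log_or: float = math.log(3.83)
    eur_braf_log_odds: float = 4.0
    gene_frequencies: dict = field(default_factory=lambda: {
        "NRAS": 0.14, "KIT": 0.14, "BRAF": 0.13, "NF1": 0.09})
    multi_hit_rate: float = 1 / 92


@dataclass
class RecurrenceModel:
    """Logistic recurrence model on the log-odds scale."""

    intercept: float = math.log(0.372 / 0.628)   # QWT recurrence rate 37.2%
    log_or_driver: float = math.log(5.31)
    log_or_stage_advanced: float = 0.5


@dataclass
class SurvivalModel:
    """Exponential proportional-hazards death model with admin censoring."""

    log_hr_driver: float = math.log(3.19)
    log_hr_age: float = 0.0
    horizon_years: float = 8.0
    target_death_rate: float = 0.176     # cohort fraction dying in horizon
    recruitment_lag_mean: float = 2.01   # years between diagnosis and entry
    left_truncation: bool = False


@dataclass
class CnaModel:
    """Copy-number generative model.

    Bin-level log2 ratios follow the purity/ploidy mixture
    log2((rho*c + 2(1-rho)) / (rho*psi + 2(1-rho))) + Gaussian noise.
    ``burden_coupling`` ties per-sample aberration rates to the latent
    instability factor shared with the mutation rate, which induces the
    planted burden-TMB correlation.
    """

    arm_event_rate: float = 0.18
    focal_event_rate: float = 4.0        # mean focal events per sample
    focal_length_mb: tuple = (1.0, 10.0)
    purity_range: tuple = (0.35, 0.95)
    gof_range: tuple = (96.0, 100.0)
    wgd_prob: float = 0.23
    bin_noise_sd: float = 0.15
    mean_depth: float = 100.0
    homdel_genes: tuple = ("CDKN2A", "NF1")
    homdel_frac: float = 0.25
    bins_per_gene: int = 8
    flank_bins: int = 8
    burden_coupling: float = 1.4
    qc_fail_frac: float = 0.06


@dataclass
class SimulationConfig:
    """All planted parameters of the synthetic cohort.

    Defaults are the study conditions: cohort size 92, ancestry Dirichlet
    calibrated to medians (81%, 13.6%, 2.5%), driver frequencies
    (NRAS 14, KIT 14, BRAF 13, NF1 9)%, TMB mean 0.95/Mb, recurrence OR
    5.31, sex OR 3.83 and death HR 3.19.
    """

    n_patients: int = 92
    ancestry_alphas: tuple = (8.33, 1.66, 0.52)   # AMR, EUR, AFR
    female_frac: float = 54 / 92
    age_mean: float = 61.0
    age_sd: float = 13.0
    stage_advanced_frac: float = 56 / 92          # stage III/IV
    drivers: DriverModel = field(default_factory=DriverModel)
    tmb_mean_per_mb: float = 0.95
    # lognormal sd chosen so the TMB median/mean ratio matches 0.87/0.95
    tmb_log_sd: float = 0.42
    burden_tmb_latent_corr: float = 0.88   # calibrated: realized GCS-TMB r ~ 0.72
    capture_size_mb: float = 50.0
    caller_sensitivity: float = 0.92
    caller_fp_rate: float = 1.0      # mean false calls per caller per sample
    baseq_mean: float = 36.0
    baseq_sd: float = 4.0
    genes: GeneUniverse = field(default_factory=GeneUniverse.default)
    lineage_log2fc: float = 3.0
    module_log2fc: float = 2.0
    oncogene_log2fc: float = 2.0
    braf_shift: float = 0.6          # 0 = none, 1 = fully cutaneous program
    nb_dispersion: float = 0.15
    library_size_range: tuple = (8e5, 1.2e6)
    cluster_props: tuple = (14 / 44, 16 / 44, 14 / 44)
    recurrence: RecurrenceModel = field(default_factory=RecurrenceModel)
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    cna: CnaModel = field(default_factory=CnaModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if any(a <= 0 for a in self.ancestry_alphas):
            raise ValueError("ancestry concentrations must be positive")
        for r in (self.female_frac, self.drivers.any_driver_rate,
                  self.drivers.multi_hit_rate, self.cna.homdel_frac,
                  self.cna.wgd_prob, self.braf_shift):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not (0 < self.library_size_range[0] <= self.library_size_range[1]):
            raise ValueError("invalid library size range")
        self.genes.validate()


_STAGE_NAMES = {0: "early", 1: "advanced"}
_COMPONENTS = ("ancestry", "clinical", "drivers", "variants",
               "expression", "copynumber", "outcomes")


def child_seeds(master_seed: int) -> dict:
    """Per-component child RNG seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(_COMPONENTS))
    return {name: c for name, c in zip(_COMPONENTS, children)}


# ---------------------------------------------------------------- calibration


def _sex_carrier_rates(any_rate: float, log_or: float, female_frac: float):
    """Male/female carrier probabilities with the planted marginal OR."""
    orr = math.exp(log_or)

    def gap(pm):
        pf = orr * pm / (1 - pm + orr * pm)
        return female_frac * pf + (1 - female_frac) * pm - any_rate

    pm = optimize.brentq(gap, 1e-9, 1 - 1e-9)
    pf = orr * pm / (1 - pm + orr * pm)
    return pm, pf


def _braf_share_intercept(slope: float, target_share: float,
                          alphas: Sequence[float]) -> float:
    """Intercept of the carrier-conditional BRAF logit vs EUR fraction.

    EUR fraction is marginally Beta(a_EUR, a_total - a_EUR) under the
    Dirichlet; solve E[sigmoid(c0 + slope * EUR)] = target_share.
    """
    a = float(alphas[1])
    b = float(sum(alphas)) - a

    def mean_share(c0):
        f = lambda e: special.expit(c0 + slope * e) * \
            math.exp((a - 1) * math.log(e) + (b - 1) * math.log(1 - e)
                     - special.betaln(a, b))
        val, _ = integrate.quad(f, 1e-12, 1 - 1e-12, limit=200)
        return val - target_share

    return optimize.brentq(mean_share, -30, 30)


def _baseline_hazard(cfg: SimulationConfig) -> float:
    """Exponential baseline rate hitting the target death fraction."""
    sv = cfg.survival
    p_driver = cfg.drivers.any_driver_rate
    hr = math.exp(sv.log_hr_driver)
    T = sv.horizon_years

    def gap(h0):
        p_die = (p_driver * (1 - math.exp(-h0 * hr * T))
                 + (1 - p_driver) * (1 - math.exp(-h0 * T)))
        return p_die - sv.target_death_rate

    return optimize.brentq(gap, 1e-8, 10.0)


# ----------------------------------------------------------------- simulators


def simulate_ancestry(n: int, alphas: Sequence[float], seed) -> pd.DataFrame:
    """Per-patient (AMR, EUR, AFR) ancestry fractions from a Dirichlet."""
    if n < 1:
        raise ValueError("n must be >= 1")
    alphas = np.asarray(alphas, dtype=float)
    if np.any(alphas <= 0):
        raise ValueError("concentration parameters must be positive")
    rng = np.random.default_rng(seed)
    x = rng.dirichlet(alphas, size=n)
    return pd.DataFrame(x, columns=["AMR", "EUR", "AFR"])


def simulate_clinical(cfg: SimulationConfig, seed) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    n = cfg.n_patients
    female = rng.random(n) < cfg.female_frac
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 25, 98).round(1)
    stage_adv = rng.random(n) < cfg.stage_advanced_frac
    ulcer = rng.random(n) < 61 / 90
    site = rng.choice(["foot", "hand", "subungual"], size=n,
                      p=[76 / 92, 4 / 92, 12 / 92])
    return pd.DataFrame({
        "patient": [f"P{i:03d}" for i in range(1, n + 1)],
        "sex": np.where(female, "female", "male"),
        "age": age,
        "stage": np.where(stage_adv, "advanced", "early"),
        "ulceration": ulcer,
        "site": site,
    })


def simulate_drivers(ancestry: pd.DataFrame, cfg: SimulationConfig,
                     covariates: pd.DataFrame, seed) -> pd.DataFrame:
    """Per-patient driver genotype with planted sex and ancestry effects."""
    if len(ancestry) != len(covariates):
        raise ValueError("ancestry and covariate tables differ in length")
    dm = cfg.drivers
    rng = np.random.default_rng(seed)
    n = len(ancestry)
    female = (covariates["sex"].to_numpy() == "female")
    pm, pf = _sex_carrier_rates(dm.any_driver_rate, dm.sex_log_or,
                                cfg.female_frac)
    p_carrier = np.where(female, pf, pm)
    carrier = rng.random(n) < p_carrier

    braf_share = dm.gene_frequencies["BRAF"] / sum(dm.gene_frequencies.values())
    c0 = _braf_share_intercept(dm.eur_braf_log_odds, braf_share,
                               cfg.ancestry_alphas)
    eur = ancestry["EUR"].to_numpy()
    p_braf = special.expit(c0 + dm.eur_braf_log_odds * eur)

    other = [g for g in DRIVER_GENES if g != "BRAF"]
    w_other = np.array([dm.gene_frequencies[g] for g in other])
    w_other = w_other / w_other.sum()

    genes_hit = [[] for _ in range(n)]
    u_braf = rng.random(n)
    u_gene = rng.random(n)
    u_multi = rng.random(n)
    multi_pick = rng.integers(0, 3, size=n)
    for i in range(n):
        if not carrier[i]:
            continue
        if u_braf[i] < p_braf[i]:
            g = "BRAF"
        else:
            g = other[int(np.searchsorted(np.cumsum(w_other), u_gene[i]))]
        genes_hit[i].append(g)
        if u_multi[i] < dm.multi_hit_rate:
            pool = [x for x in DRIVER_GENES if x != g]
            genes_hit[i].append(pool[multi_pick[i] % len(pool)])

    def category(hits):
        if len(hits) == 0:
            return "QWT"
        if len(hits) > 1:
            return "multi-hit"
        return hits[0]

    out = pd.DataFrame({
        "patient": covariates["patient"].to_numpy(),
        "driver_category": [category(h) for h in genes_hit],
        "has_driver": [len(h) > 0 for h in genes_hit],
    })
    for g in DRIVER_GENES:
        out[g] = [g in h for h in genes_hit]
    return out


_PROTEIN_CHANGES = {
    "BRAF": "p.V600E", "NRAS": "p.Q61K", "KIT": "p.L576P", "NF1": "p.R1362*",
}
_BASES = np.array(list("ACGT"))
CALLERS = ("caveman", "mutect2", "varscan2")


def simulate_variants(drivers: pd.DataFrame, latent: np.ndarray,
                      cfg: SimulationConfig, seed,
                      no_noise: bool = False) -> tuple:
    """Per-caller somatic call lists.

    Each true variant is seen by each of the three callers independently
    with probability ``caller_sensitivity``, BRAF V600E included (so some
    occurrences survive only through the rescue rule); every caller adds
    Poisson false positives. ``no_noise`` makes every caller see every true
    variant with no false positives and high base quality.

    Returns (calls table, per-patient true mutation counts).
    """
    rng = np.random.default_rng(seed)
    n = len(drivers)
    lam = cfg.tmb_mean_per_mb * cfg.capture_size_mb * \
        np.exp(cfg.tmb_log_sd * latent - cfg.tmb_log_sd ** 2 / 2)
    n_passenger = rng.poisson(lam)

    rows = []
    truth_counts = np.zeros(n, dtype=int)
    arms = arm_model()
    chrom_len = arms.groupby("chrom", sort=False)["end"].max()

    def emit(patient, chrom, pos, ref, alt, gene, pchange, is_true):
        seen = np.ones(3, dtype=bool) if no_noise else \
            (rng.random(3) < cfg.caller_sensitivity)
        if is_true and not seen.any() and no_noise:
            seen[:] = True
        for k, caller in enumerate(CALLERS):
            if not seen[k]:
                continue
            bq = 45.0 if no_noise else float(
                np.clip(rng.normal(cfg.baseq_mean, cfg.baseq_sd), 2, 60))
            rows.append((patient, caller, chrom, int(pos), ref, alt,
                         bq, False, gene, pchange))

    for i, rec in drivers.iterrows():
        patient = rec["patient"]
        hits = [g for g in DRIVER_GENES if rec[g]]
        for g in hits:
            chrom, start, end = gene_interval(g)
            pos = (start + end) // 2
            emit(patient, chrom, pos, "A", "T", g, _PROTEIN_CHANGES[g], True)
        truth_counts[i] += len(hits)
        m = int(n_passenger[i])
        truth_counts[i] += m
        if m > 0:
            chroms = rng.choice(chrom_len.index.to_numpy(), size=m)
            for c in chroms:
                pos = int(rng.integers(1, chrom_len[c]))
                ref, alt = rng.choice(_BASES, size=2, replace=False)
                emit(patient, c, pos, ref, alt, None, None, True)
        if not no_noise:
            for caller in CALLERS:
                for _ in range(int(rng.poisson(cfg.caller_fp_rate))):
                    c = rng.choice(chrom_len.index.to_numpy())
                    pos = int(rng.integers(1, chrom_len[c]))
                    ref, alt = rng.choice(_BASES, size=2, replace=False)
                    bq = float(np.clip(rng.normal(cfg.baseq_mean - 4,
                                                  cfg.baseq_sd), 2, 60))
                    rows.append((patient, caller, c, pos, ref, alt,
                                 bq, bool(rng.random() < 0.2), None, None))

    calls = pd.DataFrame(rows, columns=[
        "sample", "caller", "chrom", "pos", "ref", "alt",
        "baseq", "strand_bias", "gene", "protein_change"])
    return calls, truth_counts


def simulate_expression(labels: pd.DataFrame, cfg: SimulationConfig, seed,
                        zero_noise: bool = False) -> pd.DataFrame:
    """Negative-binomial count matrix (genes x samples).

    log2 mean = per-gene baseline + lineage effect + cluster-module effect
    + oncogene-program effect + library-size offset. BRAF-flagged acral
    samples have their lineage effect shifted toward the cutaneous program
    by ``braf_shift``. With ``zero_noise`` the exact means are returned and
    library sizes are fixed at the range midpoint.
    """
    gu = cfg.genes
    gu.validate()
    if cfg.nb_dispersion <= 0 and not zero_noise:
        raise ValueError("dispersion must be > 0 unless zero_noise")
    genes = gu.all_genes
    gidx = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    n_genes, n_samples = len(genes), len(labels)

    base = rng.uniform(3.0, 9.0, size=n_genes)            # log2 baseline
    base[[gidx[g] for g in gu.housekeeping]] = 10.0       # stable, high
    log2mu = np.tile(base[:, None], (1, n_samples))

    acral_rows = [gidx[g] for g in gu.acral]
    cut_rows = [gidx[g] for g in gu.cutaneous]
    onc_rows = [gidx[g] for g in gu.oncogene]
    module_rows = [[gidx[g] for g in m] for m in gu.modules]

    for s in range(n_samples):
        rec = labels.iloc[s]
        braf = bool(rec.get("braf", False))
        origin = rec.get("origin", "acral")
        if origin == "acral":
            w = cfg.braf_shift if braf else 0.0
            log2mu[acral_rows, s] += cfg.lineage_log2fc * (1 - w)
            log2mu[cut_rows, s] += cfg.lineage_log2fc * w
        elif origin == "cutaneous":
            log2mu[cut_rows, s] += cfg.lineage_log2fc
        else:
            raise ValueError(f"unknown origin class {origin!r}")
        if braf:
            log2mu[onc_rows, s] += cfg.oncogene_log2fc
        cluster = rec.get("cluster", 0)
        if cluster and not (isinstance(cluster, float) and np.isnan(cluster)):
            log2mu[module_rows[int(cluster) - 1], s] += cfg.module_log2fc

    lo, hi = cfg.library_size_range
    if zero_noise:
        lib = np.full(n_samples, math.sqrt(lo * hi))
    else:
        lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    mu = 2.0 ** log2mu
    mu *= lib / mu.sum(axis=0)

    if zero_noise:
        counts = mu
    else:
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu)).astype(float)
    return pd.DataFrame(counts, index=genes,
                        columns=labels["sample"].to_numpy())


def _gene_bins(gene: str, cfg: CnaModel) -> pd.DataFrame:
    """0-based half-open bins tiling a gene window plus flanks."""
    chrom, start, end = gene_interval(gene)
    width = max((end - start + 1) // cfg.bins_per_gene, 1000)
    w_start = max(0, start - 1 - cfg.flank_bins * width)
    n_bins = cfg.bins_per_gene + 2 * cfg.flank_bins
    starts = w_start + width * np.arange(n_bins)
    return pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + width,
        "gene": [gene if (s < end and e > start - 1) else "flank"
                 for s, e in zip(starts, starts + width)],
        "window": gene,
    })


def expected_log2_ratio(cn, rho: float, psi: float):
    """Mixture-model log2 ratio for tumour copy number ``cn``."""
    cn = np.asarray(cn, dtype=float)
    denom = rho * psi + 2 * (1 - rho)
    num = rho * cn + 2 * (1 - rho)
    with np.errstate(divide="ignore"):
        out = np.log2(num / denom)
    return np.where(np.isfinite(out), out, -5.0)


def simulate_copy_number(cfg: SimulationConfig, seed,
                         n_samples: Optional[int] = None,
                         latent: Optional[np.ndarray] = None,
                         sample_ids: Optional[Sequence[str]] = None) -> dict:
    """Segments, bin-level log2 ratios, purity/ploidy and planted truth.

    Integer allele-specific copy numbers are drawn per arm (occasional
    whole-arm gains/losses) with focal events layered on top; planted
    homozygous deletions zero out the configured genes in a random subset
    of samples. Bin ratios follow the purity/ploidy mixture model with
    Gaussian noise.
    """
    cm = cfg.cna
    rng = np.random.default_rng(seed)
    n = n_samples if n_samples is not None else cfg.n_patients
    if latent is None:
        latent = rng.standard_normal(n)
    latent = np.asarray(latent, dtype=float)
    if sample_ids is None:
        sample_ids = [f"P{i:03d}" for i in range(1, n + 1)]
    arms = arm_model()

    rho = rng.uniform(*cm.purity_range, size=n)
    wgd = rng.random(n) < cm.wgd_prob
    gof = rng.uniform(*cm.gof_range, size=n)
    rho_b = np.clip(rho + rng.normal(0, 0.02, n), 0.05, 1.0)
    qc_fail = rng.random(n) < cm.qc_fail_frac
    rho_b[qc_fail] = 1.0
    rho_adj = rho.copy()
    rho_adj[qc_fail] = 0.12

    homdel = {}
    seg_rows, bin_rows, pp_rows = [], [], []
    arm_p = special.expit(special.logit(cm.arm_event_rate)
                          + cm.burden_coupling * latent)
    focal_lam = cm.focal_event_rate * np.exp(
        cm.burden_coupling * latent - cm.burden_coupling ** 2 / 2)

    for i, sid in enumerate(sample_ids):
        base_cn = 4 if wgd[i] else 2
        psi_num, psi_den = 0.0, 0.0
        sample_segments = []
        for _, armrec in arms.iterrows():
            cn = base_cn
            if rng.random() < arm_p[i]:
                cn = max(0, cn + int(rng.choice([-1, 1])))
            sample_segments.append([armrec.chrom, int(armrec.start),
                                    int(armrec.end), cn])
        # focal events split an arm segment
        n_focal = int(rng.poisson(focal_lam[i]))
        for _ in range(n_focal):
            j = int(rng.integers(0, len(sample_segments)))
            chrom, s0, e0, cn0 = sample_segments[j]
            flen = int(rng.uniform(*cm.focal_length_mb) * 1e6)
            if e0 - s0 < 3 * flen:
                continue
            fs = int(rng.integers(s0, e0 - flen))
            delta = int(rng.choice([-2, -1, 1, 2]))
            fcn = max(0, cn0 + delta)
            sample_segments[j] = [chrom, s0, fs - 1, cn0]
            sample_segments.append([chrom, fs, fs + flen - 1, fcn])
            sample_segments.append([chrom, fs + flen, e0, cn0])
        # planted homozygous deletions
        genes_del = []
        for g in cm.homdel_genes:
            if rng.random() < cm.homdel_frac:
                genes_del.append(g)
                chrom, gs, ge = gene_interval(g)
                new_segs = []
                for chrom2, s0, e0, cn0 in sample_segments:
                    if chrom2 == chrom and s0 <= ge and e0 >= gs:
                        if s0 < gs:
                            new_segs.append([chrom2, s0, gs - 1, cn0])
                        new_segs.append([chrom2, max(s0, gs),
                                         min(e0, ge), 0])
                        if e0 > ge:
                            new_segs.append([chrom2, ge + 1, e0, cn0])
                    else:
                        new_segs.append([chrom2, s0, e0, cn0])
                sample_segments = new_segs
        if genes_del:
            homdel[sid] = genes_del

        for chrom, s0, e0, cn in sample_segments:
            if e0 < s0:
                continue
            n_major = int(math.ceil(cn / 2))
            seg_rows.append((sid, chrom, s0, e0, n_major, cn - n_major))
            psi_num += cn * (e0 - s0 + 1)
            psi_den += (e0 - s0 + 1)
        psi = psi_num / psi_den

        seg_df = pd.DataFrame(
            [r[1:] for r in seg_rows if r[0] == sid],
            columns=["chrom", "start", "end", "nMajor", "nMinor"])
        for g in cm.homdel_genes:
            bins = _gene_bins(g, cm).copy()
            cn_bin = np.full(len(bins), base_cn, dtype=float)
            for _, seg in seg_df[seg_df.chrom == bins.chrom.iloc[0]].iterrows():
                total = seg.nMajor + seg.nMinor
                ov = (bins.start < seg.end) & (bins.end > seg.start - 1)
                mid = (bins.start + bins.end) / 2
                ov &= (mid >= seg.start - 1) & (mid < seg.end)
                cn_bin[ov.to_numpy()] = total
            mu = expected_log2_ratio(cn_bin, rho[i], psi)
            noise = rng.normal(0, cm.bin_noise_sd, size=len(bins))
            depth_scale = (rho[i] * cn_bin + 2 * (1 - rho[i])) / \
                (rho[i] * psi + 2 * (1 - rho[i]))
            cov = rng.poisson(np.maximum(cm.mean_depth * depth_scale, 1e-9))
            bins["sample"] = sid
            bins["log2"] = mu + noise
            bins["coverage"] = cov
            bin_rows.append(bins)

        pp_rows.append((sid, float(rho_adj[i]), float(rho_b[i]), float(psi),
                        float(gof[i]), bool(wgd[i])))

    segments = pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "start", "end",
                           "nMajor", "nMinor"])
    bins_df = pd.concat(bin_rows, ignore_index=True)[
        ["sample", "chrom", "start", "end", "log2", "coverage",
         "gene", "window"]]
    purity_ploidy = pd.DataFrame(
        pp_rows, columns=["sample", "purity_a", "purity_b", "ploidy",
                          "goodness_of_fit", "wgd"])
    truth = {"homdel": homdel, "qc_fail": [sample_ids[i] for i in
                                           np.flatnonzero(qc_fail)],
             "purity_true": {sid: float(r) for sid, r in
                             zip(sample_ids, rho)}}
    return {"segments": segments, "bins": bins_df,
            "purity_ploidy": purity_ploidy, "truth": truth}


def simulate_outcomes(covariates: pd.DataFrame, cfg: SimulationConfig,
                      seed) -> pd.DataFrame:
    """Recurrence and survival columns from the planted models."""
    if "has_driver" not in covariates:
        raise ValueError("covariates must include a 'has_driver' column")
    rng = np.random.default_rng(seed)
    n = len(covariates)
    rm, sv = cfg.recurrence, cfg.survival
    driver = covariates["has_driver"].to_numpy().astype(float)
    stage_adv = (covariates["stage"].to_numpy() == "advanced").astype(float) \
        if "stage" in covariates else np.zeros(n)
    age = covariates["age"].to_numpy() if "age" in covariates \
        else np.full(n, cfg.age_mean)

    eta = (rm.intercept + rm.log_or_driver * driver
           + rm.log_or_stage_advanced * (stage_adv - cfg.stage_advanced_frac))
    recur = rng.random(n) < special.expit(eta)
    t_rec = np.where(recur,
                     rng.uniform(0.1, 0.6 * sv.horizon_years, n),
                     sv.horizon_years)

    h0 = _baseline_hazard(cfg)
    loghr = sv.log_hr_driver * driver + sv.log_hr_age * (age - cfg.age_mean)
    t_death = rng.exponential(1.0 / (h0 * np.exp(loghr)))
    death = t_death <= sv.horizon_years
    t_obs = np.minimum(t_death, sv.horizon_years)
    lag = rng.exponential(sv.recruitment_lag_mean, n)

    return pd.DataFrame({
        "patient": covariates["patient"].to_numpy(),
        "recurrence": recur.astype(int),
        "time_to_recurrence": np.round(t_rec, 4),
        "death": death.astype(int),
        "time_to_death": np.round(t_obs, 4),
        "recruitment_lag": np.round(lag, 4),
    })


# --------------------------------------------------------------------- cohort


@dataclass
class SyntheticCohort:
    """Bundled synthetic cohort with its planted ground truth."""

    config: SimulationConfig
    expression: pd.DataFrame          # genes x samples counts
    labels: pd.DataFrame              # per-sample origin/cluster/braf
    calls: pd.DataFrame               # per-caller variant calls
    segments: pd.DataFrame
    bins: pd.DataFrame
    purity_ploidy: pd.DataFrame
    clinical: pd.DataFrame
    truth: dict

    def validate(self) -> None:
        pats = set(self.clinical["patient"])
        for df, col in ((self.calls, "sample"), (self.segments, "sample"),
                        (self.purity_ploidy, "sample")):
            extra = set(df[col]) - pats
            if extra:
                raise ValueError(f"unknown sample ids: {sorted(extra)[:5]}")
        anc = self.clinical[["AMR", "EUR", "AFR"]].to_numpy()
        if np.max(np.abs(anc.sum(axis=1) - 1)) > 1e-9:
            raise ValueError("ancestry fractions must sum to 1")
        for col in ("time_to_recurrence", "time_to_death"):
            if np.any(self.clinical[col] < 0):
                raise ValueError("negative follow-up time")


def simulate_cohort(cfg: Optional[SimulationConfig] = None,
                    no_variant_noise: bool = False) -> SyntheticCohort:
    """Generate a complete cohort under the planted study conditions."""
    cfg = cfg if cfg is not None else SimulationConfig()
    cfg.validate()
    seeds = child_seeds(cfg.seed)
    n = cfg.n_patients

    ancestry = simulate_ancestry(n, cfg.ancestry_alphas, seeds["ancestry"])
    clinical = simulate_clinical(cfg, seeds["clinical"])
    drivers = simulate_drivers(ancestry, cfg, clinical, seeds["drivers"])

    rng_lat = np.random.default_rng(seeds["variants"])
    z = rng_lat.standard_normal(n)
    r0 = math.sqrt(cfg.burden_tmb_latent_corr)
    mix = math.sqrt(1 - cfg.burden_tmb_latent_corr)
    latent_tmb = r0 * z + mix * rng_lat.standard_normal(n)
    latent_cna = r0 * z + mix * rng_lat.standard_normal(n)
    calls, true_counts = simulate_variants(
        drivers, latent_tmb, cfg, rng_lat, no_noise=no_variant_noise)

    props = np.asarray(cfg.cluster_props, dtype=float)
    rng_expr = np.random.default_rng(seeds["expression"])
    clusters = rng_expr.choice([1, 2, 3], size=n, p=props / props.sum())
    labels = pd.DataFrame({
        "sample": clinical["patient"].to_numpy(),
        "origin": "acral",
        "cluster": clusters,
        "braf": drivers["BRAF"].to_numpy(),
    })
    expression = simulate_expression(labels, cfg, rng_expr)

    cn = simulate_copy_number(cfg, seeds["copynumber"], n_samples=n,
                              latent=latent_cna,
                              sample_ids=clinical["patient"].tolist())

    cov = clinical.join(drivers.set_index("patient"), on="patient")
    outcomes = simulate_outcomes(cov, cfg, seeds["outcomes"])

    clinical_full = (clinical
                     .join(ancestry)
                     .join(drivers.set_index("patient"), on="patient")
                     .join(outcomes.set_index("patient"), on="patient"))

    truth = {
        "config": _config_dict(cfg),
        "true_mutation_counts": {p: int(c) for p, c in
                                 zip(clinical["patient"], true_counts)},
        "clusters": {s: int(c) for s, c in zip(labels["sample"],
                                               labels["cluster"])},
        "driver_category": dict(zip(drivers["patient"],
                                    drivers["driver_category"])),
        "latent_instability": {p: float(v) for p, v in
                               zip(clinical["patient"], z)},
        **cn["truth"],
    }
    cohort = SyntheticCohort(
        config=cfg, expression=expression, labels=labels, calls=calls,
        segments=cn["segments"], bins=cn["bins"],
        purity_ploidy=cn["purity_ploidy"], clinical=clinical_full,
        truth=truth,
    )
    cohort.validate()
    return cohort


def _config_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    return json.loads(json.dumps(d, default=str))


# ------------------------------------------------------------------------ I/O

_VCF_HEADER = """##fileformat=VCFv4.2
##source=acrotype-synthetic
##INFO=<ID=BQ,Number=1,Type=Float,Description="Mean base quality (Phred)">
##INFO=<ID=SB,Number=0,Type=Flag,Description="Strand bias suspected">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=AA,Number=1,Type=String,Description="Protein change (HGVS p.)">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _write_vcf(path: Path, calls: pd.DataFrame) -> None:
    from .genome import _CHROMS
    contigs = "".join(f"##contig=<ID={c},length={l}>\n"
                      for c, l, _ in _CHROMS)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs))
        calls = calls.sort_values(["chrom", "pos", "ref", "alt"],
                                  key=lambda s: s.map(_chrom_key)
                                  if s.name == "chrom" else s)
        for _, r in calls.iterrows():
            info = [f"BQ={r.baseq:.1f}"]
            if r.strand_bias:
                info.append("SB")
            if isinstance(r.gene, str):
                info.append(f"GENE={r.gene}")
            if isinstance(r.protein_change, str):
                info.append(f"AA={r.protein_change}")
            fh.write(f"{r.chrom}\t{int(r.pos)}\t.\t{r.ref}\t{r.alt}\t.\t"
                     f"PASS\t{';'.join(info)}\n")


def _chrom_key(c):
    try:
        return int(c)
    except (TypeError, ValueError):
        return 100


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write the cohort as plain-text files; returns a checksum manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    files = {}

    cohort.expression.to_csv(d / "expression.tsv", sep="\t",
                             index_label="gene")
    files["expression.tsv"] = d / "expression.tsv"
    cohort.labels.to_csv(d / "labels.tsv", sep="\t", index=False)
    files["labels.tsv"] = d / "labels.tsv"
    cohort.segments.to_csv(d / "segments.tsv", sep="\t", index=False)
    files["segments.tsv"] = d / "segments.tsv"
    cohort.bins.to_csv(d / "bins.tsv", sep="\t", index=False)
    files["bins.tsv"] = d / "bins.tsv"
    cohort.purity_ploidy.to_csv(d / "purity_ploidy.tsv", sep="\t",
                                index=False)
    files["purity_ploidy.tsv"] = d / "purity_ploidy.tsv"
    cohort.clinical.to_csv(d / "clinical.tsv", sep="\t", index=False)
    files["clinical.tsv"] = d / "clinical.tsv"

    vcf_dir = d / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for (sample, caller), grp in cohort.calls.groupby(["sample", "caller"]):
        name = f"{sample}.{caller}.vcf"
        _write_vcf(vcf_dir / name, grp)
        files[f"vcf/{name}"] = vcf_dir / name

    with open(d / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    files["truth.json"] = d / "truth.json"

    manifest = {}
    for rel, path in sorted(files.items()):
        h = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest[rel] = h
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_cohort(directory) -> dict:
    """Read back the plain-text cohort files (expression, tables, truth)."""
    d = Path(directory)
    out = {
        "expression": pd.read_csv(d / "expression.tsv", sep="\t",
                                  index_col="gene"),
        "labels": pd.read_csv(d / "labels.tsv", sep="\t"),
        "segments": pd.read_csv(d / "segments.tsv", sep="\t",
                                dtype={"chrom": str}),
        "bins": pd.read_csv(d / "bins.tsv", sep="\t", dtype={"chrom": str}),
        "purity_ploidy": pd.read_csv(d / "purity_ploidy.tsv", sep="\t"),
        "clinical": pd.read_csv(d / "clinical.tsv", sep="\t"),
    }
    with open(d / "truth.json") as fh:
        out["truth"] = json.load(fh)
    return out
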