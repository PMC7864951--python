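"""Synthetic cohort generator for the sperm-methylome ageing analysis.

Generates, from one seed, everything the pipeline consumes plus the ground
truth needed for recovery tests:

* a probe manifest laid out per chromosome as interleaved co-methylation
  regions and isolated probes, and a probes x subjects beta matrix with a
  bimodal sperm-like baseline (most CpGs near 0.05 or 0.95 methylation),
  within-region correlation from a shared subject-level latent factor, and
  planted linear age effects on the M (log2-odds) scale;
* couple phenotypes: male age, BMI, smoking, infertility, female age coupled
  to male age, oocyte counts (truncated negative binomial), binomial
  fertilization / embryo-quality counts with a logistic age effect, and a
  Bernoulli live birth;
* mediator regions whose realized mean M-value enters the fertilization
  model, so the indirect age path alpha_k * beta_k is real, not notional;
* annotation tracks (CpG context partition, genic features, nucleosome
  retention, TFBS) and a TSS table with genes placed within the assignment
  window of every mediator region.

Planted per-5-year beta-scale effects are calibrated numerically: the
M-scale slope for a probe is chosen so that the linear regression of its
noise-free beta trajectory on age over the cohort's age range equals the
configured drift, which keeps the planted effect meaningful even where the
logit curve bends near the (0,1) boundary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .core import MethylomeDataset, ProbeManifest, beta_to_m, m_to_beta
from .outcomes import CoupleRecord

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_cohort",
    "true_estimands",
    "generate_annotations",
    "write_cohort",
]

LN2 = np.log(2.0)

# fertilization OR 0.92/yr split 64:36 between the mediated and direct path
_TOTAL_FERT = float(np.log(0.92))
_DEFAULT_DIRECT = 0.36 * _TOTAL_FERT
_DEFAULT_ALPHA = (0.06, 0.06, 0.06, 0.06)  # M-units per year
_DEFAULT_BETA = tuple(0.64 * _TOTAL_FERT / (4 * 0.06) for _ in range(4))

# one layout cycle: two clustered regions among isolated probes
_DEFAULT_LAYOUT = (
    (3, 300, 3000),
    (1, 0, 3000), (1, 0, 3000), (1, 0, 3000), (1, 0, 3000), (1, 0, 3000),
    (2, 500, 3000),
    (1, 0, 3000), (1, 0, 3000), (1, 0, 3000), (1, 0, 3000), (1, 0, 3000),
    (4, 250, 3000),
    (1, 0, 3000), (1, 0, 3000), (1, 0, 3000), (1, 0, 3000), (1, 0, 3000),
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the source study's structure: 100 couples, male age
    21-45 y, oocytes 15.1 +/- 8.0, smoking 8.5 %, male-factor infertility
    23.4 %, live birth 31.9 %, 91 % of age CpGs hypermethylating with
    per-5-year drifts of 0.2-11.7 % methylation, 57 % of age regions
    hypermethylating, and a fertilization age effect OR 0.92/yr of which
    64 % flows through four mediator regions.
    """

    n_couples: int = 100
    n_probes: int = 20_000
    n_chromosomes: int = 10
    chrom_length: int = 60_000_000
    region_layout: tuple = _DEFAULT_LAYOUT
    age_range: tuple[float, float] = (21.0, 45.0)

    # per-CpG age effects
    n_age_cpgs: int = 600
    effect_per_5yr_range: tuple[float, float] = (0.2, 11.7)  # percent methylation
    frac_hyper: float = 0.91

    # region-level age effects
    n_age_regions: int = 120
    frac_hyper_regions: float = 0.57

    # mediation truth (fertilization outcome)
    n_true_mediators: int = 4
    alpha_k: tuple = _DEFAULT_ALPHA  # age -> mediator, M-units / year
    beta_k: tuple = _DEFAULT_BETA    # mediator -> outcome, log-odds / M-unit
    b_age_direct: float = _DEFAULT_DIRECT  # log-odds / year, fertilization
    b_age_livebirth: float = float(np.log(0.80))

    # outcome baselines (cohort-mean success rates)
    fert_rate: float = 0.60
    day3_rate: float = 0.57
    day5_rate: float = 0.10
    day5_tq_rate: float = 0.30
    live_birth_rate: float = 0.319
    b_age_day3: float = float(np.log(0.94))
    b_age_day5: float = float(np.log(0.85))
    b_age_day5_tq: float = float(np.log(0.93))

    # oocytes: negative binomial (mean, dispersion k; var = mu + mu^2/k), >= 1
    oocyte_mean: float = 15.1
    oocyte_dispersion: float = 4.66

    # covariates
    smoking_prev: float = 0.085
    infertile_prev: float = 0.234
    bmi_mean: float = 27.5
    bmi_sd: float = 4.5
    female_age_offset: float = -1.5
    female_age_sd: float = 3.0

    # methylation noise model
    noise_sd: float = 0.30          # M-units
    within_region_rho: float = 0.6  # shared-factor fraction of noise variance
    baseline_mix: tuple[float, float] = (0.45, 0.55)  # weight near 0.05 / 0.95

    # annotation emulation
    tss_frac: float = 0.6  # fraction of non-mediator regions given a nearby TSS

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_couples < 2 or self.n_probes < 1 or self.n_chromosomes < 1:
            raise ValueError("n_couples, n_probes, n_chromosomes must be positive")
        for name in ("frac_hyper", "frac_hyper_regions", "smoking_prev",
                     "infertile_prev", "tss_frac", "within_region_rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.effect_per_5yr_range
        if not 0 < lo <= hi:
            raise ValueError("effect_per_5yr_range must be positive and ordered")
        if any(size < 1 for size, _, _ in self.region_layout):
            raise ValueError("region sizes must be >= 1")
        if len(self.alpha_k) != self.n_true_mediators or len(self.beta_k) != self.n_true_mediators:
            raise ValueError("alpha_k / beta_k length must equal n_true_mediators")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw = {k: (tuple(tuple(x) if isinstance(x, list) else x for x in v)
                   if isinstance(v, list) else v) for k, v in raw.items()}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d = {k: ([list(x) if isinstance(x, tuple) else x for x in v]
                 if isinstance(v, tuple) else v) for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class SyntheticTruth:
    """Ground truth: what was planted, where, and the implied estimands."""

    planted_cpg_ids: list[str]
    planted_cpg_effects: dict[str, float]  # per-5-yr percent methylation drift
    planted_region_ids: list[str]
    planted_region_effects: dict[str, float]
    region_probes: dict[str, list[str]]  # every layout region of >= 2 probes
    mediator_region_ids: list[str]
    alpha_k: dict[str, float]
    beta_k: dict[str, float]
    b_age_direct: float

    @property
    def nie_log(self) -> float:
        return float(sum(self.alpha_k[r] * self.beta_k[r] for r in self.mediator_region_ids))

    @property
    def total_log(self) -> float:
        return self.nie_log + self.b_age_direct

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["nie_log"] = self.nie_log
        d["total_log"] = self.total_log
        Path(path).write_text(json.dumps(d, indent=2))


def true_estimands(truth: SyntheticTruth, age_variance: float | None = None):
    """True (NIE odds ratio per year, mediation proportion) implied by truth.

    NIE_OR = exp(sum_k alpha_k beta_k); proportion = NIE / (NIE + direct) on
    the log-odds scale.  Both are per-year quantities, so `age_variance` is
    accepted for interface compatibility but does not enter the formulas.
    """
    nie = truth.nie_log
    total = nie + truth.b_age_direct
    if abs(total) < 1e-12:
        raise ZeroDivisionError("total effect is zero; mediation proportion undefined")
    return float(np.exp(nie)), float(nie / total)


# --------------------------------------------------------------------------
# probe layout


def _layout_probes(cfg: SimulationConfig):
    """Place probes chromosome by chromosome following the region layout.

    Returns (manifest frame, list of (region_probe_indices) for layout
    regions with >= 2 probes)."""
    per_chrom = int(np.ceil(cfg.n_probes / cfg.n_chromosomes))
    rows, regions = [], []
    idx = 0
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        pos = 10_000
        placed = 0
        li = 0
        while placed < per_chrom and idx < cfg.n_probes:
            size, intra, inter = cfg.region_layout[li % len(cfg.region_layout)]
            li += 1
            members = []
            for k in range(size):
                if placed >= per_chrom or idx >= cfg.n_probes:
                    break
                if pos > cfg.chrom_length:
                    raise ValueError(f"layout exceeds chromosome capacity on {chrom}")
                rows.append({"probe_id": f"cg{idx:08d}", "chrom": chrom, "pos": pos})
                members.append(idx)
                idx += 1
                placed += 1
                pos += intra if k < size - 1 else 0
            pos += inter
            if len(members) >= 2:
                regions.append(members)
    return pd.DataFrame(rows), regions


def _calibrated_m_slope(beta0: float, drift_per_5yr_pct: float, ages_grid: np.ndarray) -> float:
    """M-scale slope whose noise-free beta trajectory regresses on age with
    the requested per-year beta slope over the cohort age range."""
    target = drift_per_5yr_pct / 100.0 / 5.0  # beta units per year
    m0 = beta_to_m(beta0)
    a = ages_grid - ages_grid.mean()
    var_a = float(np.mean(a**2))

    def realized(slope_m: float) -> float:
        b = m_to_beta(m0 + slope_m * a)
        return float(np.mean(a * (b - b.mean())) / var_a)

    # linear-scale initial bracket; the realized slope is monotone in slope_m
    s0 = target / (LN2 * beta0 * (1 - beta0))
    lo, hi = 0.0, abs(s0) * 20 + 1e-3
    sign = np.sign(target)
    f = lambda s: realized(sign * s) - sign * target
    try:
        s = brentq(f, lo, hi, xtol=1e-10)
    except ValueError:
        s = abs(s0)  # saturated; fall back to the tangent slope
    return float(sign * s)


# --------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(cfg: SimulationConfig):
    """Generate (MethylomeDataset, couples, SyntheticTruth) from one seed.

    All randomness flows from ``cfg.seed`` through named substreams, so the
    output is byte-identical across runs with the same config.
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_pheno, rng_base, rng_plant, rng_noise, rng_out, _rng_annot = (
        np.random.default_rng(s) for s in streams
    )

    manifest_df, layout_regions = _layout_probes(cfg)
    n_probes = len(manifest_df)
    n = cfg.n_couples

    # ---- phenotypes ----
    age = rng_pheno.uniform(cfg.age_range[0], cfg.age_range[1], n)
    bmi = rng_pheno.normal(cfg.bmi_mean, cfg.bmi_sd, n).clip(16, 50)
    smoking = rng_pheno.random(n) < cfg.smoking_prev
    infertile = rng_pheno.random(n) < cfg.infertile_prev
    female_age = (age + cfg.female_age_offset
                  + rng_pheno.normal(0, cfg.female_age_sd, n)).clip(18, 60)
    age_c = age - age.mean()

    # ---- baselines ----
    low = rng_base.random(n_probes) < cfg.baseline_mix[0] / sum(cfg.baseline_mix)
    base_beta = np.where(
        low,
        np.clip(rng_base.normal(0.05, 0.02, n_probes), 0.005, 0.2),
        np.clip(rng_base.normal(0.95, 0.02, n_probes), 0.8, 0.995),
    )

    # ---- choose planted sites/regions ----
    region_ids = [f"true_region_{i:05d}" for i in range(len(layout_regions))]
    region_probe_ids = {
        rid: [f"cg{j:08d}" for j in members]
        for rid, members in zip(region_ids, layout_regions)
    }
    in_region = np.zeros(n_probes, bool)
    for members in layout_regions:
        in_region[members] = True
    if cfg.n_true_mediators > len(layout_regions):
        raise ValueError("n_true_mediators exceeds number of layout regions")
    region_order = rng_plant.permutation(len(layout_regions))
    mediator_idx = region_order[: cfg.n_true_mediators]
    n_age_regions = min(cfg.n_age_regions, len(layout_regions) - cfg.n_true_mediators)
    age_region_idx = region_order[cfg.n_true_mediators: cfg.n_true_mediators + n_age_regions]

    singles = np.flatnonzero(~in_region)
    if cfg.n_age_cpgs > len(singles):
        raise ValueError("n_age_cpgs exceeds the number of isolated probes")
    planted_cpg_idx = rng_plant.choice(singles, size=cfg.n_age_cpgs, replace=False)

    ages_grid = np.linspace(cfg.age_range[0], cfg.age_range[1], 101)
    lo_e, hi_e = cfg.effect_per_5yr_range
    slope_m = np.zeros(n_probes)

    def loguniform(size):
        return np.exp(rng_plant.uniform(np.log(lo_e), np.log(hi_e), size))

    # planted individual CpGs: intermediate baselines, log-uniform drifts
    cpg_effects = loguniform(cfg.n_age_cpgs)
    cpg_sign = np.where(rng_plant.random(cfg.n_age_cpgs) < cfg.frac_hyper, 1.0, -1.0)
    base_beta[planted_cpg_idx] = rng_plant.uniform(0.25, 0.75, cfg.n_age_cpgs)
    for j, eff, s in zip(planted_cpg_idx, cpg_effects, cpg_sign):
        slope_m[j] = _calibrated_m_slope(base_beta[j], s * eff, ages_grid)

    # planted age regions: one drift shared by all member probes
    region_effects: dict[str, float] = {}
    reg_eff = loguniform(len(age_region_idx))
    reg_sign = np.where(rng_plant.random(len(age_region_idx)) < cfg.frac_hyper_regions, 1.0, -1.0)
    for ridx, eff, s in zip(age_region_idx, reg_eff, reg_sign):
        members = layout_regions[ridx]
        b0 = float(rng_plant.uniform(0.25, 0.75))
        base_beta[members] = b0 + rng_plant.uniform(-0.03, 0.03, len(members))
        region_effects[region_ids[ridx]] = float(s * eff)
        for j in members:
            slope_m[j] = _calibrated_m_slope(base_beta[j], s * eff, ages_grid)

    # mediator regions: slope alpha_k in M-units/yr for every member probe
    alpha_map, beta_map = {}, {}
    for k, ridx in enumerate(mediator_idx):
        members = layout_regions[ridx]
        base_beta[members] = rng_plant.uniform(0.35, 0.65, len(members))
        slope_m[members] = cfg.alpha_k[k]
        rid = region_ids[ridx]
        alpha_map[rid] = float(cfg.alpha_k[k])
        beta_map[rid] = float(cfg.beta_k[k])

    # ---- methylation matrix on the M scale ----
    M = beta_to_m(base_beta)[:, None] + slope_m[:, None] * age_c[None, :]
    noise = rng_noise.normal(0.0, 1.0, (n_probes, n))
    rho = cfg.within_region_rho
    for members in layout_regions:
        shared = rng_noise.normal(0.0, 1.0, n)
        noise[members] = np.sqrt(rho) * shared[None, :] + np.sqrt(1 - rho) * noise[members]
    M = M + cfg.noise_sd * noise
    beta = np.clip(m_to_beta(M), 1e-6, 1 - 1e-6)

    # ---- outcomes ----
    # mediator values are the *realized* region-mean M, so the indirect path
    # is carried by the data, not just by the generating parameters
    med_values = np.stack(
        [beta_to_m(beta[layout_regions[ridx]]).mean(axis=0) for ridx in mediator_idx]
    ) if len(mediator_idx) else np.zeros((0, n))
    med_centered = med_values - med_values.mean(axis=1, keepdims=True)

    def logit(p):
        return float(np.log(p / (1 - p)))

    bmi_c = bmi - bmi.mean()
    fem_c = female_age - female_age.mean()
    cov_lp = -0.01 * bmi_c - 0.10 * smoking - 0.20 * infertile - 0.02 * fem_c

    eta_f = logit(cfg.fert_rate) + cfg.b_age_direct * age_c + cov_lp
    for k in range(len(mediator_idx)):
        eta_f = eta_f + cfg.beta_k[k] * med_centered[k]
    p_fert = 1 / (1 + np.exp(-eta_f))

    # oocytes: negative binomial truncated at >= 1
    k_disp = cfg.oocyte_dispersion
    lam = rng_out.gamma(k_disp, cfg.oocyte_mean / k_disp, n)
    oocytes = np.maximum(rng_out.poisson(lam), 1)
    fertilized = rng_out.binomial(oocytes, p_fert)

    def rate_model(base_rate, b_age):
        eta = logit(base_rate) + b_age * age_c + cov_lp
        return 1 / (1 + np.exp(-eta))

    day3 = rng_out.binomial(fertilized, rate_model(cfg.day3_rate, cfg.b_age_day3))
    day5 = rng_out.binomial(fertilized, rate_model(cfg.day5_rate, cfg.b_age_day5))
    day5_tq = rng_out.binomial(fertilized, rate_model(cfg.day5_tq_rate, cfg.b_age_day5_tq))
    p_live = rate_model(cfg.live_birth_rate, cfg.b_age_livebirth)
    live = rng_out.random(n) < p_live

    couples = [
        CoupleRecord(
            couple_id=f"couple_{i:04d}",
            male_age=float(age[i]),
            male_bmi=float(bmi[i]),
            male_smoking=bool(smoking[i]),
            male_infertile=bool(infertile[i]),
            female_age=float(female_age[i]),
            n_oocytes=int(oocytes[i]),
            n_fertilized=int(fertilized[i]),
            n_day3_hq=int(day3[i]),
            n_day5_hq=int(day5[i]),
            n_day5_tq=int(day5_tq[i]),
            live_birth=bool(live[i]),
        )
        for i in range(n)
    ]

    subject_ids = [c.couple_id for c in couples]
    ds = MethylomeDataset(ProbeManifest(manifest_df), beta, subject_ids)

    truth = SyntheticTruth(
        planted_cpg_ids=[f"cg{j:08d}" for j in planted_cpg_idx],
        planted_cpg_effects={
            f"cg{j:08d}": float(s * e)
            for j, e, s in zip(planted_cpg_idx, cpg_effects, cpg_sign)
        },
        planted_region_ids=sorted(region_effects) + sorted(alpha_map),
        planted_region_effects=region_effects,
        region_probes=region_probe_ids,
        mediator_region_ids=sorted(alpha_map),
        alpha_k=alpha_map,
        beta_k=beta_map,
        b_age_direct=float(cfg.b_age_direct),
    )
    return ds, couples, truth


# --------------------------------------------------------------------------
# annotation emulation


def _complement(intervals: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    out, cur = [], 0
    for s, e in sorted(intervals):
        s = max(s, 0)
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < length:
        out.append((cur, length))
    return out


def generate_annotations(cfg: SimulationConfig, ds: MethylomeDataset, truth: SyntheticTruth):
    """Emulated annotation inputs: CpG-context partition (island / shore /
    shelf / open sea), genic tracks, nucleosome retention, two TFBS tracks,
    and a TSS table.

    Every mediator region receives a gene TSS within the 1500 bp assignment
    window (the mediation stage restricts to gene-assigned regions); a
    `tss_frac` share of the other layout regions do as well.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(6)[5])
    man = ds.manifest.table
    chrom_span = {c: int(sub["pos"].max()) + 20_000 for c, sub in man.groupby("chrom")}

    region_pos = {}
    for rid, probes in truth.region_probes.items():
        sub = man[man["probe_id"].isin(probes)]
        region_pos[rid] = (str(sub["chrom"].iloc[0]), int(sub["pos"].min()), int(sub["pos"].max()))

    # TSS table
    tss_rows = []
    gene_i = 0
    mediators = set(truth.mediator_region_ids)
    for rid, (chrom, start, end) in sorted(region_pos.items()):
        if rid in mediators or rng.random() < cfg.tss_frac:
            offset = int(rng.integers(-1200, 1200))
            tss_rows.append({"gene_id": f"GENE{gene_i:05d}", "chrom": chrom,
                             "strand": "+" if rng.random() < 0.5 else "-",
                             "tss_pos": max(1, start + offset)})
            gene_i += 1
    for chrom, span in chrom_span.items():  # decoy genes far from probes
        for _ in range(3):
            tss_rows.append({"gene_id": f"GENE{gene_i:05d}", "chrom": chrom,
                             "strand": "+", "tss_pos": int(rng.integers(span, span + 500_000))})
            gene_i += 1
    tss = pd.DataFrame(tss_rows)

    from .annotate import AnnotationTrack

    islands, shores, shelves, seas = [], [], [], []
    genic = {"promoter": [], "exon": [], "intron": [], "enhancer": [], "intergenic": []}
    nucleosome, tf_a, tf_b = [], [], []
    for chrom, span in sorted(chrom_span.items()):
        isl = []
        # islands around every third layout region on this chromosome
        rids = [r for r, (c, _, _) in region_pos.items() if c == chrom]
        for i, rid in enumerate(sorted(rids)):
            _, s, e = region_pos[rid]
            if i % 3 == 0:
                isl.append((max(0, s - 301), e + 300))
        isl = sorted(isl)
        islands += [(chrom, s, e) for s, e in isl]
        sh, shf = [], []
        for s, e in isl:
            sh += [(max(0, s - 2000), s), (e, e + 2000)]
            shf += [(max(0, s - 4000), s - 2000), (e + 2000, e + 4000)]
        sh = [(a, b) for a, b in sh if a < b]
        shf = [(a, b) for a, b in shf if a < b]
        shores += [(chrom, s, e) for s, e in sh]
        shelves += [(chrom, s, e) for s, e in shf]
        seas += [(chrom, s, e) for s, e in _complement(isl + sh + shf, span)]

        bodies = []
        for row in tss[tss["chrom"] == chrom].itertuples():
            t = int(row.tss_pos)
            genic["promoter"].append((chrom, max(0, t - 1000), t + 1000))
            bodies.append((max(0, t - 1000), t + 8000))
            genic["exon"].append((chrom, t, t + 1500))
            genic["intron"].append((chrom, t + 1500, t + 8000))
        genic["intergenic"] += [(chrom, s, e) for s, e in _complement(bodies, span)]
        for _ in range(max(3, span // 400_000)):
            s = int(rng.integers(0, span))
            genic["enhancer"].append((chrom, s, s + int(rng.integers(200, 1500))))
            s = int(rng.integers(0, span))
            nucleosome.append((chrom, s, s + int(rng.integers(1000, 10_000))))
            s = int(rng.integers(0, span))
            tf_a.append((chrom, s, s + int(rng.integers(100, 600))))
            s = int(rng.integers(0, span))
            tf_b.append((chrom, s, s + int(rng.integers(100, 600))))

    def track(name, tuples):
        return AnnotationTrack(name, pd.DataFrame(tuples, columns=["chrom", "start", "end"]))

    tracks = [
        track("cpg_island", islands), track("cpg_shore", shores),
        track("cpg_shelf", shelves), track("open_sea", seas),
        track("promoter", genic["promoter"]), track("exon", genic["exon"]),
        track("intron", genic["intron"]), track("enhancer", genic["enhancer"]),
        track("intergenic", genic["intergenic"]),
        track("nucleosome_retained", nucleosome),
        track("tfbs_EZH2", tf_a), track("tfbs_CTCF", tf_b),
    ]
    return tracks, tss


def write_cohort(outdir, ds: MethylomeDataset, couples, truth: SyntheticTruth,
                 tracks=None, tss: pd.DataFrame | None = None) -> dict[str, str]:
    """Write all simulated inputs as plain-text files; returns the inventory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .outcomes import couples_to_frame

    files = {
        "manifest": outdir / "manifest.tsv",
        "beta": outdir / "beta.tsv",
        "phenotypes": outdir / "phenotypes.csv",
        "truth": outdir / "truth.json",
    }
    ds.write(files["manifest"], files["beta"])
    couples_to_frame(couples).to_csv(files["phenotypes"])
    truth.to_json(files["truth"])
    if tracks is not None:
        for tr in tracks:
            p = outdir / f"track_{tr.name}.bed"
            tr.intervals.to_csv(p, sep="\t", header=False, index=False)
            files[f"track_{tr.name}"] = p
    if tss is not None:
        files["tss"] = outdir / "tss.tsv"
        tss.to_csv(files["tss"], sep="\t", index=False)
    return {k: str(v) for k, v in files.items()}
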