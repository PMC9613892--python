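"""Synthetic Parkinson's-progression cohort generator.

Produces paired AMP-PD-like cohorts — a PPMI-analog training cohort with
DaTScan imaging and a PDBP-analog external cohort without it — with a planted,
configurable effect structure so the full pipeline (genotype QC, polygenic
scoring, medication-adjusted progressor labelling, subpart x horizon
submodels, stacked meta-prediction, ablation) is testable without access to
the controlled-access clinical data.

The generative model is deliberately simple: piecewise-linear latent
MDS-UPDRS subpart trajectories with three latent subtypes (motor catch-up,
non-motor catch-up, non-progressor), subject-level random slopes per
12-month interval, and i.i.d. visit noise.  The planted structure mirrors
the qualitative findings the pipeline must be able to recover:

* "catch-up" effect: low baseline impairment in the target subpart plus
  higher impairment in the non-target subparts predicts that subpart's
  short-term progression;
* a protective (negative) PD polygenic-risk-score effect on motor (MDS-UPDRS
  II/III) progression and a positive educational-attainment PRS effect on
  MDS-UPDRS III progression;
* regression to the mean after 12 months: initial progressors slow or
  reverse, initial non-progressors convert to slow progressors;
* treatment masking of observed scores by fixed per-subpart offsets;
* two cohorts with different progressor prevalence (defaults 0.64 / 0.48).

Ground-truth subtypes, latent slopes and standardized true polygenic scores
are kept in a hidden truth table consumed only by tests, never by the
pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SimConfig",
    "EffectSizes",
    "TreatmentModel",
    "LongitudinalCohort",
    "generate_cohort",
    "inject_missingness",
    "write_cohort",
    "write_genotype_data",
]

SUBTYPES = ("motor_catchup", "nonmotor_catchup", "nonprogressor")

# Per-subtype mean first-interval slopes (points/year) for (I, II, III).
SUBTYPE_SLOPE_MEANS = {
    "motor_catchup": (1.5, 2.0, 5.0),
    "nonmotor_catchup": (4.0, 1.5, 2.5),
    "nonprogressor": (-1.5, -1.5, -3.5),
}
# Per-subtype mean baseline subpart sums: catch-up subtypes start LOW in their
# target subpart and higher elsewhere (Table-1-like contrast direction).
SUBTYPE_BASELINE_MEANS = {
    "motor_catchup": (5.5, 4.0, 16.5),
    "nonmotor_catchup": (3.0, 5.2, 24.0),
    "nonprogressor": (4.6, 4.2, 21.0),
}
BASELINE_SD = (2.5, 2.5, 7.0)
POP_BASELINE_MEAN = (4.5, 4.3, 20.0)

N_ITEMS = (13, 13, 33)  # MDS-UPDRS I, II, III item counts
MOCA_SUBSCORES = {
    "moca_visuospatial": 5,
    "moca_naming": 3,
    "moca_attention": 6,
    "moca_language": 3,
    "moca_abstraction": 2,
    "moca_delayed_recall": 5,
    "moca_orientation": 6,
}

PART_NAMES = ("i", "ii", "iii")


@dataclass
class EffectSizes:
    """Signed planted coefficients on first-interval subpart slopes.

    Units are MDS-UPDRS points/year per unit of the predictor (baselines are
    centred at the population mean; polygenic scores are standardized; age is
    in decades above 62).
    """

    baseline_own: float = -0.32      # catch-up: low own baseline -> progression
    baseline_other: float = 0.2      # per non-target subpart: high baseline
                                     # there -> progression here
    pd_prs_mds2: float = -2.5        # protective PD-PRS on motor slopes: the
    pd_prs_mds3: float = -3.0        # genetic class carries the strongest
    ea_prs_mds3: float = 1.2         # unique planted signal
    age_mds3: float = 0.3
    monogenic_mds3: float = -0.5
    # subpart-specific survey predictors: better cognition feeds non-motor
    # catch-up, preserved daily function feeds MDS-II catch-up
    moca_mds1: float = 1.0           # per SD of MoCA total, on MDS-I slope
    seadl_mds2: float = 0.8          # per SD of SE-ADL, on MDS-II slope


@dataclass
class TreatmentModel:
    """Bernoulli treatment assignment and score masking.

    Treated subjects' *observed* subpart scores are shifted by
    ``masking_offsets`` at every visit (negative = symptomatic masking), so
    the medication-adjustment stage has a planted truth to recover.  The
    defaults mirror the study's correction of +0.67/+1.5/+3.67.
    """

    p_treated: float = 0.20
    masking_offsets: tuple[float, float, float] = (-0.67, -1.5, -3.67)


def _default_missingness() -> dict[str, float]:
    return {
        "moca_visuospatial": 0.03, "moca_naming": 0.03, "moca_attention": 0.03,
        "moca_language": 0.03, "moca_abstraction": 0.03,
        "moca_delayed_recall": 0.03, "moca_orientation": 0.03,
        "se_adl": 0.02, "hoehn_yahr": 0.01, "education_years": 0.02,
        "sbr_caudate_r": 0.05, "sbr_caudate_l": 0.05,
        "sbr_putamen_r": 0.05, "sbr_putamen_l": 0.05,
        # UPSIT smell test: planted on the wrong side of the >50% filter.
        "upsit_total": 0.55,
    }


@dataclass
class SimConfig:
    n_subjects: int = 500
    visit_months: tuple[int, ...] = (0, 6, 12, 18, 24, 30, 36)
    # Proportions of (motor_catchup, nonmotor_catchup, nonprogressor). When
    # None, the mix is calibrated so the expected 12-month Total progressor
    # fraction equals prevalence_target.
    subtype_mix: tuple[float, float, float] | None = None
    prevalence_target: float = 0.64
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    treatment_model: TreatmentModel = field(default_factory=TreatmentModel)
    noise_sd: tuple[float, float, float] = (0.6, 0.8, 1.5)
    # day-state noise (ON/OFF medication state, rater effects) hits all
    # three subparts of a visit together, so the Total score is noisier
    # than any single subpart
    day_noise_sd: float = 1.0
    slope_noise_sd: float = 0.8
    # shared per-subject slope factor: couples subpart progressions so the
    # between-subpart label overlap lands in the observed ~0.5-0.6 band
    shared_slope_sd: float = 1.35
    mean_reversion: float = 0.5      # 12-24 mo slope partly reverses the first
    slope_persistence: float = 0.2   # systematic propensity persists long-term
    late_drift: float = 1.5          # points/year common late progression
    missingness: dict[str, float] = field(default_factory=_default_missingness)
    visit_missing_rate: float = 0.04
    imaging_available: bool = True
    p_female: float = 0.35
    age_mean: float = 62.0
    age_sd: float = 9.0
    carrier_rates: dict[str, float] = field(
        default_factory=lambda: {"GBA": 0.15, "LRRK2": 0.18, "SNCA": 0.02})
    n_pd_snps: int = 90
    n_ea_snps: int = 763
    n_qc_variants: int = 200
    pc_outlier_rate: float = 0.0
    # optional overrides of the module-level subtype parameter tables
    subtype_slope_means: dict[str, tuple[float, float, float]] | None = None
    subtype_baseline_means: dict[str, tuple[float, float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        months = tuple(int(m) for m in self.visit_months)
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("visit_months must be strictly increasing")
        for required in (0, 12, 24, 36):
            if required not in months:
                raise ValueError(f"visit_months must include {required}")
        self.visit_months = months
        if self.subtype_mix is not None:
            mix = tuple(float(x) for x in self.subtype_mix)
            if len(mix) != 3 or any(x < 0 for x in mix):
                raise ValueError("subtype_mix needs 3 nonnegative proportions")
            if abs(sum(mix) - 1.0) > 1e-8:
                raise ValueError("subtype_mix must sum to 1")
            self.subtype_mix = mix
        if not 0 < self.prevalence_target < 1:
            raise ValueError("prevalence_target must be in (0,1)")
        for name, rate in self.missingness.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"missingness[{name!r}] outside [0,1]")
        if not 0 <= self.treatment_model.p_treated <= 1:
            raise ValueError("p_treated outside [0,1]")
        if not 0 <= self.visit_missing_rate <= 1:
            raise ValueError("visit_missing_rate outside [0,1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")


from .genetics import GenotypeData  # noqa: E402  (shared container type)


@dataclass
class LongitudinalCohort:
    """Subject-level static table + long visit table (+ hidden truth).

    ``subjects``: one row per participant with demographics, treatment flags,
    monogenic carrier flags, MoCA/SE-ADL/Hoehn&Yahr and (optionally) DaTScan
    striatal binding ratios.  ``visits``: one row per (participant, month)
    with MDS-UPDRS item responses, subpart summary scores, and Total.
    ``truth`` holds generator-internal ground truth (subtype, latent slopes,
    standardized true PRS) and is consumed only by tests.
    """

    subjects: pd.DataFrame
    visits: pd.DataFrame
    truth: pd.DataFrame | None = None

    def copy(self) -> "LongitudinalCohort":
        return LongitudinalCohort(
            self.subjects.copy(), self.visits.copy(),
            None if self.truth is None else self.truth.copy())

    def validate(self) -> None:
        v = self.visits
        if v.duplicated(["participant_id", "visit_month"]).any():
            raise ValueError("duplicate (participant, month) visit rows")
        for p, n in zip(PART_NAMES, N_ITEMS):
            items = [f"mds_updrs_{p}_item_{k:02d}" for k in range(1, n + 1)]
            if not np.allclose(v[items].sum(axis=1),
                               v[f"mds_updrs_{p}_summary_score"]):
                raise ValueError(f"subpart {p} items do not sum to summary")
        total = sum(v[f"mds_updrs_{p}_summary_score"] for p in PART_NAMES)
        if not np.allclose(total, v["mds_updrs_total_score"]):
            raise ValueError("Total != I+II+III")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _total_slope_sd(cfg: SimConfig) -> float:
    """Approximate SD of the *observed* annualized 12-month Total slope
    within a subtype, used to calibrate the subtype mix to a target
    progressor prevalence."""
    e = cfg.effect_sizes
    var = 3 * cfg.slope_noise_sd ** 2
    var += (3 * cfg.shared_slope_sd) ** 2  # shared factor enters all subparts
    # each baseline deviation enters the Total slope once as "own" and twice
    # as a non-target cross effect
    w = e.baseline_own + 2 * e.baseline_other
    var += w ** 2 * sum(s ** 2 for s in BASELINE_SD)
    var += (e.pd_prs_mds2 + e.pd_prs_mds3) ** 2 + e.ea_prs_mds3 ** 2
    var += (e.age_mds3 * cfg.age_sd / 10.0) ** 2
    var += e.moca_mds1 ** 2 + e.seadl_mds2 ** 2
    q = 1 - np.prod([1 - r for r in cfg.carrier_rates.values()])
    var += e.monogenic_mds3 ** 2 * q * (1 - q)
    # two noisy endpoints / 1 yr: per-subpart noise sums in the Total and the
    # day-state component enters all three subparts at once
    var += 2 * (sum(s ** 2 for s in cfg.noise_sd)
                + (3 * cfg.day_noise_sd) ** 2)
    return float(np.sqrt(var))


def calibrated_subtype_mix(cfg: SimConfig) -> tuple[float, float, float]:
    """Solve the subtype mix so that E[12-month Total progressor fraction]
    matches ``cfg.prevalence_target``.

    Progressor mass is split 60:40 between motor and non-motor catch-up.
    Scores are rounded to integers, so "progressor" means an integer Total
    increase >= 1; the 0.5 continuity shift accounts for rounding.
    """
    sd = _total_slope_sd(cfg)
    slope_means = cfg.subtype_slope_means or SUBTYPE_SLOPE_MEANS
    p = {k: float(norm.cdf((sum(slope_means[k]) - 0.5) / sd))
         for k in SUBTYPES}
    p_prog = 0.6 * p["motor_catchup"] + 0.4 * p["nonmotor_catchup"]
    m = (cfg.prevalence_target - p["nonprogressor"]) / (p_prog - p["nonprogressor"])
    m = float(np.clip(m, 0.0, 1.0))
    return (0.6 * m, 0.4 * m, 1.0 - m)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _allocate_items(rng: np.random.Generator, sums: np.ndarray,
                    n_items: int) -> np.ndarray:
    """Split integer subpart sums across items by multinomial draw.

    Items are feature columns, not psychometric objects; a fixed mildly
    uneven probability vector makes some items consistently 'heavier'
    without any single item echoing the subpart summary.
    """
    w = 1.0 / np.arange(2, n_items + 2) ** 0.3
    w = w / w.sum()
    out = np.empty((sums.size, n_items), dtype=int)
    for i, s in enumerate(sums):
        out[i] = rng.multinomial(int(s), w)
    return out


def _simulate_genotypes(cfg: SimConfig, rng: np.random.Generator,
                        ids: list[str], z_pd: np.ndarray, z_ea: np.ndarray
                        ) -> GenotypeData:
    """Simulate genotypes consistent with the planted standardized PRS.

    Scored SNPs are drawn independently; the raw weighted allele count is
    then rank-matched to the planted standardized score so that
    ``compute_prs`` on the emitted genotypes + weight tables reproduces the
    score that actually drives the planted slope effects (up to the
    rank-preserving transform).  QC-fodder variants come in linkage blocks
    with a few planted QC failures so pruning and filtering have real work.
    """
    n = len(ids)
    cols, meta_rows = [], []
    dose_blocks = []

    # -- LD-block fodder on chromosomes 1-2 -------------------------------
    n_blocks = max(1, cfg.n_qc_variants // 10)
    pos = 10_000
    for b in range(n_blocks):
        p_block = rng.uniform(0.05, 0.5)
        hap = np.empty((n, 2, 10), dtype=np.int8)
        hap[:, :, 0] = rng.random((n, 2)) < p_block
        for k in range(1, 10):
            keep = rng.random((n, 2)) < 0.96
            fresh = rng.random((n, 2)) < p_block
            hap[:, :, k] = np.where(keep, hap[:, :, k - 1], fresh)
        g = hap.sum(axis=1).astype(float)
        for k in range(10):
            vid = f"chr{1 + b % 2}_block{b}_v{k}"
            cols.append(vid)
            meta_rows.append((vid, 1 + b % 2, pos, "A", "G"))
            pos += 1000
        dose_blocks.append(g)
    fodder = np.concatenate(dose_blocks, axis=1)

    # planted QC failures: low call rate, monomorphic, all-het (HWE)
    special = np.empty((n, 4))
    special[:, 0] = rng.binomial(2, 0.3, n).astype(float)
    special[rng.random(n) < 0.12, 0] = np.nan          # call rate ~0.88
    special[:, 1] = 0.0                                 # monomorphic
    special[:, 2] = rng.binomial(2, 0.005, n).astype(float)  # MAF < 1%
    special[:, 3] = 1.0                                 # all het: HWE fail
    for j, tag in enumerate(["lowcall", "monomorph", "raremaf", "hwefail"]):
        vid = f"chr2_special_{tag}"
        cols.append(vid)
        meta_rows.append((vid, 2, pos, "C", "T"))
        pos += 1000

    # -- scored SNPs -------------------------------------------------------
    def scored(name: str, n_snps: int, z: np.ndarray, beta_sd: float,
               chrom0: int):
        mafs = rng.uniform(0.05, 0.5, n_snps)
        betas = rng.normal(0, beta_sd, n_snps)
        g = rng.binomial(2, mafs[None, :].repeat(n, 0)).astype(float)
        # sparse missingness to exercise the scoring imputation path
        g[rng.random(g.shape) < 0.01] = np.nan
        # effect-allele orientation: ~20% of entries use the REF allele
        flip = rng.random(n_snps) < 0.2
        wt_rows, vmeta, vids = [], [], []
        p = 5_000
        unamb = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
        for i in range(n_snps):
            ref, alt = unamb[int(rng.integers(4))]
            vid = f"rs{name}{i:04d}"
            vids.append(vid)
            chrom = chrom0 + (i % 10)
            vmeta.append((vid, chrom, p, ref, alt))
            p += 50_000
            ea = ref if flip[i] else alt
            wt_rows.append((vid, ea, betas[i]))
        wt = pd.DataFrame(wt_rows, columns=["variant_id", "effect_allele", "beta"])
        # oriented raw score with mean-imputed missing dosage
        eff = np.where(flip[None, :], 2.0 - g, g)
        colmean = np.nanmean(eff, axis=0)
        eff_f = np.where(np.isnan(eff), colmean, eff)
        raw = eff_f @ betas
        # rank-match raw score to the planted z so downstream scoring
        # recovers the score that drives the slopes
        order = np.argsort(np.argsort(raw))
        z_sorted = np.sort(z)
        matched = z_sorted[order]
        return g, vids, vmeta, wt, matched

    g_pd, v_pd, m_pd, wt_pd, z_pd_matched = scored("pd", cfg.n_pd_snps, z_pd, 0.15, 3)
    g_ea, v_ea, m_ea, wt_ea, z_ea_matched = scored("ea", cfg.n_ea_snps, z_ea, 0.05, 13)
    z_pd[:] = z_pd_matched
    z_ea[:] = z_ea_matched

    dose = np.concatenate([fodder, special, g_pd, g_ea], axis=1)
    cols = cols + v_pd + v_ea
    meta_rows = meta_rows + m_pd + m_ea
    variants = pd.DataFrame(meta_rows,
                            columns=["variant_id", "chrom", "pos", "ref", "alt"])
    variants = variants.sort_values(["chrom", "pos"], kind="stable")
    dosages = pd.DataFrame(dose, index=pd.Index(ids, name="participant_id"),
                           columns=cols)[variants["variant_id"].tolist()]

    k = 6
    pc = rng.normal(0.0, 1.0, (n, k))
    n_out = int(round(cfg.pc_outlier_rate * n))
    if n_out:
        which = rng.choice(n, n_out, replace=False)
        pc[which, 0] = 9.0 * np.sign(rng.standard_normal(n_out) + 1e-9)
    pcs = pd.DataFrame(pc, index=pd.Index(ids, name="participant_id"),
                       columns=[f"pc{i + 1}" for i in range(k)])
    pc_ref = pd.DataFrame({"mean": np.zeros(k), "sd": np.ones(k)},
                          index=pcs.columns)
    return GenotypeData(dosages, variants,
                        weights={"pd": wt_pd, "ea": wt_ea},
                        pcs=pcs, pc_ref=pc_ref)


def generate_cohort(config: SimConfig) -> tuple[LongitudinalCohort, GenotypeData]:
    """Generate one cohort and its genotype data. Deterministic given seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    ids = [f"SYN-{cfg.seed:04d}-{i:05d}" for i in range(n)]

    mix = cfg.subtype_mix or calibrated_subtype_mix(cfg)
    subtype_idx = rng.choice(3, size=n, p=mix)
    subtype = np.array(SUBTYPES)[subtype_idx]

    age = rng.normal(cfg.age_mean, cfg.age_sd, n).clip(35, 90)
    sex = np.where(rng.random(n) < cfg.p_female, "F", "M")

    # planted standardized polygenic scores; _simulate_genotypes rank-matches
    # these to the weighted allele counts of the emitted genotypes in place
    z_pd = rng.standard_normal(n)
    z_ea = rng.standard_normal(n)

    carriers = {g: rng.random(n) < r for g, r in cfg.carrier_rates.items()}
    mono_any = np.logical_or.reduce(list(carriers.values()))

    treated = rng.random(n) < cfg.treatment_model.p_treated
    levo = treated & (rng.random(n) < 0.75)
    agon = treated & (rng.random(n) < 0.50)
    other = treated & (rng.random(n) < 0.70)
    none_flag = treated & ~(levo | agon | other)
    levo = levo | none_flag

    geno = _simulate_genotypes(cfg, rng, ids, z_pd, z_ea)
    # education moderately tracks the (matched) EA score, far from collinear
    education = np.round(14 + 0.9 * z_ea + 1.9 * rng.standard_normal(n)
                         ).clip(6, 24)

    # survey instruments drawn before slopes: they carry planted
    # subpart-specific effects
    moca_rate = np.clip(rng.normal(0.10 + 0.005 * (age - cfg.age_mean), 0.06),
                        0.0, 0.6)
    moca_scores = {name: mx - rng.binomial(mx, moca_rate)
                   for name, mx in MOCA_SUBSCORES.items()}
    moca_total = np.sum(list(moca_scores.values()), axis=0)
    se_adl = np.clip(np.round((93 + rng.normal(0, 5, n)) / 5) * 5, 0, 100)

    def _z(x):
        sd = x.std()
        return (x - x.mean()) / (sd if sd > 0 else 1.0)

    e = cfg.effect_sizes
    base_means = cfg.subtype_baseline_means or SUBTYPE_BASELINE_MEANS
    slope_means = cfg.subtype_slope_means or SUBTYPE_SLOPE_MEANS
    base_mu = np.array([base_means[s] for s in subtype])
    baseline = np.maximum(base_mu + rng.standard_normal((n, 3)) * BASELINE_SD, 0.0)
    dev = baseline - np.asarray(POP_BASELINE_MEAN)

    slope_mu = np.array([slope_means[s] for s in subtype])
    other_dev = dev.sum(axis=1, keepdims=True) - dev
    shared = rng.standard_normal((n, 1)) * cfg.shared_slope_sd
    systematic = (slope_mu + shared
                  + e.baseline_own * dev
                  + e.baseline_other * other_dev)
    systematic[:, 0] += e.moca_mds1 * _z(moca_total)
    systematic[:, 1] += e.pd_prs_mds2 * z_pd + e.seadl_mds2 * _z(se_adl)
    systematic[:, 2] += (e.pd_prs_mds3 * z_pd + e.ea_prs_mds3 * z_ea
                         + e.age_mds3 * (age - cfg.age_mean) / 10.0
                         + e.monogenic_mds3 * mono_any)
    s1 = systematic + rng.standard_normal((n, 3)) * cfg.slope_noise_sd
    # later intervals: partial reversal of the first interval plus a
    # persistent systematic component — initial progressors slow or reverse
    # over 12-24 months yet keep a higher long-run rate, while the visit
    # noise of longer-horizon slopes is annualized away (longer-horizon
    # progression is the cleaner, more predictable signal)
    s2 = (-cfg.mean_reversion * s1 + cfg.slope_persistence * systematic
          + cfg.late_drift + rng.standard_normal((n, 3)) * cfg.slope_noise_sd)
    s3 = (cfg.slope_persistence * systematic + cfg.late_drift
          + rng.standard_normal((n, 3)) * cfg.slope_noise_sd)

    months = np.asarray(cfg.visit_months, dtype=float)
    frac = np.stack([np.clip(months, 0, 12) / 12.0,
                     np.clip(months - 12, 0, 12) / 12.0,
                     np.clip(months - 24, 0, 12) / 12.0])  # (3 intervals, T)
    latent = (baseline[:, :, None]
              + s1[:, :, None] * frac[0][None, None, :]
              + s2[:, :, None] * frac[1][None, None, :]
              + s3[:, :, None] * frac[2][None, None, :])  # (n, 3, T)
    noise = (rng.standard_normal(latent.shape)
             * np.asarray(cfg.noise_sd)[None, :, None]
             + rng.standard_normal((n, 1, latent.shape[2]))
             * cfg.day_noise_sd)
    mask = np.where(treated[:, None], 1.0, 0.0)[:, :, None] * np.asarray(
        cfg.treatment_model.masking_offsets)[None, :, None]
    observed = np.maximum(np.round(latent + noise + mask), 0).astype(int)

    # visit rows (baseline always kept; later visits subject to dropout)
    visit_rows = []
    item_cols = {p: [f"mds_updrs_{p}_item_{k:02d}" for k in range(1, cnt + 1)]
                 for p, cnt in zip(PART_NAMES, N_ITEMS)}
    present = rng.random((n, months.size)) >= cfg.visit_missing_rate
    present[:, 0] = True
    for t, m in enumerate(cfg.visit_months):
        keep = present[:, t]
        if not keep.any():
            continue
        row = {"participant_id": np.asarray(ids)[keep], "visit_month": m}
        total = np.zeros(keep.sum(), dtype=int)
        part_frames = []
        for pi, (p, cnt) in enumerate(zip(PART_NAMES, N_ITEMS)):
            sums = observed[keep, pi, t]
            items = _allocate_items(rng, sums, cnt)
            df = pd.DataFrame(items, columns=item_cols[p])
            df[f"mds_updrs_{p}_summary_score"] = sums
            total += sums
            part_frames.append(df)
        frame = pd.concat([pd.DataFrame(row).reset_index(drop=True),
                           *part_frames], axis=1)
        frame["mds_updrs_total_score"] = total
        visit_rows.append(frame)
    visits = pd.concat(visit_rows, ignore_index=True).sort_values(
        ["participant_id", "visit_month"], kind="stable").reset_index(drop=True)

    subjects = pd.DataFrame({"participant_id": ids,
                             "age_at_baseline": np.round(age, 1),
                             "sex": sex,
                             "education_years": education,
                             "tx_levodopa": levo.astype(int),
                             "tx_dopamine_agonist": agon.astype(int),
                             "tx_other_pd_med": other.astype(int),
                             "treated_any": treated.astype(int)})
    for g, flags in carriers.items():
        subjects[f"{g}_carrier"] = flags.astype(int)
    subjects["monogenic_any"] = mono_any.astype(int)
    for name in MOCA_SUBSCORES:
        subjects[name] = moca_scores[name]
    subjects["moca_total"] = moca_total
    subjects["se_adl"] = se_adl
    subjects["hoehn_yahr"] = np.clip(
        np.round(1.0 + 0.035 * baseline[:, 2] + rng.normal(0, 0.3, n)), 0, 5)
    if cfg.imaging_available:
        subjects["sbr_caudate_r"] = np.round(rng.normal(2.05, 0.35, n), 3)
        subjects["sbr_caudate_l"] = np.round(
            subjects["sbr_caudate_r"] + rng.normal(0, 0.12, n), 3)
        subjects["sbr_putamen_r"] = np.round(rng.normal(0.9, 0.25, n), 3)
        subjects["sbr_putamen_l"] = np.round(
            subjects["sbr_putamen_r"] + rng.normal(0, 0.1, n), 3)
    subjects["upsit_total"] = np.round(rng.normal(22, 8, n)).clip(0, 40)

    truth = pd.DataFrame({"participant_id": ids, "subtype": subtype,
                          "z_pd_prs": z_pd, "z_ea_prs": z_ea,
                          "baseline_i": baseline[:, 0],
                          "baseline_ii": baseline[:, 1],
                          "baseline_iii": baseline[:, 2]})
    for pi, p in enumerate(PART_NAMES):
        truth[f"slope12_{p}"] = s1[:, pi]
    truth["slope12_total"] = s1.sum(axis=1)

    cohort = LongitudinalCohort(subjects, visits, truth)
    rates = {k: v for k, v in cfg.missingness.items()
             if k in subjects.columns or k in visits.columns}
    cohort = inject_missingness(cohort, rates,
                                seed=int(rng.integers(2 ** 31)))
    cohort.validate()
    return cohort, geno


def inject_missingness(cohort: LongitudinalCohort,
                       rates: dict[str, float], seed: int,
                       protect_endpoints: bool = True) -> LongitudinalCohort:
    """Set named feature columns to missing at the requested per-feature rate.

    Applies to subject-level columns and to visit-level columns.  With
    ``protect_endpoints`` (default), visit-level MDS-UPDRS values at the
    label-defining months (0/12/24/36) are never deleted.
    """
    for name, r in rates.items():
        if not 0 <= r <= 1:
            raise ValueError(f"rate for {name!r} outside [0,1]")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for name, r in rates.items():
        if r == 0:
            continue
        if name in out.subjects.columns:
            hit = rng.random(len(out.subjects)) < r
            out.subjects.loc[hit, name] = np.nan
        elif name in out.visits.columns:
            hit = rng.random(len(out.visits)) < r
            if protect_endpoints and (name.startswith("mds_updrs")):
                hit &= ~out.visits["visit_month"].isin([0, 12, 24, 36]).values
            out.visits.loc[hit, name] = np.nan
        else:
            raise KeyError(f"unknown feature column: {name}")
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_cohort(cohort: LongitudinalCohort, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    cohort.visits.to_csv(outdir / "visits.tsv", sep="\t", index=False)
    if cohort.truth is not None:
        cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def write_genotype_data(geno: GenotypeData, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno.dosages.to_csv(outdir / "dosages.tsv", sep="\t")
    geno.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    for name, wt in geno.weights.items():
        wt.to_csv(outdir / f"weights_{name}.tsv", sep="\t", index=False)
    if geno.pcs is not None:
        geno.pcs.to_csv(outdir / "pcs.tsv", sep="\t")
    if geno.pc_ref is not None:
        geno.pc_ref.to_csv(outdir / "pc_ref.tsv", sep="\t")


def load_cohort(indir: str | Path, with_truth: bool = False) -> LongitudinalCohort:
    indir = Path(indir)
    subjects = pd.read_csv(indir / "subjects.tsv", sep="\t")
    visits = pd.read_csv(indir / "visits.tsv", sep="\t")
    truth = None
    if with_truth and (indir / "truth.tsv").exists():
        truth = pd.read_csv(indir / "truth.tsv", sep="\t")
    return LongitudinalCohort(subjects, visits, truth)
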