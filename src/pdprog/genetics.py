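"""Genotype QC, ancestry filtering, LD pruning, and polygenic scoring.

Implements the genetic side of the progression pipeline: per-variant quality
control (call rate, Hardy-Weinberg equilibrium, minor allele frequency),
greedy windowed LD pruning, a principal-component ancestry window against
reference-panel statistics, weighted allele-count polygenic scores (the
90-SNP Parkinson's diagnosis score and the 763-SNP educational-attainment
score in the study design, but any weight table works), and monogenic
carrier flags for GBA / LRRK2 / SNCA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeData", "QCThresholds", "PRSResult",
    "hwe_pvalue", "variant_qc", "ld_prune", "ancestry_filter",
    "compute_prs", "monogenic_flags",
    "read_dosage_tsv", "read_weight_table", "read_vcf", "write_vcf",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
MONOGENIC_GENES = ("GBA", "LRRK2", "SNCA")


class GenotypeData:
    """Dosage matrix (subjects x variants, values in [0,2] or NaN) plus
    variant metadata.

    ``dosages``: DataFrame indexed by participant id, columns = variant ids.
    ``variants``: DataFrame with columns variant_id, chrom, pos, ref, alt.
    ``weights``: optional dict of score name -> weight table
    (variant_id, effect_allele, beta).  ``pcs`` / ``pc_ref``: optional genetic
    principal-component coordinates and reference-panel mean/sd per component.
    """

    def __init__(self, dosages: pd.DataFrame, variants: pd.DataFrame,
                 weights: dict[str, pd.DataFrame] | None = None,
                 pcs: pd.DataFrame | None = None,
                 pc_ref: pd.DataFrame | None = None):
        vals = dosages.values.astype(float)
        valid = vals[~np.isnan(vals)]
        if valid.size and (valid.min() < 0 or valid.max() > 2):
            raise ValueError("dosages outside [0, 2]")
        if list(variants["variant_id"]) != list(dosages.columns):
            raise ValueError("variant metadata does not match dosage columns")
        self.dosages = dosages
        self.variants = variants.reset_index(drop=True)
        self.weights = weights or {}
        self.pcs = pcs
        self.pc_ref = pc_ref

    @property
    def n_subjects(self) -> int:
        return int(self.dosages.shape[0])

    @property
    def n_variants(self) -> int:
        return int(self.dosages.shape[1])

    def genotype_counts(self) -> pd.DataFrame:
        """Per-variant hard-call counts (hom_ref, het, hom_alt, missing);
        counts sum to n_subjects for every variant."""
        g = self.dosages.values.astype(float)
        miss = np.isnan(g)
        gr = np.where(miss, -1, np.round(g))
        out = pd.DataFrame({
            "variant_id": self.dosages.columns,
            "hom_ref": (gr == 0).sum(axis=0),
            "het": (gr == 1).sum(axis=0),
            "hom_alt": (gr == 2).sum(axis=0),
            "missing": miss.sum(axis=0),
        })
        return out

    def subset_variants(self, keep_ids: list[str]) -> "GenotypeData":
        meta = self.variants[self.variants["variant_id"].isin(set(keep_ids))]
        return GenotypeData(self.dosages[meta["variant_id"].tolist()],
                            meta.reset_index(drop=True), self.weights,
                            self.pcs, self.pc_ref)


@dataclass
class QCThresholds:
    """Variant-QC and pruning thresholds (strict inequalities for QC)."""

    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-15
    maf_min: float = 0.01
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.2
    pc_k: int = 6
    pc_sd_window: float = 7.0

    def __post_init__(self) -> None:
        if not (0 <= self.call_rate_min <= 1 and 0 <= self.maf_min <= 0.5
                and 0 <= self.hwe_p_min <= 1):
            raise ValueError("QC thresholds out of range")
        if self.prune_window < 2 or self.prune_step < 1 or not (
                0 < self.prune_r2 <= 1):
            raise ValueError("pruning parameters out of range")


@dataclass
class PRSResult:
    """Per-subject polygenic score S_j = sum_i beta_i * g_ij over matched,
    effect-allele-oriented variants."""

    scores: pd.Series
    variants_used: list[str]
    variants_skipped: dict[str, str] = field(default_factory=dict)
    name: str = "prs"

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.values).all():
            raise ValueError("non-finite polygenic score")


def hwe_pvalue(counts: tuple[int, int, int]) -> float:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg
    proportions (p^2, 2pq, q^2) given (hom_ref, het, hom_alt) counts."""
    aa, ab, bb = (int(c) for c in counts)
    if min(aa, ab, bb) < 0:
        raise ValueError("negative genotype count")
    n = aa + ab + bb
    if n == 0:
        raise ValueError("no called genotypes")
    p = (2 * aa + ab) / (2 * n)
    q = 1 - p
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([aa, ab, bb], dtype=float)
    nonzero = expected > 0
    stat = float(((observed[nonzero] - expected[nonzero]) ** 2
                  / expected[nonzero]).sum())
    return float(chi2.sf(stat, df=1))


def variant_qc(geno: GenotypeData, thr: QCThresholds | None = None) -> pd.Series:
    """Keep-mask: call rate > min AND HWE p > min AND MAF > min (all strict).

    MAF and HWE are computed on called genotypes only.
    """
    thr = thr or QCThresholds()
    if geno.n_variants == 0 or geno.n_subjects == 0:
        raise ValueError("empty genotype matrix")
    counts = geno.genotype_counts()
    called = counts[["hom_ref", "het", "hom_alt"]].sum(axis=1).values
    call_rate = called / geno.n_subjects
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = (counts["het"].values + 2 * counts["hom_alt"].values) / (
            2 * np.maximum(called, 1))
    maf = np.minimum(alt_freq, 1 - alt_freq)
    hwe = np.array([
        hwe_pvalue((r.hom_ref, r.het, r.hom_alt)) if (r.hom_ref + r.het
                                                      + r.hom_alt) else 0.0
        for r in counts.itertuples()])
    keep = ((call_rate > thr.call_rate_min)
            & (hwe > thr.hwe_p_min)
            & (maf > thr.maf_min))
    return pd.Series(keep, index=counts["variant_id"].values, name="keep")


def _window_prune(g: np.ndarray, maf: np.ndarray, window: int, step: int,
                  r2_max: float) -> np.ndarray:
    """Greedy left-to-right windowed pruning on one chromosome.

    Within each window, pairs are scanned in index order; when a pair of
    still-kept variants has squared dosage correlation > r2_max the member
    with the lower MAF is removed (tie: the right-hand variant), and the
    window is rescanned.  Deterministic by construction.
    """
    p = g.shape[1]
    kept = np.ones(p, dtype=bool)
    # mean-imputed, centred dosages for correlation
    col_mean = np.nanmean(g, axis=0)
    gi = np.where(np.isnan(g), col_mean[None, :], g) - col_mean[None, :]
    start = 0
    while start < p:
        idx = [i for i in range(start, min(start + window, p)) if kept[i]]
        changed = True
        while changed:
            changed = False
            for a_pos in range(len(idx)):
                a = idx[a_pos]
                if not kept[a]:
                    continue
                for b in idx[a_pos + 1:]:
                    if not kept[b]:
                        continue
                    va, vb = gi[:, a], gi[:, b]
                    denom = np.sqrt((va ** 2).sum() * (vb ** 2).sum())
                    r2 = 0.0 if denom == 0 else float(
                        ((va * vb).sum() / denom) ** 2)
                    if r2 > r2_max:
                        drop = a if maf[a] < maf[b] else b
                        kept[drop] = False
                        changed = True
            idx = [i for i in idx if kept[i]]
        if start + window >= p:
            break
        start += step
    return kept


def ld_prune(geno: GenotypeData, thr: QCThresholds | None = None) -> list[str]:
    """PLINK-style sliding-window LD pruning (window 50 variants, step 5,
    r^2 0.2 by default); returns the kept variant ids in input order."""
    thr = thr or QCThresholds()
    meta = geno.variants
    order = meta[["chrom", "pos"]].values
    if not all((order[i][0], order[i][1]) <= (order[i + 1][0], order[i + 1][1])
               for i in range(len(order) - 1)):
        raise ValueError("variants must be sorted by (chrom, pos)")
    counts = geno.genotype_counts()
    called = counts[["hom_ref", "het", "hom_alt"]].sum(axis=1).values
    alt_freq = (counts["het"].values + 2 * counts["hom_alt"].values) / (
        2 * np.maximum(called, 1))
    maf_all = np.minimum(alt_freq, 1 - alt_freq)
    kept_ids: list[str] = []
    for chrom in meta["chrom"].unique():
        sel = (meta["chrom"] == chrom).values
        ids = meta.loc[sel, "variant_id"].tolist()
        g = geno.dosages[ids].values.astype(float)
        kept = _window_prune(g, maf_all[sel], thr.prune_window,
                             thr.prune_step, thr.prune_r2)
        kept_ids.extend([vid for vid, k in zip(ids, kept) if k])
    return kept_ids


def ancestry_filter(pc_coords: pd.DataFrame, ref_mean: np.ndarray,
                    ref_sd: np.ndarray, k: int = 6,
                    n_sd: float = 7.0) -> pd.Series:
    """Keep subjects within ``n_sd`` reference SDs of the reference mean on
    each of the first ``k`` principal components (boundary inclusive).

    Subjects with any missing coordinate are excluded with a warning.
    """
    if k > pc_coords.shape[1]:
        raise ValueError(f"need {k} components, got {pc_coords.shape[1]}")
    x = pc_coords.iloc[:, :k].values.astype(float)
    mu = np.asarray(ref_mean, dtype=float)[:k]
    sd = np.asarray(ref_sd, dtype=float)[:k]
    missing = np.isnan(x).any(axis=1)
    if missing.any():
        log.warning("%d subjects missing PC coordinates; excluded",
                    int(missing.sum()))
    ok = (np.abs(x - mu) <= n_sd * sd).all(axis=1) & ~missing
    return pd.Series(ok, index=pc_coords.index, name="keep")


def compute_prs(geno: GenotypeData, weights: pd.DataFrame,
                name: str = "prs") -> PRSResult:
    """Weighted allele-counting polygenic score.

    Variants are matched by id; dosage is oriented to the effect allele
    (g -> 2-g when the effect allele is the reference allele).  A strand
    flip (effect allele = complement of ref/alt) is accepted only for
    unambiguous pairs; ambiguous A/T and C/G variants are skipped with a
    warning rather than guessed.  Missing dosages are imputed as twice the
    effect-allele frequency among called genotypes.
    """
    meta = geno.variants.set_index("variant_id")
    skipped: dict[str, str] = {}
    used: list[str] = []
    total = np.zeros(geno.n_subjects)
    for row in weights.itertuples():
        vid, ea, beta = row.variant_id, str(row.effect_allele).upper(), row.beta
        if not np.isfinite(beta):
            raise ValueError(f"non-finite beta for {vid}")
        if vid not in meta.index:
            skipped[vid] = "absent from genotypes"
            continue
        ref, alt = str(meta.loc[vid, "ref"]).upper(), str(meta.loc[vid, "alt"]).upper()
        ambiguous = _COMPLEMENT.get(ref) == alt
        if ea == alt:
            flip = False
        elif ea == ref:
            flip = True
        elif not ambiguous and ea == _COMPLEMENT.get(alt):
            flip = False
        elif not ambiguous and ea == _COMPLEMENT.get(ref):
            flip = True
        else:
            reason = ("ambiguous strand (A/T or C/G)" if ambiguous
                      else "effect allele matches neither allele")
            warnings.warn(f"{name}: skipping {vid}: {reason}")
            skipped[vid] = reason
            continue
        g = geno.dosages[vid].values.astype(float)
        eff = 2.0 - g if flip else g
        called = ~np.isnan(eff)
        if not called.any():
            skipped[vid] = "no called genotypes"
            continue
        eaf = eff[called].mean() / 2.0
        eff = np.where(called, eff, 2.0 * eaf)
        total += beta * eff
        used.append(vid)
    if not used:
        raise ValueError("zero matched variants: cannot compute score")
    scores = pd.Series(total, index=geno.dosages.index, name=name)
    return PRSResult(scores=scores, variants_used=used,
                     variants_skipped=skipped, name=name)


def monogenic_flags(carrier_calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-subject carrier calls for GBA/LRRK2/SNCA into one binary
    flag per gene plus a combined flag (logical OR).

    ``carrier_calls`` columns must be named after the genes (any qualifying
    call per gene counts).  Unknown gene columns raise.
    """
    unknown = [c for c in carrier_calls.columns if c not in MONOGENIC_GENES]
    if unknown:
        raise ValueError(f"unknown gene name(s): {unknown}")
    out = pd.DataFrame(index=carrier_calls.index)
    for gene in MONOGENIC_GENES:
        if gene in carrier_calls.columns:
            out[f"{gene}_carrier"] = (carrier_calls[gene].astype(float)
                                      > 0).astype(int)
        else:
            out[f"{gene}_carrier"] = 0
    out["monogenic_any"] = (out[[f"{g}_carrier" for g in MONOGENIC_GENES]]
                            .max(axis=1))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_dosage_tsv(dosage_path: str | Path,
                    variants_path: str | Path) -> GenotypeData:
    dosages = pd.read_csv(dosage_path, sep="\t", index_col=0)
    variants = pd.read_csv(variants_path, sep="\t")
    return GenotypeData(dosages, variants)


def read_weight_table(path: str | Path) -> pd.DataFrame:
    wt = pd.read_csv(path, sep="\t")
    required = {"variant_id", "effect_allele", "beta"}
    if not required.issubset(wt.columns):
        raise ValueError(f"weight table needs columns {sorted(required)}")
    if wt["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids in weight table")
    return wt


def write_vcf(geno: GenotypeData, path: str | Path) -> None:
    """Write hard-call diploid GT VCF (text, uncompressed)."""
    samples = list(geno.dosages.index)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(geno.variants["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        dose = geno.dosages.values.astype(float)
        for j, row in enumerate(geno.variants.itertuples()):
            calls = []
            for v in dose[:, j]:
                calls.append("./." if np.isnan(v) else gt_map[int(round(v))])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t"
                     f"{row.alt}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")


def read_vcf(path: str | Path) -> GenotypeData:
    """Read a diploid-GT VCF into a dosage matrix via cyvcf2."""
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for rec in vcf:
        gts = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dose = np.where(gts == 2, np.nan,
                        np.where(gts == 3, 2.0, gts.astype(float)))
        rows.append(dose)
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        meta.append((vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    variants = pd.DataFrame(meta, columns=["variant_id", "chrom", "pos",
                                           "ref", "alt"])
    dosages = pd.DataFrame(np.array(rows).T,
                           index=pd.Index(samples, name="participant_id"),
                           columns=variants["variant_id"].tolist())
    return GenotypeData(dosages, variants)
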