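"""Genotype QC, LD pruning, ancestry window, polygenic scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from pdprog.genetics import (GenotypeData, QCThresholds, ancestry_filter,
                             compute_prs, hwe_pvalue, ld_prune,
                             monogenic_flags, read_vcf, variant_qc, write_vcf)
from .conftest import make_genotypes


class TestHWE:
    def test_perfect_proportions_give_p_one(self):
        assert hwe_pvalue((25, 50, 25)) == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        # expected under p=q=0.5 at n=100: (25, 50, 25); chi2 = 1+2+1 = 4
        expected_p = float(chi2.sf(4.0, df=1))
        assert hwe_pvalue((30, 40, 30)) == pytest.approx(expected_p, rel=1e-12)

    def test_all_het_fails_hard(self):
        # chi2 = n = 100 under p=q=0.5
        assert hwe_pvalue((0, 100, 0)) < 1e-15

    @pytest.mark.parametrize("counts", [(0, 0, 0)])
    def test_empty_counts_rejected(self, counts):
        with pytest.raises(ValueError):
            hwe_pvalue(counts)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            hwe_pvalue((-1, 2, 3))


class TestVariantQC:
    def test_low_call_rate_removed(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, (100, 2)).astype(float)
        g[:11, 0] = np.nan  # call rate 0.89
        keep = variant_qc(make_genotypes(g))
        assert not keep["v0"] and keep["v1"]

    def test_monomorphic_removed(self):
        g = np.zeros((50, 2))
        g[:, 1] = np.random.default_rng(1).binomial(2, 0.4, 50)
        keep = variant_qc(make_genotypes(g))
        assert not keep["v0"]

    def test_perfect_hwe_retained(self):
        g = np.array([0] * 25 + [1] * 50 + [2] * 25, dtype=float)
        keep = variant_qc(make_genotypes(g[:, None]))
        assert keep["v0"]

    def test_hwe_violation_removed(self):
        g = np.ones((100, 1))  # all heterozygous
        keep = variant_qc(make_genotypes(g))
        assert not keep["v0"]

    def test_idempotent(self, small_cohort):
        _, geno = small_cohort
        keep = variant_qc(geno)
        filtered = geno.subset_variants(keep.index[keep].tolist())
        keep2 = variant_qc(filtered)
        assert keep2.all()

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            variant_qc(make_genotypes(np.empty((0, 0))))


def brute_force_prune(geno: GenotypeData, window: int = 50, step: int = 5,
                      r2_max: float = 0.2) -> list[str]:
    """Independent all-pairs oracle: same windowing/tie policy, computed
    with plain Python loops and per-pair correlation from first principles."""
    meta = geno.variants
    kept_all = []
    for chrom in meta["chrom"].unique():
        ids = meta.loc[meta["chrom"] == chrom, "variant_id"].tolist()
        cols = {v: geno.dosages[v].values.astype(float) for v in ids}
        maf = {}
        for v in ids:
            x = cols[v]
            x = x[~np.isnan(x)]
            f = x.sum() / (2 * len(x)) if len(x) else 0.0
            maf[v] = min(f, 1 - f)
        imputed = {}
        for v in ids:
            x = cols[v].copy()
            m = np.nanmean(x)
            x[np.isnan(x)] = m
            imputed[v] = x - x.mean()
        kept = {v: True for v in ids}
        start = 0
        while start < len(ids):
            win = ids[start:start + window]
            changed = True
            while changed:
                changed = False
                live = [v for v in win if kept[v]]
                for a, b in itertools.combinations(live, 2):
                    if not (kept[a] and kept[b]):
                        continue
                    xa, xb = imputed[a], imputed[b]
                    denom = np.sqrt((xa ** 2).sum() * (xb ** 2).sum())
                    r2 = 0.0 if denom == 0 else ((xa * xb).sum() / denom) ** 2
                    if r2 > r2_max:
                        kept[a if maf[a] < maf[b] else b] = False
                        changed = True
            if start + window >= len(ids):
                break
            start += step
        kept_all.extend(v for v in ids if kept[v])
    return kept_all


class TestLDPrune:
    def test_duplicated_variant_keeps_one(self):
        rng = np.random.default_rng(2)
        base = rng.binomial(2, 0.3, 200).astype(float)
        g = np.column_stack([base, base])
        kept = ld_prune(make_genotypes(g))
        assert len(kept) == 1

    def test_independent_variants_all_retained(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.4, (2000, 10)).astype(float)
        kept = ld_prune(make_genotypes(g))
        assert len(kept) == 10

    def test_matches_brute_force_on_block_fixture(self, small_cohort):
        _, geno = small_cohort
        # first 60 fodder variants (6 linkage blocks on chromosome 1/2)
        ids = geno.variants["variant_id"].head(60).tolist()
        sub = geno.subset_variants(ids)
        assert ld_prune(sub) == brute_force_prune(sub)

    def test_repruning_removes_nothing(self, small_cohort):
        _, geno = small_cohort
        kept = ld_prune(geno)
        sub = geno.subset_variants(kept)
        assert ld_prune(sub) == kept

    def test_output_subset_of_input(self, small_cohort):
        _, geno = small_cohort
        kept = ld_prune(geno)
        assert set(kept) <= set(geno.variants["variant_id"])

    def test_unsorted_variants_rejected(self):
        g = np.random.default_rng(4).binomial(2, 0.3, (50, 3)).astype(float)
        geno = make_genotypes(g)
        geno.variants.loc[0, "pos"] = 99_999_999
        with pytest.raises(ValueError):
            ld_prune(geno)


class TestAncestryFilter:
    def _pcs(self, rows):
        return pd.DataFrame(rows, columns=[f"pc{i}" for i in range(1, 7)])

    def test_window_boundaries(self):
        ref_mean, ref_sd = np.zeros(6), np.ones(6)
        pcs = self._pcs([np.zeros(6),                      # at the mean
                         [8.0, 0, 0, 0, 0, 0],             # 8 SD out
                         [7.0, 0, 0, 0, 0, 0]])            # exactly 7 SD
        keep = ancestry_filter(pcs, ref_mean, ref_sd)
        assert keep.tolist() == [True, False, True]

    def test_missing_coordinates_excluded(self):
        pcs = self._pcs([np.zeros(6), [np.nan, 0, 0, 0, 0, 0]])
        keep = ancestry_filter(pcs, np.zeros(6), np.ones(6))
        assert keep.tolist() == [True, False]

    def test_too_few_components_rejected(self):
        pcs = pd.DataFrame(np.zeros((2, 3)), columns=["pc1", "pc2", "pc3"])
        with pytest.raises(ValueError):
            ancestry_filter(pcs, np.zeros(6), np.ones(6))


def naive_prs(geno: GenotypeData, weights: pd.DataFrame) -> np.ndarray:
    """Double-loop scoring oracle (id match, allele orientation, 2*EAF
    imputation) written independently of the vectorized path."""
    meta = geno.variants.set_index("variant_id")
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    out = np.zeros(geno.n_subjects)
    for row in weights.itertuples():
        if row.variant_id not in meta.index:
            continue
        ref = meta.loc[row.variant_id, "ref"]
        alt = meta.loc[row.variant_id, "alt"]
        ea = row.effect_allele
        ambiguous = comp[ref] == alt
        if ea == alt or (not ambiguous and ea == comp[alt]):
            flip = False
        elif ea == ref or (not ambiguous and ea == comp[ref]):
            flip = True
        else:
            continue
        g = geno.dosages[row.variant_id].values.astype(float)
        vals = []
        for x in g:
            vals.append(np.nan if np.isnan(x) else (2 - x if flip else x))
        vals = np.array(vals)
        eaf = np.nanmean(vals) / 2
        for j in range(len(vals)):
            d = vals[j] if not np.isnan(vals[j]) else 2 * eaf
            out[j] += row.beta * d
    return out


class TestComputePRS:
    def test_zero_dosages_zero_score(self):
        geno = make_genotypes(np.zeros((5, 3)))
        wt = pd.DataFrame({"variant_id": ["v0", "v1", "v2"],
                           "effect_allele": "G", "beta": [0.1, -0.2, 0.3]})
        res = compute_prs(geno, wt)
        assert (res.scores == 0).all()

    def test_single_variant_arithmetic(self):
        geno = make_genotypes(np.array([[2.0]]))
        wt = pd.DataFrame({"variant_id": ["v0"], "effect_allele": ["G"],
                           "beta": [0.5]})
        assert compute_prs(geno, wt).scores.iloc[0] == pytest.approx(1.0)

    def test_three_variant_hand_example(self):
        geno = make_genotypes(np.array([[0.0, 1.0, 2.0]]))
        wt = pd.DataFrame({"variant_id": ["v0", "v1", "v2"],
                           "effect_allele": "G", "beta": [0.1, -0.2, 0.3]})
        assert compute_prs(geno, wt).scores.iloc[0] == pytest.approx(0.4)

    def test_ref_effect_allele_flips_dosage(self):
        geno = make_genotypes(np.array([[2.0], [0.0]]))
        wt = pd.DataFrame({"variant_id": ["v0"], "effect_allele": ["A"],
                           "beta": [1.0]})  # ref allele: dosage 2 -> 0
        assert compute_prs(geno, wt).scores.tolist() == [0.0, 2.0]

    def test_ambiguous_strand_skipped_with_warning(self):
        geno = make_genotypes(np.array([[1.0, 1.0]]), ref="A", alt="T")
        wt = pd.DataFrame({"variant_id": ["v0", "v1"],
                           "effect_allele": ["C", "T"], "beta": [1.0, 2.0]})
        with pytest.warns(UserWarning, match="ambiguous|neither"):
            res = compute_prs(geno, wt)
        assert "v0" in res.variants_skipped
        assert len(res.variants_used) + len(res.variants_skipped) == len(wt)

    def test_zero_matched_variants_rejected(self):
        geno = make_genotypes(np.zeros((2, 1)))
        wt = pd.DataFrame({"variant_id": ["nope"], "effect_allele": ["G"],
                           "beta": [1.0]})
        with pytest.raises(ValueError):
            compute_prs(geno, wt)

    def test_linearity_in_weights(self, small_cohort):
        _, geno = small_cohort
        wt = geno.weights["pd"]
        s1 = compute_prs(geno, wt).scores
        wt2 = wt.assign(beta=wt["beta"] * 3.5)
        s2 = compute_prs(geno, wt2).scores
        assert np.allclose(s2, 3.5 * s1, atol=1e-10)

    def test_matches_double_loop_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(12)
        for trial in range(50):
            n, p = int(rng.integers(3, 12)), int(rng.integers(2, 8))
            g = rng.binomial(2, rng.uniform(0.1, 0.5), (n, p)).astype(float)
            g[rng.random((n, p)) < 0.1] = np.nan
            g[:, 0] = np.nan_to_num(g[:, 0])  # at least one fully called
            geno = make_genotypes(g)
            alleles = ["G" if rng.random() < 0.7 else "A" for _ in range(p)]
            wt = pd.DataFrame({"variant_id": [f"v{j}" for j in range(p)],
                               "effect_allele": alleles,
                               "beta": rng.normal(0, 0.4, p)})
            assert np.allclose(compute_prs(geno, wt).scores.values,
                               naive_prs(geno, wt), atol=1e-10)


class TestMonogenicFlags:
    @pytest.mark.parametrize("calls,expected", [
        ({"GBA": 0, "LRRK2": 1, "SNCA": 0}, (0, 1, 0, 1)),
        ({"GBA": 0, "LRRK2": 0, "SNCA": 0}, (0, 0, 0, 0)),
        ({"GBA": 1, "LRRK2": 0, "SNCA": 1}, (1, 0, 1, 1)),
    ])
    def test_or_logic(self, calls, expected):
        df = pd.DataFrame([calls])
        out = monogenic_flags(df)
        assert tuple(out.iloc[0][["GBA_carrier", "LRRK2_carrier",
                                  "SNCA_carrier", "monogenic_any"]]) == expected

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError):
            monogenic_flags(pd.DataFrame({"APOE": [1]}))


class TestVCFRoundTrip:
    def test_hard_calls_survive(self, tmp_path):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.3, (8, 5)).astype(float)
        g[0, 0] = np.nan
        geno = make_genotypes(g)
        path = tmp_path / "toy.vcf"
        write_vcf(geno, path)
        back = read_vcf(path)
        assert list(back.dosages.columns) == list(geno.dosages.columns)
        a, b = geno.dosages.values, back.dosages.values
        assert ((a == b) | (np.isnan(a) & np.isnan(b))).all()
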