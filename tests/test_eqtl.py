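"""Association scan: model fits vs independent oracles, BH-FDR, comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from condqtl import (MonomorphicError, SimConfig, bh_fdr, call_activity,
                     compare_groups, enumerate_cis_pairs, fit_additive,
                     fit_anova, pairwise_t_tests, scan_group, simulate_study)


def brute_force_ols(g, y):
    """Normal-equations oracle: slope, t and p of y ~ 1 + g."""
    X = np.column_stack([np.ones_like(g), g])
    beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta_hat
    df = len(g) - 2
    s2 = resid @ resid / df
    se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
    t = beta_hat[1] / se
    return beta_hat[1], t, 2 * stats.t.sf(abs(t), df)


class TestEnumerateCisPairs:
    variants = pd.DataFrame({
        "id": ["s1", "s2", "s3"], "chrom": ["chr1", "chr1", "chr2"],
        "pos": [1_500_000, 1_500_000, 1_500_000],
        "ref": ["A", "A", "A"], "alt": ["C", "C", "C"]})

    def test_window_boundary(self):
        genes = pd.DataFrame({"gene_id": ["g_in", "g_out"],
                              "chrom": ["chr1", "chr1"],
                              "tss": [2_400_000, 2_600_000]})
        pairs = enumerate_cis_pairs(self.variants, genes, 1_000_000)
        keys = set(zip(pairs["snp_id"], pairs["gene_id"]))
        assert ("s1", "g_in") in keys and ("s2", "g_in") in keys
        assert not any(g == "g_out" for _, g in keys)

    def test_cross_chromosome_excluded(self):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                              "tss": [1_500_000]})
        pairs = enumerate_cis_pairs(self.variants, genes, 1_000_000)
        assert "s3" not in set(pairs["snp_id"])

    def test_distance_signed_snp_minus_tss(self):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                              "tss": [1_600_000]})
        pairs = enumerate_cis_pairs(self.variants, genes, 1_000_000)
        assert (pairs["distance"] == -100_000).all()


class TestFitAdditive:
    def test_perfect_fit_handled(self):
        beta, t, p = fit_additive([0, 1, 2], [0.0, 1.0, 2.0])
        assert beta == pytest.approx(1.0)
        assert np.isinf(t) and 0 < p < 1e-300

    def test_fixed_instance_matches_oracle(self):
        g = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = np.array([1.0, 1.2, 1.9, 2.1, 3.0, 3.2])
        beta, t, p = fit_additive(g, y)
        b0, t0, p0 = brute_force_ols(g, y)
        assert beta == pytest.approx(b0, abs=1e-10)
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_orthogonal_expression_gives_zero_slope(self):
        g = np.array([0.0, 1.0, 2.0, 1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])  # cov(g, y) = 0
        assert float(np.cov(g, y, bias=True)[0, 1]) == 0.0
        beta, _, _ = fit_additive(g, y)
        assert beta == 0.0

    def test_monomorphic_raises(self):
        with pytest.raises(MonomorphicError):
            fit_additive([1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0])

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            fit_additive([0, 1], [1.0, 2.0])

    def test_missing_dropped_pairwise(self):
        g = np.array([0, 1, 2, np.nan, 0, 2], dtype=float)
        y = np.array([1.0, 2.0, 3.0, 9.9, np.nan, 3.1])
        ok = ~(np.isnan(g) | np.isnan(y))
        beta, t, p = fit_additive(g, y)
        b0, t0, p0 = brute_force_ols(g[ok], y[ok])
        assert (beta, t, p) == pytest.approx((b0, t0, p0), abs=1e-10)

    @settings(max_examples=150, deadline=None)
    @given(st.integers(0, 10**6))
    def test_matches_linregress_on_random_instances(self, seed):
        """Random dosage/expression instances agree with scipy's fit to 1e-8."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        g = rng.integers(0, 3, n).astype(float)
        if len(np.unique(g)) < 2:
            g[0], g[1] = 0.0, 1.0
        y = rng.normal(size=n)
        beta, t, p = fit_additive(g, y)
        ref = stats.linregress(g, y)
        assert beta == pytest.approx(ref.slope, abs=1e-8)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)


class TestFitAnova:
    def test_equal_means_f_near_zero(self):
        f, p = fit_anova([0, 0, 1, 1], [1.0, 2.0, 1.0, 2.0])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_sum_of_squares_oracle(self):
        groups = [(1.0, 2.0), (3.0, 4.0), (5.0, 6.0)]
        y = np.array([v for grp in groups for v in grp])
        g = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        grand = y.mean()
        ss_between = sum(len(grp) * (np.mean(grp) - grand) ** 2 for grp in groups)
        ss_within = sum(sum((v - np.mean(grp)) ** 2 for v in grp)
                        for grp in groups)
        f_oracle = (ss_between / 2) / (ss_within / 3)
        f, p = fit_anova(g, y)
        assert f == pytest.approx(f_oracle, abs=1e-10)
        assert p == pytest.approx(stats.f.sf(f_oracle, 2, 3), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_anova([1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0])

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            fit_anova([0, 0, 1], [1.0, 2.0, 3.0])

    def test_pairwise_t_tests_cover_class_pairs(self):
        g = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        out = pairwise_t_tests(g, y)
        assert set(zip(out["class_a"], out["class_b"])) == {(0, 1), (0, 2), (1, 2)}


class TestBhFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.001, 0.01, 0.02, 0.05]),
            [0.004, 0.02, 0.0266667, 0.05], atol=1e-6)

    def test_single_p(self):
        assert bh_fdr([0.3]).tolist() == [0.3]

    def test_ties_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.05] * 10), [0.05] * 10)

    def test_invalid_p_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [-0.1]):
            with pytest.raises(ValueError):
                bh_fdr(bad)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, 200)
        np.testing.assert_allclose(
            bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10**6))
    def test_monotone_and_permutation_consistent(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-9, 1, int(rng.integers(2, 50)))
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        perm = rng.permutation(len(p))
        np.testing.assert_allclose(bh_fdr(p[perm]), adj[perm], atol=1e-15)


class TestScanGroup:
    def test_output_threshold_one_keeps_all_testable(self, study):
        part = call_activity(study.cohort, "SOX2")
        expr = study.cohort.expression.drop(index="SOX2")
        pairs = scan_group(study.genotypes, expr, part.active_patients,
                           study.gene_positions, p_out_threshold=1.1)
        assert len(pairs) == pairs.attrs["n_tested"]

    def test_empty_group_rejected(self, study):
        expr = study.cohort.expression.drop(index="SOX2")
        with pytest.raises(ValueError):
            scan_group(study.genotypes, expr, [], study.gene_positions)

    def test_monomorphic_in_group_skipped(self):
        """A SNP constant within the scanned patients is skipped, not fit."""
        from condqtl.eqtl import GenotypeMatrix

        variants = pd.DataFrame({
            "id": ["s_mono", "s_poly"], "chrom": ["chr1"] * 2,
            "pos": [100, 200], "ref": ["A"] * 2, "alt": ["C"] * 2})
        dos = np.array([[1.0] * 6, [0, 0, 1, 1, 2, 2]])
        geno = GenotypeMatrix(dos, variants, [f"p{i}" for i in range(6)])
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(2, 6)),
                            index=["gA", "gB"], columns=geno.patient_ids)
        genes = pd.DataFrame({"gene_id": ["gA", "gB"], "chrom": ["chr1"] * 2,
                              "tss": [150, 160]})
        pairs = scan_group(geno, expr, geno.patient_ids, genes,
                           p_out_threshold=1.1)
        assert set(pairs["snp_id"]) == {"s_poly"}
        assert pairs.attrs["n_skipped"] == 2
        assert pairs.attrs["n_tested"] == 2

    def test_missing_dosages_pairwise_complete(self):
        """Scan with scattered missing genotypes matches per-pair fits."""
        cfg = SimConfig(seed=9, missing_rate=0.05, n_snps=10, n_genes=5)
        study = simulate_study(cfg)
        part = call_activity(study.cohort, "SOX2")
        expr = study.cohort.expression.drop(index="SOX2")
        pairs = scan_group(study.genotypes, expr, part.active_patients,
                           study.gene_positions, p_out_threshold=1.1)
        sub = study.genotypes.subset_patients(part.active_patients)
        row = pairs.iloc[0]
        g = sub.dosages[list(sub.variants["id"]).index(row["snp_id"])]
        y = expr.loc[row["gene_id"], part.active_patients].to_numpy()
        beta, t, p = fit_additive(g, y)
        assert row["beta"] == pytest.approx(beta, abs=1e-12)
        assert row["p_value"] == pytest.approx(p, abs=1e-12)


class TestCompareGroups:
    @staticmethod
    def pairs(records, group):
        return pd.DataFrame(
            [{"snp_id": s, "gene_id": g, "distance": 0, "beta": 1.0,
              "t_stat": 1.0, "p_value": p, "fdr": f, "group": group}
             for s, g, p, f in records])

    def test_shared_and_unique_classification(self):
        act = self.pairs([("s1", "g1", 1e-5, 0.005), ("s2", "g2", 1e-4, 0.005)],
                         "active")
        inact = self.pairs([("s1", "g1", 1e-5, 0.005), ("s2", "g2", 0.04, 0.5)],
                           "inactive")
        comp = compare_groups(act, inact, 0.01)
        assert set(zip(comp.shared["snp_id"], comp.shared["gene_id"])) \
            == {("s1", "g1")}
        assert set(zip(comp.unique_to_active["snp_id"],
                       comp.unique_to_active["gene_id"])) == {("s2", "g2")}
        assert comp.unique_to_inactive.empty

    def test_sets_disjoint_and_cover_significant(self, study):
        part = call_activity(study.cohort, "SOX2")
        expr = study.cohort.expression.drop(index="SOX2")
        act = scan_group(study.genotypes, expr, part.active_patients,
                         study.gene_positions, group_label="active")
        inact = scan_group(study.genotypes, expr, part.inactive_patients,
                           study.gene_positions, group_label="inactive")
        comp = compare_groups(act, inact, 0.01)
        key = lambda df: set(zip(df["snp_id"], df["gene_id"]))
        ua, ui, sh = (key(comp.unique_to_active),
                      key(comp.unique_to_inactive), key(comp.shared))
        assert not (ua & ui) and not (ua & sh) and not (ui & sh)
        sig = (key(act[act["fdr"] < 0.01])
               | key(inact[inact["fdr"] < 0.01]))
        assert ua | ui | sh == sig
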