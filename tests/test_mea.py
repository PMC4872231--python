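"""MEA stage: pair extraction, relative transform, models, permutation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdyn import (
    RunConfig,
    compare_distributions,
    extract_pairs,
    mea_model1,
    mea_model2,
    methylation_sd,
    relative_to_reference,
    run_mea,
    spearman_permutation,
)


class TestExtractPairs:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chromosome", "tss", "strand"])

    def _cpgs(self, rows):
        return pd.DataFrame(rows, columns=["probe_id", "chromosome", "position", "snp_overlap"])

    def test_window_boundary_inclusive(self):
        genes = self._genes([("g1", "chr1", 10_000, "+")])
        cpgs = self._cpgs([("cgA", "chr1", 15_000, False), ("cgB", "chr1", 15_001, False)])
        pairs = extract_pairs(genes, cpgs, window=5000)
        assert pairs["probe_id"].tolist() == ["cgA"]
        assert pairs["tss_distance"].tolist() == [5000]

    def test_snp_probes_excluded(self):
        genes = self._genes([("g1", "chr1", 10_000, "+")])
        cpgs = self._cpgs([("cgA", "chr1", 10_100, True), ("cgB", "chr1", 10_200, False)])
        pairs = extract_pairs(genes, cpgs, window=5000)
        assert pairs["probe_id"].tolist() == ["cgB"]

    def test_strand_adjusted_distance_sign(self):
        genes = self._genes([("g+", "chr1", 10_000, "+"), ("g-", "chr2", 10_000, "-")])
        cpgs = self._cpgs([("cgA", "chr1", 11_000, False), ("cgB", "chr2", 11_000, False)])
        pairs = extract_pairs(genes, cpgs, window=5000).set_index("gene_id")
        assert pairs.loc["g+", "tss_distance"] == 1000
        assert pairs.loc["g-", "tss_distance"] == -1000  # upstream in reading direction

    def test_matches_brute_force_scan(self, rng):
        genes = self._genes(
            [(f"g{i}", f"chr{rng.integers(1, 4)}", int(rng.integers(1, 60_000)),
              "+" if rng.random() < 0.5 else "-") for i in range(30)]
        )
        cpgs = self._cpgs(
            [(f"cg{i}", f"chr{rng.integers(1, 4)}", int(rng.integers(1, 60_000)),
              bool(rng.random() < 0.2)) for i in range(200)]
        )
        pairs = extract_pairs(genes, cpgs, window=5000)
        got = set(zip(pairs["gene_id"], pairs["probe_id"]))
        expected = {
            (g.gene_id, c.probe_id)
            for g in genes.itertuples()
            for c in cpgs.itertuples()
            if g.chromosome == c.chromosome
            and not c.snp_overlap
            and abs(c.position - g.tss) <= 5000
        }
        assert got == expected


class TestRelativeToReference:
    def test_reference_element_is_one(self, rng):
        out = relative_to_reference(rng.uniform(0.5, 2, 10), ref_index=3)
        assert out[3] == 1.0

    def test_hand_computed(self):
        np.testing.assert_allclose(
            relative_to_reference(np.array([2.0, 4.0, 1.0]), 0), [1.0, 2.0, 0.5]
        )

    def test_zero_reference_excluded_not_infinite(self):
        assert relative_to_reference(np.array([0.0, 1.0, 2.0]), 0) is None


class TestModels:
    def test_model1_perfect_fit(self, rng):
        m = rng.uniform(0.8, 1.2, 24)
        b, r2 = mea_model1(3.0 + 2.0 * m, m)
        assert b == pytest.approx(2.0) and r2 == pytest.approx(1.0)

    def test_model1_r2_is_squared_pearson(self, rng):
        for _ in range(20):
            e, m = rng.normal(size=24), rng.normal(size=24)
            _, r2 = mea_model1(e, m)
            assert r2 == pytest.approx(np.corrcoef(e, m)[0, 1] ** 2, abs=1e-12)

    def test_model1_constant_inputs(self):
        assert mea_model1(np.ones(5), np.arange(5.0)) == (0.0, 0.0)
        assert mea_model1(np.arange(5.0), np.ones(5)) == (0.0, 0.0)

    def test_model2_constant_covariate_reduces_to_model1(self, rng):
        e, m = rng.normal(size=24), rng.normal(size=24)
        _, r2_1 = mea_model1(e, m)
        _, _, r2_2 = mea_model2(e, m, np.full(24, 0.3))
        assert r2_2 == pytest.approx(r2_1, abs=1e-10)

    def test_model2_pure_composition_signal_attributes_nothing_to_methylation(self):
        """E driven entirely by the covariate: methylation-attributed R^2 stays
        below the null 95th percentile at n = 24."""
        rng = np.random.default_rng(31)
        null_r2 = []
        for _ in range(500):
            x = rng.normal(size=24)
            null_r2.append(np.corrcoef(x, rng.normal(size=24))[0, 1] ** 2)
        cutoff = np.percentile(null_r2, 95)

        hits = 0
        for _ in range(50):
            ct = rng.normal(size=24)
            e = 2.0 * ct
            m = rng.normal(size=24)
            _, _, r2m = mea_model2(e, m, ct)
            hits += r2m < cutoff
        assert hits >= 45

    def test_model2_scale_invariance_in_methylation(self, rng):
        e, m, ct = rng.normal(size=24), rng.normal(size=24), rng.normal(size=24)
        _, _, a = mea_model2(e, m, ct)
        _, _, b = mea_model2(e, 7.3 * m, ct)
        assert b == pytest.approx(a, abs=1e-10)


class TestSpearmanPermutation:
    def test_monotone_pair_minimum_p(self):
        x = np.arange(24.0)
        rho, p = spearman_permutation(x, x**3, n_perm=1000, rng=0)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1001, abs=1e-3)
        assert p >= 1 / 1001

    def test_rho_matches_rank_then_pearson_with_ties(self, rng):
        for _ in range(10):
            e = rng.integers(0, 5, 20).astype(float)  # heavy ties
            m = rng.integers(0, 5, 20).astype(float)
            if np.ptp(e) == 0 or np.ptp(m) == 0:
                continue
            rho, _ = spearman_permutation(e, m, n_perm=10, rng=1)
            expected = np.corrcoef(stats.rankdata(e), stats.rankdata(m))[0, 1]
            assert rho == pytest.approx(expected, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        e, m = rng.normal(size=24), rng.normal(size=24)
        assert spearman_permutation(e, m, 500, rng=42) == spearman_permutation(
            e, m, 500, rng=42
        )

    def test_constant_series_flagged_null(self):
        assert spearman_permutation(np.ones(10), np.arange(10.0), 100, rng=0) == (0.0, 1.0)

    def test_p_bounds(self, rng):
        for _ in range(20):
            _, p = spearman_permutation(rng.normal(size=10), rng.normal(size=10), 99, rng=rng)
            assert 1 / 100 <= p <= 1.0


class TestDistributionComparison:
    def test_identical_groups_p_one(self):
        x = np.arange(10.0)
        out = compare_distributions(x, x)
        assert out["p_value"] == pytest.approx(1.0)

    def test_u_statistic_matches_pairwise_count(self, rng):
        for _ in range(10):
            a = rng.normal(size=int(rng.integers(3, 20)))
            b = rng.normal(size=int(rng.integers(3, 20)))
            out = compare_distributions(a, b)
            u = sum((ai > bi) + 0.5 * (ai == bi) for ai in a for bi in b)
            assert out["statistic"] == pytest.approx(u)

    def test_tiny_group_gives_summary_only(self):
        out = compare_distributions(np.array([1.0]), np.arange(5.0))
        assert out["degenerate"] and out["p_value"] is None

    def test_null_level(self):
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            if compare_distributions(rng.normal(size=15), rng.normal(size=15))["p_value"] < 0.05:
                hits += 1
        assert abs(hits / n_rep - 0.05) < 2.576 * np.sqrt(0.05 * 0.95 / n_rep)


class TestMethylationSD:
    def test_constant_zero(self):
        assert methylation_sd(np.full(10, 0.4)) == 0.0

    def test_hand_computed(self):
        assert methylation_sd(np.array([0.1, 0.3])) == pytest.approx(0.1414213562, abs=1e-9)


class TestRunMEA:
    def test_cea_filter_semantics(self, small_dataset, small_config):
        """Stratified MEA analyses exactly the pairs at non-CEA genes."""
        from methdyn import estimate_composition, detect_dynamic_genes, run_cea

        ds = small_dataset
        comp = estimate_composition(ds.methylation, ds.signature)
        dyn = detect_dynamic_genes(ds.expression, small_config)
        cea = run_cea(ds.expression, comp, small_config)
        pairs = extract_pairs(ds.gene_annotation, ds.cpg_annotation, 5000)
        res, summary = run_mea(
            ds.expression, ds.methylation, pairs, cea, dyn, small_config, composition=comp
        )
        cea_genes = set(cea.loc[cea["is_cea"], "gene_id"])
        assert not (set(res["gene_id"]) & cea_genes)
        expected = pairs.loc[~pairs["gene_id"].isin(cea_genes)]
        assert len(res) + summary.n_excluded_reference == len(expected)

    def test_planted_pairs_score_high_nulls_score_low(self, small_dataset, small_config):
        from methdyn import estimate_composition, detect_dynamic_genes, run_cea

        ds = small_dataset
        comp = estimate_composition(ds.methylation, ds.signature)
        dyn = detect_dynamic_genes(ds.expression, small_config)
        cea = run_cea(ds.expression, comp, small_config)
        pairs = extract_pairs(ds.gene_annotation, ds.cpg_annotation, 5000)
        res, _ = run_mea(ds.expression, ds.methylation, pairs, cea, dyn, small_config)
        planted = {(p["gene_id"], p["probe_id"]) for p in ds.truth.mea_pairs}
        keys = list(zip(res["gene_id"], res["probe_id"]))
        is_planted = np.array([k in planted for k in keys])
        analysed_planted = res.loc[is_planted]
        if len(analysed_planted):
            assert (analysed_planted["perm_p"] < 0.05).mean() >= 0.8
        null_frac = (res.loc[~is_planted, "perm_p"] < 0.05).mean()
        assert null_frac < 0.10
        assert res.loc[~is_planted, "r2_model1"].median() < 0.06
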