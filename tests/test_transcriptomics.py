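"""TMM normalization, BH adjustment, differential expression, gene-set scores
and the response-rate statistic."""

import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from radscreen import transcriptomics as tx
from radscreen.simulate import CountsSimSpec, simulate_counts

GENE50 = [f"G{i:05d}" for i in range(1, 51)]


def bh_oracle(pvals):
    """Brute-force step-up: adj_k = min over l>=k of m*p_(l)/(l+1), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    for k in range(m):
        adj_sorted[k] = min(
            min(m * sorted_p[l] / (l + 1) for l in range(k, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBHAdjust:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_worked_examples(self, pvals, expected):
        assert tx.bh_adjust(pvals) == pytest.approx(expected)

    def test_matches_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(tx.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(size=50)
            reference = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(tx.bh_adjust(p), reference, atol=1e-12)

    def test_adjusted_at_least_raw_and_order_preserving(self, rng):
        p = rng.uniform(size=100)
        adj = tx.bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(np.diff(adj[np.argsort(p, kind="mergesort")]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tx.bh_adjust([0.5, 1.5])


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]})
        assert tx.tmm_factors(counts).tolist() == [1.0, 1.0]

    def test_pure_library_size_scaling_absorbed(self, rng):
        base = rng.poisson(50, size=100)
        counts = pd.DataFrame({"a": base, "b": base * 3})
        np.testing.assert_allclose(tx.tmm_factors(counts), [1.0, 1.0], atol=1e-9)

    def test_geometric_mean_is_one(self):
        counts, _, _ = simulate_counts(
            CountsSimSpec(n_genes=500, library_size_factors=[1, 2, 0.5, 1, 1.5, 0.8], seed=11)
        )
        factors = tx.tmm_factors(counts)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tx.tmm_factors(counts)

    def test_matches_edger_reference_implementation(self):
        """Cross-check against Bioconductor edgeR's calcNormFactors on a
        small matrix with composition bias and unequal library sizes."""
        counts, _, _ = simulate_counts(
            CountsSimSpec(
                n_genes=300,
                library_size_factors=[1, 2, 0.5, 1, 1.5, 0.8],
                planted_sets=[("S", [f"G{i:05d}" for i in range(1, 31)], 1.5)],
                seed=7,
            )
        )
        mine = tx.tmm_factors(counts).to_numpy()
        with tempfile.TemporaryDirectory() as d:
            counts.to_csv(f"{d}/counts.tsv", sep="\t")
            script = (
                f'suppressMessages(library(edgeR)); '
                f'x <- read.delim("{d}/counts.tsv", row.names=1); '
                'y <- DGEList(counts=as.matrix(x)); '
                'y <- calcNormFactors(y, method="TMM"); '
                'cat(y$samples$norm.factors, sep="\\n")'
            )
            proc = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
            )
        assert proc.returncode == 0, proc.stderr
        edger = np.array([float(v) for v in proc.stdout.split()])
        np.testing.assert_allclose(mine, edger, rtol=1e-4)

    def test_normalizer_transform_shape(self):
        counts, _, _ = simulate_counts(CountsSimSpec(n_genes=100, seed=3))
        expr = tx.TMMNormalizer().fit_transform(counts)
        assert expr.shape == counts.shape
        assert np.isfinite(expr.to_numpy()).all()


class TestLowExpressionFilter:
    def test_zero_count_gene_removed(self):
        counts = pd.DataFrame(
            {"a": [0, 100, 50], "b": [0, 90, 60]}, index=["dead", "g1", "g2"]
        )
        kept = tx.filter_low_expression(counts, min_cpm=1, min_samples=2)
        assert "dead" not in kept.index

    def test_zero_threshold_is_identity(self):
        counts = pd.DataFrame({"a": [0, 1], "b": [2, 3]})
        pd.testing.assert_frame_equal(tx.filter_low_expression(counts, min_cpm=0), counts)

    def test_hand_computed_cpm_table(self):
        # library sizes 1000 and 2000; gene "low" has CPM (1000, 500):
        # below min_cpm=600 in sample a? 1000 >= 600, 500 < 600 -> only 1
        # sample passes, so with min_samples=2 it is removed
        counts = pd.DataFrame(
            {"a": [1, 499, 300, 150, 50], "b": [1, 999, 600, 300, 100]},
            index=["low", "g1", "g2", "g3", "g4"],
        )
        kept = tx.filter_low_expression(counts, min_cpm=600.0, min_samples=2)
        assert list(kept.index) == ["g1", "g2", "g3", "g4"]

    def test_everything_filtered_rejected(self):
        counts = pd.DataFrame({"a": [1, 1], "b": [1, 1]})
        with pytest.raises(ValueError, match="all genes"):
            tx.filter_low_expression(counts, min_cpm=1e9, min_samples=1)


class TestDifferentialExpression:
    def test_swapping_labels_negates_log_fold_change(self):
        counts, samples, _ = simulate_counts(
            CountsSimSpec(n_genes=300, planted_sets=[("S", GENE50, 1.0)], seed=13)
        )
        groups = samples.set_index("sample")["group"]
        forward = tx.differential_expression(counts, groups)
        swapped = groups.map({"group1": "group2", "group2": "group1"})
        # relabel so sorted order flips the contrast
        backward = tx.differential_expression(counts, swapped)
        np.testing.assert_allclose(forward["log2_fc"], -backward["log2_fc"], atol=1e-12)

    def test_planted_genes_recovered_at_raw_level(self):
        """With unmoderated t tests at n=3 vs 3 (4 degrees of freedom) a
        4-fold planted shift is detected at raw p < 0.01 for most planted
        genes; bound frozen from a 20-seed oracle simulation."""
        rates = []
        for seed in range(20):
            counts, samples, _ = simulate_counts(
                CountsSimSpec(planted_sets=[("S", GENE50, 2.0)], seed=1000 + seed)
            )
            de = tx.differential_expression(counts, samples.set_index("sample")["group"])
            planted = de.loc[de.index.isin(GENE50)]
            rates.append((planted["p_value"] < 0.01).mean())
            assert planted["log2_fc"].median() > 1.0
        assert np.mean(rates) >= 0.5

    def test_planted_genes_recovered_at_fdr_level_with_adequate_replication(self):
        # at n=8 per group the unmoderated test has the power to clear BH at 1%
        recovered = []
        for seed in range(3):
            counts, samples, _ = simulate_counts(
                CountsSimSpec(n_samples_per_group=8, planted_sets=[("S", GENE50, 2.0)], seed=seed)
            )
            de = tx.differential_expression(counts, samples.set_index("sample")["group"])
            recovered.append(de.loc[de.index.isin(GENE50), "significant"].mean())
        assert np.mean(recovered) >= 0.8

    def test_null_false_positive_proportion_small(self):
        fps = []
        for seed in range(10):
            counts, samples, _ = simulate_counts(CountsSimSpec(n_genes=1000, seed=500 + seed))
            de = tx.differential_expression(counts, samples.set_index("sample")["group"])
            fps.append(de["significant"].mean())
        assert np.mean(fps) <= 0.02

    def test_single_sample_group_rejected(self):
        counts, samples, _ = simulate_counts(CountsSimSpec(n_genes=100, seed=1))
        groups = ["group1"] + ["group2"] * 5
        with pytest.raises(ValueError, match="at least two"):
            tx.differential_expression(counts, groups)

    def test_estimator_facade(self):
        counts, samples, _ = simulate_counts(CountsSimSpec(n_genes=100, seed=2))
        est = tx.TwoGroupDifferentialExpression().fit(counts, samples.set_index("sample")["group"])
        assert est.contrast_ == "group2 vs group1"
        assert len(est.results_) <= 100


class TestEnrichmentScores:
    def _expression(self, n_genes=500, n_samples=4, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n_genes, n_samples)),
            index=[f"G{i:05d}" for i in range(1, n_genes + 1)],
            columns=[f"S{j}" for j in range(n_samples)],
        )

    def test_top_expressed_set_scores_positive(self):
        expr = self._expression()
        top = expr["S0"].nlargest(30).index.tolist()
        scores = tx.enrichment_scores(expr, {"TOP": top})
        assert scores.loc["TOP", "S0"] > 0

    def test_random_sets_standardized_under_null(self, rng):
        expr = self._expression(seed=1)
        sets = {
            f"R{k}": list(rng.choice(expr.index, size=40, replace=False))
            for k in range(1000)
        }
        scores = tx.enrichment_scores(expr, sets)["S0"]
        assert abs(scores.mean()) < 0.1
        assert scores.var() == pytest.approx(1.0, rel=0.15)

    def test_set_and_complement_score_opposite_signs(self):
        expr = self._expression(n_genes=200)
        members = list(expr.index[:60])
        complement = list(expr.index[60:])
        scores = tx.enrichment_scores(expr, {"SET": members, "COMP": complement})
        assert np.all(np.sign(scores.loc["SET"]) == -np.sign(scores.loc["COMP"]))

    def test_low_coverage_set_dropped_with_warning(self):
        expr = self._expression(n_genes=100)
        sets = {"MOSTLY_ABSENT": ["G00001", "X1", "X2", "X3"], "OK": list(expr.index[:20])}
        with pytest.warns(UserWarning, match="MOSTLY_ABSENT"):
            scores = tx.enrichment_scores(expr, sets)
        assert list(scores.index) == ["OK"]

    def test_planted_set_score_difference_positive_across_seeds(self):
        hits = 0
        for seed in range(20):
            counts, samples, sets = simulate_counts(
                CountsSimSpec(planted_sets=[("PLANTED", GENE50, 2.0)], seed=3000 + seed)
            )
            expr = tx.TMMNormalizer().fit_transform(counts)
            scores = tx.enrichment_scores(expr, sets)
            groups = samples.set_index("sample")["group"]
            diff = (
                scores.loc["PLANTED", groups[groups == "group2"].index].mean()
                - scores.loc["PLANTED", groups[groups == "group1"].index].mean()
            )
            hits += diff > 0
        assert hits >= 19


class TestDifferentialGeneSets:
    def test_planted_set_significant_and_up(self):
        counts, samples, sets = simulate_counts(
            CountsSimSpec(planted_sets=[("PLANTED", GENE50, 2.0)], seed=42)
        )
        groups = samples.set_index("sample")["group"]
        expr = tx.TMMNormalizer().fit_transform(counts)
        scores = tx.enrichment_scores(expr, sets)
        result = tx.differential_gene_sets(scores, groups)
        assert result.loc["PLANTED", "significant"]
        assert result.loc["PLANTED", "direction"] == "up"

    def test_identical_groups_have_zero_difference(self):
        scores = pd.DataFrame(
            [[1.0, 2.0, 1.0, 2.0]], index=["SET"], columns=["a", "b", "c", "d"]
        )
        result = tx.differential_gene_sets(scores, ["g1", "g1", "g2", "g2"], fdr=0.01)
        assert result.loc["SET", "mean_difference"] == pytest.approx(0.0)


class TestResponseRate:
    @pytest.mark.parametrize(
        "p,fc,expected", [(0.01, 4.0, 4.0), (0.5, 1.0, 0.0), (0.001, 0.5, -3.0)]
    )
    def test_worked_examples(self, p, fc, expected):
        assert tx.response_rate(p, fc) == pytest.approx(expected)

    @given(
        p=st.floats(1e-10, 1.0, exclude_max=False),
        fc=st.floats(1e-3, 1e3),
    )
    def test_antisymmetric_in_fold_change(self, p, fc):
        assert tx.response_rate(p, fc) == pytest.approx(
            -tx.response_rate(p, 1.0 / fc), abs=1e-9
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            tx.response_rate(0.0, 2.0)
        with pytest.raises(ValueError):
            tx.response_rate(0.5, -1.0)
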