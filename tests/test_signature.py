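"""PCA signature fitting/projection, ROC separation, survival screening."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from lungdiverge.datamodel import ClinicalTable, ExpressionMatrix
from lungdiverge.signature import (
    evaluate_separation,
    fit_pca_signature,
    kaplan_meier_table,
    project_samples,
    survival_screen,
    _tertile_split,
)

from conftest import make_clinical


def expression_from_array(arr, symbols=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    symbols = symbols or [f"G{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    ann = pd.DataFrame(
        {
            "symbol": symbols,
            "chromosome": "chr1",
            "start": np.arange(1, arr.shape[0] + 1) * 1000,
            "end": np.arange(1, arr.shape[0] + 1) * 1000 + 500,
        },
        index=[f"probe{i}" for i in range(arr.shape[0])],
    )
    return ExpressionMatrix(ann, pd.DataFrame(arr, index=ann.index, columns=samples))


def two_cluster_expression(n_per=6, n_genes=5, informative=0, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    arr = rng.normal(8.0, 0.3, (n_genes, 2 * n_per))
    arr[informative, n_per:] += gap
    labels = pd.Series(
        [0] * n_per + [1] * n_per,
        index=[f"s{j}" for j in range(2 * n_per)],
    )
    return expression_from_array(arr), labels


class TestPcaFit:
    def test_single_informative_gene_dominates_pc1(self):
        # raw-covariance PCA: the cluster gap carries nearly all variance
        expr, labels = two_cluster_expression()
        model = fit_pca_signature(expr, labels, [f"G{i}" for i in range(5)],
                                  standardize=False)
        top = np.argmax(np.abs(model.loadings[:, 0]))
        assert model.genes[top] == "G0"
        scores = model.training_scores["PC1"]
        assert abs(scores[labels == 1].mean() - scores[labels == 0].mean()) > 2.0

    def test_loadings_unit_norm_with_sign_convention(self):
        expr, labels = two_cluster_expression(seed=3)
        model = fit_pca_signature(expr, labels, [f"G{i}" for i in range(5)])
        assert np.linalg.norm(model.loadings, axis=0) == pytest.approx([1.0, 1.0])
        for k in range(2):
            imax = np.argmax(np.abs(model.loadings[:, k]))
            assert model.loadings[imax, k] > 0

    def test_sample_order_invariance(self):
        expr, labels = two_cluster_expression(seed=5)
        perm = np.random.default_rng(1).permutation(expr.values.shape[1])
        shuffled = ExpressionMatrix(expr.annotation, expr.values.iloc[:, perm])
        a = fit_pca_signature(expr, labels, [f"G{i}" for i in range(5)])
        b = fit_pca_signature(shuffled, labels.iloc[perm], [f"G{i}" for i in range(5)])
        assert a.loadings == pytest.approx(b.loadings)
        assert a.training_scores.loc["s3"].to_numpy() == pytest.approx(
            b.training_scores.loc["s3"].to_numpy()
        )

    def test_constant_genes_dropped(self):
        expr, labels = two_cluster_expression()
        vals = expr.values.copy()
        vals.iloc[4] = 5.0  # constant row
        expr2 = ExpressionMatrix(expr.annotation, vals)
        model = fit_pca_signature(expr2, labels, [f"G{i}" for i in range(5)])
        assert "G4" not in model.genes

    def test_requires_three_per_class(self):
        expr, labels = two_cluster_expression(n_per=2)
        with pytest.raises(ValueError, match="3 samples"):
            fit_pca_signature(expr, labels, [f"G{i}" for i in range(5)])


class TestProjection:
    def test_training_set_projects_to_training_scores(self):
        expr, labels = two_cluster_expression(seed=7)
        model = fit_pca_signature(expr, labels, [f"G{i}" for i in range(5)])
        scores = project_samples(model, expr)
        assert scores.to_numpy() == pytest.approx(
            model.training_scores.to_numpy()
        )

    def test_constant_offset_absorbed_by_test_centering(self):
        # per-gene platform offsets vanish under test-side standardization
        expr, labels = two_cluster_expression(seed=9)
        rng = np.random.default_rng(0)
        shift = rng.normal(0, 2, (expr.values.shape[0], 1))
        offset = ExpressionMatrix(expr.annotation, expr.values + shift)
        model = fit_pca_signature(expr, labels, [f"G{i}" for i in range(5)],
                                  standardize=False)
        got = project_samples(model, offset, center_mode="test")
        assert got.to_numpy() == pytest.approx(model.training_scores.to_numpy())

    def test_training_centering_shifts_scores_linearly(self):
        # with frozen training statistics, a per-gene offset c moves every
        # sample's score by the constant c . loadings
        expr, labels = two_cluster_expression(seed=9)
        shift = np.full((expr.values.shape[0], 1), 3.5)
        offset = ExpressionMatrix(expr.annotation, expr.values + shift)
        model = fit_pca_signature(expr, labels, [f"G{i}" for i in range(5)],
                                  standardize=False)
        got = project_samples(model, offset, center_mode="training")
        expected_shift = (shift[:, 0] @ model.loadings)
        assert got.to_numpy() == pytest.approx(
            model.training_scores.to_numpy() + expected_shift
        )

    def test_missing_genes_renormalized_with_warning(self, caplog):
        expr, labels = two_cluster_expression(seed=11, n_genes=6)
        model = fit_pca_signature(expr, labels, [f"G{i}" for i in range(6)])
        half = ExpressionMatrix(expr.annotation.iloc[:3], expr.values.iloc[:3])
        with caplog.at_level("WARNING", logger="lungdiverge"):
            scores = project_samples(model, half, min_gene_frac=0.5)
        assert "renormalized" in caplog.text
        assert scores.shape == model.training_scores.shape

    def test_too_few_shared_genes_is_error(self):
        expr, labels = two_cluster_expression(seed=13, n_genes=6)
        model = fit_pca_signature(expr, labels, [f"G{i}" for i in range(6)])
        tiny = ExpressionMatrix(expr.annotation.iloc[:2], expr.values.iloc[:2])
        with pytest.raises(ValueError, match="model genes"):
            project_samples(model, tiny, min_gene_frac=0.5)


class TestSeparation:
    def test_perfect_separation(self):
        scores = pd.Series([1, 2, 3, 10, 11, 12.0], index=list("abcdef"))
        labels = pd.Series([0, 0, 0, 1, 1, 1], index=list("abcdef"))
        assert evaluate_separation(scores, labels).auc == 1.0

    def test_orientation_free(self):
        scores = pd.Series([1, 2, 3, 10, 11, 12.0], index=list("abcdef"))
        labels = pd.Series([1, 1, 1, 0, 0, 0], index=list("abcdef"))
        res = evaluate_separation(scores, labels)
        assert res.auc == 1.0 and res.polarity == -1

    def test_label_permutation_centers_on_half(self):
        rng = np.random.default_rng(17)
        scores = pd.Series(rng.normal(size=40), index=[f"s{j}" for j in range(40)])
        labels = pd.Series([0] * 20 + [1] * 20, index=scores.index)
        aucs = []
        for _ in range(50):
            perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
            # raw (non-orientation-free) AUC is the null-centred quantity
            from lungdiverge.stats import roc_auc
            aucs.append(roc_auc(scores.to_numpy(), perm.to_numpy()))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(19)
        scores = pd.Series(rng.normal(size=30), index=[f"s{j}" for j in range(30)])
        labels = pd.Series(rng.integers(0, 2, 30), index=scores.index)
        labels.iloc[0] = 0
        labels.iloc[1] = 1
        a = evaluate_separation(scores, labels).auc
        b = evaluate_separation(np.exp(scores * 2), labels).auc
        assert a == pytest.approx(b)


class TestTertileSplit:
    def test_nine_samples_split_three_three(self):
        values = pd.Series(np.arange(9.0), index=[f"s{j}" for j in range(9)])
        low, high = _tertile_split(values)
        assert len(low) == len(high) == 3
        assert low == ["s0", "s1", "s2"] and high == ["s6", "s7", "s8"]

    def test_floor_rule_for_non_divisible_n(self):
        values = pd.Series(np.arange(10.0), index=[f"s{j}" for j in range(10)])
        low, high = _tertile_split(values)
        assert len(low) == len(high) == 3  # floor(10/3)

    def test_ties_resolved_by_stable_order(self):
        values = pd.Series([1.0] * 6, index=[f"s{j}" for j in range(6)])
        low, high = _tertile_split(values)
        assert low == ["s0", "s1"] and high == ["s4", "s5"]


def make_survival_clinical(samples, subtype, times, events):
    table = pd.DataFrame(
        {
            "subtype": subtype,
            "survival_time": times,
            "event": events,
        },
        index=samples,
    )
    return ClinicalTable(table)


class TestSurvivalScreen:
    def test_contexts_partition_and_sizes(self):
        rng = np.random.default_rng(23)
        samples = [f"a{i}" for i in range(9)] + [f"b{i}" for i in range(9)]
        clinical = make_survival_clinical(
            samples, ["AC"] * 9 + ["SqCC"] * 9,
            rng.exponential(20, 18), rng.integers(0, 2, 18),
        )
        expr = expression_from_array(rng.normal(8, 1, (2, 18)), samples=samples)
        out = survival_screen(expr, clinical, ["G0", "G1"])
        by_context = {(r.context, r.gene): r for r in out}
        assert by_context[("AC", "G0")].n_low == 3
        assert by_context[("NSCLC", "G0")].n_low == 6
        assert set(r.context for r in out) == {"AC", "SqCC", "NSCLC"}

    def test_null_gene_p_uniform(self):
        """With expression independent of survival, screen p-values over
        seeded replicates are consistent with uniformity (KS test)."""
        rng = np.random.default_rng(29)
        pvals = []
        for _ in range(60):
            n = 30
            samples = [f"s{j}" for j in range(n)]
            clinical = make_survival_clinical(
                samples, ["SqCC"] * n,
                rng.exponential(30, n), np.ones(n, dtype=int),
            )
            expr = expression_from_array(rng.normal(8, 1, (1, n)), samples=samples)
            out = survival_screen(expr, clinical, ["G0"], contexts=("SqCC",))
            pvals.append(out[0].p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_hazard_detected_with_direction(self):
        """High expression tripling the hazard: detected with the high
        tertile marked as the worse-survival group."""
        rng = np.random.default_rng(31)
        n = 60
        samples = [f"s{j}" for j in range(n)]
        expr_vals = rng.normal(8, 1, n)
        z = (expr_vals - expr_vals.mean()) / expr_vals.std()
        times = rng.exponential(1.0 / (0.05 * np.exp(np.log(3.0) * z)))
        clinical = make_survival_clinical(samples, ["AC"] * n, times, np.ones(n, int))
        expr = expression_from_array(expr_vals[None, :], samples=samples)
        out = survival_screen(expr, clinical, ["G0"], contexts=("AC",))
        assert out[0].p < 0.01
        assert out[0].direction == "high_worse"


def test_kaplan_meier_step_function():
    km = kaplan_meier_table(
        np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 1, 0, 1])
    )
    assert km["survival"].tolist() == pytest.approx([0.75, 0.5, 0.0])
    assert km["at_risk"].tolist() == [4, 3, 1]
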