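"""Metrics, ROC/MCC, statistical tests and the five CV protocols."""

import itertools

import numpy as np
import pytest

from foldstab import (
    CvScheme,
    MutationDataset,
    antisymmetry_audit,
    augment_with_reverse,
    compare_correlations_independent,
    delong_auc_test,
    evaluate_predictions,
    fit_slope,
    label_extremes,
    mcc,
    pearson_r,
    rmse,
    roc_analysis,
    run_cv,
)
from foldstab.datasets import MutationRecord, ProteinCluster
from foldstab.errors import (
    ConfigurationError,
    DegenerateInputError,
    SchemaError,
    ValidationError,
)
from foldstab.evaluate import generate_cv_splits


class TestScalarMetrics:
    def test_identity_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert rmse(x, x) == 0.0
        assert fit_slope(x, x) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_five_point_fixture_matches_hand_computation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        # moment formulae evaluated independently
        dx, dy = x - x.mean(), y - y.mean()
        r_hand = (dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum())
        assert pearson_r(x, y) == pytest.approx(r_hand)
        assert pearson_r(x, y) == pytest.approx(0.82199494, abs=1e-8)
        assert fit_slope(x, y) == pytest.approx(1.0)
        assert rmse(x, y) == pytest.approx(1.0)

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMcc:
    def test_perfect_classifier(self):
        assert mcc(50, 50, 0, 0) == 1.0

    def test_random_classifier(self):
        assert mcc(25, 25, 25, 25) == 0.0

    def test_printed_formula_arithmetic(self):
        expected = (40 * 30 - 10 * 20) / np.sqrt((40 + 10) * (40 + 20) * (30 + 10) * (30 + 20))
        assert mcc(40, 30, 10, 20) == pytest.approx(expected)
        assert mcc(40, 30, 10, 20) == pytest.approx(0.40824829, abs=1e-8)

    def test_empty_marginal_returns_zero(self):
        assert mcc(0, 10, 0, 5) == 0.0

    def test_all_zero_matrix_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            mcc(0, 0, 0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            mcc(-1, 1, 1, 1)


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == 1.0
        assert res.max_mcc == 1.0

    def test_auc_equals_concordant_pair_fraction(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.4, 0.2])
        labels = np.array([1, 1, 0, 1, 0, 0], dtype=bool)
        res = roc_analysis(scores, labels)
        pos = scores[labels]
        neg = scores[~labels]
        concordant = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p, n in itertools.product(pos, neg)
        )
        assert res.auc == pytest.approx(concordant / (len(pos) * len(neg)))
        assert res.auc == pytest.approx(8 / 9)

    def test_uninformative_scores_have_half_auc(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        assert roc_analysis(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_max_mcc_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        labels = scores + rng.normal(size=50) > 0
        res = roc_analysis(scores, labels)
        best = max(
            mcc(
                int(((scores >= t) & labels).sum()),
                int(((scores < t) & ~labels).sum()),
                int(((scores >= t) & ~labels).sum()),
                int(((scores < t) & labels).sum()),
            )
            for t in np.unique(scores)
        )
        assert res.max_mcc == pytest.approx(best)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_analysis([0.1, 0.2, 0.3], [1, 1, 1])


class TestLabelExtremes:
    def test_thresholds_are_inclusive(self):
        destab, stab = label_extremes([1.0, -1.0, 0.99, -0.99, 2.5])
        assert destab.tolist() == [True, False, False, False, True]
        assert stab.tolist() == [False, True, False, False, False]


class TestAntisymmetryAudit:
    def test_perfect_antisymmetry(self):
        pf = np.array([1.0, -0.5, 2.0, 0.3])
        r_fr, bias = antisymmetry_audit(pf, -pf)
        assert r_fr == pytest.approx(-1.0)
        assert bias == 0.0

    def test_symmetric_predictor_is_worst_case(self):
        pf = np.array([1.0, -0.5, 2.0, 0.3])
        r_fr, _ = antisymmetry_audit(pf, pf)
        assert r_fr == pytest.approx(1.0)

    def test_noisy_fixture_matches_direct_pearson(self):
        rng = np.random.default_rng(2)
        pf = rng.normal(size=100)
        pr = -pf + 0.3 * rng.normal(size=100)
        r_fr, bias = antisymmetry_audit(pf, pr)
        assert r_fr == pytest.approx(pearson_r(pf, pr))
        assert bias == pytest.approx(np.mean(pf + pr))

    def test_shape_mismatch(self):
        with pytest.raises(SchemaError):
            antisymmetry_audit([1.0, 2.0], [1.0])


class TestCorrelationComparison:
    def test_equal_correlations_give_p_one(self):
        assert compare_correlations_independent(0.5, 100, 0.5, 80) == pytest.approx(1.0)

    def test_large_difference_is_significant(self):
        assert compare_correlations_independent(0.9, 500, 0.1, 500) < 1e-6

    def test_exchange_symmetry(self):
        p1 = compare_correlations_independent(0.7, 120, 0.4, 90)
        p2 = compare_correlations_independent(0.4, 90, 0.7, 120)
        assert p1 == pytest.approx(p2)

    def test_matches_closed_form_z(self):
        from scipy import stats

        r1, n1, r2, n2 = 0.6, 60, 0.3, 80
        z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
        assert compare_correlations_independent(r1, n1, r2, n2) == pytest.approx(
            2 * stats.norm.sf(abs(z))
        )

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValidationError):
            compare_correlations_independent(1.0, 50, 0.5, 50)


class TestDelong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.4
        res = delong_auc_test(scores, scores, labels)
        assert res.p_value == 1.0
        assert res.auc_a == res.auc_b

    def test_internal_aucs_match_roc_analysis(self):
        rng = np.random.default_rng(4)
        labels = rng.random(200) < 0.5
        a = rng.normal(size=200) + labels
        b = rng.normal(size=200) + 0.5 * labels
        res = delong_auc_test(a, b, labels)
        assert res.auc_a == pytest.approx(roc_analysis(a, labels).auc, abs=1e-12)
        assert res.auc_b == pytest.approx(roc_analysis(b, labels).auc, abs=1e-12)

    def test_clear_difference_detected(self):
        rng = np.random.default_rng(5)
        labels = rng.random(500) < 0.5
        informative = labels + 0.5 * rng.normal(size=500)
        noise = rng.normal(size=500)
        assert delong_auc_test(informative, noise, labels).p_value < 1e-6

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            delong_auc_test([0.1, 0.2], [0.3, 0.1], [1, 1])


# ---------------------------------------------------------------------------
# cross-validation protocols

def make_dataset(protein_sizes: dict[str, int], paired=True, seed=0):
    """Synthetic mutation dataset with the given forward count per protein."""
    rng = np.random.default_rng(seed)
    records = []
    for pid, n in protein_sizes.items():
        for i in range(n):
            records.append(
                MutationRecord(
                    protein_id=pid, chain="A", position=i + 1, wt="L", mut="A",
                    ddg=float(rng.normal()),
                )
            )
    ds = MutationDataset("cvtest", records)
    return augment_with_reverse(ds) if paired else ds


class TestCvSplits:
    def test_cv4_yields_one_fold_per_protein(self):
        ds = make_dataset({"P1": 4, "P2": 6, "P3": 5})
        folds = list(generate_cv_splits(ds, CvScheme("CV4")))
        assert len(folds) == 3
        for train, test in folds:
            test_proteins = {ds.records[i].protein_id for i in test}
            assert len(test_proteins) == 1
            assert test_proteins.isdisjoint(ds.records[i].protein_id for i in train)
        # coverage: every mutation in exactly one test fold
        all_test = np.concatenate([test for _, test in folds])
        assert sorted(all_test) == list(range(len(ds)))

    def test_cv5_leaves_whole_clusters_out(self):
        ds = make_dataset({"P1": 4, "P2": 6, "P3": 5})
        clusters = [ProteinCluster(0, ["P1", "P2"]), ProteinCluster(1, ["P3"])]
        folds = list(generate_cv_splits(ds, CvScheme("CV5"), clusters=clusters))
        assert len(folds) == 2
        first_test_proteins = {ds.records[i].protein_id for i in folds[0][1]}
        assert first_test_proteins == {"P1", "P2"}
        all_test = np.concatenate([test for _, test in folds])
        assert sorted(all_test) == list(range(len(ds)))

    def test_cv5_without_clusters_is_a_configuration_error(self):
        ds = make_dataset({"P1": 4})
        with pytest.raises(ConfigurationError):
            list(generate_cv_splits(ds, CvScheme("CV5")))

    def test_no_pair_is_ever_split_across_train_and_test(self):
        ds = make_dataset({"P1": 10, "P2": 15, "P3": 8}, seed=1)
        pair_of = {i: r.pair_id for i, r in enumerate(ds.records)}
        for kind in ("CV1", "CV2", "CV3"):
            for seed in range(10):
                scheme = CvScheme(kind, repeats=2, seed=seed)
                for train, test in generate_cv_splits(ds, scheme):
                    train_pairs = {pair_of[i] for i in train}
                    test_pairs = {pair_of[i] for i in test}
                    assert train_pairs.isdisjoint(test_pairs)

    def test_cv3_cap_matches_min_summation_oracle(self):
        # singleton (unpaired) records with protein sizes {30, 10, 25}
        ds = make_dataset({"P1": 30, "P2": 10, "P3": 25}, paired=False)
        scheme = CvScheme("CV3", repeats=5, cap=20, seed=0)
        for train, test in generate_cv_splits(ds, scheme):
            assert len(train) + len(test) == min(30, 20) + min(10, 20) + min(25, 20)

    def test_cv1_fraction_controls_split_size(self):
        ds = make_dataset({"P1": 20, "P2": 20})
        for train, test in generate_cv_splits(ds, CvScheme("CV1", repeats=3, seed=2)):
            assert len(train) + len(test) == len(ds)
            assert len(train) == pytest.approx(0.8 * len(ds), abs=2)

    def test_bad_scheme_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            CvScheme("CV9")
        with pytest.raises(ConfigurationError):
            CvScheme("CV1", fraction=1.5)
        with pytest.raises(ConfigurationError):
            CvScheme("CV3", cap=0)


class TestRunCv:
    def test_cv4_end_to_end_on_synthetic_bundle(self, small_bundle):
        X = small_bundle.features.to_numpy()
        result = run_cv(
            small_bundle.dataset, X, CvScheme("CV4", seed=0),
            model_params={"n_trees": 60}, locations=small_bundle.locations,
        )
        assert len(result.reports) == len(small_bundle.dataset.proteins())
        assert result.summary["mean_rmse"] > 0
        assert "r_fr" in result.summary
        assert len(result.seeds) == len(result.reports)

    def test_same_seed_reproduces_cv_exactly(self, small_bundle):
        X = small_bundle.features.to_numpy()
        kw = dict(model_params={"n_trees": 40}, locations=small_bundle.locations)
        r1 = run_cv(small_bundle.dataset, X, CvScheme("CV1", repeats=2, seed=5), **kw)
        r2 = run_cv(small_bundle.dataset, X, CvScheme("CV1", repeats=2, seed=5), **kw)
        assert [rep.r for rep in r1.reports] == [rep.r for rep in r2.reports]
        assert r1.summary == r2.summary

    def test_stratified_report_covers_directions_and_signs(self, small_bundle):
        X = small_bundle.features.to_numpy()
        result = run_cv(
            small_bundle.dataset, X, CvScheme("CV2", repeats=1, seed=3),
            model_params={"n_trees": 40}, locations=small_bundle.locations,
        )
        strata = result.reports[0].strata
        assert any(k.startswith("direction=") for k in strata)
        assert any(k.startswith("sign=") for k in strata)
        assert any(k.startswith("location=") for k in strata)


class TestEvaluatePredictions:
    def test_report_fields_and_strata(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        y = x + 0.2 * rng.normal(size=50)
        groups = np.where(np.arange(50) < 25, "a", "b")
        rep = evaluate_predictions(x, y, strata={"g": groups})
        assert rep.n == 50
        assert rep.r > 0.9
        assert set(rep.strata) == {"g=a", "g=b"}
        assert rep.strata["g=a"]["n"] == 25
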