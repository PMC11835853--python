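import numpy as np
import pytest

from sspr import bayes
from sspr.bayes import BENIGN, PATHOGENIC, ModelConfig
from sspr.mna import DescriptorSet
from sspr.validation import (
    DEFAULT_LEVELS,
    DEFAULT_PLS,
    classification_metrics,
    grid_report_csv,
    grid_search,
    iap,
    kfold_auc,
    loo_auc,
)

from conftest import naive_loo_scores, random_descriptor_dataset

CFG = ModelConfig(pl=5, level=5)


def ds(*items):
    return DescriptorSet(level=5, items=frozenset(items))


def brute_force_auc(scored):
    wins = ties = 0
    pos = [s for s, l in scored if l == 1]
    neg = [s for s, l in scored if l == 0]
    for p in pos:
        for n in neg:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestIAP:
    def test_perfect_separation(self):
        assert iap([(2.0, 1), (3.0, 1), (0.0, 0), (1.0, 0)]) == 1.0

    def test_all_ties(self):
        assert iap([(1.0, 1), (1.0, 0), (1.0, 1), (1.0, 0)]) == 0.5

    def test_hand_example(self):
        scored = [(3.0, 1), (1.0, 1), (2.0, 0), (0.0, 0)]
        assert iap(scored) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            iap([(1.0, 1), (2.0, 1)])

    def test_matches_brute_force_and_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 40)
            # coarse scores to force heavy ties
            scores = rng.integers(0, 5, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            scored = list(zip(scores, labels))
            ours = iap(scored)
            assert abs(ours - brute_force_auc(scored)) < 1e-12
            assert (
                abs(ours - sklearn_metrics.roc_auc_score(labels, scores)) < 1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        base = iap(list(zip(scores, labels)))
        warped = iap(list(zip(np.exp(3 * scores), labels)))
        assert base == pytest.approx(warped, abs=1e-12)


class TestLOO:
    def test_fast_path_equals_naive_retrain(self):
        rng = np.random.default_rng(2)
        for n in (8, 14, 30):
            examples = random_descriptor_dataset(rng, n)
            fast = loo_auc(examples, CFG).per_example_scores
            naive = naive_loo_scores(examples, CFG)
            for (i, s, l), (j, t, m) in zip(fast, naive):
                assert (i, l) == (j, m)
                assert s == t  # bit-exact

    def test_disjoint_classes_are_all_neutral(self):
        examples = [
            (ds("A"), PATHOGENIC), (ds("B"), PATHOGENIC),
            (ds("X"), BENIGN), (ds("Y"), BENIGN),
        ]
        result = loo_auc(examples, CFG)
        assert all(s == 0.0 for _, s, _ in result.per_example_scores)
        assert result.auc == 0.5

    def test_duplicated_dataset_keeps_support(self, synthetic_examples):
        examples, config = synthetic_examples
        path = [e for e in examples if e[1] == PATHOGENIC][:15]
        ben = [e for e in examples if e[1] == BENIGN][:25]
        subset = path + ben
        single = loo_auc(subset, config).auc
        doubled = loo_auc(subset * 2, config).auc
        assert doubled >= single

    def test_loo_predictions_match_per_example_refits(self):
        from sspr.validation import loo_predictions

        rng = np.random.default_rng(8)
        examples = random_descriptor_dataset(rng, 12)
        preds = loo_predictions(examples, CFG)
        naive = naive_loo_scores(examples, CFG)
        assert len(preds) == len(examples)
        for (i, pred, label), (j, s, m) in zip(preds, naive):
            assert (i, label) == (j, m)
            assert pred.score == s
            assert pred.confidence == pred.pa - pred.pi
            assert -1.0 <= pred.confidence <= 1.0

    def test_small_class_rejected(self):
        examples = [
            (ds("A"), PATHOGENIC),
            (ds("B"), BENIGN), (ds("C"), BENIGN), (ds("D"), BENIGN),
        ]
        with pytest.raises(ValueError):
            loo_auc(examples, CFG)


class TestKFold:
    def test_deterministic_and_order_independent(self):
        rng = np.random.default_rng(3)
        examples = random_descriptor_dataset(rng, 24)
        a = kfold_auc(examples, 4, seed=9, config=CFG).auc
        shuffled = [examples[i] for i in rng.permutation(len(examples))]
        b = kfold_auc(shuffled, 4, seed=9, config=CFG).auc
        assert a == b

    def test_maximal_k_matches_loo_on_class_disjoint_data(self):
        # 5+5 balanced set whose classes share no descriptors: excluding a
        # benign example never changes a pathogenic score and vice versa, so
        # stratified folds at the maximal k (= class size, one example of
        # each class per fold) reproduce the LOO scores exactly
        examples = [(ds("P", "Q"), PATHOGENIC) for _ in range(5)] + [
            (ds("B"), BENIGN) for _ in range(5)
        ]
        loo = loo_auc(examples, CFG)
        kf = kfold_auc(examples, 5, seed=0, config=CFG)
        assert kf.auc == loo.auc
        assert sorted(s for _, s, _ in kf.per_example_scores) == sorted(
            s for _, s, _ in loo.per_example_scores
        )

    def test_separable_synthetic_high_auc(self, synthetic_examples):
        examples, config = synthetic_examples
        result = kfold_auc(examples, 5, seed=1, config=config)
        assert result.auc >= 0.85
        assert len(result.per_example_scores) == len(examples)

    def test_class_smaller_than_k_rejected(self):
        examples = [
            (ds("A"), PATHOGENIC), (ds("B"), PATHOGENIC),
            (ds("X"), BENIGN), (ds("Y"), BENIGN), (ds("Z"), BENIGN),
        ]
        with pytest.raises(ValueError):
            kfold_auc(examples, 3, seed=0, config=CFG)


class TestGrid:
    def test_default_axes_cardinality(self):
        assert len(DEFAULT_PLS) == 14
        assert len(DEFAULT_LEVELS) == 11
        assert len(DEFAULT_PLS) * len(DEFAULT_LEVELS) == 154

    def test_small_grid_and_tie_break(self):
        # datasets engineered so every cell has the same AUC: the tie-break
        # must pick the smallest window, then the smallest level
        def provider(pl):
            from sspr import build_molecular_graph

            return [
                (build_molecular_graph("AKA"), PATHOGENIC),
                (build_molecular_graph("AKA"), PATHOGENIC),
                (build_molecular_graph("ADA"), BENIGN),
                (build_molecular_graph("ADA"), BENIGN),
            ]

        result = grid_search(provider, pls=[5, 7], levels=[5, 6])
        assert result.n_cells == 4
        aucs = set(result.cells.values())
        assert len(aucs) == 1
        assert result.best == (5, 5)

    def test_single_cell(self, synthetic_examples):
        from sspr import SyntheticSpec, generate_synthetic
        from sspr.pipeline import make_provider

        protein, variants = generate_synthetic(SyntheticSpec(seed=11, n_variants=60))
        provider = make_provider(protein, variants)
        result = grid_search(provider, pls=[9], levels=[5])
        assert result.n_cells == 1
        assert result.best == (9, 5)

    def test_invalid_cells_excluded(self):
        def provider(pl):
            from sspr import build_molecular_graph

            # one benign example only: LOO precondition fails everywhere
            return [
                (build_molecular_graph("AKA"), PATHOGENIC),
                (build_molecular_graph("ADA"), PATHOGENIC),
                (build_molecular_graph("AEA"), BENIGN),
            ]

        with pytest.raises(ValueError, match="invalid"):
            grid_search(provider, pls=[5], levels=[5])

    def test_report_csv_shape(self):
        def provider(pl):
            from sspr import build_molecular_graph

            return [
                (build_molecular_graph("AKAKA"), PATHOGENIC),
                (build_molecular_graph("GKGKG"), PATHOGENIC),
                (build_molecular_graph("ADADA"), BENIGN),
                (build_molecular_graph("GDGDG"), BENIGN),
            ]

        result = grid_search(provider, pls=[5], levels=[5, 6])
        text = grid_report_csv(result)
        lines = text.strip().splitlines()
        assert lines[0] == "pl,level,auc_loo,valid"
        assert len(lines) == 3


class TestMetrics:
    def test_perfect_predictor(self):
        m = classification_metrics([0.9, 0.8, -0.7, -0.6], [1, 1, 0, 0])
        assert m == {"BA": 1.0, "MCC": 1.0, "F": 1.0}

    def test_hand_confusion_matrix(self):
        # TP=3, FN=1, FP=1, TN=3
        conf = [1, 1, 1, -1, 1, -1, -1, -1]
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        m = classification_metrics(conf, labels)
        assert m["BA"] == pytest.approx(0.75)
        assert m["MCC"] == pytest.approx(0.5)
        assert m["F"] == pytest.approx(0.75)

    def test_degenerate_all_positive(self):
        m = classification_metrics([1, 1, 1, 1], [1, 1, 0, 0])
        assert m["BA"] == 0.5
        assert m["MCC"] == 0.0
        assert m["F"] == pytest.approx(2 / 3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([1, -1], [1, 1])

    def test_matches_sklearn_on_random_matrices(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(6, 60)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            conf = rng.normal(size=n)
            m = classification_metrics(conf, labels)
            pred = (conf > 0).astype(int)
            assert m["BA"] == pytest.approx(
                sk.balanced_accuracy_score(labels, pred), abs=1e-12
            )
            assert m["MCC"] == pytest.approx(
                sk.matthews_corrcoef(labels, pred), abs=1e-12
            )
            assert m["F"] == pytest.approx(
                sk.f1_score(labels, pred, zero_division=0), abs=1e-12
            )
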