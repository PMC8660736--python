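"""Evaluation protocol: splits, metrics, DeLong, Fleiss, 2-D export."""

import itertools

import numpy as np
import pandas as pd
import pytest

from radlabel.corpus import GeneratorConfig, generate_corpus, to_frame
from radlabel.evaluation import (
    DegenerateVarianceError,
    UndefinedAUCError,
    UndefinedKappaError,
    classification_metrics,
    delong_test,
    export_2d_embeddings,
    fleiss_kappa,
    flip_labels,
    patient_level_split,
    repeated_evaluation,
    roc_auc,
)
from radlabel.training import LeakageError


def _frame(patient_ids, labels=None):
    n = len(patient_ids)
    return pd.DataFrame({
        "report_id": [f"r{i}" for i in range(n)],
        "patient_id": patient_ids,
        "text": ["t"] * n,
        "abnormal": labels if labels is not None else [i % 2 for i in range(n)],
    })


class TestPatientLevelSplit:
    def test_exact_divisibility_ten_patients(self):
        frame = _frame([f"p{i}" for i in range(10)])
        spec = patient_level_split(frame, seed=0)
        parts = spec.apply(frame)
        assert (len(parts["train"]), len(parts["val"]), len(parts["test"])) \
            == (6, 2, 2)

    def test_multi_report_patient_stays_in_one_bucket(self):
        frame = _frame(["a", "a", "a", "b", "c", "d", "e", "f"])
        spec = patient_level_split(frame, seed=3)
        buckets = frame["patient_id"].map(spec.assignment)
        assert buckets[frame["patient_id"] == "a"].nunique() == 1

    def test_bad_fractions_rejected(self):
        frame = _frame(["a", "b"])
        with pytest.raises(ValueError):
            patient_level_split(frame, fractions=(0.5, 0.2, 0.2))

    def test_holdout_patients_excluded(self):
        frame = _frame([f"p{i}" for i in range(10)])
        spec = patient_level_split(frame, holdout_patients={"p3", "p7"}, seed=1)
        assert spec.bucket("p3") == "excluded"
        assert spec.bucket("p7") == "excluded"
        parts = spec.apply(frame)
        held = set(parts["excluded"]["patient_id"])
        assert held == {"p3", "p7"}

    def test_seed_determinism(self):
        frame = _frame([f"p{i}" for i in range(30)])
        a = patient_level_split(frame, seed=9).assignment
        b = patient_level_split(frame, seed=9).assignment
        assert a == b

    def test_no_leakage_on_random_multi_report_corpora(self):
        for seed in range(20):
            frame = to_frame(*generate_corpus(
                GeneratorConfig(n_reports=80, seed=seed)))
            spec = patient_level_split(frame, seed=seed)
            parts = spec.apply(frame)
            pats = {k: set(parts[k]["patient_id"]) for k in
                    ("train", "val", "test")}
            for a, b in itertools.combinations(pats.values(), 2):
                assert not (a & b)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_three_of_four_concordant_pairs(self):
        assert roc_auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(4, 50))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = rng.choice(np.linspace(0, 1, 7), size=n)  # ties likely
            pos, neg = s[y == 1], s[y == 0]
            pairs = [(a, b) for a in pos for b in neg]
            expect = np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                              for a, b in pairs])
            assert roc_auc(s, y) == pytest.approx(expect, abs=1e-12)


class TestClassificationMetrics:
    def test_perfect_scores(self):
        m = classification_metrics([0.9, 0.8, 0.1], [1, 1, 0])
        assert all(v == 1.0 for v in m.values())

    def test_always_positive_predictor(self):
        m = classification_metrics([1.0] * 4, [1, 0, 1, 0])
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.0
        assert m["balanced_accuracy"] == 0.5

    def test_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(5)
        s = rng.random(50)
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        m = classification_metrics(s, y, threshold=0.4)
        pred = s >= 0.4
        tp = np.sum(pred & (y == 1))
        tn = np.sum(~pred & (y == 0))
        fp = np.sum(pred & (y == 0))
        fn = np.sum(~pred & (y == 1))
        assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
        assert m["specificity"] == pytest.approx(tn / (tn + fp))
        assert m["balanced_accuracy"] == pytest.approx(
            0.5 * (tp / (tp + fn) + tn / (tn + fp)))
        assert m["f1"] == pytest.approx(2 * tp / (2 * tp + fp + fn))


class TestDeLong:
    def test_self_comparison_gives_p_one(self):
        rng = np.random.default_rng(0)
        y = np.array([1, 0] * 10)
        s = rng.random(20)
        delta, z, p = delong_test(s, s, y)
        assert delta == 0.0 and p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        y = np.array([1] * 12 + [0] * 12)
        a = rng.random(24) + 0.3 * y
        b = rng.random(24) + 0.1 * y
        d_ab, z_ab, p_ab = delong_test(a, b, y)
        d_ba, z_ba, p_ba = delong_test(b, a, y)
        assert d_ab == pytest.approx(-d_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_unpaired_mode_requires_second_labels(self):
        y = np.array([1, 0, 1, 0])
        with pytest.raises(ValueError):
            delong_test(np.random.rand(4), np.random.rand(4), y,
                        mode="unpaired")

    def test_degenerate_variance_with_unequal_aucs(self):
        y = np.array([1, 0])
        with pytest.raises(DegenerateVarianceError):
            delong_test([0.9, 0.1], [0.1, 0.9], y)

    def test_paired_variance_matches_bootstrap(self):
        """Structural-component variance of the paired AUC difference
        agrees with a 2,000-replicate bootstrap within 20% at n=200."""
        rng = np.random.default_rng(42)
        n = 200
        y = (rng.random(n) < 0.5).astype(int)
        y[:2] = [0, 1]
        latent = y + rng.normal(0, 1, n)
        a = latent + rng.normal(0, 0.6, n)
        b = latent + rng.normal(0, 0.9, n)
        # analytic variance via z: var = (delta / z)^2
        delta, z, _ = delong_test(a, b, y)
        var_analytic = (delta / z) ** 2
        boot = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            yy = y[idx]
            if yy.min() == yy.max():
                continue
            boot.append(roc_auc(a[idx], yy) - roc_auc(b[idx], yy))
        var_boot = np.var(boot, ddof=1)
        assert abs(var_analytic - var_boot) / var_boot < 0.2


class TestFleissKappa:
    def test_perfect_agreement_mixed_marginals(self):
        counts = np.array([[2, 0], [0, 2]])
        assert fleiss_kappa(counts) == pytest.approx(1.0)

    def test_both_subjects_split_gives_minus_one(self):
        # hand evaluation: P_bar = 0, P_e = 0.5 -> kappa = -1
        counts = np.array([[1, 1], [1, 1]])
        assert fleiss_kappa(counts) == pytest.approx(-1.0)

    def test_single_category_marginals_undefined(self):
        counts = np.array([[3, 0], [3, 0]])
        with pytest.raises(UndefinedKappaError):
            fleiss_kappa(counts)

    def test_matches_statsmodels_on_random_tables(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_kappa

        rng = np.random.default_rng(2)
        for _ in range(100):
            n, k, r = int(rng.integers(3, 20)), int(rng.integers(2, 5)), 4
            counts = rng.multinomial(r, np.ones(k) / k, size=n)
            try:
                ours = fleiss_kappa(counts)
            except UndefinedKappaError:
                continue
            assert ours == pytest.approx(sm_kappa(counts), abs=1e-10)


class _OracleModel:
    """Fixed 'good classifier': generator-truth score plus Gaussian noise."""

    def __init__(self, frame, category, sigma=0.0, seed=0):
        rng = np.random.default_rng(seed)
        truth = dict(zip(frame["text"], frame[category]))
        self._scores = {
            t: v + (rng.normal(0, sigma) if sigma else 0.0)
            for t, v in truth.items()
        }

    def predict_proba(self, texts):
        return np.array([self._scores[t] for t in texts])


@pytest.fixture(scope="module")
def corpus_and_holdout():
    frame = to_frame(*generate_corpus(GeneratorConfig(n_reports=300,
                                                      seed=14)))
    patients = sorted(frame["patient_id"].unique())
    hold = set(patients[:8])
    holdout = frame[frame["patient_id"].isin(hold)].reset_index(drop=True)
    rest = frame[~frame["patient_id"].isin(hold)].reset_index(drop=True)
    return rest, holdout


class TestRepeatedEvaluation:
    @staticmethod
    def _oracle_train_fn(full_frame, sigma=0.25):
        def train_fn(train, val, category, hp, seed):
            return _OracleModel(full_frame, category, sigma=sigma, seed=seed)
        return train_fn

    def test_single_repeat_has_undefined_ci(self, corpus_and_holdout):
        rest, holdout = corpus_and_holdout
        full = pd.concat([rest, holdout])
        res = repeated_evaluation(rest, "abnormal", holdout, n_repeats=1,
                                  train_fn=self._oracle_train_fn(full))
        assert np.isnan(res["report"].ci_half_width("auc"))

    def test_perfect_classifier_gives_auc_one_ci_zero(self, corpus_and_holdout):
        rest, holdout = corpus_and_holdout
        full = pd.concat([rest, holdout])
        res = repeated_evaluation(rest, "abnormal", holdout, n_repeats=3,
                                  train_fn=self._oracle_train_fn(full, sigma=0))
        for key in ("report", "image"):
            assert res[key].mean("auc") == 1.0
            assert res[key].ci_half_width("auc") == 0.0

    def test_holdout_fixed_across_repeats(self, corpus_and_holdout):
        rest, holdout = corpus_and_holdout
        full = pd.concat([rest, holdout])
        res = repeated_evaluation(rest, "abnormal", holdout, n_repeats=4,
                                  train_fn=self._oracle_train_fn(full))
        assert res["holdout_report_ids"] == tuple(holdout["report_id"])

    def test_holdout_patient_overlap_rejected(self, corpus_and_holdout):
        rest, _ = corpus_and_holdout
        with pytest.raises(LeakageError):
            repeated_evaluation(rest, "abnormal", rest.head(5), n_repeats=1)

    def test_label_noise_lowers_measured_auc(self, corpus_and_holdout):
        """Corrupting the hold-out labels (image/report disagreement)
        strictly lowers the measured AUC of a fixed good classifier."""
        rest, holdout = corpus_and_holdout
        full = pd.concat([rest, holdout])
        noisy = holdout.copy()
        noisy["abnormal"] = flip_labels(noisy["abnormal"], 0.10, seed=3)
        fn = self._oracle_train_fn(full, sigma=0.35)
        clean = repeated_evaluation(rest, "abnormal", holdout, n_repeats=3,
                                    train_fn=fn, seed=5)
        corrupt = repeated_evaluation(rest, "abnormal", noisy, n_repeats=3,
                                      train_fn=fn, seed=5)
        assert corrupt["image"].mean("auc") < clean["image"].mean("auc")


class TestEmbeddingExport:
    def test_identical_vectors_collapse(self):
        X = np.vstack([np.ones((3, 8)), np.zeros((3, 8)) + 5.0])
        out = export_2d_embeddings(X, [0, 0, 0, 1, 1, 1], seed=0)
        same = out.iloc[:3][["x", "y"]].to_numpy()
        spread = np.linalg.norm(
            out[["x", "y"]].to_numpy().max(0) - out[["x", "y"]].to_numpy().min(0))
        assert np.linalg.norm(same - same.mean(0)) < 0.05 * spread

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 6))
        a = export_2d_embeddings(X, np.zeros(20), seed=4)
        b = export_2d_embeddings(X, np.zeros(20), seed=4)
        assert np.allclose(a[["x", "y"]], b[["x", "y"]])

    def test_two_separated_clusters_keep_silhouette(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, size=(40, 64))
        b = rng.normal(10, 1, size=(40, 64))
        X = np.vstack([a, b])
        labels = np.array([0] * 40 + [1] * 40)
        out = export_2d_embeddings(X, labels, seed=0)
        assert silhouette_score(out[["x", "y"]], labels) > 0.5

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            export_2d_embeddings(np.zeros((2, 4)), [0, 1])
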