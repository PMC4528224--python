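"""Splitting, GA search, SVM training/evaluation, repeated validation, PCA."""

import io

import joblib
import numpy as np
import pandas as pd
import pytest

from wingid.classify import (
    evaluate,
    ga_optimize,
    hierarchical_train,
    load_model,
    misidentification_rate,
    pca_overlap,
    run_repeated_validation,
    save_model,
    split_train_test,
    train_model,
)
from wingid.config import RunConfig
from wingid.errors import ModelError, WingidError
from wingid.ga import ga_maximize
from wingid.pipeline import specimens_to_table
from wingid.synthetic import (
    ShapeFamilySpec,
    default_family_specs,
    generate_family,
    overlapping_family_specs,
    separable_family_specs,
    shipped_prototypes,
)


def _table(specs, n_harmonics=15):
    specimens = [s for spec in specs for s in generate_family(spec)]
    return specimens_to_table(specimens, n_harmonics)


@pytest.fixture(scope="module")
def separable_table():
    return _table(separable_family_specs(n_specimens=12, seed=3))


@pytest.fixture(scope="module")
def overlap_table():
    return _table(overlapping_family_specs(n_specimens=16, seed=3))


def _blob_table(seed, n_per_class=10, n_features=17, shift=4.0):
    """Two Gaussian blobs as a linearly separable toy feature table."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, mu in (("A", 0.0), ("B", shift)):
        X = rng.normal(mu, 1.0, size=(n_per_class, n_features))
        for i, x in enumerate(X):
            rows.append({"source": f"{label}{i}", "label": label,
                         **{f"f{j}": v for j, v in enumerate(x)}})
    return pd.DataFrame(rows)


class TestSplit:
    def test_even_counts_split_in_half(self, separable_table):
        train, test = split_train_test(separable_table, 0.5, seed=1)
        assert (train["label"].value_counts() == 6).all()
        assert (test["label"].value_counts() == 6).all()
        assert set(train.index).isdisjoint(test.index)

    def test_odd_counts_send_extra_to_training(self):
        df = _blob_table(0, n_per_class=13)
        train, test = split_train_test(df, 0.5, seed=0)
        assert (train["label"].value_counts() == 7).all()
        assert (test["label"].value_counts() == 6).all()

    def test_same_seed_same_split(self, separable_table):
        a = split_train_test(separable_table, 0.5, seed=11)
        b = split_train_test(separable_table, 0.5, seed=11)
        assert a[0].index.equals(b[0].index) and a[1].index.equals(b[1].index)

    def test_singleton_class_rejected_by_name(self):
        df = _blob_table(0)
        df = pd.concat([df, pd.DataFrame([{**df.iloc[0].to_dict(), "label": "rare"}])],
                       ignore_index=True)
        with pytest.raises(WingidError, match="rare"):
            split_train_test(df, 0.5, seed=0)


class TestGA:
    def test_separable_classes_reach_full_cv_accuracy(self, fast_config):
        df = _blob_table(1)
        C, gamma, cv = ga_optimize(df, fast_config, seed=1)
        assert cv == 100.0
        assert C > 0 and gamma > 0

    def test_history_is_non_decreasing(self):
        rng = np.random.default_rng(0)
        _, _, history = ga_maximize(lambda g: -np.sum((g - 0.3) ** 2), [(-1, 1), (-1, 1)],
                                    rng, population=10, generations=15)
        assert np.all(np.diff(history) >= 0)

    def test_never_underperforms_default_parameters(self, fast_config):
        """GA's CV accuracy >= the (C=1, gamma=1/n_features) default on >= 8/10 datasets."""
        from wingid.classify import _cv_accuracy, _matrix
        from sklearn.model_selection import StratifiedKFold

        wins = 0
        for seed in range(10):
            spec_a = ShapeFamilySpec("A", shipped_prototypes()["notched"],
                                     n_specimens=10, seed=seed)
            spec_b = ShapeFamilySpec("B", shipped_prototypes()["notched_ii"],
                                     n_specimens=10, seed=seed + 500)
            df = _table([spec_a, spec_b], n_harmonics=8)
            X, y = _matrix(df)
            folds = list(StratifiedKFold(n_splits=fast_config.cv_folds, shuffle=True,
                                         random_state=seed % 2**31).split(X, y))
            baseline = _cv_accuracy(X, y, folds, C=1.0, gamma=1.0 / X.shape[1])
            _, _, cv = ga_optimize(df, fast_config, seed=seed)
            wins += cv >= baseline
        assert wins >= 8


class TestTrainEvaluate:
    def test_training_set_is_reclassified_perfectly_when_separable(self, separable_table):
        model = train_model(separable_table, (10.0, 0.01))
        result = evaluate(model, separable_table)
        assert result.accuracy == 100.0

    def test_serialization_round_trip(self, tmp_path, separable_table):
        model = train_model(separable_table, (10.0, 0.01))
        save_model(tmp_path / "m.joblib", model, n_harmonics=15)
        payload = load_model(tmp_path / "m.joblib")
        loaded = payload["models"][None]
        X = separable_table.filter(regex="^[abcd]").to_numpy()
        assert np.array_equal(loaded.predict(X), model.predict(X))
        assert payload["n_harmonics"] == 15

    def test_corrupt_model_rejected(self, tmp_path):
        joblib.dump({"something": "else"}, tmp_path / "bad.joblib")
        with pytest.raises(ModelError):
            load_model(tmp_path / "bad.joblib")

    def test_row_order_does_not_change_predictions(self, separable_table):
        test = separable_table.sample(frac=0.3, random_state=5)
        shuffled = separable_table.sample(frac=1.0, random_state=7)
        m1 = train_model(separable_table, (10.0, 0.01))
        m2 = train_model(shuffled, (10.0, 0.01))
        X = test.filter(regex="^[abcd]").to_numpy()
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_single_class_training_rejected(self, separable_table):
        with pytest.raises(WingidError):
            train_model(separable_table[separable_table["label"] == "broad"], (1.0, 0.1))

    def test_feature_length_mismatch_rejected(self, separable_table):
        model = train_model(separable_table, (10.0, 0.01))
        with pytest.raises(ModelError, match="feature length"):
            model.predict(np.zeros((2, 5)))

    def test_confusion_rows_sum_to_test_counts_and_recount(self, overlap_table, fast_config):
        train, test = split_train_test(overlap_table, 0.5, seed=2)
        model = train_model(train, (8.0, 0.05))
        result = evaluate(model, test)
        counts = test["label"].value_counts()
        for label in counts.index:
            assert result.confusion.loc[label].sum() == counts[label]
            # independent tally straight from the prediction list
            sub = result.predictions[result.predictions["true"] == label]
            manual = 100.0 * (sub["true"] == sub["predicted"]).mean()
            assert result.per_species[label] == pytest.approx(manual)


class TestMisidentificationRate:
    def test_zero_confusions_zero_rates(self):
        conf = pd.DataFrame(np.diag([10, 12]), index=["A", "B"], columns=["A", "B"])
        pe = misidentification_rate(conf)
        assert pe.loc["A", "B"] == 0.0 and pe.loc["B", "A"] == 0.0

    def test_one_in_twelve_is_8_33_percent(self):
        conf = pd.DataFrame([[11, 1], [0, 10]], index=["A", "B"], columns=["A", "B"])
        pe = misidentification_rate(conf)
        assert pe.loc["A", "B"] == pytest.approx(100.0 / 12.0)

    def test_global_denominator_mode(self):
        conf = pd.DataFrame([[11, 1], [0, 10]], index=["A", "B"], columns=["A", "B"])
        pe = misidentification_rate(conf, denominator="global")
        assert pe.loc["A", "B"] == pytest.approx(100.0 / 22.0)

    def test_accuracy_plus_misid_partitions_100(self, overlap_table, fast_config):
        cfg = RunConfig(n_harmonics=15, n_runs=3, cv_folds=3,
                        ga_population=6, ga_generations=3)
        report = run_repeated_validation(overlap_table, config=cfg, seed=4)
        for species in report.per_species_accuracy.index:
            total = report.per_species_accuracy[species] + report.misid_matrix.loc[species].sum()
            assert total == pytest.approx(100.0)


class TestRepeatedValidation:
    def test_separable_families_fully_identified(self, separable_table, fast_config):
        report = run_repeated_validation(separable_table, config=fast_config, seed=7)
        assert report.mean_test == 100.0
        assert (report.per_species_accuracy == 100.0).all()
        assert np.nansum(report.misid_matrix.to_numpy()) == 0.0

    def test_overlapping_families_confused_in_both_directions(self, overlap_table, fast_config):
        cfg = RunConfig(n_harmonics=15, n_runs=5, cv_folds=3,
                        ga_population=8, ga_generations=5)
        report = run_repeated_validation(overlap_table, config=cfg, seed=7)
        assert report.misid_matrix.loc["notched", "notched_ii"] > 0
        assert report.misid_matrix.loc["notched_ii", "notched"] > 0
        # every aggregate is recomputable from the per-specimen log
        log = report.predictions
        for species in report.per_species_accuracy.index:
            sub = log[log["true"] == species]
            assert report.per_species_accuracy[species] == pytest.approx(
                100.0 * (sub["true"] == sub["predicted"]).mean())

    def test_single_run_matches_direct_evaluation(self, separable_table, fast_config):
        from wingid.classify import _run_seeds

        cfg = RunConfig(n_harmonics=15, n_runs=1, cv_folds=3,
                        ga_population=8, ga_generations=5)
        report = run_repeated_validation(separable_table, config=cfg, seed=13)
        run_seed = _run_seeds(13, 1)[0]
        train, test = split_train_test(separable_table, 0.5, seed=run_seed)
        C, gamma, cv = ga_optimize(train, cfg, seed=run_seed)
        result = evaluate(train_model(train, (C, gamma)), test)
        assert report.runs.loc[0, "cv_accuracy"] == cv
        assert report.runs.loc[0, "test_accuracy"] == result.accuracy
        assert report.mean_test == result.accuracy

    def test_bitwise_reproducible_under_master_seed(self, overlap_table):
        cfg = RunConfig(n_harmonics=15, n_runs=2, cv_folds=3,
                        ga_population=6, ga_generations=3)
        a = run_repeated_validation(overlap_table, config=cfg, seed=21)
        b = run_repeated_validation(overlap_table, config=cfg, seed=21)
        assert a.runs.equals(b.runs)
        assert a.predictions.equals(b.predictions)
        assert a.misid_matrix.equals(b.misid_matrix)

    def test_report_files_written(self, tmp_path, separable_table, fast_config):
        report = run_repeated_validation(separable_table, config=fast_config, seed=3)
        report.write(tmp_path)
        for name in ("runs.csv", "per_species.csv", "misidentification.csv", "predictions.csv"):
            assert (tmp_path / name).is_file()


class TestSeparationMonotonicity:
    def test_more_divergent_prototypes_never_classify_worse(self):
        """Interpolate B away from A; accuracy(small gap) <= accuracy(large gap) >= 8/10 seeds."""
        protos = shipped_prototypes()
        base = ShapeFamilySpec("A", protos["notched"]).coefficient_matrix()
        target = ShapeFamilySpec("B", protos["broad"]).coefficient_matrix()
        n = min(len(base), len(target))
        wins = 0
        for seed in range(10):
            accs = []
            for frac in (0.08, 0.5):
                mixed = base.copy()
                mixed[:n] = (1 - frac) * base[:n] + frac * target[:n]
                rows_a = [(i + 1, *r) for i, r in enumerate(base)]
                rows_b = [(i + 1, *r) for i, r in enumerate(mixed)]
                spec_a = ShapeFamilySpec("A", tuple(rows_a), n_specimens=10, seed=seed)
                spec_b = ShapeFamilySpec("B", tuple(rows_b), n_specimens=10, seed=seed + 99)
                df = _table([spec_a, spec_b], n_harmonics=8)
                train, test = split_train_test(df, 0.5, seed=seed)
                result = evaluate(train_model(train, (10.0, 0.05)), test)
                accs.append(result.accuracy)
            wins += accs[0] <= accs[1]
        assert wins >= 8


class TestPCA:
    def test_planar_data_fully_explained_by_two_components(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 10))
        scores = rng.normal(size=(30, 2))
        X = scores @ basis
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(10)])
        df["label"] = ["A"] * 15 + ["B"] * 15
        emb = pca_overlap(df)
        assert emb.explained_fraction == pytest.approx(1.0, abs=1e-9)

    def test_explained_ratios_sum_to_one(self, separable_table):
        emb = pca_overlap(separable_table)
        assert emb.explained_ratios.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scores_match_eigendecomposition_oracle(self, separable_table):
        emb = pca_overlap(separable_table)
        X = separable_table.filter(regex="^[abcd]").to_numpy()
        Xc = X - X.mean(axis=0)
        w, v = np.linalg.eigh(Xc.T @ Xc)
        oracle = Xc @ v[:, ::-1][:, :2]
        for j in range(2):  # eigenvectors defined up to sign
            assert (np.allclose(emb.scores[:, j], oracle[:, j], atol=1e-8)
                    or np.allclose(emb.scores[:, j], -oracle[:, j], atol=1e-8))

    def test_too_few_specimens_rejected(self, separable_table):
        with pytest.raises(WingidError):
            pca_overlap(separable_table.iloc[:2])


class TestHierarchical:
    def test_single_group_equals_flat_validation(self, separable_table):
        cfg = RunConfig(n_harmonics=15, n_runs=1, cv_folds=3,
                        ga_population=6, ga_generations=3)
        flat = run_repeated_validation(separable_table, config=cfg, seed=5)
        group_of = {s: "all" for s in separable_table["label"].unique()}
        grouped = run_repeated_validation(separable_table, config=cfg, seed=5, group_of=group_of)
        assert grouped.per_species_accuracy.equals(flat.per_species_accuracy)
        assert grouped.runs["test_accuracy"].equals(flat.runs["test_accuracy"])

    def test_separating_overlapping_pair_kills_cross_group_confusion(self, fast_config):
        df = _table(default_family_specs(n_specimens=12, seed=3))
        cfg = RunConfig(n_harmonics=15, n_runs=3, cv_folds=3,
                        ga_population=8, ga_generations=5)
        flat = run_repeated_validation(df, config=cfg, seed=9)
        group_of = {"broad": "g1", "notched": "g1", "slender": "g2", "notched_ii": "g2"}
        grouped = run_repeated_validation(df, config=cfg, seed=9, group_of=group_of)
        # the overlapping pair now lives in different groups: P_e structurally 0
        assert grouped.misid_matrix.loc["notched", "notched_ii"] == 0.0
        assert grouped.misid_matrix.loc["notched_ii", "notched"] == 0.0
        assert grouped.mean_test >= flat.mean_test

    def test_final_models_one_per_group(self, separable_table, fast_config):
        group_of = {"broad": "g1", "falcate": "g1", "slender": "g2", "notched": "g2"}
        models = hierarchical_train(separable_table, group_of, config=fast_config, seed=2)
        assert set(models) == {"g1", "g2"}
        assert models["g1"].classes == ("broad", "falcate")

    def test_single_species_group_gets_trivial_assigner(self, separable_table, fast_config):
        group_of = {"broad": "solo", "falcate": "rest", "slender": "rest", "notched": "rest"}
        models = hierarchical_train(separable_table, group_of, config=fast_config, seed=2)
        assert models["solo"].svm is None
        X = separable_table.filter(regex="^[abcd]").to_numpy()[:3]
        assert list(models["solo"].predict(X)) == ["broad"] * 3

    def test_unassigned_species_rejected(self, separable_table, fast_config):
        with pytest.raises(WingidError, match="without a group"):
            hierarchical_train(separable_table, {"broad": "g1"}, config=fast_config)
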