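"""Linear-SVM classification with leave-one-replicate-out evaluation."""

import numpy as np
import pandas as pd
import pytest

from entsense.classify import (
    FEATURES_1D,
    FEATURES_2D,
    assemble_features,
    classifier_metrics,
    compare_1d_2d,
    leave_one_replicate_out,
    split_results_frame,
    train_linear_svm,
)


def make_records(
    n_reps=4,
    n_per_rep=10,
    mean_t=(0.8, 0.4),
    mean_s=(0.3, 0.7),
    sd=0.02,
    seed=0,
    on_curve=False,
):
    """Synthetic feature table: transgenic vs control clusters."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, strain, mt, ms in [
        ("transgenic", "5xFAD", mean_t[0], mean_s[0]),
        ("control", "CD1", mean_t[1], mean_s[1]),
    ]:
        for rep in range(1, n_reps + 1):
            for i in range(n_per_rep):
                if on_curve:
                    p = np.clip(rng.normal(mt, sd), 0, 1)
                    t = max(0.0, (3 * p - 1) / 2) ** 2
                    s = 1 - p**2
                    phat = p
                else:
                    t = np.clip(rng.normal(mt, sd), 0, 1)
                    s = np.clip(rng.normal(ms, sd), 0, 1)
                    phat = np.clip(np.sqrt(max(1 - s, 0)), 0, 1)
                rows.append(
                    {
                        "tangle": t,
                        "linear_entropy": s,
                        "werner_p_hat": phat,
                        "label": label,
                        "strain": strain,
                        "region": "hippocampus",
                        "replicate_id": rep,
                        "spot_id": f"{strain}-r{rep}-s{i}",
                    }
                )
    return pd.DataFrame(rows)


class TestAssembleFeatures:
    def test_one_record_per_individual_measurement(self):
        df = make_records(n_reps=4, n_per_rep=25)
        out = assemble_features(df, ("5xFAD", "CD1"), "hippocampus")
        assert len(out) == 2 * 4 * 25  # both classes, all measurements

    def test_region_partition_preserves_total(self):
        df = make_records()
        df2 = df.copy()
        df2["region"] = "cortex"
        both = pd.concat([df, df2])
        n_hip = len(assemble_features(both, region="hippocampus"))
        n_cor = len(assemble_features(both, region="cortex"))
        assert n_hip + n_cor == len(both)

    def test_empty_selection_is_empty_not_error(self):
        df = make_records()
        out = assemble_features(df, ("P301L", "NTL"))
        assert out.empty

    def test_missing_label_rejected(self):
        df = make_records()
        df.loc[0, "label"] = None
        with pytest.raises(ValueError, match="label"):
            assemble_features(df)


class TestTrainLinearSVM:
    def test_separable_clusters_perfect_training_accuracy(self):
        df = make_records()
        X = df[list(FEATURES_2D)].to_numpy()
        y = df["label"].to_numpy()
        model = train_linear_svm(X, y, seed=0)
        assert (model.predict(X) == y).all()

    def test_mirrored_two_point_problem_bisector(self):
        # one point per class, mirrored through the origin: max-margin
        # boundary is the perpendicular bisector with zero bias
        X = np.array([[1.0, 1.0], [-1.0, -1.0]])
        y = np.array(["transgenic", "control"])
        model = train_linear_svm(X, y, C_grid=[100.0], seed=0)
        assert model.bias == pytest.approx(0.0, abs=1e-6)
        w = model.weights / np.linalg.norm(model.weights)
        np.testing.assert_allclose(np.abs(w), [np.sqrt(0.5)] * 2, atol=1e-6)

    def test_deterministic_selected_c(self):
        df = make_records()
        X = df[list(FEATURES_2D)].to_numpy()
        y = df["label"].to_numpy()
        c1 = train_linear_svm(X, y, seed=11).selected_C
        c2 = train_linear_svm(X, y, seed=11).selected_C
        assert c1 == c2

    def test_single_class_rejected(self):
        X = np.zeros((5, 2))
        y = np.array(["transgenic"] * 5)
        with pytest.raises(ValueError, match="two classes"):
            train_linear_svm(X, y)


class TestClassifierMetrics:
    def test_perfect_split(self):
        m = classifier_metrics(tp=10, fp=0, fn=0, tn=10)
        for k in ("precision", "recall", "sensitivity", "specificity", "f1"):
            assert m[k] == 1.0

    def test_all_misclassified(self):
        m = classifier_metrics(tp=0, fp=5, fn=5, tn=0)
        assert m["precision"] == 0.0 and m["recall"] == 0.0

    def test_hand_computed_panel(self):
        m = classifier_metrics(tp=3, fp=1, fn=1, tn=3)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)
        # F1 is the harmonic mean of precision and recall
        assert m["f1"] == pytest.approx(
            2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
        )

    def test_undefined_ratio_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            m = classifier_metrics(tp=0, fp=0, fn=0, tn=5)
        assert np.isnan(m["precision"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            classifier_metrics(tp=-1, fp=0, fn=0, tn=0)


class TestLeaveOneReplicateOut:
    def test_one_split_per_replicate(self):
        res = leave_one_replicate_out(make_records(n_reps=4), seed=0)
        assert len(res) == 4
        assert sorted(r.held_out_replicate for r in res) == [1, 2, 3, 4]

    def test_well_separated_groups_all_metrics_one(self):
        res = leave_one_replicate_out(make_records(), seed=0)
        frame = split_results_frame(res)
        cols = ["precision", "recall", "sensitivity", "specificity", "f1"]
        assert (frame[cols] == 1.0).all().all()

    def test_overlapping_groups_near_chance(self):
        accs = []
        for seed in range(15):
            df = make_records(
                mean_t=(0.5, 0.5), mean_s=(0.5, 0.5), sd=0.05, seed=seed, n_per_rep=20
            )
            res = leave_one_replicate_out(df, seed=seed)
            for r in res:
                accs.append((r.tp + r.tn) / r.test_size)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.1)

    def test_no_leakage_from_held_out_labels(self):
        df = make_records(seed=2)
        res_a = leave_one_replicate_out(df, seed=0)
        flipped = df.copy()
        mask = flipped["replicate_id"] == 1
        flipped.loc[mask, "label"] = flipped.loc[mask, "label"].map(
            {"transgenic": "control", "control": "transgenic"}
        )
        res_b = leave_one_replicate_out(flipped, seed=0)
        r_a = next(r for r in res_a if r.held_out_replicate == 1)
        r_b = next(r for r in res_b if r.held_out_replicate == 1)
        # the fitted rule is unchanged by held-out labels
        np.testing.assert_allclose(r_a.weights, r_b.weights, atol=1e-12)
        assert r_a.selected_C == r_b.selected_C

    def test_record_order_invariance(self):
        df = make_records(seed=4)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        f_a = split_results_frame(leave_one_replicate_out(df, seed=0))
        f_b = split_results_frame(leave_one_replicate_out(shuffled, seed=0))
        cols = ["precision", "recall", "sensitivity", "specificity", "f1"]
        pd.testing.assert_frame_equal(
            f_a[cols], f_b[cols], check_exact=False, atol=1e-12
        )

    def test_replicate_in_both_classes_rejected(self):
        df = make_records()
        bad = df.copy()
        bad.loc[bad.index[:3], "label"] = "control"  # 5xFAD rows mislabeled
        with pytest.raises(ValueError, match="both classes"):
            leave_one_replicate_out(bad)


class TestCompare1D2D:
    def test_on_curve_data_gives_equal_metrics(self):
        df = make_records(mean_t=(0.9, 0.6), on_curve=True, sd=0.01)
        out = compare_1d_2d(df, seed=0)
        for m in ("precision", "recall", "f1"):
            np.testing.assert_allclose(out[f"delta_{m}"], 0.0, atol=1e-12)

    def test_off_curve_signal_favors_2d(self):
        # class signal lives only in the off-curve direction: same p (hence
        # same 1D feature) but opposite tangle offsets
        rng = np.random.default_rng(0)
        rows = []
        for label, strain, off in [("transgenic", "5xFAD", 0.1), ("control", "CD1", -0.1)]:
            for rep in range(1, 5):
                for i in range(10):
                    p = rng.normal(0.8, 0.01)
                    t = max(0.0, (3 * p - 1) / 2) ** 2 + off
                    rows.append(
                        {
                            "tangle": np.clip(t, 0, 1),
                            "linear_entropy": 1 - p**2,
                            "werner_p_hat": p,
                            "label": label,
                            "strain": strain,
                            "region": "hippocampus",
                            "replicate_id": rep,
                            "spot_id": f"{strain}-{rep}-{i}",
                        }
                    )
        out = compare_1d_2d(pd.DataFrame(rows), seed=0)
        assert (out["2d_f1"] == 1.0).all()
        acc2 = (out["2d_tp"] + out["2d_tn"]) / 20.0
        acc1 = (out["1d_tp"] + out["1d_tn"]) / 20.0
        assert (acc2 > acc1).all()

    def test_duplicated_feature_column_changes_nothing(self):
        df = make_records(seed=6)
        base = split_results_frame(
            leave_one_replicate_out(df, features=("tangle", "linear_entropy"), seed=0)
        )
        dup = split_results_frame(
            leave_one_replicate_out(
                df.assign(tangle2=df["tangle"]),
                features=("tangle", "linear_entropy", "tangle2"),
                seed=0,
            )
        )
        cols = ["precision", "recall", "f1"]
        pd.testing.assert_frame_equal(base[cols], dup[cols])
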