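"""Scaling, PCA blocks, metrics, grid search and the CV evaluation schemes."""

import numpy as np
import pytest

from gazemetrics.classify import (
    StratificationError,
    confusion_metrics,
    evaluate_lopo,
    evaluate_repeated_kfold,
    grid_search_C,
    majority_baseline,
    pca_blocks,
    scale,
    scheme_matrix,
)
from gazemetrics.config import ClassifierConfig


def _separable(n_per_class=30, n_features=21, gap=6.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_per_class, n_features))
    b = rng.standard_normal((n_per_class, n_features)) + gap
    X = np.vstack([a, b])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


# ------------------------------------------------------------------ scale

def test_scale_independent_standardizes_each_block():
    rng = np.random.default_rng(1)
    tr, te = rng.normal(5, 3, (40, 4)), rng.normal(-2, 7, (15, 4))
    str_, ste = scale(tr, te, "independent")
    for block in (str_, ste):
        assert np.allclose(block.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(block.std(axis=0), 1, atol=1e-9)


def test_scale_modes_agree_when_test_equals_train():
    rng = np.random.default_rng(2)
    tr = rng.normal(size=(30, 5))
    a = scale(tr, tr.copy(), "independent")
    b = scale(tr, tr.copy(), "train_fitted")
    assert np.allclose(a[1], b[1], atol=1e-9)


def test_scale_zero_variance_column_warns_and_centers():
    tr = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
    te = tr.copy()
    with pytest.warns(UserWarning, match="zero-variance"):
        str_, _ = scale(tr, te, "independent")
    assert np.allclose(str_[:, 0], 0.0)


# ---------------------------------------------------------------- metrics

def test_metrics_hand_example():
    m = confusion_metrics(tp=3, tn=4, fp=1, fn=2)
    assert (m.accuracy, m.tpr, m.fpr, m.precision) == pytest.approx(
        (0.7, 0.6, 0.2, 0.75)
    )


def test_metrics_perfect_and_undefined_precision():
    m = confusion_metrics(tp=5, tn=5, fp=0, fn=0)
    assert (m.accuracy, m.tpr, m.precision, m.fpr) == (1.0, 1.0, 1.0, 0.0)
    m = confusion_metrics(tp=0, tn=5, fp=0, fn=5)
    assert np.isnan(m.precision)
    with pytest.raises(ValueError):
        confusion_metrics(0, 0, 0, 0)


def test_metrics_identities_exhaustive_small_tables():
    # cross-check the definitions over every confusion table with counts <= 3
    for tp in range(4):
        for tn in range(4):
            for fp in range(4):
                for fn in range(4):
                    if tp + tn + fp + fn == 0:
                        continue
                    m = confusion_metrics(tp, tn, fp, fn)
                    assert m.accuracy == pytest.approx(
                        (tp + tn) / (tp + tn + fp + fn)
                    )
                    if fp + tn:
                        # FPR is the complement of novice recall
                        assert m.fpr == pytest.approx(1 - tn / (fp + tn))


def test_majority_baseline_values():
    labels = ["expert"] * 60 + ["novice"] * 49
    assert majority_baseline(labels) == pytest.approx(60 / 109)
    assert majority_baseline(["a", "b"]) == 0.5
    assert majority_baseline(["a"] * 7) == 1.0


# ---------------------------------------------------------------- pca

def test_pca_blocks_output_width():
    X, y = _separable(n_features=21)
    tr, te = pca_blocks(X[:40], X[40:], n_per_block=4)
    assert tr.shape[1] == 9 and te.shape[1] == 9
    # blink-rate column passes through unchanged
    assert np.allclose(tr[:, 8], X[:40, 20])


def test_pca_blocks_exact_on_low_rank_data():
    rng = np.random.default_rng(3)
    basis = rng.standard_normal((4, 10))
    coef = rng.standard_normal((50, 4))
    block = coef @ basis
    X = np.hstack([block, block, rng.standard_normal((50, 1))])
    tr, te = pca_blocks(X[:40], X[40:], n_per_block=4)
    # 4 components capture a rank-4 block exactly: distances are preserved
    from scipy.spatial.distance import pdist

    d_orig = pdist(X[:40, :10] - X[:40, :10].mean(axis=0))
    d_proj = pdist(tr[:, :4])
    assert np.allclose(d_orig, d_proj, atol=1e-8)


def test_pca_full_rotation_preserves_linear_accuracy():
    X, y = _separable(gap=1.5, seed=4)
    cfg = ClassifierConfig(kernel="linear", k_folds=5, repeats=2, seed=0,
                           pca_components_per_block=10)
    base = evaluate_repeated_kfold(X, y, cfg, "suture", use_pca=False)
    rot = evaluate_repeated_kfold(X, y, cfg, "suture", use_pca=True)
    assert rot.means["accuracy"] == pytest.approx(base.means["accuracy"], abs=0.05)


def test_pca_rank_error():
    X, y = _separable()
    with pytest.raises(ValueError, match="n_per_block"):
        pca_blocks(X[:3], X[3:6], n_per_block=4)


# ------------------------------------------------------------ grid search

def test_grid_default_has_21_candidates():
    assert len(ClassifierConfig().c_grid) == 21


def test_grid_tie_breaks_to_smallest_C():
    X, y = _separable(gap=8.0)
    cfg = ClassifierConfig(kernel="linear", k_folds=5, seed=0)
    best, table = grid_search_C(X, y, cfg)
    assert len(table) == 21
    if np.allclose(table["cv_accuracy"], 1.0):
        assert best == pytest.approx(2.0 ** -3)


def test_grid_single_value():
    X, y = _separable()
    cfg = ClassifierConfig(c_grid=(0.5,), k_folds=5)
    best, _ = grid_search_C(X, y, cfg)
    assert best == 0.5


def test_grid_single_class_raises():
    X, _ = _separable()
    with pytest.raises(StratificationError):
        grid_search_C(X, np.ones(len(X), dtype=int), ClassifierConfig(k_folds=5))


# ------------------------------------------------------------- evaluation

def test_separable_data_classified_perfectly():
    X, y = _separable(gap=8.0)
    rep = evaluate_repeated_kfold(X, y, ClassifierConfig(k_folds=5, repeats=2), "suture")
    assert rep.means["accuracy"] == 1.0
    assert rep.means["fpr"] == 0.0
    assert rep.n_folds_scored == 10
    for m in ("accuracy", "tpr", "fpr", "precision"):
        assert rep.ci_low[m] <= rep.means[m] <= rep.ci_high[m]


def test_noise_data_accuracy_near_chance():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((80, 21))
    y = np.array([0, 1] * 40)
    rep = evaluate_repeated_kfold(
        X, y, ClassifierConfig(k_folds=5, repeats=4, seed=1), "suture"
    )
    assert rep.ci_low["accuracy"] - 0.1 <= 0.5 <= rep.ci_high["accuracy"] + 0.1


def test_small_class_error_names_class():
    X, y = _separable(n_per_class=4)
    with pytest.raises(StratificationError, match="expert|novice"):
        evaluate_repeated_kfold(X, y, ClassifierConfig(k_folds=10), "suture")


def test_lopo_produces_one_report_per_participant():
    X, y = _separable(n_per_class=30, gap=8.0)
    pids = np.repeat([f"P{k}" for k in range(10)], 6)
    cfg = ClassifierConfig(k_folds=5, repeats=2, seed=0)
    reps = evaluate_lopo(X, y, pids, cfg)
    assert len(reps) == 10
    for rep in reps:
        assert rep.left_out is not None
        # the left-out participant's 6 rows never enter the evaluation
        assert rep.n_rows == 54
        assert rep.means["accuracy"] > majority_baseline(y)


def test_scheme_matrix_widths(fast_cohort_cfg):
    from gazemetrics.features import extract_features
    from gazemetrics.preprocess import preprocess_trace
    from gazemetrics.simulate import simulate_cohort

    participants, traces, timelines = simulate_cohort(fast_cohort_cfg)
    uts = {tr.participant_id: preprocess_trace(tr, timelines) for tr in traces}
    groups = dict(zip(participants["participant_id"], participants["group"]))
    suture_df, segment_df, _ = extract_features(uts, timelines, groups)
    X, y, _, use_pca = scheme_matrix(suture_df, "suture", segment_df)
    assert X.shape[1] == 21 and not use_pca
    X, _, _, use_pca = scheme_matrix(suture_df, "suture_pca", segment_df)
    assert X.shape[1] == 21 and use_pca  # reduced to 9 inside each fold
    X, _, _, _ = scheme_matrix(suture_df, "suture_pupil_only", segment_df)
    assert X.shape[1] == 20
    label = segment_df["segment_label"].iloc[0]
    X, _, _, _ = scheme_matrix(suture_df, f"segment:{label}", segment_df)
    assert X.shape[1] == 2
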