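"""SVM expertise classification with the study's evaluation schemes.

Schemes (the expert class is positive throughout):

* ``segment:<label>`` — one classifier per segment label, features are that
  segment's (APCPS, SDPCPS) pair;
* ``suture`` — all 21 features (10 APCPS + 10 SDPCPS + blink rate);
* ``suture_pupil_only`` — the 20 pupil features without the blink rate;
* ``suture_pca`` — PCA applied to the APCPS and SDPCPS blocks separately
  (4 components each, fitted on training rows only), blink rate appended,
  9 features total;
* leave-one-participant-out — the suture scheme re-evaluated with every
  suture of one participant withheld from training.

Evaluation is repeated stratified k-fold (k = 10, 10 repetitions = 100 fold
scores); train and test folds are standardized *separately* to zero mean and
unit variance by default (the ``independent`` scaling mode; a conventional
``train_fitted`` mode is available).  Metric means carry normal-approximation
95% confidence intervals across fold scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.svm import SVC

from .config import ClassifierConfig
from .features import APCPS_COLUMNS, SDPCPS_COLUMNS, SUTURE_FEATURE_COLUMNS

__all__ = [
    "CVReport",
    "Metrics",
    "StratificationError",
    "scale",
    "grid_search_C",
    "pca_blocks",
    "confusion_metrics",
    "majority_baseline",
    "evaluate_repeated_kfold",
    "evaluate_lopo",
    "scheme_matrix",
    "POSITIVE_CLASS",
]

POSITIVE_CLASS = "expert"

METRIC_NAMES = ("accuracy", "tpr", "fpr", "precision")


class StratificationError(ValueError):
    """A class has too few members for the requested stratified k-fold."""


@dataclass
class Metrics:
    accuracy: float
    tpr: float
    fpr: float
    precision: float  # NaN when no positives were predicted

    @staticmethod
    def names() -> tuple[str, ...]:
        return METRIC_NAMES


@dataclass
class CVReport:
    """Cross-validation summary: per-metric mean and 95% CI across folds."""

    scheme: str
    means: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n_folds_scored: int
    seed: int
    n_rows: int
    left_out: str | None = None
    fold_scores: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def as_records(self) -> list[dict]:
        return [
            {
                "scheme": self.scheme,
                "left_out": self.left_out or "",
                "metric": m,
                "mean": self.means[m],
                "ci_low": self.ci_low[m],
                "ci_high": self.ci_high[m],
                "n_folds": self.n_folds_scored,
                "seed": self.seed,
                "n_rows": self.n_rows,
            }
            for m in METRIC_NAMES
        ]


def _standardize(block: np.ndarray) -> np.ndarray:
    mu = block.mean(axis=0)
    sd = block.std(axis=0)
    zero = sd < 1e-12
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance column(s) left centered with unit divisor"
        )
    return (block - mu) / np.where(zero, 1.0, sd)


def scale(
    train: np.ndarray, test: np.ndarray, mode: str = "independent"
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize feature blocks to zero mean / unit variance.

    ``independent`` (default): each block is scaled by its own statistics —
    the study's literal protocol.  ``train_fitted``: the test block is scaled
    by the training statistics (the conventional leakage-safe choice).
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if mode == "independent":
        if len(train) < 2 or len(test) < 2:
            raise ValueError("independent scaling needs >= 2 rows per block")
        return _standardize(train), _standardize(test)
    if mode == "train_fitted":
        mu = train.mean(axis=0)
        sd = train.std(axis=0)
        zero = sd < 1e-12
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance column(s) left centered with unit divisor"
            )
        sd = np.where(zero, 1.0, sd)
        return (train - mu) / sd, (test - mu) / sd
    raise ValueError("mode must be 'independent' or 'train_fitted'")


def _make_svc(config: ClassifierConfig, C: float | None = None) -> SVC:
    return SVC(
        C=C if C is not None else config.C,
        kernel=config.kernel,
        gamma="scale",  # 1 / (n_features * Var(X)) bandwidth rule
    )


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> Metrics:
    """Accuracy, TPR (expert recall), FPR (novices called expert), precision.

    Precision is NaN-flagged when no positives were predicted.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be >= 0")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("confusion table is empty")
    acc = (tp + tn) / total
    tpr = tp / (tp + fn) if (tp + fn) else np.nan
    fpr = fp / (fp + tn) if (fp + tn) else np.nan
    prec = tp / (tp + fp) if (tp + fp) else np.nan
    return Metrics(accuracy=acc, tpr=tpr, fpr=fpr, precision=prec)


def majority_baseline(labels) -> float:
    """Relative frequency of the most common class."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("labels must be nonempty")
    _, counts = np.unique(labels, return_counts=True)
    return counts.max() / len(labels)


def pca_blocks(
    train: np.ndarray, test: np.ndarray, n_per_block: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Block-wise PCA for suture-level features.

    Columns 0..9 (APCPS) and 10..19 (SDPCPS) are reduced separately to
    ``n_per_block`` components each, with projections fitted on the training
    rows only; column 20 (blink rate) is appended unchanged.  Output width is
    ``2 * n_per_block + 1``.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[1] != 21 or test.shape[1] != 21:
        raise ValueError("pca_blocks expects 21-column suture feature blocks")
    if len(train) <= n_per_block:
        raise ValueError("need more than n_per_block training rows")
    out_tr, out_te = [], []
    for lo, hi in ((0, 10), (10, 20)):
        rank = np.linalg.matrix_rank(train[:, lo:hi] - train[:, lo:hi].mean(axis=0))
        if n_per_block > rank:
            raise ValueError(
                f"n_per_block={n_per_block} exceeds block rank {rank}"
            )
        p = PCA(n_components=n_per_block, svd_solver="full")
        out_tr.append(p.fit_transform(train[:, lo:hi]))
        out_te.append(p.transform(test[:, lo:hi]))
    out_tr.append(train[:, 20:21])
    out_te.append(test[:, 20:21])
    return np.hstack(out_tr), np.hstack(out_te)


def _fold_metrics(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: ClassifierConfig,
    use_pca: bool,
) -> Metrics:
    Xtr_raw, Xte_raw = X[train_idx], X[test_idx]
    ytr, yte = y[train_idx], y[test_idx]
    Xtr, Xte = scale(Xtr_raw, Xte_raw, config.scaling_mode)
    if use_pca:
        Xtr, Xte = pca_blocks(Xtr, Xte, config.pca_components_per_block)
    clf = _make_svc(config)
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    tp = int(np.sum((pred == 1) & (yte == 1)))
    tn = int(np.sum((pred == 0) & (yte == 0)))
    fp = int(np.sum((pred == 1) & (yte == 0)))
    fn = int(np.sum((pred == 0) & (yte == 1)))
    return confusion_metrics(tp, tn, fp, fn)


def _aggregate(
    scheme: str,
    per_fold: list[Metrics],
    config: ClassifierConfig,
    n_rows: int,
    left_out: str | None = None,
) -> CVReport:
    means, lo, hi, scores = {}, {}, {}, {}
    for m in METRIC_NAMES:
        vals = np.array([getattr(f, m) for f in per_fold], dtype=float)
        vals = vals[np.isfinite(vals)]
        scores[m] = vals
        if len(vals) == 0:
            means[m] = lo[m] = hi[m] = np.nan
            continue
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        means[m] = mean
        lo[m] = mean - 1.96 * se
        hi[m] = mean + 1.96 * se
    return CVReport(
        scheme=scheme, means=means, ci_low=lo, ci_high=hi,
        n_folds_scored=len(per_fold), seed=config.seed, n_rows=n_rows,
        left_out=left_out, fold_scores=scores,
    )


def _check_stratifiable(y: np.ndarray, k: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    for c, n in zip(classes, counts):
        if n < k:
            name = POSITIVE_CLASS if c == 1 else "novice"
            raise StratificationError(
                f"class {name!r} has {n} rows, fewer than k={k} folds"
            )
    if len(classes) < 2:
        raise StratificationError("need both classes present")


def evaluate_repeated_kfold(
    X: np.ndarray,
    y: np.ndarray,
    config: ClassifierConfig,
    scheme: str = "suture",
    use_pca: bool = False,
) -> CVReport:
    """Repeated stratified k-fold evaluation (k x repeats fold scores).

    ``y`` is binary with 1 = expert (positive class).  Stratification keeps
    the class ratio per fold within one row; shuffling is seeded.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_stratifiable(y, config.k_folds)
    rskf = RepeatedStratifiedKFold(
        n_splits=config.k_folds, n_repeats=config.repeats, random_state=config.seed
    )
    per_fold = [
        _fold_metrics(X, y, tr, te, config, use_pca) for tr, te in rskf.split(X, y)
    ]
    return _aggregate(scheme, per_fold, config, len(y))


def evaluate_lopo(
    X: np.ndarray,
    y: np.ndarray,
    participant_ids,
    config: ClassifierConfig,
    scheme: str = "suture",
    use_pca: bool = False,
) -> list[CVReport]:
    """Leave-one-participant-out: for each participant, re-run the repeated
    k-fold scheme on everyone else's sutures.

    Participants whose removal empties a class (or leaves a class below the
    fold count) are skipped with a warning.
    """
    pids = np.asarray(participant_ids)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    reports = []
    for pid in pd.unique(pids):
        keep = pids != pid
        try:
            _check_stratifiable(y[keep], config.k_folds)
        except StratificationError as exc:
            warnings.warn(f"leave-out {pid}: {exc}; skipped")
            continue
        rep = evaluate_repeated_kfold(
            X[keep], y[keep], config, scheme=f"lopo:{pid}", use_pca=use_pca
        )
        rep.left_out = str(pid)
        reports.append(rep)
    return reports


def grid_search_C(
    X: np.ndarray, y: np.ndarray, config: ClassifierConfig
) -> tuple[float, pd.DataFrame]:
    """Exponential grid search for the SVM penalty C by stratified k-fold
    accuracy; ties resolve to the smallest C.

    Returns the winning C and a table of mean CV accuracy per candidate.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_stratifiable(y, config.k_folds)
    skf = StratifiedKFold(
        n_splits=config.k_folds, shuffle=True, random_state=config.seed
    )
    splits = list(skf.split(X, y))
    rows = []
    best_c, best_acc = None, -np.inf
    for c in config.c_grid:
        accs = []
        for tr, te in splits:
            Xtr, Xte = scale(X[tr], X[te], config.scaling_mode)
            clf = _make_svc(config, C=c)
            clf.fit(Xtr, y[tr])
            accs.append(float(np.mean(clf.predict(Xte) == y[te])))
        acc = float(np.mean(accs))
        rows.append({"C": c, "cv_accuracy": acc})
        if acc > best_acc + 1e-12:  # strict improvement: ties keep smaller C
            best_acc, best_c = acc, c
    return best_c, pd.DataFrame(rows)


def scheme_matrix(
    suture_df: pd.DataFrame, scheme: str, segment_df: pd.DataFrame | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Slice the feature table for a named scheme.

    Returns ``(X, y, participant_ids, use_pca)``.  ``scheme`` is one of
    ``suture``, ``suture_pca``, ``suture_pupil_only`` or ``segment:<label>``
    (features from the segment-level table for that label).
    """
    if scheme.startswith("segment:"):
        label = scheme.split(":", 1)[1]
        if segment_df is None:
            raise ValueError("segment schemes need the segment-level table")
        sub = segment_df[segment_df["segment_label"] == label]
        if sub.empty:
            raise ValueError(f"unknown segment label {label!r}")
        X = sub[["apcps", "sdpcps"]].to_numpy(dtype=float)
        y = (sub["group"] == POSITIVE_CLASS).to_numpy(dtype=int)
        return X, y, sub["participant_id"].to_numpy(), False
    if scheme in ("suture", "suture_pca"):
        cols = list(SUTURE_FEATURE_COLUMNS)
    elif scheme == "suture_pupil_only":
        cols = list(APCPS_COLUMNS + SDPCPS_COLUMNS)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    X = suture_df[cols].to_numpy(dtype=float)
    y = (suture_df["group"] == POSITIVE_CLASS).to_numpy(dtype=int)
    return X, y, suture_df["participant_id"].to_numpy(), scheme == "suture_pca"
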