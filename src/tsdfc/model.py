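"""Classification: Lasso feature selection, linear SVM, nested LOOCV.

The protocol mirrors standard practice for small neuroimaging cohorts.  For
each held-out subject (outer loop), an inner leave-one-out loop over the
remaining ``S - 1`` subjects scores every hyperparameter combination
``(L, U, rho, lambda_fs)`` — window length, cluster count, retained edge
fraction, Lasso penalty — and the combination with the highest inner
accuracy wins.  The ``S - 1`` inner-fold classifiers retrained with the
winning combination then each vote on the held-out subject; the majority
label is the prediction and the mean decision value is the subject's score.

Feature selection solves

    min_a  1/2 ||y - F a||_2^2 + lambda_fs ||a||_1

with ``F`` the standardized feature matrix plus an unpenalized intercept
column and ``y`` the +1/-1 labels; the nonzero coefficients index the
selected features.  The linear SVM is trained on the selected columns with
fixed C (default 1; the penalty is not tuned).

In the default leakage-free mode every data-dependent fitting step —
k-means clustering of FC series, feature standardization, Lasso, SVM — sees
training subjects only.  ``pooled_clustering=True`` instead fits the FC-series
clustering once on the whole cohort before cross-validation, which is how
cohort-stacked high-order networks are usually described but lets the test
subject influence the cluster structure.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .features import (
    FeatureTable,
    assemble_features,
    local_clustering_coefficient,
    node_strength,
    temporal_variability,
)
from .hfcn import (
    build_hfcn,
    cluster_fc_series,
    stack_cohort,
    subject_cluster_series,
    threshold_network,
)
from .io import CohortManifest, RoiTimeSeries, load_cohort, read_manifest
from .lofcn import WindowSpec, build_dfcn

__all__ = [
    "MetricsReport",
    "CvResult",
    "lasso_select",
    "train_predict_svm",
    "majority_vote",
    "compute_metrics",
    "pooled_ttest_from_summary",
    "nested_loocv",
    "report_feature_weights",
    "ConnectivityClassifier",
    "ConnectivityResults",
]


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and derived rates; positives are the +1 class."""

    TP: int
    TN: int
    FP: int
    FN: int
    ACC: float
    SEN: float  # NaN when no positives
    SPE: float  # NaN when no negatives
    AUC: float  # NaN without scores
    ROC: tuple[tuple[float, float], ...]  # (FPR, TPR) points

    def as_dict(self) -> dict:
        return {
            "TP": self.TP,
            "TN": self.TN,
            "FP": self.FP,
            "FN": self.FN,
            "ACC": self.ACC,
            "SEN": self.SEN,
            "SPE": self.SPE,
            "AUC": self.AUC,
        }


def compute_metrics(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Sequence[float] | None = None,
) -> MetricsReport:
    """ACC, SEN, SPE from the confusion matrix; AUC/ROC from decision scores.

    ACC = (TP + TN) / S, SEN = TP / (TP + FN), SPE = TN / (TN + FP).  The ROC
    is the empirical curve of the scores with trapezoidal AUC.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == -1) & (y_pred == -1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    s = y_true.size
    acc = (tp + tn) / s if s else float("nan")
    if tp + fn == 0:
        warnings.warn("no positive subjects; sensitivity undefined", RuntimeWarning)
        sen = float("nan")
    else:
        sen = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative subjects; specificity undefined", RuntimeWarning)
        spe = float("nan")
    else:
        spe = tn / (tn + fp)
    auc = float("nan")
    roc: tuple[tuple[float, float], ...] = ()
    if scores is not None and tp + fn > 0 and tn + fp > 0:
        scores = np.asarray(scores, dtype=float)
        fpr, tpr, _ = roc_curve(y_true, scores, pos_label=1)
        roc = tuple(zip(fpr.tolist(), tpr.tolist()))
        auc = float(np.trapezoid(tpr, fpr))
    return MetricsReport(
        TP=tp, TN=tn, FP=fp, FN=fn, ACC=acc, SEN=sen, SPE=spe, AUC=auc, ROC=roc
    )


def pooled_ttest_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Two-sided pooled-variance two-sample t-test p-value from summaries.

    Student's t with df = n1 + n2 - 2; the standard check that two groups'
    reported mean +/- SD demographics do not differ.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# selection and classification primitives


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    lambda_fs: float,
    max_iter: int = 100_000,
    tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Solve min_a 1/2||y - [X, 1] a||^2 + lambda_fs ||a_features||_1.

    Returns ``(selected_indices, coefficients, intercept)``; the intercept
    (the appended all-ones column) is never penalized and never counted as a
    selected feature.  The coordinate-descent solver minimizes the per-sample
    average of the squared loss, so its penalty is ``lambda_fs / S``; on an
    orthonormal design the solution is the soft-thresholded least-squares fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lambda_fs < 0:
        raise ValueError("lambda_fs must be non-negative")
    s = X.shape[0]
    if lambda_fs == 0:
        # unpenalized least squares (Lasso solver rejects alpha=0)
        design = np.hstack([X, np.ones((s, 1))])
        coef_full, *_ = np.linalg.lstsq(design, y, rcond=None)
        coef, intercept = coef_full[:-1], float(coef_full[-1])
    else:
        model = Lasso(
            alpha=lambda_fs / s, fit_intercept=True, max_iter=max_iter, tol=tol
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign convergence chatter
            model.fit(X, y)
        coef, intercept = model.coef_.copy(), float(model.intercept_)
    selected = np.nonzero(coef != 0)[0]
    return selected, coef, intercept


def train_predict_svm(
    X_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    C: float = 1.0,
) -> tuple[int, float]:
    """Linear-kernel SVM: fit on the (selected) training columns, score one row.

    Returns ``(label, decision_value)`` with the label the sign of the
    decision value.
    """
    y_train = np.asarray(y_train, dtype=int)
    if len(set(y_train.tolist())) < 2:
        raise ValueError("SVM training set must contain both classes")
    svm = SVC(kernel="linear", C=C)
    svm.fit(np.asarray(X_train, dtype=float), y_train)
    score = float(svm.decision_function(np.atleast_2d(x_test))[0])
    label = 1 if score > 0 else -1
    if score == 0.0:
        label = 1
    return label, score


def majority_vote(votes: Sequence[int], scores: Sequence[float]) -> int:
    """Majority label; ties go to the sign of the mean decision value
    (an exact zero mean resolves to +1, logged)."""
    votes = list(votes)
    if not votes:
        raise ValueError("need at least one vote")
    pos = sum(1 for v in votes if v == 1)
    neg = len(votes) - pos
    if pos != neg:
        return 1 if pos > neg else -1
    mean_score = float(np.mean(scores))
    if mean_score == 0.0:
        warnings.warn("vote tie with zero mean score; resolving to +1", RuntimeWarning)
        return 1
    return 1 if mean_score > 0 else -1


# ---------------------------------------------------------------------------
# nested LOOCV


@dataclass(frozen=True)
class CvResult:
    """Outcome of a nested leave-one-out cross-validation run."""

    subject_ids: tuple[str, ...]
    y_true: np.ndarray
    y_pred: np.ndarray
    vote_tally: tuple[tuple[int, int], ...]  # (votes for +1, votes for -1)
    mean_scores: np.ndarray
    chosen_params: tuple[dict, ...]  # per outer fold: L, U, rho, lambda_fs
    metrics: MetricsReport
    feature_weights: dict  # (kind, index) -> accumulated |lasso coef|
    n_rois: int


def _derive_seed(*parts: int) -> int:
    """Stable sub-2^31 seed from a tuple of integers."""
    payload = ",".join(str(p) for p in parts).encode()
    return zlib.crc32(payload) % (2**31 - 1)


@dataclass
class _FoldFit:
    """One trained pipeline: clustering-derived features + scaler + Lasso + SVM."""

    X: np.ndarray  # (S, m) features of every subject under this fold's clustering
    mean: np.ndarray
    sd: np.ndarray
    selected: np.ndarray
    lasso_coef: np.ndarray
    svm: SVC
    assignment: np.ndarray  # cluster id per ROI pair
    kinds: tuple[str, ...]
    indices: tuple[int, ...]

    def predict(self, row: int) -> tuple[int, float]:
        x = (self.X[row] - self.mean) / self.sd
        score = float(self.svm.decision_function(x[self.selected][None, :])[0])
        return (1 if score > 0 else -1) if score != 0 else 1, score


class _Pipeline:
    """Shared state for one nested-LOOCV run (per-L stacks, per-fold caches)."""

    def __init__(
        self,
        timeseries: list[RoiTimeSeries],
        labels: np.ndarray,
        window_lengths: Sequence[int],
        cluster_counts: Sequence[int],
        retain_fractions: Sequence[float],
        lasso_penalties: Sequence[float],
        step: int,
        seed: int,
        pooled_clustering: bool,
        policy: str,
        svm_C: float,
    ) -> None:
        self.ts = timeseries
        self.y = np.asarray(labels, dtype=int)
        self.S = len(timeseries)
        self.N = timeseries[0].n_rois
        m = timeseries[0].n_timepoints
        p = self.N * (self.N - 1) // 2
        for g, name in (
            (window_lengths, "window_lengths"),
            (cluster_counts, "cluster_counts"),
            (retain_fractions, "retain_fractions"),
            (lasso_penalties, "lasso_penalties"),
        ):
            if len(g) == 0:
                raise ValueError(f"{name} grid must be non-empty")
        for u in cluster_counts:
            if not 1 <= u <= p:
                raise ValueError(f"cluster count {u} outside 1..P={p}")
        for r in retain_fractions:
            if not 0 < r <= 1:
                raise ValueError(f"retain fraction {r} outside (0, 1]")
        for lam in lasso_penalties:
            if lam <= 0:
                raise ValueError("lasso penalties must be positive")
        self.seed = seed
        self.pooled_clustering = pooled_clustering
        self.policy = policy
        self.svm_C = svm_C
        # combos ordered so that on accuracy ties the earlier (simpler) wins:
        # smaller L, then smaller U, then smaller rho, then LARGER penalty
        self.combos = [
            (L, U, rho, lam)
            for L in sorted(window_lengths)
            for U in sorted(cluster_counts)
            for rho in sorted(retain_fractions)
            for lam in sorted(lasso_penalties, reverse=True)
        ]
        # per-subject DFCN stacks and temporal variability depend only on L
        self.stacks: dict[int, list] = {}
        self.tv: dict[int, list] = {}
        for L in sorted(set(window_lengths)):
            spec = WindowSpec(L=L, M=m, delta=step)
            st = [build_dfcn(t, spec, policy=policy) for t in timeseries]
            self.stacks[L] = st
            self.tv[L] = [temporal_variability(s) for s in st]
        self._global_clusterings: dict = {}
        self._fold_clusterings: dict = {}
        self._feature_cache: dict = {}

    # -- clustering / features ------------------------------------------------

    def clustering_for(self, L: int, U: int, train_idx: tuple[int, ...]):
        if self.pooled_clustering:
            key = (L, U)
            if key not in self._global_clusterings:
                stacked = stack_cohort(self.stacks[L])
                self._global_clusterings[key] = cluster_fc_series(
                    stacked,
                    U,
                    seed=_derive_seed(self.seed, L, U),
                    fitted_on=tuple(t.subject_id for t in self.ts),
                )
            return self._global_clusterings[key]
        key = (L, U, train_idx)
        if key not in self._fold_clusterings:
            train_stacks = [self.stacks[L][i] for i in train_idx]
            stacked = stack_cohort(train_stacks)
            crc = _derive_seed(self.seed, L, U, *train_idx)
            self._fold_clusterings[key] = cluster_fc_series(
                stacked, U, seed=crc,
                fitted_on=tuple(self.ts[i].subject_id for i in train_idx),
            )
        return self._fold_clusterings[key]

    def features_for(
        self, L: int, U: int, rho: float, train_idx: tuple[int, ...]
    ) -> tuple[FeatureTable, np.ndarray]:
        """Feature table for ALL subjects under the clustering fit on train_idx."""
        key = (L, U, rho, train_idx)
        if key in self._feature_cache:
            return self._feature_cache[key]
        clustering = self.clustering_for(L, U, train_idx)
        strength, clust_coef = [], []
        for stack in self.stacks[L]:
            series = subject_cluster_series(stack, clustering)
            h = threshold_network(build_hfcn(series, policy=self.policy), rho)
            strength.append(node_strength(h))
            clust_coef.append(local_clustering_coefficient(h))
        table = assemble_features(self.tv[L], strength, clust_coef, self.y)
        out = (table, clustering.assignment)
        self._feature_cache[key] = out
        return out

    def fit_fold(
        self, combo: tuple, train_idx: tuple[int, ...]
    ) -> _FoldFit | None:
        """Fit scaler + Lasso + SVM on train_idx; None if single-class."""
        L, U, rho, lam = combo
        y_train = self.y[list(train_idx)]
        if len(set(y_train.tolist())) < 2:
            return None
        table, assignment = self.features_for(L, U, rho, train_idx)
        X = table.matrix
        tr = list(train_idx)
        mean = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xs = (X[tr] - mean) / sd
        selected, coef, _ = lasso_select(Xs, y_train.astype(float), lam)
        if selected.size == 0:
            # fall back to the single feature most correlated with the labels
            yc = y_train - y_train.mean()
            with np.errstate(invalid="ignore", divide="ignore"):
                num = Xs.T @ yc
                den = np.linalg.norm(Xs, axis=0) * np.linalg.norm(yc)
                corr = np.where(den > 0, np.abs(num) / den, 0.0)
            selected = np.array([int(np.argmax(corr))])
        svm = SVC(kernel="linear", C=self.svm_C)
        svm.fit(Xs[:, selected], y_train)
        return _FoldFit(
            X=X, mean=mean, sd=sd, selected=selected, lasso_coef=coef,
            svm=svm, assignment=assignment,
            kinds=table.kinds, indices=table.indices,
        )

    def clear_fold_caches(self) -> None:
        self._fold_clusterings.clear()
        self._feature_cache.clear()

    # -- outer fold -----------------------------------------------------------

    def run_outer_fold(
        self, test: int, collect_artifacts: bool = False
    ) -> dict:
        """Hold out subject ``test``; tune on the rest; ensemble-vote on it."""
        train = tuple(i for i in range(self.S) if i != test)
        fits: dict = {}
        best_combo, best_acc = None, -1.0
        for combo in self.combos:
            correct = total = 0
            for j in train:
                inner_train = tuple(i for i in train if i != j)
                fit = self.fit_fold(combo, inner_train)
                if fit is None:
                    warnings.warn(
                        "inner fold with single-class training set skipped",
                        RuntimeWarning,
                    )
                    continue
                fits[(combo, j)] = fit
                pred, _ = fit.predict(j)
                correct += int(pred == self.y[j])
                total += 1
            acc = correct / total if total else 0.0
            if acc > best_acc:
                best_acc, best_combo = acc, combo
        # ensemble: the S-1 leave-one-more-out classifiers at the winning combo
        votes, scores = [], []
        members = []
        for j in train:
            fit = fits.get((best_combo, j))
            if fit is None:
                fit = self.fit_fold(best_combo, tuple(i for i in train if i != j))
                if fit is None:
                    continue
            members.append(fit)
            v, sc = fit.predict(test)
            votes.append(v)
            scores.append(sc)
        pred = majority_vote(votes, scores)
        result = {
            "test": test,
            "pred": pred,
            "votes": (sum(1 for v in votes if v == 1),
                      sum(1 for v in votes if v == -1)),
            "mean_score": float(np.mean(scores)),
            "combo": {
                "L": best_combo[0], "U": best_combo[1],
                "rho": best_combo[2], "lambda_fs": best_combo[3],
            },
            "inner_accuracy": best_acc,
            "members": members if collect_artifacts else None,
        }
        # feature-weight accumulation over the ensemble members
        weights: dict = {}
        for fit in members:
            for col, w in enumerate(fit.lasso_coef):
                if w != 0.0:
                    key = (fit.kinds[col], fit.indices[col])
                    weights[key] = weights.get(key, 0.0) + abs(float(w))
        result["weights"] = weights
        self.clear_fold_caches()
        return result


def nested_loocv(
    timeseries: list[RoiTimeSeries],
    labels: Sequence[int],
    window_lengths: Sequence[int],
    cluster_counts: Sequence[int],
    retain_fractions: Sequence[float],
    lasso_penalties: Sequence[float],
    step: int = 1,
    seed: int = 0,
    pooled_clustering: bool = False,
    policy: str = "tolerant",
    svm_C: float = 1.0,
) -> CvResult:
    """Nested leave-one-out cross-validation with majority-vote ensembling.

    See the module docstring for the protocol.  ``policy`` is the
    constant-signal handling passed to the correlation routines (``tolerant``
    zeroes flat-window correlations, which synthetic or short data can hit).
    """
    labels = np.asarray(labels, dtype=int)
    s = len(timeseries)
    if s < 4:
        raise ValueError("nested LOOCV needs at least 4 subjects")
    if set(labels.tolist()) != {1, -1}:
        raise ValueError("labels must contain both +1 and -1")
    pipe = _Pipeline(
        timeseries, labels, window_lengths, cluster_counts,
        retain_fractions, lasso_penalties, step, seed,
        pooled_clustering, policy, svm_C,
    )
    folds = [pipe.run_outer_fold(i) for i in range(s)]
    y_pred = np.array([f["pred"] for f in folds], dtype=int)
    mean_scores = np.array([f["mean_score"] for f in folds])
    metrics = compute_metrics(labels, y_pred, mean_scores)
    weights: dict = {}
    for f in folds:
        for k, w in f["weights"].items():
            weights[k] = weights.get(k, 0.0) + w
    return CvResult(
        subject_ids=tuple(t.subject_id for t in timeseries),
        y_true=labels,
        y_pred=y_pred,
        vote_tally=tuple(f["votes"] for f in folds),
        mean_scores=mean_scores,
        chosen_params=tuple(f["combo"] for f in folds),
        metrics=metrics,
        feature_weights=weights,
        n_rois=timeseries[0].n_rois,
    )


def fit_outer_fold(
    timeseries: list[RoiTimeSeries],
    labels: Sequence[int],
    test_index: int,
    window_lengths: Sequence[int],
    cluster_counts: Sequence[int],
    retain_fractions: Sequence[float],
    lasso_penalties: Sequence[float],
    step: int = 1,
    seed: int = 0,
    pooled_clustering: bool = False,
    policy: str = "tolerant",
    svm_C: float = 1.0,
) -> dict:
    """Run a single outer fold and return its fitted internals.

    The returned dict includes the ensemble ``members`` (each with cluster
    assignment, scaler statistics, selected columns, Lasso coefficients and
    the trained SVM), which makes the fold auditable: in leakage-free mode
    none of these may depend on the held-out subject's data.
    """
    pipe = _Pipeline(
        list(timeseries), np.asarray(labels, dtype=int),
        window_lengths, cluster_counts, retain_fractions, lasso_penalties,
        step, seed, pooled_clustering, policy, svm_C,
    )
    return pipe.run_outer_fold(test_index, collect_artifacts=True)


def report_feature_weights(cv: CvResult) -> pd.DataFrame:
    """Accumulated |Lasso coefficient| per feature over all folds/classifiers,
    normalized so the largest weight is 1; sorted descending."""
    if not cv.feature_weights:
        return pd.DataFrame(columns=["kind", "index", "weight"])
    rows = [
        {"kind": k, "index": i, "weight": w}
        for (k, i), w in cv.feature_weights.items()
    ]
    df = pd.DataFrame(rows)
    wmax = df["weight"].max()
    if wmax > 0:
        df["weight"] = df["weight"] / wmax
    return df.sort_values(
        ["weight", "kind", "index"], ascending=[False, True, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# model / results objects


class ConnectivityClassifier:
    """Temporal-spatial dynamic connectivity classifier for a two-group cohort.

    Parameters
    ----------
    timeseries
        One normalized :class:`~tsdfc.io.RoiTimeSeries` per subject.
    labels
        +1 / -1 per subject (patients coded +1 by convention).
    window_lengths, cluster_counts, retain_fractions, lasso_penalties
        Hyperparameter grids searched by the inner cross-validation loop.
        Defaults are the standard sweep for a ~120-ROI, ~140-scan cohort:
        L in {20..70}, U in {300..800}, rho in {0.1..0.9}, lambda in
        {0.1..0.6}; pass smaller grids for small cohorts (U may not exceed
        N(N-1)/2).
    pooled_clustering
        Fit the FC-series clustering on the whole cohort (including each
        fold's test subject) instead of per-fold training subjects.

    Examples
    --------
    >>> model = ConnectivityClassifier(series, labels,
    ...     window_lengths=[20, 40], cluster_counts=[8],
    ...     retain_fractions=[0.5], lasso_penalties=[0.2, 0.4])
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    """

    def __init__(
        self,
        timeseries: list[RoiTimeSeries],
        labels: Sequence[int],
        window_lengths: Sequence[int] = (20, 30, 40, 50, 60, 70),
        cluster_counts: Sequence[int] = (300, 400, 500, 600, 700, 800),
        retain_fractions: Sequence[float] = (
            0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9,
        ),
        lasso_penalties: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6),
        step: int = 1,
        pooled_clustering: bool = False,
        policy: str = "tolerant",
        svm_C: float = 1.0,
    ) -> None:
        self.timeseries = list(timeseries)
        self.labels = np.asarray(labels, dtype=int)
        if len(self.timeseries) != self.labels.size:
            raise ValueError("one label per subject required")
        self.window_lengths = tuple(window_lengths)
        self.cluster_counts = tuple(cluster_counts)
        self.retain_fractions = tuple(retain_fractions)
        self.lasso_penalties = tuple(lasso_penalties)
        self.step = step
        self.pooled_clustering = pooled_clustering
        self.policy = policy
        self.svm_C = svm_C

    @classmethod
    def from_manifest(
        cls,
        manifest: str | CohortManifest,
        base_dir: str | None = None,
        orientation: str = "time_by_roi",
        **kwargs,
    ) -> "ConnectivityClassifier":
        """Build from a cohort manifest CSV (columns subject_id, path, label)."""
        if isinstance(manifest, (str,)):
            manifest = read_manifest(manifest)
        manifest.require_both_classes()
        series = load_cohort(manifest, base_dir=base_dir, orientation=orientation)
        return cls(series, manifest.labels, **kwargs)

    def fit(self, seed: int = 0) -> "ConnectivityResults":
        """Run the full nested LOOCV and return the results object."""
        cv = nested_loocv(
            self.timeseries,
            self.labels,
            window_lengths=self.window_lengths,
            cluster_counts=self.cluster_counts,
            retain_fractions=self.retain_fractions,
            lasso_penalties=self.lasso_penalties,
            step=self.step,
            seed=seed,
            pooled_clustering=self.pooled_clustering,
            policy=self.policy,
            svm_C=self.svm_C,
        )
        return ConnectivityResults(self, cv)


class ConnectivityResults:
    """Fitted cross-validation results with metrics and feature importances."""

    def __init__(self, model: ConnectivityClassifier, cv: CvResult) -> None:
        self.model = model
        self.cv = cv
        self.metrics = cv.metrics
        self.predictions = pd.DataFrame(
            {
                "subject_id": cv.subject_ids,
                "y_true": cv.y_true,
                "y_pred": cv.y_pred,
                "votes_pos": [v[0] for v in cv.vote_tally],
                "votes_neg": [v[1] for v in cv.vote_tally],
                "mean_score": cv.mean_scores,
                "L": [p["L"] for p in cv.chosen_params],
                "U": [p["U"] for p in cv.chosen_params],
                "rho": [p["rho"] for p in cv.chosen_params],
                "lambda_fs": [p["lambda_fs"] for p in cv.chosen_params],
            }
        )

    @property
    def accuracy(self) -> float:
        return self.metrics.ACC

    def feature_weights(self) -> pd.DataFrame:
        return report_feature_weights(self.cv)

    def summary(self) -> str:
        m = self.metrics
        lines = [
            "Temporal-spatial dynamic connectivity classification",
            "=" * 56,
            f"Subjects: {len(self.cv.subject_ids)}  "
            f"(+1: {int(np.sum(self.cv.y_true == 1))}, "
            f"-1: {int(np.sum(self.cv.y_true == -1))})",
            f"Protocol: nested LOOCV, majority vote of "
            f"{len(self.cv.subject_ids) - 1} classifiers per fold",
            f"Mode: {'pooled-clustering (cohort-stacked clustering)' if self.model.pooled_clustering else 'leakage-free (training-fold clustering)'}",
            "-" * 56,
            f"  ACC: {m.ACC:7.2%}    SEN: {m.SEN:7.2%}    SPE: {m.SPE:7.2%}",
            f"  AUC: {m.AUC:7.2%}    (TP={m.TP} FN={m.FN} TN={m.TN} FP={m.FP})",
            "-" * 56,
            "Chosen hyperparameters by outer fold (mode):",
        ]
        for col in ("L", "U", "rho", "lambda_fs"):
            vals = self.predictions[col]
            lines.append(f"  {col:10s} {vals.mode().iloc[0]}")
        top = self.feature_weights().head(5)
        if len(top):
            lines.append("Top discriminative features (normalized weight):")
            for _, r in top.iterrows():
                lines.append(
                    f"  {r['kind']:12s} #{int(r['index']) + 1:<5d} {r['weight']:.3f}"
                )
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Plot the ensemble-score ROC curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.metrics.ROC
        if pts:
            fpr, tpr = zip(*pts)
            ax.plot(fpr, tpr, label=f"AUC = {self.metrics.AUC:.3f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        return ax
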