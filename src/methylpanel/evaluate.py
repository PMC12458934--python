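"""Leave-one-out evaluation harness with inner model selection, a
specificity-first custom metric, minority-class resampling, and multiclass
risk-score decision criteria.

The harness mirrors a screening-assay evaluation: each sample is predicted
by a model that never saw it. For every held-out sample the training
remainder is (optionally) rebalanced with a SMOTE-ENN-style resampler, a
small pool of candidate models is scored by stratified inner 5-fold
cross-validation under the supplied metric, and the winner is refit on the
full remainder to predict the held-out sample.

The custom binary metric prioritises specificity while the number of
misclassified non-cancer samples stays within a budget (default 1): within
budget the score is ``branch_offset + specificity + 0.01·sensitivity`` with
``branch_offset > 1``, so every within-budget score strictly dominates every
over-budget score; past the budget it transitions to the
sensitivity-weighted combination ``0.8·sensitivity + 0.2·specificity``.

Multiclass risk scores (per-class probabilities summing to 1) are judged by
three criteria: best match (arg-max), rank <= 2 (minimum-rank ties count),
and within range (every class with score strictly above 1/k for k classes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE = "tumor", "normal"


class EvalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# custom metric
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CustomMetricParams:
    fp_budget: int = 1
    w_sens: float = 0.8
    w_spec: float = 0.2
    branch_offset: float = 2.0

    def __post_init__(self) -> None:
        if self.fp_budget < 0:
            raise EvalError("fp_budget must be >= 0")
        if self.w_sens < 0 or self.w_spec < 0 or \
                abs(self.w_sens + self.w_spec - 1.0) > 1e-9:
            raise EvalError("weights must be >= 0 and sum to 1")
        if self.branch_offset <= 1.0:
            raise EvalError("branch_offset must be > 1")


def custom_metric(
    y_true, y_pred, params: CustomMetricParams = CustomMetricParams(),
    pos_label=POSITIVE,
) -> float:
    """Specificity-first score (higher is better); see module docstring."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == pos_label
    neg = ~pos
    if neg.sum() == 0:
        raise EvalError("custom metric undefined without non-cancer samples")
    fp = int(np.sum(neg & (y_pred == pos_label)))
    specificity = np.sum(neg & (y_pred != pos_label)) / neg.sum()
    sensitivity = (np.sum(pos & (y_pred == pos_label)) / pos.sum()
                   if pos.sum() else 0.0)
    if fp <= params.fp_budget:
        return float(params.branch_offset + specificity + 0.01 * sensitivity)
    return float(params.w_sens * sensitivity + params.w_spec * specificity)


# ---------------------------------------------------------------------------
# SMOTE-ENN-style resampler
# ---------------------------------------------------------------------------


class SmoteEnnResampler:
    """Minority oversampling by neighbour interpolation followed by edited
    nearest-neighbour cleaning.

    Synthetic minority samples are convex combinations of a minority sample
    and one of its ``k_smote`` nearest minority neighbours, added until the
    classes balance; ENN then removes any sample whose ``k_enn`` nearest
    other samples vote against its label. Deterministic under ``seed``.
    """

    def __init__(self, k_smote: int = 5, k_enn: int = 3, seed: int = 0):
        self.k_smote = k_smote
        self.k_enn = k_enn
        self.seed = seed

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.seed)
        labels, counts = np.unique(y, return_counts=True)
        if len(labels) < 2:
            return X, y
        minority = labels[np.argmin(counts)]
        n_needed = int(counts.max() - counts.min())
        Xm = X[y == minority]
        if n_needed > 0 and Xm.shape[0] >= 2:
            k = min(self.k_smote, Xm.shape[0] - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
            _, idx = nn.kneighbors(Xm)
            base = rng.integers(0, Xm.shape[0], n_needed)
            pick = idx[base, rng.integers(1, k + 1, n_needed)]
            lam = rng.random((n_needed, 1))
            synth = Xm[base] + lam * (Xm[pick] - Xm[base])
            X = np.vstack([X, synth])
            y = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
        # ENN cleaning
        if X.shape[0] > self.k_enn + 1:
            nn = NearestNeighbors(n_neighbors=self.k_enn + 1).fit(X)
            _, idx = nn.kneighbors(X)
            keep = []
            for i in range(X.shape[0]):
                votes = y[idx[i, 1:]]
                maj = np.sum(votes == y[i]) >= (len(votes) / 2.0)
                keep.append(maj)
            keep = np.asarray(keep)
            # never remove an entire class
            for lab in labels:
                if not np.any(keep & (y == lab)):
                    keep |= y == lab
            X, y = X[keep], y[keep]
        return X, y


# ---------------------------------------------------------------------------
# candidate models
# ---------------------------------------------------------------------------


def default_candidate_factory(seed: int = 0) -> list:
    """Small deterministic candidate pool for the inner model selection."""
    return [
        LogisticRegression(C=1.0, max_iter=1000),
        LogisticRegression(C=0.05, max_iter=1000),
        RandomForestClassifier(n_estimators=60, random_state=seed),
    ]


# ---------------------------------------------------------------------------
# reports and metrics
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    balanced_accuracy: float = float("nan")
    auc: float = float("nan")
    confusion: pd.DataFrame | None = None
    accuracy_best: float = float("nan")
    accuracy_rank2: float = float("nan")
    accuracy_within_range: float = float("nan")
    mean_rank_true: float = float("nan")
    mean_within_range_size: float = float("nan")
    n_samples: int = 0
    excluded: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in ("sensitivity", "specificity", "balanced_accuracy", "auc",
                      "accuracy_best", "accuracy_rank2", "accuracy_within_range",
                      "mean_rank_true", "mean_within_range_size", "n_samples")
        }
        d["excluded"] = list(self.excluded)
        if self.confusion is not None:
            d["confusion"] = self.confusion.to_dict()
        return {k: v for k, v in d.items()
                if not (isinstance(v, float) and np.isnan(v))}


def compute_binary_metrics(
    y_true, scores, threshold: float = 0.5, pos_label=POSITIVE,
) -> EvalReport:
    """Sensitivity/specificity at the threshold, balanced accuracy, and AUC
    by the midrank statistic. AUC is NaN (flagged) for single-class labels."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    y_pred = np.where(scores > threshold, pos_label, NEGATIVE)
    pos = y_true == pos_label
    neg = ~pos
    sens = float(np.sum(pos & (y_pred == pos_label)) / pos.sum()) if pos.sum() else float("nan")
    spec = float(np.sum(neg & (y_pred != pos_label)) / neg.sum()) if neg.sum() else float("nan")
    bal = np.nanmean([sens, spec])
    if pos.sum() and neg.sum():
        auc = float(roc_auc_score(pos.astype(int), scores))
    else:
        logger.warning("AUC undefined for single-class labels")
        auc = float("nan")
    conf = pd.DataFrame(
        {
            pos_label: [np.sum(pos & (y_pred == pos_label)),
                        np.sum(neg & (y_pred == pos_label))],
            NEGATIVE: [np.sum(pos & (y_pred != pos_label)),
                       np.sum(neg & (y_pred != pos_label))],
        },
        index=[pos_label, NEGATIVE],
    )
    return EvalReport(sensitivity=sens, specificity=spec,
                      balanced_accuracy=float(bal), auc=auc, confusion=conf,
                      n_samples=len(y_true))


def multiclass_decide(
    scores, classes: Sequence[str], criterion: str = "best",
    threshold: float | None = None,
) -> object:
    """Decision from one normalized risk-score vector.

    ``best`` -> arg-max class; ``rank2`` -> set of classes with minimum rank
    <= 2 (ties count); ``within_range`` -> set of classes with score
    strictly above ``threshold`` (default 1/k).
    """
    s = np.asarray(scores, dtype=float)
    if np.any(s < 0) or abs(s.sum() - 1.0) > 1e-6:
        raise EvalError("risk scores must be >= 0 and sum to 1")
    classes = list(classes)
    if criterion == "best":
        m = s.max()
        tied = [c for c, v in zip(classes, s) if v == m]
        return sorted(tied)[0]
    if criterion == "rank2":
        ranks = {c: int(1 + np.sum(s > v)) for c, v in zip(classes, s)}
        return tuple(c for c in classes if ranks[c] <= 2)
    if criterion == "within_range":
        t = 1.0 / len(classes) if threshold is None else threshold
        return tuple(c for c, v in zip(classes, s) if v > t)
    raise EvalError(f"unknown criterion {criterion!r}")


# ---------------------------------------------------------------------------
# LOO harness
# ---------------------------------------------------------------------------


@dataclass
class CohortDataset:
    """Feature table + labels; samples with missing feature blocks are
    excluded up front with a logged reason."""

    features: pd.DataFrame
    labels: pd.Series
    excluded: tuple[str, ...] = ()

    @classmethod
    def from_table(cls, features: pd.DataFrame, labels: pd.Series) -> "CohortDataset":
        labels = labels.reindex(features.index)
        if labels.isna().any():
            raise EvalError(
                f"missing labels for {list(labels.index[labels.isna()])}"
            )
        bad = features.index[features.isna().any(axis=1)]
        if len(bad):
            logger.warning("excluding %d samples with missing feature blocks: %s",
                           len(bad), list(bad))
        keep = features.index.difference(bad, sort=False)
        return cls(features.loc[keep], labels.loc[keep], tuple(bad))


def _inner_select(
    X: np.ndarray, y: np.ndarray, candidates: list, metric: Callable,
    inner_folds: int, seed: int,
):
    """Score each candidate by stratified inner CV under the metric (mean of
    per-fold scores) and return the best (first wins ties)."""
    _, counts = np.unique(y, return_counts=True)
    n_splits = int(min(inner_folds, counts.min()))
    if n_splits < 2:
        return candidates[0]
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    best, best_score = None, -np.inf
    for cand in candidates:
        scores = []
        for tr, te in skf.split(X, y):
            model = clone(cand)
            model.fit(X[tr], y[tr])
            scores.append(metric(y[te], model.predict(X[te])))
        mean = float(np.mean(scores))
        if mean > best_score:
            best, best_score = cand, mean
    return best


def loo_evaluate(
    ds: CohortDataset,
    candidate_factory: Callable[[int], list] = default_candidate_factory,
    metric: Callable | str = "custom",
    resample: str | None = None,
    inner_folds: int = 5,
    seed: int = 0,
    task: str = "binary",
    pos_label=POSITIVE,
) -> tuple[pd.DataFrame, EvalReport]:
    """Leave-one-out evaluation; see module docstring.

    Returns (per-sample held-out prediction table, aggregated report). For
    ``task='binary'`` the prediction table carries the positive-class
    probability; for ``'multiclass'`` the per-class risk scores plus the
    three criterion outcomes.
    """
    if isinstance(metric, str):
        if metric == "custom":
            metric = lambda yt, yp: custom_metric(yt, yp, pos_label=pos_label)  # noqa: E731
        elif metric == "balanced_accuracy":
            metric = balanced_accuracy_score
        else:
            raise EvalError(f"unknown metric {metric!r}")

    X_all = ds.features.to_numpy(dtype=float)
    y_all = ds.labels.to_numpy()
    n = X_all.shape[0]
    classes = np.array(sorted(set(y_all)))
    if n < 3:
        raise EvalError("need >= 3 samples for LOO with inner CV")

    resampler = SmoteEnnResampler(seed=seed) if resample == "smote-enn" else None
    rows = []
    rng_seeds = np.random.SeedSequence(seed).spawn(n)
    for i in range(n):
        sub_seed = int(rng_seeds[i].generate_state(1)[0] % (2**31))
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X_all[mask], y_all[mask]
        if len(set(y_tr)) < 2:
            logger.warning("fold %d skipped: single-class training remainder", i)
            continue
        if resampler is not None:
            X_tr, y_tr = SmoteEnnResampler(
                resampler.k_smote, resampler.k_enn, sub_seed).fit_resample(X_tr, y_tr)
        candidates = candidate_factory(sub_seed)
        best = _inner_select(X_tr, y_tr, candidates, metric, inner_folds, sub_seed)
        model = clone(best)
        model.fit(X_tr, y_tr)
        x = X_all[i][None, :]
        pred = model.predict(x)[0]
        row = {"sample_id": ds.features.index[i], "label": y_all[i], "pred": pred}
        if hasattr(model, "predict_proba"):
            proba = model.predict_proba(x)[0]
            for cls, p in zip(model.classes_, proba):
                row[f"score_{cls}"] = float(p)
        rows.append(row)
    preds = pd.DataFrame(rows).set_index("sample_id")

    if task == "binary":
        scores = preds.get(f"score_{pos_label}")
        if scores is None:
            scores = (preds["pred"] == pos_label).astype(float)
        report = compute_binary_metrics(preds["label"], scores.to_numpy(),
                                        pos_label=pos_label)
        report.excluded = ds.excluded
        return preds, report

    # multiclass risk-score evaluation
    score_cols = [f"score_{c}" for c in classes]
    S = preds[score_cols].to_numpy(dtype=float)
    S = S / S.sum(axis=1, keepdims=True)
    n_eval = S.shape[0]
    counts = pd.DataFrame(0.0, index=classes, columns=classes)
    n_best = n_rank2 = n_within = 0
    rank_sum = size_sum = 0.0
    for i in range(n_eval):
        true = preds["label"].iloc[i]
        best = multiclass_decide(S[i], classes, "best")
        rank2 = multiclass_decide(S[i], classes, "rank2")
        within = multiclass_decide(S[i], classes, "within_range")
        counts.loc[true, best] += 1
        n_best += best == true
        n_rank2 += true in rank2
        n_within += true in within
        rank_sum += 1 + np.sum(S[i] > S[i][list(classes).index(true)])
        size_sum += len(within)
    row_sums = counts.sum(axis=1).replace(0, np.nan)
    report = EvalReport(
        confusion=counts.div(row_sums, axis=0) * 100.0,
        accuracy_best=n_best / n_eval,
        accuracy_rank2=n_rank2 / n_eval,
        accuracy_within_range=n_within / n_eval,
        mean_rank_true=rank_sum / n_eval,
        mean_within_range_size=size_sum / n_eval,
        balanced_accuracy=float(balanced_accuracy_score(preds["label"], preds["pred"])),
        n_samples=n_eval,
        excluded=ds.excluded,
    )
    return preds, report
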