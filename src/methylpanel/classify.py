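"""Binarized-profile tumor calling and tissue-of-origin classification.

A sample's beta values along a panel are binarized against per-probe cutoffs:
bit 1 means "far from the blood reference" (above the cutoff for a
low-reference probe, below it for a high-reference probe; comparisons are
strict, so a value exactly at the cutoff maps to 0). Missing betas are
masked: they count as 0 for the tumor/normal OR call and are excluded
pairwise from distances, which are rescaled by sqrt(panel_size / n_used) so
they stay comparable across missingness patterns.

Tumor/normal calling is the OR rule: tumor iff any unmasked bit is 1.

Tissue of origin is assigned by distance to per-class binary signatures
(one signature per tumor type plus the blood reference). Two distance modes:

* ``per_sample_mean`` (default): mean Euclidean distance from the sample's
  bit vector to every training member of the class;
* ``centroid``: Euclidean distance to the class's median-then-binarized
  profile.

Three decision criteria are supported — best match (arg-min distance),
"rank <= 2" (minimum-rank ties included), and "within range" (all classes
within δ of the best match, or of the sample itself under the literal
anchor). Two distance adjustments correct for class-specific distance
distributions: QFfit (the quantile fraction of the observed distance within
the class's training self-distance distribution, midpoint tie convention)
and a naive-Bayes approximation over per-probe Bernoulli rates with Laplace
smoothing ("Bayes": uniform prior; "Bayesf": class-frequency prior).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .io import REFERENCE_GROUP, BetaMatrix, tumor_types
from .select import MarkerPanel

logger = logging.getLogger(__name__)

TUMOR, NORMAL, INDETERMINATE = "tumor", "normal", "indeterminate"


class ClassificationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# binarization and the T-N OR rule
# ---------------------------------------------------------------------------


def binarize(betas, panel: MarkerPanel) -> np.ndarray:
    """Binarize beta values aligned to the panel's probe order.

    Accepts a 1-D vector (one sample) or a 2-D (n_samples, n_probes) array /
    DataFrame; returns a float array over {0.0, 1.0, NaN} of the same
    leading shape. NaN marks masked (missing) bits.
    """
    if isinstance(betas, pd.DataFrame):
        betas = betas[[p.probe_id for p in panel.probes]].to_numpy(dtype=float)
    elif isinstance(betas, pd.Series):
        betas = betas[[p.probe_id for p in panel.probes]].to_numpy(dtype=float)
    arr = np.asarray(betas, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    if arr.shape[1] != len(panel):
        raise ClassificationError(
            f"got {arr.shape[1]} values for a panel of {len(panel)} probes"
        )
    cutoffs = np.array([p.cutoff for p in panel.probes])
    low = np.array([p.reference_state == "low" for p in panel.probes])
    bits = np.where(low[None, :], arr > cutoffs[None, :], arr < cutoffs[None, :])
    bits = bits.astype(float)
    bits[np.isnan(arr)] = np.nan
    return bits[0] if squeeze else bits


def binarize_sample(betas, panel: MarkerPanel) -> np.ndarray:
    """One-sample convenience wrapper around :func:`binarize`."""
    return binarize(np.asarray(betas, dtype=float).ravel(), panel)


def call_tumor_normal(profile: np.ndarray) -> str:
    """OR rule: tumor iff any unmasked bit is 1; all-masked is indeterminate,
    never silently normal."""
    profile = np.asarray(profile, dtype=float)
    unmasked = ~np.isnan(profile)
    if not unmasked.any():
        return INDETERMINATE
    return TUMOR if np.nanmax(profile) >= 1.0 else NORMAL


# ---------------------------------------------------------------------------
# signatures and distances
# ---------------------------------------------------------------------------


@dataclass
class ClassSignature:
    label: str
    profile: np.ndarray                  # median-then-binarized class profile
    member_profiles: np.ndarray          # (n_members, panel_size), NaN-masked
    distance_distribution: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_members(self) -> int:
        return int(self.member_profiles.shape[0])


def profile_distance(a: np.ndarray, b: np.ndarray, panel_size: int) -> float:
    """Euclidean distance between bit vectors with pairwise mask exclusion
    and sqrt(panel_size / n_used) rescaling. Returns NaN when no position is
    jointly unmasked."""
    used = ~np.isnan(a) & ~np.isnan(b)
    n_used = int(used.sum())
    if n_used == 0:
        return float("nan")
    sq = float(np.sum((a[used] - b[used]) ** 2))
    return float(np.sqrt(sq * panel_size / n_used))


def distance_vector(
    sample: np.ndarray,
    sigs: Sequence[ClassSignature],
    mode: str = "per_sample_mean",
) -> pd.Series:
    """Per-class distance of one binarized sample.

    ``per_sample_mean``: mean distance to every training member of the class;
    ``centroid``: distance to the class profile.
    """
    sample = np.asarray(sample, dtype=float)
    panel_size = sample.shape[0]
    out = {}
    for sig in sigs:
        if mode == "centroid":
            d = profile_distance(sample, sig.profile, panel_size)
        elif mode == "per_sample_mean":
            ds = [profile_distance(sample, mp, panel_size)
                  for mp in sig.member_profiles]
            ds = [d for d in ds if not np.isnan(d)]
            d = float(np.mean(ds)) if ds else float("nan")
        else:
            raise ClassificationError(f"unknown distance mode {mode!r}")
        if np.isnan(d):
            raise ClassificationError(
                f"no usable (jointly unmasked) positions for class {sig.label!r}"
            )
        out[sig.label] = d
    return pd.Series(out, name="distance")


def build_class_signatures(
    m: BetaMatrix,
    ann: pd.DataFrame,
    panel: MarkerPanel,
    mode: str = "per_sample_mean",
) -> list[ClassSignature]:
    """One signature per tumor type plus the reference.

    The class profile is the binarization of the per-class per-probe median
    beta. The self-distance distribution (for QFfit) is each member's
    distance to its own class, leaving the member itself out when the class
    has more than one member.
    """
    classes = tumor_types(ann) + [REFERENCE_GROUP]
    betas = m.values.T  # samples × probes
    sigs: list[ClassSignature] = []
    for cls in classes:
        g = REFERENCE_GROUP if cls == REFERENCE_GROUP else f"{cls}.T"
        ids = [s for s in ann.index[ann["group"] == g] if s in m.sample_ids]
        if not ids:
            raise ClassificationError(f"class {cls!r} has no training samples")
        member_bits = binarize(betas.loc[ids], panel)
        med = betas.loc[ids].median(axis=0)
        profile = binarize(med, panel)
        sig = ClassSignature(cls, profile, member_bits)
        sigs.append(sig)
    for sig in sigs:
        sig.distance_distribution = _self_distances(sig, mode, len(panel))
    return sigs


def _self_distances(sig: ClassSignature, mode: str, panel_size: int) -> np.ndarray:
    n = sig.n_members
    dists = []
    for i in range(n):
        me = sig.member_profiles[i]
        if mode == "centroid":
            d = profile_distance(me, sig.profile, panel_size)
        else:
            others = [j for j in range(n) if j != i] or [i]
            ds = [profile_distance(me, sig.member_profiles[j], panel_size)
                  for j in others]
            ds = [d for d in ds if not np.isnan(d)]
            d = float(np.mean(ds)) if ds else float("nan")
        if not np.isnan(d):
            dists.append(d)
    return np.sort(np.asarray(dists))


def signatures_to_json(sigs: Sequence[ClassSignature], path: str | Path,
                       panel_hash: str = "") -> None:
    def enc(a: np.ndarray):
        return [None if np.isnan(v) else float(v) for v in np.ravel(a)]

    doc = {
        "panel_hash": panel_hash,
        "classes": [
            {
                "label": s.label,
                "profile": enc(s.profile),
                "n_members": s.n_members,
                "member_profiles": [enc(r) for r in s.member_profiles],
                "distance_distribution": [float(v) for v in s.distance_distribution],
            }
            for s in sigs
        ],
    }
    Path(path).write_text(json.dumps(doc) + "\n")


def signatures_from_json(path: str | Path) -> list[ClassSignature]:
    doc = json.loads(Path(path).read_text())

    def dec(x):
        return np.array([np.nan if v is None else float(v) for v in x])

    return [
        ClassSignature(
            c["label"], dec(c["profile"]),
            np.array([dec(r) for r in c["member_profiles"]]),
            np.asarray(c["distance_distribution"], dtype=float),
        )
        for c in doc["classes"]
    ]


# ---------------------------------------------------------------------------
# decisions
# ---------------------------------------------------------------------------


@dataclass
class ClassificationResult:
    best_match: str
    rank_of: dict[str, int]
    within_range: tuple[str, ...]
    delta: float
    distances: pd.Series
    adjusted_scores: pd.Series | None = None


def _break_ties(labels: Sequence[str]) -> str:
    """Reference loses to any tumor class; then lexicographic."""
    non_ref = sorted(l for l in labels if l != REFERENCE_GROUP)
    return non_ref[0] if non_ref else REFERENCE_GROUP


def decide(
    dv: pd.Series,
    delta: float = 0.0,
    range_anchor: str = "best_match",
) -> ClassificationResult:
    """Apply the three decision criteria to a distance vector.

    Ranks are minimum ranks (tied classes share the smallest rank). With
    ``range_anchor='best_match'`` the within-range set is
    {c : d_c <= d_min + delta} (nonempty, contains the best match); with
    ``'sample'`` it is the literal {c : d_c <= delta} and may be empty.
    """
    if len(dv) == 0:
        raise ClassificationError("empty distance vector")
    if delta < 0:
        raise ClassificationError("delta must be >= 0")
    d = dv.to_numpy(dtype=float)
    labels = list(dv.index)
    d_min = float(np.min(d))
    best = _break_ties([l for l, v in zip(labels, d) if v == d_min])
    ranks = {l: int(1 + np.sum(d < v)) for l, v in zip(labels, d)}
    if range_anchor == "best_match":
        within = tuple(l for l, v in zip(labels, d) if v <= d_min + delta)
    elif range_anchor == "sample":
        within = tuple(l for l, v in zip(labels, d) if v <= delta)
    else:
        raise ClassificationError(f"unknown range_anchor {range_anchor!r}")
    return ClassificationResult(best, ranks, within, delta, dv)


def qffit_scores(dv: pd.Series, sigs: Sequence[ClassSignature]) -> pd.Series:
    """Quantile-fraction fit: score_c = fraction of class-c training
    self-distances <= d_c, counting ties at half weight (midpoint
    convention). Lower is a better fit."""
    by_label = {s.label: s for s in sigs}
    out = {}
    for label, d in dv.items():
        sig = by_label[label]
        dist = sig.distance_distribution
        if dist.size == 0:
            raise ClassificationError(f"class {label!r} has an empty distance distribution")
        below = np.sum(dist < d)
        ties = np.sum(dist == d)
        out[label] = float((below + 0.5 * ties) / dist.size)
    return pd.Series(out, name="qffit")


def naive_bayes_scores(
    sample: np.ndarray,
    sigs: Sequence[ClassSignature],
    prior: str = "uniform",
) -> pd.Series:
    """Naive-Bayes posterior over classes from per-probe Bernoulli rates.

    Rates use a Laplace pseudocount of 1 over the unmasked training bits;
    the likelihood multiplies over the sample's unmasked bits only.
    ``prior='uniform'`` is the Bayes variant, ``'frequency'`` Bayesf.
    """
    sample = np.asarray(sample, dtype=float)
    unmasked = ~np.isnan(sample)
    n_total = sum(s.n_members for s in sigs)
    logs = {}
    for sig in sigs:
        if sig.n_members == 0:
            raise ClassificationError(f"class {sig.label!r} has no training samples")
        mp = sig.member_profiles
        n1 = np.nansum(mp, axis=0)
        nobs = np.sum(~np.isnan(mp), axis=0)
        rates = (n1 + 1.0) / (nobs + 2.0)
        if prior == "uniform":
            lp = 0.0
        elif prior == "frequency":
            lp = np.log(sig.n_members / n_total)
        else:
            raise ClassificationError(f"unknown prior {prior!r}")
        b = sample[unmasked]
        r = rates[unmasked]
        lp += float(np.sum(b * np.log(r) + (1 - b) * np.log(1 - r)))
        logs[sig.label] = lp
    s = pd.Series(logs)
    s = np.exp(s - s.max())
    return s / s.sum()


# ---------------------------------------------------------------------------
# sklearn-style classifier
# ---------------------------------------------------------------------------


class DistanceProfileClassifier(BaseEstimator, ClassifierMixin):
    """Nearest-binary-signature classifier over panel-binarized samples.

    Parameters
    ----------
    panel : MarkerPanel, optional
        When given, ``X`` is beta values aligned to the panel and is
        binarized internally; otherwise ``X`` must already be bit profiles
        over {0, 1, NaN}.
    mode : 'per_sample_mean' | 'centroid'
    adjust : None | 'qffit' | 'bayes' | 'bayesf'
        Distance adjustment applied by :meth:`predict`.
    delta, range_anchor : within-range criterion parameters.
    """

    def __init__(self, panel: MarkerPanel | None = None,
                 mode: str = "per_sample_mean", adjust: str | None = None,
                 delta: float = 0.5, range_anchor: str = "best_match"):
        self.panel = panel
        self.mode = mode
        self.adjust = adjust
        self.delta = delta
        self.range_anchor = range_anchor

    # -- helpers ------------------------------------------------------
    def _bits(self, X) -> np.ndarray:
        if self.panel is not None:
            return np.atleast_2d(binarize(X, self.panel))
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return np.atleast_2d(np.asarray(X, dtype=float))

    def fit(self, X, y):
        y = np.asarray(y)
        bits = self._bits(X)
        if bits.shape[0] != y.shape[0]:
            raise ClassificationError("X and y length mismatch")
        self.classes_ = np.array(sorted(set(y)))
        self.panel_size_ = bits.shape[1]
        self.signatures_ = []
        for cls in self.classes_:
            mp = bits[y == cls]
            med = np.nanmedian(mp, axis=0)
            profile = (med > 0.5).astype(float)
            sig = ClassSignature(str(cls), profile, mp)
            self.signatures_.append(sig)
        for sig in self.signatures_:
            sig.distance_distribution = _self_distances(
                sig, self.mode, self.panel_size_)
        return self

    def distance_vectors(self, X) -> pd.DataFrame:
        check_is_fitted(self, "signatures_")
        bits = self._bits(X)
        rows = [distance_vector(b, self.signatures_, self.mode) for b in bits]
        idx = X.index if isinstance(X, pd.DataFrame) else range(len(rows))
        return pd.DataFrame(rows, index=idx)

    def decide_all(self, X) -> list[ClassificationResult]:
        check_is_fitted(self, "signatures_")
        bits = self._bits(X)
        results = []
        for b in bits:
            dv = distance_vector(b, self.signatures_, self.mode)
            res = decide(dv, self.delta, self.range_anchor)
            if self.adjust == "qffit":
                scores = qffit_scores(dv, self.signatures_)
                res.adjusted_scores = scores
                res.best_match = _argmin_with_ties(scores)
            elif self.adjust in ("bayes", "bayesf"):
                prior = "uniform" if self.adjust == "bayes" else "frequency"
                post = naive_bayes_scores(b, self.signatures_, prior)
                res.adjusted_scores = post
                res.best_match = _argmax_with_ties(post)
            elif self.adjust is not None:
                raise ClassificationError(f"unknown adjust {self.adjust!r}")
            results.append(res)
        return results

    def predict(self, X) -> np.ndarray:
        return np.array([r.best_match for r in self.decide_all(X)])

    def predict_tumor_normal(self, X) -> np.ndarray:
        """OR-rule tumor/normal calls (detection-panel use)."""
        bits = self._bits(X)
        return np.array([call_tumor_normal(b) for b in bits])


def _argmin_with_ties(s: pd.Series) -> str:
    m = s.min()
    return _break_ties([l for l, v in s.items() if v == m])


def _argmax_with_ties(s: pd.Series) -> str:
    m = s.max()
    return _break_ties([l for l, v in s.items() if v == m])


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class PanelEvalReport:
    confusion: pd.DataFrame          # row-normalized, rows = true classes
    accuracy_best: float
    accuracy_rank2: float
    accuracy_within_range: float
    mean_rank_true: float
    mean_within_range_size: float
    n_samples: int


def evaluate_panel(
    m: BetaMatrix,
    ann: pd.DataFrame,
    panel: MarkerPanel,
    mode: str = "per_sample_mean",
    delta: float = 0.5,
    range_anchor: str = "best_match",
    n_folds: int | None = None,
    seed: int = 0,
) -> PanelEvalReport:
    """Classify every labelled sample against class signatures and report the
    row-normalized confusion matrix plus per-criterion accuracies.

    ``n_folds=None`` is resubstitution (signatures built on all samples);
    otherwise stratified k-fold with signatures built on the training part.
    """
    classes = tumor_types(ann) + [REFERENCE_GROUP]
    sample_groups = ann["group"]
    eligible = [
        s for s in m.sample_ids
        if s in sample_groups.index
        and (sample_groups[s] == REFERENCE_GROUP or sample_groups[s].endswith(".T"))
    ]
    true_class = {
        s: (REFERENCE_GROUP if sample_groups[s] == REFERENCE_GROUP
            else sample_groups[s][:-2])
        for s in eligible
    }

    if n_folds is None:
        folds = [(eligible, eligible)]
    else:
        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        y = [true_class[s] for s in eligible]
        folds = [
            ([eligible[i] for i in tr], [eligible[i] for i in te])
            for tr, te in skf.split(eligible, y)
        ]

    counts = pd.DataFrame(0.0, index=classes, columns=classes)
    n_best = n_rank2 = n_within = 0
    rank_sum = 0.0
    size_sum = 0.0
    n_total = 0
    betas = m.values.T
    for train_ids, test_ids in folds:
        sub_ann = ann.loc[train_ids]
        sigs = build_class_signatures(
            BetaMatrix(m.values[train_ids]), sub_ann, panel, mode)
        for s in test_ids:
            bits = binarize(betas.loc[s], panel)
            dv = distance_vector(bits, sigs, mode)
            res = decide(dv, delta, range_anchor)
            t = true_class[s]
            counts.loc[t, res.best_match] += 1
            n_total += 1
            n_best += res.best_match == t
            n_rank2 += res.rank_of[t] <= 2
            n_within += t in res.within_range
            rank_sum += res.rank_of[t]
            size_sum += len(res.within_range)

    row_sums = counts.sum(axis=1).replace(0, np.nan)
    confusion = counts.div(row_sums, axis=0) * 100.0
    return PanelEvalReport(
        confusion=confusion,
        accuracy_best=n_best / n_total,
        accuracy_rank2=n_rank2 / n_total,
        accuracy_within_range=n_within / n_total,
        mean_rank_true=rank_sum / n_total,
        mean_within_range_size=size_sum / n_total,
        n_samples=n_total,
    )
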