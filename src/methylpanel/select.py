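"""Marker selection: tumor-vs-normal ("unconditional") detection probes and
tissue-classification probes from a labelled beta matrix.

The selection logic works from per-group median beta values against a blood
reference whose methylation sits at the extremes of the [0, 1] scale with
minimal variance. A probe is a *detection* (T-N) candidate when

  (i)   its reference median is extreme (``<= ref_low_max`` or
        ``>= ref_high_min``),
  (ii)  its reference SD is small (``<= ref_sd_max``),
  (iii) at least one tumor type's median deviates from the reference median
        by ``>= delta_tumor``, and
  (iv)  every normal-tissue group's median stays within ``eps_normal`` of the
        reference median.

Classification candidates replace (iv) with a constraint on the *negative*
tumor types (they must look like the reference), and drop the normal-tissue
requirement. Detection panels are assembled by greedy set cover so that every
tumor type is detected by at least ``min_probes_per_type`` probes;
classification panels by greedy information-gain (conditional-entropy)
forward selection over binarized per-class profiles.

Per-probe binarization cutoffs are placed at the midpoint between the
reference median and the minimal qualifying tumor shift:
``ref_median + delta_tumor/2`` for low-reference probes, mirrored for
high-reference probes.

Both selectors are also exposed as sklearn-style transformers
(:class:`TumorNormalMarkerSelector`, :class:`ClassificationMarkerSelector`)
whose ``transform`` restricts a samples × probes table to the selected panel.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import REFERENCE_GROUP, BetaMatrix, tumor_types

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    """Raised when selection preconditions fail or a panel is infeasible."""


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds of the marker-selection filters.

    ``ref_sd_max`` defaults to 0.07, the variability bound below which the
    bulk of blood-reference probes fall; the remaining cutoffs are
    conservative defaults on the beta scale.
    """

    ref_low_max: float = 0.1
    ref_high_min: float = 0.9
    ref_sd_max: float = 0.07
    delta_tumor: float = 0.3
    eps_normal: float = 0.1
    min_probes_per_type: int = 2
    max_panel_size: int | None = None
    max_missing_frac: float = 0.2
    neg_mode: str = "eps_normal"  # or "extreme_band"

    def __post_init__(self) -> None:
        if not (0.0 <= self.ref_low_max < self.ref_high_min <= 1.0):
            raise SelectionError("need 0 <= ref_low_max < ref_high_min <= 1")
        if not (self.delta_tumor > self.eps_normal >= 0.0):
            raise SelectionError("need delta_tumor > eps_normal >= 0")
        if self.min_probes_per_type < 1:
            raise SelectionError("min_probes_per_type must be >= 1")
        if self.neg_mode not in ("eps_normal", "extreme_band"):
            raise SelectionError(f"unknown neg_mode {self.neg_mode!r}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class CandidateProbe:
    probe_id: str
    reference_state: str  # "low" | "high"
    reference_median: float
    reference_sd: float
    positive_types: tuple[str, ...]
    type_medians: dict[str, float] = field(compare=False, default_factory=dict)

    def shift(self, t: str) -> float:
        return abs(self.type_medians[t] - self.reference_median)


@dataclass(frozen=True)
class PanelProbe:
    probe_id: str
    reference_state: str
    cutoff: float


@dataclass(frozen=True)
class MarkerPanel:
    panel_kind: str  # "detection" | "classification"
    probes: tuple[PanelProbe, ...]
    params_hash: str = ""

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise SelectionError("duplicate probe ids in panel")

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    def __len__(self) -> int:
        return len(self.probes)


def panel_to_json(panel: MarkerPanel, path: str | Path) -> None:
    doc = {
        "panel_kind": panel.panel_kind,
        "probes": [asdict(p) for p in panel.probes],
        "params_hash": panel.params_hash,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def panel_from_json(path: str | Path) -> MarkerPanel:
    doc = json.loads(Path(path).read_text())
    return MarkerPanel(
        panel_kind=doc["panel_kind"],
        probes=tuple(PanelProbe(**p) for p in doc["probes"]),
        params_hash=doc.get("params_hash", ""),
    )


def probe_cutoff(reference_state: str, reference_median: float,
                 delta_tumor: float) -> float:
    """Midpoint binarization cutoff between the reference extreme and the
    minimal qualifying tumor deviation."""
    if reference_state == "low":
        return reference_median + delta_tumor / 2.0
    return reference_median - delta_tumor / 2.0


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


def _group_stats(m: BetaMatrix, ann: pd.DataFrame):
    """Per-probe reference median/SD, per-group medians and missing fractions."""
    V = m.values  # probes × samples
    ann = ann.loc[[s for s in m.sample_ids if s in ann.index]]
    ref_ids = ann.index[ann["group"] == REFERENCE_GROUP]
    if len(ref_ids) == 0:
        raise SelectionError("no reference samples in annotation")
    ref = V[ref_ids]
    stats = {
        "ref_median": ref.median(axis=1),
        "ref_sd": ref.std(axis=1, ddof=1),
    }
    medians: dict[str, pd.Series] = {}
    missing: dict[str, pd.Series] = {REFERENCE_GROUP: ref.isna().mean(axis=1)}
    for g in sorted(ann["group"].unique()):
        if g == REFERENCE_GROUP:
            continue
        cols = ann.index[ann["group"] == g]
        medians[g] = V[cols].median(axis=1)
        missing[g] = V[cols].isna().mean(axis=1)
    return stats, medians, missing


def _extreme_state(ref_median: pd.Series, p: SelectionParams) -> pd.Series:
    state = pd.Series("none", index=ref_median.index)
    state[ref_median <= p.ref_low_max] = "low"
    state[ref_median >= p.ref_high_min] = "high"
    state[ref_median.isna()] = "none"
    return state


def _missing_ok(missing: dict[str, pd.Series], p: SelectionParams) -> pd.Series:
    ok = None
    for frac in missing.values():
        this = frac <= p.max_missing_frac
        ok = this if ok is None else (ok & this)
    return ok


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------


def select_tn_candidates(
    m: BetaMatrix, ann: pd.DataFrame, p: SelectionParams = SelectionParams()
) -> list[CandidateProbe]:
    """Apply the four tumor-vs-normal candidate filters (module docstring)."""
    stats, medians, missing = _group_stats(m, ann)
    types = tumor_types(ann)
    if not types:
        raise SelectionError("no tumor (<type>.T) groups in annotation")
    state = _extreme_state(stats["ref_median"], p)
    ok = (state != "none") & (stats["ref_sd"] <= p.ref_sd_max) & _missing_ok(missing, p)

    cands: list[CandidateProbe] = []
    for probe in m.probe_ids:
        if not bool(ok.loc[probe]):
            continue
        ref_med = float(stats["ref_median"].loc[probe])
        tmeds = {t: float(medians[f"{t}.T"].loc[probe]) for t in types
                 if f"{t}.T" in medians}
        positives = tuple(t for t, v in sorted(tmeds.items())
                          if not np.isnan(v) and abs(v - ref_med) >= p.delta_tumor)
        if not positives:
            continue
        normal_ok = True
        for t in types:
            g = f"{t}.N"
            if g in medians:
                v = medians[g].loc[probe]
                if np.isnan(v) or abs(float(v) - ref_med) > p.eps_normal:
                    normal_ok = False
                    break
        if not normal_ok:
            continue
        cands.append(
            CandidateProbe(
                probe_id=probe,
                reference_state=str(state.loc[probe]),
                reference_median=ref_med,
                reference_sd=float(stats["ref_sd"].loc[probe]),
                positive_types=positives,
                type_medians=tmeds,
            )
        )
    if not cands:
        logger.warning("all probes filtered out; empty T-N candidate pool")
    return cands


def select_classification_candidates(
    m: BetaMatrix, ann: pd.DataFrame, p: SelectionParams = SelectionParams()
) -> list[CandidateProbe]:
    """Candidates for tissue-of-origin classification: extreme low-variance
    reference, >=1 positive tumor type, and every *negative* tumor type's
    median looking like the reference (normal-tissue concordance is not
    required here)."""
    stats, medians, missing = _group_stats(m, ann)
    types = tumor_types(ann)
    if len(types) < 2:
        raise SelectionError("classification selection needs >= 2 tumor types")
    state = _extreme_state(stats["ref_median"], p)
    ok = (state != "none") & (stats["ref_sd"] <= p.ref_sd_max) & _missing_ok(missing, p)

    cands: list[CandidateProbe] = []
    for probe in m.probe_ids:
        if not bool(ok.loc[probe]):
            continue
        ref_med = float(stats["ref_median"].loc[probe])
        st = str(state.loc[probe])
        tmeds = {t: float(medians[f"{t}.T"].loc[probe]) for t in types
                 if f"{t}.T" in medians}
        positives = tuple(t for t, v in sorted(tmeds.items())
                          if not np.isnan(v) and abs(v - ref_med) >= p.delta_tumor)
        if not positives:
            continue
        neg_ok = True
        for t, v in tmeds.items():
            if t in positives:
                continue
            if np.isnan(v):
                neg_ok = False
                break
            if p.neg_mode == "eps_normal":
                neg_ok = abs(v - ref_med) <= p.eps_normal
            else:  # negative types must sit inside the reference-extreme band
                neg_ok = v <= p.ref_low_max if st == "low" else v >= p.ref_high_min
            if not neg_ok:
                break
        if not neg_ok:
            continue
        cands.append(
            CandidateProbe(
                probe_id=probe,
                reference_state=st,
                reference_median=ref_med,
                reference_sd=float(stats["ref_sd"].loc[probe]),
                positive_types=positives,
                type_medians=tmeds,
            )
        )
    if not cands:
        logger.warning("all probes filtered out; empty classification pool")
    return cands


# ---------------------------------------------------------------------------
# detection panel: greedy set cover
# ---------------------------------------------------------------------------


def assemble_detection_panel(
    cands: Sequence[CandidateProbe],
    types: Sequence[str],
    p: SelectionParams = SelectionParams(),
) -> MarkerPanel:
    """Greedy set cover: repeatedly add the candidate covering the most
    still-under-covered (type, slot) pairs until every type is detected by
    ``min_probes_per_type`` probes.

    Ties break by larger minimum median shift over the types a candidate
    covers, then lexicographic probe id. Raises :class:`SelectionError` when
    a type has too few covering candidates or ``max_panel_size`` is hit with
    unmet coverage.
    """
    if not cands:
        raise SelectionError("empty candidate pool")
    types = list(types)
    cover = {c.probe_id: set(c.positive_types) & set(types) for c in cands}
    for t in types:
        n_cov = sum(1 for s in cover.values() if t in s)
        if n_cov < p.min_probes_per_type:
            raise SelectionError(
                f"type {t!r} covered by only {n_cov} candidates "
                f"(< min_probes_per_type={p.min_probes_per_type})"
            )

    need = {t: p.min_probes_per_type for t in types}
    chosen: list[CandidateProbe] = []
    remaining = {c.probe_id: c for c in cands}
    while any(n > 0 for n in need.values()):
        if p.max_panel_size is not None and len(chosen) >= p.max_panel_size:
            unmet = sorted(t for t, n in need.items() if n > 0)
            raise SelectionError(
                f"max_panel_size={p.max_panel_size} reached with types "
                f"{unmet} under-covered"
            )

        def key(c: CandidateProbe):
            covered = cover[c.probe_id]
            gain = sum(1 for t in covered if need[t] > 0)
            min_shift = min((c.shift(t) for t in covered), default=0.0)
            return (-gain, -min_shift, c.probe_id)

        best = min(remaining.values(), key=key)
        if sum(1 for t in cover[best.probe_id] if need[t] > 0) == 0:
            raise SelectionError("no candidate improves coverage")  # unreachable after feasibility check
        chosen.append(best)
        for t in cover[best.probe_id]:
            if need[t] > 0:
                need[t] -= 1
        del remaining[best.probe_id]

    probes = tuple(
        PanelProbe(c.probe_id, c.reference_state,
                   probe_cutoff(c.reference_state, c.reference_median, p.delta_tumor))
        for c in chosen
    )
    return MarkerPanel("detection", probes, params_hash=p.hash())


# ---------------------------------------------------------------------------
# classification panel: greedy information gain
# ---------------------------------------------------------------------------


def _class_bits(cands: Sequence[CandidateProbe], classes: Sequence[str],
                class_medians: dict[str, pd.Series],
                p: SelectionParams) -> np.ndarray:
    """(n_cands, n_classes) binarized per-class median profile."""
    bits = np.zeros((len(cands), len(classes)), dtype=np.int8)
    for i, c in enumerate(cands):
        cut = probe_cutoff(c.reference_state, c.reference_median, p.delta_tumor)
        for j, cls in enumerate(classes):
            med = class_medians[cls].get(c.probe_id, np.nan)
            if np.isnan(med):
                continue
            if c.reference_state == "low":
                bits[i, j] = 1 if med > cut else 0
            else:
                bits[i, j] = 1 if med < cut else 0
    return bits


def _partition_entropy(profiles: np.ndarray, weights: np.ndarray) -> float:
    """Weighted conditional entropy H(class | accumulated profile blocks)."""
    blocks: dict[bytes, list[int]] = {}
    for j in range(profiles.shape[1]):
        blocks.setdefault(profiles[:, j].tobytes(), []).append(j)
    total = weights.sum()
    h = 0.0
    for members in blocks.values():
        w = weights[members]
        wb = w.sum()
        frac = w / wb
        frac = frac[frac > 0]
        h_block = float(-np.sum(frac * np.log2(frac)))
        h += (wb / total) * h_block
    return float(h)


def entropy_panel_search(
    m: BetaMatrix,
    ann: pd.DataFrame,
    cands: Sequence[CandidateProbe],
    target_size: int | None = None,
    seed: int = 0,
    p: SelectionParams = SelectionParams(),
    include_reference: bool = True,
) -> MarkerPanel:
    """Greedy forward selection maximising information gain on the class
    partition induced by the accumulated binarized per-class profiles.

    Selection stops when every class (plus the reference, when included) has
    a unique profile, ``target_size`` is reached, or no candidate strictly
    reduces the conditional entropy (best-effort panel with a logged warning
    listing the merged classes). Ties break in a seed-shuffled candidate
    order, so the result is deterministic under (pool, seed).
    """
    if not cands:
        raise SelectionError("empty candidate pool")
    types = tumor_types(ann)
    classes = list(types) + ([REFERENCE_GROUP] if include_reference else [])
    if len(classes) < 2:
        raise SelectionError("need >= 2 classes to split")

    class_medians: dict[str, pd.Series] = {}
    counts = []
    for cls in classes:
        g = REFERENCE_GROUP if cls == REFERENCE_GROUP else f"{cls}.T"
        cols = ann.index[ann["group"] == g]
        cols = [c for c in cols if c in m.sample_ids]
        class_medians[cls] = m.values[cols].median(axis=1)
        counts.append(len(cols))
    weights = np.asarray(counts, dtype=float)

    bits = _class_bits(cands, classes, class_medians, p)
    order = np.random.default_rng(seed).permutation(len(cands))

    selected: list[int] = []
    profiles = np.zeros((0, len(classes)), dtype=np.int8)
    h = _partition_entropy(profiles, weights)
    limit = target_size if target_size is not None else len(cands)
    while len(selected) < limit and h > 0:
        best_i, best_h = None, h
        for i in order:
            if i in selected:
                continue
            trial = np.vstack([profiles, bits[i][None, :]])
            h_i = _partition_entropy(trial, weights)
            if h_i < best_h - 1e-12:
                best_i, best_h = int(i), h_i
        if best_i is None:
            merged = _merged_classes(profiles, classes)
            logger.warning(
                "entropy search stalled at H=%.3f bits; merged classes: %s",
                h, merged,
            )
            break
        selected.append(best_i)
        profiles = np.vstack([profiles, bits[best_i][None, :]])
        h = best_h

    probes = tuple(
        PanelProbe(
            cands[i].probe_id,
            cands[i].reference_state,
            probe_cutoff(cands[i].reference_state, cands[i].reference_median,
                         p.delta_tumor),
        )
        for i in selected
    )
    return MarkerPanel("classification", probes, params_hash=p.hash())


def _merged_classes(profiles: np.ndarray, classes: Sequence[str]) -> list[list[str]]:
    blocks: dict[bytes, list[str]] = {}
    for j, cls in enumerate(classes):
        blocks.setdefault(profiles[:, j].tobytes(), []).append(cls)
    return [b for b in blocks.values() if len(b) > 1]


# ---------------------------------------------------------------------------
# sklearn-style selectors
# ---------------------------------------------------------------------------


class _BaseMarkerSelector(BaseEstimator, TransformerMixin):
    """Shared fit/transform plumbing; X is samples × probes, y group labels."""

    def __init__(self, ref_low_max=0.1, ref_high_min=0.9, ref_sd_max=0.07,
                 delta_tumor=0.3, eps_normal=0.1, min_probes_per_type=2,
                 max_panel_size=None, max_missing_frac=0.2,
                 neg_mode="eps_normal"):
        self.ref_low_max = ref_low_max
        self.ref_high_min = ref_high_min
        self.ref_sd_max = ref_sd_max
        self.delta_tumor = delta_tumor
        self.eps_normal = eps_normal
        self.min_probes_per_type = min_probes_per_type
        self.max_panel_size = max_panel_size
        self.max_missing_frac = max_missing_frac
        self.neg_mode = neg_mode

    def _params(self) -> SelectionParams:
        return SelectionParams(
            ref_low_max=self.ref_low_max, ref_high_min=self.ref_high_min,
            ref_sd_max=self.ref_sd_max, delta_tumor=self.delta_tumor,
            eps_normal=self.eps_normal,
            min_probes_per_type=self.min_probes_per_type,
            max_panel_size=self.max_panel_size,
            max_missing_frac=self.max_missing_frac, neg_mode=self.neg_mode,
        )

    @staticmethod
    def _as_matrix(X, y) -> tuple[BetaMatrix, pd.DataFrame]:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"p{j}" for j in range(X.shape[1])]
            X.index = [f"s{i}" for i in range(X.shape[0])]
        m = BetaMatrix(X.T.copy())
        ann = pd.DataFrame({"group": list(y)},
                           index=pd.Index(X.index, name="sample_id"))
        return m, ann

    def transform(self, X):
        check_is_fitted(self, "panel_")
        if isinstance(X, pd.DataFrame):
            return X[self.panel_.probe_ids]
        raise TypeError("transform requires a DataFrame with probe-id columns")


class TumorNormalMarkerSelector(_BaseMarkerSelector):
    """Feature selector retaining the detection (T-N) panel probes.

    Fitted attributes: ``candidates_`` (the filtered pool), ``panel_`` (the
    greedy-cover detection panel), ``types_``.
    """

    def fit(self, X, y):
        m, ann = self._as_matrix(X, y)
        p = self._params()
        self.candidates_ = select_tn_candidates(m, ann, p)
        self.types_ = tumor_types(ann)
        self.panel_ = assemble_detection_panel(self.candidates_, self.types_, p)
        return self


class ClassificationMarkerSelector(_BaseMarkerSelector):
    """Feature selector retaining the tissue-classification panel probes
    chosen by the entropy search.

    Fitted attributes: ``candidates_``, ``panel_``, ``types_``.
    """

    def __init__(self, target_size=None, seed=0, include_reference=True,
                 ref_low_max=0.1, ref_high_min=0.9, ref_sd_max=0.07,
                 delta_tumor=0.3, eps_normal=0.1, min_probes_per_type=2,
                 max_panel_size=None, max_missing_frac=0.2,
                 neg_mode="eps_normal"):
        super().__init__(
            ref_low_max=ref_low_max, ref_high_min=ref_high_min,
            ref_sd_max=ref_sd_max, delta_tumor=delta_tumor,
            eps_normal=eps_normal, min_probes_per_type=min_probes_per_type,
            max_panel_size=max_panel_size, max_missing_frac=max_missing_frac,
            neg_mode=neg_mode,
        )
        self.target_size = target_size
        self.seed = seed
        self.include_reference = include_reference

    def fit(self, X, y):
        m, ann = self._as_matrix(X, y)
        p = self._params()
        self.candidates_ = select_classification_candidates(m, ann, p)
        self.types_ = tumor_types(ann)
        self.panel_ = entropy_panel_search(
            m, ann, self.candidates_, target_size=self.target_size,
            seed=self.seed, p=p, include_reference=self.include_reference,
        )
        return self
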