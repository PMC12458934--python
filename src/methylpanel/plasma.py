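"""Plasma WGBS signal-fraction analysis with max-of-controls thresholding.

For each panel CpG a window of ±200 bp is examined. All methylated and
unmethylated CpG calls on reads overlapping the window are summed into the
region counts (cm, cu). The signal fraction is oriented against the
reference extreme of the locus: x = cm/(cu+cm) where reference plasma is
essentially unmethylated, x = cu/(cu+cm) where it is essentially fully
methylated, so that tumor-derived signal always pushes x upward. A region
with no sequenced CpGs has an *undefined* x — propagated as missing, never
as 0.

Per-region binarization thresholds are the highest x observed in the control
plasma cohort; a patient region scores 1 iff its x strictly exceeds the
threshold, and the sample-level call is the OR over regions. By
construction, re-scoring the control cohort against its own thresholds
yields zero positive calls (no value strictly exceeds its own cohort
maximum).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import (
    CALL_METH,
    CALL_UNMETH,
    ReadMethylationRecord,
    RegionOfInterest,
    reads_by_region,
    stack_calls,
)
from .select import MarkerPanel


class PlasmaError(ValueError):
    pass


@dataclass(frozen=True)
class RegionCounts:
    sample_id: str
    region_id: str
    cu: int
    cm: int

    def __post_init__(self) -> None:
        if self.cu < 0 or self.cm < 0:
            raise PlasmaError("counts must be >= 0")


def window_region(
    region_id: str, chrom: str, site: int, cpg_positions: Sequence[int],
    flank: int = 200,
) -> RegionOfInterest:
    """Build the panel-CpG window [site - flank, site + flank + 1) and check
    the enumerated CpGs fall inside it."""
    return RegionOfInterest(
        region_id, chrom, site - flank, site + flank + 1, tuple(cpg_positions)
    )


def window_counts(
    reads: Iterable[ReadMethylationRecord], region: RegionOfInterest,
    sample_id: str = "",
) -> RegionCounts:
    """Sum methylated/unmethylated CpG calls over all reads of the window;
    missing calls contribute to neither count."""
    calls = stack_calls([r for r in reads if r.region_id == region.region_id])
    cm = int(np.sum(calls == CALL_METH))
    cu = int(np.sum(calls == CALL_UNMETH))
    return RegionCounts(sample_id, region.region_id, cu=cu, cm=cm)


def signal_fraction(rc: RegionCounts, direction: str) -> float:
    """Oriented signal fraction; NaN when the region has no coverage.

    ``direction='reference_low'`` -> x = cm/(cu+cm);
    ``'reference_high'`` -> x = cu/(cu+cm).
    """
    total = rc.cu + rc.cm
    if total == 0:
        return float("nan")
    if direction == "reference_low":
        return rc.cm / total
    if direction == "reference_high":
        return rc.cu / total
    raise PlasmaError(f"unknown direction {direction!r}")


def panel_directions(panel: MarkerPanel) -> dict[str, str]:
    """Map probe/region id -> signal-fraction direction from the panel's
    per-probe reference state."""
    return {
        p.probe_id: ("reference_low" if p.reference_state == "low"
                     else "reference_high")
        for p in panel.probes
    }


def cohort_signal_fractions(
    reads_by_sample: Mapping[str, Sequence[ReadMethylationRecord]],
    regions: Sequence[RegionOfInterest],
    directions: Mapping[str, str] | str = "reference_low",
) -> pd.DataFrame:
    """Samples × regions table of signal fractions (NaN = undefined)."""
    rows = {}
    for sid, reads in reads_by_sample.items():
        by_region = reads_by_region(reads)
        row = {}
        for region in regions:
            rc = window_counts(by_region.get(region.region_id, []), region, sid)
            direction = (directions if isinstance(directions, str)
                         else directions[region.region_id])
            row[region.region_id] = signal_fraction(rc, direction)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")[
        [r.region_id for r in regions]
    ]


def derive_thresholds(controls: pd.DataFrame) -> pd.Series:
    """Per-region threshold = max defined control x. A region with no
    defined control value raises, naming the region."""
    if controls.shape[0] < 1:
        raise PlasmaError("need >= 1 control sample")
    undefined = controls.columns[controls.notna().sum(axis=0) == 0]
    if len(undefined):
        raise PlasmaError(
            f"no defined control signal fraction for regions: {list(undefined)}"
        )
    return controls.max(axis=0, skipna=True).rename("threshold")


def call_plasma_sample(
    xs: pd.Series, thresholds: pd.Series
) -> tuple[pd.Series, str]:
    """Binarize one sample's per-region x against the thresholds (strict >)
    and call tumor iff any bit is 1.

    Undefined x gives bit 0 (flagged via NaN in the returned bit series'
    companion mask — the bit itself is 0); all-undefined is indeterminate.
    """
    xs = xs.reindex(thresholds.index)
    defined = xs.notna()
    bits = ((xs > thresholds) & defined).astype(int)
    if not defined.any():
        return bits, INDETERMINATE
    return bits, (TUMOR if bits.any() else NORMAL)


TUMOR, NORMAL, INDETERMINATE = "tumor", "normal", "indeterminate"


class MaxControlPlasmaCaller(BaseEstimator):
    """Max-of-controls thresholding as a fit/predict estimator.

    ``fit`` takes the control cohort's samples × regions signal-fraction
    table; ``predict`` returns 'tumor'/'normal'/'indeterminate' per sample,
    and ``predict_bits`` the per-region binarization.
    """

    def fit(self, X: pd.DataFrame, y=None):
        self.thresholds_ = derive_thresholds(X)
        self.n_controls_ = X.shape[0]
        return self

    def predict_bits(self, X: pd.DataFrame) -> pd.DataFrame:
        bits = {}
        for sid, row in X.iterrows():
            b, _ = call_plasma_sample(row, self.thresholds_)
            bits[sid] = b
        return pd.DataFrame.from_dict(bits, orient="index")[
            list(self.thresholds_.index)
        ]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.array(
            [call_plasma_sample(row, self.thresholds_)[1]
             for _, row in X.iterrows()]
        )
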