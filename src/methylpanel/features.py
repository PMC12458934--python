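"""Read-level QC, filtering and cumulative methylation-density features for
targeted bisulfite/enzymatic methylation sequencing.

Sample-level QC: the pooled non-CpG methylation rate (methylated CHH/CHG
cytosines over all observed ones) estimates bisulfite-conversion failure; a
sample whose rate exceeds 3% is discarded.

Read-level filters, applied in order with per-stage counts logged:

1. mean base quality < 20;
2. more than 8 methylated non-CpG cytosines on the read (unconverted
   molecule);
3. non-missing CpG calls covering < 90% of the region's expected CpGs.

Per-read percent methylation divides the methylated-CpG count by the
region's full CpG count — CpGs the read does not cover are counted as
unmethylated, which keeps the denominator consistent across reads.

The per-region feature block is the cumulative methylation-density profile:
under the default ``or_higher`` convention, feature k (k = 1..n_cpg) is the
fraction of retained reads with at least k methylated CpGs, i.e. with
"> (k-1)/n_cpg methylation" (a 4-CpG region yields bins >0%, >25%, >50%,
>75%). The rationale: tumor-derived fragment populations show similar but
not identical methylation densities, so the cumulative tail captures dilute
signal better than the mean. The ``at_or_below`` alternative reports the
fraction of reads with at most k methylated CpGs for k = 0..n_cpg-1, the
exact elementwise complement of the default grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import (
    CALL_METH,
    ReadMethylationRecord,
    RegionOfInterest,
    reads_by_region,
    stack_calls,
)

logger = logging.getLogger(__name__)


class FeatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# QC and filtering
# ---------------------------------------------------------------------------


@dataclass
class SampleQCReport:
    sample_id: str
    noncpg_meth_rate: float          # NaN when no non-CpG cytosines observed
    passed: bool | None              # None = indeterminate (no observations)
    n_reads: int

    @property
    def indeterminate(self) -> bool:
        return self.passed is None


def sample_conversion_check(
    reads: Sequence[ReadMethylationRecord],
    sample_id: str = "",
    max_rate: float = 0.03,
) -> SampleQCReport:
    """Pooled non-CpG methylation rate over all reads; fail strictly above
    ``max_rate`` (a rate of exactly 3% passes)."""
    meth = sum(r.n_noncpg_meth for r in reads)
    total = sum(r.n_noncpg_total for r in reads)
    if total == 0:
        logger.warning("sample %s: no non-CpG cytosines observed; QC indeterminate",
                       sample_id)
        return SampleQCReport(sample_id, float("nan"), None, len(reads))
    rate = meth / total
    return SampleQCReport(sample_id, rate, rate <= max_rate, len(reads))


def filter_reads(
    reads: Sequence[ReadMethylationRecord],
    region: RegionOfInterest,
    min_quality: float = 20.0,
    max_noncpg_meth: int = 8,
    min_span: float = 0.9,
) -> tuple[list[ReadMethylationRecord], dict[str, int]]:
    """Sequential read filters with per-stage in/out counts.

    Stage 1 drops reads with mean quality < ``min_quality``; stage 2 reads
    with strictly more than ``max_noncpg_meth`` methylated non-CpGs; stage 3
    reads whose non-missing calls cover < ``min_span`` of the region's CpGs.
    """
    counts = {"input": len(reads)}
    stage1 = [r for r in reads if r.mean_quality >= min_quality]
    counts["after_quality"] = len(stage1)
    stage2 = [r for r in stage1 if r.n_noncpg_meth <= max_noncpg_meth]
    counts["after_conversion"] = len(stage2)
    n_cpg = region.n_cpg
    stage3 = [r for r in stage2 if r.n_covered / n_cpg >= min_span]
    counts["after_span"] = len(stage3)
    return stage3, counts


def read_percent_methylation(
    read: ReadMethylationRecord, region: RegionOfInterest
) -> float:
    """Methylated-CpG count over the region's full CpG count; missing calls
    count as unmethylated."""
    return read.n_methylated / region.n_cpg


# ---------------------------------------------------------------------------
# cumulative features
# ---------------------------------------------------------------------------


def _fmt_pct(x: float) -> str:
    pct = 100.0 * x
    return f"{pct:g}%" if abs(pct - round(pct)) > 1e-9 else f"{round(pct):d}%"


@dataclass
class FeatureVector:
    region_id: str
    names: tuple[str, ...]           # stable column names, region:ge_k style
    thresholds: tuple[str, ...]      # human-readable bin labels
    values: np.ndarray               # NaN-filled when n_reads == 0
    n_reads: int
    convention: str = "or_higher"

    @property
    def missing(self) -> bool:
        return self.n_reads == 0


def cumulative_features(
    reads: Sequence[ReadMethylationRecord],
    region: RegionOfInterest,
    convention: str = "or_higher",
) -> FeatureVector:
    """Cumulative methylation-density feature block for one region.

    ``or_higher``: value_k = fraction of reads with >= k methylated CpGs for
    k = 1..n_cpg (bin labels "> (k-1)/n_cpg"). ``at_or_below``: value_k =
    fraction with <= k methylated CpGs for k = 0..n_cpg-1. With no reads the
    vector is flagged missing (NaN values), never zeros.
    """
    n = region.n_cpg
    if convention == "or_higher":
        ks = list(range(1, n + 1))
        names = tuple(f"{region.region_id}:ge_{k}" for k in ks)
        labels = tuple(f">{_fmt_pct((k - 1) / n)}" for k in ks)
    elif convention == "at_or_below":
        ks = list(range(0, n))
        names = tuple(f"{region.region_id}:le_{k}" for k in ks)
        labels = tuple(f"<={_fmt_pct(k / n)}" for k in ks)
    else:
        raise FeatureError(f"unknown convention {convention!r}")

    if len(reads) == 0:
        return FeatureVector(region.region_id, names, labels,
                             np.full(len(ks), np.nan), 0, convention)

    calls = stack_calls(list(reads))
    meth_counts = np.sum(calls == CALL_METH, axis=1)  # missing = unmethylated
    if convention == "or_higher":
        values = np.array([np.mean(meth_counts >= k) for k in ks])
    else:
        values = np.array([np.mean(meth_counts <= k) for k in ks])
    return FeatureVector(region.region_id, names, labels, values,
                         len(reads), convention)


def cohort_feature_table(
    reads_by_sample: Mapping[str, Sequence[ReadMethylationRecord]],
    regions: Sequence[RegionOfInterest],
    convention: str = "or_higher",
    min_quality: float = 20.0,
    max_noncpg_meth: int = 8,
    min_span: float = 0.9,
    conversion_max_rate: float = 0.03,
    apply_sample_qc: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the samples × features table (per-region blocks concatenated in
    region order) plus a per-sample QC table.

    Samples failing the conversion QC are kept in the QC table but excluded
    from the feature table when ``apply_sample_qc`` is set.
    """
    qc_rows = []
    feat_rows: dict[str, dict[str, float]] = {}
    for sid, reads in reads_by_sample.items():
        qc = sample_conversion_check(list(reads), sid, conversion_max_rate)
        qc_rows.append(
            {"sample_id": sid, "noncpg_meth_rate": qc.noncpg_meth_rate,
             "passed": qc.passed, "n_reads": qc.n_reads}
        )
        if apply_sample_qc and qc.passed is False:
            logger.warning("sample %s discarded: non-CpG methylation %.2f%% > %.0f%%",
                           sid, 100 * qc.noncpg_meth_rate, 100 * conversion_max_rate)
            continue
        by_region = reads_by_region(list(reads))
        row: dict[str, float] = {}
        for region in regions:
            kept, _ = filter_reads(
                by_region.get(region.region_id, []), region,
                min_quality, max_noncpg_meth, min_span,
            )
            fv = cumulative_features(kept, region, convention)
            row.update(dict(zip(fv.names, fv.values)))
        feat_rows[sid] = row
    features = pd.DataFrame.from_dict(feat_rows, orient="index")
    qc = pd.DataFrame(qc_rows).set_index("sample_id") if qc_rows else pd.DataFrame()
    return features, qc


class CumulativeReadFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer from per-sample read tables to the cohort feature table.

    ``transform`` takes a mapping sample_id -> reads and returns the
    samples × features DataFrame; the per-sample QC table from the last
    transform is kept on ``qc_``.
    """

    def __init__(self, regions: Sequence[RegionOfInterest] = (),
                 convention: str = "or_higher", min_quality: float = 20.0,
                 max_noncpg_meth: int = 8, min_span: float = 0.9,
                 conversion_max_rate: float = 0.03,
                 apply_sample_qc: bool = True):
        self.regions = regions
        self.convention = convention
        self.min_quality = min_quality
        self.max_noncpg_meth = max_noncpg_meth
        self.min_span = min_span
        self.conversion_max_rate = conversion_max_rate
        self.apply_sample_qc = apply_sample_qc

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: Mapping[str, Sequence[ReadMethylationRecord]]):
        features, qc = cohort_feature_table(
            X, self.regions, self.convention, self.min_quality,
            self.max_noncpg_meth, self.min_span, self.conversion_max_rate,
            self.apply_sample_qc,
        )
        self.qc_ = qc
        return features
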