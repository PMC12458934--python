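"""Readers and writers for the tabular formats used throughout the package.

Four in-memory types travel between modules:

* :class:`BetaMatrix` — probes × samples array of Illumina-style beta values
  in [0, 1] (missing allowed, carried as NaN, never imputed here);
* sample annotations — a DataFrame mapping sample id to a group label using
  the ``reference`` / ``<type>.N`` / ``<type>.T`` convention;
* :class:`RegionOfInterest` — a BED-style 0-based half-open interval with the
  ordered genomic positions of its CpGs;
* :class:`ReadMethylationRecord` — one sequenced molecule's ordered per-CpG
  methylation calls plus its non-CpG (CHH/CHG) conversion counters and mean
  base quality, i.e. the per-read table produced downstream of a
  Bismark-style methylation extractor.

All file formats are plain TSV/BED so fixtures stay text and diffable.
Coordinates are 0-based half-open; CpG positions are plus-strand cytosine
positions; records are strand-collapsed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REFERENCE_GROUP = "reference"

#: integer encoding of per-CpG calls inside ReadMethylationRecord.cpg_calls
CALL_METH = 1
CALL_UNMETH = 0
CALL_MISSING = -1

_CALL_TO_CHAR = {CALL_METH: "M", CALL_UNMETH: "U", CALL_MISSING: "."}
_CHAR_TO_CALL = {v: k for k, v in _CALL_TO_CHAR.items()}


class FormatError(ValueError):
    """A file violated the format contract (bad value, bad id, bad shape)."""


# ---------------------------------------------------------------------------
# BetaMatrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Samples × probes beta values, stored probes-as-rows.

    ``values`` is a float DataFrame indexed by probe id with sample ids as
    columns; missing beta values are NaN.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        arr = v.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            r, c = np.argwhere(bad & ~np.isnan(arr))[0]
            raise FormatError(
                f"beta value {arr[r, c]} outside [0, 1] at probe "
                f"{v.index[r]!r}, sample {v.columns[c]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_by_probes(self) -> pd.DataFrame:
        """Samples-as-rows view (the orientation sklearn estimators expect)."""
        return self.values.T


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Parse a probes × samples TSV (first column probe id, header sample ids).

    Empty cells are missing. Values outside [0, 1] and duplicate ids raise
    :class:`FormatError` naming the offender.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    try:
        vals = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric beta value ({exc})") from exc
    return BetaMatrix(vals.astype(float))


def write_beta_matrix(m: BetaMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="probe_id", na_rep="")


# ---------------------------------------------------------------------------
# Sample annotations
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation TSV (columns: sample_id, group, covariates...)."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in ann.columns or "group" not in ann.columns:
        raise FormatError(f"{path}: annotation needs 'sample_id' and 'group' columns")
    if ann["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in annotation")
    return ann.set_index("sample_id")


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index_label="sample_id")


def validate_annotation(ann: pd.DataFrame, m: BetaMatrix) -> None:
    """Every annotated sample must exist in the matrix; groups must be
    ``reference`` or ``<type>.N`` / ``<type>.T``."""
    missing = set(ann.index) - set(m.sample_ids)
    if missing:
        raise FormatError(f"annotated samples absent from matrix: {sorted(missing)}")
    for g in ann["group"].unique():
        if g == REFERENCE_GROUP:
            continue
        if not (g.endswith(".N") or g.endswith(".T")) or len(g) < 3:
            raise FormatError(f"group label {g!r} is not reference/<type>.N/<type>.T")


def tumor_types(ann: pd.DataFrame) -> list[str]:
    """Sorted tumor-type codes present as ``<type>.T`` groups."""
    return sorted({g[:-2] for g in ann["group"].unique() if g.endswith(".T")})


def group_samples(ann: pd.DataFrame, group: str) -> list[str]:
    return list(ann.index[ann["group"] == group])


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionOfInterest:
    """A target region: 0-based half-open interval with ordered CpG positions."""

    region_id: str
    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"region {self.region_id}: start {self.start} >= end {self.end}"
            )
        if len(self.cpg_positions) < 1:
            raise FormatError(f"region {self.region_id}: no CpG positions")
        for p in self.cpg_positions:
            if not (self.start <= p < self.end):
                raise FormatError(
                    f"region {self.region_id}: CpG position {p} outside "
                    f"[{self.start}, {self.end})"
                )
        if list(self.cpg_positions) != sorted(self.cpg_positions):
            raise FormatError(f"region {self.region_id}: CpG positions not sorted")

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)


def read_regions(path: str | Path) -> list[RegionOfInterest]:
    """Parse a BED3+2 file: chrom, start, end, region_id, comma-separated CpG
    positions. Returns regions in file order; an empty file yields an empty
    list with a warning."""
    regions: list[RegionOfInterest] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            chrom, start, end, region_id, cpgs = parts[:5]
            if region_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate region id {region_id!r}")
            seen.add(region_id)
            try:
                positions = tuple(int(p) for p in cpgs.split(",") if p != "")
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad CpG position list") from exc
            regions.append(
                RegionOfInterest(region_id, chrom, int(start), int(end), positions)
            )
    if not regions:
        logger.warning("%s: no regions parsed", path)
    return regions


def write_regions(regions: Iterable[RegionOfInterest], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            cpgs = ",".join(str(p) for p in r.cpg_positions)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{cpgs}\n")


def regions_by_id(regions: Iterable[RegionOfInterest]) -> dict[str, RegionOfInterest]:
    return {r.region_id: r for r in regions}


# ---------------------------------------------------------------------------
# Per-read methylation call records
# ---------------------------------------------------------------------------


@dataclass
class ReadMethylationRecord:
    """One molecule's ordered CpG calls plus conversion-QC counters.

    ``cpg_calls`` is an int8 array over {1 methylated, 0 unmethylated,
    -1 missing}, one entry per region CpG, region order.
    """

    read_id: str
    region_id: str
    cpg_calls: np.ndarray
    n_noncpg_meth: int
    n_noncpg_total: int
    mean_quality: float

    def __post_init__(self) -> None:
        self.cpg_calls = np.asarray(self.cpg_calls, dtype=np.int8)
        if self.n_noncpg_meth < 0 or self.n_noncpg_total < 0:
            raise FormatError(f"read {self.read_id}: negative non-CpG counts")
        if self.n_noncpg_meth > self.n_noncpg_total:
            raise FormatError(
                f"read {self.read_id}: n_noncpg_meth {self.n_noncpg_meth} > "
                f"n_noncpg_total {self.n_noncpg_total}"
            )

    @property
    def call_string(self) -> str:
        return "".join(_CALL_TO_CHAR[int(c)] for c in self.cpg_calls)

    @property
    def n_methylated(self) -> int:
        return int(np.sum(self.cpg_calls == CALL_METH))

    @property
    def n_covered(self) -> int:
        return int(np.sum(self.cpg_calls != CALL_MISSING))


def calls_from_string(s: str) -> np.ndarray:
    try:
        return np.array([_CHAR_TO_CALL[ch] for ch in s], dtype=np.int8)
    except KeyError as exc:
        raise FormatError(f"bad call character {exc.args[0]!r} in {s!r}") from exc


def read_read_calls(
    path: str | Path, regions: Mapping[str, RegionOfInterest] | Sequence[RegionOfInterest]
) -> list[ReadMethylationRecord]:
    """Parse the 6-column per-read TSV: read_id, region_id, call string over
    {M,U,.}, n_noncpg_meth, n_noncpg_total, mean_quality.

    Records are validated against the region set: the call string must be
    exactly as long as the region's CpG list and the region id must be known.
    """
    if not isinstance(regions, Mapping):
        regions = regions_by_id(regions)
    records: list[ReadMethylationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            read_id, region_id, calls, nm, nt, mq = parts
            region = regions.get(region_id)
            if region is None:
                raise FormatError(f"{path}:{lineno}: unknown region id {region_id!r}")
            arr = calls_from_string(calls)
            if arr.size != region.n_cpg:
                raise FormatError(
                    f"{path}:{lineno}: call string length {arr.size} != "
                    f"{region.n_cpg} CpGs of region {region_id!r}"
                )
            records.append(
                ReadMethylationRecord(read_id, region_id, arr, int(nm), int(nt), float(mq))
            )
    return records


def write_read_calls(
    records: Iterable[ReadMethylationRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.read_id}\t{r.region_id}\t{r.call_string}\t"
                f"{r.n_noncpg_meth}\t{r.n_noncpg_total}\t{r.mean_quality:g}\n"
            )


def reads_by_region(
    records: Iterable[ReadMethylationRecord],
) -> dict[str, list[ReadMethylationRecord]]:
    out: dict[str, list[ReadMethylationRecord]] = {}
    for r in records:
        out.setdefault(r.region_id, []).append(r)
    return out


def convert_bismark_extractor_output(*args, **kwargs):  # pragma: no cover
    """Converter stub: producing the 6-column per-read TSV from a
    Bismark-style methylation-extractor report.

    Expected upstream processing: run the extractor per read pair with
    overlap removal, group CpG (``z``/``Z``) calls by read and target region
    in region CpG order (``.`` for CpGs the read does not cover), count
    CHH/CHG calls (``h``/``H``/``x``/``X``) into ``n_noncpg_meth`` /
    ``n_noncpg_total``, and take the read's mean base quality from the
    alignment. This conversion shells out to external tools and is not part
    of the tested core; this package starts at the per-read call table.
    """
    raise NotImplementedError(
        "run the upstream extractor and supply the 6-column per-read TSV; "
        "see this function's docstring for the expected mapping"
    )


def stack_calls(records: Sequence[ReadMethylationRecord]) -> np.ndarray:
    """Stack the call arrays of same-region records into an (n_reads, n_cpg)
    int8 matrix for vectorised downstream work."""
    if not records:
        return np.empty((0, 0), dtype=np.int8)
    return np.stack([r.cpg_calls for r in records])
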