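"""Synthetic discovery and sequencing data with the structure the panel
workflow assumes.

Two generators:

* :func:`simulate_beta_matrix` emulates an array-based discovery cohort — a
  blood reference group whose beta values sit at the extremes of the scale
  with tiny variance at *planted* marker probes, tumor groups shifted away
  from the reference at those probes, matched normal-tissue groups that track
  the reference, and mid-scale decoy probes that no selection filter should
  retain.

* :func:`simulate_reads` / :func:`simulate_plasma_cohort` emulate targeted
  bisulfite sequencing of plasma cfDNA: each molecule is tumor-derived with
  probability ``tumor_fraction`` (the ctDNA dilution), CpG calls are Bernoulli
  draws at the origin-specific methylation rate, and incomplete bisulfite
  conversion shows up as methylated non-CpG cytosines at rate
  ``conversion_error``.

Beta noise is drawn from a Beta distribution re-parameterised by (mean, SD),
which respects the bounded [0, 1] scale. Every generator is a pure function
of its config, including the seed; per-sample and per-region streams are
derived from the master seed with ``numpy.random.SeedSequence`` spawning so
cohorts are reproducible sample-by-sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import (
    CALL_MISSING,
    REFERENCE_GROUP,
    BetaMatrix,
    ReadMethylationRecord,
    RegionOfInterest,
)


class ConfigError(ValueError):
    """A simulation config violated its invariants."""


# ---------------------------------------------------------------------------
# Beta matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedProbe:
    """A probe with a planted tumor-vs-reference deviation.

    ``classes`` are the tumor types whose tumor samples shift; everyone else
    (reference, normals, negative tumor types) stays at ``ref_level``.
    """

    probe_index: int
    classes: tuple[str, ...]
    shift: float
    ref_level: float = 0.02

    def tumor_level(self) -> float:
        return self.ref_level + self.shift


@dataclass(frozen=True)
class BetaSimConfig:
    """Configuration of the synthetic discovery cohort.

    Defaults are the study conditions used throughout the test-suite:
    5 tumor classes, 500 probes, reference SD 0.01 at planted probes,
    a +0.5 tumor shift, and mid-scale decoys with SD 0.1.
    """

    n_classes: int = 5
    n_ref: int = 30
    n_tumor_per_class: int = 20
    n_normal_per_class: int = 20
    n_probes: int = 500
    planted_tn: tuple[PlantedProbe, ...] = ()
    planted_class: tuple[PlantedProbe, ...] = ()
    ref_extreme_sd: float = 0.01
    decoy_sd: float = 0.1
    decoy_mean: float = 0.5
    seed: int = 0

    def class_labels(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_classes)]

    def all_planted(self) -> tuple[PlantedProbe, ...]:
        return tuple(self.planted_tn) + tuple(self.planted_class)

    def validate(self) -> None:
        if min(self.n_classes, self.n_ref, self.n_tumor_per_class,
               self.n_normal_per_class, self.n_probes) < 0:
            raise ConfigError("counts must be >= 0")
        labels = set(self.class_labels())
        seen: set[int] = set()
        for p in self.all_planted():
            if not (0 <= p.probe_index < self.n_probes):
                raise ConfigError(f"planted probe index {p.probe_index} out of range")
            if p.probe_index in seen:
                raise ConfigError(f"probe index {p.probe_index} planted twice")
            seen.add(p.probe_index)
            if not set(p.classes) <= labels:
                raise ConfigError(f"planted classes {p.classes} not in {sorted(labels)}")
            if not (0.0 <= p.ref_level <= 1.0):
                raise ConfigError(f"ref_level {p.ref_level} outside [0, 1]")
            if not (0.0 <= p.tumor_level() <= 1.0):
                raise ConfigError(
                    f"shift {p.shift} pushes tumor median {p.tumor_level()} outside [0, 1]"
                )


def default_beta_config(
    n_classes: int = 5,
    n_probes: int = 500,
    tn_probes_per_class: int = 2,
    class_probes_per_class: int = 2,
    shift: float = 0.5,
    seed: int = 0,
    **kwargs,
) -> BetaSimConfig:
    """Standard planted layout: per class, ``tn_probes_per_class`` detection
    probes (half low-reference, half high-reference) and
    ``class_probes_per_class`` class-specific probes, all with the same
    |shift| away from the reference extreme."""
    labels = [f"C{i + 1}" for i in range(n_classes)]
    planted_tn: list[PlantedProbe] = []
    planted_class: list[PlantedProbe] = []
    idx = 0
    for ci, lab in enumerate(labels):
        for j in range(tn_probes_per_class):
            low = (idx % 2) == 0
            planted_tn.append(
                PlantedProbe(idx, (lab,), shift if low else -shift,
                             ref_level=0.02 if low else 0.98)
            )
            idx += 1
        for j in range(class_probes_per_class):
            low = (idx % 2) == 0
            planted_class.append(
                PlantedProbe(idx, (lab,), shift if low else -shift,
                             ref_level=0.02 if low else 0.98)
            )
            idx += 1
    if idx > n_probes:
        raise ConfigError("n_probes too small for the planted layout")
    return BetaSimConfig(
        n_classes=n_classes,
        n_probes=n_probes,
        planted_tn=tuple(planted_tn),
        planted_class=tuple(planted_class),
        seed=seed,
        **kwargs,
    )


def _beta_draw(rng: np.random.Generator, mean: float, sd: float, size) -> np.ndarray:
    """Beta-distribution draws with the requested mean and SD, clipped into
    the open unit interval. Falls back to clipped Gaussian draws when the
    (mean, SD) pair is outside the Beta-feasible range."""
    m = float(np.clip(mean, 1e-4, 1 - 1e-4))
    if sd <= 0:
        return np.full(size, m)
    var = sd * sd
    limit = m * (1 - m)
    if var >= limit:  # no Beta distribution has this much spread at this mean
        return np.clip(rng.normal(m, sd, size), 0.0, 1.0)
    nu = limit / var - 1.0
    return rng.beta(m * nu, (1 - m) * nu, size)


def simulate_beta_matrix(
    cfg: BetaSimConfig,
) -> tuple[BetaMatrix, pd.DataFrame, dict[str, dict]]:
    """Generate (BetaMatrix, sample annotation, truth map).

    The truth map records, per planted probe id, its reference level, shift
    and positive classes, plus the decoy probe ids, so selection tests can
    score recovery exactly.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    labels = cfg.class_labels()

    sample_ids: list[str] = [f"ref{i + 1}" for i in range(cfg.n_ref)]
    groups: list[str] = [REFERENCE_GROUP] * cfg.n_ref
    for lab in labels:
        sample_ids += [f"{lab}.T{i + 1}" for i in range(cfg.n_tumor_per_class)]
        groups += [f"{lab}.T"] * cfg.n_tumor_per_class
        sample_ids += [f"{lab}.N{i + 1}" for i in range(cfg.n_normal_per_class)]
        groups += [f"{lab}.N"] * cfg.n_normal_per_class

    n_samples = len(sample_ids)
    probe_ids = [f"cg{i:06d}" for i in range(cfg.n_probes)]
    values = np.empty((cfg.n_probes, n_samples))

    group_arr = np.array(groups)
    planted = {p.probe_index: p for p in cfg.all_planted()}
    for j in range(cfg.n_probes):
        p = planted.get(j)
        if p is None:
            values[j] = _beta_draw(rng, cfg.decoy_mean, cfg.decoy_sd, n_samples)
            continue
        row = _beta_draw(rng, p.ref_level, cfg.ref_extreme_sd, n_samples)
        for lab in p.classes:
            mask = group_arr == f"{lab}.T"
            row[mask] = _beta_draw(rng, p.tumor_level(), cfg.ref_extreme_sd,
                                   int(mask.sum()))
        values[j] = row

    matrix = BetaMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))
    ann = pd.DataFrame({"group": groups}, index=pd.Index(sample_ids, name="sample_id"))
    truth = {
        "planted_tn": {
            probe_ids[p.probe_index]: {
                "classes": list(p.classes), "shift": p.shift, "ref_level": p.ref_level
            }
            for p in cfg.planted_tn
        },
        "planted_class": {
            probe_ids[p.probe_index]: {
                "classes": list(p.classes), "shift": p.shift, "ref_level": p.ref_level
            }
            for p in cfg.planted_class
        },
        "decoys": [probe_ids[j] for j in range(cfg.n_probes) if j not in planted],
    }
    return matrix, ann, truth


# ---------------------------------------------------------------------------
# Per-read sequencing data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadSimConfig:
    """Configuration of the per-read simulator for one sample.

    ``background_meth``/``tumor_meth`` are per-CpG methylation probabilities
    for molecules of background (healthy cfDNA) vs tumor origin at
    low-reference loci; ``conversion_error`` is the probability that a
    non-CpG cytosine escapes conversion and is reported methylated.
    """

    regions: tuple[RegionOfInterest, ...]
    depth: int = 2000
    tumor_fraction: float = 0.0
    background_meth: float = 0.01
    tumor_meth: float = 0.85
    conversion_error: float = 0.005
    n_noncpg_per_read: int = 20
    missing_rate: float = 0.0
    haplotype_mode: bool = False
    quality_mean: float = 36.0
    quality_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("tumor_fraction", "background_meth", "tumor_meth",
                     "conversion_error", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        if self.depth < 0 or self.n_noncpg_per_read < 0:
            raise ConfigError("depth and n_noncpg_per_read must be >= 0")
        if not self.regions:
            raise ConfigError("at least one region required")


def simulate_reads(cfg: ReadSimConfig) -> list[ReadMethylationRecord]:
    """Simulate ``depth`` molecules per region.

    Each molecule is tumor-origin with probability ``tumor_fraction``; its
    CpG calls are independent Bernoulli draws at the origin's methylation
    rate (or, in haplotype mode, tumor molecules take one shared draw per
    molecule, emulating fully concordant methylation haplotypes).
    """
    cfg.validate()
    master = np.random.SeedSequence(cfg.seed)
    records: list[ReadMethylationRecord] = []
    for region, ss in zip(cfg.regions, master.spawn(len(cfg.regions))):
        rng = np.random.default_rng(ss)
        n, k = cfg.depth, region.n_cpg
        if n == 0:
            continue
        is_tumor = rng.random(n) < cfg.tumor_fraction
        if cfg.haplotype_mode:
            hap = rng.random(n) < cfg.tumor_meth  # one draw per tumor molecule
            calls = (rng.random((n, k)) < cfg.background_meth)
            calls[is_tumor] = hap[is_tumor, None]
        else:
            p = np.where(is_tumor, cfg.tumor_meth, cfg.background_meth)
            calls = rng.random((n, k)) < p[:, None]
        calls = calls.astype(np.int8)
        if cfg.missing_rate > 0:
            calls[rng.random((n, k)) < cfg.missing_rate] = CALL_MISSING
        nm = rng.binomial(cfg.n_noncpg_per_read, cfg.conversion_error, n)
        mq = np.clip(rng.normal(cfg.quality_mean, cfg.quality_sd, n), 2.0, 42.0)
        for i in range(n):
            records.append(
                ReadMethylationRecord(
                    read_id=f"{region.region_id}:r{i + 1}",
                    region_id=region.region_id,
                    cpg_calls=calls[i],
                    n_noncpg_meth=int(nm[i]),
                    n_noncpg_total=cfg.n_noncpg_per_read,
                    mean_quality=float(mq[i]),
                )
            )
    return records


def toy_panel_regions(
    n_regions: int = 8, n_cpg: int = 4, spacing: int = 1000, flank: int = 200
) -> tuple[RegionOfInterest, ...]:
    """Evenly spaced toy regions on one contig, each a panel-CpG ±``flank``
    window containing ``n_cpg`` CpGs."""
    regions = []
    for i in range(n_regions):
        centre = (i + 1) * (2 * flank + spacing)
        start, end = centre - flank, centre + flank + 1
        cpgs = tuple(centre - 2 * j for j in range(n_cpg))[::-1]
        regions.append(
            RegionOfInterest(f"reg{i + 1:02d}", "chrS", start, end, cpgs)
        )
    return tuple(regions)


def simulate_plasma_cohort(
    case_cfg: ReadSimConfig,
    control_cfg: ReadSimConfig,
    n_cases: int,
    n_controls: int,
    seed: int = 0,
) -> tuple[dict[str, list[ReadMethylationRecord]], pd.Series]:
    """Simulate a labelled plasma cohort: per-sample read tables plus a
    label Series ('tumor'/'normal' indexed by sample id).

    Controls must have ``tumor_fraction == 0``. Per-sample seeds derive
    deterministically from the cohort seed.
    """
    if control_cfg.tumor_fraction > 0:
        raise ConfigError("control_cfg.tumor_fraction must be 0")
    if n_cases < 0 or n_controls < 0:
        raise ConfigError("cohort sizes must be >= 0")
    master = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   master.spawn(n_cases + n_controls)]
    reads: dict[str, list[ReadMethylationRecord]] = {}
    labels: dict[str, str] = {}
    for i in range(n_cases):
        sid = f"case{i + 1:03d}"
        reads[sid] = simulate_reads(replace(case_cfg, seed=child_seeds[i]))
        labels[sid] = "tumor"
    for i in range(n_controls):
        sid = f"ctrl{i + 1:03d}"
        reads[sid] = simulate_reads(replace(control_cfg, seed=child_seeds[n_cases + i]))
        labels[sid] = "normal"
    return reads, pd.Series(labels, name="label")
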