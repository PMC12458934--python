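"""End-to-end pipeline orchestration from a single JSON/YAML-style config.

A config is a dict with a ``seed``, an ``out_dir`` and a ``stages`` list;
each stage is a dict with a ``stage`` name plus stage-specific parameters.
Stages run in order, write text artifacts into ``out_dir``, and every
artifact is recorded in a manifest with its SHA-256, so a rerun with an
identical config reproduces identical manifest hashes.

Supported stages: ``simulate_beta``, ``select_detection``,
``select_classification``, ``sign``, ``classify``, ``simulate_cohort``,
``features``, ``plasma_call``, ``evaluate``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, evaluate, features, io, plasma, select, simulate

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _selection_params(block: dict) -> select.SelectionParams:
    keys = {f for f in select.SelectionParams.__dataclass_fields__}
    return select.SelectionParams(**{k: v for k, v in block.items() if k in keys})


def run_pipeline(cfg: dict) -> dict:
    """Execute the configured stages; return the manifest dict (also written
    to ``out_dir/manifest.json``)."""
    out_dir = Path(cfg.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", [])
    if not stages:
        raise PipelineError("config has no stages")

    # early validation: every referenced input file must exist
    for block in stages:
        for key, val in block.items():
            if key.endswith("_path") and key.startswith("in_"):
                if not Path(val).exists():
                    raise PipelineError(f"stage {block.get('stage')}: missing input {val}")

    artifacts: dict[str, str] = {}
    state: dict = {}

    def save(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        artifacts[name] = _sha256(path)
        return path

    for block in stages:
        stage = block.get("stage")
        logger.info("running stage %s", stage)
        if stage == "simulate_beta":
            cfg_b = simulate.default_beta_config(
                seed=block.get("seed", seed),
                **{k: v for k, v in block.items() if k in (
                    "n_classes", "n_probes", "tn_probes_per_class",
                    "class_probes_per_class", "shift")},
            )
            m, ann, truth = simulate.simulate_beta_matrix(cfg_b)
            state.update(matrix=m, ann=ann, truth=truth)
            save("beta.tsv", lambda p: io.write_beta_matrix(m, p))
            save("annotation.tsv", lambda p: io.write_annotation(ann, p))
            save("truth.json", lambda p: p.write_text(json.dumps(truth, indent=2)))
        elif stage in ("select_detection", "select_classification"):
            params = _selection_params(block)
            m, ann = state["matrix"], state["ann"]
            if stage == "select_detection":
                cands = select.select_tn_candidates(m, ann, params)
                panel = select.assemble_detection_panel(
                    cands, io.tumor_types(ann), params)
                name = "panel_detection.json"
                state["detection_panel"] = panel
            else:
                cands = select.select_classification_candidates(m, ann, params)
                panel = select.entropy_panel_search(
                    m, ann, cands, target_size=block.get("target_size"),
                    seed=block.get("seed", seed), p=params)
                name = "panel_classification.json"
                state["classification_panel"] = panel
            save(name, lambda p: select.panel_to_json(panel, p))
        elif stage == "sign":
            panel = state["classification_panel"]
            sigs = classify.build_class_signatures(
                state["matrix"], state["ann"], panel)
            state["signatures"] = sigs
            save("signatures.json",
                 lambda p: classify.signatures_to_json(sigs, p, panel.params_hash))
        elif stage == "classify":
            panel = state["classification_panel"]
            report = classify.evaluate_panel(
                state["matrix"], state["ann"], panel,
                delta=block.get("delta", 0.5), seed=block.get("seed", seed))
            doc = {
                "accuracy_best": report.accuracy_best,
                "accuracy_rank2": report.accuracy_rank2,
                "accuracy_within_range": report.accuracy_within_range,
                "mean_rank_true": report.mean_rank_true,
                "mean_within_range_size": report.mean_within_range_size,
                "n_samples": report.n_samples,
                "confusion_pct": report.confusion.round(3).to_dict(),
            }
            save("classification_report.json",
                 lambda p: p.write_text(json.dumps(doc, indent=2)))
        elif stage == "simulate_cohort":
            regions = simulate.toy_panel_regions(
                n_regions=block.get("n_regions", 8),
                n_cpg=block.get("n_cpg", 4))
            case_cfg = simulate.ReadSimConfig(
                regions=regions, depth=block.get("depth", 2000),
                tumor_fraction=block.get("tumor_fraction", 0.3))
            control_cfg = simulate.ReadSimConfig(
                regions=regions, depth=block.get("depth", 2000),
                tumor_fraction=0.0)
            reads, labels = simulate.simulate_plasma_cohort(
                case_cfg, control_cfg, block.get("n_cases", 30),
                block.get("n_controls", 30), seed=block.get("seed", seed))
            state.update(regions=regions, cohort_reads=reads, cohort_labels=labels)
            save("regions.bed", lambda p: io.write_regions(regions, p))
            save("cohort_labels.tsv",
                 lambda p: labels.to_frame().to_csv(p, sep="\t"))
        elif stage == "features":
            feats, qc = features.cohort_feature_table(
                state["cohort_reads"], state["regions"],
                convention=block.get("convention", "or_higher"))
            state["features"] = feats
            save("features.tsv", lambda p: feats.to_csv(p, sep="\t"))
            save("qc.tsv", lambda p: qc.to_csv(p, sep="\t"))
        elif stage == "plasma_call":
            xs = plasma.cohort_signal_fractions(
                state["cohort_reads"], state["regions"])
            labels = state["cohort_labels"]
            controls = xs.loc[labels[labels == "normal"].index]
            caller = plasma.MaxControlPlasmaCaller().fit(controls)
            calls = pd.Series(caller.predict(xs), index=xs.index, name="call")
            out = xs.copy()
            out["call"] = calls
            save("plasma_calls.tsv", lambda p: out.to_csv(p, sep="\t"))
        elif stage == "evaluate":
            ds = evaluate.CohortDataset.from_table(
                state["features"], state["cohort_labels"])
            preds, report = evaluate.loo_evaluate(
                ds, metric=block.get("metric", "custom"),
                resample=block.get("resample"),
                seed=block.get("seed", seed),
                task=block.get("task", "binary"))
            save("predictions.tsv", lambda p: preds.to_csv(p, sep="\t"))
            save("eval_report.json",
                 lambda p: p.write_text(json.dumps(report.to_dict(), indent=2)))
        else:
            raise PipelineError(f"unknown stage {stage!r}")

    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16],
        "artifacts": artifacts,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
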