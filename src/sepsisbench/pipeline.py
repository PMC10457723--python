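"""Config-driven pipeline: simulate -> phenotype -> score -> timeliness ->
evaluate, with a run manifest.

Every stage writes CSV outputs under the run directory; the manifest
records the config snapshot, seed, and SHA-256 digest of every input and
output file, so a re-run with the same seed can be checked for bitwise
reproducibility (timestamps are recorded but excluded from that contract).
A stage failure aborts with the stage name; outputs of earlier stages are
left in place.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import pandas as pd

from . import evaluation, phenotyping, scoring, timeliness
from .cohort import Cohort, read_cohort, write_cohort
from .config import PipelineConfig, config_to_yaml
from .errors import SepsisBenchError
from .synth import generate_cohort

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class StageError(SepsisBenchError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: str) -> str:
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")
    return path


def run_pipeline(config: PipelineConfig, out_dir: str,
                 seed: int | None = None,
                 cohort: Cohort | None = None) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    ``seed`` overrides ``config.cohort.seed``; ``cohort`` skips simulation
    and analyses the given cohort instead.
    """
    config.validate()
    if seed is not None:
        config = dataclasses.replace(
            config, cohort=dataclasses.replace(config.cohort, seed=int(seed)))
    os.makedirs(out_dir, exist_ok=True)
    outputs: dict[str, str] = {}
    started = time.time()

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    def _simulate() -> Cohort:
        c = cohort if cohort is not None else generate_cohort(config.cohort)
        outputs.update(write_cohort(c, os.path.join(out_dir, "cohort")))
        return c

    full = stage("simulate", _simulate)

    def _phenotype():
        clean_obs, dropped = scoring.clean_observations(full.observations)
        cleaned = Cohort(full.admissions, clean_obs, full.orders,
                         full.dx_codes, full.truth)
        provisional = phenotyping.phenotype_cohort(cleaned, config.phenotype)
        retained, report = phenotyping.apply_exclusions(
            cleaned, config.phenotype, labels=provisional)
        keep = set(retained.admission_ids())
        labels = provisional[provisional["admission_id"].isin(keep)]
        labels = labels.reset_index(drop=True)
        outputs["labels"] = _write_csv(labels, os.path.join(out_dir, "labels.csv"))
        outputs["exclusions"] = _write_csv(
            report.to_frame(), os.path.join(out_dir, "exclusions.csv"))
        if len(dropped):
            outputs["dropped_observations"] = _write_csv(
                dropped, os.path.join(out_dir, "dropped_observations.csv"))
        return retained, labels, report

    retained, labels, report = stage("phenotype", _phenotype)

    def _score():
        streams = scoring.score_cohort(retained, config=config.scoring)
        outputs["scores"] = _write_csv(
            scoring.streams_to_frame(streams),
            os.path.join(out_dir, "scores.csv"))
        return streams

    streams = stage("score", _score)

    def _timeliness():
        thresholds = dict(timeliness.DEFAULT_THRESHOLDS)
        thresholds["PSS"] = (float(config.pss_threshold), "absolute")
        crossings, summary, curve = timeliness.timeliness_cohort(
            retained, labels, streams, thresholds)
        outputs["crossings"] = _write_csv(
            crossings, os.path.join(out_dir, "crossings.csv"))
        outputs["timeliness_summary"] = _write_csv(
            summary, os.path.join(out_dir, "timeliness_summary.csv"))
        outputs["fig2_data"] = _write_csv(
            curve, os.path.join(out_dir, "fig2_data.csv"))
        return crossings, summary, curve

    crossings, summary, curve = stage("timeliness", _timeliness)

    def _evaluate():
        table2 = evaluation.classification_table(labels, streams)
        outputs["table2"] = _write_csv(table2, os.path.join(out_dir, "table2.csv"))
        outputs["mcnemar"] = _write_csv(
            evaluation.mcnemar_table(labels, streams),
            os.path.join(out_dir, "mcnemar.csv"))
        outputs["table1"] = _write_csv(
            evaluation.cohort_table(retained.admissions, labels),
            os.path.join(out_dir, "table1.csv"))
        return table2

    table2 = stage("evaluate", _evaluate)
    del crossings, summary, curve, table2, report

    manifest = {
        "tool": "sepsisbench",
        "version": __version__,
        "seed": config.cohort.seed,
        "config_yaml": config_to_yaml(config),
        "stages": ["simulate", "phenotype", "score", "timeliness", "evaluate"],
        "outputs": {name: {"path": os.path.relpath(path, out_dir),
                           "sha256": _sha256(path)}
                    for name, path in sorted(outputs.items())},
        "started_unix": started,
        "finished_unix": time.time(),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_run(out_dir: str) -> dict[str, pd.DataFrame]:
    """Read back the per-stage CSV outputs of a finished run."""
    out: dict[str, pd.DataFrame] = {}
    for name in ("labels", "exclusions", "scores", "crossings",
                 "timeliness_summary", "fig2_data", "table2", "mcnemar",
                 "table1"):
        path = os.path.join(out_dir, f"{name}.csv")
        if os.path.exists(path):
            out[name] = pd.read_csv(path)
    out["cohort"] = read_cohort(os.path.join(out_dir, "cohort"))  # type: ignore
    return out
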