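"""End-to-end orchestration: epochs -> wear -> trips -> leisure -> outcomes
-> validity -> environment scores -> association models, with a run
manifest recording per-stage attrition."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assoc import fit_association_models
from .config import StudyConfig
from .envscores import internal_consistency, score_questionnaire
from .io import read_diary, read_epochs, read_questionnaire, write_table
from .leisure import compute_outcomes, diary_outcomes, filter_leisure_trips
from .preprocess import flag_valid_days, include_participants
from .trips import detect_trips, trips_to_frame
from .validity import compare_table

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Provenance + attrition accounting of one pipeline run."""

    config_hash: str
    inputs: dict
    seed: int | None
    version: str = __version__
    stage_counts: dict = field(default_factory=dict)

    def record(self, stage: str, n: int) -> None:
        self.stage_counts[stage] = int(n)

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "version": self.version, "seed": self.seed, "config_hash": self.config_hash,
            "inputs": self.inputs, "stage_counts": self.stage_counts,
        }, sort_keys=False))


@dataclass
class PipelineResult:
    weardays: pd.DataFrame
    inclusion: pd.DataFrame
    trips: pd.DataFrame
    leisure_trips: pd.DataFrame
    gps_outcomes: pd.DataFrame
    diary_outcomes: pd.DataFrame
    comparison: pd.DataFrame
    env_scores: pd.DataFrame
    models: pd.DataFrame
    manifest: RunManifest


def run_from_frames(epochs, diary, questionnaire, config: StudyConfig,
                    nagq: int = 25, fit_models: bool = True,
                    manifest: RunManifest | None = None) -> PipelineResult:
    """Run the full analysis chain on in-memory tables."""
    manifest = manifest or RunManifest(config_hash="", inputs={}, seed=None)
    manifest.record("epochs", len(epochs))
    manifest.record("participants_in", epochs["participant_id"].nunique())

    weardays = flag_valid_days(epochs, config)
    inclusion = include_participants(weardays, config)
    manifest.record("valid_days", int(weardays["is_valid"].sum()))
    manifest.record("participants_included", int(inclusion["included"].sum()))
    manifest.record("participants_excluded", int((~inclusion["included"]).sum()))

    trips = detect_trips(epochs, config)
    manifest.record("trips_detected", len(trips))
    leisure = filter_leisure_trips(trips, weardays, config)
    manifest.record("leisure_trips", len(leisure))

    gps_out = compute_outcomes(leisure, weardays, inclusion)
    diary_out = diary_outcomes(diary, weardays, inclusion)
    comparison = compare_table(gps_out, diary_out)

    scores = score_questionnaire(questionnaire) if questionnaire is not None else pd.DataFrame()
    models = pd.DataFrame()
    if fit_models and not scores.empty:
        models = fit_association_models(gps_out, scores, weardays, nagq=nagq)

    return PipelineResult(weardays, inclusion, trips_to_frame(trips),
                          trips_to_frame(leisure), gps_out, diary_out, comparison,
                          scores, models, manifest)


def run_pipeline(config_path, out_dir=None, nagq: int = 25,
                 fit_models: bool = True) -> Path:
    """Run the pipeline from a YAML run-configuration file.

    The run config names the input files and the study configuration::

        inputs:
          gps: gps.csv            # or .gpx
          accel: accel.csv
          diary: diary.csv
          questionnaire: questionnaire.csv
        study_config: study_config.yaml
        out_dir: out/
        seed: 1
    """
    config_path = Path(config_path)
    text = config_path.read_text()
    run_cfg = yaml.safe_load(text)
    base = config_path.parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    inputs = run_cfg["inputs"]
    for key in ("gps", "accel", "diary"):
        if key not in inputs or not resolve(inputs[key]).exists():
            raise FileNotFoundError(f"missing input: {key} ({inputs.get(key)})")
    config = StudyConfig.load(resolve(run_cfg["study_config"]))
    out = Path(out_dir or resolve(run_cfg.get("out_dir", "out")))
    out.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        config_hash=hashlib.sha256(text.encode()).hexdigest()[:16],
        inputs={k: str(v) for k, v in inputs.items()},
        seed=run_cfg.get("seed"),
    )
    epochs = read_epochs(resolve(inputs["gps"]), resolve(inputs["accel"]), config)
    diary = read_diary(resolve(inputs["diary"]))
    questionnaire = (read_questionnaire(resolve(inputs["questionnaire"]))
                     if "questionnaire" in inputs else None)

    result = run_from_frames(epochs, diary, questionnaire, config,
                             nagq=nagq, fit_models=fit_models, manifest=manifest)

    write_table(result.weardays, out / "weardays.csv")
    write_table(result.inclusion, out / "inclusion.csv")
    write_table(result.trips, out / "trips.csv")
    write_table(result.leisure_trips, out / "leisure_trips.csv")
    write_table(result.gps_outcomes, out / "outcomes_gps.csv")
    write_table(result.diary_outcomes, out / "outcomes_diary.csv")
    write_table(result.comparison, out / "comparison.csv")
    if not result.env_scores.empty:
        write_table(result.env_scores, out / "env_scores.csv")
        alphas = internal_consistency(questionnaire)
        alphas.rename_axis("subscale").reset_index().to_csv(out / "internal_consistency.csv", index=False)
    if not result.models.empty:
        write_table(result.models, out / "models.csv")
    result.manifest.write(out / "run_manifest.yaml")
    return out
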