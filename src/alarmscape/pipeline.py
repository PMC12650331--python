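"""End-to-end pipeline: simulate -> alarms -> windows -> patterns -> train.

A single :class:`RunConfig` drives the whole run; every stage writes its
CSV/JSON outputs before the next starts and a :class:`RunManifest` with
checksums, derived stage seeds and wall-clock times is written on success.
Stage seeds are derived as ``master_seed + stage ordinal`` so a stage can be
re-run in isolation with the same randomness.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .alarms import builtin_cutoffs, detect_episodes, episodes_to_frame, summarize_alarms
from .classify import ModelSpec, compare_models
from .clustering import DBSCANParams, extract_pattern_features
from .cohort import DEFAULT_PATTERNS, CohortConfig, generate_cohort
from .io import (
    events_from_manifest,
    iter_series,
    read_manifest,
    write_cohort,
)
from .windows import window_cohort_alarms

STAGES = ("simulate", "alarms", "windows", "patterns", "train")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str = "run"
    organization: str = "WHO"  # "WHO" | "GOAL3" | "both"
    window_hours: float = 8.0
    n_segments: int = 4
    anchor_policy: str = "midpoint"
    dbscan: DBSCANParams = field(default_factory=DBSCANParams)
    cluster_space: str = "value-duration"
    models: tuple[str, ...] = ("random_forest", "svm", "decision_tree")
    balance: bool = True
    train_fraction: float = 0.7
    master_seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if self.organization not in ("WHO", "GOAL3", "both"):
            raise ValueError("organization must be WHO, GOAL3 or both")
        if self.window_hours <= 0 or self.n_segments < 1:
            raise ValueError("window_hours and n_segments must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        for fam in self.models:
            ModelSpec(family=fam)  # validates the family name
        # fail before any stage runs, not mid-pipeline
        builtin_cutoffs(self.organizations()[0])

    def organizations(self) -> list[str]:
        return ["WHO", "GOAL3"] if self.organization == "both" else [self.organization]

    def stage_seed(self, stage: str) -> int:
        return int(self.master_seed + STAGES.index(stage))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        dbscan = DBSCANParams(**raw.pop("dbscan", {}))
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(cohort=cohort, dbscan=dbscan, **raw)


@dataclass
class RunManifest:
    """Provenance record of one run."""

    config: dict
    version: str
    stage_seeds: dict[str, int]
    checksums: dict[str, str] = field(default_factory=dict)
    wall_clock_s: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order and write the run manifest.

    On stage failure a ``FAILED`` marker naming the stage is left in the
    output directory, partial outputs are retained, and
    :class:`StageFailure` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = config.cohort
    # the simulate stage owns the cohort seed: derive it from the master
    cohort_cfg = CohortConfig(**{**asdict(cohort_cfg), "seed": config.stage_seed("simulate")})
    manifest = RunManifest(
        config={**_plain(asdict(config)), "cohort": _plain(asdict(cohort_cfg))},
        version=__version__,
        stage_seeds={s: config.stage_seed(s) for s in STAGES},
    )
    current = "simulate"
    try:
        outputs: list[Path] = []

        t0 = time.perf_counter()
        cohort_dir = out / "cohort"
        patterns = (
            DEFAULT_PATTERNS[config.organizations()[0]]
            if config.organization != "both"
            else DEFAULT_PATTERNS["WHO"]
        )
        patients = generate_cohort(cohort_cfg, patterns)
        write_cohort(patients, cohort_dir)
        outputs.append(cohort_dir / "manifest.csv")
        manifest.wall_clock_s["simulate"] = time.perf_counter() - t0

        cohort_manifest = read_manifest(cohort_dir)
        events = events_from_manifest(cohort_manifest)
        ages = cohort_manifest.set_index("patient_id")["age_months"]

        for org in config.organizations():
            current = "alarms"
            t0 = time.perf_counter()
            table = builtin_cutoffs(org)
            episodes = []
            spans_rows = []
            for row, series in iter_series(cohort_dir, cohort_cfg.sample_interval):
                episodes.extend(
                    detect_episodes(series, float(ages[row["patient_id"]]), table)
                )
                spans_rows.append(
                    {
                        "patient_id": row["patient_id"],
                        "start": series.start,
                        "end": series.end,
                    }
                )
            alarms = episodes_to_frame(episodes)
            alarms_path = out / f"alarms_{org.lower()}.csv"
            alarms.to_csv(alarms_path, index=False)
            outputs.append(alarms_path)
            summary = summarize_alarms(alarms, cohort_manifest)[org]
            summary_path = out / f"alarm_summary_{org.lower()}.csv"
            summary.to_csv(summary_path)
            outputs.append(summary_path)
            manifest.wall_clock_s[f"alarms_{org}"] = time.perf_counter() - t0

            current = "windows"
            t0 = time.perf_counter()
            spans = pd.DataFrame(spans_rows)
            windowed = window_cohort_alarms(
                alarms,
                events,
                spans=spans,
                window_hours=config.window_hours,
                n_segments=config.n_segments,
                anchor_policy=config.anchor_policy,
            )
            windowed_path = out / f"windowed_{org.lower()}.csv"
            windowed.to_csv(windowed_path, index=False)
            outputs.append(windowed_path)
            manifest.wall_clock_s[f"windows_{org}"] = time.perf_counter() - t0

            current = "patterns"
            t0 = time.perf_counter()
            features = extract_pattern_features(
                windowed, config.dbscan, space=config.cluster_space
            )
            features_path = out / f"features_{org.lower()}.csv"
            features.to_csv(features_path, index=False)
            outputs.append(features_path)
            manifest.wall_clock_s[f"patterns_{org}"] = time.perf_counter() - t0

            current = "train"
            t0 = time.perf_counter()
            from .classify import assemble_dataset

            dataset = assemble_dataset(
                features,
                cohort_manifest,
                balance=config.balance,
                seed=config.stage_seed("train"),
            )
            specs = [ModelSpec(family=f) for f in config.models]
            comparison, reports = compare_models(
                specs,
                dataset,
                train_fraction=config.train_fraction,
                seed=config.stage_seed("train"),
            )
            comparison_path = out / f"model_comparison_{org.lower()}.csv"
            comparison.to_csv(comparison_path, index=False)
            outputs.append(comparison_path)
            reports_path = out / f"reports_{org.lower()}.json"
            reports_path.write_text(
                json.dumps(
                    {fam: r.to_dict() for fam, r in reports.items()},
                    indent=2,
                    sort_keys=True,
                )
            )
            outputs.append(reports_path)
            manifest.wall_clock_s[f"train_{org}"] = time.perf_counter() - t0

        for path in outputs:
            manifest.checksums[str(path.relative_to(out))] = _sha256(path)
        (out / "run_manifest.json").write_text(manifest.to_json())
        return manifest
    except Exception as exc:  # noqa: BLE001 - marker + re-raise with stage name
        (out / "FAILED").write_text(f"stage: {current}\nerror: {exc}\n")
        raise StageFailure(current, exc) from exc


def _plain(obj):
    """Make a config dict JSON-serializable (tuples/paths to lists/str)."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
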