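"""End-to-end orchestration: simulate -> metrics -> stats -> report.

Every stage is usable in memory (lists of recordings / DataFrames) or on
disk (trial CSVs + manifest), and every output directory gets a
run-metadata JSON recording the configuration hash and master seed so runs
are reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import imu_io
from .imu_io import ColumnMapping, Recording, RecordingMeta, read_manifest
from .kinematics import IntegrationConfig, compute_metrics
from .preprocess import PreprocessConfig
from .stats import BatteryConfig, run_battery, write_report
from .synthetic import CohortSpec, default_cohort_spec, make_cohort, TRUTH_COLUMNS

__all__ = [
    "PipelineConfig",
    "config_hash",
    "simulate_cohort",
    "metrics_from_recordings",
    "metrics_from_manifest",
    "stats_report",
    "run_all",
]

log = logging.getLogger("fessmotion")


@dataclass
class PipelineConfig:
    """One YAML file configures every stage.

    Sections mirror the module configs; ``cohort: default`` (or an absent
    section) uses the shipped set-point cohort.
    """

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    stats: BatteryConfig = field(default_factory=BatteryConfig)
    cohort: CohortSpec = field(default_factory=default_cohort_spec)
    mapping: ColumnMapping = field(default_factory=ColumnMapping.default)
    acc_units_in: str = "m_s2"
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path | None) -> "PipelineConfig":
        if path is None:
            return cls()
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "preprocess" in raw:
            kwargs["preprocess"] = PreprocessConfig(**raw["preprocess"])
        if "integration" in raw:
            kwargs["integration"] = IntegrationConfig(**raw["integration"])
        if "stats" in raw:
            sec = dict(raw["stats"])
            for key in ("metrics", "hands", "procedures", "groups"):
                if key in sec:
                    sec[key] = tuple(sec[key])
            kwargs["stats"] = BatteryConfig(**sec)
        cohort = raw.get("cohort", "default")
        if isinstance(cohort, str):
            kwargs["cohort"] = (default_cohort_spec() if cohort == "default"
                                else CohortSpec.from_yaml(cohort))
        elif cohort is not None:
            kwargs["cohort"] = CohortSpec.from_dict(cohort)
        if "mapping" in raw:
            kwargs["mapping"] = ColumnMapping.from_dict(raw["mapping"])
        for key in ("acc_units_in", "master_seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_jsonable(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_run_meta(outdir: Path, cfg: PipelineConfig, seed: int, stage: str) -> None:
    meta = {"stage": stage, "seed": int(seed), "config_hash": config_hash(cfg)}
    (outdir / f"run_meta_{stage}.json").write_text(json.dumps(meta, indent=1))


def simulate_cohort(cfg: PipelineConfig, outdir: str | Path, seed: int | None = None
                    ) -> tuple[Path, pd.DataFrame]:
    """Generate the configured cohort and write trial CSVs, manifest and truth.

    Returns the manifest path and the manifest/truth DataFrame.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.master_seed if seed is None else int(seed)
    recordings, truths, manifest = make_cohort(cfg.cohort, seed)
    trials = outdir / "trials"
    for rec, row_path in zip(recordings, manifest["path"]):
        imu_io.write_recording_csv(rec, trials / row_path)
    manifest = manifest.copy()
    manifest["path"] = ["trials/" + p for p in manifest["path"]]
    manifest_path = outdir / "manifest.csv"
    manifest[list(imu_io.MANIFEST_COLUMNS)].to_csv(manifest_path, index=False)
    manifest[list(TRUTH_COLUMNS)].to_csv(outdir / "truth.csv", index=False)
    _write_run_meta(outdir, cfg, seed, "simulate")
    log.info("wrote %d trials to %s", len(recordings), trials)
    return manifest_path, manifest


def metrics_from_recordings(recordings: list[Recording],
                            cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """One tidy metrics row per recording (in-memory path)."""
    cfg = cfg or PipelineConfig()
    rows = []
    for rec in recordings:
        m = compute_metrics(rec, cfg.preprocess, cfg.integration)
        rows.append({
            "participant_id": rec.meta.participant_id, "group": rec.meta.group,
            "hand": rec.meta.hand, "procedure": rec.meta.procedure,
            **m.to_dict(),
        })
    return pd.DataFrame(rows)


def metrics_from_manifest(manifest_path: str | Path,
                          cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Metrics for every manifest row; per-file failures are logged, not fatal."""
    cfg = cfg or PipelineConfig()
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = read_manifest(manifest_path)
    rows, failures = [], 0
    for rec_row in manifest.itertuples(index=False):
        path = base / rec_row.path
        try:
            sidecar = path.with_name(path.name + ".meta.json")
            if sidecar.exists():
                meta = imu_io.read_sidecar_meta(sidecar)
            else:
                meta = RecordingMeta(
                    participant_id=str(rec_row.participant_id), group=rec_row.group,
                    hand=rec_row.hand, procedure=rec_row.procedure,
                    acc_units_in=cfg.acc_units_in)
            rec = imu_io.read_recording_csv(path, cfg.mapping, meta)
            m = compute_metrics(rec, cfg.preprocess, cfg.integration)
            rows.append({
                "participant_id": str(rec_row.participant_id), "group": rec_row.group,
                "hand": rec_row.hand, "procedure": rec_row.procedure,
                **m.to_dict(),
            })
        except Exception as exc:  # noqa: BLE001 - robustness over 240 files
            failures += 1
            log.warning("skipping %s: %s", path, exc)
    log.info("metrics: %d ok, %d failed", len(rows), failures)
    if not rows:
        raise RuntimeError("no readable recordings in manifest")
    return pd.DataFrame(rows)


def stats_report(metrics: pd.DataFrame, outdir: str | Path,
                 cfg: PipelineConfig | None = None) -> dict[str, Path]:
    """Run the statistical battery and write the report files."""
    cfg = cfg or PipelineConfig()
    tests, summaries = run_battery(metrics, cfg.stats)
    paths = write_report(tests, summaries, outdir)
    _write_run_meta(Path(outdir), cfg, cfg.master_seed, "stats")
    return paths


def run_all(cfg: PipelineConfig, outdir: str | Path, seed: int | None = None
            ) -> dict[str, Path]:
    """simulate -> metrics -> stats in one call, everything on disk."""
    outdir = Path(outdir)
    manifest_path, _ = simulate_cohort(cfg, outdir, seed)
    metrics = metrics_from_manifest(manifest_path, cfg)
    metrics_path = outdir / "metrics.csv"
    metrics.to_csv(metrics_path, index=False)
    paths = stats_report(metrics, outdir / "report", cfg)
    paths["manifest"] = manifest_path
    paths["metrics"] = metrics_path
    return paths
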