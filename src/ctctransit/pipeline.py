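"""End-to-end pipeline: generate -> simulate -> estimate -> report.

Every run writes its outputs into a fresh ``out_dir`` together with a
``manifest.json`` recording the tool version, a SHA-256 hash of the resolved
configuration, the seed, input/output paths, timestamps, and the run status.
No stage mutates its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .estimation import EstimateReport, build_report
from .synthetic import CohortConfig, default_config, generate_cohort

__all__ = ["RunManifest", "run_pipeline", "load_config", "configure_logging"]

logger = logging.getLogger("ctctransit")


def configure_logging(json_lines: bool = False, level: int = logging.INFO) -> None:
    """Structured logging to stderr; optionally JSON-lines."""
    handler = logging.StreamHandler(sys.stderr)
    if json_lines:
        class _JsonFormatter(logging.Formatter):
            def format(self, record: logging.LogRecord) -> str:
                return json.dumps(
                    {
                        "level": record.levelname,
                        "stage": getattr(record, "stage", "-"),
                        "message": record.getMessage(),
                    }
                )

        handler.setFormatter(_JsonFormatter())
    else:
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    seed: int
    inputs: dict
    outputs: dict
    started_utc: str
    finished_utc: str | None
    status: str
    failed_stage: str | None = None

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path


def _config_hash(config: CohortConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def load_config(config_path: str | Path) -> CohortConfig:
    """Load a cohort config JSON, filling unspecified fields from the shipped
    calibration defaults. Validation errors carry the offending field path."""
    raw = json.loads(Path(config_path).read_text())
    return default_config(**raw)


def run_pipeline(
    config_path: str | Path | None,
    out_dir: str | Path,
    *,
    config: CohortConfig | None = None,
) -> tuple[EstimateReport, RunManifest]:
    """Run generate -> simulate -> estimate and write all artifacts.

    Pass either a config file path or an in-memory ``CohortConfig``. On a
    stage failure the manifest is still written with ``status='failed'`` and
    the failing stage, then the exception propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    stage = "configure"
    try:
        if config is None:
            if config_path is None:
                raise ValueError("either config_path or config is required")
            config = load_config(config_path)
        chash = _config_hash(config)
        (out / "config.json").write_text(
            json.dumps(config.model_dump(mode="json"), indent=2) + "\n"
        )

        stage = "generate"
        logger.info("generating cohort: n=%d device=%s", config.n_clusters,
                    config.device_code, extra={"stage": stage})
        _, events, viability = generate_cohort(config, out_dir=out)

        stage = "estimate"
        logger.info("estimating from %d events", len(events), extra={"stage": stage})
        report = build_report(events, viability_cells=viability if not viability.empty else None)
        report.to_json(out / "report.json")
        (out / "report.md").write_text(report.to_markdown())

        manifest = RunManifest(
            tool_version=__version__,
            config_hash=chash,
            seed=config.seed,
            inputs={"config": str(config_path) if config_path else "<in-memory>"},
            outputs={
                "events": str(out / "events.csv"),
                "viability": str(out / "viability.csv"),
                "report_json": str(out / "report.json"),
                "report_md": str(out / "report.md"),
            },
            started_utc=started,
            finished_utc=datetime.now(timezone.utc).isoformat(),
            status="ok",
        )
        manifest.write(out)
        return report, manifest
    except Exception:
        manifest = RunManifest(
            tool_version=__version__,
            config_hash="",
            seed=getattr(config, "seed", -1) if config is not None else -1,
            inputs={"config": str(config_path) if config_path else "<in-memory>"},
            outputs={},
            started_utc=started,
            finished_utc=datetime.now(timezone.utc).isoformat(),
            status="failed",
            failed_stage=stage,
        )
        manifest.write(out)
        logger.exception("pipeline failed at stage %s", stage, extra={"stage": stage})
        raise
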