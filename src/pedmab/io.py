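"""File I/O: dataset CSVs with provenance sidecars, reports, run manifests.

CSV dialect: comma-separated, UTF-8, header row, ``.`` decimal; times in
days, concentrations in μg/mL (stated in the headers).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ValidationError

from .exceptions import ConfigError
from .synthetic import ObservedDataset, StudyDesign


def write_dataset_csv(dataset: ObservedDataset, directory) -> tuple[Path, Path]:
    """Write one dataset as CSV plus a JSON provenance sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{dataset.study_id}.csv"
    df = dataset.records.copy()
    df.insert(0, "study_id", dataset.study_id)
    df.to_csv(csv_path, index=False, float_format="%.10g")
    sidecar = directory / f"{dataset.study_id}.provenance.json"
    payload = {"design": dataset.design.model_dump(),
               "provenance": dataset.provenance}
    sidecar.write_text(json.dumps(payload, indent=2))
    return csv_path, sidecar


def read_dataset_csv(csv_path) -> ObservedDataset:
    """Load a dataset written by :func:`write_dataset_csv`."""
    csv_path = Path(csv_path)
    sidecar = csv_path.parent / f"{csv_path.stem}.provenance.json"
    if not sidecar.exists():
        raise ConfigError(f"missing provenance sidecar for {csv_path}")
    raw = json.loads(sidecar.read_text())
    design = StudyDesign(**raw["design"])
    df = pd.read_csv(csv_path)
    records = df[["arm", "time_days", "conc_ug_per_ml"]].copy()
    return ObservedDataset(study_id=design.study_id, design=design,
                           records=records, provenance=raw.get("provenance", {}))


def load_yaml_config(path, schema: type[BaseModel]):
    """Parse and validate a YAML config file against a pydantic schema.

    Raises :class:`ConfigError` with the offending field path on schema
    violations; nothing is written before validation completes.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    try:
        return schema(**raw)
    except ValidationError as exc:
        locs = "; ".join(".".join(str(p) for p in e["loc"]) + ": " + e["msg"]
                         for e in exc.errors())
        raise ConfigError(f"invalid config {path}: {locs}") from exc


@dataclass
class RunManifest:
    """Record of one CLI run; written last so its presence marks success."""

    command: str
    config_path: str | None
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    seed: int | None = None
    software_version: str = ""
    timestamp: str = ""

    def write(self, directory) -> Path:
        from . import __version__
        self.software_version = __version__
        self.timestamp = datetime.now(timezone.utc).isoformat()
        path = Path(directory) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2))
        return path


def report_markdown(report) -> str:
    """Human-readable Markdown rendering of a ValidationReport."""
    lines = [f"# Translation report: {report.drug_name}",
             "",
             f"Acceptance threshold: {report.threshold}-fold",
             "",
             "## Fitted drug-specific parameters",
             "",
             f"- sigma_v = {report.fitted['sigma_v']:.4f}",
             f"- sigma_l = {report.fitted['sigma_l']:.4f}",
             f"- kdeg = {report.fitted['kdeg']:.4g} 1/day",
             ""]
    for stage in report.stages:
        status = "skipped" if not stage.executed else ("PASS" if stage.passed else "FAIL")
        lines += [f"## Stage: {stage.name} [{status}]", ""]
        if stage.entries:
            lines.append("| study | arm | n | AAFE | fold Cmax | fold AUC | fold t1/2 |")
            lines.append("|---|---|---|---|---|---|---|")
            for e in stage.entries:
                fmt = lambda v: "n/a" if v is None else f"{v:.2f}"
                lines.append(f"| {e.study_id} | {e.arm} | {e.n_points} | "
                             f"{e.aafe:.2f} | {fmt(e.fold_cmax)} | "
                             f"{fmt(e.fold_auc)} | {fmt(e.fold_thalf)} |")
            lines.append("")
    lines += ["## Log", ""] + [f"- {entry}" for entry in report.log] + [""]
    return "\n".join(lines)
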