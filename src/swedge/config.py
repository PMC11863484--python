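"""Scenario configuration files, result serialisation and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortScheme
from .datagen import no_trend, seasonal_trend, secular_trend
from .design import DesignConfiguration, build_complete_design, read_design_csv
from .engine import ScenarioConfig, SimulationSummary
from .inference import build_time_basis
from .variance import CorrelationSpec

__all__ = ["load_scenario", "write_results", "RunManifest", "fixture_path", "list_fixtures"]

_TOP_KEYS = {
    "design",
    "time_basis",
    "allocation",
    "sd_total",
    "icc",
    "cac",
    "iac",
    "cohort",
    "effect",
    "baseline_mean",
    "trend",
    "alpha",
    "n_sims",
    "master_seed",
}
_REQUIRED = {"design", "sd_total", "icc", "effect", "n_sims", "master_seed", "cohort"}


class ConfigError(ValueError):
    pass


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture file."""
    path = resources.files("swedge") / "fixtures" / name
    if not path.is_file():
        raise FileNotFoundError(f"no packaged fixture named {name!r}")
    return Path(str(path))


def list_fixtures() -> list[str]:
    base = resources.files("swedge") / "fixtures"
    return sorted(p.name for p in base.iterdir() if p.is_file())


def _build_design(spec, allocation, base_dir: Path) -> DesignConfiguration:
    if isinstance(spec, str):
        if spec.endswith(".csv"):
            path = Path(spec)
            if not path.is_absolute():
                candidate = base_dir / path
                path = candidate if candidate.exists() else fixture_path(spec)
            design = read_design_csv(path)
        else:
            design = read_design_csv(fixture_path(spec))
    elif isinstance(spec, dict):
        if spec.get("kind") != "complete":
            raise ConfigError("design dict must have kind: complete")
        design = build_complete_design(
            int(spec["n_sequences"]), spec.get("n_periods")
        )
    else:
        raise ConfigError("design must be a CSV path, fixture name or dict")
    if allocation is not None:
        if len(allocation) != design.n_sequences:
            raise ConfigError(
                f"allocation has {len(allocation)} entries for "
                f"{design.n_sequences} sequences"
            )
        design = design.with_allocation(allocation)
    return design


def _build_trend(spec):
    if spec is None:
        return no_trend()
    kind = spec.get("kind", "none")
    if kind == "none":
        return no_trend()
    if kind == "seasonal":
        return seasonal_trend(
            float(spec["amplitude"]), float(spec.get("peak_month", 7.0))
        )
    if kind == "secular":
        return secular_trend(float(spec["slope_per_year"]))
    raise ConfigError(f"unknown trend kind {kind!r}")


def load_scenario(path) -> ScenarioConfig:
    """Load and validate a YAML/JSON scenario file into a ScenarioConfig.

    Defaults applied: alpha 0.05, baseline_mean 100, cac 1, iac 0,
    sampling_mode expected_counts, no trend.  Unknown keys are rejected.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(
            f"{path}: expected a mapping with keys {sorted(_REQUIRED)}"
        )
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    missing = _REQUIRED - set(raw)
    if missing:
        raise ConfigError(f"{path}: missing required keys {sorted(missing)}")

    try:
        correlations = CorrelationSpec(
            sd_total=float(raw["sd_total"]),
            icc=float(raw["icc"]),
            cac=float(raw.get("cac", 1.0)),
            iac=float(raw.get("iac", 0.0)),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc

    cohort_raw = dict(raw["cohort"])
    try:
        scheme = CohortScheme(
            kind=cohort_raw.pop("kind"),
            eligible_per_school=int(cohort_raw.pop("eligible_per_school")),
            recruitment_rate=float(cohort_raw.pop("recruitment_rate", 1.0)),
            retention_rate=float(cohort_raw.pop("retention_rate", 1.0)),
            sampling_mode=cohort_raw.pop("sampling_mode", "expected_counts"),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: cohort missing field {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"{path}: cohort: {exc}") from exc
    if cohort_raw:
        raise ConfigError(f"{path}: cohort has unknown fields {sorted(cohort_raw)}")

    design = _build_design(raw["design"], raw.get("allocation"), path.parent)
    basis = None
    if "time_basis" in raw:
        tb = dict(raw["time_basis"])
        months = [lab.months for lab in design.period_labels]
        try:
            basis = build_time_basis(months, tb.pop("kind"), **tb)
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: time_basis: {exc}") from exc
    return ScenarioConfig(
        design=design,
        correlations=correlations,
        scheme=scheme,
        effect=float(raw["effect"]),
        n_sims=int(raw["n_sims"]),
        master_seed=int(raw["master_seed"]),
        baseline_mean=float(raw.get("baseline_mean", 100.0)),
        trend=_build_trend(raw.get("trend")),
        alpha=float(raw.get("alpha", 0.05)),
        basis=basis,
    )


@dataclass
class RunManifest:
    """Inventory of one run's outputs with content checksums."""

    master_seed: int
    created: str
    outputs: dict[str, str]  # filename -> sha256
    counts: dict[str, int]

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(result, out_dir, master_seed: int = 0) -> RunManifest:
    """Write a summary or sweep table as CSV plus a JSON manifest.

    Identical inputs reproduce identical file checksums (the manifest's
    timestamp is informational and excluded from the checksummed outputs).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    counts: dict[str, int] = {}
    if isinstance(result, SimulationSummary):
        frame = pd.DataFrame([asdict(result)])
        target = out_dir / "summary.csv"
        frame.to_csv(target, index=False, float_format="%.10g")
        outputs["summary.csv"] = _sha256(target)
        counts["n_sims"] = result.n_sims
        counts["n_excluded"] = result.n_excluded
    elif isinstance(result, pd.DataFrame):
        target = out_dir / "sweep.csv"
        result.to_csv(target, index=False, float_format="%.10g")
        outputs["sweep.csv"] = _sha256(target)
        counts["rows"] = len(result)
        if "n_excluded" in result:
            counts["n_excluded"] = int(result["n_excluded"].sum())
    else:
        raise TypeError(f"cannot serialise result of type {type(result).__name__}")
    manifest = RunManifest(
        master_seed=master_seed,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
        outputs=outputs,
        counts=counts,
    )
    manifest.write(out_dir)
    return manifest
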