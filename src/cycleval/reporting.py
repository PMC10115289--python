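"""Config loading, result serialization, and run manifests.

Configs are YAML (or JSON — a YAML subset) documents mirroring the
:class:`~cycleval.config.AppraisalConfig` field names; unknown keys are
rejected so typos fail loudly.  Reports are deterministic CSV/JSON:
identical inputs and tool version produce byte-identical files.  Every
currency column name carries an explicit unit tag (``intl_dollar`` or
``gbp``) because the appraisal works in two currencies linked by a PPP
coefficient.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .breakeven import BreakEvenResult, BreakEvenSummary
from .config import AppraisalConfig, validate_config
from .engine import appraise
from .sensitivity import SensitivityRow

__all__ = [
    "ConfigError",
    "RunManifest",
    "load_config",
    "save_config",
    "config_digest",
    "write_breakeven_reports",
    "write_sensitivity_report",
]


class ConfigError(ValueError):
    """A config file failed to parse or validate; lists every violation."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("invalid configuration:\n  " + "\n  ".join(self.violations))


class RunManifest(BaseModel):
    """Provenance record written beside every report."""

    model_config = ConfigDict(frozen=True)

    config_digest: str
    tool_version: str
    command: str
    timestamp: str = ""


def load_config(path: Union[str, Path]) -> AppraisalConfig:
    """Read and validate an appraisal config from YAML/JSON.

    Raises :class:`ConfigError` with every violation (unknown keys, type
    errors, broken invariants) rather than just the first.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        config = AppraisalConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigError(msgs) from exc
    violations = validate_config(config)
    if violations:
        raise ConfigError(violations)
    return config


def save_config(config: AppraisalConfig, path: Union[str, Path]) -> Path:
    """Write a config as YAML; ``load_config`` of the result is identity."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
    return path


def config_digest(config: AppraisalConfig) -> str:
    """Stable SHA-256 digest of a config's canonical JSON form."""
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _pct(share: float) -> str:
    return f"{100.0 * share:.3f}"


def _dollars(value: float) -> str:
    return f"{value:.0f}" if abs(value) >= 1.0 else f"{value:.4f}"


def _manifest(config: AppraisalConfig, command: str, timestamp: str) -> RunManifest:
    return RunManifest(
        config_digest=config_digest(config),
        tool_version=__version__,
        command=command,
        timestamp=timestamp,
    )


def write_breakeven_reports(
    config: AppraisalConfig,
    results: Sequence[BreakEvenResult],
    summary: Optional[BreakEvenSummary],
    out_dir: Union[str, Path],
    command: str = "breakeven",
    timestamp: str = "",
) -> dict[str, Path]:
    """Write the scenario-block CSV, JSON summary and manifest.

    The CSV has one row per scenario × domain (deaths-or-tonnes plus
    discounted value, mirroring the four-domain result layout); the JSON
    carries the summary statistics in both $ and £.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    econ = config.economics

    rows = []
    for r in results:
        appraisal = appraise(config, r.post)
        for imp in appraisal.impacts:
            rows.append(
                {
                    "scenario": f"shift from level {r.scenario.source_level}",
                    "source_level": r.scenario.source_level,
                    "required_shift_pct": _pct(r.scenario.shifted_share),
                    "new_regular_cyclists": r.new_regular_cyclists,
                    "domain": imp.domain,
                    "annual_deaths": f"{imp.annual_deaths_delta:.4f}",
                    "annual_tonnes_co2": f"{imp.annual_tonnes_co2_delta:.2f}",
                    "value_intl_dollar": _dollars(imp.discounted_value),
                    "bcr": f"{appraisal.bcr:.4f}",
                }
            )
    columns = [
        "scenario",
        "source_level",
        "required_shift_pct",
        "new_regular_cyclists",
        "domain",
        "annual_deaths",
        "annual_tonnes_co2",
        "value_intl_dollar",
        "bcr",
    ]
    csv_path = out / "breakeven_scenarios.csv"
    pd.DataFrame(rows, columns=columns).to_csv(csv_path, index=False)

    json_path = out / "breakeven_summary.json"
    payload = {
        "intervention_cost_intl_dollar": config.intervention.cost_intl_dollars,
        "intervention_cost_gbp": round(
            config.intervention.cost_intl_dollars * econ.ppp_coefficient, 2
        ),
        "cycleway_length_km": config.intervention.cycleway_length_km,
        "summary": None,
    }
    if summary is not None:
        payload["summary"] = {
            "mean_new_regular_cyclists": summary.mean_new_regular_cyclists,
            "mean_shifted_share_pct": round(100.0 * summary.mean_shifted_share, 4),
            "mean_share_of_population_pct": (
                round(100.0 * summary.mean_share_of_population, 4)
                if summary.mean_share_of_population is not None
                else None
            ),
            "cyclists_per_km": round(summary.cyclists_per_km, 2),
            "per_cyclist_annual_value_intl_dollar": round(summary.per_cyclist_annual_value, 2),
            "per_cyclist_annual_value_gbp": round(
                summary.per_cyclist_annual_value * econ.ppp_coefficient, 2
            ),
        }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        _manifest(config, command, timestamp).model_dump_json(indent=2) + "\n"
    )
    return {"scenarios": csv_path, "summary": json_path, "manifest": manifest_path}


def write_sensitivity_report(
    config: AppraisalConfig,
    rows: Sequence[SensitivityRow],
    out_dir: Union[str, Path],
    command: str = "sensitivity",
    timestamp: str = "",
) -> dict[str, Path]:
    """Write the one-way sensitivity grid as CSV plus a manifest.

    ``tornado_rank`` orders variations by |BCR − 1| at the base shift
    (1 = most influential), the usual tornado-diagram ordering.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    deviations = [abs(r.bcr_at_base_shift - 1.0) for r in rows]
    order = sorted(range(len(rows)), key=lambda i: -deviations[i])
    rank = {i: k + 1 for k, i in enumerate(order)}

    records = []
    for i, r in enumerate(rows):
        records.append(
            {
                "variation": r.variation.label,
                "parameter": r.variation.parameter,
                "bcr_at_base_shift": f"{r.bcr_at_base_shift:.3f}",
                "regular_cyclist_share_pct": (
                    _pct(config.population.baseline.shares[0] + r.breakeven_share)
                    if r.feasible
                    else ""
                ),
                "absolute_regular_cyclists": r.absolute_regular_cyclists if r.feasible else "",
                "additional_vs_base": r.additional_vs_base if r.feasible else "",
                "feasible": r.feasible,
                "tornado_rank": rank[i],
            }
        )
    columns = [
        "variation",
        "parameter",
        "bcr_at_base_shift",
        "regular_cyclist_share_pct",
        "absolute_regular_cyclists",
        "additional_vs_base",
        "feasible",
        "tornado_rank",
    ]
    csv_path = out / "sensitivity.csv"
    pd.DataFrame(records, columns=columns).to_csv(csv_path, index=False)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        _manifest(config, command, timestamp).model_dump_json(indent=2) + "\n"
    )
    return {"sensitivity": csv_path, "manifest": manifest_path}
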