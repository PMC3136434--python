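"""Layered run configuration: a YAML file plus CLI overrides.

Unknown keys are rejected (no silent defaults for typos) and every
report embeds the effective configuration, so a run is reproducible from
its own output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .solvation import DEFAULT_GAMMA, DEFAULT_SA_OFFSET, PBSettings

__all__ = ["RunConfig", "load_config", "write_report", "SCHEMA_VERSION"]

SCHEMA_VERSION = "bindscan-report-1"


@dataclass
class RunConfig:
    """Package-wide knobs; units: Å, kcal/mol, ps, K."""

    temperature_K: float = 300.0
    stride_ps: float | None = None
    scan_stride_ps: float | None = None
    entropy_stride_ps: float | None = None
    window_ps: float = 12000.0
    convergence_tol_kcal_mol: float = 1.0
    gamma_kcal_mol_A2: float = DEFAULT_GAMMA
    sa_offset_kcal_mol: float = DEFAULT_SA_OFFSET
    ch_length_A: float = 1.09
    hbond_distance_A: float = 3.5
    hbond_angle_deg: float = 120.0
    rmsd_bound_A: float = 2.0
    softcore_alpha: float = 0.5
    softcore_power: int = 1
    seed: int = 0
    output_dir: str = "."
    pb: PBSettings = field(default_factory=PBSettings)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load YAML config (if any) and apply keyword overrides on top."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        data.update(raw)
    for k, v in overrides.items():
        if v is not None:
            data[k] = v
    pb_data = data.pop("pb", {})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    pb_known = {f.name for f in dataclasses.fields(PBSettings)}
    pb_unknown = set(pb_data) - pb_known
    if pb_unknown:
        raise ValueError(f"unknown pb config keys: {sorted(pb_unknown)}")
    cfg = RunConfig(**data)
    cfg.pb = PBSettings(**pb_data)
    return cfg


def write_report(payload: dict, config: RunConfig, path: str | Path) -> None:
    """Versioned JSON report embedding the effective configuration."""
    doc = {"schema_version": SCHEMA_VERSION,
           "config": config.as_dict(),
           **payload}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True,
                                     default=float) + "\n")
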