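"""Run configuration: strict parsing of TOML/YAML/JSON parameter files.

A config file has one ``genes.<name>`` block per reporter, a ``cycle`` block,
an optional ``measurement`` block, an optional ``interventions`` list and one
optional block named after the scenario with scenario-specific options.
Rates are per minute; any key ending in ``_h`` (hours) or ``_d`` (days) is
converted to minutes at parse time, and degradation may be given as
``mrna_half_life_h`` / ``protein_half_life_h`` instead of rates.  Unknown
keys are rejected by name.  Every run writes a manifest echoing the fully
resolved configuration (all units in minutes) and the seed.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .gene_model import CellCycleParams, GeneParams, half_life_to_rate
from .presets import CYCLE, gene_preset
from .synthetic_data import MeasurementModel

__all__ = ["RunConfig", "parse_config", "SCENARIOS"]

SCENARIOS = ("simulate", "subclone", "frap", "silencing", "synth", "analyze")

_GENE_KEYS = {
    "preset", "channel", "k_open", "k_close", "k_burst", "burst_size_mean",
    "k_tl", "delta_m", "delta_p",
    "mrna_half_life_min", "mrna_half_life_h",
    "protein_half_life_min", "protein_half_life_h",
    "open_dwell_h", "closed_dwell_h",
}
_CYCLE_KEYS = {"T_div_min", "T_div_h", "cv_div"}
_MEAS_KEYS = {"noise_cv", "floor_mean", "floor_sd", "gain"}
_IV_KEYS = {"kind", "time_min", "time_h", "gene", "bleach_fraction"}
_TOP_KEYS = {"scenario", "seed", "out_dir", "genes", "cycle", "measurement",
             "interventions"} | set(SCENARIOS)

_SCENARIO_KEYS = {
    "simulate": {"t_end_min", "t_end_h", "t_end_d", "dt_min", "clamp", "init",
                 "partition_mode"},
    "subclone": {"n_subclones", "duration_d", "snapshot_days", "max_cells",
                 "parental_n", "classes"},
    "frap": {"n_cells", "bleach_fraction", "observe_min", "observe_h",
             "control", "dt_min", "n_envelope"},
    "silencing": {"t_clamp_min", "t_clamp_h", "t_end_min", "t_end_h", "t_end_d",
                  "dt_min"},
    "synth": {"modality", "n_founders", "n_cells", "duration_min", "duration_h",
              "frame_interval_min", "max_cells"},
    "analyze": {"input", "value_columns", "max_lag_min"},
}

_MIN_PER = {"_min": 1.0, "_h": 60.0, "_d": 1440.0}


def _to_minutes(key: str, value: float) -> tuple[str, float]:
    """Normalize a suffixed duration key to minutes (key keeps ``_min``)."""
    for suffix, factor in _MIN_PER.items():
        if key.endswith(suffix):
            return key[: -len(suffix)] + "_min", float(value) * factor
    return key, value


def _check_keys(block: dict, allowed: set, where: str) -> None:
    for k in block:
        if k not in allowed:
            raise ConfigError(f"unknown key {k!r} in {where}")


@dataclass
class RunConfig:
    """Fully resolved run configuration (all durations in minutes)."""

    scenario: str
    seed: int
    out_dir: str
    genes: tuple
    cycle: CellCycleParams
    measurement: MeasurementModel
    interventions: list = field(default_factory=list)
    options: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        """JSON-serializable echo of the resolved configuration."""
        return {
            "scenario": self.scenario,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "genes": [
                {k: getattr(g, k) for k in (
                    "name", "k_open", "k_close", "k_burst", "burst_size_mean",
                    "k_tl", "delta_m", "delta_p")}
                for g in self.genes
            ],
            "cycle": {"T_div_min": self.cycle.T_div, "cv_div": self.cycle.cv_div},
            "measurement": {
                "noise_cv": self.measurement.noise_cv,
                "floor_mean": self.measurement.floor_mean,
                "floor_sd": self.measurement.floor_sd,
                "gain": self.measurement.gain,
            },
            "interventions": list(self.interventions),
            "options": self.options,
        }


def _parse_gene(name: str, block: dict) -> GeneParams:
    _check_keys(block, _GENE_KEYS, f"genes.{name}")
    base = None
    if "preset" in block:
        base = gene_preset(block["preset"], block.get("channel", "yfp"))
    fields = {} if base is None else {
        k: getattr(base, k) for k in ("k_open", "k_close", "k_burst",
                                      "burst_size_mean", "k_tl", "delta_m",
                                      "delta_p")
    }
    for key, value in block.items():
        if key in ("preset", "channel"):
            continue
        if key.startswith("mrna_half_life"):
            k, v = _to_minutes(key.replace("mrna_half_life", "x"), value)
            fields["delta_m"] = half_life_to_rate(v)
        elif key.startswith("protein_half_life"):
            k, v = _to_minutes(key.replace("protein_half_life", "x"), value)
            fields["delta_p"] = half_life_to_rate(v)
        elif key == "open_dwell_h":
            fields["k_close"] = 1.0 / (60.0 * float(value))
        elif key == "closed_dwell_h":
            fields["k_open"] = 1.0 / (60.0 * float(value))
        else:
            fields[key] = float(value)
    missing = {"k_open", "k_close", "k_burst", "burst_size_mean", "k_tl",
               "delta_m", "delta_p"} - set(fields)
    if missing:
        raise ConfigError(
            f"genes.{name}: missing required key(s) {sorted(missing)} "
            "(or give a preset)"
        )
    try:
        return GeneParams(name=name, **fields)
    except ValueError as exc:
        raise ConfigError(f"genes.{name}: {exc}") from exc


def _load(path: Path) -> dict:
    text = path.read_text()
    suffix = path.suffix.lower()
    if suffix == ".toml":
        return tomllib.loads(text)
    if suffix == ".json":
        return json.loads(text)
    if suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    # no/unknown extension: try the three formats in turn
    for loader in (tomllib.loads, json.loads, yaml.safe_load):
        try:
            data = loader(text)
        except Exception:
            continue
        if isinstance(data, dict):
            return data
    raise ConfigError(f"could not parse {path} as TOML, JSON or YAML")


def parse_config(path, scenario: str | None = None) -> RunConfig:
    """Parse and validate a config file into a :class:`RunConfig`.

    ``scenario`` overrides the file's own ``scenario`` key (used by the CLI,
    where the subcommand decides which scenario-options block applies).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = _load(path)
    if not isinstance(data, dict):
        raise ConfigError(f"config root of {path} must be a mapping")
    _check_keys(data, _TOP_KEYS, "config root")

    scenario = scenario or data.get("scenario", "simulate")
    if scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario {scenario!r}; one of {SCENARIOS}")

    gene_blocks = data.get("genes")
    if gene_blocks:
        genes = tuple(_parse_gene(name, dict(block))
                      for name, block in gene_blocks.items())
    else:
        genes = (gene_preset("stable", "yfp"), gene_preset("stable", "cfp"))

    cyc = dict(data.get("cycle", {}))
    _check_keys(cyc, _CYCLE_KEYS, "cycle")
    T_div = CYCLE.T_div
    if "T_div_h" in cyc:
        T_div = 60.0 * float(cyc["T_div_h"])
    if "T_div_min" in cyc:
        T_div = float(cyc["T_div_min"])
    try:
        cycle = CellCycleParams(T_div=T_div, cv_div=float(cyc.get("cv_div", 0.0)))
    except ValueError as exc:
        raise ConfigError(f"cycle: {exc}") from exc

    meas_block = dict(data.get("measurement", {}))
    _check_keys(meas_block, _MEAS_KEYS, "measurement")
    try:
        measurement = MeasurementModel(**{k: float(v)
                                          for k, v in meas_block.items()})
    except ValueError as exc:
        raise ConfigError(f"measurement: {exc}") from exc

    gene_index = {g.name: i for i, g in enumerate(genes)}
    interventions = []
    for i, iv in enumerate(data.get("interventions", [])):
        iv = dict(iv)
        _check_keys(iv, _IV_KEYS, f"interventions[{i}]")
        if "kind" not in iv or not ("time_min" in iv or "time_h" in iv):
            raise ConfigError(f"interventions[{i}]: needs 'kind' and a time")
        time = float(iv.get("time_min", 60.0 * iv.get("time_h", 0.0)))
        gene = iv.get("gene")
        if isinstance(gene, str):
            if gene not in gene_index:
                raise ConfigError(f"interventions[{i}]: unknown gene {gene!r}")
            gene = gene_index[gene]
        interventions.append({
            "kind": iv["kind"], "time_min": time, "gene": gene,
            "bleach_fraction": float(iv.get("bleach_fraction", 1.0)),
        })

    options = dict(data.get(scenario, {}))
    _check_keys(options, _SCENARIO_KEYS[scenario], f"{scenario} options")
    resolved = {}
    for key, value in options.items():
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            key, value = _to_minutes(key, value)
        resolved[key] = value

    return RunConfig(
        scenario=scenario,
        seed=int(data.get("seed", 0)),
        out_dir=str(data.get("out_dir", "memsim_out")),
        genes=genes,
        cycle=cycle,
        measurement=measurement,
        interventions=interventions,
        options=resolved,
    )
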