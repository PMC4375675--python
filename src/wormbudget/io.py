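"""Configuration parsing, CSV/JSON writers, fixture generation and run
manifests.

Configs are YAML with explicit field-units (degrees C, kg/m^2); internal
computation uses kelvin, grams, kJ and days.  All CSV output is
comma-separated UTF-8 with a header row and '.' decimals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .landscape import SeasonalField
from .scenarios import Cohort, ExposureConfig, ScenarioConfig, TransferEvent


class ConfigError(ValueError):
    """A scenario configuration file is malformed."""


_TOP_KEYS = {
    "name", "replicates", "duration_days", "arena_m2", "environment",
    "initial_population", "feeding", "initial_food_g_per_patch",
    "background_mortality", "exposure", "transfer", "field", "record_events",
}
_ENV_KEYS = {"mode", "temperature_c", "moisture_pct"}
_COHORT_KEYS = {"stage", "count", "mass_g"}
_FEED_KEYS = {"day", "grams"}
_EXPOSURE_KEYS = {"submodel", "concentration_mg_kg", "start_day", "k_growth", "k_repro"}
_TRANSFER_KEYS = {"day", "n_adults", "reset_food"}


def _check_keys(d: dict, allowed: set, context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {context}")


def parse_config_dict(raw: dict) -> ScenarioConfig:
    """Build a validated :class:`ScenarioConfig` from a parsed YAML mapping."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(raw, _TOP_KEYS, "scenario config")
    for req in ("name", "replicates", "duration_days", "arena_m2"):
        if req not in raw:
            raise ConfigError(f"missing required key {req!r}")
    env = raw.get("environment", {}) or {}
    _check_keys(env, _ENV_KEYS, "environment")
    cohorts = []
    for i, c in enumerate(raw.get("initial_population", []) or []):
        _check_keys(c, _COHORT_KEYS, f"initial_population[{i}]")
        cohorts.append(Cohort(stage=c["stage"], count=int(c["count"]),
                              mass_g=c.get("mass_g")))
    feeding = []
    for i, f in enumerate(raw.get("feeding", []) or []):
        _check_keys(f, _FEED_KEYS, f"feeding[{i}]")
        if f["grams"] < 0:
            raise ConfigError(f"feeding[{i}].grams is negative")
        feeding.append((int(f["day"]), float(f["grams"])))
    exposure = None
    if raw.get("exposure"):
        e = raw["exposure"]
        _check_keys(e, _EXPOSURE_KEYS, "exposure")
        exposure = ExposureConfig(
            submodel=e["submodel"],
            concentration=float(e["concentration_mg_kg"]),
            start_day=int(e.get("start_day", 0)),
            k_growth=e.get("k_growth"),
            k_repro=e.get("k_repro"),
        )
    transfer = None
    if raw.get("transfer"):
        t = raw["transfer"]
        _check_keys(t, _TRANSFER_KEYS, "transfer")
        transfer = TransferEvent(day=int(t["day"]), n_adults=int(t["n_adults"]),
                                 reset_food=bool(t.get("reset_food", True)))
    fieldenv = SeasonalField.from_dict(raw["field"]) if raw.get("field") else None
    try:
        return ScenarioConfig(
            name=str(raw["name"]),
            replicates=int(raw["replicates"]),
            duration_days=int(raw["duration_days"]),
            arena_m2=float(raw["arena_m2"]),
            temperature_c=float(env.get("temperature_c", 20.0)),
            moisture_pct=float(env.get("moisture_pct", 80.0)),
            environment_mode=str(env.get("mode", "fixed")),
            field=fieldenv,
            initial_population=cohorts,
            feeding=feeding,
            initial_food_g_per_patch=float(raw.get("initial_food_g_per_patch", 0.0)),
            background_mortality=raw.get("background_mortality"),
            exposure=exposure,
            transfer=transfer,
            record_events=bool(raw.get("record_events", True)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(cfg: ScenarioConfig) -> dict:
    """Serialisable mapping; ``parse_config_dict`` round-trips it."""
    d: dict = {
        "name": cfg.name,
        "replicates": cfg.replicates,
        "duration_days": cfg.duration_days,
        "arena_m2": cfg.arena_m2,
        "environment": {
            "mode": cfg.environment_mode,
            "temperature_c": cfg.temperature_c,
            "moisture_pct": cfg.moisture_pct,
        },
        "initial_population": [
            {"stage": c.stage, "count": c.count, **({"mass_g": c.mass_g} if c.mass_g is not None else {})}
            for c in cfg.initial_population
        ],
        "feeding": [{"day": d_, "grams": g} for d_, g in cfg.feeding],
    }
    if cfg.initial_food_g_per_patch:
        d["initial_food_g_per_patch"] = cfg.initial_food_g_per_patch
    if cfg.background_mortality is not None:
        d["background_mortality"] = cfg.background_mortality
    if cfg.field is not None:
        d["field"] = cfg.field.to_dict()
    if cfg.exposure is not None:
        e = cfg.exposure
        d["exposure"] = {
            "submodel": e.submodel,
            "concentration_mg_kg": e.concentration,
            "start_day": e.start_day,
            **({"k_growth": e.k_growth} if e.k_growth is not None else {}),
            **({"k_repro": e.k_repro} if e.k_repro is not None else {}),
        }
    if cfg.transfer is not None:
        d["transfer"] = {
            "day": cfg.transfer.day,
            "n_adults": cfg.transfer.n_adults,
            "reset_food": cfg.transfer.reset_food,
        }
    if not cfg.record_events:
        d["record_events"] = False
    return d


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario configuration from a YAML file."""
    p = Path(path)
    if not p.is_file():
        raise ConfigError(f"config file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {p}: {exc}") from exc
    return parse_config_dict(raw)


def save_config(cfg: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def config_hash(cfg: ScenarioConfig) -> str:
    """Stable content hash of a scenario configuration."""
    canonical = yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Fixtures


def generate_dr_fixture(
    k_tox: float,
    doses: list[float],
    reps: int,
    noise_cv: float,
    seed: int,
    control: float = 100.0,
    trait: str = "growth",
) -> pd.DataFrame:
    """Synthetic dose-response table: ``control * exp(k_tox C)`` with
    multiplicative lognormal noise of the given coefficient of variation.

    Emulates the replicated concentration-trait tables used for curve
    fitting; deterministic per seed.
    """
    if 0.0 not in [float(d) for d in doses]:
        raise ValueError("doses must include the control concentration 0")
    rng = np.random.default_rng(seed)
    rows = []
    sigma = _lognormal_sigma(noise_cv)
    for c in doses:
        for r in range(reps):
            mean = control * np.exp(k_tox * c)
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma)) if sigma > 0 else 1.0
            rows.append(
                {"concentration": float(c), "trait": trait,
                 "value": float(mean * noise), "replicate": r}
            )
    return pd.DataFrame(rows)


def _lognormal_sigma(cv: float) -> float:
    """Lognormal sigma giving a multiplicative coefficient of variation cv."""
    return float(np.sqrt(np.log1p(cv**2)))


# ---------------------------------------------------------------------------
# Run manifests and result writing


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-exactly."""

    config_hash: str
    master_seed: int
    n_replicates: int
    package_version: str
    outputs: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def write_results(
    results,
    manifest: RunManifest,
    outdir: str | Path,
    overwrite: bool = True,
) -> list[Path]:
    """Write tidy per-day CSVs, the event log and the manifest.

    Returns the written paths.  Re-running with the same manifest reproduces
    byte-identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pop_path = out / "population.csv"
    ev_path = out / "events.csv"
    man_path = out / "manifest.json"
    for p in (pop_path, ev_path, man_path):
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists and overwrite=False")
    pop_frames = []
    ev_frames = []
    for i, res in enumerate(results):
        f = res.to_frame()
        f.insert(0, "replicate", i)
        pop_frames.append(f)
        e = res.events_frame()
        e.insert(0, "replicate", i)
        ev_frames.append(e)
    pop = (pd.concat(pop_frames, ignore_index=True) if pop_frames
           else pd.DataFrame(columns=["replicate", "day", "stage", "count", "biomass_g",
                                      "cocoons_cum", "temperature_c", "moisture_pct",
                                      "food_total_g"]))
    ev = (pd.concat(ev_frames, ignore_index=True) if ev_frames
          else pd.DataFrame(columns=["replicate", "day", "event", "agent_id"]))
    pop.to_csv(pop_path, index=False)
    ev.to_csv(ev_path, index=False)
    manifest.outputs = [pop_path.name, ev_path.name]
    man_path.write_text(manifest.to_json())
    return [pop_path, ev_path, man_path]
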