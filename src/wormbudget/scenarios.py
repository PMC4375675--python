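"""Scenario configurations: laboratory presets, the field study, and the
one-at-a-time local sensitivity driver.

Laboratory presets reproduce the published experimental protocols they are
named after (arena size, worm numbers, feeding schedule, temperature); the
field scenario runs the seasonal manure-heap environment.  The sensitivity
driver perturbs physiological parameters and environmental baselines one at
a time by a fixed fraction and reports the elasticity of population outputs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .landscape import SeasonalField
from .params import PARAMETER_NAMES, EnergyBudgetParams

CELSIUS_OFFSET = 273.15


@dataclass
class Cohort:
    """A group of identical individuals in the initial population.

    ``mass_g`` may be None, in which case masses are drawn uniformly over the
    stage's range (juveniles: [Mb, Mp); adults: [Mp, Mm]).  Ignored for
    cocoons, which start with the full endowment.
    """

    stage: str  # "cocoon" | "juvenile" | "adult"
    count: int
    mass_g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.stage not in ("cocoon", "juvenile", "adult"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.count < 0:
            raise ValueError(f"cohort count must be non-negative, got {self.count}")


@dataclass
class ExposureConfig:
    """Constant, spatially uniform pesticide exposure applied from
    ``start_day`` through one of the toxicity submodels T1-T4.

    ``k_growth`` / ``k_repro`` are the fitted dose-response coefficients
    (per mg/kg) for the growth and reproduction trait curves; which of them a
    submodel needs depends on the submodel (T4 needs neither).
    """

    submodel: str
    concentration: float
    start_day: int = 0
    k_growth: Optional[float] = None
    k_repro: Optional[float] = None

    def __post_init__(self) -> None:
        if self.submodel not in ("T1", "T2", "T3", "T4"):
            raise ValueError(f"unknown toxicity submodel {self.submodel!r}")
        if self.concentration < 0:
            raise ValueError("exposure concentration must be non-negative")


@dataclass
class TransferEvent:
    """Mid-experiment transfer to fresh substrate: on ``day``, up to
    ``n_adults`` surviving adults are retained, all other individuals and any
    remaining food are removed (feeding on the same day then restocks)."""

    day: int
    n_adults: int
    reset_food: bool = True


@dataclass
class ScenarioConfig:
    """Full description of one simulation experiment."""

    name: str
    replicates: int
    duration_days: int
    arena_m2: float
    temperature_c: float = 20.0
    moisture_pct: float = 80.0
    environment_mode: str = "fixed"  # "fixed" | "field"
    field: Optional[SeasonalField] = None
    initial_population: list[Cohort] = dc_field(default_factory=list)
    feeding: list[tuple[int, float]] = dc_field(default_factory=list)
    initial_food_g_per_patch: float = 0.0
    background_mortality: Optional[bool] = None  # None -> on in field mode only
    exposure: Optional[ExposureConfig] = None
    transfer: Optional[TransferEvent] = None
    record_events: bool = True

    def __post_init__(self) -> None:
        if self.environment_mode not in ("fixed", "field"):
            raise ValueError(f"unknown environment mode {self.environment_mode!r}")
        if self.environment_mode == "field" and self.field is None:
            self.field = SeasonalField()
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        for d, g in self.feeding:
            if g < 0:
                raise ValueError(f"feeding quantity on day {d} is negative")

    @property
    def mortality_enabled(self) -> bool:
        if self.background_mortality is None:
            return self.environment_mode == "field"
        return self.background_mortality

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + CELSIUS_OFFSET


# ---------------------------------------------------------------------------
# Presets


def available_presets() -> list[str]:
    """Names of the bundled scenario presets."""
    root = importlib.resources.files("wormbudget") / "presets"
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> ScenarioConfig:
    """Load a bundled scenario preset by name (e.g. ``bostrom1987``)."""
    from .io import parse_config_dict  # deferred: io imports this module

    import yaml

    path = importlib.resources.files("wormbudget") / "presets" / f"{name}.yaml"
    if not path.is_file():
        raise KeyError(f"unknown preset {name!r}; available: {available_presets()}")
    return parse_config_dict(yaml.safe_load(path.read_text()))


def field_scenario(
    duration_days: int = 365,
    replicates: int = 4,
    arena_m2: float = 1.0,
    fieldenv: Optional[SeasonalField] = None,
) -> ScenarioConfig:
    """The seasonal manure-heap field scenario: a 1 m^2 arena initialised at
    field-like densities (50 adults, 100 juveniles, 100 cocoons per m^2)."""
    return ScenarioConfig(
        name="field",
        replicates=replicates,
        duration_days=duration_days,
        arena_m2=arena_m2,
        environment_mode="field",
        field=fieldenv or SeasonalField(),
        initial_population=[
            Cohort("adult", round(50 * arena_m2)),
            Cohort("juvenile", round(100 * arena_m2)),
            Cohort("cocoon", round(100 * arena_m2)),
        ],
    )


# ---------------------------------------------------------------------------
# Local sensitivity analysis

#: Environmental baselines used in the sensitivity experiment.
SENSITIVITY_BASELINES = {"soil_temp_c": 25.0, "soil_moisture_pct": 60.0, "food_g_per_patch": 20.0}

ENV_PARAMETERS = ("soil_T", "soil_SM", "food_X")


@dataclass
class SensitivityDesign:
    """One-at-a-time design: each parameter (physiological constants plus the
    environmental baselines) is increased by ``perturbation`` (default +10%)
    and the change in year-mean outputs measured against a shared baseline.

    Temperatures (Tref and the soil-temperature baseline) are perturbed on
    the kelvin scale.  With ``paired_seeds`` each perturbed replicate shares
    its random stream with the matching baseline replicate, which reduces the
    Monte-Carlo variance of the ratio.
    """

    parameters: Sequence[str] = tuple(PARAMETER_NAMES) + ENV_PARAMETERS
    perturbation: float = 0.10
    replicates: int = 100
    duration_days: int = 365
    paired_seeds: bool = True

    def __post_init__(self) -> None:
        known = set(PARAMETER_NAMES) | set(ENV_PARAMETERS)
        unknown = set(self.parameters) - known
        if unknown:
            raise ValueError(f"unknown sensitivity parameters: {sorted(unknown)}")


OUTPUTS = ("adult_biomass", "juvenile_biomass", "cocoons_per_adult")


def sensitivity_ratio(baseline_mean: float, perturbed_mean: float,
                      perturbation: float = 0.10) -> float:
    """Elasticity: (% change in output) / (% change in parameter).

    An unchanged output gives exactly 0 (also in the degenerate 0%
    perturbation limit, where paired runs are identical).
    """
    if baseline_mean == 0:
        raise ValueError("sensitivity ratio undefined for zero baseline output")
    if perturbed_mean == baseline_mean:
        return 0.0
    if perturbation == 0:
        raise ValueError("output changed under a 0% perturbation; ratio undefined")
    return (100.0 * (perturbed_mean - baseline_mean) / baseline_mean) / (100.0 * perturbation)


def _sensitivity_scenario(design: SensitivityDesign,
                          env_overrides: Optional[dict] = None) -> ScenarioConfig:
    """Field scenario with all seasonal means pinned to the sensitivity
    baselines (optionally perturbed)."""
    env = dict(SENSITIVITY_BASELINES)
    if env_overrides:
        env.update(env_overrides)
    fieldenv = SeasonalField(
        soil_temp_c={s: env["soil_temp_c"] for s in ("autumn", "winter", "spring", "summer")},
        soil_moisture_pct={
            s: env["soil_moisture_pct"] for s in ("autumn", "winter", "spring", "summer")
        },
        # g/patch -> kg/m^2 so the seasonal replenishment hits the baseline
        manure_kg_m2={
            s: env["food_g_per_patch"] / 10.0 for s in ("autumn", "winter", "spring", "summer")
        },
    )
    cfg = field_scenario(
        duration_days=design.duration_days, replicates=design.replicates, fieldenv=fieldenv
    )
    cfg.name = "sensitivity-field"
    cfg.record_events = False
    return cfg


def _scenario_outputs(results) -> dict[str, float]:
    """Year-mean outputs of one replicate set.

    Biomass outputs are per-individual (time-mean of the daily mean adult and
    juvenile body mass), matching the per-individual reproductive output
    (cumulative cocoons per time-mean adult count); individual-level outputs
    are bounded by the physiology, so their elasticities reflect parameter
    effects rather than the amplitude of population booms and crashes.
    """
    out = {k: [] for k in OUTPUTS}
    for res in results:
        with np.errstate(invalid="ignore", divide="ignore"):
            adult_m = np.where(
                res.count_adult > 0,
                res.biomass_adult / np.maximum(res.count_adult, 1), np.nan)
            juv_m = np.where(
                res.count_juvenile > 0,
                res.biomass_juvenile / np.maximum(res.count_juvenile, 1), np.nan)
        mean_adults = float(np.mean(res.count_adult))
        cpa = res.cocoons_cum[-1] / mean_adults if mean_adults > 0 else np.nan
        out["adult_biomass"].append(float(np.nanmean(adult_m)))
        out["juvenile_biomass"].append(float(np.nanmean(juv_m)))
        out["cocoons_per_adult"].append(cpa)
    return out


def run_sensitivity(design: SensitivityDesign, seed: int,
                    params: Optional[EnergyBudgetParams] = None) -> pd.DataFrame:
    """Run the one-at-a-time sensitivity experiment.

    Returns a tidy frame with one row per (parameter, output): the
    sensitivity ratio computed from replicate means, and its standard error
    across paired replicates.
    """
    from . import abm_engine  # deferred to avoid an import cycle

    base_params = params or EnergyBudgetParams()
    baseline_cfg = _sensitivity_scenario(design)
    baseline_results = abm_engine.run(baseline_cfg, seed=seed, params=base_params)
    base_out = _scenario_outputs(baseline_results)

    rows = []
    for pname in design.parameters:
        if pname in ENV_PARAMETERS:
            overrides = dict(SENSITIVITY_BASELINES)
            if pname == "soil_T":
                # perturb on the kelvin scale
                t_k = (SENSITIVITY_BASELINES["soil_temp_c"] + CELSIUS_OFFSET) * (
                    1 + design.perturbation
                )
                overrides["soil_temp_c"] = t_k - CELSIUS_OFFSET
            elif pname == "soil_SM":
                overrides["soil_moisture_pct"] *= 1 + design.perturbation
            else:
                overrides["food_g_per_patch"] *= 1 + design.perturbation
            cfg = _sensitivity_scenario(design, overrides)
            pert_params = base_params
        else:
            cfg = _sensitivity_scenario(design)
            pert_params = base_params.replace(
                **{pname: getattr(base_params, pname) * (1 + design.perturbation)}
            )
        pert_seed = seed if design.paired_seeds else seed + 1
        pert_results = abm_engine.run(cfg, seed=pert_seed, params=pert_params)
        pert_out = _scenario_outputs(pert_results)

        for output in OUTPUTS:
            b = np.asarray(base_out[output], dtype=float)
            p = np.asarray(pert_out[output], dtype=float)
            ratio = sensitivity_ratio(np.nanmean(b), np.nanmean(p), design.perturbation)
            with np.errstate(divide="ignore", invalid="ignore"):
                per_pair = (100.0 * (p - b) / b) / (100.0 * design.perturbation)
            per_pair = per_pair[np.isfinite(per_pair)]
            se = float(np.std(per_pair, ddof=1) / np.sqrt(len(per_pair))) if len(per_pair) > 1 else np.nan
            rows.append(
                {"parameter": pname, "output": output, "sensitivity": float(ratio), "se": se}
            )
    return pd.DataFrame(rows)
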