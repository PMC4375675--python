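"""Daily scheduler binding individual energy budgets to the landscape.

Each simulated day: the environment updates (fixed laboratory conditions or
seasonal field draws, plus any scheduled feeding), hatched individuals are
processed in random order (move, feed from and deplete their patch, run the
energy-allocation cascade, transition to adult at the maturity mass), cocoons
incubate, background mortality is applied (field conditions), and observers
record stage-structured counts and biomasses.  Density dependence is emergent:
individuals interact only by depleting shared food patches and by mating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import energy_budget as eb
from .landscape import (
    Landscape,
    PATCH_SIDE_M,
    daily_field_draw,
    is_season_start,
    scheduled_feed,
    season_of_day,
    season_start_replenish,
)
from .params import EnergyBudgetParams
from .scenarios import CELSIUS_OFFSET, ScenarioConfig

STEP_LENGTH_M = 0.05  #: distance travelled per day by juveniles and adults
TURN_RANGE_DEG = 90.0  #: turning angle drawn uniformly from +/- this range


@dataclass(slots=True)
class Agent:
    """One individual: worm state plus continuous position and heading.

    ``progress`` is cocoon development in [0, 1] (unused after hatching).
    """

    id: int
    stage: eb.Stage
    M: float
    reserve: float
    x: float
    y: float
    heading: float
    repro_pool: float = 0.0
    progress: float = 0.0
    age: int = 0
    born_day: int = 0


def background_mortality_rate(SM: float, T: float) -> float:
    """Daily background mortality probability from soil moisture (%) and soil
    temperature (K); an empirical quadratic regression, clamped at zero."""
    if not 0 <= SM <= 100:
        raise ValueError(f"soil moisture must lie in [0, 100] %, got {SM}")
    rate_pct = (
        12.7 - 0.0010 * SM - 0.0861 * T + 0.000009 * SM * SM + 0.000147 * T * T
    )
    return max(rate_pct, 0.0) / 100.0


def move(agent: Agent, rng: np.random.Generator, landscape: Landscape) -> None:
    """Random walk step: turn by U(-90, 90) degrees, advance 5 cm, reflect at
    the arena boundary.  Cocoons never move."""
    if agent.stage is eb.Stage.COCOON:
        return
    _move(agent, rng.uniform(-TURN_RANGE_DEG, TURN_RANGE_DEG),
          landscape.width_m, landscape.height_m)


def _move(agent: Agent, turn_deg: float, width: float, height: float) -> None:
    agent.heading = (agent.heading + turn_deg) % 360.0
    rad = math.radians(agent.heading)
    x = agent.x + STEP_LENGTH_M * math.cos(rad)
    y = agent.y + STEP_LENGTH_M * math.sin(rad)
    if x < 0.0 or x > width:
        x = -x if x < 0.0 else 2.0 * width - x
        agent.heading = (180.0 - agent.heading) % 360.0
    if y < 0.0 or y > height:
        y = -y if y < 0.0 else 2.0 * height - y
        agent.heading = (-agent.heading) % 360.0
    agent.x = min(max(x, 0.0), width)
    agent.y = min(max(y, 0.0), height)


def mate_present(agent: Agent, population: list[Agent]) -> bool:
    """True iff at least one *other* adult currently occupies the same patch."""
    if agent.stage is not eb.Stage.ADULT:
        raise ValueError("mate_present applies to adults")
    ap = (int(agent.y / PATCH_SIDE_M), int(agent.x / PATCH_SIDE_M))
    for other in population:
        if other.id != agent.id and other.stage is eb.Stage.ADULT:
            if (int(other.y / PATCH_SIDE_M), int(other.x / PATCH_SIDE_M)) == ap:
                return True
    return False


@dataclass
class SimulationResult:
    """Daily observer records for one replicate."""

    count_cocoon: np.ndarray
    count_juvenile: np.ndarray
    count_adult: np.ndarray
    biomass_juvenile: np.ndarray
    biomass_adult: np.ndarray
    cocoons_cum: np.ndarray
    temperature_c: np.ndarray
    moisture_pct: np.ndarray
    food_total: np.ndarray
    n_initial: int
    initial_survivors: int
    events: list = field(default_factory=list)

    @property
    def days(self) -> np.ndarray:
        return np.arange(len(self.count_adult))

    def mean_individual_biomass(self) -> np.ndarray:
        """Daily mean body mass over hatched individuals (g); NaN when the
        hatched population is empty."""
        n = self.count_juvenile + self.count_adult
        total = self.biomass_juvenile + self.biomass_adult
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, total / np.maximum(n, 1), np.nan)

    def cocoons_per_adult(self) -> np.ndarray:
        """Daily cumulative cocoons produced per current adult."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.count_adult > 0,
                            self.cocoons_cum / np.maximum(self.count_adult, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        """Tidy daily records: one row per (day, stage)."""
        frames = []
        for stage, count, biomass in (
            ("cocoon", self.count_cocoon, None),
            ("juvenile", self.count_juvenile, self.biomass_juvenile),
            ("adult", self.count_adult, self.biomass_adult),
        ):
            frames.append(
                pd.DataFrame(
                    {
                        "day": self.days,
                        "stage": stage,
                        "count": count,
                        "biomass_g": biomass if biomass is not None else np.zeros_like(count, dtype=float),
                        "cocoons_cum": self.cocoons_cum,
                        "temperature_c": self.temperature_c,
                        "moisture_pct": self.moisture_pct,
                        "food_total_g": self.food_total,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True).sort_values(["day", "stage"], ignore_index=True)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["day", "event", "agent_id"])


class Simulation:
    """One replicate of a scenario; call :meth:`step` day by day or
    :meth:`run_all` for the whole duration."""

    def __init__(
        self,
        config: ScenarioConfig,
        seed_seq: np.random.SeedSequence,
        params: Optional[EnergyBudgetParams] = None,
    ):
        self.config = config
        self.params = params or EnergyBudgetParams()
        streams = seed_seq.spawn(5)
        self.rng_init = np.random.default_rng(streams[0])
        self.rng_env = np.random.default_rng(streams[1])
        self.rng_move = np.random.default_rng(streams[2])
        self.rng_mort = np.random.default_rng(streams[3])
        self.rng_shuffle = np.random.default_rng(streams[4])

        self.landscape = Landscape(config.arena_m2)
        if config.initial_food_g_per_patch:
            self.landscape.food += config.initial_food_g_per_patch
        self.day = 0
        self._next_id = 0
        self.agents: list[Agent] = []
        self.cocoons_cum = 0
        self._adult_patch_count: dict[tuple[int, int], int] = {}
        self._rec: dict[str, list] = {k: [] for k in (
            "cc", "cj", "ca", "bj", "ba", "cum", "t", "sm", "food")}
        self.events: list[tuple] = []
        self._stressed_params: Optional[EnergyBudgetParams] = None
        if config.exposure is not None:
            from .toxicology import stressed_parameters

            exp = config.exposure
            curves = {}
            if exp.k_growth is not None:
                curves["growth"] = exp.k_growth
            if exp.k_repro is not None:
                curves["reproduction"] = exp.k_repro
            self._stressed_params = stressed_parameters(
                self.params, exp.submodel, curves, exp.concentration
            )
        self._init_population()
        self.initial_ids = {a.id for a in self.agents if a.stage is not eb.Stage.COCOON}

    # -- setup ------------------------------------------------------------

    def _spawn_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def _init_population(self) -> None:
        p = self.params
        for cohort in self.config.initial_population:
            for _ in range(cohort.count):
                x = self.rng_init.uniform(0.0, self.landscape.width_m)
                y = self.rng_init.uniform(0.0, self.landscape.height_m)
                heading = self.rng_init.uniform(0.0, 360.0)
                if cohort.stage == "cocoon":
                    a = Agent(self._spawn_id(), eb.Stage.COCOON, p.Mc,
                              p.Mc * p.Ec, x, y, heading,
                              progress=0.0)
                else:
                    stage = eb.Stage.ADULT if cohort.stage == "adult" else eb.Stage.JUVENILE
                    if cohort.mass_g is not None:
                        mass = cohort.mass_g
                    elif stage is eb.Stage.ADULT:
                        mass = self.rng_init.uniform(p.Mp, p.Mm)
                    else:
                        mass = self.rng_init.uniform(p.Mb, p.Mp)
                    # mid-capacity reserve avoids immediate starvation or
                    # reserve-driven reproduction artefacts at start-up
                    a = Agent(self._spawn_id(), stage, mass, 0.5 * mass * p.Ec,
                              x, y, heading)
                    if stage is eb.Stage.ADULT:
                        key = self.landscape.patch_index(x, y)
                        self._adult_patch_count[key] = self._adult_patch_count.get(key, 0) + 1
                self.agents.append(a)

    # -- daily processes --------------------------------------------------

    def _effective_params(self) -> EnergyBudgetParams:
        exp = self.config.exposure
        if exp is not None and self.day >= exp.start_day and self._stressed_params is not None:
            return self._stressed_params
        return self.params

    def _environment(self) -> tuple[float, float]:
        cfg = self.config
        if cfg.environment_mode == "field":
            season = season_of_day(self.day)
            if is_season_start(self.day):
                season_start_replenish(self.landscape, cfg.field, season, self.rng_env)
            t_c, sm = daily_field_draw(cfg.field, season, self.rng_env)
        else:
            t_c, sm = cfg.temperature_c, cfg.moisture_pct
        return t_c, sm

    def _transfer(self) -> None:
        """Retain up to n surviving adults, discard everything else and
        (optionally) the remaining food."""
        tr = self.config.transfer
        adults = [a for a in self.agents if a.stage is eb.Stage.ADULT]
        keep_order = self.rng_shuffle.permutation(len(adults))
        keep = {adults[i].id for i in keep_order[: tr.n_adults]}
        for a in self.agents:
            if a.id not in keep:
                self.events.append((self.day, "transfer_removed", a.id))
        self.agents = [a for a in self.agents if a.id in keep]
        self._rebuild_adult_map()
        if tr.reset_food:
            self.landscape.food[:] = 0.0

    def _rebuild_adult_map(self) -> None:
        self._adult_patch_count.clear()
        for a in self.agents:
            if a.stage is eb.Stage.ADULT:
                key = self.landscape.patch_index(a.x, a.y)
                self._adult_patch_count[key] = self._adult_patch_count.get(key, 0) + 1

    def step(self) -> None:
        """Advance the simulation one day."""
        cfg = self.config
        p = self._effective_params()
        land = self.landscape
        food = land.food
        width, height = land.width_m, land.height_m
        cols = land.cols

        # (1) environment and feeding
        if cfg.transfer is not None and self.day == cfg.transfer.day:
            self._transfer()
        t_c, sm = self._environment()
        scheduled_feed(land, cfg.feeding, self.day)
        T = t_c + CELSIUS_OFFSET
        adult_map = self._adult_patch_count

        # (2) hatched individuals in random order: move, feed, allocate
        hatched = [a for a in self.agents if a.stage is not eb.Stage.COCOON]
        order = self.rng_shuffle.permutation(len(hatched))
        turns = self.rng_move.uniform(-TURN_RANGE_DEG, TURN_RANGE_DEG, size=len(hatched))
        new_cocoons: list[Agent] = []
        dead: set[int] = set()
        side = PATCH_SIDE_M
        for k, idx in enumerate(order):
            a = hatched[idx]
            is_adult = a.stage is eb.Stage.ADULT
            if is_adult:
                old_key = (int(a.y / side), int(a.x / side))
            _move(a, turns[k], width, height)
            row = int(a.y / side)
            col = int(a.x / side)
            if row >= land.rows:
                row = land.rows - 1
            if col >= cols:
                col = cols - 1
            key = (row, col)
            if is_adult and key != old_key:
                adult_map[old_key] -= 1
                adult_map[key] = adult_map.get(key, 0) + 1
            mate = is_adult and adult_map.get(key, 0) >= 2
            X = float(food[row, col])
            M, reserve, pool, ledger = eb._allocate_core(
                is_adult, a.M, a.reserve, a.repro_pool, T, X, mate, p
            )
            if ledger.ingested_g > 0.0:
                food[row, col] = X - ledger.ingested_g
            a.M = M
            a.reserve = reserve
            a.repro_pool = pool
            a.age += 1
            if ledger.cocoons_produced:
                self.cocoons_cum += ledger.cocoons_produced
                for _ in range(ledger.cocoons_produced):
                    c = Agent(self._spawn_id(), eb.Stage.COCOON, p.Mc, p.Mc * p.Ec,
                              a.x, a.y, 0.0, progress=0.0, born_day=self.day)
                    new_cocoons.append(c)
                    self.events.append((self.day, "cocoon_laid", c.id))
            if ledger.died:
                dead.add(a.id)
                self.events.append((self.day, "death_starvation", a.id))
                if is_adult:
                    adult_map[key] -= 1
            elif not is_adult and M >= p.Mp:
                a.stage = eb.Stage.ADULT
                adult_map[key] = adult_map.get(key, 0) + 1
                self.events.append((self.day, "matured", a.id))

        # (3) cocoon incubation and hatching
        maint_c = p.B0 * p.Mc ** 0.75 * math.exp(-p.E / (p.k_B * T))
        dev = math.exp((-p.E / p.k_B) * (1.0 / T - 1.0 / p.Tref)) / p.T0
        for a in self.agents:
            if a.stage is not eb.Stage.COCOON or a.id in dead:
                continue
            a.reserve -= maint_c
            a.age += 1
            if a.reserve < 0.0:
                dead.add(a.id)
                self.events.append((self.day, "death_incubation", a.id))
                continue
            a.progress += dev
            if a.progress >= 1.0 - 1e-9:
                a.stage = eb.Stage.JUVENILE
                a.M = p.Mb
                a.reserve = min(a.reserve, p.Mb * p.Ec)
                a.heading = float(self.rng_move.uniform(0.0, 360.0))
                self.events.append((self.day, "hatched", a.id))

        # (4) background mortality (juveniles and adults)
        if cfg.mortality_enabled:
            prob = background_mortality_rate(sm, T)
            if prob > 0.0:
                alive_hatched = [
                    a for a in self.agents
                    if a.stage is not eb.Stage.COCOON and a.id not in dead
                ]
                draws = self.rng_mort.random(len(alive_hatched))
                for a, u in zip(alive_hatched, draws):
                    if u < prob:
                        dead.add(a.id)
                        self.events.append((self.day, "death_background", a.id))
                        if a.stage is eb.Stage.ADULT:
                            key = (int(a.y / side), int(a.x / side))
                            adult_map[key] -= 1

        if dead:
            self.agents = [a for a in self.agents if a.id not in dead]
        self.agents.extend(new_cocoons)

        # (5) observers
        cc = cj = ca = 0
        bj = ba = 0.0
        for a in self.agents:
            if a.stage is eb.Stage.COCOON:
                cc += 1
            elif a.stage is eb.Stage.JUVENILE:
                cj += 1
                bj += a.M
            else:
                ca += 1
                ba += a.M
        r = self._rec
        r["cc"].append(cc)
        r["cj"].append(cj)
        r["ca"].append(ca)
        r["bj"].append(bj)
        r["ba"].append(ba)
        r["cum"].append(self.cocoons_cum)
        r["t"].append(t_c)
        r["sm"].append(sm)
        r["food"].append(land.total_food())
        self.day += 1

    def run_all(self) -> SimulationResult:
        for _ in range(self.config.duration_days):
            self.step()
        return self.result()

    def result(self) -> SimulationResult:
        r = self._rec
        alive_ids = {a.id for a in self.agents}
        return SimulationResult(
            count_cocoon=np.asarray(r["cc"], dtype=int),
            count_juvenile=np.asarray(r["cj"], dtype=int),
            count_adult=np.asarray(r["ca"], dtype=int),
            biomass_juvenile=np.asarray(r["bj"], dtype=float),
            biomass_adult=np.asarray(r["ba"], dtype=float),
            cocoons_cum=np.asarray(r["cum"], dtype=int),
            temperature_c=np.asarray(r["t"], dtype=float),
            moisture_pct=np.asarray(r["sm"], dtype=float),
            food_total=np.asarray(r["food"], dtype=float),
            n_initial=len(self.initial_ids),
            initial_survivors=len(self.initial_ids & alive_ids),
            events=list(self.events) if self.config.record_events else [],
        )


def run(
    config: ScenarioConfig,
    seed: int,
    n_replicates: Optional[int] = None,
    params: Optional[EnergyBudgetParams] = None,
) -> list[SimulationResult]:
    """Run ``n_replicates`` independent replicates of a scenario.

    Replicates draw from sub-streams of one master seed, so results are
    deterministic given (config, seed) and replicate streams are mutually
    independent.
    """
    n = n_replicates if n_replicates is not None else config.replicates
    master = np.random.SeedSequence(seed)
    reps = master.spawn(n)
    out = []
    for ss in reps:
        sim = Simulation(config, ss, params=params)
        out.append(sim.run_all())
    return out
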