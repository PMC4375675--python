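"""Individual-level metabolic equations and the daily energy-allocation cascade.

Every function here is pure: worm state goes in, a new state and an itemised
energy ledger come out.  The cascade follows the physiological-ecology
priority ordering — maintenance first, then (for mated adults) reproduction,
then growth, with any remainder stored as reserve.  Reserves fund maintenance
and reproduction when food is short, but only down to half of the reserve
capacity ``M*Ec``; below that threshold the worm is starving and catabolises
structural tissue to cover maintenance, dying when its mass falls to the
birth mass.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

from .params import EnergyBudgetParams


class Stage(enum.Enum):
    """Life-cycle stage; transitions are monotone cocoon -> juvenile -> adult."""

    COCOON = "cocoon"
    JUVENILE = "juvenile"
    ADULT = "adult"


@dataclass(frozen=True)
class WormState:
    """State of a hatched individual.

    stage: juvenile or adult; M: structural mass (g); reserve: stored energy
    (kJ), bounded by ``M*Ec``; repro_pool: energy accumulated towards the next
    cocoon (kJ); age in days.
    """

    stage: Stage
    M: float
    reserve: float = 0.0
    repro_pool: float = 0.0
    age: int = 0


@dataclass(frozen=True)
class CocoonState:
    """State of an incubating cocoon: remaining reserve (kJ) and
    development progress in [0, 1]."""

    reserve: float
    progress: float = 0.0
    age: int = 0


@dataclass(frozen=True)
class DailyEnvironment:
    """Conditions experienced by one individual on one day.

    T: soil temperature (K); SM: soil moisture (%); X: food density of the
    occupied patch (g per 0.01 m^2); C: pesticide concentration (mg/kg).
    """

    T: float
    SM: float = 60.0
    X: float = 0.0
    C: float = 0.0

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError(f"temperature must be positive kelvin, got {self.T}")
        if not 0 <= self.SM <= 100:
            raise ValueError(f"soil moisture must lie in [0, 100] %, got {self.SM}")
        if self.X < 0:
            raise ValueError(f"food density must be non-negative, got {self.X}")
        if self.C < 0:
            raise ValueError(f"concentration must be non-negative, got {self.C}")


class EnergyLedger(NamedTuple):
    """Itemised account of one day's energy flows for one individual (kJ).

    The entries satisfy, to floating-point accuracy::

        assimilated + reserve_withdrawn + Ec*catabolised_g
            == maintenance_paid + repro_spent + growth_spent
               + reserve_deposited + discarded

    ``reserve_delta = reserve_deposited - reserve_withdrawn - reserve_clamp_loss``
    and ``mass_delta = growth_spent/(Ec+Es) - catabolised_g``.
    """

    ingested_g: float
    assimilated: float
    maintenance_paid: float
    repro_spent: float
    growth_spent: float
    reserve_deposited: float
    reserve_withdrawn: float
    reserve_clamp_loss: float
    catabolised_g: float
    discarded: float
    reserve_delta: float
    mass_delta: float
    cocoons_produced: int
    died: bool


def arrhenius_factor(T: float, params: EnergyBudgetParams) -> float:
    """Temperature correction ``exp((-E/k_B)(1/T - 1/Tref))``.

    Equals 1 at the reference temperature and increases monotonically with T.
    """
    if not T > 0:
        raise ValueError(f"temperature must be positive kelvin, got {T}")
    return math.exp((-params.E / params.k_B) * (1.0 / T - 1.0 / params.Tref))


def maintenance_rate(M: float, T: float, params: EnergyBudgetParams,
                     B0: Optional[float] = None) -> float:
    """Basal metabolic rate ``B = B0 * M^(3/4) * exp(-E/(k_B*T))`` in kJ/day.

    Note the absolute Arrhenius form here; the other rate equations use the
    relative form anchored at Tref.
    """
    if not M > 0:
        raise ValueError(f"mass must be positive, got {M}")
    if not T > 0:
        raise ValueError(f"temperature must be positive kelvin, got {T}")
    b0 = params.B0 if B0 is None else B0
    return b0 * M ** 0.75 * math.exp(-params.E / (params.k_B * T))


def ingestion_rate(M: float, T: float, X: float, params: EnergyBudgetParams,
                   IGmax: Optional[float] = None) -> float:
    """Ingestion in g food/day: type II functional response in food density X,
    surface-area scaling M^(2/3), relative Arrhenius temperature scaling."""
    if not M > 0:
        raise ValueError(f"mass must be positive, got {M}")
    if X < 0:
        raise ValueError(f"food density must be non-negative, got {X}")
    ig = params.IGmax if IGmax is None else IGmax
    return ig * arrhenius_factor(T, params) * X / (params.h + X) * M ** (2.0 / 3.0)


def assimilated_energy(ingested: float, params: EnergyBudgetParams) -> float:
    """Energy made available from ingested food: ``ingested * Ex * Ae`` (kJ)."""
    if ingested < 0:
        raise ValueError(f"ingested mass must be non-negative, got {ingested}")
    return ingested * params.Ex * params.Ae


def max_growth_increment(M: float, T: float, params: EnergyBudgetParams,
                         rB: Optional[float] = None) -> float:
    """Maximum daily mass gain ``rB * f(T) * (Mm^(1/3) M^(2/3) - M)`` in g/day.

    Zero at the asymptotic mass; masses above Mm yield a clamped zero
    increment.  Realising a gain dM costs ``dM * (Ec + Es)`` kJ.
    """
    if not M > 0:
        raise ValueError(f"mass must be positive, got {M}")
    r = params.rB if rB is None else rB
    inc = r * arrhenius_factor(T, params) * (params.Mm ** (1.0 / 3.0) * M ** (2.0 / 3.0) - M)
    return max(inc, 0.0)


def vb_mass_at_age(t: float, params: EnergyBudgetParams) -> float:
    """Closed-form von Bertalanffy mass at age ``t`` days under optimal
    conditions at the reference temperature."""
    if t < 0:
        raise ValueError(f"age must be non-negative, got {t}")
    shape = 1.0 - (1.0 - (params.Mb / params.Mm) ** (1.0 / 3.0)) * math.exp(-params.rB * t / 3.0)
    return params.Mm * shape ** 3


def max_reproduction_allocation(M: float, T: float, params: EnergyBudgetParams,
                                rm: Optional[float] = None) -> float:
    """Maximum daily energy allocation to reproduction for an adult:
    ``rm * f(T) * M`` (kJ/day), linear in adult mass."""
    if not M > 0:
        raise ValueError(f"mass must be positive, got {M}")
    r = params.rm if rm is None else rm
    return r * arrhenius_factor(T, params) * M


def _allocate_core(
    is_adult: bool,
    M: float,
    reserve: float,
    repro_pool: float,
    T: float,
    X: float,
    mate_present: bool,
    p: EnergyBudgetParams,
) -> tuple:
    """Scalar fast path of the daily allocation cascade.

    Returns ``(M, reserve, repro_pool, ledger)``.  Used directly by the ABM
    engine to avoid per-agent dataclass overhead; :func:`allocate_day` is the
    public wrapper.
    """
    f = math.exp((-p.E / p.k_B) * (1.0 / T - 1.0 / p.Tref))

    # (1) ingestion and assimilation; intake can never exceed the patch stock
    if X > 0.0:
        intake = p.IGmax * f * X / (p.h + X) * M ** (2.0 / 3.0)
        if intake > X:
            intake = X
    else:
        intake = 0.0
    assimilated = intake * p.Ex * p.Ae
    avail = assimilated

    # (2) maintenance: from assimilated energy first, then from reserve down
    # to the half-capacity threshold
    B = p.B0 * M ** 0.75 * math.exp(-p.E / (p.k_B * T))
    half = 0.5 * M * p.Ec
    from_food = B if avail >= B else avail
    avail -= from_food
    deficit = B - from_food
    withdrawn = 0.0
    if deficit > 0.0:
        w = reserve - half
        if w > deficit:
            w = deficit
        if w > 0.0:
            reserve -= w
            withdrawn += w
            deficit -= w

    # (3) reproduction: adults with a mate, funded from assimilated energy
    # then from reserve above the half threshold
    repro = 0.0
    cocoons = 0
    if is_adult and mate_present:
        cap = p.rm * f * M
        r1 = cap if avail >= cap else avail
        avail -= r1
        need = cap - r1
        if need > 0.0:
            r2 = reserve - half
            if r2 > need:
                r2 = need
            if r2 > 0.0:
                reserve -= r2
                withdrawn += r2
                repro = r1 + r2
            else:
                repro = r1
        else:
            repro = r1
        if repro > 0.0:
            repro_pool += repro
            cost = p.Mc * (p.Ec + p.Es)
            if repro_pool >= cost:
                cocoons = int(repro_pool / cost)
                repro_pool -= cocoons * cost

    # (4) growth: funded only from assimilated energy
    growth_spent = 0.0
    if avail > 0.0:
        inc = p.rB * f * (p.Mm ** (1.0 / 3.0) * M ** (2.0 / 3.0) - M)
        if inc > 0.0:
            g_cap = inc * (p.Ec + p.Es)
            growth_spent = g_cap if avail >= g_cap else avail
            avail -= growth_spent
    new_M = M + growth_spent / (p.Ec + p.Es)

    # (5) surplus into reserve, capped at capacity; any overflow is discarded
    deposited = 0.0
    discarded = 0.0
    if avail > 0.0:
        room = new_M * p.Ec - reserve
        deposited = room if avail >= room else avail
        if deposited < 0.0:
            deposited = 0.0
        reserve += deposited
        discarded = avail - deposited

    # (6) starvation: remaining maintenance deficit is met by catabolising
    # tissue at Ec per gram
    catabolised = 0.0
    if deficit > 0.0:
        catabolised = deficit / p.Ec
        new_M -= catabolised

    # reserve capacity shrinks with mass; excess is clamped off
    clamp_loss = reserve - new_M * p.Ec
    if clamp_loss > 0.0:
        reserve -= clamp_loss
    else:
        clamp_loss = 0.0

    # (7) death at birth mass, reachable only through tissue loss
    died = new_M < p.Mb

    ledger = EnergyLedger(
        ingested_g=intake,
        assimilated=assimilated,
        maintenance_paid=B,
        repro_spent=repro,
        growth_spent=growth_spent,
        reserve_deposited=deposited,
        reserve_withdrawn=withdrawn,
        reserve_clamp_loss=clamp_loss,
        catabolised_g=catabolised,
        discarded=discarded,
        reserve_delta=deposited - withdrawn - clamp_loss,
        mass_delta=new_M - M,
        cocoons_produced=cocoons,
        died=died,
    )
    return new_M, reserve, repro_pool, ledger


def allocate_day(
    state: WormState,
    env: DailyEnvironment,
    mate_present: bool,
    params: EnergyBudgetParams,
) -> tuple[WormState, EnergyLedger]:
    """Advance a hatched individual through one day's energy allocation.

    Applies, in order: ingestion/assimilation; maintenance (assimilated
    energy first, then reserve down to the half threshold); for mated adults,
    reproduction up to ``rm f(T) M`` with the same reserve rule, converting
    each accumulated ``Mc (Ec+Es)`` kJ into one cocoon; growth up to the von
    Bertalanffy increment from assimilated energy only; storage of the
    remainder; tissue catabolism for any unpaid maintenance; and the
    starvation-death check at the birth mass.
    """
    if state.stage is Stage.COCOON:
        raise ValueError("allocate_day applies to hatched stages; use cocoon_day")
    M, reserve, pool, ledger = _allocate_core(
        state.stage is Stage.ADULT,
        state.M,
        state.reserve,
        state.repro_pool,
        env.T,
        env.X,
        mate_present,
        params,
    )
    new_state = WormState(
        stage=state.stage, M=M, reserve=reserve, repro_pool=pool, age=state.age + 1
    )
    return new_state, ledger


def cocoon_day(
    state: CocoonState, T: float, params: EnergyBudgetParams
) -> tuple[Optional[CocoonState], Optional[WormState], bool]:
    """Advance a cocoon one day: pay maintenance from the endowment and
    accumulate temperature-dependent development.

    Returns ``(cocoon, hatchling, died)``: exactly one of the first two is
    non-None unless the cocoon died.  Development advances by ``f(T)/T0`` per
    day, so incubation takes T0 days at the reference temperature; the
    hatchling emerges at the birth mass carrying the residual reserve
    (clamped to the hatchling's capacity ``Mb*Ec``).
    """
    maint = maintenance_rate(params.Mc, T, params)
    reserve = state.reserve - maint
    if reserve < 0.0:
        return None, None, True
    progress = state.progress + arrhenius_factor(T, params) / params.T0
    # tolerance absorbs accumulation error so T0 daily steps at Tref hatch
    # on day T0 exactly
    if progress >= 1.0 - 1e-9:
        hatchling = WormState(
            stage=Stage.JUVENILE,
            M=params.Mb,
            reserve=min(max(reserve, 0.0), params.Mb * params.Ec),
            repro_pool=0.0,
            age=0,
        )
        return None, hatchling, False
    return CocoonState(reserve=reserve, progress=progress, age=state.age + 1), None, False


def initial_cocoon(params: EnergyBudgetParams) -> CocoonState:
    """A freshly laid cocoon with its full energy endowment ``Mc*Ec``."""
    return CocoonState(reserve=params.Mc * params.Ec, progress=0.0, age=0)
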