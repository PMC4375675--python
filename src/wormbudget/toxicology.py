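"""Dose-response estimation and the four toxicity submodels.

Sublethal pesticide effects are summarised by exponentially declining
dose-response curves ``R(C) = exp(k_tox * C)`` fitted without intercept, so
the control response is 1 by construction.  A toxicity submodel (T1-T4) is a
hypothesis about which physiological parameters the chemical acts on:

========  ==========================  ==========================================
submodel  stressed parameters         predicted signature
========  ==========================  ==========================================
T1        IGmax                       growth more reduced than reproduction
T2        IGmax and rm                growth and reproduction similarly reduced
T3        rB and rm                   reproduction more reduced than growth
T4        B0 (raised above 100 mg/kg) accelerated weight loss when food is short
========  ==========================  ==========================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .params import EnergyBudgetParams

SUBMODELS = ("T1", "T2", "T3", "T4")

#: Number of fitted toxicity coefficients per submodel (used by AICc).
N_TOX_COEFFICIENTS = {"T1": 1, "T2": 2, "T3": 2, "T4": 1}

#: Concentration (mg/kg) above which T4 raises maintenance costs.
T4_THRESHOLD = 100.0


@dataclass(frozen=True)
class DoseResponseCurve:
    """Fitted exponential dose-response for one life-cycle trait.

    ``k_tox`` is the chemical-specific coefficient (per mg/kg; negative for
    declining traits); ``r_squared`` and ``n_obs`` are fit diagnostics.
    """

    k_tox: float
    trait: str
    r_squared: float = float("nan")
    n_obs: int = 0

    def response(self, C: float) -> float:
        """Fraction of the control value at concentration C; R(0) = 1."""
        return math.exp(self.k_tox * C)


def fit_dose_response(
    table: pd.DataFrame,
    trait: str = "growth",
    concentration_col: str = "concentration",
    value_col: str = "value",
) -> DoseResponseCurve:
    """Fit ``R(C) = exp(k_tox C)`` to a dose-response observation table.

    Trait values are first converted to fractions of the control mean (the
    mean value at C = 0), then ``ln(fraction)`` is regressed on C by least
    squares *without intercept*, which forces the fitted curve through
    R(0) = 1.

    Parameters
    ----------
    table:
        Rows of (concentration mg/kg, trait value), one row per replicate;
        must include control rows at concentration 0 and strictly positive
        trait values.
    """
    c = np.asarray(table[concentration_col], dtype=float)
    v = np.asarray(table[value_col], dtype=float)
    if np.any(v <= 0):
        raise ValueError("dose-response trait values must be strictly positive")
    if not np.any(c == 0):
        raise ValueError("dose-response table must include a control (concentration 0)")
    if len(np.unique(c)) < 2:
        raise ValueError("dose-response table needs at least two distinct concentrations")
    control = v[c == 0].mean()
    y = np.log(v / control)
    ssc = float(np.dot(c, c))
    k = float(np.dot(c, y) / ssc)
    resid = y - k * c
    sst = float(np.dot(y, y))
    r2 = 1.0 - float(np.dot(resid, resid)) / sst if sst > 0 else 1.0
    return DoseResponseCurve(k_tox=k, trait=trait, r_squared=r2, n_obs=len(v))


CurveLike = Union[DoseResponseCurve, float]


def _response(curve: CurveLike, C: float) -> float:
    k = curve.k_tox if isinstance(curve, DoseResponseCurve) else float(curve)
    return math.exp(k * C)


def stressed_parameters(
    base: EnergyBudgetParams,
    submodel: str,
    curves: dict[str, CurveLike],
    C: float,
) -> EnergyBudgetParams:
    """Physiological parameters under exposure to concentration C.

    ``curves`` maps trait names ("growth", "reproduction") to fitted
    dose-response curves (or bare k_tox coefficients).  T1 scales IGmax by
    the growth curve; T2 scales IGmax by the growth curve and rm by the
    reproduction curve; T3 scales rB and rm likewise; T4 leaves everything
    unchanged up to 100 mg/kg and raises B0 linearly (B0 * 0.01 * C) above
    it — the step at the threshold is part of the rule.
    """
    if submodel not in SUBMODELS:
        raise ValueError(f"unknown toxicity submodel {submodel!r}")
    if C < 0:
        raise ValueError("concentration must be non-negative")

    def need(trait: str) -> CurveLike:
        if trait not in curves:
            raise ValueError(f"submodel {submodel} requires a {trait!r} dose-response curve")
        return curves[trait]

    if submodel == "T1":
        return base.replace(IGmax=base.IGmax * _response(need("growth"), C))
    if submodel == "T2":
        return base.replace(
            IGmax=base.IGmax * _response(need("growth"), C),
            rm=base.rm * _response(need("reproduction"), C),
        )
    if submodel == "T3":
        return base.replace(
            rB=base.rB * _response(need("growth"), C),
            rm=base.rm * _response(need("reproduction"), C),
        )
    # T4
    if C <= T4_THRESHOLD:
        return base
    return base.replace(B0=base.B0 * 0.01 * C)


def predicted_observation(
    submodel: str,
    scenario,
    curves: dict[str, CurveLike],
    C: float,
    seed: int,
    observation_days: Sequence[int],
    start_day: int = 0,
    n_replicates: Optional[int] = None,
) -> pd.DataFrame:
    """Simulated trait-vs-time table for one submodel at one concentration.

    Runs the laboratory scenario with the stressed parameters applied from
    ``start_day`` and returns, at each observation day, the replicate-mean
    individual biomass ("growth") and cumulative cocoons per adult
    ("reproduction"), in long format keyed by (time, concentration, trait).
    """
    import dataclasses

    from . import abm_engine
    from .scenarios import ExposureConfig

    cfg = dataclasses.replace(scenario)
    k_growth = curves.get("growth")
    k_repro = curves.get("reproduction")
    cfg.exposure = ExposureConfig(
        submodel=submodel,
        concentration=C,
        start_day=start_day,
        k_growth=(k_growth.k_tox if isinstance(k_growth, DoseResponseCurve) else k_growth),
        k_repro=(k_repro.k_tox if isinstance(k_repro, DoseResponseCurve) else k_repro),
    )
    results = abm_engine.run(cfg, seed=seed, n_replicates=n_replicates)
    growth = np.nanmean([r.mean_individual_biomass() for r in results], axis=0)
    repro = np.nanmean([r.cocoons_per_adult() for r in results], axis=0)
    rows = []
    for d in observation_days:
        i = int(d)
        rows.append({"time": d, "concentration": C, "trait": "growth", "value": growth[i]})
        rows.append({"time": d, "concentration": C, "trait": "reproduction", "value": repro[i]})
    return pd.DataFrame(rows)
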