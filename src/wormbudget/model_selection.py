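"""Small-sample AIC comparison of toxicity submodels against observations.

Goodness of fit is measured on normalised residuals (model minus observed,
divided by observed).  Submodels are ranked by AICc differences; the evidence
ratio exp(delta/2) gives the odds against a poorer submodel relative to the
best one.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

ALIGNMENT_KEYS = ("time", "concentration", "trait")


def aicc(residuals: Sequence[float], n_params: int) -> float:
    """Small-sample Akaike information criterion.

    ``AICc = n ln(sigma^2) + 2 n' n / (n - n' - 1)`` with
    ``sigma^2 = sum(residual^2)/n`` (natural log).  A perfect fit
    (all residuals zero) returns ``-inf`` as the sentinel minimal value.
    """
    res = np.asarray(residuals, dtype=float)
    n = len(res)
    if n <= n_params + 1:
        raise ValueError(
            f"AICc undefined: need n > n' + 1, got n={n}, n'={n_params}"
        )
    sigma2 = float(np.dot(res, res)) / n
    penalty = 2.0 * n_params * n / (n - n_params - 1)
    if sigma2 == 0.0:
        return float("-inf")
    return n * math.log(sigma2) + penalty


def residuals(
    model_table: pd.DataFrame,
    observation_table: pd.DataFrame,
    keys: Sequence[str] = ALIGNMENT_KEYS,
    value_col: str = "value",
) -> np.ndarray:
    """Normalised differences ``(model - observed)/observed`` between two
    long-format tables matched on ``keys``.

    Every observation must have exactly one matching model row; observed
    values of zero are rejected (normalisation undefined).
    """
    keys = list(keys)
    m = model_table[keys + [value_col]].rename(columns={value_col: "model"})
    o = observation_table[keys + [value_col]].rename(columns={value_col: "observed"})
    merged = o.merge(m, on=keys, how="left", validate="one_to_one")
    if merged["model"].isna().any():
        missing = merged.loc[merged["model"].isna(), keys].to_dict("records")
        raise ValueError(f"model table has no rows for observations: {missing[:5]}")
    obs = merged["observed"].to_numpy(dtype=float)
    if np.any(obs == 0):
        raise ValueError("observed values of zero cannot be normalised")
    return (merged["model"].to_numpy(dtype=float) - obs) / obs


def evidence_ratio(delta: float) -> float:
    """Odds against a submodel with AICc difference ``delta`` from the best."""
    return math.exp(delta / 2.0)


def compare(
    submodel_fits: Mapping[str, Union[float, tuple]],
) -> pd.DataFrame:
    """Rank submodels by AICc.

    ``submodel_fits`` maps submodel id to either a precomputed AICc value or
    a ``(residuals, n_params)`` pair.  Returns a frame indexed ascending by
    delta with columns aicc, delta, evidence_ratio; the best submodel has
    delta 0 and evidence ratio 1.
    """
    if len(submodel_fits) < 2:
        raise ValueError("compare needs at least two submodels")
    values = {}
    for name, fit in submodel_fits.items():
        values[name] = float(fit) if np.isscalar(fit) else aicc(*fit)
    best = min(values.values())
    rows = []
    for name, a in values.items():
        # a perfect-fit sentinel (-inf) yields delta 0 for itself and +inf
        # for every competitor
        delta = 0.0 if a == best else a - best
        rows.append(
            {
                "submodel": name,
                "aicc": a,
                "delta": delta,
                "evidence_ratio": evidence_ratio(delta),
            }
        )
    df = pd.DataFrame(rows).sort_values(["delta", "submodel"], ignore_index=True)
    return df
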