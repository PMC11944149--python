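"""Flux prediction from the fitted mode-usage distribution.

Once the usage probabilities p_j are known, the overall growth stoichiometry
is the probability-weighted mix of the modes' external equations,
``ν_i = Σ_j ν_{j,i}·p_j`` (glucose stays exactly −1 because every mode is
glucose-normalized), external rates are ``r_i = ξ̂·ν_i`` and internal
reaction rates are ``r_k = ξ̂·Σ_j p_j·v_{k,j}`` with ``v_{k,j}`` mode j's
glucose-normalized net flux through reaction k. Rates are reported relative
to the glucose uptake rate (glucose = 100 %) by default; the predicted rate
vector always lies in the nullspace of S_int.

Comparison with measured fluxes is an ordinary least-squares regression on
the percent-of-glucose scale, with outlier exclusion explicit, user-supplied
and recorded in the result — never automatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .efm import ElementaryModeSet


class ComparisonError(ValueError):
    """Not enough shared reactions to regress after exclusions."""


@dataclass
class FluxPrediction:
    """Predicted rate structure for one strain."""

    overall_stoich: dict[str, float]  # per mol glucose
    external_rates: dict[str, float]  # mmol/(h·gCDW) signed
    internal_rates: dict[str, float]  # mmol/(h·gCDW) signed, per reaction
    xi_hat: float  # mol/(h·gCDW)

    def internal_percent(self) -> dict[str, float]:
        """Internal rates relative to glucose uptake = 100 %."""
        scale = 100.0 / (self.xi_hat * 1000.0)
        return {k: v * scale for k, v in self.internal_rates.items()}

    def external_percent(self) -> dict[str, float]:
        scale = 100.0 / (self.xi_hat * 1000.0)
        return {k: v * scale for k, v in self.external_rates.items()}


@dataclass
class FluxComparison:
    """Measured-vs-predicted regression summary."""

    pairs: pd.DataFrame  # reaction, measured, predicted, residual
    excluded_ids: list[str]
    r_squared: float
    slope: float
    intercept: float

    def to_frame(self) -> pd.DataFrame:
        return self.pairs


def overall_stoichiometry(
    p: Sequence[float], modes: ElementaryModeSet
) -> dict[str, float]:
    """Overall growth-equation coefficients ``ν_i = Σ_j p_j·ν_{j,i}``."""
    p = np.asarray(p, dtype=float)
    if len(p) != len(modes.modes):
        raise ValueError("probability vector length != number of modes")
    out: dict[str, float] = {}
    for pj, mode in zip(p, modes.modes):
        for met, coeff in mode.external_stoich.items():
            out[met] = out.get(met, 0.0) + pj * float(coeff)
    return out


def external_rates(
    p: Sequence[float], modes: ElementaryModeSet, xi_hat: float
) -> dict[str, float]:
    """Specific external production rates ``r_i = ξ̂·Σ_j p_j·ν_{j,i}``.

    ξ̂ in mol/(h·gCDW); rates returned in mmol/(h·gCDW), signed (uptake
    negative).
    """
    nu = overall_stoichiometry(p, modes)
    return {met: xi_hat * 1000.0 * coeff for met, coeff in nu.items()}


def internal_rates(
    p: Sequence[float], modes: ElementaryModeSet, xi_hat: float
) -> dict[str, float]:
    """Specific internal reaction rates ``r_k = ξ̂·Σ_j p_j·v_{k,j}``.

    Reversible split pairs are already recombined in the mode vectors, so
    the result is the signed net flux per reaction id, mmol/(h·gCDW).
    """
    p = np.asarray(p, dtype=float)
    if len(p) != len(modes.modes):
        raise ValueError("probability vector length != number of modes")
    rates = dict.fromkeys(modes.reaction_ids, 0.0)
    for pj, mode in zip(p, modes.modes):
        for rid, v in mode.flux.items():
            rates[rid] += pj * float(v)
    return {rid: xi_hat * 1000.0 * v for rid, v in rates.items()}


def predict_fluxes(
    p: Sequence[float], modes: ElementaryModeSet, xi_hat: float
) -> FluxPrediction:
    """Bundle overall stoichiometry plus external and internal rates."""
    return FluxPrediction(
        overall_stoich=overall_stoichiometry(p, modes),
        external_rates=external_rates(p, modes, xi_hat),
        internal_rates=internal_rates(p, modes, xi_hat),
        xi_hat=xi_hat,
    )


def compare_to_measured(
    predicted: Mapping[str, float],
    measured: Mapping[str, float] | pd.DataFrame,
    exclusions: Iterable[str] = (),
) -> FluxComparison:
    """OLS regression of measured against predicted reaction rates.

    ``measured`` maps reaction id to rate (or is a DataFrame with columns
    ``reaction`` and ``value``); both sides should be on the same scale
    (conventionally percent of glucose uptake). Excluded reactions are
    dropped from the regression but echoed in the result.

    Raises
    ------
    ComparisonError
        If fewer than 3 shared reactions remain after exclusion.
    """
    if isinstance(measured, pd.DataFrame):
        measured = dict(zip(measured["reaction"], measured["value"]))
    exclusions = sorted(set(exclusions))
    shared = [
        rid for rid in measured if rid in predicted and rid not in exclusions
    ]
    if len(shared) < 3:
        raise ComparisonError(
            f"only {len(shared)} shared reactions after exclusions; need >= 3"
        )
    meas = np.array([float(measured[r]) for r in shared])
    pred = np.array([float(predicted[r]) for r in shared])
    if np.allclose(pred, pred[0]):
        raise ComparisonError("predicted rates are constant; regression undefined")
    fit = stats.linregress(pred, meas)
    residuals = meas - (fit.slope * pred + fit.intercept)
    pairs = pd.DataFrame(
        {
            "reaction": shared,
            "measured": meas,
            "predicted": pred,
            "residual": residuals,
        }
    )
    return FluxComparison(
        pairs=pairs,
        excluded_ids=list(exclusions),
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )
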