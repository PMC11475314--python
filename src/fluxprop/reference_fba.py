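"""The noiseless reference state: "true" growth rate and completed rate set.

Construction mirrors how experimental datasets are turned into FBA
constraints: every measured exchange is pinned to its dataset rate (equality
bounds — the reference is a noiseless construct, uncertainty intervals enter
only during propagation), unmeasured uptakes (cysteine and tryptophan, for
which quantitative data are typically unavailable) and any dataset-listed
unconstrained exchanges stay at the network defaults, and biomass production
is maximized.  The unmeasured uptakes are then estimated by fixing growth at
the optimum and minimizing their total uptake magnitude; when such an amino
acid is consumed only by biomass synthesis the estimate equals the biomass
requirement mu * b_i exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from fluxprop.model_core import (
    MetabolicNetwork,
    fix_and_minimize,
    solve_fba,
)
from fluxprop.synthetic_data import DEFAULT_UNMEASURED, CellLineDataset


@dataclass(frozen=True)
class ReferenceState:
    """Reference growth rate and the completed exchange-rate set."""

    mu_ref: float
    rates_complete: dict[str, float]
    flux_vector: pd.Series | None = None


class ReferenceInfeasibleError(RuntimeError):
    """The measured rates admit no steady-state flux distribution."""


def build_reference(
    dataset: CellLineDataset,
    network: MetabolicNetwork,
    unmeasured: Iterable[str] = DEFAULT_UNMEASURED,
) -> ReferenceState:
    """Constrain measured exchanges, maximize biomass, complete missing uptakes.

    Returns the reference growth rate mu_ref and ``rates_complete`` covering
    every metabolite simulated downstream (measured rates plus LP-estimated
    unmeasured uptakes).
    """
    unmeasured = [m for m in unmeasured if m in network.biomass_precursors()]
    bounds = _pinned_bounds(dataset, network)
    res = solve_fba(network, bounds, objective=network.biomass_reaction_id, sense="max")
    if not res.optimal:
        pins = {m: dataset.rates[m] for m in sorted(dataset.rates)}
        raise ReferenceInfeasibleError(
            f"reference FBA {res.status} for {dataset.name!r}; pinned exchanges: {pins}"
        )
    mu_ref = res.objective_value
    estimated = fix_and_minimize(network, bounds, mu_ref, unmeasured) if unmeasured else {}
    rates = dict(dataset.rates)
    rates.update(estimated)
    return ReferenceState(mu_ref=mu_ref, rates_complete=rates, flux_vector=res.fluxes)


def _pinned_bounds(dataset: CellLineDataset, network: MetabolicNetwork) -> dict[str, tuple[float, float]]:
    bounds = {}
    for met, q in dataset.rates.items():
        if met in dataset.unconstrained_exchanges:
            continue
        try:
            rid = network.exchange_map[met]
        except KeyError:
            raise KeyError(f"no exchange reaction for measured metabolite {met!r}") from None
        bounds[rid] = (q, q)
    return bounds


def save_reference(ref: ReferenceState, rates_csv: str, scalars_json: str) -> None:
    """Serialize to a rates CSV + scalar JSON pair."""
    pd.DataFrame(
        {"metabolite": list(ref.rates_complete), "q_mmol_per_gdw_h": list(ref.rates_complete.values())}
    ).to_csv(rates_csv, index=False)
    with open(scalars_json, "w") as fh:
        json.dump({"mu_ref_per_h": ref.mu_ref}, fh, indent=1)


def load_reference(rates_csv: str, scalars_json: str) -> ReferenceState:
    table = pd.read_csv(rates_csv)
    with open(scalars_json) as fh:
        scalars = json.load(fh)
    rates = dict(zip(table["metabolite"], table["q_mmol_per_gdw_h"].astype(float)))
    return ReferenceState(mu_ref=float(scalars["mu_ref_per_h"]), rates_complete=rates)
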