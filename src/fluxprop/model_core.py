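"""Stoichiometric models and the linear programs behind every growth prediction.

A :class:`MetabolicNetwork` wraps a :class:`cobra.Model` together with the
metadata the rest of the pipeline needs: which reaction is the biomass
pseudo-reaction, how extracellular metabolite names map onto exchange
reactions, and which amino acids the network cannot synthesize.  All flux
units are mmol gDW^-1 h^-1 except the biomass flux, which is the specific
growth rate in h^-1.  Exchange fluxes follow the standard constraint-based
sign convention: negative = uptake, positive = secretion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import cobra
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: requested solver tolerance; optimality asserted downstream at 1e-6
SOLVER_TOLERANCE = 1e-9


class FluxBoundsError(ValueError):
    """Raised for malformed flux bounds or unknown reaction identifiers."""


@dataclass(frozen=True)
class FluxBounds:
    """Per-reaction (lower, upper) flux bounds overriding the defaults."""

    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for rid, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise FluxBoundsError(f"lower bound {lb} > upper bound {ub} for {rid!r}")

    def items(self):
        return self.bounds.items()


@dataclass(frozen=True)
class FBAResult:
    """Outcome of one linear program.

    ``status`` is ``"optimal"``, ``"infeasible"`` or ``"unbounded"``;
    ``objective_value`` and ``fluxes`` are only present when optimal.
    """

    status: str
    objective_value: float | None = None
    fluxes: pd.Series | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class MetabolicNetwork:
    """A stoichiometric model plus the bookkeeping for exchange constraints."""

    model: cobra.Model
    biomass_reaction_id: str
    exchange_map: dict[str, str]
    essential_set: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        rxns = {r.id for r in self.model.reactions}
        if self.biomass_reaction_id not in rxns:
            raise ValueError(f"biomass reaction {self.biomass_reaction_id!r} not in model")
        for met, rid in self.exchange_map.items():
            if rid not in rxns:
                raise ValueError(f"exchange reaction {rid!r} (metabolite {met!r}) not in model")
        self._default_bounds = {r.id: (r.lower_bound, r.upper_bound) for r in self.model.reactions}

    # -- descriptive accessors -------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.model.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.model.reactions]

    @property
    def default_bounds(self) -> dict[str, tuple[float, float]]:
        return dict(self._default_bounds)

    @property
    def stoichiometry(self) -> dict[str, dict[str, float]]:
        """Sparse metabolite -> {reaction -> coefficient} map."""
        smap: dict[str, dict[str, float]] = {}
        for rxn in self.model.reactions:
            for met, coef in rxn.metabolites.items():
                smap.setdefault(met.id, {})[rxn.id] = float(coef)
        return smap

    @property
    def biomass_coefficients(self) -> dict[str, float]:
        """Positive precursor demand b_i (mmol per gDW) of the biomass reaction."""
        rxn = self.model.reactions.get_by_id(self.biomass_reaction_id)
        return {m.id: -float(c) for m, c in rxn.metabolites.items() if c < 0}

    def biomass_precursors(self) -> frozenset[str]:
        return frozenset(self.biomass_coefficients)

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            model=self.model.copy(),
            biomass_reaction_id=self.biomass_reaction_id,
            exchange_map=dict(self.exchange_map),
            essential_set=self.essential_set,
        )


def _configure_solver(model: cobra.Model) -> None:
    model.solver = "glpk"
    model.tolerance = SOLVER_TOLERANCE


def _apply_bounds(model: cobra.Model, bounds: FluxBounds | Mapping[str, tuple[float, float]] | None) -> None:
    if bounds is None:
        return
    items = bounds.items()
    known = {r.id for r in model.reactions}
    for rid, (lb, ub) in items:
        if rid not in known:
            raise FluxBoundsError(f"unknown reaction id {rid!r} in bounds")
        if lb > ub:
            raise FluxBoundsError(f"lower bound {lb} > upper bound {ub} for {rid!r}")
        model.reactions.get_by_id(rid).bounds = (lb, ub)


def _classify_status(raw: str) -> str:
    if raw == "optimal":
        return "optimal"
    if raw in ("unbounded",):
        return "unbounded"
    return "infeasible"


def solve_fba(
    network: MetabolicNetwork,
    bounds: FluxBounds | Mapping[str, tuple[float, float]] | None = None,
    objective: str | None = None,
    sense: str = "max",
) -> FBAResult:
    """Solve max/min ``v_objective`` subject to ``S v = 0`` and flux bounds.

    Infeasibility and unboundedness are reported through ``FBAResult.status``,
    never raised.  Unknown reaction ids in ``objective`` or ``bounds`` are
    input errors and do raise.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    objective = objective or network.biomass_reaction_id
    # a fresh copy keeps results independent of solver warm-start history
    model = network.model.copy()
    if objective not in {r.id for r in model.reactions}:
        raise FluxBoundsError(f"unknown objective reaction {objective!r}")
    _apply_bounds(model, bounds)
    model.objective = model.reactions.get_by_id(objective)
    model.objective_direction = sense
    try:
        sol = model.optimize()
    except cobra.exceptions.OptimizationError:
        return FBAResult(status=_classify_status(model.solver.status))
    status = _classify_status(sol.status)
    if status != "optimal":
        return FBAResult(status=status)
    return FBAResult(status="optimal", objective_value=float(sol.objective_value), fluxes=sol.fluxes)


class InfeasibleGrowthError(RuntimeError):
    """Pinning the growth rate made the linear program infeasible."""


def fix_and_minimize(
    network: MetabolicNetwork,
    bounds: FluxBounds | Mapping[str, tuple[float, float]] | None,
    fixed_growth: float,
    target_exchanges: Iterable[str],
) -> dict[str, float]:
    """Fix biomass flux and minimize the summed uptake magnitude of targets.

    The targets are metabolite names (resolved through ``exchange_map``); their
    exchange fluxes are restricted to uptake (v <= 0) and the total uptake
    magnitude is minimized in a single LP, which is deterministic and
    independent of target order.  Returns metabolite -> optimal exchange flux.
    """
    targets = list(target_exchanges)
    missing = [t for t in targets if t not in network.exchange_map]
    if missing:
        raise FluxBoundsError(f"no exchange reaction for metabolites {missing}")
    # fresh copy keeps results independent of solver warm-start history
    model = network.model.copy()
    _apply_bounds(model, bounds)
    biomass = model.reactions.get_by_id(network.biomass_reaction_id)
    biomass.bounds = (fixed_growth, fixed_growth)
    coeffs = {}
    for met in targets:
        rxn = model.reactions.get_by_id(network.exchange_map[met])
        rxn.upper_bound = min(rxn.upper_bound, 0.0)
        # uptake flux is negative; maximizing the sum minimizes |uptake|
        coeffs[rxn.forward_variable] = 1.0
        coeffs[rxn.reverse_variable] = -1.0
    model.objective = model.problem.Objective(0, direction="max")
    model.objective.set_linear_coefficients(coeffs)
    try:
        sol = model.optimize()
    except cobra.exceptions.OptimizationError:
        sol = None
    if sol is None or _classify_status(sol.status) != "optimal":
        raise InfeasibleGrowthError(
            f"model infeasible with growth pinned to {fixed_growth:.6g} h^-1"
        )
    return {met: float(sol.fluxes[network.exchange_map[met]]) for met in targets}


# -- loading ------------------------------------------------------------------


def load_toy_network() -> MetabolicNetwork:
    """Load the packaged CHO-like toy network (plain-text reaction table).

    ~60 reactions: 23 measured extracellular metabolites (glucose, lactate,
    ammonium, 20 amino acids), a biomass reaction with amino-acid demand
    coefficients, aerobic glycolysis/oxidation, per-amino-acid catabolic
    routes, synthesis routes for nonessential amino acids only, and urea
    overflow for excess nitrogen.
    """
    path = resources.files("fluxprop.data").joinpath("toy_network.tsv")
    return load_reaction_table(str(path))


def load_reaction_table(path: str) -> MetabolicNetwork:
    """Build a network from a TSV of (reaction id, equation string, lb, ub)."""
    biomass_id = None
    essential: frozenset[str] = frozenset()
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("biomass_reaction:"):
                    biomass_id = body.split(":", 1)[1].strip()
                elif body.startswith("essential:"):
                    essential = frozenset(
                        s.strip() for s in body.split(":", 1)[1].split(",") if s.strip()
                    )
                continue
            if not line or line.startswith("reaction_id\t"):
                continue
            rid, eq, lb, ub = line.split("\t")
            rows.append((rid, eq, float(lb), float(ub)))
    if biomass_id is None:
        raise ValueError(f"{path}: missing '# biomass_reaction:' header")
    model = cobra.Model("toy_cho")
    cobra_logger = logging.getLogger("cobra.core.model")
    level = cobra_logger.level
    cobra_logger.setLevel(logging.ERROR)  # metabolite creation from strings is intended
    try:
        for rid, eq, lb, ub in rows:
            rxn = cobra.Reaction(rid)
            model.add_reactions([rxn])
            rxn.build_reaction_from_string(eq, verbose=False)
            rxn.bounds = (lb, ub)
    finally:
        cobra_logger.setLevel(level)
    model.compartments = {"c": "cell"}
    for met in model.metabolites:
        met.compartment = "c"
    _configure_solver(model)
    exchange_map = _detect_exchanges(model)
    return MetabolicNetwork(
        model=model,
        biomass_reaction_id=biomass_id,
        exchange_map=exchange_map,
        essential_set=essential,
    )


def _detect_exchanges(model: cobra.Model) -> dict[str, str]:
    """Map metabolite name -> exchange reaction (single-metabolite boundary)."""
    emap: dict[str, str] = {}
    for rxn in model.reactions:
        if len(rxn.metabolites) == 1 and rxn.id.startswith(("EX_", "R_EX_")):
            met = next(iter(rxn.metabolites))
            emap[met.id] = rxn.id
    return emap


def load_sbml(
    path: str,
    biomass_reaction_id: str | None = None,
    essential_set: Iterable[str] = (),
) -> MetabolicNetwork:
    """Load an SBML (FBC) model, e.g. a genome-scale CHO reconstruction.

    The biomass reaction is taken from ``biomass_reaction_id`` if given,
    otherwise from the model objective, otherwise by name match against
    ``biomass``.  Models without FBC bounds fall back to cobra's defaults
    (a warning is logged).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = cobra.io.read_sbml_model(path)
    _configure_solver(model)
    if biomass_reaction_id is None:
        obj_rxns = [r.id for r in model.reactions if r.objective_coefficient]
        if len(obj_rxns) == 1:
            biomass_reaction_id = obj_rxns[0]
        else:
            named = [r.id for r in model.reactions if "biomass" in r.id.lower()]
            if len(named) == 1:
                biomass_reaction_id = named[0]
            elif named:
                # prefer a 'specific' variant as in genome-scale CHO models
                specific = [r for r in named if "specific" in r.lower()]
                biomass_reaction_id = specific[0] if specific else named[0]
            else:
                raise ValueError(
                    f"{path}: no objective and no reaction named like 'biomass'; "
                    "pass biomass_reaction_id explicitly"
                )
    if not any(abs(b) < 1000 for r in model.reactions for b in r.bounds):
        logger.warning("%s: no finite FBC bounds found; using defaults", path)
    exchange_map = {}
    for rxn in model.exchanges:
        met = next(iter(rxn.metabolites))
        exchange_map[met.id] = rxn.id
    return MetabolicNetwork(
        model=model,
        biomass_reaction_id=biomass_reaction_id,
        exchange_map=exchange_map,
        essential_set=frozenset(essential_set),
    )


def write_sbml(network: MetabolicNetwork, path: str) -> None:
    """Write the network to SBML (FBC v2); round-trips through load_sbml."""
    model = network.model
    with model:
        model.objective = model.reactions.get_by_id(network.biomass_reaction_id)
        cobra.io.write_sbml_model(model, path)


def min_ratio_growth(capacities: Mapping[str, float], biomass_coefficients: Mapping[str, float]) -> float:
    """Closed-form growth bound when only precursor uptake capacities limit.

    With uptake capacity ``c_i`` (magnitude) for each limiting biomass
    precursor i and demand coefficient ``b_i``, the maximal growth rate is
    ``min_i c_i / b_i``.  Used as the independent oracle for LP solutions on
    the toy network.
    """
    return min(capacities[m] / biomass_coefficients[m] for m in capacities)


def mass_balance_residual(network: MetabolicNetwork, fluxes: pd.Series) -> float:
    """Max |S v| over metabolites; ~0 for any valid FBA solution."""
    residual = 0.0
    for mid, row in network.stoichiometry.items():
        residual = max(residual, abs(sum(c * fluxes[rid] for rid, c in row.items())))
    return float(residual)
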