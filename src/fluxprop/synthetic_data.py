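"""Cell-line datasets: exchange rates, medium composition, biomass parameters.

A :class:`CellLineDataset` carries everything needed to turn specific rates
into concentration time courses: per-metabolite exchange rates q_i
(mmol gDW^-1 h^-1, uptake negative), initial medium concentrations [i]_0
(mM), the cell dry mass (pg/cell), the initial viable-cell density
(cells/mL) and the exponential-phase horizon (h).  The initial biomass
concentration is

    BM_0 [g/L] = density [cells/mL] x dry mass [pg/cell] x 1e-9,

the single unit conversion in the package (pg/mL = 1e-9 g/L).

Datasets are generated against the packaged toy network so that (a) the
reference FBA with every measured exchange pinned to its rate is feasible
and (b) the optimal growth rate equals the requested one: essential
amino-acid uptakes are drawn as multiples f_i >= 1 of the biomass
requirement mu*b_i with the smallest f forced to 1, glucose uptake covers
glycolytic lactate output plus biosynthesis with margin, and ammonium
secretion is set below the net nitrogen release of amino-acid catabolism.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from fluxprop.model_core import MetabolicNetwork, load_toy_network

#: cells/mL x pg/cell -> g/L
PG_PER_CELL_DENSITY_TO_G_PER_L = 1e-9

#: amino acids the toy-network reference leaves unmeasured (estimated by LP)
DEFAULT_UNMEASURED = ("cysteine", "tryptophan")


class DatasetError(ValueError):
    """Inconsistent or impossible dataset parameters."""


@dataclass(frozen=True)
class CellLineDataset:
    """Per-cell-line inputs for rate simulation and FBA constraints."""

    name: str
    rates: Mapping[str, float]
    initial_concentrations: Mapping[str, float]
    dry_mass_per_cell: float  # pg/cell
    initial_cell_density: float  # viable cells/mL
    horizon: float = 90.0  # h of exponential phase
    unconstrained_exchanges: frozenset[str] = field(default_factory=frozenset)
    placeholder: bool = False  # True for synthetic stand-in fixtures

    def __post_init__(self) -> None:
        if self.bm0 <= 0:
            raise DatasetError("initial biomass BM0 must be positive")
        if self.horizon <= 0:
            raise DatasetError("horizon must be positive")
        for met, c0 in self.initial_concentrations.items():
            if c0 < 0:
                raise DatasetError(f"negative initial concentration for {met!r}")
        missing = [m for m in self.rates if m not in self.initial_concentrations]
        if missing:
            raise DatasetError(f"rates without initial concentrations: {missing}")

    @property
    def bm0(self) -> float:
        """Initial biomass concentration in g/L."""
        return self.initial_cell_density * self.dry_mass_per_cell * PG_PER_CELL_DENSITY_TO_G_PER_L

    def check_positivity(self, mu: float) -> None:
        """Verify the ideal trajectory of every consumed metabolite stays >= 0."""
        growth = self.bm0 * (math.exp(mu * self.horizon) - 1.0) / mu
        for met, q in self.rates.items():
            if q >= 0:
                continue
            final = self.initial_concentrations[met] + q * growth
            if final < 0:
                raise DatasetError(
                    f"{self.name}: {met} depleted before the {self.horizon} h horizon "
                    f"(final ideal concentration {final:.4g} mM)"
                )


# -- generation ---------------------------------------------------------------


def _assemble_rates(
    network: MetabolicNetwork,
    mu: float,
    aa_factors: Mapping[str, float],
    gln_factor: float,
    q_glc: float,
    q_lac: float,
    nh4_fraction: float,
) -> dict[str, float]:
    """Turn uptake multiples of the biomass requirement into a consistent rate set.

    ``aa_factors[a] = f`` means uptake ``q_a = -f * b_a * mu`` (negative f =
    net secretion).  Ammonium secretion is set to ``nh4_fraction`` of the net
    nitrogen release so the pinned-exchange reference LP keeps disposal slack;
    glucose must cover biomass demand, minimal biosynthesis and the glycolytic
    flux forced by the lactate rate.
    """
    b = network.biomass_coefficients
    factors = dict(aa_factors)
    factors["glutamine"] = gln_factor
    rates: dict[str, float] = {"glucose": q_glc, "lactate": q_lac}
    for aa, f in factors.items():
        rates[aa] = -f * b[aa] * mu

    # nitrogen bookkeeping includes the unmeasured AAs at exactly f = 1
    p_net = 0.0
    synth_min = 0.0
    for aa in sorted(set(factors) | set(DEFAULT_UNMEASURED)):
        q = rates.get(aa, -b[aa] * mu)
        p_net += -q - b[aa] * mu
        if aa not in network.essential_set:
            synth_min += max(0.0, b[aa] * mu + q)
    if p_net <= 0:
        raise DatasetError("net nitrogen release is nonpositive; increase glutamine excess")
    rates["ammonium"] = nh4_fraction * p_net

    glc_demand = b["glucose"] * mu + synth_min + q_lac / 2.0
    if -q_glc < glc_demand:
        raise DatasetError(
            f"glucose uptake {q_glc} cannot cover demand {glc_demand:.4g} "
            "(biomass + biosynthesis + glycolysis)"
        )
    return rates


def generate_cellline(
    seed: int,
    n_aa: int = 17,
    mu_true: float = 0.035,
    rate_span: float = 2.0,
    n_limiting: int = 3,
    network: MetabolicNetwork | None = None,
) -> CellLineDataset:
    """Draw a random but self-consistent cell line for the toy network.

    ``n_limiting`` essential amino acids are consumed near their biomass
    requirement (f in [1, 1.5], the smallest exactly 1, so the reference
    growth rate equals ``mu_true``); the remaining essentials are consumed
    with larger excess, nonessentials between 0.4x and 2x their requirement
    (alanine secreted), glutamine and glucose at high rates and lactate and
    ammonium secreted.  Rate magnitudes span at least ``rate_span`` orders of
    magnitude.  Fully reproducible from ``seed``.
    """
    if n_aa < 5:
        raise ValueError("n_aa must be >= 5")
    if not (0.01 <= mu_true <= 0.06):
        raise ValueError("mu_true must lie in [0.01, 0.06] h^-1 (exponential-phase range)")
    network = network or load_toy_network()
    rng = np.random.default_rng(seed)
    b = network.biomass_coefficients

    essentials = sorted(m for m in network.essential_set if m not in DEFAULT_UNMEASURED)
    noness = sorted(
        m for m in b
        if m not in network.essential_set and m not in ("glucose", "glutamine")
    )
    pool = essentials + noness
    included = pool[:n_aa]
    inc_ess = [m for m in included if m in network.essential_set]
    inc_non = [m for m in included if m not in network.essential_set]
    if not inc_ess:
        raise ValueError("at least one essential amino acid must be included")
    n_limiting = min(n_limiting, len(inc_ess))

    factors: dict[str, float] = {}
    limiting = list(rng.choice(inc_ess, size=n_limiting, replace=False))
    for k, aa in enumerate(limiting):
        factors[aa] = 1.0 if k == 0 else float(rng.uniform(1.02, 1.5))
    for aa in inc_ess:
        if aa not in factors:
            factors[aa] = float(rng.uniform(1.6, 4.0))
    for aa in inc_non:
        if aa == "alanine":
            factors[aa] = -float(rng.uniform(0.3, 0.8))  # net secretion
        else:
            factors[aa] = float(rng.uniform(0.4, 2.0))
    gln_factor = float(rng.uniform(3.5, 6.0))

    # glucose/lactate sized after the amino-acid draws so magnitudes span
    # the requested range
    min_q = min(abs(-f * b[aa] * mu_true) for aa, f in factors.items())
    # biosynthesis deficit of nonessentials: b*mu + q = b*mu*(1 - f) when positive
    synth_min = sum(max(0.0, b[aa] * mu_true * (1.0 - factors[aa])) for aa in inc_non)
    needs_core = b["glucose"] * mu_true + synth_min
    q_glc_mag = max(2.5 * needs_core, min_q * 10.0 ** rate_span)
    glyc_budget = q_glc_mag - 1.3 * needs_core
    if glyc_budget <= 0:
        raise DatasetError("cannot size glucose uptake: no glycolytic budget")
    q_lac = 2.0 * 0.7 * glyc_budget
    nh4_fraction = float(rng.uniform(0.4, 0.7))

    rates = _assemble_rates(network, mu_true, factors, gln_factor, -q_glc_mag, q_lac, nh4_fraction)

    dry_mass = float(rng.uniform(230.0, 290.0))
    density = 1.6e5
    bm0 = density * dry_mass * PG_PER_CELL_DENSITY_TO_G_PER_L
    growth = bm0 * (math.exp(mu_true * 90.0) - 1.0) / mu_true

    conc: dict[str, float] = {}
    for met, q in rates.items():
        if q < 0:
            frac = float(rng.uniform(0.15, 0.8))  # fraction consumed by the horizon
            conc[met] = -q * growth / frac
        else:
            conc[met] = float(rng.uniform(0.05, 0.5))
    for aa in DEFAULT_UNMEASURED:
        frac = float(rng.uniform(0.2, 0.6))
        conc[aa] = 1.5 * b[aa] * mu_true * growth / frac

    ds = CellLineDataset(
        name=f"toyline-{seed}",
        rates=rates,
        initial_concentrations=conc,
        dry_mass_per_cell=dry_mass,
        initial_cell_density=density,
        horizon=90.0,
    )
    ds.check_positivity(mu_true)
    return ds


# -- fixed fixtures -----------------------------------------------------------

_K1PAR_FACTORS = {
    "arginine": 1.12, "histidine": 2.4, "isoleucine": 2.6, "leucine": 1.9,
    "lysine": 1.22, "methionine": 2.1, "phenylalanine": 1.35, "threonine": 1.0,
    "valine": 1.8,
    "alanine": -0.5, "asparagine": 1.4, "aspartate": 1.2, "glutamate": 0.8,
    "glycine": 0.6, "proline": 0.3, "serine": 1.3, "tyrosine": 1.1,
}
_HYHER_FACTORS = {
    "arginine": 1.18, "histidine": 1.8, "isoleucine": 2.8, "leucine": 1.3,
    "lysine": 1.0, "methionine": 1.35, "phenylalanine": 1.45, "threonine": 1.9,
    "valine": 2.0,
    "alanine": -0.4, "asparagine": 1.3, "aspartate": 1.1, "glutamate": 0.7,
    "glycine": 0.5, "proline": 0.35, "serine": 1.2, "tyrosine": 1.0,
}
#: chemically-defined-medium-like initial concentrations (mM)
_MEDIUM_MM = {
    "glucose": 36.0, "lactate": 0.5, "ammonium": 0.1, "glutamine": 8.0,
    "alanine": 0.5, "arginine": 2.5, "asparagine": 5.0, "aspartate": 1.5,
    "cysteine": 0.5, "glutamate": 1.0, "glycine": 1.0, "histidine": 1.0,
    "isoleucine": 3.0, "leucine": 4.5, "lysine": 3.0, "methionine": 1.2,
    "phenylalanine": 2.0, "proline": 2.5, "serine": 5.0, "threonine": 3.5,
    "tryptophan": 0.35, "tyrosine": 1.3, "valine": 3.5,
}

_BUILTIN_SPECS = {
    # name: (mu at reference, dry mass pg/cell, factors, gln excess, q_glc, q_lac)
    "K1par-like": (0.0384, 252.3, _K1PAR_FACTORS, 5.0, -0.30, 0.40),
    "HYher-like": (0.0321, 279.0, _HYHER_FACTORS, 4.5, -0.26, 0.34),
}


def builtin_dataset(name: str) -> CellLineDataset:
    """Fixed, versioned toy cell lines patterned on two real CHO conditions.

    The biomass parameters (dry mass 252.3 / 279 pg per cell, initial density
    1.6e5 cells/mL, 90 h exponential phase) and the reference growth rates
    (0.0384 / 0.0321 h^-1) match the published conditions; the per-metabolite
    rate and medium-concentration profiles are synthetic placeholders
    constructed for the toy network, not transcribed measurements.  The
    near-limiting essential amino acids (uptake < 1.5x biomass requirement)
    are {arginine, lysine, phenylalanine, threonine} + the LP-estimated
    cysteine and tryptophan for K1par-like and {arginine, leucine, lysine,
    methionine, phenylalanine} + cysteine/tryptophan for HYher-like.
    """
    if name not in _BUILTIN_SPECS:
        raise KeyError(f"unknown dataset {name!r}; available: {sorted(_BUILTIN_SPECS)}")
    mu, dry_mass, factors, gln_factor, q_glc, q_lac = _BUILTIN_SPECS[name]
    network = load_toy_network()
    rates = _assemble_rates(network, mu, factors, gln_factor, q_glc, q_lac, nh4_fraction=0.5)
    ds = CellLineDataset(
        name=name,
        rates=rates,
        initial_concentrations=dict(_MEDIUM_MM),
        dry_mass_per_cell=dry_mass,
        initial_cell_density=1.6e5,
        horizon=90.0,
        placeholder=True,
    )
    ds.check_positivity(mu)
    return ds


def scaled_dataset(base: CellLineDataset, mu_base: float, mu_new: float, name: str | None = None) -> CellLineDataset:
    """Rescale every exchange rate by ``mu_new / mu_base``.

    Produces a hypothetical slower/faster line with the same relative rate
    profile, used for growth-difference detectability experiments.
    """
    s = mu_new / mu_base
    return replace(
        base,
        name=name or f"{base.name}-x{s:.3f}",
        rates={m: q * s for m, q in base.rates.items()},
    )


# -- persistence --------------------------------------------------------------

_HEADER_KEYS = ("name", "dry_mass_per_cell_pg", "initial_cell_density_per_ml",
                "horizon_h", "unconstrained_exchanges")


def save_dataset(dataset: CellLineDataset, path: str) -> None:
    """Write a dataset as a commented-header CSV (one row per metabolite)."""
    with open(path, "w") as fh:
        fh.write("# fluxprop cell-line dataset\n")
        fh.write(f"# name: {dataset.name}\n")
        fh.write(f"# dry_mass_per_cell_pg: {dataset.dry_mass_per_cell!r}\n")
        fh.write(f"# initial_cell_density_per_ml: {dataset.initial_cell_density!r}\n")
        fh.write(f"# horizon_h: {dataset.horizon!r}\n")
        fh.write(f"# unconstrained_exchanges: {','.join(sorted(dataset.unconstrained_exchanges))}\n")
        fh.write("metabolite,rate_mmol_per_gdw_h,initial_concentration_mM\n")
        for met in sorted(dataset.initial_concentrations):
            q = dataset.rates.get(met)
            q_str = repr(q) if q is not None else ""
            fh.write(f"{met},{q_str},{dataset.initial_concentrations[met]!r}\n")


def load_dataset(path: str, column_map: Mapping[str, str] | None = None) -> CellLineDataset:
    """Read a dataset CSV written by :func:`save_dataset`.

    ``column_map`` renames external column layouts onto the canonical
    ``metabolite`` / ``rate_mmol_per_gdw_h`` / ``initial_concentration_mM``
    names, so deposit-style tables can be ingested without editing.
    A missing rate field marks the metabolite as unmeasured (it still
    contributes its initial concentration).
    """
    header: dict[str, str] = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("# ").rstrip("\n")
                if ":" in stripped:
                    key, val = stripped.split(":", 1)
                    header[key.strip()] = val.strip()
            else:
                body_lines.append(line)
    table = pd.read_csv(io.StringIO("".join(body_lines)), float_precision="round_trip")
    if column_map:
        table = table.rename(columns=dict(column_map))
    rates = {}
    conc = {}
    for _, row in table.iterrows():
        met = str(row["metabolite"])
        conc[met] = float(row["initial_concentration_mM"])
        q = row.get("rate_mmol_per_gdw_h")
        if q is not None and not pd.isna(q):
            rates[met] = float(q)
    unconstrained = frozenset(
        s for s in header.get("unconstrained_exchanges", "").split(",") if s
    )
    return CellLineDataset(
        name=header.get("name", "unnamed"),
        rates=rates,
        initial_concentrations=conc,
        dry_mass_per_cell=float(header["dry_mass_per_cell_pg"]),
        initial_cell_density=float(header["initial_cell_density_per_ml"]),
        horizon=float(header.get("horizon_h", 90.0)),
        unconstrained_exchanges=unconstrained,
    )
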