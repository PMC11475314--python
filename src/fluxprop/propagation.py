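"""The Monte-Carlo engine: from noisy time courses to FBA growth distributions.

Per draw the engine (i) optionally perturbs the cell-concentration series and
re-estimates the growth rate from it (the "Sim 2" wiring: that draw's
estimated mu is then used both to generate and to fit the concentration
profiles, as an experimenter would), (ii) simulates noisy concentration
profiles for every reference metabolite, (iii) fits each profile to obtain
q_hat and its standard error, (iv) constrains each exchange reaction to
[q_hat - SE, q_hat + SE] — symmetric even when noise has flipped the sign of
q_hat, with non-converged fits and dataset-listed exceptions left at the
network default bounds — and (v) maximizes biomass, recording the optimum or
the infeasibility.  Everything is reproducible from the config seed; draws
that hit an unbounded LP are counted as anomalies alongside infeasible ones
but logged with their own status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from fluxprop.model_core import MetabolicNetwork
from fluxprop.rate_fitting import fit_growth, fit_rates_batch
from fluxprop.reference_fba import ReferenceState
from fluxprop.simulate import (
    BiomassSeries,
    NoiseModel,
    SamplingSchedule,
    draw_streams,
    ideal_concentration,
    noisy_measurements,
)
from fluxprop.synthetic_data import CellLineDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PropagationConfig:
    """Monte-Carlo run parameters."""

    schedule: SamplingSchedule
    noise: NoiseModel
    n_draws: int = 1000
    perturb_biomass: bool = False  # Sim 2: re-estimate mu per draw
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass
class PropagationResult:
    """Per-draw fitted rates, FBA growth and feasibility."""

    mu_fba: np.ndarray  # (n_draws,), NaN where not optimal
    feasible: np.ndarray  # bool
    statuses: np.ndarray  # str: optimal | infeasible | unbounded
    q_hat: pd.DataFrame  # draws x metabolites
    se_q: pd.DataFrame
    converged: pd.DataFrame  # bool
    mu_used: np.ndarray  # growth rate used in Eq-(1) simulation/fitting per draw
    reference: ReferenceState = field(repr=False, default=None)
    config: PropagationConfig = field(repr=False, default=None)

    @property
    def n_draws(self) -> int:
        return int(self.mu_fba.size)

    @property
    def feasible_fraction(self) -> float:
        return float(self.feasible.mean())

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-draw fit table (draw, metabolite, q_hat, se_q, converged)."""
        long = self.q_hat.stack().rename("q_hat").reset_index()
        long.columns = ["draw", "metabolite", "q_hat"]
        long["se_q"] = self.se_q.stack().values
        long["converged"] = self.converged.stack().values
        return long

    def summary(self) -> dict:
        ok = self.feasible
        ratios = self.mu_fba[ok] / self.reference.mu_ref if ok.any() else np.array([])
        qtl = (
            {f"q{int(100*p)}": float(np.quantile(ratios, p, method="median_unbiased"))
             for p in (0.25, 0.5, 0.75)}
            if ratios.size >= 2 else {}
        )
        return {
            "n_draws": self.n_draws,
            "feasible_fraction": self.feasible_fraction,
            "n_unbounded": int((self.statuses == "unbounded").sum()),
            "mu_ref_per_h": float(self.reference.mu_ref),
            "growth_ratio_quantiles": qtl,
        }


def propagate(
    reference: ReferenceState,
    dataset: CellLineDataset,
    network: MetabolicNetwork,
    config: PropagationConfig,
) -> PropagationResult:
    """Run the full error-propagation Monte Carlo.

    At zero noise every draw must be feasible with mu equal to the reference
    optimum; a configuration where even the noiseless draw fails raises.
    """
    mets = list(reference.rates_complete)
    missing = [m for m in mets if m not in dataset.initial_concentrations]
    if missing:
        raise KeyError(f"no initial concentration for {missing}")
    sched = config.schedule
    n_draws = config.n_draws
    rsd = np.array([config.noise.rsd_for(m) for m in mets])
    i0 = np.array([dataset.initial_concentrations[m] for m in mets])
    q_true = np.array([reference.rates_complete[m] for m in mets])

    q_hat = np.empty((n_draws, len(mets)))
    se_q = np.empty((n_draws, len(mets)))
    mu_used = np.full(n_draws, reference.mu_ref)

    streams = draw_streams(config.seed, n_draws)

    if not config.perturb_biomass:
        # shared design matrix: simulate per draw (fixed stream layout), fit in batch
        values = np.empty((n_draws, len(mets), sched.n_replicates, sched.n_times))
        ideal = np.stack([
            ideal_concentration(i0[k], q_true[k], reference.mu_ref, dataset.bm0, sched.times)
            for k in range(len(mets))
        ])
        for d, (_, rng_c) in enumerate(streams):
            z = rng_c.standard_normal((len(mets), sched.n_replicates, sched.n_times))
            values[d] = ideal[:, None, :] + rsd[:, None, None] * np.abs(ideal)[:, None, :] * z
        qh, se, _, _ = fit_rates_batch(values, sched.times, dataset.bm0, reference.mu_ref)
        q_hat[:], se_q[:] = qh, se
    else:
        bm_ideal = dataset.bm0 * np.exp(reference.mu_ref * sched.times)
        for d, (rng_b, rng_c) in enumerate(streams):
            bm_values = noisy_measurements(bm_ideal, config.noise.biomass_rsd, rng_b, sched.n_replicates)
            gfit = fit_growth(BiomassSeries(times=sched.times, values=bm_values))
            mu_d = gfit.mu_hat if gfit.converged else reference.mu_ref
            mu_used[d] = mu_d
            ideal = np.stack([
                ideal_concentration(i0[k], q_true[k], mu_d, dataset.bm0, sched.times)
                for k in range(len(mets))
            ])
            z = rng_c.standard_normal((len(mets), sched.n_replicates, sched.n_times))
            vals = ideal[:, None, :] + rsd[:, None, None] * np.abs(ideal)[:, None, :] * z
            qh, se, _, _ = fit_rates_batch(vals, sched.times, dataset.bm0, mu_d)
            q_hat[d], se_q[d] = qh, se

    converged = np.isfinite(q_hat) & np.isfinite(se_q)

    mu_fba, feasible, statuses = _solve_draws(
        network, dataset, mets, q_hat, se_q, converged
    )

    if not np.isfinite(mu_fba).any() and float(np.max(rsd)) == 0.0:
        raise RuntimeError("all draws infeasible at zero noise: configuration error")

    cols = pd.Index(mets, name="metabolite")
    return PropagationResult(
        mu_fba=mu_fba,
        feasible=feasible,
        statuses=statuses,
        q_hat=pd.DataFrame(q_hat, columns=cols),
        se_q=pd.DataFrame(se_q, columns=cols),
        converged=pd.DataFrame(converged, columns=cols),
        mu_used=mu_used,
        reference=reference,
        config=config,
    )


def _solve_draws(network, dataset, mets, q_hat, se_q, converged):
    """Maximize biomass per draw with exchanges bounded to [q-SE, q+SE]."""
    # fresh copy: draw results depend only on the draw sequence, not on any
    # solver warm-start state left behind by earlier solves on this network
    model = network.model.copy()
    defaults = network.default_bounds
    n_draws = q_hat.shape[0]
    mu_fba = np.full(n_draws, np.nan)
    feasible = np.zeros(n_draws, dtype=bool)
    statuses = np.empty(n_draws, dtype=object)
    model.objective = model.reactions.get_by_id(network.biomass_reaction_id)
    model.objective_direction = "max"
    rxns = [model.reactions.get_by_id(network.exchange_map[m]) for m in mets]
    for d in range(n_draws):
        for k, rxn in enumerate(rxns):
            if mets[k] in dataset.unconstrained_exchanges or not converged[d, k]:
                rxn.bounds = defaults[rxn.id]
            else:
                rxn.bounds = (q_hat[d, k] - se_q[d, k], q_hat[d, k] + se_q[d, k])
        obj = model.slim_optimize(error_value=np.nan)
        raw = model.solver.status
        if raw == "optimal" and np.isfinite(obj):
            mu_fba[d] = obj
            feasible[d] = True
            statuses[d] = "optimal"
        elif raw == "unbounded":
            statuses[d] = "unbounded"
            logger.warning("draw %d: unbounded LP (counted as anomaly)", d)
        else:
            statuses[d] = "infeasible"
    return mu_fba, feasible, statuses


def grouped_propagate(
    reference: ReferenceState,
    dataset: CellLineDataset,
    network: MetabolicNetwork,
    config: PropagationConfig,
    rsd_by_group: Mapping[frozenset | tuple, float],
) -> PropagationResult:
    """Propagate with per-group concentration RSDs.

    ``rsd_by_group`` maps metabolite sets to RSD values; the sets must
    partition the simulated metabolites (overlaps and gaps are errors).
    With every group at the same RSD and the same seed this is identical to
    :func:`propagate`, and because the underlying standard normals do not
    depend on the RSD, runs at different group levels share random numbers.
    """
    mets = set(reference.rates_complete)
    per_met: dict[str, float] = {}
    for group, rsd_value in rsd_by_group.items():
        for m in group:
            if m in per_met:
                raise ValueError(f"metabolite {m!r} appears in more than one group")
            per_met[m] = float(rsd_value)
    uncovered = mets - set(per_met)
    if uncovered:
        raise ValueError(f"metabolites not covered by any group: {sorted(uncovered)}")
    noise = NoiseModel(concentration_rsd=per_met, biomass_rsd=config.noise.biomass_rsd)
    return propagate(reference, dataset, network, replace(config, noise=noise))
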