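"""Ideal and noisy time courses of metabolite and biomass concentrations.

During the exponential phase the ideal metabolite concentration follows

    [i](t) = [i]_0 + q_i * BM_0 / mu * (exp(mu t) - 1)

and the biomass follows BM(t) = BM_0 exp(mu t).  Measurement noise is
additive Gaussian with a standard deviation proportional to the ideal value
(a fixed relative standard deviation per time point), independent across
replicates, time points, metabolites and Monte-Carlo draws.  Negative
simulated concentrations are legitimate measurement-error artifacts and are
deliberately not clamped.

Reproducibility contract: one root seed spawns one substream per draw, and
each draw's substream splits into a biomass stream and a concentration
stream.  The underlying standard-normal variates therefore do not depend on
the noise level, which gives common random numbers across RSD scenarios
for free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from fluxprop.synthetic_data import CellLineDataset


@dataclass(frozen=True)
class SamplingSchedule:
    """Sampling times (h, strictly increasing from 0) and replicate count."""

    times: np.ndarray
    n_replicates: int = 3

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("schedule needs at least two time points")
        if t[0] != 0.0:
            raise ValueError("schedule must start at t=0 (seeding time)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_times(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class NoiseModel:
    """Relative standard deviations of the measurements.

    ``concentration_rsd`` is either one global value or a metabolite -> RSD
    map; ``biomass_rsd`` applies to cell-concentration measurements.  All
    RSDs must lie in [0, 1).
    """

    concentration_rsd: float | Mapping[str, float] = 0.1
    biomass_rsd: float = 0.06

    def __post_init__(self) -> None:
        for v in self._all_values():
            if not (0.0 <= v < 1.0):
                raise ValueError(f"RSD {v} outside [0, 1)")

    def _all_values(self):
        if isinstance(self.concentration_rsd, Mapping):
            yield from self.concentration_rsd.values()
        else:
            yield self.concentration_rsd
        yield self.biomass_rsd

    def rsd_for(self, metabolite: str) -> float:
        if isinstance(self.concentration_rsd, Mapping):
            try:
                return float(self.concentration_rsd[metabolite])
            except KeyError:
                raise KeyError(f"no concentration RSD configured for {metabolite!r}") from None
        return float(self.concentration_rsd)


@dataclass(frozen=True)
class ConcentrationProfile:
    """Replicate x time matrix of measured concentrations for one metabolite."""

    metabolite: str
    times: np.ndarray
    values: np.ndarray  # shape (n_replicates, n_times), mM

    def __post_init__(self) -> None:
        if self.values.shape[-1] != np.asarray(self.times).size:
            raise ValueError("values and times have inconsistent shapes")


@dataclass(frozen=True)
class BiomassSeries:
    """Replicate x time matrix of biomass concentrations (g/L)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape[-1] != np.asarray(self.times).size:
            raise ValueError("values and times have inconsistent shapes")


def ideal_concentration(i0: float, q: float, mu: float, bm0: float, t) -> np.ndarray | float:
    """Exponential-phase metabolite concentration; vectorized over ``t``."""
    if mu <= 0:
        raise ValueError("mu must be positive (exponential-phase assumption)")
    t = np.asarray(t, dtype=float)
    out = i0 + q * bm0 / mu * (np.exp(mu * t) - 1.0)
    return out if out.ndim else float(out)


def make_schedule(
    kind: str = "regular",
    interval_h: float = 6.0,
    horizon_h: float = 90.0,
    n_replicates: int = 3,
    shift_variant: str | None = None,
) -> SamplingSchedule:
    """Build a sampling schedule.

    ``regular``: t = 0, d, 2d, ... up to the horizon.  ``shift``: four samples
    per working day spaced ``interval_h`` apart (4 h or 2.5 h) with the
    remaining gap (12 h or 16.5 h) either at the start of each day
    (``shift_variant="gap_first"``: 0, 12, 16, 20, 24, 36, ...) or after the
    dense block (``"gap_after_dense"``: 0, 4, 8, 12, 24, 28, ...).
    """
    if kind == "regular":
        if horizon_h < 2 * interval_h:
            raise ValueError("interval must fit at least twice into the horizon")
        times = np.arange(0.0, horizon_h + 1e-9, interval_h)
    elif kind == "shift":
        block = 3.0 * interval_h
        if block >= 24.0:
            raise ValueError("dense block must be shorter than one day")
        if shift_variant == "gap_after_dense":
            offsets = np.array([0.0, 1.0, 2.0, 3.0]) * interval_h
            days = np.arange(0.0, horizon_h + 1e-9, 24.0)
            times = (days[:, None] + offsets[None, :]).ravel()
        elif shift_variant == "gap_first":
            offsets = 24.0 - np.array([3.0, 2.0, 1.0, 0.0]) * interval_h
            days = np.arange(0.0, horizon_h + 1e-9, 24.0)
            times = np.concatenate([[0.0], (days[:, None] + offsets[None, :]).ravel()])
        else:
            raise ValueError(f"unknown shift_variant {shift_variant!r}")
        times = np.unique(times[times <= horizon_h + 1e-9])
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    return SamplingSchedule(times=times, n_replicates=n_replicates)


# -- random-stream plumbing ---------------------------------------------------


def draw_streams(seed: int, n_draws: int) -> list[tuple[np.random.Generator, np.random.Generator]]:
    """Per-draw (biomass, concentration) generator pairs from one root seed."""
    root = np.random.SeedSequence(seed)
    pairs = []
    for child in root.spawn(n_draws):
        b_seq, c_seq = child.spawn(2)
        pairs.append((np.random.default_rng(b_seq), np.random.default_rng(c_seq)))
    return pairs


def noisy_measurements(
    ideal: np.ndarray, rsd: float, rng: np.random.Generator, n_replicates: int
) -> np.ndarray:
    """Add proportional Gaussian noise: value = ideal + rsd*|ideal|*z.

    ``ideal`` has shape (..., n_times); the result gains a replicate axis
    before the time axis.  Standard normals are always drawn so that the
    stream position is independent of ``rsd`` (common random numbers).
    """
    z = rng.standard_normal(ideal.shape[:-1] + (n_replicates, ideal.shape[-1]))
    return ideal[..., None, :] + rsd * np.abs(ideal[..., None, :]) * z


def simulate_profiles(
    reference,
    dataset: CellLineDataset,
    schedule: SamplingSchedule,
    noise: NoiseModel,
    n_draws: int,
    seed: int,
    mu: float | None = None,
) -> dict[str, np.ndarray]:
    """Simulate noisy concentration profiles for every reference metabolite.

    Returns metabolite -> array of shape (n_draws, n_replicates, n_times).
    ``reference`` provides the true rates and growth rate (anything with
    ``rates_complete`` and ``mu_ref``); ``mu`` overrides the growth rate used
    in the ideal curves.  Metabolites missing an initial concentration raise
    a KeyError naming them.
    """
    mu = reference.mu_ref if mu is None else mu
    mets = list(reference.rates_complete)
    missing = [m for m in mets if m not in dataset.initial_concentrations]
    if missing:
        raise KeyError(f"no initial concentration for {missing}")
    ideals = {
        m: ideal_concentration(
            dataset.initial_concentrations[m], reference.rates_complete[m], mu, dataset.bm0, schedule.times
        )
        for m in mets
    }
    out = {m: np.empty((n_draws, schedule.n_replicates, schedule.n_times)) for m in mets}
    for d, (_, rng_c) in enumerate(draw_streams(seed, n_draws)):
        z = rng_c.standard_normal((len(mets), schedule.n_replicates, schedule.n_times))
        for k, m in enumerate(mets):
            out[m][d] = ideals[m][None, :] + noise.rsd_for(m) * np.abs(ideals[m])[None, :] * z[k]
    return out


def simulate_biomass(
    dataset: CellLineDataset,
    mu: float,
    schedule: SamplingSchedule,
    biomass_rsd: float,
    n_draws: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy biomass series BM_0 exp(mu t) + eps, eps ~ N(0, (rsd*ideal)^2).

    Returns (times, values) with values of shape (n_draws, n_replicates,
    n_times).  The random streams match the biomass substreams used by the
    propagation engine, so growth-fit experiments and full propagation runs
    share draws for a given seed.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    ideal = dataset.bm0 * np.exp(mu * schedule.times)
    out = np.empty((n_draws, schedule.n_replicates, schedule.n_times))
    for d, (rng_b, _) in enumerate(draw_streams(seed, n_draws)):
        out[d] = noisy_measurements(ideal, biomass_rsd, rng_b, schedule.n_replicates)
    return schedule.times, out


def profiles_to_frame(profiles: Mapping[str, np.ndarray], times: Sequence[float]) -> "pd.DataFrame":
    """Tidy (draw, metabolite, replicate, time_h, value) table for export."""
    import pandas as pd

    rows = []
    for met, arr in profiles.items():
        n_draws, n_rep, n_t = arr.shape
        d_idx, r_idx, t_idx = np.indices((n_draws, n_rep, n_t))
        rows.append(pd.DataFrame({
            "draw": d_idx.ravel(),
            "metabolite": met,
            "replicate": r_idx.ravel(),
            "time_h": np.asarray(times)[t_idx.ravel()],
            "value": arr.ravel(),
        }))
    return pd.concat(rows, ignore_index=True)
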