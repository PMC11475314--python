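"""Config-driven end-to-end runs: reference -> propagation -> summaries.

A :class:`RunConfig` (plain YAML) names the dataset and network sources, the
sampling schedule, the noise level, the draw count and a mandatory seed
(wall-clock seeding is deliberately impossible).  :func:`run_experiment`
validates everything up front — a bad config fails before any output is
written — then executes the pipeline and writes a self-describing output
directory: the echoed config with its hash, the reference state, the
per-draw fit and growth tables, and a JSON summary.  Outputs contain no
timestamps, so identical configs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping

import yaml

import fluxprop
from fluxprop.model_core import MetabolicNetwork, load_sbml, load_toy_network
from fluxprop.propagation import PropagationConfig, propagate
from fluxprop.reference_fba import build_reference, save_reference
from fluxprop.simulate import NoiseModel, make_schedule
from fluxprop.stats import growth_ratio_summary, summarize_rse
from fluxprop.synthetic_data import _BUILTIN_SPECS, builtin_dataset, load_dataset


class ConfigError(ValueError):
    """Invalid or unresolvable run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one experiment."""

    experiment: str
    dataset: str  # builtin fixture name or dataset CSV path
    seed: int
    network: str = "toy"  # "toy" or an SBML path
    schedule_kind: str = "regular"
    interval_h: float = 6.0
    shift_variant: str | None = None
    n_replicates: int = 3
    rsd: float | Mapping[str, float] = 0.1
    biomass_rsd: float = 0.06
    perturb_biomass: bool = False
    n_draws: int = 1000
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = [k for k in ("experiment", "dataset", "seed") if k not in raw]
        if missing:
            raise ConfigError(f"missing required config keys: {missing}")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _resolve(config: RunConfig):
    if config.network == "toy":
        network = load_toy_network()
    elif os.path.exists(config.network):
        network = load_sbml(config.network)
    else:
        raise ConfigError(f"network source {config.network!r} not found")
    if config.dataset in _BUILTIN_SPECS:
        dataset = builtin_dataset(config.dataset)
    elif os.path.exists(config.dataset):
        dataset = load_dataset(config.dataset)
    else:
        raise ConfigError(
            f"dataset {config.dataset!r} is neither a builtin fixture "
            f"({sorted(_BUILTIN_SPECS)}) nor an existing CSV path"
        )
    schedule = make_schedule(
        kind=config.schedule_kind,
        interval_h=config.interval_h,
        n_replicates=config.n_replicates,
        shift_variant=config.shift_variant,
        horizon_h=dataset.horizon,
    )
    noise = NoiseModel(concentration_rsd=config.rsd, biomass_rsd=config.biomass_rsd)
    return network, dataset, schedule, noise


def run_experiment(config: RunConfig) -> str:
    """Execute reference -> propagate -> stats; returns the output directory.

    Partial failures after validation leave a machine-readable
    ``error_manifest.json`` in the output directory.
    """
    network, dataset, schedule, noise = _resolve(config)  # validates before any output
    outdir = os.path.join(config.outdir, f"{config.experiment}-{config.digest()}")
    os.makedirs(outdir, exist_ok=True)
    _write_provenance(config, outdir)
    try:
        reference = build_reference(dataset, network)
        pconfig = PropagationConfig(
            schedule=schedule,
            noise=noise,
            n_draws=config.n_draws,
            perturb_biomass=config.perturb_biomass,
            seed=config.seed,
        )
        result = propagate(reference, dataset, network, pconfig)

        save_reference(reference, os.path.join(outdir, "reference_rates.csv"),
                       os.path.join(outdir, "reference.json"))
        result.to_frame().to_csv(os.path.join(outdir, "rate_fits.csv"), index=False)
        draws = result.mu_fba
        with open(os.path.join(outdir, "growth_draws.csv"), "w") as fh:
            fh.write("draw,mu_fba_per_h,feasible,status\n")
            for d in range(result.n_draws):
                mu = "" if not result.feasible[d] else repr(float(draws[d]))
                fh.write(f"{d},{mu},{bool(result.feasible[d])},{result.statuses[d]}\n")
        summarize_rse(result).to_csv(os.path.join(outdir, "rse_summary.csv"))
        summary = result.summary()
        summary["growth_ratio"] = growth_ratio_summary(result)
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
    except Exception as exc:  # noqa: BLE001 - manifest then re-raise
        with open(os.path.join(outdir, "error_manifest.json"), "w") as fh:
            json.dump({"error": type(exc).__name__, "message": str(exc)}, fh, indent=1)
        raise
    return outdir


def _write_provenance(config: RunConfig, outdir: str) -> None:
    echo = asdict(config)
    with open(os.path.join(outdir, "config_echo.yaml"), "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=True)
    with open(os.path.join(outdir, "provenance.json"), "w") as fh:
        json.dump(
            {"config_hash": config.digest(), "seed": config.seed,
             "fluxprop_version": fluxprop.__version__},
            fh, indent=1, sort_keys=True,
        )
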