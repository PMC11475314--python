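# One error-propagation experiment on the packaged toy network.
experiment: toy-daily-10pct
dataset: K1par-like     # builtin fixture name or a dataset CSV path
network: toy            # "toy" or a path to an SBML (FBC) model
schedule_kind: regular  # or "shift" with shift_variant gap_first/gap_after_dense
interval_h: 24.0
n_replicates: 3
rsd: 0.10               # concentration measurement RSD (global or per-metabolite map)
biomass_rsd: 0.06
perturb_biomass: false  # true = re-estimate mu from noisy cell counts per draw
n_draws: 500
seed: 42
outdir: results
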