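# fluxprop

Monte-Carlo error propagation from batch-culture measurements into
flux-balance-analysis (FBA) growth predictions.

## The problem

Growth predictions for mammalian cell factories (CHO cells in particular)
are made by constraining a stoichiometric model with measured exchange rates
— the specific uptake/secretion rates of glucose, lactate, ammonium and ~20
amino acids — and maximizing a biomass objective.  Those rates are not
measured directly: they are *fitted* from metabolite concentration time
courses sampled a handful of times during the exponential phase of a batch
culture, with 2–20% measurement noise per sample.  `fluxprop` quantifies how
that measurement error and the sampling schedule propagate into the FBA
growth prediction, and answers design questions such as: which metabolites
must be measured accurately, how often must one sample, and how large a
growth difference between two cell lines can be reliably detected at all?

It is aimed at modelers and experimentalists planning rate-measurement
campaigns for constraint-based models, and is usable end to end with no
external data: a packaged CHO-like toy network plus a synthetic cell-line
generator reproduce the statistical structure of real batch datasets.

## The model

During exponential growth at specific rate μ (h⁻¹), biomass and metabolite
concentrations follow

    BM(t)  = BM₀ e^{μt}
    [i](t) = [i]₀ + q_i (BM₀/μ)(e^{μt} − 1)

with q_i the exchange rate of metabolite i (mmol gDW⁻¹ h⁻¹, uptake
negative) and BM₀ [g/L] = cell density [cells/mL] × dry mass [pg/cell] ×
10⁻⁹.  Simulated measurements add independent Gaussian noise with a fixed
relative standard deviation (RSD) per sample.  Per Monte-Carlo draw the
pipeline refits (q_i, [i]₀) for every metabolite by least squares (μ, BM₀
fixed), takes the asymptotic standard error SE_i, constrains every exchange
reaction of the metabolic network to [q̂_i − SE_i, q̂_i + SE_i], and
maximizes biomass subject to S·v = 0.  Recorded per draw: the predicted μ,
or infeasibility.  Summaries cover the relative standard errors of the rates
(RSE = SE/|q̂|), quantiles of μ_predicted/μ_reference, feasibility
fractions, group-wise noise experiments (e.g. essential amino acids whose
uptake is below 1.5× their biomass requirement μ·b_i) and all-pairs ranking
of two cell lines.

## Worked example

```python
from fluxprop import (NoiseModel, PropagationConfig, build_reference,
                      builtin_dataset, growth_ratio_summary, load_toy_network,
                      make_schedule, propagate)

network = load_toy_network()
dataset = builtin_dataset("K1par-like")      # 252.3 pg/cell, 1.6e5 cells/mL
reference = build_reference(dataset, network)
print(reference.mu_ref)                      # 0.0384  (1/h)

cfg = PropagationConfig(schedule=make_schedule("regular", 24.0),  # daily
                        noise=NoiseModel(concentration_rsd=0.20),
                        n_draws=500, seed=5)
result = propagate(reference, dataset, network, cfg)
print(round(result.feasible_fraction, 2))    # 0.55
print(round(growth_ratio_summary(result)["iqr"], 2))  # 0.97
```

Reading: with daily sampling and 20% concentration noise, almost half of the
constrained FBA problems have no feasible solution at all, and among the
feasible ones the predicted growth rate scatters over an interquartile range
of ~1× the true value — single daily samples are simply not enough to feed
an FBA model.  Re-running at 2% noise and 6 h sampling gives feasibility
1.0 and IQR ≈ 0.05.

The `examples/` directory walks through each capability (reference states,
RSE vs sampling frequency, error propagation, metabolite-group experiments,
cell-line ranking, config-driven runs); each script prints a few numbers and
says what they mean.

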