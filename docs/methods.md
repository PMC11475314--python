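# Methods

## Scope and model

`fluxprop` studies one question: how does measurement error in batch-culture
time courses propagate, through rate fitting, into flux-balance-analysis
(FBA) growth predictions?  The pipeline has four stages — reference state,
simulation, fitting, propagation — and a statistics layer on top.

**Exponential-phase kinetics.**  All time courses assume balanced
exponential growth: biomass BM(t) = BM₀e^{μt} and metabolite concentration
[i](t) = [i]₀ + q_i(BM₀/μ)(e^{μt} − 1).  BM₀ is derived once from cell
density × dry mass per cell (pg/mL → 10⁻⁹ g/L); this is the package's single
unit conversion and is tested explicitly to prevent silent 10³ errors.
Death phase, stationary phase and fed-batch feeding are out of scope.

**Reference state.**  Measured exchanges are pinned with *equality* bounds
(lb = ub = q) and biomass is maximized; the reference is a noiseless
construct, so uncertainty intervals enter only during propagation.
Unmeasured essential uptakes (cysteine, tryptophan by default) are then
estimated by fixing μ at the optimum and minimizing their summed uptake
magnitude in a single LP — a joint minimization is deterministic and
independent of target order.  When such an amino acid is consumed only by
biomass synthesis the estimate equals μ·b_i exactly, which the tests assert.

**Noise model.**  Measurements are ideal value + N(0, (RSD·ideal)²),
independent per replicate, time point, metabolite and draw.  Negative
simulated concentrations are legitimate artifacts and are never clamped.
One root seed spawns a substream per draw; each substream splits into a
biomass stream and a concentration stream, and standard normals are drawn
before scaling by the RSD.  Consequences: (i) results are bit-reproducible
from the seed, (ii) different RSD scenarios share the same underlying
normals (common random numbers), so monotonicity comparisons across noise
levels are paired, and (iii) growth-fit experiments and full propagation
runs see identical biomass draws for a given seed.

**Rate fitting.**  With μ and BM₀ treated as known constants, the
concentration model is *linear* in its free parameters ([i]₀, q_i).  The
ordinary (unweighted) least-squares fit over all replicate points jointly is
therefore solved in closed form, and the reported asymptotic covariance
s²(XᵀX)⁻¹ is exactly what an iterative nonlinear fitter would report at the
same optimum.  The fit is deliberately unweighted despite the
heteroscedastic noise — this matches the default behavior of standard
nonlinear least-squares tooling in this field; a one-step inverse-variance
reweighting is available behind `weighted=True` but is off everywhere.
Growth fitting (BM₀e^{μt}) is genuinely nonlinear: Levenberg–Marquardt,
started from the log-linear regression estimate, tolerances 10⁻⁸, at most
200 function evaluations; failures and non-positive μ̂ are reported as
non-converged, never raised.

**Propagation.**  Per draw, every exchange reaction of each fitted
metabolite is bounded to [q̂ − SE, q̂ + SE]; the interval is kept symmetric
even when noise has flipped the sign of q̂ (a flipped essential uptake then
forces secretion and the LP goes infeasible — that is an outcome to count,
not an error).  Non-converged fits and dataset-listed exceptions keep the
network default bounds.  Biomass is maximized with GLPK (requested tolerance
10⁻⁹; mass balance asserted at 10⁻⁶); infeasible and unbounded outcomes are
recorded per draw, unbounded ones separately as anomalies.  Every public LP
entry point solves on a fresh model copy so results never depend on solver
warm-start history — this is what makes identical configs byte-identical.
With biomass perturbation enabled ("Sim 2" wiring), each draw first fits
(μ̂, BM̂₀) from its own noisy biomass series and uses that μ̂ both to
generate and to fit the draw's concentration profiles, as an experimenter
would; BM₀ keeps its true value, since dry mass is treated as a fixed,
separately determined cell-line constant.

## The toy network and synthetic cell lines

The packaged network (58 reactions) emulates the constraint structure of a
genome-scale CHO model at toy size: 23 exchanged metabolites (glucose,
lactate, ammonium, 20 amino acids), a biomass reaction with realistic
amino-acid demand coefficients (0.05–0.6 mmol/gDW) plus a glucose term,
aerobic glycolysis and full oxidation, catabolic disposal routes for every
amino acid, synthesis routes only for the nine nonessential ones, and urea
overflow for excess nitrogen.  Because essential amino acids have no
synthesis route, the maximal growth rate under uptake capacities c_i is the
closed form min_i c_i/b_i — the independent oracle used throughout the test
suite against the LP solver.

Synthetic cell lines are drawn so that the equality-pinned reference FBA is
feasible *by construction* and its optimum equals the requested μ: a
configurable subset of essential amino acids is consumed at 1.0–1.5× the
biomass requirement (the smallest multiple forced to exactly 1.0, making
that amino acid growth-limiting), the rest at larger excess; glucose uptake
covers biomass demand, minimal biosynthesis and the glycolytic flux implied
by the lactate rate with ≥30% oxidation slack; ammonium secretion is set to
half the net nitrogen release so nitrogen disposal never caps growth near
the optimum.  Rate magnitudes span ≥2 orders of magnitude (glucose ~0.2–0.3
vs. tryptophan ~0.002 mmol/gDW/h).  Initial concentrations are sized so
every consumed metabolite survives the 90 h horizon with margin.

The two fixed fixtures (`K1par-like`, `HYher-like`) carry published
biomass parameters — dry mass 252.3/279 pg per cell, 1.6×10⁵ cells/mL, 90 h
exponential phase — and are constructed to hit reference growth rates
0.0384/0.0321 h⁻¹ (a 16% gap) with the same near-limiting amino-acid sets
that the corresponding real cell lines show ({arg, lys, phe, thr} + the
LP-estimated cys/trp, and {arg, leu, lys, met, phe} + cys/trp).  Their
per-metabolite rate and medium profiles are *synthetic placeholders*
(`placeholder=True`), chemically-defined-medium-like but not transcribed
measurements; conclusions that depend on a specific real medium (e.g. the
exact identity of the top-7 highest-RSE metabolites) should be drawn from
user-supplied data loaded via the dataset CSV schema.

What passing tests do and do not show: the generator reproduces the
*structural* phenomena — RSE inversely related to rate magnitude at fixed
medium pool, RSE tripling from 6 h to daily sampling, growth predictions
governed by the near-requirement essential amino acids, sub-linear growth
error scaling, ranking power growing with the true gap.  It does not model
biological replicate variance distinct from measurement error, correlated
errors within an analytical batch, lognormal noise, or drifts of μ within
the exponential window; absolute error magnitudes on real data will differ
with the medium and instrument.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `concentration_rsd` | 0.02–0.20 | per-sample relative SD of metabolite measurements (study range) |
| `biomass_rsd` | 0.06 | cell-count RSD (typical automated counter accuracy) |
| schedule | regular 6/12/24 h over 90 h (16/8/4 points), or shift patterns with 4 samples/day | sampling design |
| `n_replicates` | 3 | independent replicate cultures per time point |
| `n_draws` | 1000 | Monte-Carlo sample size |
| `factor` (low-uptake set) | 1.5 | threshold on uptake / biomass requirement |

Shift schedules place the daily 4-sample block either after the gap
("gap_first": 0, 12, 16, 20, 24, 36, …) or before it ("gap_after_dense":
0, 4, 8, 12, 24, 28, …), with 4 h or 2.5 h spacing.

## Numerical and statistical choices

- Quantiles (including IQRs) use the median-unbiased estimator, stated here
  because IQR values are compared across implementations.
- In cell-line ranking, pairs with an infeasible member are dropped from the
  denominator (and counted); exact μ ties are conservatively scored as
  incorrect, with the tie rate reported.
- Ties in top-k-by-RSE break toward the smaller |q| (the more error-prone
  rate).
- Replicates are fitted jointly (all points in one design matrix) rather
  than averaged per time point; for the balanced designs used here the
  point estimates coincide, and joint fitting keeps the residual degrees of
  freedom explicit.
- RSE summaries use converged draws only and report the non-convergence
  count.

Problem sizes in the shipped tests and acceptance script (hundreds to 1000
draws, 300–500-draw propagations) were chosen as the smallest sizes at which
the Monte-Carlo noise of each asserted statistic is comfortably below its
assertion margin.

## A note on the square-root law

The spread of the propagated growth prediction grows sub-linearly with the
concentration noise, but the mechanism is selective: the predicted μ is a
minimum over several near-limiting uptake capacities, bounded below by
zero, and draws whose fitted rates conflict outright drop out as infeasible.
Both effects truncate the tails precisely where noise is large.  At daily
sampling — where infeasibility is common — quadrupling the concentration RSD
from 5% to 20% roughly doubles the growth RSD (ratio ≈ 2.3 on the toy
fixture, the square-root-like regime).  At dense 6 h sampling almost every
draw stays feasible and the scaling is close to linear (ratio ≈ 4), which is
also visible in the IQR ladder the dense-sampling experiments produce.  The
acceptance test for this law therefore runs at daily sampling, the regime
the law describes.

## Known limitations

- The biomass objective is the only objective implemented; alternative
  objectives change which measurements matter.
- No flux variability analysis, parsimonious FBA, or gene–reaction rules.
- `load_sbml` supports genome-scale FBC models (biomass detection by
  objective or name), but no genome-scale model is bundled; full-scale
  replication requires the user to supply the SBML file and rate tables.
- The toy network's catabolic and biosynthetic routes are single-step
  lumped reactions; only the constraint structure, not the pathway biology,
  is represented.
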