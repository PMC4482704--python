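# Methods

`riverscape` couples five model stages so that a change at the catchment or
reach scale propagates to a species-level statement about whether fish and
macroinvertebrates are likely to (re)populate a river reach. This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic data generator does and does not emulate.

## Flow regime

Daily discharge ensembles are reduced to flow-duration-curve statistics.
`exceedance_quantile` sorts a series descending, assigns Weibull plotting
positions i/(N+1), and interpolates linearly; outside the plotting-position
range the extreme values are returned. Qp denotes the discharge *exceeded*
p% of the time (hydrological convention, so Q75 ≤ Q50 ≤ Q25). Two products
feed downstream stages:

* **Q10** as the bankfull-proxy (channel-forming) discharge. It is computed
  per run on the full series and averaged across runs; pooling all runs
  first is available as a flag (`pooled_q10`), since either reading of
  "ensemble Q10" is defensible and the two differ only through FDC
  curvature.
* **Monthly Q75/Q50/Q25**: for each run, all days of a calendar month are
  pooled across years (maximizing the per-month sample rather than
  averaging per-year quantiles), quantiles computed, then averaged across
  runs. Leap days belong to February. Gaps in the daily series are an
  error, never silently dropped.

## Channel geometry and stage

Equilibrium bankfull width follows a downstream hydraulic-geometry (regime)
power law W = a·Q^b, fitted by OLS on ln W vs ln Q. `fit_regime` keeps the
log-residual standard deviation and the predictor's centred sum of squares
so `predict_width` can attach a log-space Student-t interval at a new
discharge. The default is a *prediction* interval (includes residual
variance — appropriate for a new reach); a mean-response interval is a
flag. When only (a, b, resid_sd, n) are supplied, the leverage term is
unavailable and se = s·√(1 + 1/n) is used.

Stage–discharge comes from a single-cross-section normal-depth Manning
inversion: wetted area and perimeter are computed from the surveyed
station–elevation polyline below a trial stage (vertical bank segments
contribute |Δz| of perimeter and no area; stations are therefore allowed to
be non-decreasing rather than strictly increasing), Q = A·R^(2/3)·√S / n,
and stage is found by bisection to 0.1 mm — tight enough that round-trip
discharge errors stay below 0.1% even at shallow stages. Stages above a
section endpoint are an overbank error unless vertical wall extension is
requested. This deliberately replaces a 1D step-backwater model: the chain
only consumes the downstream rating curve, and a steady normal-depth
relation is the minimal faithful stand-in. Compound/overbank geometry and
backwater effects are out of scope.

## Fish habitat: Mamdani fuzzy inference and WUA

Habitat preference for velocity and depth is encoded as trapezoidal fuzzy
sets (breakpoints z1 ≤ z2 ≤ z3 ≤ z4; z2 = z3 gives triangles, z1 = z2 a
crisp, left-closed shoulder) and an expert rule base. Inference uses the
classical Mamdani operator set — AND = min, implication = min (clip),
aggregation = max, centroid defuzzification — with the output domain [0, 1]
sampled at 0.001. These operators are the standard choice where a rule
system names the Mamdani scheme without further detail. When no rule fires
the suitability is 0 with an `undefined` flag: a conservative fallback,
since an unmodelled hydraulic combination then contributes nothing to
usable area.

WUA is the suitability-weighted sum of wet-cell areas. Monthly WUA series
(one value per month, driven by the monthly flow statistic — Q50 by
default, Q75/Q25 alongside) are standardized by the bankfull wetted area,
the maximum attainable value, yielding percentages whose median, range and
minimum are reported; the minimum flags a potential seasonal bottleneck.
WUA is an *area of suitable habitat*, not a prediction of presence or
abundance, and is not comparable across species in absolute terms.

## Macroinvertebrate habitat: substrate-based abundance

Abundance is Σ_k density_k × fraction_k × reach area, from
substrate-specific densities (ind/m²) and the reach's substrate
composition. Water quality corrects the reach-level abundance through
piecewise-linear dose–response factors in [0, 1]; multiple parameters
combine by the minimum (limiting-factor principle) by default, by product
as an option. Agreement between predicted and observed communities uses the
Renkonen percentage similarity (Σ min of relative percentages, 0–100).

Relative abundance standardizes the present-state prediction against
natural reference substrate conditions. Because natural cover varies,
references are *ranges* per class (e.g. 5–20% gravel); compositions are
Monte Carlo sampled as independent uniforms within the ranges renormalized
to the simplex (rejection sampling available when strict post-normalization
range adherence matters), and the median and min–max of the resulting
percentage are reported. Correction is applied per reach, not per
substrate. Abundances stay real-valued; rounding to individuals would add
nothing but discretization noise.

## Dispersal and re-colonization potential

The river network is a downstream-oriented DAG of reaches discretized into
cells of ~Δx (default 50 m; each edge uses equal cells of length/round(L/Δx)
so shares are insensitive to ragged remainders). Barriers sit on edges with
per-direction passabilities; in binary mode a passability at or below the
blocking threshold (default 0, i.e. only fully impassable structures block)
removes the corresponding directional arc at the cell boundary nearest the
barrier. Only upstream blocking is active by default; downstream passage
over weirs is assumed free.

**Fish.** Movement follows a leptokurtic two-component Gaussian mixture
(stationary share with σ_stat, mobile share p_mobile with σ_mob). The
operational rule is binary: the 99% quantile D of the absolute-displacement
mixture (bracketed root-finding to 1e-6 relative tolerance) defines
reachability, i.e. 1% of source individuals are predicted to move further.
A cell is reachable if some source reaches it along the network within D
without an impassable upstream crossing. The share of reachable network
length is the re-colonization potential; low/high kernel variants (e.g.
from a movement-regression confidence band) give the interval. Multi-year
periods scale σ by √t (diffusive default) or t (linear option). A full
probability-redistribution mode (splitting kernel mass at confluences)
is a possible extension; the binary quantile rule is what the assessment
consumes.

**Macroinvertebrates.** Three modes — aerial adult flight, aquatic upstream
larval movement, aquatic downstream drift — are evaluated by multi-source
Dijkstra accumulated cost (edge cost = length × per-metre friction; on
rasters, 8-neighbour moves with diagonal step ×√2 and mean endpoint
friction). Aquatic modes run on the network graph (upstream mode respects
barriers and moves only against flow; downstream mode only with flow);
the aerial mode runs on a land-cover friction raster when one is supplied
(accumulated cost sampled at each network cell's coordinates) and otherwise
on the network with barriers ignored. A cell is reachable under a scenario
when any mode's cost falls at or below that mode's threshold —
conservative (home range) or progressive (maximum individual movement) —
and the number of modes reaching each cell (0–3) is reported with the
per-mode shares.

**Sources.** Occupied cells can come from surveys or from thresholding a
species distribution model's presence probabilities at the value maximizing
sensitivity + specificity (Youden's J), with candidate thresholds at the
observed probabilities and ties broken toward the lowest threshold (the
more inclusive source set).

## Final assessment

Each species becomes a point on (standardized habitat metric,
re-colonization potential). Within each group the axes are ranked densely
in descending order (ties share a rank), and a four-quadrant classification
is applied with boundary values counting as "high". Thresholds default to
the within-group median on each axis — the combination is
semi-quantitative and no absolute cut generalizes across rivers — but any
fixed thresholds can be supplied; with quantile-based thresholds the
classification is invariant under monotone rescaling of an axis. Fish use
the monthly median WUA share as the headline metric with the monthly
minimum as a bottleneck indicator; ranking is per-axis (a single joint
ordering would hide which axis limits a species).

`run_chain` executes the stages in order on synthetic inputs, is a pure
function of its config (single seed fanned out to fixed substreams), writes
one artifact per stage, and logs parameters plus sha256 checksums — no
timestamps — so reruns are byte-identical.

## Synthetic riverscape

The generator provides statistically structured stand-ins for every input:

* **Hydrographs**: q(d) = mean · (1 + A·cos(2π(doy − peak)/365)) ·
  exp(N(0, sd²)). Defaults (mean 3 m³/s, amplitude 0.6, log-sd 0.35, winter
  peak) give a mid-sized Atlantic lowland regime with Q10 near 6 m³/s. No
  autocorrelation, flood recessions or snow dynamics are emulated.
* **Hydraulic grids**: straight channel, parabolic cross-channel bed, water
  level from the Manning normal-depth inversion at the requested discharge,
  velocity ∝ depth^(2/3) rescaled so the section flux matches the discharge
  within 1%. Width 11 m, thalweg depth 1.4 m, 0.5 m cells (0.25 m²) match a
  typical near-natural lowland reach. The default slope (0.0007) is set for
  hydraulic self-consistency: it makes bankfull conveyance ≈ 7 m³/s for
  this geometry, whereas the very flat slopes of backwater-dominated field
  reaches cannot be represented by a normal-depth model at all. No
  planform variation, secondary currents or bedforms.
* **Networks**: random dendritic trees (each reach attaches upstream of a
  uniformly chosen node; branching probability 0 degenerates to a chain),
  lognormal reach lengths around 1 km, barriers by a Poisson process at
  0.16 km⁻¹ with passability 0, sparse Bernoulli source cells (2%
  occupancy, scattered refugia). Real drainage geometry (Horton ratios,
  valley confinement) is not emulated.
* **Substrate**: Dirichlet draws with per-class concentrations
  (sand-dominated by default), plus a degenerate pure-sand option for the
  degraded baseline.

Species parameter sets (fuzzy rule bases for a shallow-water minnow and a
pool roach; substrate densities and nitrate dose–response curves for a
psammophilous mayfly and a lithophilous caddisfly) are illustrative
expert-style constructions, not field-derived preference data. Passing
tests on synthetic data therefore demonstrates the *mechanics* of the chain
— correctness of the statistics, hydraulics, inference, graph algorithms,
and their coupling — not the predictive skill of any particular species
parameterization on a real river.

## Numerical choices and problem sizes

* Centroid defuzzification samples [0, 1] at 0.001; equivalence with a
  dense-grid integration oracle holds to 1e-3.
* Stage bisection: 0.1 mm; kernel quantile: 1e-6 relative; reference
  sampling: 500–2000 draws depending on use.
* The shipped chain runs 10 hydrograph runs × 5 years, a 40×22-cell grid
  per month, a 30-reach network at Δx = 50 m, and 500 reference
  compositions — sizes chosen so a full chained run completes in seconds
  while every stage still exercises its full code path.
* Statistical acceptance checks (e.g. 90% interval coverage of the regime
  exponent over 500 replicates) use fixed seeds and tolerance bands sized
  by binomial sampling error.

## Known limitations

Hydraulics are steady, single-section and normal-depth; habitat uses only
velocity and depth (temperature, oxygen and cover are plausible
extensions); WUA does not translate into abundance; dispersal reachability
is binary with no demography, within-generation timing, or partial
passability in the binary rule; species interactions are not modelled; the
quadrant classification depends on the chosen thresholds wherever a group's
values cluster near the median split.
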