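# Methods

`streammox` models the link between methane-oxidation (MOX) kinetics in
stream sediments and the structure of the methanotroph (MOB) community that
carries them out. It has two halves: a forward half (a synthetic-study
generator with known ground truth) and an inverse half (the estimators a
field study would apply to its measurements). Every estimator is validated
by recovery against the generator's planted truth.

## Chamber incubation model

Sediment MOX follows Michaelis–Menten kinetics per unit sediment surface
area,

    V(S) = V_max · S / (K_S + S),

with `V_max` in nmol CH4 m⁻² h⁻¹ and `K_S` in µM. In a closed, well-mixed,
headspace-free chamber holding sediment of surface area `A` (m²) under a
water volume `V_w` (mL), the dissolved CH4 concentration obeys

    dC/dt = −(A / V_w) · V_max · C / (K_S + C),

optionally plus a volumetric streamwater term `−w_max · C/(K_w + C)` for the
planktonic community (this term is what sediment-free blank chambers
measure). The default chamber is a 760 cm³ cylinder with ~25 g wet sediment;
`A` is wet mass × specific surface area. The specific area (default
1 m² g⁻¹) is a free configuration constant: absolute per-m² scales in the
synthetic study are conventional, and rescaling `A` rescales `V_max` only
(`K_S` is invariant, which is tested).

Each measurement withdraws `v` mL (default 30) and replaces it with
air-equilibrated streamwater, so concentrations jump to
`C·(V_w−v)/V_w + C_repl·v/V_w`. The initial concentration comes from
equilibrating streamwater with air amended to 1% CH4 at 20 °C (~15.6 µM via
the solubility model below). CO2 is produced and O2 consumed in fixed
stoichiometric ratios to the CH4 oxidised (defaults: 1 CO2 and
`2(1−CUE)+CUE` O2 per CH4, carbon-use efficiency CUE = 0.5). The CO2/O2
series are quality-control only: intervals with dissolved O2 below 50 µM are
flagged as potentially O2-limited and excluded from fitting.

The simulator integrates each inter-event segment with an adaptive solver
(LSODA, rtol 1e-10) and tracks consumption as an independent quadrature
state, so the mass ledger (consumed + remaining + removed − added − initial)
closes only to solver accuracy; the tests require 1e-9 relative at every
sampling event. Measurement noise is multiplicative lognormal (mean-one)
applied to reported values only; the internal state stays exact and is
retained as ground truth.

## Kinetics inversion

Between events the chamber ODE has the classical implicit progress-curve
solution `K_S ln(C0/C) + (C0 − C) = (A/V_w)·V_max·t`, which the trajectory
fitter evaluates exactly by bracketed root finding — no re-integration, so a
fit costs milliseconds and the simulator (ODE) and the fitter (implicit
form) remain independent routes. Fitting minimises *relative* residuals
between observed and modelled concentrations: the error model is
multiplicative, and the low-concentration tail carries most of the `K_S`
information. Replicate chambers are fit jointly with shared parameters by
default.

Optimisation is bounded multi-start least squares (5 seeded starts,
`V_max ∈ [0, 10×max observed rate]`, `K_S ∈ [1e-3, 10×max S]`; ties broken
by RSS then smaller `K_S`); standard errors come from the Gauss–Newton
`(JᵀJ)⁻¹` approximation. A series whose total dilution-corrected consumption
is below 10% of the initial CH4 inventory is reported as `V_max = K_S = 0`
("no detectable MOX"): noise alone produces apparent consumption of a few
percent, while any real multi-day MOX signal consumes far more.

A pointwise mode is retained for comparability: per-interval rates
`V = consumed/(A·Δt)` at `S` = the geometric mean of the interval's
(event-adjusted) endpoint concentrations, fit directly to the rate law.
Blank correction subtracts interval-matched mean blank consumption per
chamber *before* area normalisation; it is exact only while blank and
sediment chambers sit at similar concentrations, so it is accurate early in
an incubation and degrades as the trajectories diverge (tested at a 10%
streamwater contribution: first-day intervals recover sediment-only rates
within 2%).

Derived quantities: the putative in-situ MOX rate is the fitted rate law
evaluated at ambient streamwater CH4 — a lab-kinetics extrapolation, hence
"putative" — and carbon fixation is that rate × CUE (1 C per CH4).

## Headspace gas chemistry

Dissolved CH4/CO2 are measured by equilibrating 30 mL of sample with 30 mL
N2, transferring the headspace and diluting it to 50 mL with N2. The forward
model solves the closed two-phase mass balance with temperature-dependent
Henry solubilities (Sander compilation: H_cp(298 K) = 1.4e-3 M atm⁻¹ for
CH4, 3.3e-2 for CO2, van 't Hoff slopes 1900/2400 K; valid 0–40 °C) and
applies the dilution factor. The balance is linear in concentration, so the
inversion is exact; round trips are tested to 1e-6 relative. Ionic-strength
corrections are omitted (freshwater) and CO2 is treated as free dissolved
CO2 — carbonate speciation would make the reported "CO2" a lower bound at
these pH values, a deliberate, documented simplification. The streamwater
CH4:CO2 ratio is provided as a proxy for in-situ CH4 production.

## Community landscape

The landscape procedure types communities the way enterotype analyses do,
but over OTU (species) scores:

1. Sites with fewer than 2 MOB OTUs are excluded (extremely oligotrophic
   samples carry no co-occurrence information about methanotrophs).
2. Bray–Curtis dissimilarities on per-site relative abundances.
3. Non-metric MDS (k = 2) by SMACOF majorization with Kruskal's monotone
   regression, reporting stress-1 ∈ [0, 1]; 20 restarts (first from
   classical scaling, rest random, seeded), best solution centred and
   rotated to principal axes. Disparities are rescaled to the distances'
   sum of squares every iteration and the configuration is renormalised —
   without this the configuration silently collapses toward a point.
   Per-restart stress traces are kept so monotone descent is testable.
4. OTU scores = relative-abundance-weighted averages of site scores.
5. A 2-D Gaussian kernel density over OTU scores (Scott's rule by default)
   on a grid covering the scores with a margin of max(5% of span, 3 kernel
   SD) so the density integrates to ~1; peaks are 8-connected components
   above a density cutoff (default 0.5), each reported at its maximum.
   Absolute density values depend on bandwidth and grid and are not
   comparable across datasets; peak structure is.
6. MOB OTU scores are clustered with seeded k-means (k = 2). OTUs farther
   than `outlier_rule` (default 3) × a robust cluster scale from their
   cluster's core are labelled unassigned. The scale is deliberately
   robust: the cluster centre is the coordinate-wise median of members, the
   radius the median distance of the closer half, floored at 5% of the
   centre separation; clusters with fewer than 3 members count as stray
   coalitions. After flagging, k-means is refit once on the retained OTUs.
   A plain centroid + median-radius rule fails here because a handful of
   coherent outliers drags the centroid and inflates the radius until
   nothing is flagged.
7. A convex hull around each MOB cluster's scores collects the non-MOB OTUs
   inside it (boundary counts as inside; a collinear cluster degrades to a
   thin buffered segment with a warning), and their taxonomy is compared
   with the whole community: per-taxon share among hull members vs share in
   the background, their ratio, and an optional one-sided permutation p
   (equal-size random member sets). Shares are per-OTU, not read-weighted.

The environmental ordination is standard PCA (centred, optionally scaled)
with envfit-style vector fitting: each variable is regressed on the score
axes, R² is the squared multiple correlation and p comes from seeded
permutation of the variable. `fit_surface` fits a per-site variable over the
score plane with a thin-plate-spline radial basis and a ridge penalty chosen
by leave-one-out cross-validation — a deliberately simpler smoother than a
full generalized additive model, adequate for ~14 sites, reporting LOO R².

## Synthetic-study generator

The generator emulates the study conditions end to end; its defaults are the
conditions all recovery tests and the acceptance script run under.

* **Sites.** 14 sites in three catchment archetypes — 2 alpine, 6 forested,
  6 agriculture/urban — with archetype mean concentrations and lognormal
  between-site spread (CV 0.35). Porewater CH4 always exceeds streamwater
  CH4 (means 0.05/6.0/3.5 µM porewater vs 0.005/0.15/0.40 µM streamwater
  by archetype). True kinetics follow the supply: `V_max` = 90 × streamwater
  CH4 (spanning ~0–54 nmol m⁻² h⁻¹), `K_S` = 0.9 × porewater CH4 (spanning
  ~0.5–11 µM), and the alpine sites are planted at `V_max = K_S = 0`.
* **Depth profiles.** CH4 rises from the streamwater value at depth 0 to
  the porewater value with a unimodal bump peaking exactly at 10 cm
  (`g(z) = (z/10)·e^{1−z/10}`); O2 decays monotonically with depth.
* **OTU table.** 2000 OTUs, 150,000 counts per site (Poisson around
  expected abundances; amplicon surveys of this kind typically sequence
  hundreds of thousands of reads per site). 36 MOB
  OTUs flagged by *Methylococcaceae* taxonomy: 23 "cluster 1" core OTUs
  whose abundance scales as (streamwater CH4)^1.5 — the exponent places
  alpine MOB relative abundance at the observed ~0.001% floor so alpine
  sites drop out by the sparse-site rule; 7 "cluster 2" OTUs restricted to
  the five most forest-dominated sites; 6 sporadic low-abundance outliers,
  each detected in one cluster-2 site and one site outside the subset, so
  their scores fall in the gap between the two co-occurrence groups.
  Background OTUs get lognormal sizes and Gaussian niche responses along
  three rank-standardised gradient axes (streamwater CH4, porewater CH4,
  and one unmeasured axis). Continuous niches matter: discrete archetype
  preferences make all between-group dissimilarities exceed all
  within-group ones, and non-metric MDS then admits a degenerate zero-stress
  collapse.
* **pmoA counts.** Proportional to MOB relative abundance × total cells
  (one copy per genome), with a detection limit below which values are
  censored.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: sequencing compositionality beyond Poisson sampling,
chimeras and OTU-calling artefacts, temperature dependence of kinetics,
two-component (high-/low-affinity) MOX, methanogenesis in the sediment
column, and spatial autocorrelation among sites.

## Associations

Ordinary least squares with exact t-based p-values for the slope
(`scipy.stats.linregress`), raw p-values (no multiple-testing correction by
default; Benjamini–Hochberg available), and explicit per-analysis exclusion
lists — e.g. a wetland-draining outlier site, or sites with porewater CH4
below 1 µM for which the K_S-to-porewater percentage is numerically
meaningless. Sites with `V_max = 0` are dropped from that comparison
automatically. pmoA copies are converted to "cells harbouring pmoA"
assuming one copy per genome; log10 transforms are available for marker
counts.

## Numerical choices and problem sizes

* ODE: LSODA, rtol 1e-10/atol 1e-13; implicit-solution root finding:
  brentq at xtol 1e-15.
* nMDS: convergence when stress change < 1e-6, 500 iterations max,
  20 restarts.
* k-means: 20 initialisations, seeded.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give identical outputs.
* Test and acceptance problem sizes: 14 sites × 3 replicate chambers,
  twice-daily sampling over 4 days, 2000 OTUs at 150k counts/site, 200
  Monte-Carlo fits for noise calibration, 100 random chamber geometries for
  the mass-balance check. The full suite runs in about a minute.

## Known limitations

* Blank correction is interval-matched, not concentration-matched; it
  over-corrects late intervals once sediment chambers deplete below the
  blanks (documented, tested at its accurate range).
* The (0,0) "no detectable MOX" convention conflates "no methanotrophs"
  with "activity below the consumption threshold".
* `fit_surface` is a penalised smoother, not a full GAM; with ~14 sites its
  LOO R² is noisy for non-smooth responses.
* Peak counts from the density landscape depend on bandwidth and cutoff;
  only their qualitative structure (how many planted modes survive a given
  cutoff) is meaningful.
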