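# Methods

This note documents the models, the estimation machinery, the synthetic
data generator, and the numerical and design choices behind `tscmdyn`.

## Model family

All cell-kinetic models assume a linear, one-way differentiation pathway
from naive T cells (T_N) into the stem-cell-like memory pool (T_SCM),
with both pools at population steady state over the study period.
Recruitment of a naive cell (per-capita rate `Δ`, per day) triggers a
clonal burst of `k` divisions producing `2^k` T_SCM cells; `k` is treated
as a fixed integer in 0–20 (larger bursts are not biologically
plausible), and every analysis can be repeated across that range (the
k-scan). Nonlinear (density-dependent) differentiation and
dedifferentiation from downstream memory subsets are out of scope.

**Label kinetics.** Deuterium enrichment of DNA is driven by body-water
enrichment `U(t)`, an empirical two-phase exponential (rise to plateau
`f_r` at turnover rate `δ_w` from baseline `β_s`; exponential washout
after label cessation at `τ = 49` days). `U(t)` is fitted per subject
from saliva measurements, with `τ` fixed to the protocol value, and is
then treated as known. The fraction-of-labelled-DNA equations are linear
ODEs driven by `c·U(t)`, where `c` is the subject-level amplification
between body-water and adenosine enrichment.

Three variants:

* *homogeneous*: the disappearance rate of labelled T_SCM DNA equals the
  bulk steady-state replacement rate, `d_s = 2^k Δ T_N/T_SCM + p_s`;
* *implicit heterogeneity*: that constraint is relaxed (`d_s*` free) —
  in a kinetically heterogeneous pool, labelled cells over-represent the
  fast subpopulations and are lost faster than the bulk;
* *explicit heterogeneity*: two subpopulations, a fraction `f` of each
  burst entering the second (slow) pool. Substituting the steady-state
  size ties makes the fraction equations depend on the subpopulation
  rates only — `Δ` and `f` drop out of the labelling observable
  entirely, which is exactly why labelling alone cannot resolve the
  subpopulations and the telomere and vaccine data are needed.

The measured bulk T_SCM label fraction and telomere difference are
size-weighted means of the subpopulation values (a sorter sees a single
T_SCM gate); the weights are the steady-state relative sizes.

**Telomere difference.** With `δ` base pairs lost per division (default
50, accepted range 35–70) and telomerase compensating all but `C` of the
burst divisions (`0 ≤ C ≤ k`), the difference between mean T_SCM and
naive telomere lengths, `Θ` (bp, positive when T_SCM cells have divided
more), follows a scalar linear ODE relaxing at rate `Δ 2^k T_N/T_SCM` to
`Θ_ss = Cδ + (p_s − p_n) δ T_SCM/(2^(k−1) Δ T_N)`. `C` is handled in
three modes — free within `[0, k]`, fixed 0, fixed `k` — because the
telomerase activity of these pools is not known independently.

**Vaccine decay.** Cross-sectional antigen-specific T_SCM frequencies
are modelled as `A (r e^(−αt) + (1−r) e^(−βt))` with `α, β` the two
subpopulations' net clonal loss rates (`d_si − p_si`, converted to
per-year) and `r = 1 − f`: each vaccine-induced clone is assumed to
split between the pools like a naive-derived burst. The linkage function
is configurable; `A` is a free cohort-level amplitude. Residuals for
this data type are taken on log10(frequency) because observations span
several orders of magnitude over ~35 years; values below an optional
detection limit are treated as left-censored.

**Derived quantities.** Clonal half-life `ln 2/(d − p)` (duration of
memory for a clone, not the population-replacement half-life); degree of
self-renewal `1/(d − p)` (mean residence time of a cell and its progeny;
infinite for a non-decaying pool); fraction of newly generated T_SCM
cells of naive origin; steady-state relative subpopulation sizes;
initial antigen-specific clone size `1e11 · 2^k · Δ · f` (naive pool
~1e11 cells; representative `Δ = 1e-5` and `f = 1` for bulk-pool
lifespans).

## Solvers and oracles

The label-fraction ODEs are linear with piecewise-exponential forcing,
so the production solver augments the state vector with the forcing
exponential and evaluates the exact matrix exponential at each requested
time (eigendecomposition per phase, vectorised over times, with a
per-time `expm` fallback whenever two rates are numerically coincident
and the eigenbasis approaches defectiveness). This is exact to machine
precision and fast enough for thousand-replicate simulation studies.
Two independent routes guard it: an adaptive LSODA integration
(rtol 1e-8, atol 1e-10, integrated piecewise around the kink at `τ`) and
a deliberately naive fixed-step Euler integrator (dt = 1e-3 d; also in a
batch form vectorised across parameter draws). Solver-oracle agreement
is asserted at 1e-4 relative to each curve's maximum — pointwise
relative comparison at the earliest times would measure Euler's own
truncation error on near-zero values rather than solver disagreement.

The telomere mean-division ODE is cross-checked against a brute-force
division-indexed compartment system (cells binned by divisions
undergone, default 200 classes). Because the mean divisional age of a
stationary pool grows linearly without bound and the size-weighted
division distribution of a strongly self-renewing pool has a geometric
tail with ratio `2p/(p+d)`, the truncated system is only trustworthy on
a bounded time window; the oracle therefore caps its integration time,
verifies the truncated tail mass (< 1e-9 of each pool), reports whether
steady state was reached, and is compared against the closed-form
transient at the same finite time otherwise.

The Gillespie implementation exploits the fact that in a linear
birth–death process the event-type probabilities `p/(p+d)` do not depend
on the population size, so event batches can be pre-drawn and cumulated
vectorially without any approximation — the algorithm remains the exact
SSA. Per-run substreams are spawned from the master seed
(`numpy.random.SeedSequence`), so ensembles are reproducible and
order-independent. The closed-form extinction law
`P(extinct by t) = q(t)^n0`, `q(t) = d(1−e^(−(d−p)t))/(d − p e^(−(d−p)t))`,
serves both as an independent distributional check on the SSA and as the
route to lifespan quantiles for clone sizes (up to `1e6·2^k` cells)
where event-by-event simulation is impractical — the k-scan's
precursor-lifespan column uses it.

## Fitting

One fitting unit is a subject/lineage bundle: naive and T_SCM label
time courses, one `Θ`, and optionally the vaccine cohort. Rates are
fitted on log10 (magnitudes span 1e-5–1e-1 per day; default bounds
1e-6–0.3), `f` on the unit interval, `C` linearly in `[0, k]`.
Optimisation is a seeded Latin-hypercube multi-start (default 20 points)
polished by trust-region bounded least squares; every start's outcome is
logged so multimodality is visible, and ties are broken toward the
lowest slow-loss rate, then lexicographically. Refitting from a returned
optimum reproduces its SSR to 1e-8 relative, and identical seed and
configuration give identical results.

**Weighting.** The default strategy standardises every residual by its
measurement SD (label on the natural fraction scale, `Θ` in bp, vaccine
on log10). This is the weighting under which the weighted SSR is a
chi-square functional and Fisher's F-test for nested variants keeps its
nominal type-I error; simulation at the study design confirms a
rejection rate of ~0.04 at nominal 0.05 over 1,000 null replicates.
Four alternative strategies are exposed (equal, count-normalised,
per-dataset SSR/(n·σ²), telomere-upweighted ×10, vaccine-upweighted
×10) for sensitivity analyses; the SSR/(n·σ²) form deliberately
equalises dataset influence at the cost of the F-test's calibration.

**The amplification factor `c` is fixed by default.** With `c` free, a
homogeneous model can reproduce the label curve of a heterogeneous pool
almost exactly: a single pool's uptake/loss asymmetry is an amplitude
effect, and a free amplitude absorbs it (we measured homogeneous and
implicit SSRs within 0.03% of each other on noise-free heterogeneous
data). The heavy-water amplification of adenosine enrichment is
subject-level chemistry, measurable by calibration independent of the
cell kinetics, so the package treats `c` as known per subject
(`FitConfig.c_fixed`), which restores the homogeneity test's power
(median p ~ 1e-9 on synthetic heterogeneous data at study noise); a
free-`c` mode within bounds [0.5, 6] remains available.

**Model comparison.** Homogeneous vs implicit (and naive-pool
homogeneous vs relaxed) differ by exactly one parameter; `n` is the
number of residual points (label points + 1 telomere point + any vaccine
points). The full model is always additionally polished from the reduced
optimum, enforcing the nested SSR ordering by construction. Per-dataset
p-values are pooled with Fisher's combination (−2Σln p ~ χ²(2m)); the
median p is reported alongside. The constrained fit bounds the slow
subpopulation half-life (default 5–15 years) and, when the bound binds,
compares constrained and unconstrained SSRs by an F-test with one
effective parameter removed — "compatible" means statistically
indistinguishable.

**Confidence intervals.** Default: parametric bootstrap — resimulate
measurement noise around the fitted curves, refit from the point
estimate, take percentile intervals; refits use unbounded
Levenberg–Marquardt when every free parameter is log-scaled (positivity
is then automatic, and LM is much faster along sloppy ridges), with a
soft box two decades beyond the fitting bounds to prevent overflow. A
profile-likelihood mode (F-ratio threshold on a local grid) is also
provided. Percentile-bootstrap coverage is close to nominal for
identifiable quantities (measured ~0.93 for `d_s*`, ~0.97 for `d_s` at
nominal 0.95) but degrades along the structurally sloppy
`Δ·ratio`-vs-`p_s` ridge (~0.65) — interval statements about those
individual parameters should use the profile mode or be read as
ridge-conditional. A bootstrap refit failure rate above 20% sets a
warning flag.

## Synthetic studies

The generator emulates the study conditions: 5 subjects; 7-week
labelling (`τ = 49` d); 12 label sampling times to day 280; 11 saliva
times to day 84; CD4 and CD8 lineages; one `Θ` per subject/lineage; a
37-subject vaccine cross-section with log-uniform times over 0.27–35
years. Noise is Gaussian: label SD 5e-4 (fraction units, additive,
truncated at zero), `Θ` SD 150 bp, saliva SD 2e-3, vaccine log10 SD 0.3
— chosen once as visually comparable to published labelling scatter.
Between-subject variation is applied to the water parameters (lognormal,
CV 0.1); kinetic ground truth is shared across subjects so recovery is
scored against a single target. The default truth uses naive
proliferation 5e-4/day, fast-subpopulation proliferation 0.015/day and
half-life 0.41 y, slow-subpopulation proliferation 0.002/day and
half-life 8.74 y, burst fraction f = 0.058, k = 5, c = 4, body-water
plateau 0.02 with turnover 0.06/day, δ = 50 bp with C = 2, and vaccine
amplitude 5e-4.

What passing closed-loop tests does *not* show: real labelling data have
non-Gaussian and heteroscedastic measurement error, within-subject
kinetic variability, possible departures from population steady state,
and an unknown vaccine-clone linkage — recovery under the generator is a
necessary, not sufficient, condition for trustworthy real-data fits.

## Simulation-study sizes

The shipped acceptance computations use 1,000 null replicates for the
F-test type-I error, 40 for power, 100 random draws for solver-oracle
agreement, 25 replicates for explicit-model recovery, 200 outer × 40
bootstrap replicates for CI coverage, 10,000 runs for the single-cell
Gillespie check and 1,000 for the large-clone half-life; the lean
homogeneity-test protocol for large simulation studies fits the reduced
model from two multi-starts and polishes the full model from the reduced
optimum only. The pipeline's Gillespie stage scales the initial clone
size down (configurable `gillespie_scale`) because a full-size slow
clone (~6e7 cells) generates ~1e9 events per realisation.

## Known limitations

* `k` and the individual rates are structurally poorly identifiable from
  labelling alone; conclusions should be drawn from the k-scan and from
  identifiable combinations (bulk replacement rate, net loss rates).
* The implicit (one-pool) model cannot represent a two-pool bulk curve
  exactly; its fitted `d_s*` is an effective, label-weighted loss rate.
* The explicit model fixes the number of subpopulations at two.
* Fraction observables assume constant pool sizes; growth or attrition
  of the compartments during the study would bias rate estimates.
* The compartment oracle requires integer `C`; the fitted `C` is
  continuous.
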