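# tscmdyn

Quantitative dynamics of human stem cell-like memory T (T_SCM) cells:
mechanistic ODE models, joint multi-dataset fitting, and exact stochastic
simulation of antigen-specific clone fates.

## The scientific problem

Long-lived T-cell memory is hypothesised to be maintained by a
self-renewing precursor population, the CD95+ CCR7+ CD45RA+ T_SCM subset.
Whether circulating T_SCM cells actually have the dynamics of a stem cell
population — long clonal half-lives and a high degree of self-renewal —
cannot be read off any single data type. This package implements a joint
analysis of three complementary in-vivo measurements:

1. **Deuterium (heavy-water) labelling.** Subjects drink ²H₂O for 7 weeks;
   the fraction F of labelled deoxyadenosine in sorted naive and T_SCM DNA
   traces proliferation and disappearance. With body-water enrichment
   `U(t)` (fitted per subject from saliva), amplification factor `c`, naive
   proliferation `p_n`, per-capita recruitment `Δ` with a clonal burst of
   `k` divisions, T_SCM self-renewal `p_s`, and labelled-DNA loss rate
   `d_s*`, the fractions at population steady state obey

       dF_TN/dt   = p_n (c U(t) − F_TN)
       dF_TSCM/dt = (Δ T_N/T_SCM) ((2^k − 1) c U(t) + F_TN) + p_s c U(t) − d_s* F_TSCM

   Constraining `d_s* = d_s = 2^k Δ T_N/T_SCM + p_s` asserts kinetic
   *homogeneity*; leaving `d_s*` free admits *implicit heterogeneity*, and
   an *explicit* variant models two subpopulations (a fraction `f` of each
   burst entering the slow pool).

2. **Telomere length.** Each division removes `δ ≈ 50` bp; the difference
   Θ between mean T_SCM and naive telomere lengths counts excess divisional
   history, with steady state
   `Θ = Cδ + (p_s − p_n) δ T_SCM / (2^(k−1) Δ T_N)`
   (`C` = burst divisions not compensated by telomerase).

3. **Vaccine cross-section.** Tetramer⁺ T_SCM frequencies measured once per
   subject 0.27–35 years after yellow-fever vaccination decay
   biexponentially, `F(t) = A (r e^(−αt) + (1−r) e^(−βt))`, with
   `α, β` the subpopulations' net clonal loss rates and `r = 1 − f`.

Fits minimise an inverse-variance-weighted sum of squared residuals over
any subset of the three data types (seeded Latin-hypercube multi-start +
bounded least squares); nested variants are compared with Fisher's F-test;
clone fates (extinction times, population half-lives) are simulated with
the exact Gillespie algorithm. Key derived quantities: clonal half-life
`ln 2/(d−p)` (the duration of memory, not the population-replacement
half-life) and the degree of self-renewal `1/(d−p)`.

A first-class synthetic-study generator reproduces the statistical shape
of all four inputs from known ground truth, so every estimator is tested
closed-loop (generate → fit → score).

## Worked example

```python
import numpy as np
from tscmdyn import (FitConfig, fit_model, default_truth, StudyDesign,
                     generate_study)

study = generate_study(default_truth(), StudyDesign(), seed=1)
data = study.fit_data("S01", "CD8", include_yfv=True)
cfg = FitConfig(variant="explicit", datasets=("label", "telomere", "yfv"),
                c_fixed=4.0, n_starts=8, seed=3)
fit = fit_model(cfg, data)
for k, v in fit.derived.items():
    print(f"{k:>22s}: {v:.3f}")
```

prints

```
     half_life_1_years: 0.403
     half_life_2_years: 10.120
       relative_size_2: 0.571
                     f: 0.050
   fraction_from_naive: 0.216
     self_renewal_days: 5332.744
```

i.e. the fit recovers a fast T_SCM subpopulation (half-life ≈ 0.4 years,
ground truth 0.41) and a slow one (half-life ≈ 10 years, ground truth
8.74), with ≈ 5% of each clonal burst entering the slow pool, which
nevertheless makes up ≈ 57% of the T_SCM compartment and shows a degree
of self-renewal of ≈ 5,300 days.

The same analysis runs end to end from the shell:

```bash
tscmdyn synth --seed 1 --outdir study/
tscmdyn run-all --data study/ --seed 1 --outdir results/
tscmdyn report --results results/
```

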