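# Methods

## Free-energy model

The package analyses alchemical annihilation simulations. A solute's
Coulomb and Lennard-Jones interactions are switched off along a coupling
parameter λ interpreted as *annihilation progress*: (λ_C, λ_LJ) = (0, 0)
is the fully interacting state, (1, 1) the fully decoupled one. The
two-stage path ramps λ_C first (λ_LJ held at 0) and λ_LJ second (λ_C
held at 1); with the default 0.05 steps in both stages this is 41 states
and 40 windows. The schedule is bookkeeping only — no soft-core or other
potential is evaluated here; work values arrive from files or the
synthetic generator.

For each window pair i → i+1 the work W = U_{i+1} − U_i is sampled in
both neighbouring ensembles. The window free energy ΔG_i is the root of
the Bennett acceptance ratio (BAR) self-consistency condition

    ⟨f((W − ΔG_i)/RT)⟩_i = ⟨f(−(W − ΔG_i)/RT)⟩_{i+1},   f(x) = 1/(1+eˣ).

The left side is strictly decreasing and the right strictly increasing
in ΔG_i, so the residual (left − right) is strictly monotone and the
root unique. For unequal sample counts the standard Bennett offset
M = RT ln(n_f/n_r) enters the fermi arguments and the two averages are
count-weighted; both corrections vanish for equal-length sampling, which
is the default regime. A leg total is the ordered sum of window free
energies; the solvation free energy is assembled from the solvent and
gas legs as ΔG_solv = (−total_solvent) − (−total_gas), the negations
converting from annihilation direction to the physical coupling
direction so that favourable solvation is negative. Independent
replicate runs are combined by arithmetic mean with stderr = sd/√n (no
weighting scheme is imposed; replicates are treated as exchangeable).

logP_ow = −(ΔG_octanol − ΔG_water)/(ln 10 · R·T). The denominator
constant is ln(10) = 2.302585…; an option reproduces the commonly
typeset rounding 2.303 (difference < 0.02 % of logP). Correction terms
for charge-set perturbation between environments are not implemented —
the two ΔG values are combined as-is.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| R | 8.3145×10⁻³ | kJ·mol⁻¹·K⁻¹ | CODATA, to the precision used throughout |
| T | 298.15 | K | ambient simulation temperature |
| λ steps | 0.05 / 0.05 | — | 41-state, 40-window two-stage path |
| BAR root tolerance | 10⁻⁸ | kJ/mol | far below the 0.01 kJ/mol reporting precision |
| bootstrap resamples | 200 | — | replicate-style uncertainty, cheap at these n |
| kcal→kJ | 4.184 | — | thermochemical calorie |
| dielectric prefactor C | 3.0339×10⁴ | K·Å³·D⁻² | derived below |

## Numerical choices

- **Root finding.** The BAR root is bracketed at
  [min W − 50RT, max W + 50RT], doubled up to 60 times if needed, then
  refined with Brent's method. After convergence the residual must
  straddle zero at ±max(10·tol, 10⁻⁷); a flat plateau there means the
  forward and reverse work distributions share no support at double
  precision, and an overlap-failure error carrying the overlap
  diagnostic is raised instead of returning a meaningless midpoint.
- **Bootstrap stderr.** 200 seeded resamples per window. All resample
  roots are found by a single vectorised bisection (tolerance 10⁻⁶
  kJ/mol — an order below the bootstrap sd at the default sample sizes),
  which keeps 40-window legs fast; the point estimate itself still uses
  Brent at 10⁻⁸.
- **Overlap diagnostic.** Histogram intersection of the two empirical
  work distributions on a 50-bin grid spanning the pooled range; 1 for
  identical sets, 0 for disjoint. It is a diagnostic, not an input to
  the estimate.
- **Leg sums** use compensated summation; per-window stderrs combine in
  quadrature only when every window carries one.
- **Schedules** validate step divisibility with a 10⁻⁹ tolerance and
  store λ rounded to 10 decimals, absorbing binary-fraction artifacts
  of steps like 0.05.
- **Exponential averaging** (the one-sided Jarzynski cross-check) is
  evaluated through log-sum-exp and never overflows.

## Dielectric constant

The static dielectric constant comes from the total-dipole fluctuation
of the solvent box (Gaussian-CGS form):

    ε = 1 + 4π (⟨M²⟩ − ⟨M⟩²) / (3 k_B T ⟨V⟩)

With the fluctuation in Debye², volume in Å³ and temperature in K, the
unit reduction collapses into a single constant
C = 4π(10⁻¹⁸ esu·cm)²/(3 · 1.380649×10⁻¹⁶ erg/K · 10⁻²⁴ cm³)
= 3.0339×10⁴ K·Å³·D⁻², kept in one auditable place (`constants.py`).
⟨V⟩ is the arithmetic mean of per-frame volumes (NPT); the fluctuation
subtracts the *vector* mean, so ε is invariant under global rotations
and constant dipole offsets. The formula is implemented literally — as
the ratio of averages Flu/⟨V⟩. Evaluating it on a reported set of
water-box statistics (Flu = 20914.2 D², ⟨V⟩ = 22290.7 Å, T = 298.15 K)
gives ε ≈ 96.5, a few percent above the ε ≈ 92.7 quoted alongside such
statistics in the literature; averaging the instantaneous ratio Flu/V
frame-wise instead of taking the ratio of averages produces shifts of
this order. The package does not switch conventions silently.

The reported per-molecule dipole ⟨μ⟩ is the proxy ⟨|M|⟩/n_molecules:
without per-molecule dipoles in the input the true molecular average is
unrecoverable, and for orientationally disordered liquids the proxy is
far below the single-molecule magnitude (random-walk cancellation,
E|M| ≈ μ₀√(8n/3π)). It is labelled as a proxy in the output.

## Charge-environment algebra

Atomic partial charges may be fitted with the molecule embedded in
vacuum (v), octanol (o) or water (w). The water leg uses one compound
charge set (3 options, P_water{x}); the octanol leg uses a compound and
an octanol-solvent set (9 options, P_octanol{x,y}); a logP value pairs
one of each (27 options, P_logP{x,{y,z}}). Enumeration order is fixed at
v, o, w. Comparison statistics per set: Pearson R, R² = R², RMSE and MAE
against the identity line (so systematic offset shows up even at R = 1),
and an OLS regression of calculated (y) on experimental (x) — the axis
convention is recorded in the report. "Best combination" is the argmax
of R with ties broken by lower RMSE and then label order.

## Synthetic data: what it emulates, what it does not

- **Work samples** are Gaussian and exactly Crooks-consistent: forward
  ~ N(ΔG + σ²/2RT, σ), reverse ~ N(ΔG − σ²/2RT, σ). This is the unique
  family in which BAR has the closed-form large-n limit
  (mean_f + mean_r)/2, enabling analytic checks. Default regime:
  σ = 2RT, 1000 samples/side, 40 windows — sized so the full suite runs
  in minutes while keeping window-level stderr near 0.05 kJ/mol. Real
  work distributions can be skewed, heavy-tailed and autocorrelated;
  passing tests therefore certify the estimator and its plumbing, not
  robustness to non-Gaussian MD output. No decorrelation/subsampling is
  applied: inputs are taken as independent samples.
- **Dipole trajectories** are i.i.d. zero-mean Gaussian dipole
  components with per-component variance (ε−1)T·V/(3C), matching the
  estimator's expectation exactly. Real trajectories have a finite
  correlation time and a nonzero Kirkwood g-factor structure; neither is
  emulated.
- **Compound tables** (default 58 compounds, 8 chemical groups) draw a
  shared compound-size free-energy component plus solvent-specific
  deviations and a per-group lipophilicity offset, then produce
  calculated columns as slope_env·ΔG_exp + offset_env + N(0, sd). The
  default slopes (water leg 1.10/1.02/1.00 for v/o/w; octanol leg
  1.00/0.92/0.85 with a small additive solvent-charge effect) make the
  (w, {v,·}) pairings slope-matched and the (v, {w,·}) pairings the most
  mismatched, so the pairing-sensitivity phenomenon is reproducible by
  construction and checkable against the truth sheet. The group labels
  carry no chemistry — only a shared gap offset.

## Limitations

- No MBAR/multistate estimation, no thermodynamic integration, no
  autocorrelation analysis; BAR per window pair only.
- No finite-size or standard-state corrections; octanol is treated as a
  pure (dry) solvent.
- No charge fitting, force-field assignment or MD execution — the
  package starts at work samples and dipole/volume time series.
- The energy-file dialect is deliberately minimal (whitespace columns,
  '#'/'@' comments); native MD-engine binary formats are out of scope.
- The 13.26 kJ/mol ↔ 3.16 kcal/mol equivalence sometimes quoted in
  tables corresponds to truncation, not rounding (13.26/4.184 = 3.169);
  the converter keeps the exact factor and leaves presentation rounding
  to the caller.
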