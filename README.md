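# alchempart

Analysis toolkit for predicting octanol–water partition coefficients
(logP_ow) from alchemical free-energy simulations, and for studying how
the solvent environment assumed when fitting atomic partial charges
propagates into the predicted logP_ow.

logP_ow — the base-10 log of a compound's octanol/water partition
coefficient — is a standard lipophilicity index in drug discovery.
Alchemical annihilation simulations estimate the solvation free energy
ΔG of a compound in each solvent by gradually switching off its Coulomb
and then its Lennard-Jones interactions along a coupling parameter λ,
and the partition coefficient follows from the difference:

    logP_ow = −(ΔG_octanol − ΔG_water) / (ln 10 · R·T)

`alchempart` covers the analysis side of that workflow (it does not run
molecular dynamics):

- **BAR estimation** — per λ-window free energies from forward/reverse
  work samples W = U_{i+1} − U_i via the Bennett acceptance ratio
  self-consistency equation
  ⟨f((W−ΔG_i)/RT)⟩_i = ⟨f(−(W−ΔG_i)/RT)⟩_{i+1}, f(x) = 1/(1+eˣ),
  solved by bracketed root finding, with a seeded bootstrap standard
  error and a histogram-overlap diagnostic per window.
- **λ schedules** — the two-stage annihilation path (Coulomb ramp at
  λ_LJ = 0, then LJ ramp at λ_C = 1); the default 0.05/0.05 stepping
  gives 41 states and 40 windows.
- **Thermodynamic cycle** — solvation ΔG assembled from the solvent and
  gas annihilation legs, with replicate aggregation.
- **Parameter-set algebra** — atomic charges can be fitted in vacuum
  (v), octanol (o) or water (w); the package enumerates the 3 water-leg
  sets P_water{x}, 9 octanol-leg sets P_octanol{x,y} and 27 logP
  combinations P_logP{x,{y,z}}, and compares each against experiment
  (Pearson R, R², RMSE, MAE, regression line).
- **Dielectric properties** — the solvent-box dielectric constant from
  total-dipole fluctuations, ε = 1 + 4π(⟨M²⟩−⟨M⟩²)/(3 k_B T ⟨V⟩).
- **Synthetic data** — Crooks-consistent Gaussian work samples, dipole
  trajectories with a prescribed ε, and compound tables with known
  calc-vs-exp structure, so every estimator can be tested against
  ground truth.

## Worked example

Estimate one window free energy from synthetic Crooks-consistent work
samples (truth 0.9 kJ/mol, spread 2RT, 1000 samples per side):

```python
from alchempart import SyntheticWindowSpec, gen_crooks_window, bar_window

ws = gen_crooks_window(SyntheticWindowSpec(
    delta_g_true=0.9, sigma=2 * 8.3145e-3 * 298.15, n_samples=1000, seed=17))
w = bar_window(ws, seed=17)
print(f"window dG = {w.delta_g:.3f} +/- {w.stderr:.3f} kJ/mol (overlap {w.overlap:.2f})")
```

prints `window dG = 0.911 +/- 0.128 kJ/mol (overlap 0.31)` — the truth
0.9 is recovered within one bootstrap standard error, and the 0.31
overlap says the forward and reverse work distributions share roughly a
third of their probability mass (comfortable for BAR).

The partition coefficient from two solvation free energies (here the
values −10.22 and −34.91 kJ/mol at 298.15 K):

```python
from alchempart import logp_from_dg
print(f"{logp_from_dg(-34.91, -10.22):.2f}")   # -> 4.33
```

The full pipeline on a synthetic 58-compound dataset:

```sh
alchempart run --seed 1 --output-dir out/
```

writes `water_report.csv` (3 rows), `octanol_report.csv` (9 rows),
`logp_report.csv` (27 rows), a per-group error profile and a provenance
manifest, and prints the best combination by Pearson R — for seed 1,
`P_logP{o,{v,o}}` with R = 0.95, ahead of `P_logP{w,{v,o}}` at
R = 0.947. The spread of R across the 27 rows (best 0.95, worst 0.83 at
`P_logP{v,{w,w}}` for this seed) is the combination
sensitivity the package is built to expose: water-leg and octanol-leg
parameter sets whose calc-vs-exp slopes differ leak the compound-size
signal into the logP difference and degrade its correlation, even though
each leg alone correlates with experiment at R > 0.99.

Other subcommands: `alchempart simulate` (synthetic fixtures plus a
`truth.json` sheet), `bar` (work table → per-window ΔG and leg sum),
`cycle`, `logp`, `dielectric`, `compare`. All accept `--help`.

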