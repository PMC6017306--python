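"""Synthetic fixtures with known ground truth.

Every generator here is a pure function of its seed and emulates the
*statistical* structure of an alchemical logP study -- never actual MD
energetics.

Work samples are Gaussian and Crooks-consistent: if forward work in
ensemble i is N(dG + sigma^2/2RT, sigma) and the same W sampled in
ensemble i+1 is N(dG - sigma^2/2RT, sigma), the Crooks relation
P_f(W)/P_r(W) = exp((W - dG)/RT) holds exactly, and the BAR estimate has
the closed-form large-n limit (mean_fwd + mean_rev)/2.  The Gaussian
family is chosen precisely because this closed form gives analytic
checks; heavier-tailed work models are out of scope.

Compound tables mimic a calculated-vs-experimental study: calculated
dG = slope_env * experimental dG + offset_env + noise, with slopes that
depend on the charge-fitting environment.  Combining a water-leg and an
octanol-leg whose slopes differ leaks the compound-size signal into the
logP difference and degrades its correlation -- the sensitivity
phenomenon the analysis pipeline is designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bar_core import WorkSampleSet
from .constants import DEFAULT_TEMPERATURE, rt
from .dielectric import DipoleTrajectory
from .lambda_windows import LambdaSchedule, window_pairs
from .partition_logp import (
    ENVIRONMENTS,
    CompoundRecord,
    ParameterSetLabel,
    logp_from_dg,
)

#: chemical-group vocabulary of the compound generator
DEFAULT_GROUPS = {
    "alkane": 0.12,
    "alcohol": 0.16,
    "ether": 0.12,
    "ketone": 0.14,
    "ester": 0.14,
    "amine": 0.12,
    "aromatic": 0.12,
    "phosphate": 0.08,
}

#: calc-vs-exp slope per charge environment, water leg
DEFAULT_WATER_SLOPES = {"v": 1.10, "o": 1.02, "w": 1.00}
#: calc-vs-exp slope per compound charge environment, octanol leg
DEFAULT_OCTANOL_SLOPES = {"v": 1.00, "o": 0.92, "w": 0.85}
#: octanol-solvent charge environment: slight additive effect only
DEFAULT_OCTANOL_SOLVENT_SHIFT = {"v": 0.0, "o": -0.3, "w": -0.6}


@dataclass(frozen=True)
class SyntheticWindowSpec:
    """Prescription for one Crooks-consistent Gaussian work window."""

    delta_g_true: float  # kJ/mol
    sigma: float  # kJ/mol work spread
    n_samples: int  # per side
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Prescription for a compound table with hidden truth sheet."""

    n_compounds: int = 58
    group_proportions: dict = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    water_slopes: dict = field(default_factory=lambda: dict(DEFAULT_WATER_SLOPES))
    octanol_slopes: dict = field(default_factory=lambda: dict(DEFAULT_OCTANOL_SLOPES))
    octanol_solvent_shift: dict = field(
        default_factory=lambda: dict(DEFAULT_OCTANOL_SOLVENT_SHIFT)
    )
    noise_sd: float = 1.5  # kJ/mol, random part of calc dG
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds < 3:
            raise ValueError("need at least 3 compounds")
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group proportions must sum to 1, got {total}")


def gen_crooks_window(spec: SyntheticWindowSpec) -> WorkSampleSet:
    """Draw forward/reverse work samples consistent with the Crooks relation."""
    rng = np.random.default_rng(spec.seed)
    shift = 0.0
    if spec.sigma > 0:
        shift = spec.sigma**2 / (2.0 * rt(spec.temperature))
    fwd = rng.normal(spec.delta_g_true + shift, spec.sigma, spec.n_samples)
    rev = rng.normal(spec.delta_g_true - shift, spec.sigma, spec.n_samples)
    return WorkSampleSet(forward=fwd, reverse=rev, temperature=spec.temperature)


def gen_annihilation_run(
    schedule: LambdaSchedule,
    profile: list[float],
    sigma: float,
    n_samples: int,
    seed: int,
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[list[WorkSampleSet], float]:
    """One Crooks window per adjacent schedule pair; returns the true total."""
    pairs = window_pairs(schedule)
    if len(profile) != len(pairs):
        raise ValueError(
            f"profile length {len(profile)} != window count {len(pairs)}"
        )
    windows = [
        gen_crooks_window(
            SyntheticWindowSpec(
                delta_g_true=dg,
                sigma=sigma,
                n_samples=n_samples,
                temperature=temperature,
                seed=seed + i,
            )
        )
        for i, dg in enumerate(profile)
    ]
    return windows, float(np.sum(profile))


def gen_dipole_trajectory(
    epsilon_target: float,
    volume: float = 22000.0,
    temperature: float = DEFAULT_TEMPERATURE,
    n_frames: int = 100_000,
    n_molecules: int = 723,
    seed: int = 0,
) -> DipoleTrajectory:
    """Gaussian total-dipole trajectory with a prescribed dielectric constant.

    Each Cartesian component is i.i.d. N(0, s) with
    s^2 = (eps_target - 1) * T * V / (3 C), so the Kirkwood estimator's
    expectation is exactly eps_target.
    """
    from .constants import DIELECTRIC_C

    if epsilon_target < 1.0:
        raise ValueError("epsilon_target must be >= 1")
    if volume <= 0:
        raise ValueError("volume must be positive")
    s2 = (epsilon_target - 1.0) * temperature * volume / (3.0 * DIELECTRIC_C)
    rng = np.random.default_rng(seed)
    m = rng.normal(0.0, np.sqrt(s2), (n_frames, 3))
    return DipoleTrajectory(
        dipoles=m, volumes=volume, temperature=temperature, n_molecules=n_molecules
    )


def gen_compound_dataset(
    spec: SyntheticDatasetSpec,
) -> tuple[list[CompoundRecord], dict]:
    """Compound table emulating a 58-compound, 27-combination logP study.

    Experimental solvation free energies share a compound-size component
    (so dG_water and dG_octanol are strongly correlated, as for real small
    molecules) plus independent solvent-specific deviations and a
    group-level lipophilicity offset; the experimental logP follows from
    the two dGs.  Calculated columns apply the per-environment slope and
    offset plus Gaussian noise.  The returned truth sheet records every
    prescribed parameter and the noiseless per-compound values.
    """
    rng = np.random.default_rng(spec.seed)
    groups = list(spec.group_proportions)
    counts = _apportion(spec.n_compounds, [spec.group_proportions[g] for g in groups])
    group_of = [g for g, c in zip(groups, counts) for _ in range(c)]
    n = spec.n_compounds

    # group lipophilicity: shifts the octanol-water gap, not each dG alone
    group_gap = {g: rng.uniform(-6.0, 2.0) for g in groups}
    size = rng.uniform(-45.0, -5.0, n)  # shared compound-size component
    dev_w = rng.normal(0.0, 3.0, n)
    dev_o = rng.normal(0.0, 3.0, n)
    exp_w = size + dev_w
    exp_o = size + dev_o - 8.0 + np.array([group_gap[g] for g in group_of])
    exp_logp = np.array(
        [logp_from_dg(o, w, spec.temperature) for o, w in zip(exp_o, exp_w)]
    )

    records = []
    for i in range(n):
        calc = {}
        for x in ENVIRONMENTS:
            lab = str(ParameterSetLabel("water", x))
            calc[lab] = float(
                spec.water_slopes[x] * exp_w[i] + rng.normal(0.0, spec.noise_sd)
            )
        for y in ENVIRONMENTS:
            for z in ENVIRONMENTS:
                lab = str(ParameterSetLabel("octanol", y, z))
                calc[lab] = float(
                    spec.octanol_slopes[y] * exp_o[i]
                    + spec.octanol_solvent_shift[z]
                    + rng.normal(0.0, spec.noise_sd)
                )
        records.append(
            CompoundRecord(
                name=f"cmpd{i + 1:03d}",
                chemical_group=group_of[i],
                exp_dg_water=float(exp_w[i]),
                exp_dg_octanol=float(exp_o[i]),
                exp_logp=float(exp_logp[i]),
                calc_dg=calc,
            )
        )

    truth = {
        "seed": spec.seed,
        "n_compounds": n,
        "noise_sd": spec.noise_sd,
        "temperature": spec.temperature,
        "water_slopes": dict(spec.water_slopes),
        "octanol_slopes": dict(spec.octanol_slopes),
        "octanol_solvent_shift": dict(spec.octanol_solvent_shift),
        "group_gap": group_gap,
        "exp_dg_water": exp_w.tolist(),
        "exp_dg_octanol": exp_o.tolist(),
        "exp_logp": exp_logp.tolist(),
        "matched_logp_label": "P_logP{w,{v,o}}",
        "mismatched_logp_label": "P_logP{v,{w,o}}",
    }
    return records, truth


def _apportion(total: int, proportions: list[float]) -> list[int]:
    """Largest-remainder split of ``total`` into integer group counts."""
    raw = [p * total for p in proportions]
    counts = [int(x) for x in raw]
    rem = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts
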