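"""Dielectric constant and dipole statistics of a solvent box.

The static dielectric constant of a simulated liquid follows from the
fluctuation of the box's total dipole moment M (Kirkwood fluctuation
formula, Gaussian-CGS form):

    eps = 1 + 4*pi * (<M^2> - <M>^2) / (3 * k_B * T * <V>)

Internally the unit factors (Debye, A^3, erg/K) are folded into the single
prefactor ``constants.DIELECTRIC_C`` so that the formula is evaluated
directly on Debye^2, A^3 and K quantities.

The per-molecule mean dipole <mu> is reported as <|M|>/n_molecules, a
proxy: without per-molecule dipoles in the input the true molecular
average is not recoverable, and vector cancellation makes the proxy a
lower bound for orientationally disordered liquids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE, DIELECTRIC_C


@dataclass(frozen=True)
class DipoleTrajectory:
    """Total-dipole (Debye) and volume (A^3) time series of a solvent box."""

    dipoles: np.ndarray  # (n_frames, 3)
    volumes: np.ndarray | float  # per-frame, or a single constant
    temperature: float = DEFAULT_TEMPERATURE
    n_molecules: int = 1

    def __post_init__(self):
        m = np.atleast_2d(np.asarray(self.dipoles, dtype=float))
        if m.shape[1] != 3:
            raise ValueError("dipoles must have three components per frame")
        object.__setattr__(self, "dipoles", m)
        v = np.asarray(self.volumes, dtype=float)
        if v.ndim == 0:
            v = np.full(m.shape[0], float(v))
        if v.shape[0] != m.shape[0]:
            raise ValueError("volumes length must match frame count")
        if np.any(v <= 0):
            raise ValueError("volumes must be positive")
        object.__setattr__(self, "volumes", v)
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")

    @property
    def n_frames(self) -> int:
        return self.dipoles.shape[0]


@dataclass(frozen=True)
class DielectricResult:
    epsilon: float
    mean_molecular_dipole: float  # Debye, <|M|>/n_molecules proxy
    fluctuation: float  # Debye^2
    mean_volume: float  # A^3

    def __post_init__(self):
        if self.epsilon < 1.0:
            raise ValueError("epsilon must be >= 1")
        if self.fluctuation < 0.0:
            raise ValueError("fluctuation must be >= 0")


def dipole_fluctuation(traj: DipoleTrajectory) -> float:
    """<|M|^2> - |<M>|^2 in Debye^2, the vector-mean-removed fluctuation."""
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for a fluctuation estimate")
    m = traj.dipoles
    msq = float(np.mean(np.sum(m * m, axis=1)))
    mean = m.mean(axis=0)
    return msq - float(mean @ mean)


def dielectric_constant(traj: DipoleTrajectory) -> float:
    """Kirkwood fluctuation estimate of the static dielectric constant."""
    flu = dipole_fluctuation(traj)
    vbar = float(np.mean(traj.volumes))
    return 1.0 + DIELECTRIC_C * flu / (traj.temperature * vbar)


def mean_molecular_dipole(traj: DipoleTrajectory) -> float:
    """Time average of |M| divided by the molecule count (proxy <mu>)."""
    if traj.n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    return float(np.mean(np.linalg.norm(traj.dipoles, axis=1))) / traj.n_molecules


def analyze(traj: DipoleTrajectory) -> DielectricResult:
    """All solvent-box properties in one report."""
    return DielectricResult(
        epsilon=dielectric_constant(traj),
        mean_molecular_dipole=mean_molecular_dipole(traj),
        fluctuation=dipole_fluctuation(traj),
        mean_volume=float(np.mean(traj.volumes)),
    )
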