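"""Assembly of solvation free energies from annihilation legs.

The thermodynamic cycle runs two annihilations: one of the fully solvated
compound (solvent leg) and one of the isolated compound (gas leg).  Both
annihilations remove interactions, so their work totals are typically
positive for a favourably solvated compound.  The solvation free energy on
the conventional scale (negative = favourable transfer into solvent) is

    dG_solv = dG_solvent - dG_gas = (-solvent annihilation total)
                                    - (-gas annihilation total)
            = -(total_solvent - total_gas)

because each leg's physical (coupling) direction is the reverse of the
annihilation actually simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bar_core import LegResult


@dataclass(frozen=True)
class SolvationFreeEnergy:
    """Assembled solvation free energy for one (compound, solvent, set)."""

    compound: str
    solvent: str  # "water" | "octanol"
    parameter_set: str
    delta_g: float  # kJ/mol, mean over replicates
    replicate_values: tuple[float, ...] = ()
    stderr: float | None = None

    def __post_init__(self):
        if self.solvent not in ("water", "octanol"):
            raise ValueError(f"solvent must be 'water' or 'octanol', got {self.solvent!r}")
        if self.replicate_values:
            m = float(np.mean(self.replicate_values))
            if not math.isclose(m, self.delta_g, rel_tol=0, abs_tol=1e-9):
                raise ValueError("delta_g must equal the replicate mean")


def solvation_from_legs(leg_solvent: LegResult, leg_gas: LegResult) -> float:
    """Solvation free energy (kJ/mol) from the two annihilation legs.

    Each leg total is negated to convert from annihilation direction to the
    physical coupling direction before the cycle difference is taken.
    """
    if leg_solvent.leg_kind != "solvent_annihilation":
        raise ValueError(f"first leg must be solvent_annihilation, got {leg_solvent.leg_kind!r}")
    if leg_gas.leg_kind != "gas_annihilation":
        raise ValueError(f"second leg must be gas_annihilation, got {leg_gas.leg_kind!r}")
    return (-leg_solvent.total_delta_g) - (-leg_gas.total_delta_g)


def aggregate_replicates(values: list[float]) -> tuple[float, float | None]:
    """Mean and standard error of independent replicate dG values.

    stderr = sample sd / sqrt(n); None for a single replicate.
    """
    if len(values) == 0:
        raise ValueError("need at least one replicate value")
    mean = float(np.mean(values))
    if len(values) == 1:
        return mean, None
    return mean, float(np.std(values, ddof=1) / math.sqrt(len(values)))
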