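"""Octanol-water partition coefficients and the charge-environment algebra.

logP_ow follows directly from the difference of the two solvation free
energies:

    logP_ow = -(dG_octanol - dG_water) / (ln(10) * R * T)

A positive logP_ow means the compound prefers octanol (is lipophilic).

Atomic charges can be fitted with the compound embedded in vacuum (v),
octanol (o) or water (w); for the octanol box the solvent molecules'
charges carry their own environment label.  That yields 3 water-phase
parameter sets P_water{x}, 9 octanol-phase sets P_octanol{x,y} and
3 x 9 = 27 logP combinations P_logP{x,{y,z}}.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import pandas as pd

from .constants import LN10, R_KJ

ENVIRONMENTS = ("v", "o", "w")  # vacuum, octanol, water


@dataclass(frozen=True, order=True)
class ParameterSetLabel:
    """A charge-environment parameter set: water, octanol or logp kind.

    String forms match the field notation exactly: ``P_water{x}``,
    ``P_octanol{x,y}`` and ``P_logP{x,{y,z}}``.
    """

    kind: str  # "water" | "octanol" | "logp"
    compound_env: str
    octanol_env: str | None = None
    water_compound_env: str | None = None

    def __post_init__(self):
        if self.kind not in ("water", "octanol", "logp"):
            raise ValueError(f"unknown kind {self.kind!r}")
        envs = [self.compound_env, self.octanol_env, self.water_compound_env]
        n_expected = {"water": 1, "octanol": 2, "logp": 3}[self.kind]
        present = [e for e in envs if e is not None]
        if len(present) != n_expected or envs[:n_expected] != present:
            raise ValueError(f"{self.kind} label needs exactly {n_expected} environment(s)")
        for e in present:
            if e not in ENVIRONMENTS:
                raise ValueError(f"environment must be one of {ENVIRONMENTS}, got {e!r}")

    def __str__(self) -> str:
        if self.kind == "water":
            return f"P_water{{{self.compound_env}}}"
        if self.kind == "octanol":
            return f"P_octanol{{{self.compound_env},{self.octanol_env}}}"
        # logp: compound_env is the water-leg x; octanol pair is {y,z}
        return f"P_logP{{{self.water_compound_env},{{{self.compound_env},{self.octanol_env}}}}}"

    @property
    def water_label(self) -> "ParameterSetLabel":
        if self.kind != "logp":
            raise ValueError("water_label is defined only for logp labels")
        return ParameterSetLabel("water", self.water_compound_env)

    @property
    def octanol_label(self) -> "ParameterSetLabel":
        if self.kind != "logp":
            raise ValueError("octanol_label is defined only for logp labels")
        return ParameterSetLabel("octanol", self.compound_env, self.octanol_env)


_WATER_RE = re.compile(r"^P_water\{([vow])\}$")
_OCT_RE = re.compile(r"^P_octanol\{([vow]),([vow])\}$")
_LOGP_RE = re.compile(r"^P_logP\{([vow]),\{([vow]),([vow])\}\}$")


def parse_label(text: str) -> ParameterSetLabel:
    """Parse a label string back into its structured form."""
    if m := _WATER_RE.match(text):
        return ParameterSetLabel("water", m.group(1))
    if m := _OCT_RE.match(text):
        return ParameterSetLabel("octanol", m.group(1), m.group(2))
    if m := _LOGP_RE.match(text):
        return ParameterSetLabel("logp", m.group(2), m.group(3), m.group(1))
    raise ValueError(f"unrecognised parameter-set label {text!r}")


def enumerate_parameter_sets() -> tuple[
    list[ParameterSetLabel], list[ParameterSetLabel], list[ParameterSetLabel]
]:
    """All water (3), octanol (9) and logp (27) labels in v,o,w order."""
    water = [ParameterSetLabel("water", x) for x in ENVIRONMENTS]
    octanol = [
        ParameterSetLabel("octanol", x, y) for x in ENVIRONMENTS for y in ENVIRONMENTS
    ]
    logp = [
        ParameterSetLabel("logp", y, z, x)
        for x in ENVIRONMENTS
        for y in ENVIRONMENTS
        for z in ENVIRONMENTS
    ]
    return water, octanol, logp


@dataclass
class CompoundRecord:
    """One compound's experimental values and per-set calculated dGs."""

    name: str
    chemical_group: str
    exp_dg_water: float | None = None
    exp_dg_octanol: float | None = None
    exp_logp: float | None = None
    calc_dg: dict[str, float] = None  # keyed by str(ParameterSetLabel)

    def __post_init__(self):
        if self.calc_dg is None:
            self.calc_dg = {}
        if (
            self.exp_dg_water is None
            and self.exp_dg_octanol is None
            and self.exp_logp is None
        ):
            raise ValueError(f"compound {self.name!r} has no experimental value")


def logp_from_dg(
    dg_octanol: float,
    dg_water: float,
    temperature: float = 298.15,
    factor_as_printed: bool = False,
) -> float:
    """logP_ow from the two solvation free energies (kJ/mol).

    ``factor_as_printed`` uses the typeset constant 2.303 instead of
    ln(10) = 2.302585...; the difference is below 0.02% of logP.
    """
    if not (math.isfinite(dg_octanol) and math.isfinite(dg_water)):
        raise ValueError("free energies must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    factor = 2.303 if factor_as_printed else LN10
    return -(dg_octanol - dg_water) / (factor * R_KJ * temperature)


def logp_table(
    records: list[CompoundRecord],
    selection: list[ParameterSetLabel],
    temperature: float = 298.15,
) -> pd.DataFrame:
    """Compute logP for every compound x selected logp label.

    A cell is NA when either underlying dG is missing for that compound;
    missing inputs never silently become zeros.
    """
    if not selection:
        raise ValueError("selection of logp labels must be non-empty")
    for lab in selection:
        if lab.kind != "logp":
            raise ValueError(f"selection must contain logp labels, got {lab}")
    cols = {}
    for lab in selection:
        wkey, okey = str(lab.water_label), str(lab.octanol_label)
        vals = []
        for rec in records:
            dgw = rec.calc_dg.get(wkey)
            dgo = rec.calc_dg.get(okey)
            if dgw is None or dgo is None:
                vals.append(float("nan"))
            else:
                vals.append(logp_from_dg(dgo, dgw, temperature))
        cols[str(lab)] = vals
    return pd.DataFrame(cols, index=[r.name for r in records])
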