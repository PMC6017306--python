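"""Tabular input/output for work samples, compound tables and trajectories.

No science lives here.  Work tables follow xvg habits: lines starting with
'#' or '@' are comments, data lines are whitespace-separated
``window direction value``.  Compound tables are CSV/TSV with a header;
missing calculated values stay explicitly missing (NA).  All file energies
are kJ/mol unless the caller requests kcal/mol conversion on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, KJ_PER_KCAL
from .dielectric import DipoleTrajectory
from .partition_logp import CompoundRecord, enumerate_parameter_sets

#: numeric text precision: energies 4 decimals, logP/statistics 2
ENERGY_FMT = "%.4f"
STAT_FMT = "%.2f"


class ParseError(ValueError):
    """Malformed input line, carrying its 1-based line number."""

    def __init__(self, lineno: int, msg: str):
        super().__init__(f"line {lineno}: {msg}")
        self.lineno = lineno


@dataclass(frozen=True)
class WorkTable:
    """All samples for one (window, direction) pair."""

    window_index: int
    direction: str  # "forward" | "reverse"
    samples: np.ndarray  # kJ/mol
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if self.window_index < 0:
            raise ValueError("window_index must be >= 0")
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"direction must be forward/reverse, got {self.direction!r}")
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.size == 0:
            raise ValueError("samples must be non-empty")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples must be finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")


def read_work_table(
    source, temperature: float = DEFAULT_TEMPERATURE, units: str = "kJ"
) -> list[WorkTable]:
    """Parse a work-sample file into one WorkTable per (window, direction).

    Every non-comment line must parse; nothing is silently dropped.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    factor = {"kJ": 1.0, "kcal": KJ_PER_KCAL}.get(units)
    if factor is None:
        raise ValueError(f"units must be 'kJ' or 'kcal', got {units!r}")
    buckets: dict[tuple[int, str], list[float]] = {}
    n_data = 0
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "@")):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ParseError(lineno, f"expected 'window direction value', got {line!r}")
        try:
            window = int(parts[0])
        except ValueError:
            raise ParseError(lineno, f"window index {parts[0]!r} is not an integer") from None
        direction = parts[1].lower()
        if direction not in ("forward", "reverse"):
            raise ParseError(lineno, f"direction {parts[1]!r} is not forward/reverse")
        try:
            value = float(parts[2])
        except ValueError:
            raise ParseError(lineno, f"work value {parts[2]!r} is not a number") from None
        buckets.setdefault((window, direction), []).append(value * factor)
        n_data += 1
    if n_data == 0:
        raise ValueError("work-table input contains no data lines")
    tables = [
        WorkTable(window_index=w, direction=d, samples=np.array(v), temperature=temperature)
        for (w, d), v in sorted(buckets.items())
    ]
    assert sum(t.samples.size for t in tables) == n_data
    return tables


def write_work_table(tables: list[WorkTable], stream=None) -> str:
    """Write work tables in the dialect read_work_table accepts."""
    out = ["# window direction work_kJ_per_mol"]
    for t in tables:
        for v in t.samples:
            out.append(f"{t.window_index} {t.direction} {ENERGY_FMT % v}")
    text = "\n".join(out) + "\n"
    if stream is not None:
        stream.write(text)
    return text


_EXP_COLS = ["compound", "chemical_group", "exp_dg_water", "exp_dg_octanol", "exp_logp"]


def _valid_calc_labels() -> set[str]:
    water, octanol, _ = enumerate_parameter_sets()
    return {str(l) for l in water + octanol}


def read_compound_table(source, sep: str = ",") -> list[CompoundRecord]:
    """Read a compound CSV/TSV into typed records; NA stays missing."""
    if isinstance(source, str):
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=sep)
    missing = [c for c in ("compound", "chemical_group") if c not in df.columns]
    if missing:
        raise ValueError(f"compound table lacks required column(s): {missing}")
    dupes = df["compound"][df["compound"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate compound name(s): {sorted(set(dupes))}")
    valid = _valid_calc_labels()
    calc_cols = [c for c in df.columns if c not in _EXP_COLS]
    unknown = [c for c in calc_cols if c not in valid]
    if unknown:
        raise ValueError(
            f"unknown parameter-set column(s) {unknown}; valid labels: {sorted(valid)}"
        )
    records = []
    for _, row in df.iterrows():
        calc = {
            c: float(row[c]) for c in calc_cols if pd.notna(row[c])
        }
        records.append(
            CompoundRecord(
                name=str(row["compound"]),
                chemical_group=str(row["chemical_group"]),
                exp_dg_water=_opt(row.get("exp_dg_water")),
                exp_dg_octanol=_opt(row.get("exp_dg_octanol")),
                exp_logp=_opt(row.get("exp_logp")),
                calc_dg=calc,
            )
        )
    return records


def _opt(v) -> float | None:
    return None if v is None or pd.isna(v) else float(v)


def write_compound_table(records: list[CompoundRecord], stream=None, sep: str = ",") -> str:
    """Write records as CSV with stable column order (exp cols, then labels)."""
    calc_cols = sorted({k for r in records for k in r.calc_dg})
    rows = []
    for r in records:
        row = {
            "compound": r.name,
            "chemical_group": r.chemical_group,
            "exp_dg_water": r.exp_dg_water,
            "exp_dg_octanol": r.exp_dg_octanol,
            "exp_logp": r.exp_logp,
        }
        row.update({c: r.calc_dg.get(c) for c in calc_cols})
        rows.append(row)
    df = pd.DataFrame(rows, columns=_EXP_COLS + calc_cols)
    buf = io.StringIO()
    df.to_csv(buf, sep=sep, index=False, float_format="%.6f")
    text = buf.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def read_dipole_trajectory(
    source,
    temperature: float = DEFAULT_TEMPERATURE,
    n_molecules: int = 1,
) -> DipoleTrajectory:
    """Read a (frame, M_x, M_y, M_z, V) plain-text table with '#' comments."""
    if isinstance(source, str):
        source = io.StringIO(source)
    dip, vol = [], []
    n_data = 0
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "@")):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ParseError(lineno, f"expected 'frame Mx My Mz V', got {line!r}")
        try:
            vals = [float(p) for p in parts[1:]]
        except ValueError:
            raise ParseError(lineno, f"non-numeric field in {line!r}") from None
        dip.append(vals[:3])
        vol.append(vals[3])
        n_data += 1
    if n_data == 0:
        raise ValueError("dipole-trajectory input contains no data lines")
    return DipoleTrajectory(
        dipoles=np.array(dip),
        volumes=np.array(vol),
        temperature=temperature,
        n_molecules=n_molecules,
    )


def write_dipole_trajectory(traj: DipoleTrajectory, stream=None) -> str:
    out = ["# frame M_x M_y M_z V"]
    for i, (m, v) in enumerate(zip(traj.dipoles, traj.volumes)):
        out.append(f"{i} {m[0]:.6f} {m[1]:.6f} {m[2]:.6f} {v:.4f}")
    text = "\n".join(out) + "\n"
    if stream is not None:
        stream.write(text)
    return text
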