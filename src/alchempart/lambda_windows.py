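"""Two-stage annihilation lambda schedule.

An alchemical annihilation decouples a solute from its surroundings in two
stages: the Coulomb interactions are ramped off first (lambda_c from 0 to 1
with lambda_lj held at 0), then the van der Waals interactions (lambda_lj
from 0 to 1 with lambda_c held at 1).  Lambda here is *annihilation
progress*: (0, 0) is the fully interacting state, (1, 1) the fully
decoupled one.  The schedule is pure bookkeeping -- no potential is ever
evaluated; work samples arrive from files or the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass

_DIV_TOL = 1e-9
_ROUND = 10


@dataclass(frozen=True, order=True)
class LambdaState:
    """One point on the annihilation path."""

    lambda_c: float
    lambda_lj: float

    def __post_init__(self) -> None:
        for name, v in (("lambda_c", self.lambda_c), ("lambda_lj", self.lambda_lj)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered annihilation path from (0,0) to (1,1)."""

    states: tuple[LambdaState, ...]

    def __post_init__(self) -> None:
        s = self.states
        if len(s) < 2:
            raise ValueError("schedule needs at least 2 states")
        if s[0] != LambdaState(0.0, 0.0) or s[-1] != LambdaState(1.0, 1.0):
            raise ValueError("schedule must run from (0,0) to (1,1)")
        if len(set(s)) != len(s):
            raise ValueError("schedule states must be unique")
        for a, b in zip(s, s[1:]):
            if b.lambda_c < a.lambda_c or b.lambda_lj < a.lambda_lj:
                raise ValueError("lambda_c and lambda_lj must be non-decreasing")
        for st in s:
            if st.lambda_lj > 0.0 and st.lambda_c != 1.0:
                raise ValueError("lambda_lj may exceed 0 only once lambda_c = 1")

    def __len__(self) -> int:
        return len(self.states)


def _stage_points(step: float, stage: str) -> list[float]:
    if not 0.0 < step <= 1.0:
        raise ValueError(f"{stage} step must be in (0, 1], got {step}")
    n = 1.0 / step
    if abs(n - round(n)) > _DIV_TOL * max(1.0, n):
        raise ValueError(f"{stage} step {step} does not divide 1 evenly")
    n = round(n)
    return [round(i / n, _ROUND) for i in range(n + 1)]


def build_schedule(step_c: float = 0.05, step_lj: float = 0.05) -> LambdaSchedule:
    """Build the Coulomb-then-LJ schedule; (1, 0) appears exactly once.

    The default 0.05/0.05 stepping gives 41 states (21 Coulomb points plus
    21 LJ points sharing the (1, 0) turning state).
    """
    coul = [LambdaState(c, 0.0) for c in _stage_points(step_c, "coulomb")]
    lj = [LambdaState(1.0, l) for l in _stage_points(step_lj, "lennard-jones")[1:]]
    return LambdaSchedule(tuple(coul + lj))


def window_pairs(schedule: LambdaSchedule) -> list[tuple[LambdaState, LambdaState]]:
    """Adjacent state pairs along the path, in order; length = n_states - 1."""
    s = schedule.states
    if len(s) < 2:
        raise ValueError("need at least 2 states to form windows")
    return list(zip(s, s[1:]))


def schedule_to_csv(schedule: LambdaSchedule) -> str:
    """Serialize as two-column CSV (lambda_c, lambda_lj)."""
    lines = ["lambda_c,lambda_lj"]
    lines += [f"{st.lambda_c:.10g},{st.lambda_lj:.10g}" for st in schedule.states]
    return "\n".join(lines) + "\n"


def schedule_from_csv(text: str) -> LambdaSchedule:
    rows = [ln for ln in text.strip().splitlines() if ln.strip()]
    states = []
    for ln in rows[1:]:
        c, l = ln.split(",")
        states.append(LambdaState(float(c), float(l)))
    return LambdaSchedule(tuple(states))
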