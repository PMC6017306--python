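"""Bennett acceptance ratio (BAR) estimation of per-window free energies.

For each pair of neighbouring lambda windows i and i+1, the work
W = U_{i+1} - U_i is sampled both in ensemble i ("forward") and in
ensemble i+1 ("reverse").  The BAR estimate of the window free energy
dG_i is the unique root of the self-consistency condition

    < f((W - dG)/RT) >_i  =  < f(-(W - dG)/RT) >_{i+1}

with f the Fermi function f(x) = 1/(1 + exp(x)).  The left side falls
and the right side rises as dG grows, so the residual (left - right) is
strictly increasing and the root is unique.  For unequal sample counts
the standard Bennett offset M = RT ln(n_f/n_r) enters the fermi
arguments and the two averages are count-weighted, which reduces exactly
to the equal-length form when n_f = n_r.

A leg (solvent annihilation or gas annihilation) is the ordered sum of
its window free energies.  Per-window uncertainty is estimated by a
seeded bootstrap over the work samples; an exponential-averaging
(Jarzynski) estimator is provided as a one-sided cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .constants import DEFAULT_TEMPERATURE, rt

__all__ = [
    "WorkSampleSet",
    "WindowFreeEnergy",
    "LegResult",
    "OverlapFailure",
    "bar_residual",
    "bar_window",
    "sum_windows",
    "exp_estimator",
    "overlap_diagnostic",
]


class OverlapFailure(RuntimeError):
    """Raised when no sign change brackets the BAR root; carries the overlap."""

    def __init__(self, msg: str, overlap: float):
        super().__init__(msg)
        self.overlap = overlap


@dataclass(frozen=True)
class WorkSampleSet:
    """Forward/reverse samples of W = U_{i+1} - U_i for one window pair.

    ``forward`` values are drawn in ensemble i, ``reverse`` values are the
    same quantity drawn in ensemble i+1 (note: not sign-flipped work).
    Energies in kJ/mol, temperature in K.
    """

    forward: np.ndarray
    reverse: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        fwd = np.asarray(self.forward, dtype=float)
        rev = np.asarray(self.reverse, dtype=float)
        object.__setattr__(self, "forward", fwd)
        object.__setattr__(self, "reverse", rev)
        if fwd.size == 0 or rev.size == 0:
            raise ValueError("forward and reverse sample sets must be non-empty")
        if not (np.all(np.isfinite(fwd)) and np.all(np.isfinite(rev))):
            raise ValueError("work samples must be finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")

    @property
    def rt(self) -> float:
        return rt(self.temperature)


@dataclass(frozen=True)
class WindowFreeEnergy:
    """BAR result for a single window pair."""

    delta_g: float  # kJ/mol
    stderr: float | None  # kJ/mol; None when not estimated
    overlap: float  # histogram-intersection diagnostic in [0, 1]
    n_forward: int
    n_reverse: int

    def __post_init__(self):
        if not math.isfinite(self.delta_g):
            raise ValueError("delta_g must be finite")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")


@dataclass(frozen=True)
class LegResult:
    """Sum of window free energies along one annihilation leg."""

    total_delta_g: float
    per_window: tuple[WindowFreeEnergy, ...]
    leg_kind: str  # "solvent_annihilation" | "gas_annihilation"

    @property
    def stderr(self) -> float | None:
        """Quadrature-combined stderr; None unless every window carries one."""
        errs = [w.stderr for w in self.per_window]
        if any(e is None for e in errs):
            return None
        return float(np.sqrt(np.sum(np.square(errs))))


def _weighted_residual(dg, fwd, rev, rtval):
    """Count-weighted Bennett residual, vectorised over trailing axes of dg."""
    nf, nr = fwd.shape[-1], rev.shape[-1]
    m = rtval * math.log(nf / nr)
    dg = np.asarray(dg, dtype=float)[..., None]
    left = expit(-(fwd - dg + m) / rtval).mean(axis=-1)  # expit(-x) = fermi(x)
    right = expit((rev - dg + m) / rtval).mean(axis=-1)
    nbar = 0.5 * (nf + nr)
    return (nf * left - nr * right) / nbar


def bar_residual(delta_g_trial: float, ws: WorkSampleSet) -> float:
    """Self-consistency residual at a trial dG; strictly increasing in dG.

    Returns mean_i[f((W-dG)/RT)] - mean_{i+1}[f(-(W-dG)/RT)] for equal
    sample counts, saturating at -1 and +1 as dG -> -inf / +inf.
    """
    return float(_weighted_residual(delta_g_trial, ws.forward, ws.reverse, ws.rt))


def _bracket(ws: WorkSampleSet) -> tuple[float, float]:
    rtv = ws.rt
    allw = np.concatenate([ws.forward, ws.reverse])
    lo = float(allw.min()) - 50.0 * rtv
    hi = float(allw.max()) + 50.0 * rtv
    for _ in range(60):
        if bar_residual(lo, ws) < 0.0 < bar_residual(hi, ws):
            return lo, hi
        mid = 0.5 * (lo + hi)
        span = hi - lo
        lo, hi = mid - span, mid + span
    raise OverlapFailure(
        "BAR residual does not change sign within the expanded bracket; "
        "forward/reverse work distributions likely do not overlap",
        overlap=overlap_diagnostic(ws),
    )


def bar_window(
    ws: WorkSampleSet,
    tol: float = 1e-8,
    n_bootstrap: int = 200,
    seed: int | None = 0,
) -> WindowFreeEnergy:
    """Solve the BAR self-consistency equation for one window pair.

    The root is bracketed around the sample range and refined with Brent's
    method to ``tol`` (kJ/mol).  ``n_bootstrap`` seeded resamples give the
    stderr (set to 0 to skip); the overlap diagnostic is always attached.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    lo, hi = _bracket(ws)
    dg = float(brentq(bar_residual, lo, hi, args=(ws,), xtol=tol))
    # a genuine root must straddle zero; a flat residual plateau means the
    # two work distributions share no support at double precision
    delta = max(10.0 * tol, 1e-7)
    if not (bar_residual(dg - delta, ws) < 0.0 < bar_residual(dg + delta, ws)):
        raise OverlapFailure(
            "BAR self-consistency residual is flat around the nominal root; "
            "forward/reverse work distributions do not overlap",
            overlap=overlap_diagnostic(ws),
        )
    err = None
    if n_bootstrap > 0:
        err = _bootstrap_stderr(ws, n_bootstrap, seed, lo, hi)
    return WindowFreeEnergy(
        delta_g=dg,
        stderr=err,
        overlap=overlap_diagnostic(ws),
        n_forward=int(ws.forward.size),
        n_reverse=int(ws.reverse.size),
    )


def _bootstrap_stderr(ws, n_boot, seed, lo, hi, tol=1e-6):
    """Bootstrap sd of the BAR root, all resamples bisected simultaneously."""
    rng = np.random.default_rng(seed)
    fwd = ws.forward[rng.integers(0, ws.forward.size, (n_boot, ws.forward.size))]
    rev = ws.reverse[rng.integers(0, ws.reverse.size, (n_boot, ws.reverse.size))]
    rtv = ws.rt
    a = np.full(n_boot, lo)
    b = np.full(n_boot, hi)
    # widen until every replicate's root is straddled (rarely needed)
    for _ in range(60):
        bad = _weighted_residual(a, fwd, rev, rtv) >= 0
        if not bad.any():
            break
        a[bad] -= b[bad] - a[bad]
    for _ in range(60):
        bad = _weighted_residual(b, fwd, rev, rtv) <= 0
        if not bad.any():
            break
        b[bad] += b[bad] - a[bad]
    while np.max(b - a) > tol:
        mid = 0.5 * (a + b)
        neg = _weighted_residual(mid, fwd, rev, rtv) < 0
        a = np.where(neg, mid, a)
        b = np.where(neg, b, mid)
    roots = 0.5 * (a + b)
    return float(np.std(roots, ddof=1))


def sum_windows(per_window: list[WindowFreeEnergy], leg_kind: str) -> LegResult:
    """Accumulate window free energies into a leg total.

    The leg stderr combines per-window stderrs in quadrature when all
    windows carry one.
    """
    if not per_window:
        raise ValueError("cannot sum an empty window list")
    if leg_kind not in ("solvent_annihilation", "gas_annihilation"):
        raise ValueError(f"unknown leg kind {leg_kind!r}")
    total = float(math.fsum(w.delta_g for w in per_window))
    return LegResult(total_delta_g=total, per_window=tuple(per_window), leg_kind=leg_kind)


def exp_estimator(ws: WorkSampleSet, direction: str = "forward") -> float:
    """One-sided exponential-averaging (Jarzynski) free energy estimate.

    forward: -RT ln < exp(-W/RT) >_i;  reverse: +RT ln < exp(+W/RT) >_{i+1}.
    Evaluated via log-sum-exp to avoid overflow.
    """
    rtv = ws.rt
    if direction == "forward":
        w = ws.forward
        return float(-rtv * (logsumexp(-w / rtv) - math.log(w.size)))
    if direction == "reverse":
        w = ws.reverse
        return float(rtv * (logsumexp(w / rtv) - math.log(w.size)))
    raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")


def overlap_diagnostic(ws: WorkSampleSet, n_bins: int = 50) -> float:
    """Histogram-intersection area of the two work distributions.

    Both sample sets are binned on a common grid spanning their pooled
    range; the summed per-bin minimum of the two normalised histograms is
    1 for identical distributions and 0 for disjoint supports.
    """
    fwd, rev = ws.forward, ws.reverse
    lo = min(fwd.min(), rev.min())
    hi = max(fwd.max(), rev.max())
    if lo == hi:  # all samples identical
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    pf, _ = np.histogram(fwd, bins=edges)
    pr, _ = np.histogram(rev, bins=edges)
    return float(np.minimum(pf / fwd.size, pr / rev.size).sum())
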