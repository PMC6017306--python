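"""BAR estimator checked against independent oracles.

The oracles never call the implementation path they verify: the residual
oracle re-evaluates the self-consistency condition with 50-digit decimal
arithmetic, and the root oracle scans a dense dG grid of that decimal
residual for its sign change.
"""

import decimal
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alchempart import (
    WorkSampleSet,
    bar_residual,
    bar_window,
    exp_estimator,
    gen_crooks_window,
    overlap_diagnostic,
    sum_windows,
    SyntheticWindowSpec,
)
from alchempart.bar_core import OverlapFailure, WindowFreeEnergy
from alchempart.constants import DEFAULT_TEMPERATURE, rt

RT = rt(DEFAULT_TEMPERATURE)


def decimal_residual(dg, fwd, rev, temperature=DEFAULT_TEMPERATURE, prec=50):
    """Eq-style residual with 50-digit decimal arithmetic (independent oracle)."""
    ctx = decimal.Context(prec=prec)
    rtv = ctx.divide(ctx.multiply(decimal.Decimal("8.3145e-3"), decimal.Decimal(str(temperature))), 1)
    one = decimal.Decimal(1)
    dg = decimal.Decimal(str(dg))

    def fermi(x):
        return ctx.divide(one, ctx.add(one, ctx.exp(x)))

    left = sum(fermi(ctx.divide(decimal.Decimal(str(w)) - dg, rtv)) for w in fwd) / len(fwd)
    right = sum(fermi(-ctx.divide(decimal.Decimal(str(w)) - dg, rtv)) for w in rev) / len(rev)
    return float(left - right)


def grid_root(fwd, rev, lo, hi, step=1e-6, chunk=1_000_000):
    """Brute-force dense-grid scan of the residual for its sign change.

    Includes the Bennett count offset M = RT ln(n_f/n_r) and count
    weighting, so it targets the same estimator for unequal sample sizes
    (both vanish for equal counts).
    """
    f = np.asarray(fwd, dtype=float)[None, :]
    r = np.asarray(rev, dtype=float)[None, :]
    nf, nr = f.size, r.size
    m = RT * math.log(nf / nr)
    start = lo
    while start < hi:
        grid = np.arange(start, min(start + chunk * step, hi), step)
        left = (1.0 / (1.0 + np.exp((f - grid[:, None] + m) / RT))).mean(axis=1)
        right = (1.0 / (1.0 + np.exp(-(r - grid[:, None] + m) / RT))).mean(axis=1)
        res = (nf * left - nr * right) / (0.5 * (nf + nr))
        if res[-1] >= 0.0:
            i = int(np.searchsorted(res, 0.0))
            if i > 0:
                return 0.5 * (grid[i - 1] + grid[i])
        start = float(grid[-1]) + step
    raise AssertionError("no sign change on the scanned grid")


class TestResidual:
    def test_symmetric_single_samples_zero_at_w(self):
        ws = WorkSampleSet([5.0], [5.0])
        assert bar_residual(5.0, ws) == pytest.approx(0.0, abs=1e-15)

    def test_saturation_limits(self):
        ws = WorkSampleSet([5.0], [5.0])
        assert bar_residual(-1e5, ws) == pytest.approx(-1.0)
        assert bar_residual(1e5, ws) == pytest.approx(1.0)

    def test_matches_decimal_oracle(self, small_work_set):
        got = bar_residual(2.0, small_work_set)
        want = decimal_residual(2.0, [2.0, 3.0], [1.0, 2.5])
        assert got == pytest.approx(want, abs=1e-12)

    def test_strictly_increasing(self, small_work_set):
        trials = np.linspace(-5, 8, 40)
        vals = [bar_residual(t, small_work_set) for t in trials]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestBarWindow:
    def test_single_symmetric_sample(self):
        wfe = bar_window(WorkSampleSet([5.0], [5.0]), n_bootstrap=0)
        assert wfe.delta_g == pytest.approx(5.0, abs=1e-8)

    def test_symmetric_sample_sets(self):
        wfe = bar_window(WorkSampleSet([4.0, 6.0], [4.0, 6.0]), n_bootstrap=0)
        assert wfe.delta_g == pytest.approx(5.0, abs=1e-8)

    def test_matches_grid_scan_root(self, small_work_set):
        wfe = bar_window(small_work_set, n_bootstrap=0)
        want = grid_root([2.0, 3.0], [1.0, 2.5], lo=-1.0, hi=6.0)
        assert wfe.delta_g == pytest.approx(want, abs=1e-6)

    def test_root_straddles_residual_sign(self, gaussian_window):
        dg = bar_window(gaussian_window, n_bootstrap=0).delta_g
        assert bar_residual(dg - 1e-4, gaussian_window) < 0
        assert bar_residual(dg + 1e-4, gaussian_window) > 0

    def test_antisymmetry_under_direction_swap(self, gaussian_window):
        """Swapping ensembles and negating W negates the estimate."""
        ws = gaussian_window
        flipped = WorkSampleSet(-ws.reverse, -ws.forward, ws.temperature)
        a = bar_window(ws, n_bootstrap=0).delta_g
        b = bar_window(flipped, n_bootstrap=0).delta_g
        assert a == pytest.approx(-b, abs=1e-7)

    @given(shift=st.floats(-100, 100))
    @settings(max_examples=25, deadline=None)
    def test_shift_equivariance(self, shift):
        """Adding a constant to every work value shifts dG by exactly it."""
        ws = gen_crooks_window(SyntheticWindowSpec(3.0, sigma=RT, n_samples=200, seed=7))
        base = bar_window(ws, n_bootstrap=0).delta_g
        shifted = WorkSampleSet(ws.forward + shift, ws.reverse + shift, ws.temperature)
        assert bar_window(shifted, n_bootstrap=0).delta_g == pytest.approx(
            base + shift, abs=1e-6
        )

    def test_gaussian_closed_form_limit(self, gaussian_window):
        """For equal-variance Crooks Gaussians BAR converges to the mid-mean."""
        ws = gaussian_window
        wfe = bar_window(ws, seed=1)
        closed = 0.5 * (ws.forward.mean() + ws.reverse.mean())
        assert wfe.delta_g == pytest.approx(closed, abs=3 * wfe.stderr)

    def test_disjoint_distributions_raise_overlap_failure(self):
        ws = WorkSampleSet(
            np.full(50, -4000.0) + np.linspace(0, 1, 50),
            np.full(50, 4000.0) + np.linspace(0, 1, 50),
        )
        with pytest.raises(OverlapFailure) as exc:
            bar_window(ws, n_bootstrap=0)
        assert exc.value.overlap == 0.0

    def test_bootstrap_stderr_is_seeded_and_plausible(self, gaussian_window):
        a = bar_window(gaussian_window, seed=5)
        b = bar_window(gaussian_window, seed=5)
        assert a.stderr == b.stderr
        # Gaussian theory: sd of mid-mean = sigma / sqrt(2n)
        theory = 2 * RT / math.sqrt(2 * 10_000)
        assert a.stderr == pytest.approx(theory, rel=0.35)


class TestLegSum:
    def test_exact_sum(self):
        wins = [WindowFreeEnergy(dg, None, 1.0, 1, 1) for dg in (1.0, 2.0, -0.5)]
        leg = sum_windows(wins, "solvent_annihilation")
        assert leg.total_delta_g == pytest.approx(2.5, abs=1e-12)
        assert leg.stderr is None

    def test_zero_windows_sum_to_zero(self):
        wins = [WindowFreeEnergy(0.0, 0.1, 1.0, 1, 1)] * 40
        leg = sum_windows(wins, "gas_annihilation")
        assert leg.total_delta_g == 0.0
        assert leg.stderr == pytest.approx(0.1 * math.sqrt(40))

    def test_empty_and_bad_kind_rejected(self):
        with pytest.raises(ValueError):
            sum_windows([], "solvent_annihilation")
        with pytest.raises(ValueError):
            sum_windows([WindowFreeEnergy(0.0, None, 1.0, 1, 1)], "nope")


class TestExpEstimator:
    def test_one_sample_identity(self):
        ws = WorkSampleSet([3.0], [3.0])
        assert exp_estimator(ws, "forward") == pytest.approx(3.0)
        assert exp_estimator(ws, "reverse") == pytest.approx(3.0)

    def test_constant_samples(self):
        ws = WorkSampleSet([2.0, 2.0], [9.9])
        assert exp_estimator(ws, "forward") == pytest.approx(2.0)

    def test_jarzynski_limit_on_gaussian_samples(self):
        ws = gen_crooks_window(
            SyntheticWindowSpec(5.0, sigma=RT, n_samples=200_000, seed=11)
        )
        assert exp_estimator(ws, "forward") == pytest.approx(5.0, abs=0.05)
        assert exp_estimator(ws, "reverse") == pytest.approx(5.0, abs=0.05)

    def test_overflow_guarded(self):
        ws = WorkSampleSet([-5000.0, -4999.0], [1.0])
        assert math.isfinite(exp_estimator(ws, "forward"))

    def test_bar_bias_dominates_exp_bias(self):
        """BAR's two-sided estimate beats one-sided EXP at moderate overlap."""
        truth, n_rep = 6.0, 100
        bar_est, exp_est = [], []
        for seed in range(n_rep):
            ws = gen_crooks_window(
                SyntheticWindowSpec(truth, sigma=2 * RT, n_samples=200, seed=seed)
            )
            bar_est.append(bar_window(ws, n_bootstrap=0).delta_g)
            exp_est.append(exp_estimator(ws, "forward"))
        assert abs(np.mean(bar_est) - truth) <= abs(np.mean(exp_est) - truth)


class TestOverlap:
    def test_identical_sets_give_one(self):
        w = np.linspace(0, 1, 100)
        assert overlap_diagnostic(WorkSampleSet(w, w.copy())) == 1.0

    def test_disjoint_sets_give_zero(self):
        assert (
            overlap_diagnostic(
                WorkSampleSet(np.linspace(0, 1, 50), np.linspace(500, 501, 50))
            )
            == 0.0
        )

    def test_gaussians_one_sigma_apart_match_quadrature(self):
        """Overlap of N(0,1) and N(1,1) is 2*Phi(-1/2) ~ 0.617."""
        from scipy.stats import norm

        rng = np.random.default_rng(0)
        ws = WorkSampleSet(rng.normal(0, 1, 10_000), rng.normal(1, 1, 10_000))
        want = 2 * norm.cdf(-0.5)
        assert overlap_diagnostic(ws) == pytest.approx(want, abs=0.02)
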