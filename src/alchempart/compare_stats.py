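"""Model-vs-experiment comparison statistics.

Pearson R / R^2, RMSE and MAE against the identity line, and an
ordinary-least-squares regression of calculated (y) on experimental (x).
"MAE" follows the field's occasional reading "mean average error" and is
the plain mean absolute error.  RMSE and MAE are deviations from the
identity line, not regression residuals, so a perfectly correlated but
offset prediction still shows its systematic error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import KJ_PER_KCAL

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonReport:
    n: int
    r: float
    r2: float
    rmse: float
    mae: float
    slope: float
    intercept: float

    #: axis convention baked into slope/intercept
    axis_note = "OLS of calculated (y) on experimental (x)"


def comparison_report(experimental, calculated) -> ComparisonReport:
    """Compare calculated against experimental values (equal-length, n>=3)."""
    x = np.asarray(experimental, dtype=float)
    y = np.asarray(calculated, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("experimental and calculated must be equal-length 1-D")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("inputs must be finite (filter missing values first)")
    for name, v in (("experimental", x), ("calculated", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} values are constant; correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    ols = stats.linregress(x, y)
    diff = y - x
    return ComparisonReport(
        n=int(x.size),
        r=r,
        r2=r * r,
        rmse=float(np.sqrt(np.mean(diff**2))),
        mae=float(np.mean(np.abs(diff))),
        slope=float(ols.slope),
        intercept=float(ols.intercept),
    )


def pairwise_correlation(vectors: dict[str, np.ndarray]):
    """Symmetric Pearson-r matrix over labelled equal-length vectors."""
    import pandas as pd

    labels = list(vectors)
    arrs = [np.asarray(vectors[k], dtype=float) for k in labels]
    n = {a.size for a in arrs}
    if len(n) != 1:
        raise ValueError("all vectors must have equal length")
    if n.pop() < 3:
        raise ValueError("need at least 3 observations per vector")
    k = len(labels)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = stats.pearsonr(arrs[i], arrs[j]).statistic
    return pd.DataFrame(mat, index=labels, columns=labels)


def group_error_profile(records, logp_label, temperature: float = 298.15):
    """Signed logP error (calculated - experimental) per compound, by group.

    Records lacking exp_logp or either underlying dG are skipped with a
    logged warning.  Input order is preserved within each group.
    """
    from .partition_logp import logp_from_dg

    wkey, okey = str(logp_label.water_label), str(logp_label.octanol_label)
    profile: dict[str, list[tuple[str, float]]] = {}
    for rec in records:
        if rec.exp_logp is None:
            logger.warning("compound %s lacks exp_logp; skipped", rec.name)
            continue
        dgw, dgo = rec.calc_dg.get(wkey), rec.calc_dg.get(okey)
        if dgw is None or dgo is None:
            logger.warning("compound %s lacks calculated dG for %s; skipped", rec.name, logp_label)
            continue
        err = logp_from_dg(dgo, dgw, temperature) - rec.exp_logp
        profile.setdefault(rec.chemical_group, []).append((rec.name, err))
    return profile


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert between kJ/mol and kcal/mol (factor 4.184)."""
    units = {"kJ/mol", "kcal/mol"}
    for u in (from_unit, to_unit):
        if u not in units:
            raise ValueError(f"unknown unit {u!r}; expected one of {sorted(units)}")
    if from_unit == to_unit:
        return value
    if from_unit == "kJ/mol":
        return value / KJ_PER_KCAL
    return value * KJ_PER_KCAL
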