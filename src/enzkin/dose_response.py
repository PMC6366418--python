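"""Percent inhibition and IC50 estimation.

Inhibition at inhibitor concentration I is 100 * (1 - v_I / v_0)
against the uninhibited control velocity v_0.  Compounds whose mean
inhibition never reaches 50% within the tested range are reported as
"% at the highest tested concentration"; otherwise a two-parameter
log-logistic curve

    pct(I) = 100 / (1 + (IC50 / I)^h)

(floor 0, ceiling 100; ``h`` the Hill slope) is fitted to the
per-concentration means and the IC50 is reported with a jackknife SE
over independent experiments.  A four-parameter variant with free floor
and ceiling is available for curves that plateau short of complete
inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .errors import DegenerateControlError, InsufficientDataError

__all__ = ["DoseResponseResult", "percent_inhibition", "estimate_ic50"]


@dataclass
class DoseResponseResult:
    compound: str
    reported_as: str  # "IC50" or "percent_at_top"
    top_conc: float
    pct_at_top: float
    ic50: Optional[float] = None
    ic50_se: Optional[float] = None
    hill: Optional[float] = None
    warnings: list[str] = field(default_factory=list)


def percent_inhibition(v_inhibited: float, v_control: float) -> float:
    """100 * (1 - v_I / v_0); may be slightly negative under noise."""
    if v_control <= 0:
        raise DegenerateControlError(f"control velocity must be > 0, got {v_control}")
    return 100.0 * (1.0 - v_inhibited / v_control)


def _logistic(logI: np.ndarray, log_ic50: float, log_h: float) -> np.ndarray:
    # pct = 100 / (1 + (IC50/I)^h), computed in log space for stability
    return 100.0 / (1.0 + np.exp(np.exp(log_h) * (log_ic50 - logI)))


def _fit_logistic(conc: np.ndarray, pct: np.ndarray, four_param: bool) -> tuple[float, float]:
    """Fit the log-logistic to (conc, pct) means at I > 0; returns (ic50, hill)."""
    logI = np.log(conc)
    ic50_init = _interp_ic50(conc, pct)
    x0 = [np.log(ic50_init), 0.0]
    if four_param:
        def resid(x):
            bottom, top = x[2], x[3]
            return pct - (bottom + (top - bottom) / 100.0 * _logistic(logI, x[0], x[1]))
        x0 = x0 + [0.0, 100.0]
    else:
        def resid(x):
            return pct - _logistic(logI, x[0], x[1])
    sol = least_squares(resid, x0, method="lm", xtol=1e-13, ftol=1e-13)
    return float(np.exp(sol.x[0])), float(np.exp(sol.x[1]))


def _interp_ic50(conc: np.ndarray, pct: np.ndarray) -> float:
    """Log-linear interpolation of the 50% crossing; fallback geometric mean."""
    order = np.argsort(conc)
    c, p = conc[order], pct[order]
    above = np.nonzero(p >= 50.0)[0]
    if above.size and above[0] > 0:
        i = above[0]
        frac = (50.0 - p[i - 1]) / (p[i] - p[i - 1])
        return float(np.exp(np.log(c[i - 1]) + frac * (np.log(c[i]) - np.log(c[i - 1]))))
    if above.size:  # already >= 50% at the lowest tested concentration
        return float(c[0])
    return float(np.exp(np.mean(np.log(c))))


def estimate_ic50(
    concentrations: Sequence[float],
    pct: Sequence[float],
    top_conc: Optional[float] = None,
    *,
    replicates: Optional[Sequence[int]] = None,
    compound: str = "",
    four_param: bool = False,
) -> DoseResponseResult:
    """IC50 (or % at top concentration) from per-observation inhibition data.

    ``concentrations`` may repeat (one entry per replicate measurement);
    fitting uses the mean inhibition per concentration.  When
    ``replicates`` labels independent experiments, the IC50 SE is the
    jackknife (leave-one-experiment-out) standard error.

    If the mean inhibition never reaches 50%, the result is reported as
    the mean % at the highest tested concentration instead of an IC50,
    and no curve is fitted.  A response that *decreases* with
    concentration beyond noise (negative Spearman rank correlation)
    attaches a quality warning but still produces a result.
    """
    conc = np.asarray(concentrations, dtype=float)
    pct_arr = np.asarray(pct, dtype=float)
    if conc.shape != pct_arr.shape:
        raise ValueError("concentrations and pct must have the same length")
    levels = np.unique(conc)
    if levels.size < 4 or 0.0 not in levels:
        raise InsufficientDataError(
            "need >=4 distinct concentrations including the 0 control"
        )
    if top_conc is None:
        top_conc = float(levels.max())

    warnings_list: list[str] = []
    pos = conc > 0
    rho = stats.spearmanr(conc[pos], pct_arr[pos]).statistic
    if np.isfinite(rho) and rho < 0:
        warnings_list.append(
            f"inhibition decreases with concentration (Spearman rho = {rho:.2f})"
        )

    pos_levels = levels[levels > 0]
    means = np.array([pct_arr[conc == c].mean() for c in pos_levels])
    pct_top = float(pct_arr[conc == top_conc].mean())

    if means.max() < 50.0:
        return DoseResponseResult(
            compound=compound,
            reported_as="percent_at_top",
            top_conc=top_conc,
            pct_at_top=pct_top,
            warnings=warnings_list,
        )

    ic50, hill = _fit_logistic(pos_levels, means, four_param)
    se = None
    if replicates is not None:
        rep = np.asarray(replicates)
        labels = np.unique(rep)
        if labels.size >= 2:
            loo = []
            for lab in labels:
                keep = rep != lab
                c_k, p_k = conc[keep], pct_arr[keep]
                lv = np.unique(c_k[c_k > 0])
                m_k = np.array([p_k[c_k == c].mean() for c in lv])
                try:
                    loo.append(_fit_logistic(lv, m_k, four_param)[0])
                except Exception:  # non-convergent deletion fit: skip
                    continue
            if len(loo) >= 2:
                m = len(loo)
                se = float(np.std(loo, ddof=1) * (m - 1) / np.sqrt(m))
    return DoseResponseResult(
        compound=compound,
        reported_as="IC50",
        top_conc=top_conc,
        pct_at_top=pct_top,
        ic50=ic50,
        ic50_se=se,
        hill=hill,
        warnings=warnings_list,
    )
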