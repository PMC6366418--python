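"""Mechanism discrimination: extra sum-of-squares F test and AICc.

Two complementary criteria arbitrate between nested fits on the same
observation set:

* the extra sum-of-squares F test asks whether the SSR drop bought by
  the extra parameter(s) of the complex model exceeds what the residual
  variance would produce by chance,

      F = [(SSR_s - SSR_c) / (df_s - df_c)] / (SSR_c / df_c)

  referred to the F(df_num, df_den) distribution;

* the small-sample corrected Akaike criterion, in its Gaussian-SSR form

      AICc = N ln(SSR/N) + 2K + 2K(K+1)/(N - K - 1)

  where K counts the fitted kinetic parameters plus the residual
  variance.

The decision procedure runs the F test along every nesting edge, keeps
the mechanisms that are neither beaten by a significantly better complex
model nor unnecessarily complex themselves, and picks the lowest AICc
among the survivors, breaking near-ties (< 2 AICc units) toward fewer
parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, NestingError, SelectionError
from .fitting import FitResult
from .mechanisms import Mechanism

__all__ = ["FTestResult", "SelectionResult", "extra_ss_f_test", "aicc", "select_mechanism"]

#: AICc near-tie window (units of AICc) within which the simpler model wins.
AICC_TIE_WINDOW = 2.0

#: Nesting edges tested during selection (simple, complex).
NESTING_EDGES: tuple[tuple[Mechanism, Mechanism], ...] = (
    (Mechanism.NONE, Mechanism.COMPETITIVE),
    (Mechanism.NONE, Mechanism.NONCOMPETITIVE),
    (Mechanism.NONE, Mechanism.UNCOMPETITIVE),
    (Mechanism.NONE, Mechanism.MIXED),
    (Mechanism.COMPETITIVE, Mechanism.MIXED),
    (Mechanism.NONCOMPETITIVE, Mechanism.MIXED),
    (Mechanism.UNCOMPETITIVE, Mechanism.MIXED),
)


@dataclass(frozen=True)
class FTestResult:
    simple_mech: Mechanism
    complex_mech: Mechanism
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    alpha: float
    prefer_complex: bool


@dataclass
class SelectionResult:
    chosen: Mechanism
    aicc_table: dict[Mechanism, float]
    f_tests: list[FTestResult]
    alpha: float
    retained: list[Mechanism] = field(default_factory=list)


def extra_ss_f_test(simple: FitResult, complex: FitResult, alpha: float = 0.05) -> FTestResult:
    """Extra sum-of-squares F test between two nested fits.

    ``prefer_complex`` is True when the observed F exceeds the upper
    ``1 - alpha`` quantile of F(df_num, df_den), equivalently p < alpha.
    A (numerically) negative SSR difference is clamped to F = 0 with a
    warning, since a properly warm-started complex fit can never be
    worse than its nested special case.
    """
    if not simple.mech.is_nested_in(complex.mech):
        raise NestingError(
            f"{simple.mech.value!r} is not nested within {complex.mech.value!r}"
        )
    if simple.n_obs != complex.n_obs:
        raise NestingError("F test requires fits on the identical observation set")
    df_num = simple.dof - complex.dof
    df_den = complex.dof
    if df_num < 1 or df_den < 1:
        raise InsufficientDataError("not enough degrees of freedom for the F test")
    diff = simple.ssr - complex.ssr
    if diff < 0:
        # within optimizer tolerance the two fits are tied; a genuinely
        # worse complex fit means the warm-start guarantee was violated
        if abs(diff) > 1e-4 * max(simple.ssr, 1e-300):
            warnings.warn(
                "complex model fits worse than its nested special case "
                f"({complex.mech.value} vs {simple.mech.value}); F clamped to 0",
                stacklevel=2,
            )
        diff = 0.0
    if complex.ssr == 0.0:
        f_stat = 0.0 if diff == 0.0 else np.inf
        p = 1.0 if diff == 0.0 else 0.0
    else:
        f_stat = (diff / df_num) / (complex.ssr / df_den)
        p = float(stats.f.sf(f_stat, df_num, df_den))
    return FTestResult(
        simple_mech=simple.mech,
        complex_mech=complex.mech,
        f_stat=float(f_stat),
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        alpha=alpha,
        prefer_complex=p < alpha,
    )


def aicc(fit: FitResult, count_variance: bool = True) -> float:
    """Corrected Akaike score of one fit (lower is better).

    ``count_variance=True`` (default, statistically standard for
    SSR-based AICc) counts the residual variance as a parameter:
    K = k_params + 1.  Scores are comparable only across fits on the
    identical observation set.
    """
    n = fit.n_obs
    k = fit.k_params + (1 if count_variance else 0)
    if n - k - 1 < 1:
        raise InsufficientDataError(
            f"AICc undefined: N - K - 1 = {n - k - 1} < 1 (N={n}, K={k})"
        )
    if fit.ssr <= 0.0:
        return -np.inf  # perfect fit: dominates any finite score
    return float(n * np.log(fit.ssr / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


def select_mechanism(
    fits: list[FitResult], alpha: float = 0.05, count_variance: bool = True
) -> SelectionResult:
    """Choose the inhibition mechanism supported by the evidence.

    Procedure: (1) F tests along every nesting edge; (2) retain a
    mechanism only if no significantly better complex model beats it and,
    for the complex mechanisms, only if they beat *every* simpler model
    on their chain; (3) lowest AICc among the retained candidates wins,
    with near-ties (< 2 units) resolved toward fewer parameters.
    """
    by_mech = {f.mech: f for f in fits}
    if set(by_mech) != set(Mechanism):
        raise SelectionError("selection requires exactly one fit per mechanism")
    if len({f.n_obs for f in fits}) != 1:
        raise SelectionError("all fits must share the same observation set")
    bad = [f.mech.value for f in fits if not f.converged]
    if bad:
        raise SelectionError(f"non-converged fits: {bad}")

    f_tests = [
        extra_ss_f_test(by_mech[s], by_mech[c], alpha=alpha) for s, c in NESTING_EDGES
    ]
    sig = {(t.simple_mech, t.complex_mech): t.prefer_complex for t in f_tests}

    three_param = (Mechanism.COMPETITIVE, Mechanism.NONCOMPETITIVE, Mechanism.UNCOMPETITIVE)
    retained: list[Mechanism] = []
    if not any(sig[(Mechanism.NONE, c)] for c in (*three_param, Mechanism.MIXED)):
        retained.append(Mechanism.NONE)
    for m in three_param:
        if sig[(Mechanism.NONE, m)] and not sig[(m, Mechanism.MIXED)]:
            retained.append(m)
    if sig[(Mechanism.NONE, Mechanism.MIXED)] and all(
        sig[(m, Mechanism.MIXED)] for m in three_param
    ):
        retained.append(Mechanism.MIXED)
    if not retained:
        # mutually inconclusive evidence: fall back to pure AICc ranking
        retained = list(by_mech)

    scores = {m: aicc(by_mech[m], count_variance=count_variance) for m in by_mech}
    best = min(scores[m] for m in retained)
    near_best = [m for m in retained if scores[m] <= best + AICC_TIE_WINDOW]
    chosen = min(near_best, key=lambda m: (by_mech[m].k_params, scores[m]))

    return SelectionResult(
        chosen=chosen,
        aicc_table=scores,
        f_tests=f_tests,
        alpha=alpha,
        retained=sorted(retained, key=lambda m: scores[m]),
    )
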