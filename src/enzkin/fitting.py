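"""Nonlinear least-squares fitting of the inhibition mechanisms.

Each mechanism is fitted to *individual* velocity observations (one per
well), never to per-condition means: averaging replicates before fitting
discards the replicate scatter that the F test needs and can flip the
selected mechanism near a decision boundary.

Fitting is done in log-parameter space (positivity for free), by
derivative-based least squares, with a deterministic seeded multistart:
the supplied initial guess plus log-normal perturbations (SD 0.5 natural
log) until the best SSR stops improving.  The cascade fits the five
mechanisms in order of complexity, warm-starting each model from the
optimum of its nested predecessor, which also guarantees SSR
monotonicity along every nesting chain up to optimizer tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import InsufficientDataError, UnidentifiableError
from .mechanisms import KineticParameters, Mechanism, rate_law
from .rates import VelocityObservation

__all__ = ["FitResult", "fit_model", "fit_cascade", "default_init", "CASCADE_ORDER"]

#: Fitting order: simplest first, mixed last (seeded from the best
#: three-parameter optimum).
CASCADE_ORDER = (
    Mechanism.NONE,
    Mechanism.COMPETITIVE,
    Mechanism.NONCOMPETITIVE,
    Mechanism.UNCOMPETITIVE,
    Mechanism.MIXED,
)

#: Placeholder for an "effectively absent" inhibition constant when a
#: nested optimum seeds a more complex model (factor 1 + I/K ~ 1).
_NEAR_ABSENT_KI = 1.0e12

_SSR_STABLE_RTOL = 1.0e-12
_MULTISTART_PATIENCE = 3


@dataclass(frozen=True)
class FitResult:
    """One mechanism fitted to one observation set."""

    mech: Mechanism
    params: KineticParameters
    ssr: float
    n_obs: int
    k_params: int
    converged: bool
    n_starts_used: int

    @property
    def dof(self) -> int:
        return self.n_obs - self.k_params


def _pack(params: KineticParameters, mech: Mechanism) -> np.ndarray:
    """Log-parameter vector in the mechanism's canonical order."""
    vals = {"vmax": params.vmax, "km": params.km, "kic": params.kic, "kiu": params.kiu}
    vals["ki"] = params.kic  # noncompetitive shared constant
    return np.log([vals[name] for name in mech.free_parameters])


def _unpack(x: np.ndarray, mech: Mechanism) -> KineticParameters:
    theta = dict(zip(mech.free_parameters, np.exp(np.clip(x, -250.0, 250.0))))
    if mech is Mechanism.NONCOMPETITIVE:
        ki = theta.pop("ki")
        theta["kic"] = ki
        theta["kiu"] = ki
    return KineticParameters(**theta)


def _residual_fn(mech: Mechanism, S: np.ndarray, I: np.ndarray, v: np.ndarray):
    uses_kic, uses_kiu = mech.uses_kic, mech.uses_kiu
    nonc = mech is Mechanism.NONCOMPETITIVE

    def residuals(x: np.ndarray) -> np.ndarray:
        with np.errstate(all="ignore"):
            p = np.exp(np.clip(x, -250.0, 250.0))
            if nonc:
                kic = kiu = p[2]
            else:
                kic = p[2] if uses_kic else None
                kiu = p[-1] if uses_kiu else None
            r = v - rate_law(p[0], p[1], kic, kiu, S, I)
        # keep the optimizer on the rails if a trial step overflowed
        return np.nan_to_num(r, nan=1e6, posinf=1e6, neginf=-1e6)

    return residuals


def _check_preconditions(
    S: np.ndarray, I: np.ndarray, mech: Mechanism, n_obs: int
) -> None:
    if n_obs <= mech.n_parameters:
        raise InsufficientDataError(
            f"{n_obs} observations cannot constrain {mech.n_parameters} parameters"
        )
    if np.unique(S).size < 2:
        raise InsufficientDataError("observations must span >=2 substrate levels")
    if mech is not Mechanism.NONE:
        if np.unique(I).size < 2 or not np.any(I > 0):
            raise UnidentifiableError(
                f"mechanism {mech.value!r} needs >=2 inhibitor levels with I>0 present"
            )
        if not np.any(I == 0):
            raise InsufficientDataError("uninhibited control observations (I=0) required")


def default_init(obs: Sequence[VelocityObservation], mech: Mechanism) -> KineticParameters:
    """Data-driven starting values.

    Vmax starts 20% above the largest uninhibited velocity, Km at the
    median substrate level; inhibition constants start at the inhibitor
    level that roughly halves the uninhibited mean velocity (falling
    back to the median tested level).
    """
    v = np.array([o.v for o in obs])
    S = np.array([o.cond.S for o in obs])
    I = np.array([o.cond.I for o in obs])
    control = v[I == 0]
    vmax0 = 1.2 * float(np.max(control if control.size else v))
    vmax0 = max(vmax0, 1e-12)
    km0 = float(np.median(S))
    if mech is Mechanism.NONE:
        return KineticParameters(vmax=vmax0, km=km0)
    ki0 = _half_effect_level(v, I)
    if mech is Mechanism.COMPETITIVE:
        return KineticParameters(vmax=vmax0, km=km0, kic=ki0)
    if mech is Mechanism.UNCOMPETITIVE:
        return KineticParameters(vmax=vmax0, km=km0, kiu=ki0)
    return KineticParameters(vmax=vmax0, km=km0, kic=ki0, kiu=ki0)


def _half_effect_level(v: np.ndarray, I: np.ndarray) -> float:
    """Inhibitor level where mean velocity first drops below half of control."""
    levels = np.unique(I[I > 0])
    if levels.size == 0:
        return 1.0
    v0 = float(np.mean(v[I == 0])) if np.any(I == 0) else float(np.max(v))
    if v0 > 0:
        for lev in levels:
            if float(np.mean(v[I == lev])) <= 0.5 * v0:
                return float(lev)
    return float(np.median(levels))


def fit_model(
    obs: Sequence[VelocityObservation],
    mech: Mechanism,
    init: Optional[KineticParameters] = None,
    *,
    extra_starts: Sequence[KineticParameters] = (),
    n_starts: int = 10,
    perturb_sd: float = 0.5,
    seed: int = 0,
) -> FitResult:
    """Least-squares fit of *mech* to individual velocity observations.

    Parameters are optimized in natural-log space (hence strictly
    positive).  The optimizer restarts from ``init``, any
    ``extra_starts`` (e.g. nested optima in the cascade) and up to
    ``n_starts`` seeded log-normal perturbations of ``init``, stopping
    early once the best SSR has been stable for a few starts.
    """
    v = np.array([o.v for o in obs], dtype=float)
    S = np.array([o.cond.S for o in obs], dtype=float)
    I = np.array([o.cond.I for o in obs], dtype=float)
    _check_preconditions(S, I, mech, len(obs))
    if init is None:
        init = default_init(obs, mech)

    residuals = _residual_fn(mech, S, I, v)
    rng = np.random.default_rng(seed)
    x0 = _pack(init, mech)
    starts = [x0] + [_pack(p, mech) for p in extra_starts]

    best_x = None
    best_ssr = np.inf
    converged = False
    stale = 0
    n_used = 0
    i = 0
    while i < len(starts) + n_starts:
        if i < len(starts):
            x_start = starts[i]
        else:
            x_start = x0 + rng.normal(0.0, perturb_sd, size=x0.size)
        i += 1
        n_used += 1
        sol = least_squares(
            residuals, x_start, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=2000 * x0.size,
        )
        ssr = float(2.0 * sol.cost)
        if ssr < best_ssr * (1.0 - _SSR_STABLE_RTOL):
            best_ssr, best_x = ssr, sol.x
            converged = bool(sol.status > 0)
            stale = 0
        else:
            stale += 1
            if best_x is None:
                best_ssr, best_x = ssr, sol.x
                converged = bool(sol.status > 0)
        if i >= len(starts) and stale >= _MULTISTART_PATIENCE:
            break

    return FitResult(
        mech=mech,
        params=_unpack(best_x, mech),
        ssr=best_ssr,
        n_obs=len(obs),
        k_params=mech.n_parameters,
        converged=converged,
        n_starts_used=n_used,
    )


def fit_cascade(
    obs: Sequence[VelocityObservation], *, seed: int = 0, n_starts: int = 10
) -> list[FitResult]:
    """Fit all five mechanisms, simplest first, each seeded by its predecessors.

    The uninhibited fit supplies (Vmax, Km) to every inhibition model;
    each three-parameter optimum (with its constant carried over and the
    missing one set effectively absent) seeds the mixed fit.  Results
    are returned in cascade order: none, competitive, noncompetitive,
    uncompetitive, mixed.
    """
    fits: dict[Mechanism, FitResult] = {}

    f_none = fit_model(obs, Mechanism.NONE, n_starts=n_starts, seed=seed)
    fits[Mechanism.NONE] = f_none
    vmax_n, km_n = f_none.params.vmax, f_none.params.km
    ki0 = _half_effect_level(
        np.array([o.v for o in obs]), np.array([o.cond.I for o in obs])
    )

    three_param = {
        Mechanism.COMPETITIVE: dict(kic=ki0),
        Mechanism.NONCOMPETITIVE: dict(kic=ki0, kiu=ki0),
        Mechanism.UNCOMPETITIVE: dict(kiu=ki0),
    }
    degenerate = {
        Mechanism.COMPETITIVE: dict(kic=_NEAR_ABSENT_KI),
        Mechanism.NONCOMPETITIVE: dict(kic=_NEAR_ABSENT_KI, kiu=_NEAR_ABSENT_KI),
        Mechanism.UNCOMPETITIVE: dict(kiu=_NEAR_ABSENT_KI),
    }
    for mech, extra in three_param.items():
        init = KineticParameters(vmax=vmax_n, km=km_n, **extra)
        # start equivalent to the uninhibited optimum: SSR can only go down
        nested_start = KineticParameters(vmax=vmax_n, km=km_n, **degenerate[mech])
        fits[mech] = fit_model(
            obs, mech, init, extra_starts=[nested_start], n_starts=n_starts, seed=seed
        )

    best3 = min(
        (fits[m] for m in three_param), key=lambda f: f.ssr
    )
    kic0 = best3.params.kic if best3.params.kic is not None else ki0
    kiu0 = best3.params.kiu if best3.params.kiu is not None else ki0
    init_mixed = KineticParameters(vmax=best3.params.vmax, km=best3.params.km, kic=kic0, kiu=kiu0)
    mixed_starts = []
    for m in three_param:
        p = fits[m].params
        mixed_starts.append(
            KineticParameters(
                vmax=p.vmax,
                km=p.km,
                kic=p.kic if p.kic is not None else _NEAR_ABSENT_KI,
                kiu=p.kiu if p.kiu is not None else _NEAR_ABSENT_KI,
            )
        )
    fits[Mechanism.MIXED] = fit_model(
        obs, Mechanism.MIXED, init_mixed, extra_starts=mixed_starts,
        n_starts=n_starts, seed=seed,
    )
    return [fits[m] for m in CASCADE_ORDER]
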