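"""Jackknife dispersion estimates for fitted kinetic constants.

Each observation (one well's velocity) is deleted in turn and the
selected mechanism refitted, warm-started at the full-data optimum.  Two
dispersion summaries are reported for every parameter:

* ``sd`` — the plain sample standard deviation (ddof=1) of the
  leave-one-out estimates, the primary output;
* ``tukey_se`` — the classical jackknife standard error,
  sqrt((n-1)/n * sum((theta_i - theta_bar)^2)), which equals
  ``sd * (n-1)/sqrt(n)`` exactly.

The plain SD understates the textbook jackknife SE by that factor; both
are carried so either convention can be quoted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import InsufficientDataError
from .fitting import FitResult, fit_model
from .mechanisms import KineticParameters, Mechanism
from .rates import VelocityObservation

__all__ = ["JackknifeReport", "jackknife_sd", "leave_one_out"]


@dataclass
class JackknifeReport:
    mech: Mechanism
    point: KineticParameters
    parameter_names: tuple[str, ...]
    sd: dict[str, float]
    tukey_se: dict[str, float]
    n_leaveouts: int
    estimates: np.ndarray  # (n_used, k) leave-one-out parameter matrix
    excluded: list[int] = field(default_factory=list)  # non-convergent leave-outs


def leave_one_out(
    values: Sequence, estimator: Callable[[Sequence], float]
) -> tuple[float, np.ndarray]:
    """Plain SD (ddof=1) of ``estimator`` applied to each deletion set.

    Generic scalar form, e.g. for the sample mean the leave-one-out SD
    equals the sample SD divided by (n - 1).
    """
    n = len(values)
    if n < 2:
        raise InsufficientDataError("jackknife needs at least 2 observations")
    est = np.array(
        [estimator([v for j, v in enumerate(values) if j != i]) for i in range(n)],
        dtype=float,
    )
    return float(np.std(est, ddof=1)), est


def jackknife_sd(
    obs: Sequence[VelocityObservation],
    mech: Mechanism,
    estimator: Optional[Callable[[Sequence[VelocityObservation]], FitResult]] = None,
    *,
    full_fit: Optional[FitResult] = None,
    seed: int = 0,
) -> JackknifeReport:
    """Leave-one-out SDs of the kinetic constants under *mech*.

    ``estimator`` maps an observation subset to a :class:`FitResult`;
    the default refits *mech* warm-started at the full-data optimum
    (no multistart — the deletion sets sit in the same basin).  A
    leave-one-out fit that fails to converge is excluded and recorded.
    """
    n = len(obs)
    if n < mech.n_parameters + 2:
        raise InsufficientDataError(
            f"jackknife needs n >= k + 2 = {mech.n_parameters + 2}, got {n}"
        )
    if full_fit is None:
        full_fit = fit_model(obs, mech, seed=seed) if estimator is None else estimator(obs)
    if estimator is None:
        warm = full_fit.params

        def estimator(subset: Sequence[VelocityObservation]) -> FitResult:
            return fit_model(subset, mech, warm, n_starts=0, seed=seed)

    names = mech.free_parameters
    rows: list[list[float]] = []
    excluded: list[int] = []
    for i in range(n):
        subset = [o for j, o in enumerate(obs) if j != i]
        fit = estimator(subset)
        if not fit.converged:
            excluded.append(i)
            continue
        rows.append(_param_vector(fit.params, names))
    est = np.asarray(rows, dtype=float)
    if est.shape[0] < 2:
        raise InsufficientDataError("fewer than 2 convergent leave-one-out fits")
    sd_vec = np.std(est, axis=0, ddof=1)
    m = est.shape[0]
    tukey_vec = sd_vec * (m - 1) / np.sqrt(m)
    return JackknifeReport(
        mech=mech,
        point=full_fit.params,
        parameter_names=names,
        sd=dict(zip(names, sd_vec.tolist())),
        tukey_se=dict(zip(names, tukey_vec.tolist())),
        n_leaveouts=n,
        estimates=est,
        excluded=excluded,
    )


def _param_vector(params: KineticParameters, names: tuple[str, ...]) -> list[float]:
    vals = params.as_dict()
    vals["ki"] = params.kic  # shared noncompetitive constant
    return [float(vals[name]) for name in names]
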