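"""Michaelis-Menten inhibition mechanisms and the general rate law.

The velocity of product formation in the presence of a reversible
inhibitor is modelled by

    v = Vmax * S / ( Km * (1 + I/Kic) + S * (1 + I/Kiu) )

where ``S`` is the substrate concentration (mM), ``I`` the inhibitor
concentration (uM), ``Kic`` the competitive and ``Kiu`` the uncompetitive
inhibition constant (both uM).  Dropping one or both inhibition terms
(the corresponding factor becomes 1) yields the classical nested family:

==============  ==========================  ==============
mechanism       free parameters             constraint
==============  ==========================  ==============
none            Vmax, Km                    no I terms
competitive     Vmax, Km, Kic               Kiu term absent
uncompetitive   Vmax, Km, Kiu               Kic term absent
noncompetitive  Vmax, Km, Ki                Kic == Kiu == Ki
mixed           Vmax, Km, Kic, Kiu          none
==============  ==========================  ==============

Absent constants are represented by ``None`` (their factor is exactly 1),
never by infinity, so parameter counts used by information criteria are
explicit and no overflow can occur.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .errors import DomainError, ParameterMismatchError

__all__ = [
    "Mechanism",
    "KineticParameters",
    "Condition",
    "evaluate_rate",
    "apparent_constants",
    "validate_params",
]


class Mechanism(str, Enum):
    """The five nested inhibition mechanisms."""

    NONE = "none"
    COMPETITIVE = "competitive"
    UNCOMPETITIVE = "uncompetitive"
    NONCOMPETITIVE = "noncompetitive"
    MIXED = "mixed"

    @property
    def free_parameters(self) -> tuple[str, ...]:
        """Names of the free kinetic parameters, in fitting order."""
        return _FREE_PARAMS[self]

    @property
    def n_parameters(self) -> int:
        """Number of free kinetic parameters (2, 3 or 4)."""
        return len(_FREE_PARAMS[self])

    @property
    def nested_within(self) -> frozenset["Mechanism"]:
        """Mechanisms of which this one is a constrained special case."""
        return _NESTED_WITHIN[self]

    def is_nested_in(self, other: "Mechanism") -> bool:
        return other in self.nested_within

    @property
    def uses_kic(self) -> bool:
        return self in (Mechanism.COMPETITIVE, Mechanism.NONCOMPETITIVE, Mechanism.MIXED)

    @property
    def uses_kiu(self) -> bool:
        return self in (Mechanism.UNCOMPETITIVE, Mechanism.NONCOMPETITIVE, Mechanism.MIXED)


_FREE_PARAMS: dict[Mechanism, tuple[str, ...]] = {
    Mechanism.NONE: ("vmax", "km"),
    Mechanism.COMPETITIVE: ("vmax", "km", "kic"),
    Mechanism.UNCOMPETITIVE: ("vmax", "km", "kiu"),
    # noncompetitive binds a single Ki to both slots: 3 free parameters
    Mechanism.NONCOMPETITIVE: ("vmax", "km", "ki"),
    Mechanism.MIXED: ("vmax", "km", "kic", "kiu"),
}

_NESTED_WITHIN: dict[Mechanism, frozenset[Mechanism]] = {
    Mechanism.NONE: frozenset(
        {
            Mechanism.COMPETITIVE,
            Mechanism.UNCOMPETITIVE,
            Mechanism.NONCOMPETITIVE,
            Mechanism.MIXED,
        }
    ),
    Mechanism.COMPETITIVE: frozenset({Mechanism.MIXED}),
    Mechanism.UNCOMPETITIVE: frozenset({Mechanism.MIXED}),
    Mechanism.NONCOMPETITIVE: frozenset({Mechanism.MIXED}),
    Mechanism.MIXED: frozenset(),
}


@dataclass(frozen=True)
class KineticParameters:
    """Kinetic constants of one mechanism.

    Parameters
    ----------
    vmax : float
        Maximal velocity, umol/min.
    km : float
        Michaelis constant, mM.
    kic : float, optional
        Competitive inhibition constant, uM.  ``None`` means the
        competitive factor is absent (identically 1).
    kiu : float, optional
        Uncompetitive inhibition constant, uM.  ``None`` means the
        uncompetitive factor is absent.
    """

    vmax: float
    km: float
    kic: Optional[float] = None
    kiu: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("vmax", "km"):
            val = getattr(self, name)
            if not np.isfinite(val) or val <= 0:
                raise ParameterMismatchError(f"{name} must be finite and > 0, got {val}")
        for name in ("kic", "kiu"):
            val = getattr(self, name)
            if val is not None and (not np.isfinite(val) or val <= 0):
                raise ParameterMismatchError(f"{name} must be finite and > 0, got {val}")

    @property
    def ki(self) -> Optional[float]:
        """The shared constant of a noncompetitive parameter set."""
        if self.kic is not None and self.kic == self.kiu:
            return self.kic
        return None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {"vmax": self.vmax, "km": self.km, "kic": self.kic, "kiu": self.kiu}


@dataclass(frozen=True)
class Condition:
    """One assay condition: substrate S (mM) and inhibitor I (uM)."""

    S: float
    I: float = 0.0

    def __post_init__(self) -> None:
        if not self.S > 0:
            raise DomainError(f"substrate concentration must be > 0, got {self.S}")
        if self.I < 0:
            raise DomainError(f"inhibitor concentration must be >= 0, got {self.I}")


def validate_params(params: KineticParameters, mech: Mechanism) -> None:
    """Check that *params* carries exactly the constants *mech* needs.

    Raises
    ------
    ParameterMismatchError
        If a required constant is missing, a forbidden one is present,
        or a noncompetitive set has Kic != Kiu.
    """
    if mech.uses_kic and params.kic is None:
        raise ParameterMismatchError(f"mechanism {mech.value!r} requires Kic")
    if mech.uses_kiu and params.kiu is None:
        raise ParameterMismatchError(f"mechanism {mech.value!r} requires Kiu")
    if not mech.uses_kic and params.kic is not None:
        raise ParameterMismatchError(f"mechanism {mech.value!r} does not take Kic")
    if not mech.uses_kiu and params.kiu is not None:
        raise ParameterMismatchError(f"mechanism {mech.value!r} does not take Kiu")
    if mech is Mechanism.NONCOMPETITIVE and params.kic != params.kiu:
        raise ParameterMismatchError(
            f"noncompetitive inhibition requires Kic == Kiu, got {params.kic} != {params.kiu}"
        )


def rate_law(
    vmax: float,
    km: float,
    kic: Optional[float],
    kiu: Optional[float],
    S: np.ndarray | float,
    I: np.ndarray | float,
) -> np.ndarray | float:
    """Vectorised general rate law; absent constants mean factor 1.

    Low-level kernel used by the fitter; does no validation.
    """
    alpha_c = 1.0 if kic is None else 1.0 + np.asarray(I) / kic
    alpha_u = 1.0 if kiu is None else 1.0 + np.asarray(I) / kiu
    S = np.asarray(S) if not np.isscalar(S) else S
    return vmax * S / (km * alpha_c + S * alpha_u)


def evaluate_rate(params: KineticParameters, mech: Mechanism, cond: Condition) -> float:
    """Initial velocity (umol/min) under *mech* at condition *cond*.

    At ``I = 0`` every mechanism sharing (Vmax, Km) returns the same
    Michaelis-Menten velocity; the result always lies in (0, Vmax].
    """
    validate_params(params, mech)
    return float(rate_law(params.vmax, params.km, params.kic, params.kiu, cond.S, cond.I))


def apparent_constants(
    params: KineticParameters, mech: Mechanism, I: float
) -> tuple[float, float]:
    """Apparent (Vmax_app, Km_app) at inhibitor concentration *I* (uM).

    Rearranging the rate law into Michaelis-Menten form gives

        Vmax_app = Vmax / (1 + I/Kiu)
        Km_app   = Km * (1 + I/Kic) / (1 + I/Kiu)

    so that ``v = Vmax_app * S / (Km_app + S)`` exactly.  Useful for
    diagnostic (Lineweaver-Burk style) plots.
    """
    validate_params(params, mech)
    if I < 0:
        raise DomainError(f"inhibitor concentration must be >= 0, got {I}")
    alpha_c = 1.0 if params.kic is None else 1.0 + I / params.kic
    alpha_u = 1.0 if params.kiu is None else 1.0 + I / params.kiu
    return params.vmax / alpha_u, params.km * alpha_c / alpha_u
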