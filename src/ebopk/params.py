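"""Individual-level kinetic parameters, dose events and concentration profiles.

Units are fixed throughout the package: amounts in mg, volumes in L, times in
hours, clearances in L/h, concentrations in mg/L.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InputError, ParameterError

IV = "IV"
PO = "PO"


@dataclass(frozen=True)
class StructuralParams:
    """Fixed-effect kinetic parameters of a single individual.

    Three-compartment mammillary disposition with linear elimination from the
    central compartment, plus oral input through a chain of ``n_transit``
    transit compartments feeding an absorption depot.

    Parameters
    ----------
    CL : float
        Systemic clearance (L/h).
    V1, V2, V3 : float
        Central and peripheral distribution volumes (L).
    Q2, Q3 : float
        Inter-compartmental clearances (L/h).
    ka_fed, ka_fasted : float
        First-order absorption rate constants (1/h) from the depot, selected
        per dose by its fed flag.
    ktr : float or None
        Transit rate constant (1/h) shared by all transit compartments. ``None``
        ties the transit rate to the dose-specific ka (a common
        parameterisation); the default configuration uses an independent ktr.
    n_transit : int
        Number of transit compartments ahead of the depot (>= 0).
    F : float
        Absolute oral bioavailability. Dimensionless; the typical value lies
        in (0, 1] but individual values drawn from a log-normal distribution
        may exceed 1 in the upper tail.
    """

    CL: float
    V1: float
    Q2: float
    V2: float
    Q3: float
    V3: float
    ka_fed: float
    ka_fasted: float
    ktr: Optional[float] = 1.5
    n_transit: int = 3
    F: float = 1.0

    def __post_init__(self) -> None:
        for name in ("CL", "V1", "Q2", "V2", "Q3", "V3", "ka_fed", "ka_fasted"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be strictly positive, got {v!r}")
        if self.ktr is not None and not (np.isfinite(self.ktr) and self.ktr > 0):
            raise ParameterError(f"ktr must be strictly positive or None, got {self.ktr!r}")
        if not (isinstance(self.n_transit, (int, np.integer)) and self.n_transit >= 0):
            raise ParameterError(f"n_transit must be a non-negative integer, got {self.n_transit!r}")
        if not (np.isfinite(self.F) and self.F > 0):
            raise ParameterError(f"F must be strictly positive, got {self.F!r}")

    def transit_rate(self, fed: bool) -> float:
        """Transit rate constant for a dose with the given fed status."""
        if self.ktr is None:
            return self.ka_fed if fed else self.ka_fasted
        return self.ktr

    def ka(self, fed: bool) -> float:
        return self.ka_fed if fed else self.ka_fasted


@dataclass(frozen=True)
class DoseEvent:
    """One administration: IV bolus, IV zero-order infusion, or oral dose.

    ``fed`` must be given for PO doses (food slows or speeds absorption via
    the route-specific ka) and must be None for IV doses.  ``duration`` is the
    infusion length in hours; 0 means bolus, and oral doses are always
    instantaneous inputs into the first transit compartment.
    """

    time: float
    amount: float
    route: str
    duration: float = 0.0
    fed: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.route not in (IV, PO):
            raise InputError(f"route must be 'IV' or 'PO', got {self.route!r}")
        if not (np.isfinite(self.amount) and self.amount >= 0):
            raise InputError(f"amount must be non-negative, got {self.amount!r}")
        if not (np.isfinite(self.duration) and self.duration >= 0):
            raise InputError(f"duration must be non-negative, got {self.duration!r}")
        if not np.isfinite(self.time):
            raise InputError(f"time must be finite, got {self.time!r}")
        if self.route == PO:
            if self.fed is None:
                raise InputError("fed flag is required for PO doses")
            if self.duration != 0:
                raise InputError("oral doses must have duration 0")
        elif self.fed is not None:
            raise InputError("fed flag is only defined for PO doses")


@dataclass(frozen=True)
class ConcentrationProfile:
    """Central-compartment concentration (mg/L) at strictly increasing times."""

    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)
        if t.ndim != 1 or c.shape != t.shape:
            raise InputError("times and conc must be 1-D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise InputError("times must be strictly increasing")
        if not np.all(np.isfinite(c)):
            raise InputError("concentrations must be finite")
        if np.any(c < 0):
            raise InputError("concentrations must be non-negative")
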