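"""Population level of the hierarchy.

Maps typical values + body-weight covariate + log-normal random effects to an
individual's :class:`~ebopk.params.StructuralParams`, and defines the combined
proportional + additive residual-error model.  Random effects are carried on
systemic clearance and on absolute bioavailability (diagonal covariance); all
clearances scale allometrically with body weight (default exponent 0.75) and
all volumes with exponent 1.0 about a 70 kg reference.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
import numpy as np
import yaml

from .errors import ContractError, ParameterError
from .params import StructuralParams

ETA_NAMES = ("CL", "F")

_THETA_FIELDS = ("CL", "V1", "Q2", "V2", "Q3", "V3", "ka_fed", "ka_fasted", "ktr", "F")


@dataclass(frozen=True)
class Subject:
    """A trial participant: identifier, body weight (kg) and population flag."""

    id: int | str
    wt: float
    population: str = "healthy"  # "healthy" or "patient" (MAC lung disease)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.wt) and self.wt > 0):
            raise ParameterError(f"WT must be strictly positive, got {self.wt!r}")


@dataclass(frozen=True)
class PopulationModel:
    """Typical values, allometry, IIV variances and residual-error parameters.

    ``omega_cl`` and ``omega_f`` are the variances of the log-normal random
    effects on CL and F (diagonal covariance).  ``sigma_prop`` is the
    proportional residual SD (fraction of the prediction) and ``sigma_add``
    the additive residual SD (mg/L); at least one must be positive.
    """

    theta: StructuralParams
    omega_cl: float
    omega_f: float
    sigma_prop: float
    sigma_add: float
    allo_exp_cl: float = 0.75
    allo_exp_v: float = 1.0
    ref_wt: float = 70.0

    def __post_init__(self) -> None:
        if self.omega_cl < 0 or self.omega_f < 0:
            raise ParameterError("omega variances must be non-negative")
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ParameterError("sigma values must be non-negative")
        if self.sigma_prop == 0 and self.sigma_add == 0:
            raise ParameterError("at least one residual-error component must be positive")
        if not (np.isfinite(self.ref_wt) and self.ref_wt > 0):
            raise ParameterError("ref_wt must be strictly positive")

    @property
    def omega(self) -> np.ndarray:
        """Diagonal of the random-effect covariance, ordered as ETA_NAMES."""
        return np.array([self.omega_cl, self.omega_f])

    def replace(self, **kw) -> "PopulationModel":
        """Return a copy with fields replaced; theta fields go through ``theta_kw``."""
        theta_kw = kw.pop("theta_kw", None)
        if theta_kw:
            kw["theta"] = dataclasses.replace(self.theta, **theta_kw)
        return dataclasses.replace(self, **kw)


def individual_params(pop: PopulationModel, subj: Subject, eta: np.ndarray) -> StructuralParams:
    """Individual kinetic parameters from typical values, weight and random effects.

    CL carries both the allometric factor ``(WT/ref_wt)**allo_exp_cl`` and the
    log-normal random effect; Q2/Q3 scale allometrically only; volumes scale
    with ``allo_exp_v``; F carries its random effect; absorption rates are
    unscaled.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (len(ETA_NAMES),):
        raise ContractError(f"eta must have shape ({len(ETA_NAMES)},), got {eta.shape}")
    th = pop.theta
    fw_cl = (subj.wt / pop.ref_wt) ** pop.allo_exp_cl
    fw_v = (subj.wt / pop.ref_wt) ** pop.allo_exp_v
    return dataclasses.replace(
        th,
        CL=th.CL * fw_cl * np.exp(eta[0]),
        Q2=th.Q2 * fw_cl,
        Q3=th.Q3 * fw_cl,
        V1=th.V1 * fw_v,
        V2=th.V2 * fw_v,
        V3=th.V3 * fw_v,
        F=th.F * np.exp(eta[1]),
    )


def iiv_cv_percent(omega_kk: float) -> float:
    """Log-normal coefficient of variation (%) from a random-effect variance.

    ``100 * sqrt(exp(omega) - 1)``; strictly increasing, 0 at 0.
    """
    if omega_kk < 0:
        raise ParameterError("variance must be non-negative")
    return 100.0 * np.sqrt(np.expm1(omega_kk))


def variance_from_cv_percent(cv: float) -> float:
    """Inverse of :func:`iiv_cv_percent`."""
    if cv < 0:
        raise ParameterError("CV% must be non-negative")
    return float(np.log1p((cv / 100.0) ** 2))


def residual_observe(true_conc, eps, pop: PopulationModel):
    """Apply the combined residual-error model to a true concentration.

    ``DV = c * (1 + sigma_prop * eps1) + sigma_add * eps2`` with independent
    standard-normal ``eps = (eps1, eps2)``, so
    ``Var(DV | c) = (sigma_prop * c)**2 + sigma_add**2``.
    """
    c = np.asarray(true_conc, dtype=float)
    if np.any(c < 0):
        raise ParameterError("true concentration must be non-negative")
    eps = np.asarray(eps, dtype=float)
    e1, e2 = eps[..., 0], eps[..., 1]
    return c * (1.0 + pop.sigma_prop * e1) + pop.sigma_add * e2


def default_model() -> PopulationModel:
    """Reference population model used by the generator and examples.

    Typical values are synthetic reference values chosen to be plausible for a
    renally cleared oral/IV antibacterial dosed at 500 mg q24h; they are not
    estimates from clinical data.  The IIV magnitudes correspond to a CV of
    7.9% on clearance and 32.7% on bioavailability.
    """
    theta = StructuralParams(
        CL=12.0, V1=30.0, Q2=8.0, V2=60.0, Q3=2.0, V3=120.0,
        ka_fed=0.6, ka_fasted=1.2, ktr=1.5, n_transit=3, F=0.85,
    )
    return PopulationModel(
        theta=theta,
        omega_cl=variance_from_cv_percent(7.9),
        omega_f=variance_from_cv_percent(32.7),
        sigma_prop=0.10,
        sigma_add=0.05,
    )


# --------------------------------------------------------------------------
# configuration files (YAML)


def model_to_dict(pop: PopulationModel) -> dict:
    theta = {f: getattr(pop.theta, f) for f in _THETA_FIELDS}
    theta["n_transit"] = pop.theta.n_transit
    return {
        "theta": theta,
        "allometry": {
            "exp_clearance": pop.allo_exp_cl,
            "exp_volume": pop.allo_exp_v,
            "ref_wt": pop.ref_wt,
        },
        "omega": {
            "CL": {"variance": pop.omega_cl},
            "F": {"variance": pop.omega_f},
        },
        "sigma": {"prop": pop.sigma_prop, "add": pop.sigma_add},
    }


def _omega_entry(entry) -> float:
    """An omega block entry is either {'variance': v} or {'cv_percent': cv}."""
    if isinstance(entry, dict):
        if "variance" in entry:
            return float(entry["variance"])
        if "cv_percent" in entry:
            return variance_from_cv_percent(float(entry["cv_percent"]))
    raise ParameterError(f"omega entries need a 'variance' or 'cv_percent' key, got {entry!r}")


def model_from_dict(d: dict) -> PopulationModel:
    th = dict(d["theta"])
    theta = StructuralParams(
        CL=float(th["CL"]), V1=float(th["V1"]), Q2=float(th["Q2"]), V2=float(th["V2"]),
        Q3=float(th["Q3"]), V3=float(th["V3"]),
        ka_fed=float(th["ka_fed"]), ka_fasted=float(th["ka_fasted"]),
        ktr=None if th.get("ktr") is None else float(th["ktr"]),
        n_transit=int(th.get("n_transit", 3)),
        F=float(th.get("F", 1.0)),
    )
    allo = d.get("allometry", {})
    om = d.get("omega", {})
    sig = d.get("sigma", {})
    return PopulationModel(
        theta=theta,
        omega_cl=_omega_entry(om["CL"]) if "CL" in om else 0.0,
        omega_f=_omega_entry(om["F"]) if "F" in om else 0.0,
        sigma_prop=float(sig.get("prop", 0.0)),
        sigma_add=float(sig.get("add", 0.0)),
        allo_exp_cl=float(allo.get("exp_clearance", 0.75)),
        allo_exp_v=float(allo.get("exp_volume", 1.0)),
        ref_wt=float(allo.get("ref_wt", 70.0)),
    )


def save_model(pop: PopulationModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(pop), fh, sort_keys=False)


def load_model(path) -> PopulationModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
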