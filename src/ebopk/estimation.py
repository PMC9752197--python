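"""Nonlinear mixed-effects estimation.

Population parameters are estimated by minimising the sum over subjects of
the Laplace -2 log marginal likelihood (see :mod:`ebopk.laplace`).  The outer
search runs on transformed coordinates (log for positive typical values and
residual SDs, log-SD for the omega variances) so invariants hold by
construction, using Nelder-Mead with warm-started inner modes.  Empirical
Bayes estimates (conditional modes at the final parameters) feed the
eta- and epsilon-shrinkage diagnostics.

Subjects with no oral dose carry no information on the bioavailability random
effect; their eta_F integrates out exactly and is dropped from that subject's
inner problem (the EBE is reported as 0, i.e. fully shrunk).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .dataio import PKDataset, SubjectRecord
from .errors import FitError, ParameterError
from .laplace import PENALTY, laplace_m2ll
from .params import PO
from .population import (
    ETA_NAMES,
    PopulationModel,
    Subject,
    individual_params,
    iiv_cv_percent,
)
from .structural import ProfileEvaluator

THETA_NAMES = ("CL", "V1", "Q2", "V2", "Q3", "V3", "ka_fed", "ka_fasted", "ktr", "F")
VARIANCE_NAMES = ("omega_CL", "omega_F", "sigma_prop", "sigma_add")
PARAM_NAMES = THETA_NAMES + VARIANCE_NAMES

_LOG2PI = float(np.log(2 * np.pi))
_VAR_FLOOR = 1e-12


class _SubjectModel:
    """Likelihood machinery for one subject.

    Caches the (IV, unit-F oral) profile pair keyed by the exact float value
    of eta_CL: bioavailability enters the prediction linearly, so moving along
    eta_F never re-propagates the kinetics.
    """

    def __init__(self, rec: SubjectRecord, n_transit: int):
        self.rec = rec
        self.evaluator = ProfileEvaluator(rec.doses, rec.obs_times, n_transit=n_transit)
        self.has_po = any(d.route == PO for d in rec.doses)
        self.y = rec.dv
        self.n_obs = rec.dv.size
        self.subject = Subject(id=rec.id, wt=rec.wt)
        self._pop: Optional[PopulationModel] = None
        self._cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def set_population(self, pop: PopulationModel) -> None:
        self._pop = pop
        self._cache.clear()

    def _parts(self, eta_cl: float):
        hit = self._cache.get(eta_cl)
        if hit is None:
            try:
                with np.errstate(over="ignore"):
                    p = individual_params(self._pop, self.subject, np.array([eta_cl, 0.0]))
                hit = self.evaluator.conc_parts(p)
            except (ParameterError, FloatingPointError, np.linalg.LinAlgError):
                hit = None  # un-evaluable corner: signalled as infinite -2LL
            if len(self._cache) > 256:
                self._cache.clear()
            self._cache[eta_cl] = hit
        return hit

    def predict(self, eta: np.ndarray) -> np.ndarray:
        parts = self._parts(float(eta[0]))
        if parts is None:
            return np.full(self.n_obs, np.nan)
        a, b = parts
        with np.errstate(over="ignore"):
            f_i = self._pop.theta.F * np.exp(float(eta[1]))
        return a + f_i * b

    def nll2(self, eta: np.ndarray) -> float:
        """-2 log p(y | eta) under the combined residual-error model."""
        pop = self._pop
        c = self.predict(eta)
        if not np.all(np.isfinite(c)):
            return np.inf
        v = (pop.sigma_prop * c) ** 2 + pop.sigma_add**2
        v = np.maximum(v, _VAR_FLOOR)
        r = self.y - c
        return float(np.sum(r * r / v + np.log(v)) + self.n_obs * _LOG2PI)

    def active_dims(self, pop: PopulationModel) -> list[int]:
        """Random-effect dimensions that both vary and touch this subject's data."""
        dims = []
        if pop.omega_cl > 0:
            dims.append(0)
        if pop.omega_f > 0 and self.has_po:
            dims.append(1)
        return dims

    def marginal_m2ll(
        self, pop: PopulationModel, eta_warm: np.ndarray | None = None
    ) -> tuple[float, np.ndarray, bool]:
        """Laplace -2 log marginal likelihood and the full EBE vector."""
        if self._pop is not pop:
            self.set_population(pop)
        dims = self.active_dims(pop)
        eta_full = np.zeros(len(ETA_NAMES))

        def nll2_active(eta_a):
            eta_full_local = eta_full.copy()
            eta_full_local[dims] = eta_a
            return self.nll2(eta_full_local)

        w = pop.omega[dims]
        warm = None if eta_warm is None else np.asarray(eta_warm, dtype=float)[dims]
        ofv_i, eta_hat_a, ok = laplace_m2ll(nll2_active, w, eta0=warm)
        eta_hat = np.zeros(len(ETA_NAMES))
        eta_hat[dims] = eta_hat_a
        return ofv_i, eta_hat, ok


def _build_models(data: PKDataset, n_transit: int) -> list[_SubjectModel]:
    models = [_SubjectModel(rec, n_transit) for rec in data.subjects()]
    if not any(m.n_obs > 0 for m in models):
        raise FitError("dataset contains no usable observations (EVID 0, MDV 0)")
    return models


def conditional_objective(
    pop: PopulationModel,
    data: PKDataset,
    *,
    _models: Sequence[_SubjectModel] | None = None,
    _warm: dict | None = None,
) -> float:
    """Objective function value: -2 x approximate marginal log-likelihood.

    Each subject's integrand is expanded about its conditional mode (Laplace);
    parameter regions where predictions blow up return a large finite penalty
    instead of raising.
    """
    models = _models if _models is not None else _build_models(data, pop.theta.n_transit)
    total = 0.0
    for i, m in enumerate(models):
        warm = _warm.get(i) if _warm is not None else None
        ofv_i, eta_hat, ok = m.marginal_m2ll(pop, eta_warm=warm)
        if _warm is not None and ok:
            _warm[i] = eta_hat
        total += ofv_i
    return float(total)


# --------------------------------------------------------------------------
# parameter transforms


def _pack(pop: PopulationModel, free: Sequence[str]) -> np.ndarray:
    x = []
    for name in free:
        if name in THETA_NAMES:
            v = getattr(pop.theta, name)
            if v is None or v <= 0:
                raise FitError(f"free parameter {name} needs a positive initial value")
            x.append(np.log(v))
        elif name.startswith("omega_"):
            v = pop.omega_cl if name == "omega_CL" else pop.omega_f
            if v <= 0:
                raise FitError(f"free parameter {name} needs a positive initial variance")
            x.append(np.log(np.sqrt(v)))  # log-SD
        else:
            v = pop.sigma_prop if name == "sigma_prop" else pop.sigma_add
            if v <= 0:
                raise FitError(f"free parameter {name} needs a positive initial value")
            x.append(np.log(v))
    return np.array(x)


def _unpack(x: np.ndarray, free: Sequence[str], template: PopulationModel) -> PopulationModel:
    theta_kw = {}
    kw = {}
    for val, name in zip(x, free):
        if name in THETA_NAMES:
            theta_kw[name] = float(np.exp(val))
        elif name == "omega_CL":
            kw["omega_cl"] = float(np.exp(2 * val))
        elif name == "omega_F":
            kw["omega_f"] = float(np.exp(2 * val))
        elif name == "sigma_prop":
            kw["sigma_prop"] = float(np.exp(val))
        else:
            kw["sigma_add"] = float(np.exp(val))
    return template.replace(theta_kw=theta_kw, **kw)


# --------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    """Estimation output: final model, objective, EBEs and diagnostics."""

    pop: PopulationModel
    ofv: float
    ofv_init: float
    etas: pd.DataFrame  # columns: ID, eta_CL, eta_F
    eta_shrinkage: dict  # name -> percent (NaN where undefined)
    eps_shrinkage: float
    converged: bool
    n_evals: int
    fixed: frozenset
    message: str = ""
    se: Optional[dict] = None

    def summary(self) -> str:
        pop = self.pop
        lines = [
            "Population PK fit",
            f"  OFV: {self.ofv:.4f}  (initial {self.ofv_init:.4f})",
            f"  converged: {self.converged}  evaluations: {self.n_evals}",
            "  typical values:",
        ]
        for name in THETA_NAMES:
            v = getattr(pop.theta, name)
            tag = " [fixed]" if name in self.fixed else ""
            lines.append(f"    {name:10s} {'tied to ka' if v is None else format(v, '.6g')}{tag}")
        lines.append("  interindividual variability (CV%):")
        lines.append(f"    CL  {iiv_cv_percent(pop.omega_cl):.2f}%"
                     f"  (variance {pop.omega_cl:.6g})"
                     f"  shrinkage {self.eta_shrinkage.get('CL', float('nan')):.1f}%")
        lines.append(f"    F   {iiv_cv_percent(pop.omega_f):.2f}%"
                     f"  (variance {pop.omega_f:.6g})"
                     f"  shrinkage {self.eta_shrinkage.get('F', float('nan')):.1f}%")
        lines.append("  residual error:")
        lines.append(f"    proportional SD {pop.sigma_prop:.4g}, additive SD {pop.sigma_add:.4g} mg/L")
        lines.append(f"    epsilon-shrinkage {self.eps_shrinkage:.1f}%")
        return "\n".join(lines)


def eta_shrinkage(etas: np.ndarray, omega_var: float) -> float:
    """Eta-shrinkage (%) = 100 * (1 - SD(EBE) / omega_SD); NaN if omega is 0."""
    if omega_var < 0:
        raise ParameterError("variance must be non-negative")
    if omega_var == 0:
        warnings.warn("omega is 0: eta-shrinkage undefined", stacklevel=2)
        return float("nan")
    sd = float(np.std(np.asarray(etas, dtype=float), ddof=1))
    return 100.0 * (1.0 - sd / np.sqrt(omega_var))


def ebes(pop: PopulationModel, data: PKDataset) -> pd.DataFrame:
    """Empirical Bayes estimates (conditional modes) for every subject."""
    models = _build_models(data, pop.theta.n_transit)
    rows = []
    for m in models:
        m.set_population(pop)
        _, eta_hat, _ = m.marginal_m2ll(pop)
        rows.append({"ID": m.rec.id, "eta_CL": eta_hat[0], "eta_F": eta_hat[1]})
    return pd.DataFrame(rows)


def _iwres(models: Iterable[_SubjectModel], pop: PopulationModel, etas: pd.DataFrame) -> np.ndarray:
    eta_map = {row["ID"]: np.array([row["eta_CL"], row["eta_F"]]) for _, row in etas.iterrows()}
    out = []
    for m in models:
        m.set_population(pop)
        c = m.predict(eta_map[m.rec.id])
        v = np.maximum((pop.sigma_prop * c) ** 2 + pop.sigma_add**2, _VAR_FLOOR)
        out.append((m.y - c) / np.sqrt(v))
    return np.concatenate(out) if out else np.zeros(0)


def ebe_and_shrinkage(fit: "FitResult", data: PKDataset) -> "FitResult":
    """Recompute EBEs, eta-shrinkage and epsilon-shrinkage for a fitted model."""
    pop = fit.pop
    models = _build_models(data, pop.theta.n_transit)
    etas = ebes(pop, data)
    shr = {}
    for k, name in enumerate(ETA_NAMES):
        om = pop.omega[k]
        if om == 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                shr[name] = float("nan")
        else:
            shr[name] = eta_shrinkage(etas[f"eta_{name}"].to_numpy(), om)
    iw = _iwres(models, pop, etas)
    eps = 100.0 * (1.0 - float(np.std(iw, ddof=1))) if iw.size > 1 else float("nan")
    fit.etas = etas
    fit.eta_shrinkage = shr
    fit.eps_shrinkage = eps
    return fit


# --------------------------------------------------------------------------
# fitting


def fit(
    data: PKDataset,
    init: PopulationModel,
    fixed: Iterable[str] = (),
    *,
    seed: int | None = None,
    n_starts: int = 1,
    maxfev: int | None = None,
    compute_se: bool = False,
) -> FitResult:
    """Maximum (approximate) marginal likelihood estimation.

    ``fixed`` names parameters held at their initial values (from
    ``THETA_NAMES`` + ``VARIANCE_NAMES``, or the string ``"all"``).  The outer
    optimiser is Nelder-Mead on transformed coordinates; inner conditional
    modes are warm-started across evaluations.  ``n_starts > 1`` adds seeded
    perturbed restarts and keeps the best minimum.

    Estimating bioavailability from a dataset without oral doses is not
    identifiable; such requests are downgraded to fixed with a warning.
    """
    if isinstance(fixed, str):
        fixed = set(PARAM_NAMES) if fixed == "all" else {fixed}
    fixed = set(fixed)
    unknown = fixed - set(PARAM_NAMES)
    if unknown:
        raise FitError(f"unknown parameter name(s) in fixed: {sorted(unknown)}")
    if init.theta.ktr is None:
        fixed.add("ktr")  # tied-to-ka configuration has no separate transit rate

    models = _build_models(data, init.theta.n_transit)
    any_po = any(m.has_po for m in models)
    if not any_po:
        for name in ("F", "omega_F", "ka_fed", "ka_fasted", "ktr"):
            if name not in fixed:
                warnings.warn(
                    f"{name} is not identifiable without oral doses; holding it fixed",
                    stacklevel=2,
                )
                fixed.add(name)

    free = [n for n in PARAM_NAMES if n not in fixed]
    warm: dict[int, np.ndarray] = {}

    def objective(x):
        try:
            pop = _unpack(x, free, init)
        except (ParameterError, OverflowError):
            return PENALTY
        try:
            return conditional_objective(pop, data, _models=models, _warm=warm)
        except FloatingPointError:
            return PENALTY

    ofv_init = conditional_objective(init, data, _models=models, _warm=warm)
    if not free:
        result = FitResult(
            pop=init, ofv=ofv_init, ofv_init=ofv_init,
            etas=pd.DataFrame(), eta_shrinkage={}, eps_shrinkage=float("nan"),
            converged=True, n_evals=1, fixed=frozenset(fixed),
            message="all parameters fixed; objective evaluated at the initial model",
        )
        return ebe_and_shrinkage(result, data)

    x0 = _pack(init, free)
    maxfev = maxfev or 400 * len(free)
    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.normal(0, 0.15, size=x0.size) for _ in range(n_starts - 1)]
    best = None
    n_evals = 0
    for s in starts:
        res = minimize(
            objective, s, method="Nelder-Mead",
            options={"fatol": 0.05, "xatol": 1e-3, "maxfev": maxfev, "adaptive": True},
        )
        n_evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res

    pop_hat = _unpack(best.x, free, init)
    ofv_hat = conditional_objective(pop_hat, data, _models=models, _warm=warm)
    if ofv_hat > ofv_init:  # optimiser never beats the start only if it stalled at it
        pop_hat, ofv_hat = init, ofv_init
    result = FitResult(
        pop=pop_hat, ofv=float(ofv_hat), ofv_init=float(ofv_init),
        etas=pd.DataFrame(), eta_shrinkage={}, eps_shrinkage=float("nan"),
        converged=bool(best.success), n_evals=n_evals, fixed=frozenset(fixed),
        message=str(best.message),
    )
    if compute_se:
        result.se = _standard_errors(objective, best.x, free)
    return ebe_and_shrinkage(result, data)


def _standard_errors(objective, x_hat: np.ndarray, free: Sequence[str]) -> dict:
    """Asymptotic SEs from a finite-difference Hessian of the objective.

    The covariance of the transformed estimates is ``2 * H^-1`` (the objective
    is -2 log L); the delta method maps SDs back to the natural scale.
    Failure (non-PD Hessian) is reported as NaNs rather than an error.
    """
    d = x_hat.size
    step = 1e-3
    H = np.zeros((d, d))
    f0 = objective(x_hat)
    fp = np.array([objective(x_hat + step * np.eye(d)[k]) for k in range(d)])
    fm = np.array([objective(x_hat - step * np.eye(d)[k]) for k in range(d)])
    for k in range(d):
        H[k, k] = (fp[k] - 2 * f0 + fm[k]) / step**2
    for j in range(d):
        for k in range(j + 1, d):
            fpp = objective(x_hat + step * (np.eye(d)[j] + np.eye(d)[k]))
            fmm = objective(x_hat - step * (np.eye(d)[j] + np.eye(d)[k]))
            H[j, k] = H[k, j] = (fpp - fp[j] - fp[k] - fm[j] - fm[k] + fmm + 2 * f0) / (2 * step**2)
    out = {}
    try:
        cov = 2.0 * np.linalg.inv(H)
        sd_x = np.sqrt(np.maximum(np.diag(cov), 0))
    except np.linalg.LinAlgError:
        sd_x = np.full(d, np.nan)
    for k, name in enumerate(free):
        # natural value = exp(x) (or exp(2x) for variances): |d nat/dx| = nat (or 2*nat)
        nat = np.exp(x_hat[k])
        if name.startswith("omega_"):
            out[name] = float(2 * np.exp(2 * x_hat[k]) * sd_x[k])
        else:
            out[name] = float(nat * sd_x[k])
    return out
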