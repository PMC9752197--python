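"""Synthetic clinical-program generator.

Emulates a pooled oral/IV development program: Phase 1 studies in healthy
volunteers with rich sampling (single and multiple dose, IV and PO, a
fed/fasted crossover) and Phase 2 studies in MAC lung disease patients with
lower body weight and sparse sampling.  The shipped default program is an
explicit reconstruction constrained to pooled totals of 138 subjects and 2637
PK samples; the per-study split, schedules and weight distributions are
package choices (no study-level design tables are public), documented in the
methods note.

Randomness is fully seeded: each subject draws from an independent stream
keyed by (seed, study index, subject index), so edits to one study never
perturb another study's subjects.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .dataio import CMT_CENTRAL, CMT_DEPOT, PKDataset, from_rows
from .errors import InputError
from .params import IV, PO, DoseEvent
from .population import PopulationModel, Subject, individual_params, residual_observe
from .structural import ProfileEvaluator, steady_state_metrics

__all__ = [
    "StudyDesign",
    "ProgramRoster",
    "default_program",
    "recovery_program",
    "generate",
    "simulate_regimen_exposures",
    "load_roster",
    "save_roster",
]


@dataclass(frozen=True)
class StudyDesign:
    """One study arm: a fixed dosing schedule and sampling times for every subject.

    ``doses`` carry absolute times (h from each subject's first dose);
    ``sample_times`` likewise.  Body weight is log-normal with the given
    median (kg) and CV (fraction).
    """

    study_id: str
    phase: int
    n_subjects: int
    doses: tuple[DoseEvent, ...]
    sample_times: tuple[float, ...]
    wt_median: float = 75.0
    wt_cv: float = 0.15
    population: str = "healthy"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InputError("n_subjects must be >= 1")
        if any(t < 0 for t in self.sample_times):
            raise InputError("sampling times must be non-negative")
        if any(d.amount <= 0 for d in self.doses):
            raise InputError("dose amounts must be positive")
        if not (self.wt_median > 0 and self.wt_cv >= 0):
            raise InputError("weight distribution parameters invalid")

    @property
    def route(self) -> str:
        routes = {d.route for d in self.doses}
        return routes.pop() if len(routes) == 1 else "MIXED"


@dataclass(frozen=True)
class ProgramRoster:
    studies: tuple[StudyDesign, ...]

    def __post_init__(self) -> None:
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise InputError("study ids must be unique")

    @property
    def n_subjects(self) -> int:
        return sum(s.n_subjects for s in self.studies)

    @property
    def n_samples(self) -> int:
        return sum(s.n_subjects * len(s.sample_times) for s in self.studies)


def _iv_q24h(n_days: int, amount: float = 500.0, duration: float = 1.0) -> tuple[DoseEvent, ...]:
    return tuple(DoseEvent(24.0 * d, amount, IV, duration) for d in range(n_days))


def _po_q24h(n_days: int, amount: float = 500.0, fed: bool = True) -> tuple[DoseEvent, ...]:
    return tuple(DoseEvent(24.0 * d, amount, PO, 0.0, fed) for d in range(n_days))


def default_program() -> ProgramRoster:
    """The pooled seven-study program: 3 Phase-1 IV, 2 Phase-1 PO, 2 Phase-2 IV.

    Totals are exactly 138 subjects and 2637 PK samples.  Phase 1 uses rich
    serial sampling in healthy volunteers (median weight 75 kg); Phase 2 uses
    at most 4 samples per patient (median weight 55 kg, reflecting the lower
    body weight of the patient population).
    """
    day = 24.0
    p1_iv_sad = StudyDesign(
        "P1-IV-SAD", 1, 15,
        doses=(DoseEvent(0.0, 500.0, IV, 1.0),),
        sample_times=(0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0,
                      8.0, 12.0, 16.0, 24.0, 36.0, 48.0),
    )
    mad_days = 7
    p1_iv_mad = StudyDesign(
        "P1-IV-MAD", 1, 16,
        doses=_iv_q24h(mad_days),
        sample_times=tuple(
            [0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0]          # day 1
            + [day * d for d in range(1, 7)]                         # pre-dose troughs
            + [144.0 + t for t in (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0,
                                   8.0, 10.0, 12.0, 16.0, 20.0, 24.0, 36.0, 48.0)]  # day 7
        ),
    )
    p1_iv_inf = StudyDesign(
        "P1-IV-INF", 1, 12,
        doses=(DoseEvent(0.0, 750.0, IV, 3.0),),
        sample_times=(0.5, 1.0, 2.0, 3.0, 3.25, 3.5, 4.0, 5.0, 6.0, 8.0, 12.0,
                      16.0, 24.0, 36.0, 48.0),
    )
    per_period = (0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0,
                  24.0, 36.0, 48.0)
    p1_po_food = StudyDesign(
        "P1-PO-FOOD", 1, 25,
        doses=(DoseEvent(0.0, 500.0, PO, 0.0, fed=False),
               DoseEvent(168.0, 500.0, PO, 0.0, fed=True)),
        sample_times=per_period + tuple(168.0 + t for t in per_period),
    )
    po_days = 14
    p1_po_mad = StudyDesign(
        "P1-PO-MAD", 1, 20,
        doses=_po_q24h(po_days, fed=True),
        sample_times=tuple(
            [0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0]     # day 1
            + [day * d for d in range(1, 13)]                         # troughs
            + [312.0 + t for t in (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0,
                                   12.0, 16.0, 20.0, 24.0, 36.0, 48.0, 72.0)]  # day 14
        ),
    )
    p2_a = StudyDesign(
        "P2-IV-A", 2, 30,
        doses=_iv_q24h(14),
        sample_times=(1.5, 24.0, 74.0, 313.5),
        wt_median=55.0, population="patient",
    )
    p2_b = StudyDesign(
        "P2-IV-B", 2, 20,
        doses=_iv_q24h(14),
        sample_times=(2.0, 48.0, 170.0, 312.0),
        wt_median=55.0, population="patient",
    )
    return ProgramRoster((p1_iv_sad, p1_iv_mad, p1_iv_inf, p1_po_food, p1_po_mad, p2_a, p2_b))


def recovery_program(
    n_iv: int = 40, n_po_fed: int = 30, n_po_fasted: int = 30, dose: float = 500.0
) -> ProgramRoster:
    """Rich single-dose design for simulate-then-refit parameter recovery.

    Every subject contributes 12 serial samples over 36 h; the mixed IV /
    PO-fed / PO-fasted arms make clearance, bioavailability and both
    absorption rates identifiable in one pooled fit.
    """
    times = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0, 36.0)
    studies = []
    if n_iv:
        studies.append(StudyDesign(
            "REC-IV", 1, n_iv, doses=(DoseEvent(0.0, dose, IV, 1.0),), sample_times=times))
    if n_po_fed:
        studies.append(StudyDesign(
            "REC-PO-FED", 1, n_po_fed,
            doses=(DoseEvent(0.0, dose, PO, 0.0, fed=True),), sample_times=times))
    if n_po_fasted:
        studies.append(StudyDesign(
            "REC-PO-FAST", 1, n_po_fasted,
            doses=(DoseEvent(0.0, dose, PO, 0.0, fed=False),), sample_times=times))
    return ProgramRoster(tuple(studies))


def generate(roster: ProgramRoster, truth: PopulationModel, seed: int) -> PKDataset:
    """Simulate the full program under the truth model into a NONMEM-style dataset.

    Deterministic given the seed; observation rows (EVID 0, MDV 0) count
    exactly ``roster.n_samples`` and subject ids count ``roster.n_subjects``.
    """
    rows: list[dict] = []
    for s_idx, study in enumerate(roster.studies):
        evaluator = ProfileEvaluator(
            study.doses, np.asarray(study.sample_times, dtype=float),
            n_transit=truth.theta.n_transit,
        )
        sigma_wt = np.sqrt(np.log1p(study.wt_cv**2))
        for j in range(study.n_subjects):
            rng = np.random.default_rng(np.random.SeedSequence([seed, s_idx, j]))
            sid = 100 * (s_idx + 1) + (j + 1)
            wt = float(study.wt_median * np.exp(sigma_wt * rng.standard_normal()))
            eta = rng.standard_normal(2) * np.sqrt(truth.omega)
            p_i = individual_params(truth, Subject(sid, wt, study.population), eta)
            a, b = evaluator.conc_parts(p_i)
            conc = a + p_i.F * b
            eps = rng.standard_normal((conc.size, 2))
            dv = residual_observe(conc, eps, truth)
            sub_rows = []
            for d in study.doses:
                sub_rows.append({
                    "ID": sid, "TIME": d.time, "AMT": d.amount,
                    "RATE": d.amount / d.duration if d.duration > 0 else 0.0,
                    "EVID": 1, "CMT": CMT_DEPOT if d.route == PO else CMT_CENTRAL,
                    "DV": np.nan, "MDV": 1, "WT": wt,
                    "FED": int(d.fed) if d.route == PO else 0,
                    "ROUTE": d.route, "STUDY": study.study_id,
                })
            for t, y in zip(study.sample_times, dv):
                sub_rows.append({
                    "ID": sid, "TIME": float(t), "AMT": np.nan, "RATE": 0.0,
                    "EVID": 0, "CMT": CMT_CENTRAL, "DV": float(y), "MDV": 0,
                    "WT": wt, "FED": 0, "ROUTE": np.nan, "STUDY": study.study_id,
                })
            sub_rows.sort(key=lambda r: (r["TIME"], r["EVID"]))
            rows.extend(sub_rows)
    if not rows:
        return PKDataset(pd.DataFrame(columns=pd.Index(
            ["ID", "TIME", "AMT", "RATE", "EVID", "CMT", "DV", "MDV",
             "WT", "FED", "ROUTE", "STUDY"])))
    return from_rows(rows)


def simulate_regimen_exposures(
    truth: PopulationModel,
    dose: DoseEvent,
    n_subjects: int,
    seed: int,
    interval: float = 24.0,
    wt_median: Optional[float] = None,
    wt_cv: float = 0.0,
) -> pd.DataFrame:
    """Steady-state exposure distribution under a periodic regimen.

    Draws ``n_subjects`` individuals (weight fixed at the reference unless a
    distribution is given), applies interindividual variability, and returns
    per-subject ``AUC_tau`` (mg*h/L), ``Cmax``, ``Cmin`` and ``Ctrough``
    (mg/L) at steady state.
    """
    if n_subjects < 1:
        raise InputError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    sigma_wt = np.sqrt(np.log1p(wt_cv**2)) if wt_cv > 0 else 0.0
    records = []
    for i in range(n_subjects):
        if wt_median is None:
            wt = truth.ref_wt
        else:
            wt = float(wt_median * np.exp(sigma_wt * rng.standard_normal()))
        eta = rng.standard_normal(2) * np.sqrt(truth.omega)
        p_i = individual_params(truth, Subject(i + 1, wt), eta)
        metrics = steady_state_metrics(p_i, dose, interval)
        records.append({"ID": i + 1, "WT": wt, **metrics})
    return pd.DataFrame(records)


def exposure_summary(exposures: pd.DataFrame, pcts: Sequence[float] = (5, 25, 50, 75, 95)) -> pd.DataFrame:
    """Percentile summary of the exposure metrics."""
    cols = ["AUC_tau", "Cmax", "Cmin", "Ctrough"]
    return pd.DataFrame(
        {c: np.percentile(exposures[c], pcts) for c in cols},
        index=[f"p{int(p)}" for p in pcts],
    )


# --------------------------------------------------------------------------
# roster configuration files


def _dose_to_dict(d: DoseEvent) -> dict:
    out = {"time": d.time, "amount": d.amount, "route": d.route, "duration": d.duration}
    if d.route == PO:
        out["fed"] = bool(d.fed)
    return out


def save_roster(roster: ProgramRoster, path) -> None:
    data = {"studies": [
        {
            "study_id": s.study_id, "phase": s.phase, "n_subjects": s.n_subjects,
            "doses": [_dose_to_dict(d) for d in s.doses],
            "sample_times": list(s.sample_times),
            "wt_median": s.wt_median, "wt_cv": s.wt_cv, "population": s.population,
        }
        for s in roster.studies
    ]}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_roster(path) -> ProgramRoster:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    studies = []
    for s in data["studies"]:
        doses = tuple(
            DoseEvent(float(d["time"]), float(d["amount"]), d["route"],
                      float(d.get("duration", 0.0)),
                      bool(d["fed"]) if d["route"] == PO else None)
            for d in s["doses"]
        )
        studies.append(StudyDesign(
            study_id=str(s["study_id"]), phase=int(s["phase"]),
            n_subjects=int(s["n_subjects"]), doses=doses,
            sample_times=tuple(float(t) for t in s["sample_times"]),
            wt_median=float(s.get("wt_median", 75.0)),
            wt_cv=float(s.get("wt_cv", 0.15)),
            population=str(s.get("population", "healthy")),
        ))
    return ProgramRoster(tuple(studies))
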