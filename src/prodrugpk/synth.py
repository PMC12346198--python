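"""Synthetic study-data generation.

Emulates the data-generating process of small serial-sampling mouse PK
studies (n = 3 animals of ~30 g per dose group, single IV bolus or oral
dose, fixed sampling schedules out to 12–24 h), triplicate semi-log
dose-response plates, and plasma-stability timecourses.

The PK generator layers, in order: log-normal inter-individual variability
(IIV) on selected disposition parameters, the structural compartment model,
multiplicative proportional residual error, and censoring of values below
the lower limit of quantification (BLQ).  All randomness flows from a
single seeded generator per dataset, recorded in the output metadata.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .compounds import ROUTE_IV, ROUTE_PO, Compound, DoseEvent, dose_umol
from .dataset import PKDataset
from .model import (
    CombinedModelParams,
    DispositionParams,
    simulate_combined,
    simulate_single,
)
from .stability import STABILITY_TIMES_MIN, StabilityTimecourse

# Serial-sampling schedules (h after dose).
IV_SCHEDULE = (0.083, 0.25, 0.5, 1.0, 2.0, 6.0, 12.0)
PO_SCHEDULE = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0)
# Variants used for one compound pair: the 1 h (IV) or 4 h (PO) draw is
# omitted and a 24 h draw added.
IV_SCHEDULE_LATE = (0.083, 0.25, 0.5, 2.0, 6.0, 12.0, 24.0)
PO_SCHEDULE_LATE = (0.25, 0.5, 1.0, 2.0, 8.0, 12.0, 24.0)

DEFAULT_LLOQ = 0.01  # µmol/L


@dataclass(frozen=True)
class ErrorModel:
    """Residual and between-animal variability.

    ``proportional_sd`` is the residual CV (fraction); ``iiv_sd`` maps
    disposition parameter names (e.g. ``"CL"``, ``"Vc"``) to log-scale SDs
    of the between-animal distribution.
    """

    proportional_sd: float = 0.15
    iiv_sd: Mapping[str, float] = field(default_factory=lambda: {"CL": 0.2, "Vc": 0.2})

    def __post_init__(self) -> None:
        if not self.proportional_sd >= 0:
            raise ValueError("proportional_sd must be >= 0")
        if any(v < 0 for v in self.iiv_sd.values()):
            raise ValueError("iiv_sd entries must be >= 0")


NOISELESS = ErrorModel(proportional_sd=0.0, iiv_sd={})


@dataclass(frozen=True)
class StudyDesign:
    """One dose group of a serial-sampling study."""

    route: str
    dose_mg_per_kg: float
    schedule: tuple[float, ...]
    n_per_group: int = 3
    body_weight: float = 0.030
    lloq: float = DEFAULT_LLOQ

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        sched = np.asarray(self.schedule, float)
        if sched.size == 0 or np.any(sched <= 0) or np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must be strictly increasing and positive")
        if self.route not in (ROUTE_IV, ROUTE_PO):
            raise ValueError(f"unknown route {self.route!r}")


def default_schedule(route: str, late: bool = False) -> tuple[float, ...]:
    if route == ROUTE_IV:
        return IV_SCHEDULE_LATE if late else IV_SCHEDULE
    return PO_SCHEDULE_LATE if late else PO_SCHEDULE


def _perturb(params: DispositionParams, iiv_sd: Mapping[str, float], rng: np.random.Generator) -> DispositionParams:
    updates = {}
    for name, sd in iiv_sd.items():
        if sd == 0 or not hasattr(params, name):
            continue
        value = getattr(params, name)
        if value is None:
            continue
        updates[name] = value * math.exp(rng.normal(0.0, sd))
    return dataclasses.replace(params, **updates) if updates else params


def generate_pk_cohort(
    design: StudyDesign,
    params: DispositionParams | CombinedModelParams,
    error: ErrorModel,
    compound: Compound,
    seed: int | np.random.Generator,
    subject_prefix: str = "S",
) -> PKDataset:
    """Simulate one dose group and return it as a :class:`PKDataset`.

    With :class:`CombinedModelParams` and a pro-drug compound both analytes
    are observed on the same schedule; otherwise a single analyte.  IIV is
    drawn per animal and per disposition block, residual noise is
    multiplicative ``conc × (1 + ε)`` with ``ε ~ N(0, proportional_sd)``,
    and any value below ``design.lloq`` becomes a BLQ record.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.asarray(design.schedule, float)
    dose_rows, obs_rows = [], []
    for i in range(design.n_per_group):
        sid = f"{subject_prefix}{i + 1}"
        dose = DoseEvent(
            subject_id=sid,
            time=0.0,
            route=design.route,
            dose_mg_per_kg=design.dose_mg_per_kg,
            compound=compound,
            body_weight=design.body_weight,
        )
        if isinstance(params, CombinedModelParams):
            subject_params = CombinedModelParams(
                prodrug=_perturb(params.prodrug, error.iiv_sd, rng),
                parent=_perturb(params.parent, error.iiv_sd, rng),
                Fm=params.Fm,
            )
            profiles = simulate_combined(subject_params, dose, times)
            if compound.role == "parent":
                profiles = (profiles[1],)  # no pro-drug analyte in a parent-only arm
        else:
            subject_params = _perturb(params, error.iiv_sd, rng)
            profiles = (simulate_single(subject_params, dose, times),)
        dose_rows.append(
            {
                "subject_id": sid,
                "time_h": 0.0,
                "amt_umol": dose_umol(dose),
                "route": design.route,
                "compound": compound.name,
            }
        )
        for profile in profiles:
            conc = profile.conc.copy()
            if error.proportional_sd > 0:
                conc = conc * (1.0 + rng.normal(0.0, error.proportional_sd, size=conc.shape))
            conc = np.maximum(conc, 0.0)
            blq = conc < design.lloq
            for t, c, b in zip(times, conc, blq):
                obs_rows.append(
                    {
                        "subject_id": sid,
                        "analyte": profile.analyte,
                        "time_h": float(t),
                        "conc_umol_per_L": math.nan if b else float(c),
                        "blq": bool(b),
                    }
                )
    return PKDataset(
        doses=pd.DataFrame(dose_rows),
        observations=pd.DataFrame(obs_rows),
        lloq=design.lloq,
        meta={
            f"{subject_prefix}_design": dataclasses.asdict(design),
            f"{subject_prefix}_compound": compound.name,
        },
    )


def generate_dose_response(
    ic50: float,
    top: float,
    bottom: float,
    conc_grid: np.ndarray,
    cv: float,
    seed: int | np.random.Generator,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Triplicate plate responses from a unit-slope three-parameter curve.

    Responses are ``bottom + (top − bottom)/(1 + X/IC50)`` with
    multiplicative proportional noise of coefficient of variation ``cv``.
    Returns columns ``concentration_uM, replicate, response``.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    conc = np.asarray(conc_grid, float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        mean = bottom + (top - bottom) / (1.0 + conc / ic50)
        resp = mean * (1.0 + rng.normal(0.0, cv, size=conc.shape)) if cv > 0 else mean
        for x, y in zip(conc, resp):
            rows.append({"concentration_uM": float(x), "replicate": rep, "response": float(y)})
    return pd.DataFrame(rows)


def semilog_grid(low: float = 0.01, high: float = 30.0) -> np.ndarray:
    """Semi-log (half-decade) concentration series from ``low`` to ``high`` µM."""
    n = int(round(2 * (math.log10(high) - math.log10(low)))) + 1
    grid = 10 ** (math.log10(low) + 0.5 * np.arange(n))
    return np.minimum(grid, high)


def generate_stability(
    k_prodrug: float,
    conversion_yield: float,
    seed: int | np.random.Generator,
    matrix: str = "human_plasma",
    baseline: float = 100.0,
    noise_cv: float = 0.0,
) -> StabilityTimecourse:
    """Plasma-stability timecourse with first-order pro-drug disappearance.

    The pro-drug signal decays as ``baseline × exp(−k t)``; the parent
    signal accumulates as ``conversion_yield × (baseline − prodrug(t))``,
    i.e. a molar fraction of the consumed pro-drug appears as parent.
    """
    if k_prodrug < 0:
        raise ValueError("k_prodrug must be >= 0")
    if not 0.0 <= conversion_yield <= 1.0:
        raise ValueError("conversion_yield must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.asarray(STABILITY_TIMES_MIN, float)
    prodrug = baseline * np.exp(-k_prodrug * t)
    parent = conversion_yield * (baseline - prodrug)
    if noise_cv > 0:
        prodrug = prodrug * (1.0 + rng.normal(0.0, noise_cv, size=t.shape))
        parent = parent * (1.0 + rng.normal(0.0, noise_cv, size=t.shape))
        prodrug = np.maximum(prodrug, 0.0)
        parent = np.maximum(parent, 0.0)
        prodrug[0] = max(prodrug[0], 1e-9)
    return StabilityTimecourse(times_min=t, prodrug_signal=prodrug, parent_signal=parent, matrix=matrix)
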