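"""Linear compartment models for a pro-drug and its parent drug.

Two structural models are provided:

* a single-analyte, two-compartment disposition model with first-order
  elimination from the central compartment and, for oral dosing, a
  first-order absorption depot;
* a combined pro-drug → parent model in which a fraction ``Fm`` of the
  pro-drug's systemic clearance forms the parent drug in the parent's
  central compartment, the remaining ``1 − Fm`` being eliminated
  irreversibly; the parent has its own two-compartment disposition.

Both are linear, constant-coefficient ODE systems in compartment *amounts*
(µmol), so they are solved in closed form by eigendecomposition of the rate
matrix (with a matrix-exponential fallback near eigenvalue degeneracy).
Concentrations are central amounts divided by the central volume.

Units: amounts µmol, volumes L, clearances L/h, rate constants 1/h,
concentrations µmol/L, time h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .compounds import ROUTE_IV, ROUTE_PO, DoseEvent, dose_umol

ANALYTE_PRODRUG = "prodrug"
ANALYTE_PARENT = "parent"


@dataclass(frozen=True)
class DispositionParams:
    """Two-compartment disposition parameters for one analyte.

    ``CL`` systemic clearance (L/h), ``Vc`` central volume (L), ``Q``
    intercompartmental clearance (L/h, 0 collapses to one compartment),
    ``Vp`` peripheral volume (L), ``Ka`` first-order absorption rate (1/h,
    oral dosing only) and ``F`` oral bioavailability (fraction).
    """

    CL: float
    Vc: float
    Q: float
    Vp: float
    Ka: float | None = None
    F: float = 1.0

    def __post_init__(self) -> None:
        for name in ("CL", "Vc", "Vp"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{name} must be finite and > 0, got {value}")
        if not (self.Q >= 0 and math.isfinite(self.Q)):
            raise ValueError(f"Q must be finite and >= 0, got {self.Q}")
        if self.Ka is not None and not (self.Ka > 0 and math.isfinite(self.Ka)):
            raise ValueError(f"Ka must be finite and > 0, got {self.Ka}")
        if not (0.0 <= self.F <= 1.0):
            raise ValueError(f"F must lie in [0, 1], got {self.F}")

    @property
    def kel(self) -> float:
        """First-order elimination rate constant CL/Vc (1/h)."""
        return self.CL / self.Vc


@dataclass(frozen=True)
class CombinedModelParams:
    """Joint pro-drug → parent model parameters.

    ``prodrug`` and ``parent`` each carry their own two-compartment
    disposition (the parent's ``CL`` is the parent clearance CLp).  ``Fm``
    is the fraction of the pro-drug's systemic elimination that forms
    parent drug.
    """

    prodrug: DispositionParams
    parent: DispositionParams
    Fm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.Fm <= 1.0):
            raise ValueError(f"Fm must lie in [0, 1], got {self.Fm}")


@dataclass(frozen=True)
class SimulatedProfile:
    """A concentration–time profile for one analyte."""

    times: np.ndarray
    conc: np.ndarray
    analyte: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "conc", np.asarray(self.conc, dtype=float))
        if self.times.shape != self.conc.shape:
            raise ValueError("times and conc must have equal length")


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D vector")
    if np.any(times < 0) or not np.all(np.isfinite(times)):
        raise ValueError("times must be finite and >= 0")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    return times


def solve_linear_amounts(A: np.ndarray, x0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Amounts ``x(t) = exp(A t) x0`` at each time; shape (n_times, n_states).

    Uses the eigendecomposition of ``A`` when its eigenvector matrix is
    well conditioned (exact for distinct eigenvalues), otherwise falls back
    to a matrix exponential per time point (handles e.g. Ka equal to a
    disposition eigenvalue).  Tiny negative values from round-off are
    clipped to zero.
    """
    times = np.asarray(times, dtype=float)
    lam, V = np.linalg.eig(A)
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        use_eig = np.linalg.cond(V) < 1e8
        if use_eig:
            w = np.linalg.solve(V, x0.astype(complex))
            out = np.real(np.exp(np.outer(times, lam)) * w @ V.T)
        else:
            out = np.empty((times.size, x0.size))
            for i, t in enumerate(times):
                out[i] = expm(A * t) @ x0
    # extreme trial parameter sets during optimisation can overflow; keep
    # the output finite so the optimiser sees a large-but-usable residual
    out = np.nan_to_num(out, nan=1e12, posinf=1e12, neginf=-1e12)
    return np.where(out > 0, out, np.where(out > -1e-9 * max(1.0, np.abs(x0).max()), 0.0, out))


def single_analyte_matrix(params: DispositionParams, oral: bool) -> np.ndarray:
    """Rate matrix over states (depot, central, peripheral) or (central, peripheral)."""
    k10 = params.CL / params.Vc
    k12 = params.Q / params.Vc
    k21 = params.Q / params.Vp
    disp = np.array([[-(k10 + k12), k21], [k12, -k21]])
    if not oral:
        return disp
    if params.Ka is None:
        raise ValueError("oral simulation requires Ka")
    A = np.zeros((3, 3))
    A[0, 0] = -params.Ka
    A[1, 0] = params.Ka
    A[1:, 1:] = disp
    return A


def combined_matrix(params: CombinedModelParams, oral: bool) -> np.ndarray:
    """Rate matrix over ([depot,] prodrug central, prodrug peripheral, parent central, parent peripheral).

    The formation flux Fm·(CL/Vc)·A_central(prodrug) enters the parent
    central compartment; the (1 − Fm) remainder leaves the system.
    """
    pd, pa = params.prodrug, params.parent
    Apd = single_analyte_matrix(pd, oral)
    Apa = single_analyte_matrix(pa, oral=False)
    n = Apd.shape[0]
    A = np.zeros((n + 2, n + 2))
    A[:n, :n] = Apd
    A[n:, n:] = Apa
    central = n - 2  # index of prodrug central compartment
    A[n, central] = params.Fm * pd.CL / pd.Vc
    return A


def _initial_state(n_states: int, depot_index: int | None, central_index: int, dose: DoseEvent, F: float) -> np.ndarray:
    amount = dose_umol(dose)
    x0 = np.zeros(n_states)
    if dose.route == ROUTE_IV:
        x0[central_index] = amount
    else:
        if depot_index is None:
            raise ValueError("PO dose requires a depot state")
        x0[depot_index] = F * amount
    return x0


def simulate_single(params: DispositionParams, dose: DoseEvent, times: np.ndarray) -> SimulatedProfile:
    """Simulate the single-analyte model; returns concentration in µmol/L.

    IV doses are boluses into the central compartment at the dose time;
    oral doses place ``F × dose`` into the absorption depot.  Times before
    the dose time yield zero concentration.
    """
    times = _check_times(times)
    amounts = compartment_amounts_single(params, dose, times)
    central = 1 if dose.route == ROUTE_PO else 0
    analyte = ANALYTE_PRODRUG if dose.compound.role == "prodrug" else ANALYTE_PARENT
    return SimulatedProfile(times=times, conc=amounts[:, central] / params.Vc, analyte=analyte)


def compartment_amounts_single(params: DispositionParams, dose: DoseEvent, times: np.ndarray) -> np.ndarray:
    """Compartment amounts (µmol) for the single-analyte model; zero before dosing."""
    times = _check_times(times)
    oral = dose.route == ROUTE_PO
    A = single_analyte_matrix(params, oral)
    x0 = _initial_state(A.shape[0], 0 if oral else None, 1 if oral else 0, dose, params.F)
    rel = times - dose.time
    out = np.zeros((times.size, A.shape[0]))
    post = rel >= 0
    if np.any(post):
        out[post] = solve_linear_amounts(A, x0, rel[post])
    return out


def simulate_combined(
    params: CombinedModelParams, dose: DoseEvent, times: np.ndarray
) -> tuple[SimulatedProfile, SimulatedProfile]:
    """Simulate pro-drug and parent profiles after a single dose.

    A pro-drug dose feeds both analytes through the conversion flux.  A
    parent-compound dose (the parent-only cohort) involves no pro-drug:
    its profile is the single-analyte parent simulation and the pro-drug
    concentration is identically zero.
    """
    times = _check_times(times)
    if dose.compound.role == "parent":
        parent = simulate_single(params.parent, dose, times)
        zero = SimulatedProfile(times=times, conc=np.zeros_like(times), analyte=ANALYTE_PRODRUG)
        return zero, SimulatedProfile(times=times, conc=parent.conc, analyte=ANALYTE_PARENT)
    amounts = compartment_amounts_combined(params, dose, times)
    oral = dose.route == ROUTE_PO
    c_pd = amounts[:, 1 if oral else 0] / params.prodrug.Vc
    c_pa = amounts[:, 3 if oral else 2] / params.parent.Vc
    return (
        SimulatedProfile(times=times, conc=c_pd, analyte=ANALYTE_PRODRUG),
        SimulatedProfile(times=times, conc=c_pa, analyte=ANALYTE_PARENT),
    )


def predict_single_conc(params: DispositionParams, route: str, amt_umol: float, times: np.ndarray) -> np.ndarray:
    """Concentration (µmol/L) for a dose at t = 0 given directly in µmol.

    The amount-level entry point used by the estimators, where doses are
    already molar and no compound metadata is involved.
    """
    oral = route == ROUTE_PO
    A = single_analyte_matrix(params, oral)
    x0 = np.zeros(A.shape[0])
    central = 1 if oral else 0
    if oral:
        x0[0] = params.F * amt_umol
    else:
        x0[0] = amt_umol
    amounts = solve_linear_amounts(A, x0, np.asarray(times, dtype=float))
    return amounts[:, central] / params.Vc


def predict_combined_conc(
    params: CombinedModelParams, route: str, amt_umol: float, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(pro-drug, parent) concentrations for a pro-drug dose given in µmol."""
    oral = route == ROUTE_PO
    A = combined_matrix(params, oral)
    x0 = np.zeros(A.shape[0])
    central = 1 if oral else 0
    if oral:
        x0[0] = params.prodrug.F * amt_umol
    else:
        x0[0] = amt_umol
    amounts = solve_linear_amounts(A, x0, np.asarray(times, dtype=float))
    n = 3 if oral else 2
    return amounts[:, central] / params.prodrug.Vc, amounts[:, n] / params.parent.Vc


def compartment_amounts_combined(params: CombinedModelParams, dose: DoseEvent, times: np.ndarray) -> np.ndarray:
    """Compartment amounts (µmol) for the combined model after a pro-drug dose."""
    times = _check_times(times)
    if dose.compound.role != "prodrug":
        raise ValueError("combined amounts are defined for a pro-drug dose")
    oral = dose.route == ROUTE_PO
    A = combined_matrix(params, oral)
    central = 1 if oral else 0
    x0 = _initial_state(A.shape[0], 0 if oral else None, central, dose, params.prodrug.F)
    rel = times - dose.time
    out = np.zeros((times.size, A.shape[0]))
    post = rel >= 0
    if np.any(post):
        out[post] = solve_linear_amounts(A, x0, rel[post])
    return out
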