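"""Non-compartmental exposure analysis (NCA).

Model-free summaries of a concentration–time profile: Cmax/Tmax, linear
trapezoidal AUC to the last observation (AUC_all), extrapolation to
infinity via the terminal slope λz, clearance for IV dosing
(CL = dose/AUC_inf) and oral bioavailability as a dose-normalized AUC
ratio.  λz is estimated by log-linear regression on a terminal window of
at least three points chosen by best adjusted R², excluding Tmax —
the common NCA convention.

AUC uses the linear trapezoid throughout (not linear-up/log-down); the
choice is deliberate and documented, see docs/methods.md.  When a dose
event is supplied, the gap between dose time and first sample is closed
the standard way: a log-linearly back-extrapolated C0 for an IV bolus,
C(0) = 0 for extravascular dosing.

Below-quantification (BLQ) policy: leading BLQ observations are set to 0,
trailing BLQ observations are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .compounds import ROUTE_IV, DoseEvent, dose_umol
from .model import SimulatedProfile


@dataclass
class NCAResult:
    """Per-profile NCA parameters; non-estimable quantities are ``None``."""

    cmax: float
    tmax: float
    auc_all: float
    auc_inf: float | None = None
    lambda_z: float | None = None
    cl: float | None = None
    f: float | None = None
    n_lambda_points: int = 0
    flags: list[str] = field(default_factory=list)


def auc_trapezoid(times: np.ndarray, conc: np.ndarray) -> float:
    """Linear trapezoidal area from the first to the last observation."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if times.size < 2:
        raise ValueError("AUC requires at least 2 observations")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    return float(np.trapezoid(conc, times))


def apply_blq_policy(times, conc, blq) -> tuple[np.ndarray, np.ndarray]:
    """Leading BLQ observations become 0; trailing BLQ observations are dropped."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    blq = np.asarray(blq, dtype=bool)
    keep = np.ones(times.size, dtype=bool)
    quantified = np.flatnonzero(~blq)
    if quantified.size == 0:
        raise ValueError("all observations are below the quantification limit")
    first, last = quantified[0], quantified[-1]
    conc = conc.copy()
    conc[:first] = 0.0
    blq_lead = np.arange(times.size) < first
    keep = (np.arange(times.size) <= last)
    # interior BLQ: treated as 0 (conservative for AUC)
    conc[blq & keep & ~blq_lead] = 0.0
    return times[keep], conc[keep]


def _lambda_z(times: np.ndarray, conc: np.ndarray, tmax_idx: int):
    """Terminal slope by best-adjusted-R² log-linear regression.

    Candidate windows run from each start index after Tmax to the last
    positive observation and must contain >= 3 positive points.  Returns
    (lambda_z, n_points, intercept) or ``None`` when no candidate window
    has a negative slope.
    """
    positive = conc > 0
    last = np.flatnonzero(positive)
    if last.size == 0:
        return None
    last = last[-1]
    best = None
    for start in range(tmax_idx + 1, last - 1):
        idx = np.flatnonzero(positive[start : last + 1]) + start
        if idx.size < 3:
            continue
        t, logc = times[idx], np.log(conc[idx])
        fit = stats.linregress(t, logc)
        if fit.slope >= 0:
            continue
        n = idx.size
        r2 = fit.rvalue**2
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if best is None or adj > best[0] + 1e-4:
            best = (adj, -fit.slope, n, fit.intercept)
    if best is None:
        return None
    return best[1], best[2], best[3]


def nca_profile(
    profile: SimulatedProfile | tuple[np.ndarray, np.ndarray],
    dose: DoseEvent | None = None,
    blq: np.ndarray | None = None,
) -> NCAResult:
    """NCA of one concentration–time profile.

    Accepts a :class:`SimulatedProfile` or a ``(times, conc)`` pair;
    ``blq`` optionally marks below-quantification records.  For an IV dose,
    clearance ``CL = dose_µmol / AUC_inf`` is reported.  λz and the
    derived quantities are flagged missing when the terminal phase cannot
    be characterised (fewer than 3 positive terminal points, or no
    decline).
    """
    if isinstance(profile, SimulatedProfile):
        times, conc = profile.times, profile.conc
    else:
        times, conc = profile
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if blq is not None:
        times, conc = apply_blq_policy(times, conc, blq)
    if times.size < 3:
        raise ValueError("NCA requires at least 3 observations")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    # close the dose-to-first-sample gap the standard way: log-linear
    # back-extrapolated C0 for an IV bolus, C(0) = 0 for extravascular
    auc_times, auc_conc = times, conc
    if dose is not None and times[0] > dose.time:
        if dose.route == ROUTE_IV and conc[0] > 0 and conc[1] > 0 and conc[1] < conc[0]:
            slope = (np.log(conc[1]) - np.log(conc[0])) / (times[1] - times[0])
            c0 = float(np.exp(np.log(conc[0]) - slope * (times[0] - dose.time)))
        elif dose.route == ROUTE_IV:
            c0 = float(conc[0])
        else:
            c0 = 0.0
        auc_times = np.concatenate([[dose.time], times])
        auc_conc = np.concatenate([[c0], conc])

    imax = int(np.argmax(conc))
    result = NCAResult(
        cmax=float(conc[imax]),
        tmax=float(times[imax]),
        auc_all=auc_trapezoid(auc_times, auc_conc),
    )
    term = _lambda_z(times, conc, imax)
    if term is None:
        result.flags.append("lambda_z not estimable")
    else:
        lz, n, _ = term
        result.lambda_z = float(lz)
        result.n_lambda_points = n
        c_last = conc[conc > 0][-1]
        result.auc_inf = result.auc_all + float(c_last) / lz
    if dose is not None and result.auc_inf is not None and dose.route == ROUTE_IV:
        result.cl = dose_umol(dose) / result.auc_inf
    return result


def bioavailability(po: NCAResult, po_dose_umol: float, iv: NCAResult, iv_dose_umol: float) -> float:
    """Oral bioavailability F = (AUC_po/dose_po) / (AUC_iv/dose_iv).

    Uses AUC_inf when available on both profiles, AUC_all otherwise.
    Values above 1 are legal output (flagged by callers as implausible).
    """
    if po_dose_umol <= 0 or iv_dose_umol <= 0:
        raise ValueError("doses must be > 0")
    if po.auc_inf is not None and iv.auc_inf is not None:
        auc_po, auc_iv = po.auc_inf, iv.auc_inf
    else:
        auc_po, auc_iv = po.auc_all, iv.auc_all
    if auc_iv <= 0:
        raise ValueError("IV AUC must be > 0")
    return (auc_po / po_dose_umol) / (auc_iv / iv_dose_umol)


def fold_change(a: float, b: float) -> float:
    """Ratio a/b; ``b`` must be positive."""
    if not b > 0:
        raise ValueError(f"denominator must be > 0, got {b}")
    return a / b


def summarize_group(results: list[NCAResult]) -> pd.DataFrame:
    """Geometric mean and geometric CV per NCA parameter across subjects.

    Non-positive or missing values are excluded (with a note in the ``n``
    column reflecting the values actually used).  Geometric CV is
    ``sqrt(exp(s²) − 1)`` with ``s`` the SD of log values; undefined for a
    single value.
    """
    if not results:
        raise ValueError("empty group")
    rows = {}
    for name in ("cmax", "tmax", "auc_all", "auc_inf", "lambda_z", "cl", "f"):
        values = np.array(
            [getattr(r, name) for r in results if getattr(r, name) is not None], dtype=float
        )
        values = values[values > 0]
        if values.size == 0:
            continue
        logs = np.log(values)
        gmean = float(np.exp(logs.mean()))
        gcv = float(np.sqrt(np.expm1(logs.var(ddof=1)))) if values.size > 1 else math.nan
        rows[name] = {"geomean": gmean, "gcv": gcv, "n": int(values.size)}
    return pd.DataFrame(rows).T
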