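"""Pooled maximum-likelihood estimation of compartmental parameters.

Two-stage procedure for pro-drug → parent studies:

1. :func:`fit_single` — each analyte's concentration–time data is fitted
   separately to the two-compartment model (with an absorption depot for
   oral arms).
2. :func:`fit_combined` — the single-analyte estimates seed a joint fit of
   the combined conversion model over all cohorts (pro-drug dosing, parent
   observed after pro-drug dosing, and a parent-only dosing arm), which
   estimates the fraction converted ``Fm``.

Estimator
---------
Observations are pooled across animals (naive-pooled estimation: a single
typical parameter vector, no per-animal random effects — between-animal
variability lives only in the data-generating simulator).  The proportional
residual-error model is handled by log-transforming both sides: minimising
the sum of squared log-residuals is the maximum-likelihood fit under
log-normal multiplicative noise, and a close approximation to a
proportional-error likelihood at bioanalytical noise levels.

Below-quantification (BLQ) records are not discarded: each contributes a
one-sided hinge residual ``max(0, log(pred/LLOQ))`` that penalises
predictions above the quantification limit — a least-squares surrogate for
censored likelihood.  This is what makes a no-conversion dataset (parent
entirely BLQ) informative about Fm.

All positive parameters are searched on the log scale, fractions (F, Fm)
on the logit scale, and the search is bounded to [1e-6, 1e6] in natural
units, so every iterate satisfies the structural constraints.
Optimisation is trust-region-reflective least squares with a few jittered
restarts against local minima; standard errors come from the local
curvature (J'J), with bound-hitting parameters flagged.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .compounds import ROUTE_IV, ROUTE_PO
from .dataset import PKDataset
from .model import (
    ANALYTE_PARENT,
    ANALYTE_PRODRUG,
    CombinedModelParams,
    DispositionParams,
    predict_combined_conc,
    predict_single_conc,
)
from .nca import auc_trapezoid

_CONC_FLOOR = 1e-12  # guards log() against predicted underflow

# parameters are bounded to [1e-6, 1e6] in natural units (|log| <= 13.8155);
# the same bound on the logit scale keeps fractions off exactly 0 and 1
_BOUND = math.log(1e6)


@dataclass
class FitResult:
    params: DispositionParams | CombinedModelParams
    objective: float
    standard_errors: dict[str, float] | None
    converged: bool
    n_obs: int
    message: str = ""
    flags: list[str] = field(default_factory=list)


def _logit(p: float) -> float:
    p = min(max(p, 1e-8), 1 - 1e-8)
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class _ObsGroup:
    """Pooled observations of one analyte for one (route, dose) cohort."""

    route: str
    amt: float
    times: np.ndarray  # unique times at which predictions are needed
    obs_map: np.ndarray  # index into `times` for each quantified record
    log_obs: np.ndarray
    blq_map: np.ndarray  # index into `times` for each BLQ record
    log_lloq: float | None

    def residuals(self, pred: np.ndarray) -> list[np.ndarray]:
        log_pred = np.log(np.maximum(pred, _CONC_FLOOR))
        parts = [log_pred[self.obs_map] - self.log_obs]
        if self.blq_map.size and self.log_lloq is not None:
            parts.append(np.maximum(0.0, log_pred[self.blq_map] - self.log_lloq))
        return parts


def _group_observations(ds: PKDataset, analyte: str) -> list[_ObsGroup]:
    subject_dose = {row.subject_id: (row.route, float(row.amt_umol)) for row in ds.doses.itertuples()}
    obs = ds.observations
    obs = obs[obs["analyte"] == analyte]
    quantified: dict[tuple[str, float], list[tuple[float, float]]] = {}
    censored: dict[tuple[str, float], list[float]] = {}
    for row in obs.itertuples():
        key = subject_dose[row.subject_id]
        if bool(row.blq) or not row.conc_umol_per_L > 0:
            censored.setdefault(key, []).append(float(row.time_h))
        else:
            quantified.setdefault(key, []).append((float(row.time_h), math.log(row.conc_umol_per_L)))
    groups = []
    log_lloq = math.log(ds.lloq) if ds.lloq else None
    for key in sorted(set(quantified) | set(censored)):
        t_obs = np.array([p[0] for p in quantified.get(key, [])])
        log_c = np.array([p[1] for p in quantified.get(key, [])])
        t_blq = np.array(censored.get(key, []), dtype=float) if log_lloq is not None else np.array([])
        times = np.unique(np.concatenate([t_obs, t_blq]))
        groups.append(
            _ObsGroup(
                route=key[0],
                amt=key[1],
                times=times,
                obs_map=np.searchsorted(times, t_obs),
                log_obs=log_c,
                blq_map=np.searchsorted(times, t_blq),
                log_lloq=log_lloq,
            )
        )
    return groups


def _remap(group: _ObsGroup, union: np.ndarray) -> _ObsGroup:
    idx = np.searchsorted(union, group.times)
    return dataclasses.replace(group, times=union, obs_map=idx[group.obs_map], blq_map=idx[group.blq_map])


def initial_disposition(data: PKDataset, analyte: str) -> DispositionParams:
    """Data-informed starting values.

    From an IV arm, clearance is seeded by dose/AUC and the central volume
    by dose over the earliest concentration; remaining parameters use
    generic ratios.  Without an IV arm, broad mouse-scale defaults are
    returned (the multi-start search does the rest).
    """
    cl0, vc0 = 0.05, 0.05
    for group in _group_observations(data, analyte):
        if group.route != ROUTE_IV or group.log_obs.size < 2:
            continue
        order = np.argsort(group.obs_map)
        t = group.times[group.obs_map[order]]
        c = np.exp(group.log_obs[order])
        uniq, inv = np.unique(t, return_inverse=True)
        mean_c = np.array([c[inv == i].mean() for i in range(uniq.size)])
        if uniq.size >= 2:
            auc = auc_trapezoid(uniq, mean_c)
            if auc > 0:
                cl0 = group.amt / auc
        vc0 = group.amt / mean_c[0]
        break
    return DispositionParams(CL=cl0, Vc=vc0, Q=cl0 / 2.0, Vp=2.0 * vc0, Ka=1.0, F=0.3)


def _pack_disposition(p: DispositionParams, oral: bool) -> tuple[list[float], list[str]]:
    theta = [math.log(p.CL), math.log(p.Vc), math.log(max(p.Q, 1e-6)), math.log(p.Vp)]
    names = ["CL", "Vc", "Q", "Vp"]
    if oral:
        theta += [math.log(p.Ka if p.Ka else 1.0), _logit(p.F if 0 < p.F < 1 else 0.3)]
        names += ["Ka", "F"]
    return theta, names


def _unpack_disposition(theta: np.ndarray, oral: bool) -> DispositionParams:
    kwargs = dict(CL=math.exp(theta[0]), Vc=math.exp(theta[1]), Q=math.exp(theta[2]), Vp=math.exp(theta[3]))
    if oral:
        kwargs.update(Ka=math.exp(theta[4]), F=_expit(theta[5]))
    return DispositionParams(**kwargs)


def _run_multistart(residual, x0: np.ndarray, n_starts: int, seed: int, jitter: float = 0.3):
    rng = np.random.default_rng(seed)
    best = None
    x0 = np.clip(np.asarray(x0, float), -_BOUND + 1e-6, _BOUND - 1e-6)
    starts = [x0]
    starts += [
        np.clip(x0 + rng.normal(0.0, jitter, size=len(x0)), -_BOUND + 1e-6, _BOUND - 1e-6)
        for _ in range(n_starts - 1)
    ]
    for start in starts:
        try:
            res = least_squares(
                residual, start, method="trf", bounds=(-_BOUND, _BOUND), x_scale="jac",
                xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimisation starts failed")
    return best


def _bound_flags(res, names: list[str]) -> list[str]:
    at_bound = [n for n, x in zip(names, res.x) if abs(x) >= _BOUND - 1e-3]
    return [f"parameter(s) at search bound: {', '.join(at_bound)}"] if at_bound else []


def _standard_errors(res, names: list[str], values: dict[str, float], fractions: set[str]) -> dict[str, float] | None:
    n, p = res.fun.size, res.x.size
    if n <= p:
        return None
    s2 = 2.0 * res.cost / (n - p)
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * s2
    except np.linalg.LinAlgError:
        return None
    se_t = np.sqrt(np.maximum(np.diag(cov), 0.0))
    out = {}
    for name, se in zip(names, se_t):
        v = values[name]
        # delta method back to the natural scale
        out[name] = v * (1.0 - v) * se if name in fractions else v * se
    return out


def fit_single(
    data: PKDataset,
    analyte: str | None = None,
    init: DispositionParams | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Pooled fit of the two-compartment model to one analyte's data.

    ``data`` may mix IV and oral arms; absorption parameters (Ka, F) are
    free only when an oral arm is present.  Requires at least 4 quantified
    observations.
    """
    if analyte is None:
        analytes = data.analytes
        if len(analytes) != 1:
            raise ValueError(f"dataset holds analytes {analytes}; specify one")
        analyte = analytes[0]
    groups = _group_observations(data, analyte)
    n_obs = sum(g.log_obs.size for g in groups)
    if n_obs < 4:
        raise ValueError(f"need >= 4 quantified observations, got {n_obs}")
    oral = any(g.route == ROUTE_PO for g in groups)
    if init is None:
        init = initial_disposition(data, analyte)
    x0, names = _pack_disposition(init, oral)
    n_res = n_obs + sum(g.blq_map.size for g in groups)

    def residual(theta: np.ndarray) -> np.ndarray:
        try:
            p = _unpack_disposition(theta, oral)
        except (ValueError, OverflowError):
            return np.full(n_res, 1e6)
        parts = []
        for g in groups:
            pred = predict_single_conc(p, g.route, g.amt, g.times)
            parts.extend(g.residuals(pred))
        return np.concatenate(parts)

    res = _run_multistart(residual, np.array(x0), n_starts, seed)
    params = _unpack_disposition(res.x, oral)
    values = dataclasses.asdict(params)
    return FitResult(
        params=params,
        objective=float(2.0 * res.cost),
        standard_errors=_standard_errors(res, names, values, fractions={"F"}),
        converged=bool(res.status > 0),
        n_obs=n_obs,
        message=res.message,
        flags=_bound_flags(res, names),
    )


def _combined_residual_builder(prodrug_data, parent_data, parent_only_data):
    pd_groups = _group_observations(prodrug_data, ANALYTE_PRODRUG)
    pa_groups = {(g.route, g.amt): g for g in _group_observations(parent_data, ANALYTE_PARENT)}
    only_groups = (
        _group_observations(parent_only_data, ANALYTE_PARENT) if parent_only_data is not None else []
    )
    # align pro-drug and formed-parent records on a shared grid per cohort
    cohorts: list[tuple[str, float, np.ndarray, _ObsGroup | None, _ObsGroup | None]] = []
    for g in pd_groups:
        match = pa_groups.pop((g.route, g.amt), None)
        if match is None:
            cohorts.append((g.route, g.amt, g.times, g, None))
            continue
        union = np.unique(np.concatenate([g.times, match.times]))
        cohorts.append((g.route, g.amt, union, _remap(g, union), _remap(match, union)))
    for g in pa_groups.values():
        # parent observed after pro-drug dosing without matching pro-drug records
        cohorts.append((g.route, g.amt, g.times, None, g))

    def residual_of(params: CombinedModelParams) -> np.ndarray:
        parts = []
        for route, amt, times, g_pd, g_pa in cohorts:
            conc_pd, conc_pa = predict_combined_conc(params, route, amt, times)
            if g_pd is not None:
                parts.extend(g_pd.residuals(conc_pd))
            if g_pa is not None:
                parts.extend(g_pa.residuals(conc_pa))
        for g in only_groups:
            pred = predict_single_conc(params.parent, g.route, g.amt, g.times)
            parts.extend(g.residuals(pred))
        return np.concatenate(parts)

    n_obs = sum(g.log_obs.size for g in pd_groups) + sum(
        g.log_obs.size for g in list(pa_groups.values())
    )
    return residual_of


def combined_objective(
    params: CombinedModelParams,
    prodrug_data: PKDataset,
    parent_data: PKDataset,
    parent_only_data: PKDataset | None,
) -> float:
    """Sum of squared (log and censoring) residuals of the combined model
    at ``params`` — the quantity :func:`fit_combined` minimises, exposed so
    a seed point (e.g. the stage-one estimates) can be compared with the
    final fit."""
    residual = _combined_residual_builder(prodrug_data, parent_data, parent_only_data)
    return float(np.sum(residual(params) ** 2))


def fit_combined(
    prodrug_data: PKDataset,
    parent_data: PKDataset,
    parent_only_data: PKDataset | None,
    init_from: tuple[FitResult | DispositionParams, FitResult | DispositionParams],
    fm_init: float = 0.3,
    n_starts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Joint fit of the pro-drug → parent model; estimates ``Fm``.

    ``prodrug_data`` and ``parent_data`` hold the pro-drug and parent
    analyte observations after pro-drug dosing; ``parent_only_data`` is the
    parent-compound dosing arm that pins down the parent's own disposition
    (without it, Fm and the parent central volume are not separately
    identifiable and a warning is issued).  ``init_from`` carries the
    stage-one single-analyte estimates used as the seed point.
    """
    if parent_only_data is None:
        warnings.warn(
            "no parent-only dosing arm: Fm and the parent central volume are "
            "not separately identifiable from metabolite data alone",
            stacklevel=2,
        )
    init_pd = init_from[0].params if isinstance(init_from[0], FitResult) else init_from[0]
    init_pa = init_from[1].params if isinstance(init_from[1], FitResult) else init_from[1]

    oral_pd = ROUTE_PO in set(prodrug_data.doses["route"]) | set(parent_data.doses["route"])
    oral_pa = parent_only_data is not None and ROUTE_PO in set(parent_only_data.doses["route"])
    x_pd, names_pd = _pack_disposition(init_pd, oral_pd)
    x_pa, names_pa = _pack_disposition(init_pa, oral_pa)
    x0 = np.array(x_pd + x_pa + [_logit(fm_init)])
    names = [f"prodrug.{n}" for n in names_pd] + [f"parent.{n}" for n in names_pa] + ["Fm"]
    split = len(x_pd)

    def unpack(theta: np.ndarray) -> CombinedModelParams:
        return CombinedModelParams(
            prodrug=_unpack_disposition(theta[:split], oral_pd),
            parent=_unpack_disposition(theta[split:-1], oral_pa),
            Fm=_expit(theta[-1]),
        )

    residual_of = _combined_residual_builder(prodrug_data, parent_data, parent_only_data)
    base = residual_of(unpack(x0))
    n_res = base.size
    n_obs = (
        prodrug_data.filter(analyte=ANALYTE_PRODRUG).n_obs
        + parent_data.filter(analyte=ANALYTE_PARENT).n_obs
        + (parent_only_data.n_obs if parent_only_data is not None else 0)
    )

    def residual(theta: np.ndarray) -> np.ndarray:
        try:
            params = unpack(theta)
        except (ValueError, OverflowError):
            return np.full(n_res, 1e6)
        return residual_of(params)

    res = _run_multistart(residual, x0, n_starts, seed)
    params = unpack(res.x)
    flags = _bound_flags(res, names)
    if params.Fm > 0.99 or params.Fm < 0.005:
        flags.append("Fm at boundary of [0, 1]")
    values = {}
    for name in names:
        if name == "Fm":
            values[name] = params.Fm
        else:
            block, attr = name.split(".")
            values[name] = getattr(getattr(params, block), attr)
    return FitResult(
        params=params,
        objective=float(2.0 * res.cost),
        standard_errors=_standard_errors(res, names, values, fractions={"prodrug.F", "parent.F", "Fm"}),
        converged=bool(res.status > 0),
        n_obs=n_obs,
        message=res.message,
        flags=flags,
    )
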