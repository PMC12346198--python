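"""Three-parameter logistic (unit Hill slope) dose-response fitting.

Inhibition curves from AR-ELISA and cytotoxicity plates are fitted by
non-linear least squares to

    Y = Bottom + (Top − Bottom) / (1 + X / IC50)

with parameters {Top, Bottom, IC50} and the Hill slope fixed at one — the
usual "three parameter" inhibition model.  IC50 is estimated on the log
scale, which keeps it positive and makes the asymptotic 95% confidence
interval multiplicative, matching how such intervals are reported
(e.g. 1.33 µM, CI 0.96–1.9).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np


@dataclass
class DoseResponseFit:
    top: float
    bottom: float
    ic50: float
    ci95_low: float | None
    ci95_high: float | None
    residual_sd: float
    n_points: int
    converged: bool
    flags: list[str] = field(default_factory=list)


def _model(x: np.ndarray, top: float, bottom: float, log_ic50: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + x / math.exp(log_ic50))


def fit_3pl(conc: np.ndarray, response: np.ndarray) -> DoseResponseFit:
    """Fit the unit-slope 3-parameter logistic to (possibly replicated) data.

    ``conc`` in µM; zero-concentration (vehicle) wells are legal and anchor
    the Top asymptote.  Requires at least 4 distinct positive
    concentrations.  Flat data (no dose dependence) is returned with
    ``converged = False``; an IC50 outside the tested range is flagged as
    an extrapolation.
    """
    conc = np.asarray(conc, float)
    response = np.asarray(response, float)
    if conc.shape != response.shape:
        raise ValueError("conc and response must have equal length")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    positive = conc[conc > 0]
    if np.unique(positive).size < 4:
        raise ValueError("need >= 4 distinct positive concentrations")

    span = response.max() - response.min()
    if span <= 0 or (response.std() < 1e-12 * max(1.0, abs(response.mean()))):
        return DoseResponseFit(
            top=float(response.mean()),
            bottom=float(response.mean()),
            ic50=math.nan,
            ci95_low=None,
            ci95_high=None,
            residual_sd=float(response.std()),
            n_points=int(conc.size),
            converged=False,
            flags=["flat response; no dose dependence"],
        )

    params = lmfit.Parameters()
    params.add("top", value=float(response.max()))
    params.add("bottom", value=float(response.min()))
    params.add("log_ic50", value=float(np.log(np.median(positive))), min=math.log(positive.min()) - 12, max=math.log(positive.max()) + 12)

    def residual(p):
        return response - _model(conc, p["top"].value, p["bottom"].value, p["log_ic50"].value)

    result = lmfit.minimize(residual, params, method="leastsq")
    top = float(result.params["top"].value)
    bottom = float(result.params["bottom"].value)
    log_ic50 = float(result.params["log_ic50"].value)
    ic50 = math.exp(log_ic50)
    stderr = result.params["log_ic50"].stderr
    flags: list[str] = []
    if stderr is not None and math.isfinite(stderr):
        ci_low = ic50 * math.exp(-1.959964 * stderr)
        ci_high = ic50 * math.exp(1.959964 * stderr)
    else:
        ci_low = ci_high = None
        flags.append("IC50 confidence interval not estimable")
    if bottom > top:
        # fitted curve increasing with concentration: not an inhibition curve
        flags.append("fitted Bottom exceeds Top; no inhibition detected")
    if not (positive.min() <= ic50 <= positive.max()):
        flags.append("IC50 outside tested concentration range (extrapolated)")
    n_free = int(result.nvarys)
    dof = max(conc.size - n_free, 1)
    residual_sd = float(np.sqrt(np.sum(np.asarray(result.residual) ** 2) / dof))
    return DoseResponseFit(
        top=top,
        bottom=bottom,
        ic50=float(ic50),
        ci95_low=ci_low,
        ci95_high=ci_high,
        residual_sd=residual_sd,
        n_points=int(conc.size),
        converged=bool(result.success),
        flags=flags,
    )


def ic50_exceeds_range(fit: DoseResponseFit, max_conc: float) -> bool:
    """True when the IC50 (or its lower confidence bound) reaches the top
    tested concentration — the ">max, CI not determined" reporting
    convention.  The boundary is inclusive."""
    if math.isnan(fit.ic50):
        return True
    if fit.ic50 >= max_conc:
        return True
    return fit.ci95_low is not None and fit.ci95_low >= max_conc


def format_ic50(fit: DoseResponseFit, max_conc: float, digits: int = 2) -> tuple[str, str]:
    """(IC50, CI) strings following the ">max / ND" convention for
    out-of-range estimates."""
    if ic50_exceeds_range(fit, max_conc):
        return f">{max_conc:g}", "ND"
    ic50 = f"{fit.ic50:.{digits}f}"
    if fit.ci95_low is None or fit.ci95_high is None:
        return ic50, "ND"
    return ic50, f"{fit.ci95_low:.{digits}g}-{fit.ci95_high:.{digits}g}"
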