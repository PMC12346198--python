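"""Plasma-stability metrics for ester pro-drugs.

An in-vitro stability assay incubates the pro-drug in plasma and samples
paired pro-drug/parent signals at fixed times (0–360 min).  The module
computes percent pro-drug remaining relative to baseline, a first-order
disappearance rate and half-life by log-linear regression, and the fold
increase of the parent signal over its baseline — the three summaries used
to judge whether a conjugate is cleaved in plasma at all.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

STABILITY_TIMES_MIN = (0.0, 30.0, 60.0, 120.0, 180.0, 360.0)


@dataclass(frozen=True)
class StabilityTimecourse:
    """Paired pro-drug/parent signals over a plasma incubation."""

    times_min: np.ndarray
    prodrug_signal: np.ndarray
    parent_signal: np.ndarray
    matrix: str = "human_plasma"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_min", np.asarray(self.times_min, float))
        object.__setattr__(self, "prodrug_signal", np.asarray(self.prodrug_signal, float))
        object.__setattr__(self, "parent_signal", np.asarray(self.parent_signal, float))
        if not (self.times_min.shape == self.prodrug_signal.shape == self.parent_signal.shape):
            raise ValueError("times and signals must have equal length")
        if self.times_min[0] != 0:
            raise ValueError("timecourse must include t = 0")
        if np.any(self.prodrug_signal < 0) or np.any(self.parent_signal < 0):
            raise ValueError("signals must be non-negative")
        if not self.prodrug_signal[0] > 0:
            raise ValueError("pro-drug baseline signal must be > 0")


@dataclass
class DecayFit:
    k_per_min: float | None
    t_half_min: float | None
    stable: bool
    n_points: int


def percent_remaining(tc: StabilityTimecourse) -> np.ndarray:
    """Percent of the baseline pro-drug signal at each timepoint."""
    return 100.0 * tc.prodrug_signal / tc.prodrug_signal[0]


def decay_halflife(tc: StabilityTimecourse) -> DecayFit:
    """First-order disappearance rate and half-life by log-linear regression.

    Non-positive signals after baseline are dropped with a warning.  A
    non-positive fitted rate is reported as ``stable`` (no measurable
    decay) with rate and half-life ``None``.
    """
    mask = tc.prodrug_signal > 0
    if np.any(~mask):
        warnings.warn(f"dropping {int((~mask).sum())} non-positive stability point(s)", stacklevel=2)
    t = tc.times_min[mask]
    s = tc.prodrug_signal[mask]
    if t.size < 3:
        raise ValueError("decay fit requires >= 3 positive timepoints")
    fit = stats.linregress(t, np.log(s))
    k = -fit.slope
    if k <= 0:
        return DecayFit(k_per_min=None, t_half_min=None, stable=True, n_points=int(t.size))
    return DecayFit(k_per_min=float(k), t_half_min=float(math.log(2) / k), stable=False, n_points=int(t.size))


def parent_formation_fold(tc: StabilityTimecourse, lloq: float | None = None) -> tuple[float, list[str]]:
    """Parent signal at the last timepoint as a fold over its baseline.

    A zero baseline is substituted by the assay LLOQ (flagged); without an
    LLOQ the fold is undefined and reported as ``inf`` with a flag.
    """
    flags: list[str] = []
    baseline = tc.parent_signal[0]
    if baseline <= 0:
        if lloq is not None and lloq > 0:
            baseline = lloq
            flags.append("baseline below quantification; fold computed against LLOQ")
        else:
            flags.append("baseline zero and no LLOQ; fold undefined")
            return math.inf, flags
    return float(tc.parent_signal[-1] / baseline), flags


def stability_report(tc: StabilityTimecourse, lloq: float | None = None) -> dict:
    """Joint summary of one timecourse.

    ``no_conversion`` is raised when the pro-drug is essentially stable
    (>= 90% remaining at the final timepoint) while the parent signal has
    not materially risen (fold <= 1.2) — the signature of a conjugate that
    plasma enzymes do not cleave.  Both the endpoint and the whole-course
    minimum percent remaining are reported.
    """
    pct = percent_remaining(tc)
    fold, flags = parent_formation_fold(tc, lloq=lloq)
    decay = decay_halflife(tc)
    no_conversion = pct[-1] >= 90.0 and fold <= 1.2
    return {
        "matrix": tc.matrix,
        "percent_remaining_end": float(pct[-1]),
        "percent_remaining_min": float(pct.min()),
        "parent_fold": fold,
        "k_per_min": decay.k_per_min,
        "t_half_min": decay.t_half_min,
        "stable": decay.stable,
        "no_conversion": bool(no_conversion),
        "flags": flags,
    }
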