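"""Derived pro-drug → parent conversion kinetics.

Given a fitted combined model, the conversion process is summarised by
first-order rate constants and amounts:

* ``Kel = CL/Vc`` of the pro-drug — its overall elimination rate constant;
* ``Kmet = Fm × Kel`` — the metabolite-formation rate constant;
* conversion half-life ``ln 2 / Kmet``;
* amount of parent formed at complete conversion, ``Fm`` times the
  systemically absorbed dose (``F × dose`` for oral, the full dose IV);
* conversion rate = amount / (5 × half-life), treating five half-lives
  as the time to effectively complete conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .compounds import ROUTE_PO, DoseEvent, dose_umol
from .model import CombinedModelParams


@dataclass
class ConversionMetrics:
    kel_per_h: float
    fm: float
    kmet_per_h: float
    conversion_half_life_h: float
    amount_at_complete_conversion_umol: float
    conversion_rate_umol_per_h: float
    flags: list[str] = field(default_factory=list)


def conversion_metrics(params: CombinedModelParams, dose: DoseEvent) -> ConversionMetrics:
    """Conversion summary for one fitted model and dose event.

    ``Fm = 0`` yields a zero formation rate constant, an infinite
    half-life and a zero conversion rate, flagged ``no conversion``.
    """
    kel = params.prodrug.kel
    fm = params.Fm
    kmet = fm * kel
    absorbed = dose_umol(dose)
    if dose.route == ROUTE_PO:
        absorbed *= params.prodrug.F
    amount = fm * absorbed
    flags: list[str] = []
    if kmet > 0:
        half_life = math.log(2) / kmet
        rate = amount / (5.0 * half_life)
    else:
        half_life = math.inf
        rate = 0.0
        flags.append("no conversion")
    return ConversionMetrics(
        kel_per_h=kel,
        fm=fm,
        kmet_per_h=kmet,
        conversion_half_life_h=half_life,
        amount_at_complete_conversion_umol=amount,
        conversion_rate_umol_per_h=rate,
        flags=flags,
    )
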