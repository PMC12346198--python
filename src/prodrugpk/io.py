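"""Dataset readers and writers.

PK datasets travel as a single CSV with population-PK style columns:

    ID, TIME, AMT, DV, EVID, MDV, BLQ, ANALYTE, ROUTE, COMPOUND, LLOQ

``EVID = 1`` marks dose rows (AMT in µmol, DV empty), ``EVID = 0``
observation rows (DV in µmol/L, empty with ``MDV = 1``/``BLQ = 1`` for
below-quantification records).  Numbers are written with repr-exact
formatting so a write/read/write round trip is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import PKDataset

PK_CSV_COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "MDV", "BLQ", "ANALYTE", "ROUTE", "COMPOUND", "LLOQ"]


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return repr(float(x))


def write_pk_csv(ds: PKDataset, path: str | Path) -> None:
    rows = []
    for r in ds.doses.itertuples():
        rows.append(
            {
                "ID": r.subject_id,
                "TIME": _fmt(r.time_h),
                "AMT": _fmt(r.amt_umol),
                "DV": "",
                "EVID": 1,
                "MDV": 1,
                "BLQ": 0,
                "ANALYTE": "",
                "ROUTE": r.route,
                "COMPOUND": r.compound,
                "LLOQ": _fmt(ds.lloq),
            }
        )
    for r in ds.observations.itertuples():
        blq = bool(r.blq)
        rows.append(
            {
                "ID": r.subject_id,
                "TIME": _fmt(r.time_h),
                "AMT": "",
                "DV": "" if blq else _fmt(r.conc_umol_per_L),
                "EVID": 0,
                "MDV": 1 if blq else 0,
                "BLQ": int(blq),
                "ANALYTE": r.analyte,
                "ROUTE": "",
                "COMPOUND": "",
                "LLOQ": _fmt(ds.lloq),
            }
        )
    frame = pd.DataFrame(rows, columns=PK_CSV_COLUMNS)
    frame.to_csv(path, index=False, lineterminator="\n")


def read_pk_csv(path: str | Path) -> PKDataset:
    """Read and validate a PK dataset CSV; schema problems name the column
    or line at fault."""
    frame = pd.read_csv(
        path,
        dtype={"ID": str, "ANALYTE": str, "ROUTE": str, "COMPOUND": str},
        float_precision="round_trip",
    )
    missing = [c for c in PK_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"PK CSV {path} is missing required column(s) {missing}")
    bad = frame[~frame["EVID"].isin([0, 1])]
    if not bad.empty:
        # +2: header line plus 1-based numbering
        lines = (bad.index + 2).tolist()
        raise ValueError(f"PK CSV {path}: invalid EVID on line(s) {lines}")
    doses = frame[frame["EVID"] == 1]
    obs = frame[frame["EVID"] == 0]
    bad_obs = obs[(obs["BLQ"] == 0) & obs["DV"].isna()]
    if not bad_obs.empty:
        lines = (bad_obs.index + 2).tolist()
        raise ValueError(f"PK CSV {path}: observation without DV on line(s) {lines}")
    lloq_values = frame["LLOQ"].dropna().unique()
    if len(lloq_values) > 1:
        raise ValueError(f"PK CSV {path}: inconsistent LLOQ values {sorted(lloq_values)}")
    return PKDataset(
        doses=pd.DataFrame(
            {
                "subject_id": doses["ID"].to_numpy(),
                "time_h": doses["TIME"].to_numpy(float),
                "amt_umol": doses["AMT"].to_numpy(float),
                "route": doses["ROUTE"].to_numpy(),
                "compound": doses["COMPOUND"].to_numpy(),
            }
        ),
        observations=pd.DataFrame(
            {
                "subject_id": obs["ID"].to_numpy(),
                "analyte": obs["ANALYTE"].to_numpy(),
                "time_h": obs["TIME"].to_numpy(float),
                "conc_umol_per_L": obs["DV"].to_numpy(float),
                "blq": obs["BLQ"].to_numpy(bool),
            }
        ),
        lloq=float(lloq_values[0]) if len(lloq_values) == 1 else None,
    )


def write_profile_csv(profiles, subject_id: str, path: str | Path) -> None:
    """Tidy CSV (subject, analyte, time_h, conc_umol_per_L) of simulated profiles."""
    rows = []
    for profile in profiles:
        for t, c in zip(profile.times, profile.conc):
            rows.append(
                {
                    "subject": subject_id,
                    "analyte": profile.analyte,
                    "time_h": repr(float(t)),
                    "conc_umol_per_L": repr(float(c)),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def read_stability_csv(path: str | Path):
    """Read a stability timecourse CSV (time_min, analyte, signal, matrix)."""
    from .stability import StabilityTimecourse

    frame = pd.read_csv(path)
    required = {"time_min", "analyte", "signal", "matrix"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"stability CSV {path} missing column(s) {sorted(missing)}")
    out = []
    for matrix, grp in frame.groupby("matrix"):
        pivot = grp.pivot_table(index="time_min", columns="analyte", values="signal").sort_index()
        out.append(
            StabilityTimecourse(
                times_min=pivot.index.to_numpy(float),
                prodrug_signal=pivot["prodrug"].to_numpy(float),
                parent_signal=pivot["parent"].to_numpy(float),
                matrix=str(matrix),
            )
        )
    return out
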