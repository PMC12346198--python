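"""Tabular PK dataset container.

A :class:`PKDataset` holds dosing events and timed concentration
observations in two tidy tables, mirroring the analysis-dataset layout
used by population-PK software (dose rows and observation rows
distinguished by an event marker).  Concentrations are µmol/L; records
below the lower limit of quantification (LLOQ) carry a BLQ flag and no
concentration value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DOSE_COLUMNS = ["subject_id", "time_h", "amt_umol", "route", "compound"]
OBS_COLUMNS = ["subject_id", "analyte", "time_h", "conc_umol_per_L", "blq"]


@dataclass
class PKDataset:
    doses: pd.DataFrame
    observations: pd.DataFrame
    lloq: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in DOSE_COLUMNS if c not in self.doses.columns]
        if missing:
            raise ValueError(f"dose table missing columns {missing}")
        missing = [c for c in OBS_COLUMNS if c not in self.observations.columns]
        if missing:
            raise ValueError(f"observation table missing columns {missing}")
        self.validate()

    def validate(self) -> None:
        obs = self.observations
        dup = obs.duplicated(subset=["subject_id", "analyte", "time_h"])
        if dup.any():
            bad = obs.loc[dup, ["subject_id", "analyte", "time_h"]].iloc[0].tolist()
            raise ValueError(f"duplicate observation time for subject/analyte {bad}")
        quantified = obs.loc[~obs["blq"].astype(bool), "conc_umol_per_L"]
        if quantified.isna().any():
            raise ValueError("non-BLQ observation without a concentration value")
        if (quantified < 0).any():
            raise ValueError("negative concentration")
        per_subject = self.doses.groupby("subject_id").size()
        if (per_subject != 1).any():
            raise ValueError("each subject must carry exactly one dose event")

    @property
    def subjects(self) -> list[str]:
        return sorted(self.doses["subject_id"].unique())

    @property
    def analytes(self) -> list[str]:
        return sorted(self.observations["analyte"].unique())

    @property
    def n_obs(self) -> int:
        return int((~self.observations["blq"].astype(bool)).sum())

    def filter(self, analyte: str | None = None, subjects: list[str] | None = None) -> "PKDataset":
        """Subset by analyte and/or subjects; dose rows follow the subjects."""
        obs = self.observations
        doses = self.doses
        if analyte is not None:
            obs = obs[obs["analyte"] == analyte]
        if subjects is not None:
            obs = obs[obs["subject_id"].isin(subjects)]
            doses = doses[doses["subject_id"].isin(subjects)]
        return PKDataset(
            doses=doses.reset_index(drop=True),
            observations=obs.reset_index(drop=True),
            lloq=self.lloq,
            meta=dict(self.meta),
        )


def concat_datasets(datasets: list[PKDataset]) -> PKDataset:
    """Stack cohorts into one dataset; subject ids must not collide."""
    if not datasets:
        raise ValueError("nothing to concatenate")
    doses = pd.concat([d.doses for d in datasets], ignore_index=True)
    obs = pd.concat([d.observations for d in datasets], ignore_index=True)
    lloqs = {d.lloq for d in datasets if d.lloq is not None}
    if len(lloqs) > 1:
        raise ValueError(f"cannot merge datasets with differing LLOQs {sorted(lloqs)}")
    meta: dict = {}
    for d in datasets:
        meta.update(d.meta)
    return PKDataset(doses=doses, observations=obs, lloq=lloqs.pop() if lloqs else None, meta=meta)


def observed_arrays(ds: PKDataset, analyte: str):
    """Quantified (subject_id, times, conc) triples for one analyte, sorted by time."""
    out = []
    obs = ds.observations
    obs = obs[(obs["analyte"] == analyte) & (~obs["blq"].astype(bool))]
    for sid, grp in obs.groupby("subject_id"):
        grp = grp.sort_values("time_h")
        out.append((sid, grp["time_h"].to_numpy(float), grp["conc_umol_per_L"].to_numpy(float)))
    return out
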