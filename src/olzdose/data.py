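"""TDM event datasets in NONMEM-style tabular form.

A :class:`TDMDataset` wraps a pandas DataFrame with one row per event:
dose rows (EVID=1, AMT in mg) and observation rows (EVID=0, DV in ng/mL,
MDV=0 when the DV is usable).  Subject-level covariates (WT kg, QUE flag,
plus any extra columns used as covariate candidates) are repeated on every
row of a subject.  Dose rows may carry SS (steady-state flag) and II
(interdose interval, h); when those columns are absent, dosing is taken
as steady-state q12h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TDMDataset", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ["ID", "TIME", "AMT", "EVID", "MDV", "DV", "WT", "QUE"]

_DEFAULT_II = 12.0


class TDMDataset:
    """Validated therapeutic-drug-monitoring event table."""

    def __init__(self, df: pd.DataFrame):
        self.df = _validate(df.copy())

    # -- basic properties -------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_obs(self) -> int:
        d = self.df
        return int(((d["EVID"] == 0) & (d["MDV"] == 0)).sum())

    def subject_table(self) -> pd.DataFrame:
        """One row per subject with its covariate values (first-row values)."""
        return self.df.groupby("ID", sort=False).first().reset_index()

    def observations(self) -> pd.DataFrame:
        d = self.df
        return d[(d["EVID"] == 0) & (d["MDV"] == 0)]

    def resample_subjects(self, rng: np.random.Generator) -> "TDMDataset":
        """Nonparametric bootstrap resample: draw subjects with replacement
        (dataset size preserved), re-labelling IDs 1..n."""
        ids = self.subject_ids
        picks = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for new_id, sid in enumerate(picks, start=1):
            block = self.df[self.df["ID"] == sid].copy()
            block["ID"] = new_id
            parts.append(block)
        return TDMDataset(pd.concat(parts, ignore_index=True))

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"TDMDataset(n_subjects={self.n_subjects}, n_obs={self.n_obs})"


@dataclass
class ObsDesign:
    """Flat per-observation arrays used by the likelihood and diagnostics.

    Each observation is mapped to its governing dose row (most recent dose
    at or before it); ``t_after`` is time since that dose, folded into
    [0, tau] for steady-state dosing.
    """

    sub_idx: np.ndarray      # (n_obs,) int, 0-based subject index
    dv: np.ndarray           # (n_obs,)
    t_after: np.ndarray      # (n_obs,)
    amt: np.ndarray          # (n_obs,) per-administration dose, mg
    tau: np.ndarray          # (n_obs,) interdose interval, h
    wt: np.ndarray           # (n_obs,)
    que: np.ndarray          # (n_obs,)
    extras: dict             # name -> (n_obs,) arrays for extra covariates
    subject_ids: np.ndarray  # (n_subjects,) original IDs
    wt_sub: np.ndarray       # (n_subjects,)
    que_sub: np.ndarray      # (n_subjects,)
    extras_sub: dict         # name -> (n_subjects,)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_obs(self) -> int:
        return len(self.dv)


def build_design(dataset: TDMDataset, extra_names=()) -> ObsDesign:
    """Extract the observation design from a dataset.

    Observations with no preceding dose row raise; steady-state dosing is
    assumed (SS column, default 1) so ``t_after`` is reduced modulo the
    interval.
    """
    df = dataset.df
    ss = df["SS"] if "SS" in df.columns else pd.Series(1, index=df.index)
    ii = df["II"] if "II" in df.columns else pd.Series(_DEFAULT_II, index=df.index)

    ids = dataset.subject_ids
    id_to_idx = {sid: k for k, sid in enumerate(ids)}

    rows = {k: [] for k in ("sub", "dv", "t", "amt", "tau", "wt", "que")}
    ex_rows = {name: [] for name in extra_names}
    sub_first = dataset.subject_table().set_index("ID")
    for name in extra_names:
        if name not in df.columns:
            raise KeyError(f"covariate column {name!r} not in dataset")

    for sid, block in df.groupby("ID", sort=False):
        doses = block[block["EVID"] == 1]
        obs = block[(block["EVID"] == 0) & (block["MDV"] == 0)]
        for _, o in obs.iterrows():
            prior = doses[doses["TIME"] <= o["TIME"]]
            if prior.empty:
                raise ValueError(f"subject {sid}: observation at t={o['TIME']} precedes all doses")
            d = prior.iloc[-1]
            tau = float(ii.loc[d.name])
            dt = float(o["TIME"] - d["TIME"])
            if int(ss.loc[d.name]) == 1:
                dt = dt % tau  # periodic at steady state; trough == t=0 value
            rows["sub"].append(id_to_idx[sid])
            rows["dv"].append(float(o["DV"]))
            rows["t"].append(dt)
            rows["amt"].append(float(d["AMT"]))
            rows["tau"].append(tau)
            rows["wt"].append(float(o["WT"]))
            rows["que"].append(int(o["QUE"]))
            for name in extra_names:
                ex_rows[name].append(float(o[name]))

    return ObsDesign(
        sub_idx=np.asarray(rows["sub"], dtype=int),
        dv=np.asarray(rows["dv"], dtype=float),
        t_after=np.asarray(rows["t"], dtype=float),
        amt=np.asarray(rows["amt"], dtype=float),
        tau=np.asarray(rows["tau"], dtype=float),
        wt=np.asarray(rows["wt"], dtype=float),
        que=np.asarray(rows["que"], dtype=float),
        extras={k: np.asarray(v, dtype=float) for k, v in ex_rows.items()},
        subject_ids=ids,
        wt_sub=sub_first.loc[ids, "WT"].to_numpy(dtype=float),
        que_sub=sub_first.loc[ids, "QUE"].to_numpy(dtype=float),
        extras_sub={
            name: sub_first.loc[ids, name].to_numpy(dtype=float) for name in extra_names
        },
    )


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    for col in REQUIRED_COLUMNS:
        if col == "DV":
            continue
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if not bad.empty:
            raise ValueError(f"non-numeric value in column {col} at row {bad.index[0]}")
    df["DV"] = pd.to_numeric(df["DV"], errors="coerce")

    for i, row in df.iterrows():
        evid = int(row["EVID"])
        if evid == 1:
            if not np.isnan(row["DV"]) and row["DV"] != 0:
                raise ValueError(f"row {i}: dose row (EVID=1) must not carry a DV")
            if row["AMT"] < 0:
                raise ValueError(f"row {i}: negative dose amount")
        elif evid == 0:
            if row["AMT"] != 0:
                raise ValueError(f"row {i}: observation row (EVID=0) must not carry AMT")
            if int(row["MDV"]) == 0:
                if np.isnan(row["DV"]) or row["DV"] < 0:
                    raise ValueError(f"row {i}: observation with MDV=0 needs DV >= 0")
        else:
            raise ValueError(f"row {i}: unsupported EVID {evid}")
        if row["TIME"] < 0:
            raise ValueError(f"row {i}: negative TIME")
        if int(row["QUE"]) not in (0, 1):
            raise ValueError(f"row {i}: QUE must be 0 or 1")
        if row["WT"] <= 0:
            raise ValueError(f"row {i}: non-positive weight")

    for sid, block in df.groupby("ID", sort=False):
        if (block["EVID"] == 1).sum() < 1:
            raise ValueError(f"subject {sid}: no dose row")
        t = block["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise ValueError(f"subject {sid}: TIME not non-decreasing")
    return df
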