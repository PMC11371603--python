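"""Reading/writing TDM datasets, result reports and run manifests."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .data import REQUIRED_COLUMNS, TDMDataset
from .dosing import PTAGrid, Recommendation
from .estimation import FitResult, _get_param
from .validate import BootstrapResult, VPCResult

__all__ = [
    "read_tdm",
    "write_tdm",
    "write_report",
    "load_config",
    "write_manifest",
]


def read_tdm(path) -> TDMDataset:
    """Read a NONMEM-style event CSV (ID, TIME, AMT, EVID, MDV, DV, WT,
    QUE, optional SS/II and extra covariate columns) into a validated
    dataset.  Parse problems raise with the offending row number."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, na_values=["", "."])
    return TDMDataset(df)


def write_tdm(dataset: TDMDataset, path) -> None:
    df = dataset.df.copy()
    df["DV"] = df["DV"].where(df["EVID"] == 0, other=pd.NA)
    df.to_csv(path, index=False, na_rep=".")


def _fit_table(fit: FitResult, boot: BootstrapResult | None = None) -> pd.DataFrame:
    rows = []
    for name in fit.free_names:
        row = dict(parameter=name, estimate=_get_param(fit.model, name),
                   rse_pct=fit.rse.get(name), fixed=False)
        if boot is not None and name in boot.summary.index:
            s = boot.summary.loc[name]
            row.update(bootstrap_median=s["median"], ci_lo=s["ci_lo"],
                       ci_hi=s["ci_hi"], bias_pct=s["bias_pct"])
        rows.append(row)
    for name in ("ka", "allo_cl", "allo_v", "ref_weight"):
        rows.append(dict(parameter=name, estimate=getattr(fit.model, name),
                         rse_pct=None, fixed=True))
    for name in fit.fixed_mask:
        rows.append(dict(parameter=name, estimate=_get_param(fit.model, name),
                         rse_pct=None, fixed=True))
    return pd.DataFrame(rows)


def write_report(obj, path) -> list[Path]:
    """Write machine- and human-readable summaries of a result object.

    Fit results become a parameter table (estimate, RSE, bootstrap
    median/CI/bias when available); PTA grids one CSV row per cell;
    recommendations a band/dose/PTA-range table; VPC results the binned
    percentile tables.  Returns the written paths.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def csv(df: pd.DataFrame, suffix: str) -> None:
        p = path.with_suffix("") if path.suffix else path
        p = p.parent / f"{p.name}{suffix}"
        df.to_csv(p, index=False)
        written.append(p)

    if isinstance(obj, FitResult):
        csv(_fit_table(obj), ".csv")
        meta = dict(ofv=obj.ofv, converged=obj.converged, n_subjects=obj.n_subjects,
                    n_obs=obj.n_obs, n_evals=obj.n_evals, message=obj.message)
        p = path.parent / (path.stem + ".json")
        p.write_text(json.dumps(meta, indent=2))
        written.append(p)
    elif isinstance(obj, tuple) and len(obj) == 2 and isinstance(obj[0], FitResult):
        fit, boot = obj
        csv(_fit_table(fit, boot), ".csv")
    elif isinstance(obj, BootstrapResult):
        df = obj.summary.reset_index(names="parameter")
        df["n_replicates"] = obj.n_replicates
        df["n_failed"] = obj.n_failed
        csv(df, ".csv")
    elif isinstance(obj, PTAGrid):
        csv(obj.table, ".csv")
    elif isinstance(obj, Recommendation):
        df = obj.bands.copy()
        df.insert(0, "frequency", obj.frequency)
        df.insert(1, "quetiapine", obj.quetiapine)
        csv(df, ".csv")
    elif isinstance(obj, VPCResult):
        frames = []
        for label, frame in (("observed", obj.observed), ("sim_median", obj.sim_median),
                             ("sim_lo", obj.sim_lo), ("sim_hi", obj.sim_hi)):
            f = frame.copy()
            f.insert(0, "series", label)
            f.insert(1, "percentile", f.index)
            frames.append(f)
        csv(pd.concat(frames, ignore_index=True), ".csv")
    else:
        raise TypeError(f"cannot report object of type {type(obj).__name__}")
    return written


def load_config(path) -> dict:
    """Load a YAML run configuration (may be empty)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_manifest(out_dir, command: str, seed, config: dict | None = None) -> Path:
    """Record what produced the outputs: command, seed, config, version."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = dict(command=command, seed=seed, config=config or {},
                    package_version=__version__)
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2))
    return p
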