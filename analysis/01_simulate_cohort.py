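#!/usr/bin/env python
"""Generate the synthetic TDM cohorts the analysis runs on.

Writes two NONMEM-style event CSVs under results/:

* ``tdm_cohort.csv`` — 39 subjects with the default (estimation-friendly)
  quetiapine prevalence of 0.3 and heterogeneous TDM dosing;
* ``tdm_cohort_paper_prevalence.csv`` — the same design with the observed
  2/39 quetiapine prevalence.

Both use truncated-normal weights (70.01 +/- 8.23 kg on [45, 85] kg) and
steady-state trough sampling with combined residual error under the final
model parameters.
"""

import argparse
from pathlib import Path

from olzdose import default_model
from olzdose.cohort import CohortSpec, make_dataset, paper_faithful_spec
from olzdose.io import write_manifest, write_tdm

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    args = ap.parse_args()

    model = default_model()
    OUT.mkdir(parents=True, exist_ok=True)

    ds = make_dataset(CohortSpec(), model, seed=args.seed)
    write_tdm(ds, OUT / "tdm_cohort.csv")
    sub = ds.subject_table()
    print(f"tdm_cohort.csv: {ds.n_subjects} subjects, {ds.n_obs} trough observations")
    print(f"  weight {sub['WT'].mean():.1f} +/- {sub['WT'].std():.1f} kg "
          f"({sub['WT'].min():.1f}-{sub['WT'].max():.1f})")
    print(f"  quetiapine co-medication: {int(sub['QUE'].sum())}/{len(sub)}")
    dv = ds.observations()["DV"]
    print(f"  troughs {dv.min():.1f}-{dv.max():.1f} ng/mL (median {dv.median():.1f})")

    ds_pf = make_dataset(paper_faithful_spec(), model, seed=args.seed)
    write_tdm(ds_pf, OUT / "tdm_cohort_paper_prevalence.csv")
    n_que = int(ds_pf.subject_table()["QUE"].sum())
    print(f"tdm_cohort_paper_prevalence.csv: quetiapine {n_que}/39")

    write_manifest(OUT, "analysis/01_simulate_cohort.py", args.seed)


if __name__ == "__main__":
    main()
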