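#!/usr/bin/env python
"""Validate the fitted model: bootstrap, VPC and goodness-of-fit tables.

Bootstrap resamples subjects with replacement and refits (100 replicates
here — enough for stable medians and interval endpoints at reporting
precision); the VPC simulates 500 replicate datasets on the observed
design.  Writes results/bootstrap.csv, results/vpc.csv and
results/gof.csv.
"""

import argparse
from pathlib import Path

from olzdose import bootstrap, default_model, fit, gof, vpc
from olzdose.cohort import CohortSpec, make_dataset
from olzdose.io import read_tdm, write_manifest, write_report

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--n-bootstrap", type=int, default=100)
    args = ap.parse_args()

    path = OUT / "tdm_cohort.csv"
    ds = read_tdm(path) if path.exists() else make_dataset(
        CohortSpec(), default_model(), seed=args.seed)

    result = fit(ds, default_model(), seed=args.seed)
    print(f"fit: OFV {result.ofv:.2f}, converged={result.converged}")

    boot = bootstrap(ds, result, n_replicates=args.n_bootstrap, seed=args.seed)
    ok = args.n_bootstrap - boot.n_failed
    print(f"bootstrap: {ok}/{args.n_bootstrap} replicates converged"
          + (" [UNRELIABLE]" if boot.unreliable else ""))
    print(boot.summary.round(3).to_string())

    v = vpc(ds, result.model, n_simulations=500, seed=args.seed)
    inside = sum(
        (v.sim_lo.loc[p, c] <= v.observed.loc[p, c] <= v.sim_hi.loc[p, c])
        for c in v.observed.columns for p in v.percentiles)
    total = len(v.observed.columns) * len(v.percentiles)
    print(f"VPC: observed percentiles inside 95% simulation bands in "
          f"{inside}/{total} bin-percentile cells")

    table = gof(ds, result)
    print(f"GOF: mean |iWRES| {table['abs_iwres'].mean():.2f}, "
          f"max |WRES| {table['wres'].abs().max():.2f}")

    OUT.mkdir(parents=True, exist_ok=True)
    write_report((result, boot), OUT / "bootstrap")
    write_report(v, OUT / "vpc")
    table.to_csv(OUT / "gof.csv", index=False)
    write_manifest(OUT, "analysis/03_validate_model.py", args.seed)


if __name__ == "__main__":
    main()
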