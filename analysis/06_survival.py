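#!/usr/bin/env python
"""Survival stratified by RSI: Kaplan-Meier curves, log-rank test,
univariate Cox hazard ratio and the optimal RSI cutpoint for overall
survival. Run 01 and 02 first.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from rsikit.survival import cox_univariate, km_fit, logrank, surv_cutpoint


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--minprop", type=float, default=0.1)
    args = ap.parse_args()

    surv = pd.read_csv(args.cohort / "survival.tsv", sep="\t")
    scores = pd.read_csv(args.outdir / "rsi_scores.tsv", sep="\t")
    merged = surv.merge(scores, on="sample_id")
    t = merged["time"].to_numpy()
    e = merged["event"].to_numpy()

    curves = []
    for label, grp in merged.groupby("category"):
        km = km_fit(grp["time"].to_numpy(), grp["event"].to_numpy())
        curves.append(pd.DataFrame({"group": label, "time": km.times,
                                    "survival": km.survival,
                                    "at_risk": km.at_risk}))
    args.outdir.mkdir(parents=True, exist_ok=True)
    pd.concat(curves, ignore_index=True).to_csv(
        args.outdir / "km_curves.tsv", sep="\t", index=False)

    chi2, p = logrank(t, e, merged["category"].to_numpy())
    hr = cox_univariate(
        t, e, (merged["category"] == "RSI-High").to_numpy().astype(float))
    cp = surv_cutpoint(t, e, merged["rsi"].to_numpy(), args.minprop)
    doc = {
        "logrank": {"chi2": chi2, "p": p},
        "cox_rsi_high": {"hr": hr.hr, "ci": [hr.ci_low, hr.ci_high], "p": hr.p},
        "optimal_cutpoint": {"value": cp.value, "statistic": cp.statistic,
                             "n_low": cp.n_low, "n_high": cp.n_high},
    }
    (args.outdir / "survival_results.json").write_text(json.dumps(doc, indent=2))
    print(f"log-rank chi2 {chi2:.2f}, p = {p:.3g}")
    print(f"Cox HR (RSI-High vs Low) {hr.hr:.2f} "
          f"(95% CI {hr.ci_low:.2f}-{hr.ci_high:.2f}, p = {hr.p:.3g})")
    print(f"optimal survival cutpoint {cp.value:.3f} "
          f"(|z| = {cp.statistic:.2f}; {cp.n_low} low / {cp.n_high} high)")
    print("note: a cutpoint selected and tested on the same data overstates "
          "separation; validate on an independent replicate")


if __name__ == "__main__":
    main()
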