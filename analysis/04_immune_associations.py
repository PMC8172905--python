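#!/usr/bin/env python
"""Immune-association statistics on the scored cohort.

Macrophage polarisation (log2 M1/M2) and its Spearman correlation with RSI,
RSI vs TCIA z correlation, Mann-Whitney comparison of RSI between C2 and
non-C2, one-way ANOVA of RSI across all six subtypes, and the differential
filter rule applied to a demonstration table. Run 01-03 first.
"""
import argparse
from pathlib import Path

import pandas as pd

from rsikit.immune import (
    anova_across_groups,
    filter_differential,
    group_compare,
    m1_m2_log_ratio,
    spearman_with_p,
    validate_immune_fractions,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    scores = pd.read_csv(args.outdir / "rsi_scores.tsv", sep="\t"
                         ).set_index("sample_id")
    enr = pd.read_csv(args.outdir / "tcia_enrichment.tsv", sep="\t"
                      ).set_index("sample_id")
    frac = validate_immune_fractions(pd.read_csv(
        args.cohort / "immune_fractions.tsv", sep="\t", index_col=0))
    cov = pd.read_csv(args.cohort / "covariates.tsv", sep="\t"
                      ).set_index("sample_id")

    ratio = m1_m2_log_ratio(frac)
    rows = []
    rho, p = spearman_with_p(scores.loc[enr.index, "rsi"].to_numpy(),
                             enr["z"].to_numpy())
    rows.append(("rsi_vs_tcia_z", rho, p, len(enr)))
    common = ratio.values.index
    rho, p = spearman_with_p(scores.loc[common, "rsi"].to_numpy(),
                             ratio.values.to_numpy())
    rows.append(("rsi_vs_log2_m1_m2", rho, p, len(common)))
    assoc = pd.DataFrame(rows, columns=["pair", "spearman_rho", "p", "n"])
    args.outdir.mkdir(parents=True, exist_ok=True)
    assoc.to_csv(args.outdir / "immune_associations.tsv", sep="\t", index=False)
    print(assoc.to_string(index=False))
    print(f"({ratio.n_excluded} samples excluded for structural M1/M2 zeros)")

    subtype = cov.loc[scores.index, "immune_subtype"]
    u, p_mw = group_compare(scores["rsi"].to_numpy(),
                            (subtype == "C2").to_numpy())
    f, p_an = anova_across_groups(scores["rsi"].to_numpy(), subtype.to_numpy())
    print(f"RSI C2 vs non-C2: Mann-Whitney U={u:.0f}, p={p_mw:.3g}")
    print(f"RSI across subtypes: ANOVA F={f:.2f}, p={p_an:.3g}")

    demo = pd.DataFrame({
        "feature": ["TAP2_like", "weak", "boundary"],
        "logFC": [-1.33, 0.5, 1.0],
        "adj_p": [0.01, 0.001, 0.01],
    })
    kept = filter_differential(demo)
    kept.to_csv(args.outdir / "differential_filtered.tsv", sep="\t", index=False)
    print(f"differential filter kept {len(kept)}/{len(demo)} rows: "
          f"{kept['feature'].tolist()}")


if __name__ == "__main__":
    main()
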