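#!/usr/bin/env python
"""Paired cohort statistics on the measured features.

Produces the per-layer paired comparison table (mean (SD) per segment,
paired-difference CI and p, count with the ganglionic value greater), the
registry descriptives, and the full-wall vs weight/age correlations.
"""

import json
from pathlib import Path

import pandas as pd

from hdmorph.io import write_cohort_table
from hdmorph.paired_stats import cohort_descriptives, cohort_table, pearson

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    feats = pd.read_csv(RESULTS / "specimen_features.csv")
    table = cohort_table(feats)
    write_cohort_table(table, RESULTS / "cohort_table.csv")

    registry = pd.read_csv(RESULTS / "patient_registry.csv")
    cohort_descriptives(registry).round(3).to_csv(RESULTS / "descriptives.csv", index=False)

    merged = feats.merge(registry, on="patient_id", how="inner")
    correlations = {}
    for cov, col in (("weight", "weight_kg"), ("age", "age_days")):
        correlations[cov] = {}
        for seg in ("aganglionic", "ganglionic"):
            sub = merged[merged.segment == seg].dropna(subset=["full_wall", col])
            r, p = pearson(sub["full_wall"], sub[col])
            correlations[cov][seg] = {"r": round(r, 3), "p": round(p, 3), "n": len(sub)}
    (RESULTS / "correlations.json").write_text(json.dumps(correlations, indent=2))

    mi = table.set_index("feature").loc["muscularis_interna"]
    print(f"muscularis interna: diff {mi['mean_diff']:.3f} mm "
          f"(CI {mi['ci_low']:.3f} to {mi['ci_high']:.3f}), p = {mi['p']:.2e}, "
          f"ganglionic greater in {int(mi['n_ganglionic_greater'])}/{int(mi['n'])}")
    w = correlations["weight"]["aganglionic"]
    print(f"full wall vs weight (aganglionic): r = {w['r']}, p = {w['p']}")


if __name__ == "__main__":
    main()
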