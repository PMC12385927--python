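#!/usr/bin/env python
"""Apply the cohort inclusion criteria to the simulated registry.

Filters on age at surgery ≤ 1 year, no prior stoma, primary surgery,
aganglionic length ≤ 25 cm, and image quality, tallying each exclusion
under its first failing criterion.
"""

import json
from pathlib import Path

import pandas as pd

from hdmorph.paired_stats import apply_inclusion_criteria

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    registry = pd.read_csv(RESULTS / "patient_registry.csv")
    included, tally = apply_inclusion_criteria(registry)
    included.to_csv(RESULTS / "included_patients.csv", index=False)
    summary = {"n_registry": len(registry), "n_included": len(included),
               "excluded": tally}
    (RESULTS / "exclusion_tally.json").write_text(json.dumps(summary, indent=2))

    print(f"registry: {len(registry)} patients")
    for name, count in tally.items():
        print(f"  excluded ({name}): {count}")
    print(f"included: {len(included)}")


if __name__ == "__main__":
    main()
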