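#!/usr/bin/env python
"""Generate the working cohort for the analysis chain.

Simulates the "childhood" longitudinal scenario: six follow-up ages whose
active-component counts ramp 10, 26, 63, 68, 71, 72, with a scripted
cluster architecture (a broad multi-source cluster at every age, a stable
4-component mite cluster from age 3, a grass cluster that absorbs members
at age 5, a single-component mould cluster later reabsorbed, two clusters
newly formed at age 11, one dividing at age 16) and outcomes generated from
a logistic model on the final-age sensitization profiles.

Panels, truth tables and outcomes are bulky intermediates and go under
scratch/cohort/ (regenerate them by re-running this script; they are a pure
function of the seed).
"""

from pathlib import Path

import pandas as pd

from allergotype.panel_io import write_panel
from allergotype.synthetic_cohort import scenario, simulate_longitudinal

SEED = 17
OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = simulate_longitudinal(scenario("childhood", SEED))
    for quant in cohort.quant_panels:
        write_panel(quant, OUT / f"panel_{quant.age_label}.csv")
    for age, membership in cohort.true_memberships.items():
        pd.Series(membership, name="cluster").rename_axis("component").to_csv(
            OUT / f"truth_membership_{age}.csv"
        )
    cohort.outcomes.astype(int).to_csv(OUT / "outcomes.csv")
    sizes = {p.age_label: len(p.subject_ids) for p in cohort.quant_panels}
    print(f"cohort written to {OUT}")
    print(f"  ages and roster sizes: {sizes}")
    print(f"  components in universe: {len(cohort.spec.universe)}")
    print(f"  outcome prevalences: {cohort.outcomes.mean().round(3).to_dict()}")


if __name__ == "__main__":
    main()
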