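#!/usr/bin/env python
"""Associate cluster sensitization with asthma and rhinitis.

Builds subject-level sensitization profiles from the final-age clustering
(sensitized to a cluster = positive to >= 1 member component; the
all-negative group is "nonsensitized"), derives current asthma by the
2-of-3 rule, and estimates univariable and multiple logistic odds ratios.
The cross-age confusion matrix of cluster sensitization between age 5 and
age 16 is also written.  Outputs under results/associations/.
"""

from pathlib import Path

import pandas as pd

from allergotype.outcome_association import (
    build_profiles,
    cross_age_confusion,
    derive_outcomes,
    multiple_or,
    results_table,
    univariable_or,
)
from allergotype.panel_io import active_components, binarize_panel, read_panel

ROOT = Path(__file__).resolve().parent.parent
BASE = ROOT / "results"
SCRATCH = ROOT / "scratch"
OUT = BASE / "associations"


def profiles_for(age: str) -> pd.DataFrame:
    panel = binarize_panel(read_panel(SCRATCH / "cohort" / f"panel_{age}.csv", age))
    membership = pd.read_csv(
        BASE / "membership" / f"membership_{age}.csv", index_col="component"
    )["modal_cluster"]
    active = active_components(panel)
    return build_profiles(panel, membership.to_dict(), active)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    outcomes = derive_outcomes(
        pd.read_csv(SCRATCH / "cohort" / "outcomes.csv", index_col="subject_id").astype(float)
    )
    results = []
    for age in ("5", "16"):
        profiles = profiles_for(age)
        indicators = profiles.drop(columns="nonsensitized")
        for outcome_name in ("current_asthma", "current_wheeze", "current_rhinitis"):
            y = outcomes[outcome_name]
            for cluster in indicators.columns:
                results.append(
                    univariable_or(y, indicators[cluster].astype(float),
                                   outcome_name=f"{outcome_name}@{age}",
                                   exposure_name=str(cluster))
                )
            results.extend(
                multiple_or(y, indicators.astype(float),
                            outcome_name=f"{outcome_name}@{age}")
            )
    table = results_table(results)
    table.to_csv(OUT / "odds_ratios.csv", index=False, float_format="%.4g")

    confusion = cross_age_confusion(profiles_for("5"), profiles_for("16"))
    confusion.rename_axis("cluster_age5").to_csv(OUT / "confusion_age5_vs_age16.csv")

    significant = table[(table["model"] == "multiple") & (table["p"] < 0.05)]
    print(f"{len(table)} estimates written; significant multiple-model associations:")
    for r in significant.itertuples(index=False):
        print(f"  {r.outcome} ~ cluster {r.exposure}: OR {r.OR:.2f} "
              f"({r.ci_low:.2f}-{r.ci_high:.2f}), p={r.p:.3g}, n={r.n}")
    print(f"association tables in {OUT}")


if __name__ == "__main__":
    main()
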