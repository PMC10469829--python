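"""Cross-tabulate the simulated sample and screen variables for missingness.

Reads results/sample.csv (run 02_simulate_survey.py first), produces a
sample-distribution table per covariate with Pearson chi-square tests of
association with the death outcome, and demonstrates the one-third
missingness screen.  Writes results/descriptives.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from svybias import crosstab_outcome, screen_missingness
from svybias.io import read_table, write_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sample = read_table(OUT / "sample.csv")
    blocks = []
    for variable in ("sex", "residence"):
        ct = crosstab_outcome(sample, variable)
        print(
            f"{variable}: chi2={ct.statistic:.3f} (df={ct.df}), p={ct.p_value:.4f}"
        )
        print(ct.table.to_string(index=False))
        blocks.append(
            ct.table.assign(variable=variable, chi_square=ct.statistic, p=ct.p_value)
        )
    overall = crosstab_outcome(sample.assign(all="all"), "all")
    print(
        f"overall: {overall.overall['n']:,} children, "
        f"{overall.overall['events']:,} deaths ({overall.overall['event_pct']}%)"
    )

    # missingness screen on a copy with one heavily incomplete variable,
    # mimicking variables dropped for >= 1/3 missing values
    noisy = sample.copy()
    rng = np.random.default_rng(0)
    noisy["birth_weight"] = np.where(
        rng.random(len(noisy)) < 0.4, np.nan, rng.normal(3.1, 0.5, len(noisy))
    )
    kept, report = screen_missingness(noisy, ["sex", "residence", "birth_weight"])
    print("\nmissingness screen (threshold 1/3):")
    print(report.to_string(index=False))
    print("kept for modelling:", kept)

    write_table(pd.concat(blocks, ignore_index=True), OUT / "descriptives.csv", {}, 0)


if __name__ == "__main__":
    main()
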