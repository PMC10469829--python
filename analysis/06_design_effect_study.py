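"""Replicated study of what weighting buys under an informative design.

Draws 100 independent surveys with outcome-correlated inclusion
(informativeness 1.0, cluster SD 0.7) and measures, per replicate:
the bias of the unweighted and design-weighted sample rates, whether
the pseudo-likelihood intercept is closer to the truth than the
unweighted one, and whether the design-weighted pipeline (weighted
model + population-weighted prediction) beats the design-ignorant one.
Writes results/design_effect_study.csv.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from svybias import (
    ModelSpec,
    SimConfig,
    cluster_rates,
    draw_two_stage_sample,
    fit_logit,
    generate_population,
    population_rate,
    predict_rate_population_weighted,
    predict_rate_unweighted,
)
from svybias.io import write_table

OUT = Path(__file__).resolve().parents[1] / "results"
REPS = 100

SPEC = ModelSpec(covariates={"sex": ("male", "female"), "residence": ("urban", "rural")})
WSPEC = dataclasses.replace(SPEC, weighting="pseudo_likelihood")
MARGINAL = ModelSpec(covariates={"sex": ("male", "female")})
MARGINAL_W = dataclasses.replace(MARGINAL, weighting="pseudo_likelihood")


def main() -> None:
    rows = []
    for r in range(REPS):
        cfg = SimConfig(cluster_effect_sd=0.7, informativeness=1.0, seed=100_000 + r)
        pop = generate_population(cfg)
        sample, clusters = draw_two_stage_sample(pop, cfg)
        truth = population_rate(pop)
        b0 = cfg.true_coefficients["intercept"]

        unw_i = fit_logit(sample, MARGINAL).params["intercept"]
        wtd_i = fit_logit(sample, MARGINAL_W).params["intercept"]
        ignorant = predict_rate_unweighted(fit_logit(sample, SPEC), sample)
        aware = predict_rate_population_weighted(
            cluster_rates(fit_logit(sample, WSPEC), sample), clusters
        )
        rows.append(
            {
                "replicate": r,
                "population_rate": truth,
                "unweighted_rate_bias": sample["y"].mean() - truth,
                "weighted_rate_bias": np.average(sample["y"], weights=sample["weight"])
                - truth,
                "unweighted_intercept_error": unw_i - b0,
                "weighted_intercept_error": wtd_i - b0,
                "ignorant_prediction_bias": ignorant.estimate - truth,
                "aware_prediction_bias": aware.estimate - truth,
            }
        )
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    write_table(table, OUT / "design_effect_study.csv", {"reps": REPS}, 100_000)

    intercept_wins = (
        table["weighted_intercept_error"].abs() < table["unweighted_intercept_error"].abs()
    ).mean()
    prediction_wins = (
        table["aware_prediction_bias"].abs() < table["ignorant_prediction_bias"].abs()
    ).mean()
    with pd.option_context("display.width", 160, "display.max_columns", 20):
        print(table.drop(columns="replicate").describe().loc[["mean", "std"]].round(4))
    print(
        f"\nweighted intercept closer to truth in {100*intercept_wins:.0f}% of "
        f"{REPS} replicates; design-weighted prediction closer in "
        f"{100*prediction_wins:.0f}%"
    )
    print(
        "Ignoring the design inflates the estimated rate (high-mortality "
        "clusters are over-sampled); the N_c/n_c weights remove almost all "
        "of that bias."
    )


if __name__ == "__main__":
    main()
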