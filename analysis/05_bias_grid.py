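"""Run the sample-fraction x weighting bias grid on the simulated survey.

Reads results/sample.csv and results/clusters.csv, regenerates the
population to know the true rate, and runs the full grid: cluster
subsamples at 100/75/50/25%, model fitted unweighted and
pseudo-likelihood-weighted, rates predicted unweighted,
cluster-weighted, and population-weighted.  Writes results/bias_grid.csv
and prints the formatted table.
"""

from pathlib import Path

from svybias import (
    ExperimentConfig,
    ModelSpec,
    SimConfig,
    format_results_table,
    generate_population,
    population_rate,
    run_bias_grid,
)
from svybias.io import read_table, write_table

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1

SPEC = ModelSpec(covariates={"sex": ("male", "female"), "residence": ("urban", "rural")})


def main() -> None:
    sample = read_table(OUT / "sample.csv")
    clusters = read_table(OUT / "clusters.csv")
    truth = population_rate(generate_population(SimConfig(seed=SEED)))

    config = ExperimentConfig(
        spec=SPEC,
        reference_rate=truth,
        seed=SEED,
        include_population_weighted=True,
    )
    rows = run_bias_grid(sample, clusters, config)
    print(f"reference (population) rate: {truth:.4f}\n")
    print(format_results_table(rows))
    write_table(rows, OUT / "bias_grid.csv", config.spec, SEED)


if __name__ == "__main__":
    main()
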