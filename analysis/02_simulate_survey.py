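"""Generate the synthetic census frame and draw the two-stage survey sample.

Uses the package defaults: 500 equally sized clusters of 120 children
(15% urban), a logistic outcome model with cluster random intercepts
(SD 0.5) giving a population under-five death rate near 9%, and a
stratified two-stage sample of 100 clusters with 12 children per urban
and 22 per rural cluster.  Writes results/sample.csv and
results/clusters.csv and prints the design summary.
"""

from pathlib import Path

from svybias import SimConfig, draw_two_stage_sample, generate_population, population_rate
from svybias.io import write_table

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    config = SimConfig(seed=SEED)
    pop = generate_population(config)
    sample, clusters = draw_two_stage_sample(pop, config)

    OUT.mkdir(exist_ok=True)
    write_table(sample, OUT / "sample.csv", config, SEED)
    write_table(clusters, OUT / "clusters.csv", config, SEED)

    rate = population_rate(pop)
    print(f"population: {len(pop):,} children in {config.n_clusters_total} clusters")
    print(f"population outcome rate: {rate:.4f}")
    print(f"sample: {len(sample):,} children in {len(clusters)} clusters")
    print(f"unweighted sample rate: {sample['y'].mean():.4f}")
    by_stratum = clusters.groupby("stratum")[["n_c"]].agg(["count", "mean"])
    print(by_stratum)
    print(
        "weights by stratum:",
        sample.groupby("stratum")["weight"].first().round(3).to_dict(),
    )
    print(f"wrote {OUT/'sample.csv'} and {OUT/'clusters.csv'}")


if __name__ == "__main__":
    main()
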