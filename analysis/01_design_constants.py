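"""Recompute the survey design constants from the printed census counts.

The 2018 census counted 2,552,406 under-five children in 18,772 equally
sized enumeration clusters; the 2008 census 2,370,011 children in
12,631 clusters.  From these the per-cluster populations N_c, example
child weights N_c/n_c, and the finite population correction factors of
each survey round are pure arithmetic.  Writes
results/design_constants.csv.
"""

from pathlib import Path

import pandas as pd

from svybias import child_weight, finite_population_correction, per_cluster_population

OUT = Path(__file__).resolve().parents[1] / "results"

FRAMES = {
    # survey year -> (census children, census clusters, children sampled)
    "2004": (2_370_011, 12_631, 10_914),
    "2010": (2_370_011, 12_631, 19_967),
    "2015-16": (2_552_406, 18_772, 17_286),
}


def main() -> None:
    rows = []
    for year, (children, clusters, sampled) in FRAMES.items():
        N_c = per_cluster_population(children, clusters)
        rows.append(
            {
                "survey": year,
                "census_children": children,
                "census_clusters": clusters,
                "children_sampled": sampled,
                "N_c": round(N_c, 3),
                "weight_if_one_child_sampled": round(child_weight(N_c, 1), 3),
                "weight_if_20_children_sampled": round(child_weight(N_c, 20), 3),
                "fpc": round(finite_population_correction(children, sampled), 4),
            }
        )
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "design_constants.csv", index=False)
    print(table.to_string(index=False))
    print(
        "\nEvery sampled child stands for N_c/n_c population children; the FPC "
        "factors are ~1, which is why they are reported but not applied."
    )


if __name__ == "__main__":
    main()
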