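#!/usr/bin/env python
"""Cross-dataset consensus: intersect differential sets and test significance.

The plus and minus gene sets of the four screened datasets are intersected
(all pairwise and higher-order subsets tabulated as Venn counts) and the
full four-way intersection is tested against 1,000 size-matched random
intersections. With the planted study this recovers the shared marker as
the sole plus-direction consensus gene at a permutation p far below 0.05.
"""

import json
from pathlib import Path

import pandas as pd

from gbmscreen.consensus import (
    DatasetSets,
    DifferentialSetFamily,
    permutation_intersection_p,
    venn_counts,
)

SCRATCH = Path("scratch/screen")
RESULTS = Path("results")
LABELS = ("DS1", "DS2", "DS3", "DS4")
SEED = 1
ALPHA = 0.05


def load_family() -> DifferentialSetFamily:
    sets = {}
    for label in LABELS:
        df = pd.read_csv(SCRATCH / f"{label}_screen_OS.tsv", sep="\t")
        tested = df[df["skip_reason"].fillna("") == ""]
        passing = tested[(tested["wald_p"] < ALPHA) & (tested["logrank_p"] < ALPHA)]
        sets[label] = DatasetSets(
            universe=set(tested["feature"]),
            plus_set=set(passing[passing["beta"] > 0]["feature"]),
            minus_set=set(passing[passing["beta"] < 0]["feature"]),
        )
    return DifferentialSetFamily(sets)


def main() -> None:
    family = load_family()
    out = {}
    for i, direction in enumerate(("plus", "minus")):
        rep = permutation_intersection_p(
            family, list(LABELS), direction, n_iterations=1000, seed=SEED + i
        )
        out[direction] = {
            "members": sorted(rep.members),
            "observed_size": rep.observed_size,
            "p_value": rep.p_value,
            "p_value_corrected": rep.p_value_corrected,
        }
        with open(RESULTS / f"venn_OS_{direction}.tsv", "w") as fh:
            fh.write("datasets\tintersection_size\n")
            for combo, size in sorted(venn_counts(family, direction).items()):
                fh.write("+".join(combo) + f"\t{size}\n")
        print(f"{direction}: 4-way intersection = {out[direction]['members']}, "
              f"permutation p = {rep.p_value:.3g}")
    (RESULTS / "consensus_OS.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
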