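#!/usr/bin/env python
"""Pathway-level screen: activation scores and their survival association.

A toy pathway collection is generated over the shared gene universe (40
random pathways of 10-25 members with mixed activator/repressor roles; one
"reporter" pathway concentrates on the planted marker). Per dataset the
quantile-normalized expression is converted to case-to-normal ratios, PAL
scores are computed and screened with the same tertile Cox/log-rank
procedure as genes, and the four-way plus/minus pathway intersections are
permutation-tested.
"""

import json
from pathlib import Path

import numpy as np

from gbmscreen.consensus import DatasetSets, DifferentialSetFamily, permutation_intersection_p
from gbmscreen.io_formats import Pathway, PathwayCollection, read_counts_matrix, read_survival_table, write_gmt
from gbmscreen.pathway_activation import case_to_normal_ratio, pal_scores, screen_pathways
from gbmscreen.preprocess import quantile_normalize
from gbmscreen.survival_stats import ScreenConfig, screened_universe, select_differential

STUDY = Path("scratch/study")
RESULTS = Path("results")
LABELS = ("DS1", "DS2", "DS3", "DS4")
SEED = 1
MARKER = "GS00001"


def toy_pathways(rng: np.random.Generator) -> PathwayCollection:
    shared = [f"GS{i + 1:05d}" for i in range(1000)]
    pathways = []
    for k in range(40):
        size = int(rng.integers(10, 26))
        members = rng.choice(shared, size, replace=False)
        roles = rng.choice([1.0, -1.0], size, p=[0.8, 0.2])
        pathways.append(Pathway(f"PW{k:03d}", f"random pathway {k}", dict(zip(members, roles))))
    # reporter pathway: the marker plus a few passengers, all activators
    passengers = [g for g in rng.choice(shared[1:], 9, replace=False)]
    pathways.append(Pathway("PW_MARKER", "marker reporter", {MARKER: 1.0, **{g: 1.0 for g in passengers}}))
    return PathwayCollection(pathways)


def main() -> None:
    rng = np.random.default_rng(SEED)
    collection = toy_pathways(rng)
    write_gmt(collection, RESULTS / "toy_pathways.gmt")
    config = ScreenConfig()
    sets = {}
    counts = {}
    for label in LABELS:
        matrix = quantile_normalize(read_counts_matrix(STUDY / f"{label}_counts.tsv", label))
        survival = read_survival_table(STUDY / f"{label}_os.tsv", "OS")
        pal = pal_scores(case_to_normal_ratio(matrix), collection, min_genes=10)
        results = screen_pathways(pal, survival, config)
        plus, minus = select_differential(results, config)
        sets[label] = DatasetSets(screened_universe(results), plus, minus)
        counts[label] = {"scored": len(pal.pathway_ids), "plus": len(plus), "minus": len(minus)}
        print(f"{label}: {counts[label]['scored']} pathways scored, "
              f"{counts[label]['plus']} plus / {counts[label]['minus']} minus")
    family = DifferentialSetFamily(sets)
    out = {"per_dataset": counts}
    for i, direction in enumerate(("plus", "minus")):
        rep = permutation_intersection_p(family, list(LABELS), direction, 1000, seed=SEED + i)
        out[direction] = {
            "members": sorted(rep.members),
            "observed_size": rep.observed_size,
            "p_value": rep.p_value,
        }
        print(f"{direction}: 4-way pathway intersection = {out[direction]['members']}, "
              f"p = {rep.p_value:.3g}")
    (RESULTS / "pathway_consensus_OS.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
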