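#!/usr/bin/env python
"""Over-representation analysis of the consensus gene set.

The plus-direction consensus members from the gene-level intersection are
tested against a generated flat term database (one term per block of the
shared universe, plus a compact term containing the planted marker) with
hypergeometric tails and Benjamini-Hochberg FDR. The background universe is
the intersection of the datasets' screened universes, matching the pool the
screen selected from.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gbmscreen.enrichment import hypergeometric_enrichment, significant_terms
from gbmscreen.io_formats import Pathway, PathwayCollection, write_gmt

SCRATCH = Path("scratch/screen")
RESULTS = Path("results")
LABELS = ("DS1", "DS2", "DS3", "DS4")
SEED = 1
MARKER = "GS00001"


def toy_terms(rng: np.random.Generator) -> PathwayCollection:
    shared = [f"GS{i + 1:05d}" for i in range(1000)]
    terms = [
        Pathway(f"TERM{k:03d}", f"random term {k}",
                {g: 1.0 for g in rng.choice(shared, int(rng.integers(15, 60)), replace=False)})
        for k in range(10)
    ]
    terms.append(Pathway("TERM_MARKER", "marker module", {MARKER: 1.0, shared[500]: 1.0, shared[501]: 1.0}))
    return PathwayCollection(terms)


def main() -> None:
    universes = []
    for label in LABELS:
        df = pd.read_csv(SCRATCH / f"{label}_screen_OS.tsv", sep="\t")
        universes.append(set(df[df["skip_reason"].fillna("") == ""]["feature"]))
    universe = set.intersection(*universes)
    consensus = json.loads((RESULTS / "consensus_OS.json").read_text())
    query = set(consensus["plus"]["members"]) & universe
    if not query:
        print("no plus-direction consensus members; nothing to enrich")
        return
    terms = toy_terms(np.random.default_rng(SEED))
    write_gmt(terms, RESULTS / "toy_terms.gmt")
    results = hypergeometric_enrichment(query, terms, universe)
    sig = significant_terms(results, threshold=0.05)
    with open(RESULTS / "enrichment_OS_plus.tsv", "w") as fh:
        fh.write("term_id\tterm_size\tquery_size\toverlap\tp_value\tq_value\n")
        for r in sig:
            fh.write(f"{r.term_id}\t{r.term_size}\t{r.query_size}\t{r.overlap}"
                     f"\t{r.p_value:.6g}\t{r.q_value:.6g}\n")
    print(f"query of {len(query)} consensus genes against {len(terms)} terms "
          f"over a universe of {len(universe)}: {len(sig)} significant terms")
    for r in sig:
        print(f"  {r.term_id}: overlap {r.overlap}/{r.term_size}, q = {r.q_value:.3g}")


if __name__ == "__main__":
    main()
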