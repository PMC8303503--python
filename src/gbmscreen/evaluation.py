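"""Measurement harnesses that exercise the pipeline end to end.

These functions recompute, from scratch, the quantities used to judge the
package: the printed cohort numbers from the packaged tables, agreement of
the Cox fit / log-rank test / BH adjustment with independent oracles,
agreement of the permutation intersection test with its exact
hypergeometric tail, and recovery/calibration rates of the full screen on
synthetic multi-dataset studies. Both the acceptance script and the
acceptance tests run them; every number they return is computed at call
time.
"""

from __future__ import annotations

import numpy as np

from .cohort_summary import (
    DEFAULT_OS_RANGE,
    DEFAULT_PFS_RANGE,
    summarize_cohort,
    summarize_readstats,
)
from .consensus import (
    DatasetSets,
    DifferentialSetFamily,
    exact_two_set_p,
    intersect_sets,
    permutation_intersection_p,
)
from .io_formats import load_fixture
from .preprocess import log_transform, quantile_normalize
from .survival_stats import (
    ScreenConfig,
    cox_binary_fit,
    logrank_test,
    screen_features,
    screened_universe,
    select_differential,
)
from .synthetic_data import PlantedMarker, SyntheticConfig, generate_study

#: Study conditions of the synthetic benchmark: four datasets of 2,000
#: genes x 200 samples, one marker at beta = 1 shared by all datasets.
BENCHMARK_MARKER = "GS00001"


def benchmark_config(seed: int, planted: bool) -> SyntheticConfig:
    markers = (PlantedMarker(BENCHMARK_MARKER, 1.0, "all"),) if planted else ()
    return SyntheticConfig(planted_markers=markers, seed=seed)


# ---------------------------------------------------------------------------
# In-paper cohort numbers
# ---------------------------------------------------------------------------


def cohort_numbers() -> dict[str, float]:
    """Summary statistics of the packaged clinical and sequencing tables."""
    cohort = summarize_cohort(
        load_fixture("table1_clinical"), os_range=DEFAULT_OS_RANGE, pfs_range=DEFAULT_PFS_RANGE
    )
    reads = summarize_readstats(load_fixture("table2_readstats"))
    return {
        "n_patients": cohort.n_patients,
        "age_mean": round(cohort.age_mean, 2),
        "pct_male": round(cohort.pct_male, 2),
        "kps_min": cohort.kps_min,
        "kps_median": cohort.kps_median,
        "os_n": cohort.os_n,
        "os_mean": round(cohort.os_mean, 1),
        "pfs_n": cohort.pfs_n,
        "pfs_mean": round(cohort.pfs_mean, 1),
        "n_libraries": reads.n_libraries,
        "reads_total_mean": round(reads.total_mean, 2),
        "reads_mapped_mean": round(reads.mapped_mean, 2),
    }


# ---------------------------------------------------------------------------
# Oracle agreement: Cox fit, log-rank, BH
# ---------------------------------------------------------------------------


def _naive_log_partial_likelihood(beta: float, t, e, x) -> float:
    """Direct product-form partial likelihood; independent of the fitter."""
    ll = 0.0
    for i in range(len(t)):
        if e[i]:
            denom = sum(np.exp(beta * x[j]) for j in range(len(t)) if t[j] >= t[i])
            ll += beta * x[i] - np.log(denom)
    return ll


def _grid_search_beta(t, e, x, lo=-6.0, hi=6.0) -> float:
    coarse = np.linspace(lo, hi, 2401)
    b0 = coarse[int(np.argmax([_naive_log_partial_likelihood(b, t, e, x) for b in coarse]))]
    fine = np.linspace(b0 - 0.01, b0 + 0.01, 801)
    return float(fine[int(np.argmax([_naive_log_partial_likelihood(b, t, e, x) for b in fine]))])


def cox_grid_oracle_check(n_instances: int = 60, seed: int = 0) -> dict[str, float]:
    """Max |beta - grid-search beta| over random no-tie instances with <= 8 records."""
    import pandas as pd

    from .io_formats import SurvivalTable

    rng = np.random.default_rng(seed)
    worst = 0.0
    checked = 0
    attempts = 0
    while checked < n_instances and attempts < 50 * n_instances:
        attempts += 1
        n = int(rng.integers(4, 9))
        t = np.round(rng.uniform(1, 100, n), 3)
        e = rng.integers(0, 2, n)
        x = rng.integers(0, 2, n)
        if len(np.unique(t)) < n or e.sum() == 0 or x.min() == x.max():
            continue
        labels = {f"s{i}": int(v) for i, v in enumerate(x)}
        sv = SurvivalTable(
            pd.DataFrame({"sample_id": list(labels), "time": t, "event": e}), endpoint="OS"
        )
        beta, _, _ = cox_binary_fit(labels, sv)
        if np.isnan(beta):  # monotone likelihood: the oracle diverges too
            continue
        worst = max(worst, abs(beta - _grid_search_beta(t, e, x)))
        checked += 1
    return {"max_abs_delta_beta": worst, "n_instances": checked}


def logrank_hand_examples_check() -> dict[str, float]:
    """Exact agreement with hand-tallied hypergeometric log-rank examples."""
    import pandas as pd

    from .io_formats import SurvivalTable

    def stat(times, events, labels):
        sv = SurvivalTable(
            pd.DataFrame(
                {"sample_id": [f"s{i}" for i in range(len(times))], "time": times, "event": events}
            ),
            endpoint="OS",
        )
        return logrank_test({f"s{i}": v for i, v in enumerate(labels)}, sv)[0]

    errors = [
        abs(stat([1, 3, 2, 4], [1, 1, 1, 1], [1, 1, 0, 0]) - 8 / 13),
        abs(stat([1, 2], [1, 0], [1, 0]) - 1.0),
        abs(stat([1, 2, 1, 2], [1, 1, 1, 1], [1, 1, 0, 0]) - 0.0),
    ]
    return {"max_abs_error": float(max(errors)), "n_examples": len(errors)}


def bh_reference_check(n_vectors: int = 100, seed: int = 0) -> dict[str, float]:
    """Max |q - statsmodels fdr_bh q| over random p-value vectors."""
    from statsmodels.stats.multitest import multipletests

    from .enrichment import bh_adjust

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.random(int(rng.integers(1, 50)))
        ours = bh_adjust(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        worst = max(worst, float(np.max(np.abs(ours - ref))))
    return {"max_abs_delta_q": worst, "n_vectors": n_vectors}


# ---------------------------------------------------------------------------
# Permutation test vs exact hypergeometric tail
# ---------------------------------------------------------------------------

#: (universe sizes, shared size, set sizes, observed overlap) configurations
PERMUTATION_GRID = [
    ((10, 10), 10, (5, 5), 5),
    ((10, 10), 10, (5, 5), 3),
    ((30, 30), 30, (10, 8), 3),
    ((40, 40), 40, (12, 12), 4),
    ((25, 20), 12, (8, 7), 3),
    ((50, 45), 30, (15, 10), 5),
]


def _two_set_family(universe_sizes, shared, set_sizes, observed) -> DifferentialSetFamily:
    (u1, u2), (k1, k2) = universe_sizes, set_sizes
    ua = [f"a{i}" for i in range(u1 - shared)] + [f"s{i}" for i in range(shared)]
    ub = [f"b{i}" for i in range(u2 - shared)] + [f"s{i}" for i in range(shared)]
    a = {f"s{i}" for i in range(observed)}
    b = set(a)
    # pad each set to its size without creating further overlap
    extra_a = [x for x in ua if x not in a and x not in b][: k1 - observed]
    a |= set(extra_a)
    extra_b = [x for x in ub if x not in a and x not in b][: k2 - observed]
    b |= set(extra_b)
    assert len(a) == k1 and len(b) == k2 and len(a & b) == observed
    return DifferentialSetFamily(
        {
            "A": DatasetSets(set(ua), a, set()),
            "B": DatasetSets(set(ub), b, set()),
        }
    )


def permutation_exact_agreement(n_iterations: int = 10_000, seed: int = 0) -> dict[str, float]:
    """Max z-score of |permutation p - exact tail| over the benchmark grid."""
    worst_z = 0.0
    worst_abs = 0.0
    for i, (universes, shared, sizes, observed) in enumerate(PERMUTATION_GRID):
        fam = _two_set_family(universes, shared, sizes, observed)
        rep = permutation_intersection_p(fam, ["A", "B"], "plus", n_iterations, seed=seed + i)
        exact = exact_two_set_p(universes, sizes, shared, observed)
        sd = max(np.sqrt(exact * (1 - exact) / n_iterations), 1e-12)
        worst_z = max(worst_z, abs(rep.p_value - exact) / sd)
        worst_abs = max(worst_abs, abs(rep.p_value - exact))
    return {
        "max_abs_z": worst_z,
        "max_abs_delta_p": worst_abs,
        "n_configs": len(PERMUTATION_GRID),
        "n_iterations": n_iterations,
    }


# ---------------------------------------------------------------------------
# Synthetic-study benchmarks: recovery and null calibration
# ---------------------------------------------------------------------------


def _screen_study(study, config: ScreenConfig):
    """OS screen of every dataset; returns results and differential families."""
    sets = {}
    results = {}
    for ds in study.datasets:
        matrix = log_transform(quantile_normalize(ds.counts))
        res = screen_features(matrix, ds.os, config)
        plus, minus = select_differential(res, config)
        label = ds.counts.dataset_label
        results[label] = res
        sets[label] = DatasetSets(universe=screened_universe(res), plus_set=plus, minus_set=minus)
    return results, DifferentialSetFamily(sets)


def consensus_recovery(n_seeds: int = 20, seed: int = 0, n_iterations: int = 1000) -> dict:
    """Fraction of studies where the planted marker is the sole plus consensus."""
    config = ScreenConfig()
    sole = 0
    recovered = 0
    p_values = []
    for i in range(n_seeds):
        study = generate_study(benchmark_config(seed=seed + i, planted=True))
        _, family = _screen_study(study, config)
        members = intersect_sets(family, family.labels, "plus")
        rep = permutation_intersection_p(
            family, family.labels, "plus", n_iterations, seed=seed + i
        )
        p_values.append(rep.p_value)
        if BENCHMARK_MARKER in members:
            recovered += 1
        if members == {BENCHMARK_MARKER}:
            sole += 1
    return {
        "sole_member_fraction": sole / n_seeds,
        "recovered_fraction": recovered / n_seeds,
        "median_p_value": float(np.median(p_values)),
        "n_seeds": n_seeds,
    }


def null_calibration(n_seeds: int = 20, seed: int = 0, n_iterations: int = 1000) -> dict:
    """Dual-filter pass rate and consensus p under an all-null study."""
    config = ScreenConfig()
    per_dataset_rates: dict[str, list[float]] = {}
    p_above = 0
    for i in range(n_seeds):
        study = generate_study(benchmark_config(seed=seed + i, planted=False))
        results, family = _screen_study(study, config)
        for label, res in results.items():
            tested = [r for r in res if r.skip_reason is None and r.converged]
            rate = float(
                np.mean([(r.wald_p < config.alpha) and (r.logrank_p < config.alpha) for r in tested])
            )
            per_dataset_rates.setdefault(label, []).append(rate)
        rep = permutation_intersection_p(
            family, family.labels, "plus", n_iterations, seed=seed + i
        )
        if rep.p_value > 0.05:
            p_above += 1
    mean_rates = {label: float(np.mean(v)) for label, v in per_dataset_rates.items()}
    all_rates = [r for v in per_dataset_rates.values() for r in v]
    return {
        "mean_pass_rate_per_dataset": mean_rates,
        "max_mean_pass_rate": max(mean_rates.values()),
        "overall_pass_rate": float(np.mean(all_rates)),
        # binomial MC resolution of the overall rate estimate
        "pass_rate_mc_sd": float(np.sqrt(0.05 * 0.95 / (len(all_rates) * 2000))),
        "consensus_p_above_alpha_fraction": p_above / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Normalization / PAL invariants
# ---------------------------------------------------------------------------


def normalization_invariants(seed: int = 0) -> dict[str, float]:
    """Deviations from the quantile-normalization and PAL identities."""
    from .io_formats import GeneExpressionMatrix, Pathway, PathwayCollection
    from .pathway_activation import CNRMatrix, pal_scores

    rng = np.random.default_rng(seed)
    n_genes, n_samples = 400, 30
    # tie-free columns: distinct values within every sample
    vals = np.column_stack(
        [
            rng.choice(10 * n_genes, n_genes, replace=False) * rng.uniform(0.5, 2.0)
            for _ in range(n_samples)
        ]
    )
    m = GeneExpressionMatrix(
        [f"g{i}" for i in range(n_genes)], [f"s{j}" for j in range(n_samples)], vals, "bench"
    )
    once = quantile_normalize(m)
    sorted_cols = np.sort(once.values, axis=0)
    col_dev = float(np.max(np.abs(sorted_cols - sorted_cols[:, [0]])))
    twice = quantile_normalize(
        GeneExpressionMatrix(once.gene_ids, once.sample_ids, once.values, "bench")
    )
    idem_dev = float(np.max(np.abs(twice.values - once.values)))

    genes = [f"g{i}" for i in range(12)]
    cnr_flat = CNRMatrix(genes, [f"s{j}" for j in range(5)], np.ones((12, 5)))
    fwd = PathwayCollection([Pathway("P", "P", {g: (1.0 if i % 2 else -1.0) for i, g in enumerate(genes)})])
    rev = PathwayCollection([Pathway("P", "P", {g: (-1.0 if i % 2 else 1.0) for i, g in enumerate(genes)})])
    flat_pal = pal_scores(cnr_flat, fwd, min_genes=1)
    flat_dev = float(np.max(np.abs(flat_pal.values)))
    cnr_rand = CNRMatrix(genes, [f"s{j}" for j in range(5)], np.exp(rng.normal(0, 1, (12, 5))))
    p_fwd = pal_scores(cnr_rand, fwd, min_genes=1)
    p_rev = pal_scores(cnr_rand, rev, min_genes=1)
    antisym_dev = float(np.max(np.abs(p_fwd.values + p_rev.values)))

    return {
        "qn_column_distribution_max_delta": col_dev,
        "qn_idempotence_max_delta": idem_dev,
        "pal_flat_input_max_abs": flat_dev,
        "pal_role_flip_antisymmetry_max_delta": antisym_dev,
    }
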