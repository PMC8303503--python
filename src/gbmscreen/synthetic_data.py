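"""Synthetic multi-dataset survival studies with planted expression markers.

The generator emulates the statistical structure the screen assumes: several
expression datasets with distinct batch structure, negative-binomial counts
with lognormal gene-level means, and survival times from an exponential
proportional-hazards model in which a configurable set of planted genes
modulates the hazard through their standardized log(1 + count) values. A
marker planted in all datasets plays the role of a shared ("consensus")
biomarker; everything else is null.

Defaults describe a glioblastoma-sized study: four datasets of 200 samples
and 2,000 genes each, baseline hazard 0.05 events/month (median survival
about 14 months) and uniform censoring over five years of follow-up
(about two-thirds of records end in an observed event).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneExpressionMatrix, SurvivalTable, ValidationError
from .survival_stats import GeneSurvivalResult, ScreenConfig


class ConfigError(ValueError):
    """Invalid synthetic-study configuration."""


@dataclass(frozen=True)
class PlantedMarker:
    """A gene whose expression modulates the hazard.

    ``beta`` is the log hazard ratio per standard deviation of the gene's
    log(1 + count) value; ``datasets`` is a tuple of dataset labels or
    ``"all"``.
    """

    gene_id: str
    beta: float
    datasets: tuple[str, ...] | str = "all"


@dataclass
class SyntheticConfig:
    n_datasets: int = 4
    genes_per_dataset: int = 2000
    samples_per_dataset: tuple[int, ...] = (200, 200, 200, 200)
    shared_gene_fraction: float = 0.5
    planted_markers: tuple[PlantedMarker, ...] = ()
    baseline_hazard: float = 0.05  # events per month
    censoring_time_max: float = 60.0  # months
    batch_shift_sd: float = 0.5  # SD of per-dataset, per-gene log-mean shift
    nb_dispersion: float = 10.0  # NB size parameter; var = m + m^2 / size
    mean_log_expression_sd: float = 1.0  # SD of gene-level log means
    base_log_mean: float = math.log(100.0)  # typical gene mean count
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 1 or self.genes_per_dataset < 1:
            raise ConfigError("need >= 1 dataset and >= 1 gene")
        if len(self.samples_per_dataset) != self.n_datasets:
            raise ConfigError("samples_per_dataset length must equal n_datasets")
        if any(n < 1 for n in self.samples_per_dataset):
            raise ConfigError("every dataset needs >= 1 sample")
        if not 0.0 <= self.shared_gene_fraction <= 1.0:
            raise ConfigError("shared_gene_fraction must be in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if self.censoring_time_max <= 0:
            raise ConfigError("censoring_time_max must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")


def dataset_labels(config: SyntheticConfig) -> list[str]:
    return [f"DS{i + 1}" for i in range(config.n_datasets)]


def shared_gene_ids(config: SyntheticConfig) -> list[str]:
    n_shared = round(config.shared_gene_fraction * config.genes_per_dataset)
    return [f"GS{i + 1:05d}" for i in range(n_shared)]


@dataclass
class SyntheticDataset:
    counts: GeneExpressionMatrix
    os: SurvivalTable
    pfs: SurvivalTable


@dataclass
class SyntheticStudy:
    datasets: list[SyntheticDataset]
    #: gene_id -> (beta, tuple of dataset labels the marker was planted in)
    truth: dict[str, tuple[float, tuple[str, ...]]]
    config: SyntheticConfig

    @property
    def labels(self) -> list[str]:
        return [d.counts.dataset_label for d in self.datasets]


def _survival_from_hazard(
    rng: np.random.Generator,
    hazard: np.ndarray,
    censor_max: float,
    sample_ids: Sequence[str],
    endpoint: str,
) -> SurvivalTable:
    event_time = rng.exponential(1.0 / hazard)
    censor_time = (1.0 - rng.random(len(hazard))) * censor_max  # in (0, max]
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return SurvivalTable(
        pd.DataFrame({"sample_id": list(sample_ids), "time": time, "event": event}),
        endpoint=endpoint,
    )


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Draw a full multi-dataset study, reproducible from ``config.seed``.

    Counts are negative-binomial with lognormal gene means; a per-dataset,
    per-gene Gaussian shift on the log mean creates batch structure. OS and
    PFS are drawn independently from exponential proportional-hazards
    models; the PFS time scale is 0.7x the OS scale (progression precedes
    death on average).
    """
    rng = np.random.default_rng(config.seed)
    labels = dataset_labels(config)
    shared = shared_gene_ids(config)
    n_specific = config.genes_per_dataset - len(shared)

    # gene universe and planted-marker validation per dataset
    gene_ids_by_ds: dict[str, list[str]] = {}
    for d, label in enumerate(labels):
        specific = [f"{label}_G{i + 1:05d}" for i in range(n_specific)]
        gene_ids_by_ds[label] = shared + specific

    truth: dict[str, tuple[float, tuple[str, ...]]] = {}
    planted_by_ds: dict[str, list[PlantedMarker]] = {label: [] for label in labels}
    for marker in config.planted_markers:
        targets = tuple(labels) if marker.datasets == "all" else tuple(marker.datasets)
        for label in targets:
            if label not in gene_ids_by_ds:
                raise ConfigError(f"unknown dataset label {label!r} for marker {marker.gene_id}")
            if marker.gene_id not in gene_ids_by_ds[label]:
                raise ConfigError(
                    f"planted gene {marker.gene_id!r} is not in dataset {label}'s gene universe"
                )
            planted_by_ds[label].append(marker)
        truth[marker.gene_id] = (marker.beta, targets)

    # shared genes keep one log-mean across datasets so batch shifts are the
    # only systematic between-dataset difference
    shared_mu = config.base_log_mean + rng.normal(0.0, config.mean_log_expression_sd, len(shared))

    datasets: list[SyntheticDataset] = []
    for d, label in enumerate(labels):
        n_s = config.samples_per_dataset[d]
        gene_ids = gene_ids_by_ds[label]
        specific_mu = config.base_log_mean + rng.normal(
            0.0, config.mean_log_expression_sd, n_specific
        )
        mu = np.concatenate([shared_mu, specific_mu])
        shift = rng.normal(0.0, config.batch_shift_sd, len(gene_ids))
        mean = np.exp(mu + shift)[:, None]  # genes x 1
        # gamma-Poisson mixture == negative binomial with size = dispersion
        lam = rng.gamma(config.nb_dispersion, mean / config.nb_dispersion, (len(gene_ids), n_s))
        counts = rng.poisson(lam).astype(float)
        sample_ids = [f"{label}_S{i + 1:04d}" for i in range(n_s)]
        matrix = GeneExpressionMatrix(gene_ids, sample_ids, counts, label, scale="raw_counts")

        log_risk = np.zeros(n_s)
        row_of = {g: i for i, g in enumerate(gene_ids)}
        for marker in planted_by_ds[label]:
            logx = np.log1p(counts[row_of[marker.gene_id]])
            sd = logx.std()
            z = (logx - logx.mean()) / sd if sd > 0 else np.zeros(n_s)
            log_risk += marker.beta * z
        hazard_os = config.baseline_hazard * np.exp(log_risk)
        hazard_pfs = (config.baseline_hazard / 0.7) * np.exp(log_risk)
        os_table = _survival_from_hazard(rng, hazard_os, config.censoring_time_max, sample_ids, "OS")
        pfs_table = _survival_from_hazard(
            rng, hazard_pfs, config.censoring_time_max, sample_ids, "PFS"
        )
        datasets.append(SyntheticDataset(matrix, os_table, pfs_table))
    return SyntheticStudy(datasets=datasets, truth=truth, config=config)


def null_fraction_check(
    study: SyntheticStudy,
    screen_results: Mapping[str, Sequence[GeneSurvivalResult]] | Sequence[GeneSurvivalResult],
    config: ScreenConfig | None = None,
) -> float:
    """Fraction of screened features passing the dual p < alpha filter.

    Calibration harness: requires a study generated without planted
    markers, so the returned fraction estimates the screen's null pass
    rate (the dual criterion is conservative relative to a single test at
    the same alpha).
    """
    if study.truth:
        raise ValidationError("null_fraction_check requires a study with no planted markers")
    if isinstance(screen_results, Mapping):
        pooled: list[GeneSurvivalResult] = [r for rs in screen_results.values() for r in rs]
    else:
        pooled = list(screen_results)
    pooled = [r for r in pooled if r.skip_reason is None]
    if not pooled:
        raise ValidationError("no screened features to calibrate on")
    config = config or ScreenConfig()
    n_pass = sum(
        1
        for r in pooled
        if r.converged
        and not (np.isnan(r.wald_p) or np.isnan(r.logrank_p))
        and r.wald_p < config.alpha
        and r.logrank_p < config.alpha
    )
    return n_pass / len(pooled)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Write each dataset's counts and survival TSVs plus a truth JSON."""
    from .io_formats import write_counts_matrix, write_survival_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds in study.datasets:
        label = ds.counts.dataset_label
        write_counts_matrix(ds.counts, out / f"{label}_counts.tsv")
        write_survival_table(ds.os, out / f"{label}_os.tsv")
        write_survival_table(ds.pfs, out / f"{label}_pfs.tsv")
    truth = {g: {"beta": b, "datasets": list(ds)} for g, (b, ds) in study.truth.items()}
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
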