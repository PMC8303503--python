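"""End-to-end orchestration: preprocess -> screen -> consensus (-> PAL, enrichment).

``run_full`` executes the whole workflow on any number of datasets, writing
every intermediate as TSV plus a single JSON run report. Endpoints are
processed independently and per-dataset endpoint availability is
config-driven: a dataset without a PFS table simply sits out the PFS
consensus (with a log note), it does not abort the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .consensus import DifferentialSetFamily, DatasetSets, permutation_intersection_p, venn_counts
from .enrichment import hypergeometric_enrichment, significant_terms
from .io_formats import (
    ValidationError,
    read_counts_matrix,
    read_gmt,
    read_survival_table,
)
from .pathway_activation import case_to_normal_ratio, pal_scores, screen_pathways
from .preprocess import log_transform, quantile_normalize
from .survival_stats import (
    ScreenConfig,
    results_to_frame,
    screen_features,
    screened_universe,
    select_differential,
)

logger = logging.getLogger(__name__)

ENRICH_P_THRESHOLD = 0.05  # intersections with permutation p below this are enriched


@dataclass
class DatasetSpec:
    label: str
    counts_path: str
    survival_paths: dict[str, str]  # endpoint -> path


@dataclass
class RunConfig:
    datasets: list[DatasetSpec]
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    consensus_iterations: int = 1000
    seed: int = 0
    pathways_path: str | None = None
    min_genes: int = 10
    terms_path: str | None = None
    fdr: float = 0.05
    out_dir: str = "gbmscreen_run"

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValidationError("run config needs at least one dataset")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        datasets = [
            DatasetSpec(d["label"], d["counts"], dict(d.get("survival", {})))
            for d in raw["datasets"]
        ]
        screen = ScreenConfig(**raw.get("screen", {}))
        return cls(
            datasets=datasets,
            screen=screen,
            consensus_iterations=int(raw.get("consensus_iterations", 1000)),
            seed=int(raw.get("seed", 0)),
            pathways_path=raw.get("pathways"),
            min_genes=int(raw.get("min_genes", 10)),
            terms_path=raw.get("terms"),
            fdr=float(raw.get("fdr", 0.05)),
            out_dir=raw.get("out_dir", "gbmscreen_run"),
        )


@dataclass
class RunReport:
    version: str
    seed: int
    timestamp: str
    differential_counts: dict  # endpoint -> label -> {"plus": n, "minus": n}
    intersections: dict  # "genes"/"pathways" -> endpoint -> direction -> report dict
    consensus_members: dict  # endpoint -> direction -> sorted members (genes)
    pal_screen_counts: dict  # endpoint -> label -> {"plus": n, "minus": n}

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and dataset label."""

    def __init__(self, stage: str, label: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for dataset {label!r}: {cause}")
        self.stage = stage
        self.label = label


def _stage(stage: str, label: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with context
        raise StageError(stage, label, exc) from exc


def _consensus_block(
    families: dict[str, DifferentialSetFamily],
    iterations: int,
    seed: int,
    out_dir: Path,
    prefix: str,
):
    """Full-subset intersection + permutation p per endpoint and direction."""
    reports: dict = {}
    members: dict = {}
    offset = 0
    for endpoint, family in sorted(families.items()):
        if len(family.labels) < 2:
            logger.info("%s/%s: fewer than 2 datasets, consensus skipped", prefix, endpoint)
            continue
        reports[endpoint] = {}
        members[endpoint] = {}
        for direction in ("plus", "minus"):
            rep = permutation_intersection_p(
                family, family.labels, direction, n_iterations=iterations, seed=seed + offset
            )
            offset += 1
            reports[endpoint][direction] = {
                "datasets": list(rep.dataset_subset),
                "observed_size": rep.observed_size,
                "p_value": rep.p_value,
                "p_value_corrected": rep.p_value_corrected,
                "n_iterations": rep.n_iterations,
                "seed": rep.seed,
            }
            members[endpoint][direction] = sorted(rep.members)
            counts = venn_counts(family, direction)
            with open(out_dir / f"{prefix}_venn_{endpoint}_{direction}.tsv", "w") as fh:
                fh.write("datasets\tintersection_size\n")
                for combo, size in sorted(counts.items()):
                    fh.write("+".join(combo) + f"\t{size}\n")
    return reports, members


def run_full(config: RunConfig) -> RunReport:
    """Run the complete workflow and write all outputs under ``out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    differential_counts: dict = {}
    gene_families: dict[str, dict[str, DatasetSets]] = {}
    pal_families: dict[str, dict[str, DatasetSets]] = {}
    pal_counts: dict = {}

    pathways = read_gmt(config.pathways_path) if config.pathways_path else None

    for spec in config.datasets:
        label = spec.label
        logger.info("dataset %s: reading counts", label)
        counts = _stage("read_counts", label, read_counts_matrix, spec.counts_path, label)
        normalized = _stage("quantile_normalize", label, quantile_normalize, counts)
        logged = _stage("log_transform", label, log_transform, normalized)

        pal = None
        if pathways is not None:
            cnr = _stage("case_to_normal_ratio", label, case_to_normal_ratio, normalized)
            pal = _stage("pal_scores", label, pal_scores, cnr, pathways, config.min_genes)
            pal.to_frame().to_csv(out_dir / f"{label}_pal.tsv", sep="\t", float_format="%.10g")

        for endpoint, surv_path in sorted(spec.survival_paths.items()):
            survival = _stage("read_survival", label, read_survival_table, surv_path, endpoint)
            logger.info("dataset %s endpoint %s: screening %d genes", label, endpoint, logged.n_genes)
            results = _stage("screen_genes", label, screen_features, logged, survival, config.screen)
            results_to_frame(results).to_csv(
                out_dir / f"{label}_screen_{endpoint}.tsv", sep="\t", index=False, float_format="%.10g"
            )
            plus, minus = select_differential(results, config.screen)
            for direction, s in (("plus", plus), ("minus", minus)):
                (out_dir / f"{label}_{endpoint}_{direction}.txt").write_text(
                    "".join(f"{g}\n" for g in sorted(s))
                )
            differential_counts.setdefault(endpoint, {})[label] = {
                "plus": len(plus),
                "minus": len(minus),
            }
            gene_families.setdefault(endpoint, {})[label] = DatasetSets(
                universe=screened_universe(results), plus_set=plus, minus_set=minus
            )

            if pal is not None:
                pal_results = _stage("screen_pathways", label, screen_pathways, pal, survival, config.screen)
                results_to_frame(pal_results).to_csv(
                    out_dir / f"{label}_pal_screen_{endpoint}.tsv",
                    sep="\t",
                    index=False,
                    float_format="%.10g",
                )
                p_plus, p_minus = select_differential(pal_results, config.screen)
                pal_counts.setdefault(endpoint, {})[label] = {
                    "plus": len(p_plus),
                    "minus": len(p_minus),
                }
                pal_families.setdefault(endpoint, {})[label] = DatasetSets(
                    universe=screened_universe(pal_results), plus_set=p_plus, minus_set=p_minus
                )

    gene_fams = {ep: DifferentialSetFamily(sets) for ep, sets in gene_families.items()}
    gene_reports, consensus_members = _consensus_block(
        gene_fams, config.consensus_iterations, config.seed, out_dir, "genes"
    )
    intersections = {"genes": gene_reports}
    if pal_families:
        pal_fams = {ep: DifferentialSetFamily(sets) for ep, sets in pal_families.items()}
        pal_reports, _ = _consensus_block(
            pal_fams, config.consensus_iterations, config.seed + 1000, out_dir, "pathways"
        )
        intersections["pathways"] = pal_reports

    # enrichment of significant consensus gene sets against the term database
    if config.terms_path:
        terms = read_gmt(config.terms_path)
        for endpoint, by_dir in gene_reports.items():
            family = gene_fams[endpoint]
            universe = set.intersection(*(family[lb].universe for lb in family.labels))
            for direction, rep in by_dir.items():
                query = set(consensus_members[endpoint][direction])
                if rep["p_value"] >= ENRICH_P_THRESHOLD or not query:
                    continue
                enr = hypergeometric_enrichment(query & universe, terms, universe)
                sig = significant_terms(enr, config.fdr)
                with open(out_dir / f"enrichment_{endpoint}_{direction}.tsv", "w") as fh:
                    fh.write("term_id\tterm_size\tquery_size\toverlap\tp_value\tq_value\n")
                    for r in sig:
                        fh.write(
                            f"{r.term_id}\t{r.term_size}\t{r.query_size}\t{r.overlap}"
                            f"\t{r.p_value:.6g}\t{r.q_value:.6g}\n"
                        )

    report = RunReport(
        version=__version__,
        seed=config.seed,
        timestamp=datetime.now(timezone.utc).isoformat(),
        differential_counts=differential_counts,
        intersections=intersections,
        consensus_members=consensus_members,
        pal_screen_counts=pal_counts,
    )
    (out_dir / "run_report.json").write_text(report.to_json())
    return report
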