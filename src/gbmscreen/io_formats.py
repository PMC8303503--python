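"""Readers, writers and in-memory containers for the pipeline's external formats.

Expression matrices travel as TSV (genes in rows, first column gene ids,
header row of sample ids), survival tables as TSV with columns
``sample_id``, ``time``, ``event``, and gene sets / pathways as GMT.
The GMT dialect accepts an optional ``:+1`` / ``:-1`` suffix on each member
encoding its activator/repressor role weight (ARR); members without a
suffix default to activator (+1). Plain GMT therefore parses unchanged.

Two small clinical tables (patient characteristics and per-library read
statistics of the experimental glioblastoma cohort) ship with the package
and are available through :func:`load_fixture`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW_COUNTS = "raw_counts"
QUANTILE_NORMALIZED = "quantile_normalized"
LOG_TRANSFORMED = "log_transformed"
_SCALES = (RAW_COUNTS, QUANTILE_NORMALIZED, LOG_TRANSFORMED)

ENDPOINTS = ("OS", "PFS")

#: Free-text values in the clinical table that denote a missing measurement.
MISSING_MARKERS = ("/", "Not performed", "")


class ValidationError(ValueError):
    """Input data violates a container invariant."""


class IdentifierCollisionError(ValidationError):
    """Duplicate gene or sample identifiers in an input file."""


class GMTParseError(ValueError):
    """Malformed line in a GMT gene-set file."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class GeneExpressionMatrix:
    """A genes x samples numeric matrix with identifiers and a scale tag.

    Parameters
    ----------
    gene_ids, sample_ids:
        Unique row and column identifiers, in matrix order.
    values:
        Float array of shape ``(len(gene_ids), len(sample_ids))``. Raw
        counts must be non-negative.
    dataset_label:
        Name of the dataset/batch the matrix belongs to. Batches are
        analysed as separate datasets throughout the pipeline.
    scale:
        One of ``raw_counts``, ``quantile_normalized``, ``log_transformed``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    dataset_label: str
    scale: str = RAW_COUNTS

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in _SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise IdentifierCollisionError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IdentifierCollisionError("duplicate sample identifiers")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite expression values")
        if self.scale == RAW_COUNTS and np.any(self.values < 0):
            raise ValidationError("raw counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    # The survival screen works on any feature x sample matrix; expose a
    # scale-agnostic alias shared with PALMatrix.
    @property
    def feature_ids(self) -> list[str]:
        return self.gene_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def read_counts_matrix(path: str | Path, dataset_label: str) -> GeneExpressionMatrix:
    """Read a raw-counts TSV (gene ids in the first column, samples in the header)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        # pandas would silently mangle duplicate column names
        raise IdentifierCollisionError(f"{path}: duplicate sample identifiers in header")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValidationError(f"{path}: negative count values")
    return GeneExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
        dataset_label=dataset_label,
        scale=RAW_COUNTS,
    )


def write_counts_matrix(matrix: GeneExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with full float precision (round-trip exact)."""
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Survival tables
# ---------------------------------------------------------------------------


@dataclass
class SurvivalTable:
    """Right-censored time-to-event records for one endpoint (OS or PFS).

    ``time`` is months since diagnosis, strictly positive; ``event`` is 1
    when the event (death / progression) was observed and 0 when the record
    is censored.
    """

    data: pd.DataFrame  # columns: sample_id, time, event
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        df = self.data.loc[:, ["sample_id", "time", "event"]].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["time"] = df["time"].astype(float)
        df["event"] = df["event"].astype(int)
        if df["sample_id"].duplicated().any():
            raise IdentifierCollisionError("duplicate sample ids in survival table")
        if (df["time"] <= 0).any():
            raise ValidationError("survival times must be strictly positive")
        if not df["event"].isin((0, 1)).all():
            raise ValidationError("event flag must be 0 or 1")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def arrays_for(self, sample_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, events) aligned to ``sample_ids`` (all must be present)."""
        indexed = self.data.set_index("sample_id")
        sub = indexed.loc[list(sample_ids)]
        return sub["time"].to_numpy(), sub["event"].to_numpy()


def read_survival_table(path: str | Path, endpoint: str = "OS") -> SurvivalTable:
    """Read a survival TSV, dropping (and logging) rows with missing time/event."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip")
    missing = {"sample_id", "time", "event"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    complete = df.dropna(subset=["time", "event"])
    n_dropped = len(df) - len(complete)
    if n_dropped:
        logger.info("%s: dropped %d incomplete survival records", path, n_dropped)
    return SurvivalTable(complete, endpoint=endpoint)


def write_survival_table(table: SurvivalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Gene sets / pathways (GMT)
# ---------------------------------------------------------------------------


@dataclass
class Pathway:
    pathway_id: str
    name: str
    #: gene id -> signed role weight (ARR); +1 activator, -1 repressor.
    members: dict[str, float]


@dataclass
class PathwayCollection:
    """An ordered collection of gene sets with signed member role weights."""

    pathways: list[Pathway] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in self.pathways:
            if not p.members:
                raise ValidationError(f"pathway {p.pathway_id} has no members")
            if not all(np.isfinite(list(p.members.values()))):
                raise ValidationError(f"pathway {p.pathway_id}: non-finite role weight")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def ids(self) -> list[str]:
        return [p.pathway_id for p in self.pathways]


def _parse_member(token: str) -> tuple[str, float]:
    if ":" in token:
        gene, _, weight = token.rpartition(":")
        try:
            return gene, float(weight)
        except ValueError:
            pass  # a gene id containing ':' with no numeric suffix
    return token, 1.0


def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse a GMT file; member tokens may carry a ``:+1``/``:-1`` role suffix."""
    pathways: list[Pathway] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            members = dict(_parse_member(tok) for tok in fields[2:] if tok)
            pathways.append(Pathway(pathway_id=fields[0], name=fields[1], members=members))
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in collection:
            tokens = [f"{g}:{int(w):+d}" if w != 1.0 else g for g, w in p.members.items()]
            fh.write("\t".join([p.pathway_id, p.name, *tokens]) + "\n")


# ---------------------------------------------------------------------------
# Packaged clinical fixtures
# ---------------------------------------------------------------------------


@dataclass
class ClinicalTable:
    """Patient-level clinicopathological records of the experimental cohort.

    Missing values (encoded ``/`` or ``Not performed`` in the source) are
    mapped to NaN / <NA>, never to zero. Footnote markers on numeric values
    are stripped (the 90-month time-to-progression carries a ``*`` flagging
    progression recorded after the analysis).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not ((df["kps"] >= 0) & (df["kps"] <= 100)).all():
            raise ValidationError("KPS outside [0, 100]")
        if not (df["age_at_diagnosis"] > 0).all():
            raise ValidationError("non-positive age")
        if not df["sex"].isin(("M", "F")).all():
            raise ValidationError("sex must be M or F")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ReadStatsTable:
    """Per-library sequencing statistics (millions of reads)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not ((df["uniquely_mapped"] > 0) & (df["total_reads"] > 0)).all():
            raise ValidationError("read counts must be positive")
        if not (df["uniquely_mapped"] <= df["total_reads"]).all():
            raise ValidationError("uniquely mapped reads exceed total reads")

    def __len__(self) -> int:
        return len(self.data)


def _clean_numeric(series: pd.Series) -> pd.Series:
    """Strip footnote markers and map missing markers to NaN."""

    def conv(v):
        if pd.isna(v):
            return np.nan
        s = str(v).replace("*", "").strip()
        if s in MISSING_MARKERS:
            return np.nan
        return float(s)

    return series.map(conv)


def fixture_path(name: str) -> Path:
    return Path(str(resources.files("gbmscreen.data").joinpath(f"{name}.tsv")))


def load_fixture(name: str) -> ClinicalTable | ReadStatsTable:
    """Load a packaged table: ``table1_clinical`` or ``table2_readstats``."""
    if name == "table1_clinical":
        df = pd.read_csv(fixture_path(name), sep="\t", dtype=str)
        for col in ("age_at_diagnosis", "kps", "os_months", "ttp_months"):
            df[col] = _clean_numeric(df[col])
        for col in ("idh1_r132h", "atrx_loss", "p53", "adjuvant_therapy", "therapy"):
            df[col] = df[col].map(lambda v: pd.NA if str(v).strip() in MISSING_MARKERS else v)
        return ClinicalTable(df)
    if name == "table2_readstats":
        df = pd.read_csv(fixture_path(name), sep="\t", dtype={"sample_id": str, "library_id": str})
        return ReadStatsTable(df)
    raise KeyError(f"unknown fixture {name!r}; expected 'table1_clinical' or 'table2_readstats'")
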