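"""Cohort and sequencing summary statistics of the experimental tables.

The endpoint summaries accept optional inclusive ranges restricting which
OS / time-to-progression values enter the analysis set. The experimental
cohort's published analysis set is range-defined: OS over (2, 58) months
keeps 15 of 16 patients (one patient's 91-month OS falls outside), and
time-to-progression over (2, 37) keeps 14 (the 90-month progression was
recorded after the analysis; one patient has no progression record).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ClinicalTable, ReadStatsTable, ValidationError

#: Inclusive ranges reproducing the experimental cohort's analysis sets.
DEFAULT_OS_RANGE = (2.0, 58.0)
DEFAULT_PFS_RANGE = (2.0, 37.0)


@dataclass
class CohortSummary:
    n_patients: int
    n_male: int
    pct_male: float
    n_female: int
    pct_female: float
    age_mean: float
    age_min: float
    age_max: float
    kps_min: float
    kps_median: float
    os_n: int
    os_mean: float
    os_min: float
    os_max: float
    pfs_n: int
    pfs_mean: float
    pfs_min: float
    pfs_max: float

    def rounded(self) -> dict[str, float | int]:
        """Reporting view: floats rounded half-even to 2 decimals."""
        out = {}
        for k, v in self.__dict__.items():
            out[k] = round(float(v), 2) if isinstance(v, float) else v
        return out


@dataclass
class ReadStatsSummary:
    n_libraries: int
    total_mean: float
    total_min: float
    total_max: float
    mapped_mean: float
    mapped_min: float
    mapped_max: float

    def rounded(self) -> dict[str, float | int]:
        return {
            k: (round(float(v), 2) if isinstance(v, float) else v)
            for k, v in self.__dict__.items()
        }


def _endpoint_stats(values: np.ndarray, rng: tuple[float, float] | None):
    values = values[~np.isnan(values)]
    if rng is not None:
        lo, hi = rng
        values = values[(values >= lo) & (values <= hi)]
    if values.size == 0:
        return 0, np.nan, np.nan, np.nan
    return int(values.size), float(values.mean()), float(values.min()), float(values.max())


def summarize_cohort(
    table: ClinicalTable,
    os_range: tuple[float, float] | None = None,
    pfs_range: tuple[float, float] | None = None,
) -> CohortSummary:
    """Demographics, KPS and endpoint summaries of a clinical table.

    ``os_range`` / ``pfs_range`` restrict (inclusively) which non-missing
    values enter the OS / progression summaries; None keeps all.
    """
    df = table.data
    if len(df) == 0:
        raise ValidationError("empty clinical table")
    n = len(df)
    n_male = int((df["sex"] == "M").sum())
    n_female = int((df["sex"] == "F").sum())
    age = df["age_at_diagnosis"].to_numpy(dtype=float)
    kps = df["kps"].to_numpy(dtype=float)
    os_n, os_mean, os_min, os_max = _endpoint_stats(df["os_months"].to_numpy(dtype=float), os_range)
    pfs_n, pfs_mean, pfs_min, pfs_max = _endpoint_stats(
        df["ttp_months"].to_numpy(dtype=float), pfs_range
    )
    return CohortSummary(
        n_patients=n,
        n_male=n_male,
        pct_male=100.0 * n_male / n,
        n_female=n_female,
        pct_female=100.0 * n_female / n,
        age_mean=float(age.mean()),
        age_min=float(age.min()),
        age_max=float(age.max()),
        kps_min=float(kps.min()),
        kps_median=float(np.median(kps)),
        os_n=os_n,
        os_mean=os_mean,
        os_min=os_min,
        os_max=os_max,
        pfs_n=pfs_n,
        pfs_mean=pfs_mean,
        pfs_min=pfs_min,
        pfs_max=pfs_max,
    )


def summarize_readstats(table: ReadStatsTable) -> ReadStatsSummary:
    """Means and ranges of total and uniquely mapped reads (millions)."""
    df = table.data
    if len(df) == 0:
        raise ValidationError("empty read-statistics table")
    total = df["total_reads"].to_numpy(dtype=float)
    mapped = df["uniquely_mapped"].to_numpy(dtype=float)
    return ReadStatsSummary(
        n_libraries=len(df),
        total_mean=float(total.mean()),
        total_min=float(total.min()),
        total_max=float(total.max()),
        mapped_mean=float(mapped.mean()),
        mapped_min=float(mapped.min()),
        mapped_max=float(mapped.max()),
    )
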