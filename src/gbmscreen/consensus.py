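"""Cross-dataset intersections of differential sets and their permutation test.

The observed intersection of plus (or minus) sets across datasets is
compared against a size-matched random null: each iteration draws, for every
dataset, a uniform random subset of that dataset's screened universe with
the same cardinality as its observed differential set, and intersects them.
The p-value is the fraction of iterations whose random intersection is at
least as large as the observed one ("equal or higher"), so it can be 0 at
finite iteration counts; a (count + 1)/(n + 1) corrected value is carried
alongside for auditing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import ValidationError

_CHUNK = 2048  # iterations per vectorized block, caps memory


@dataclass
class DatasetSets:
    """One dataset's screened universe and its plus/minus differential sets."""

    universe: set[str]
    plus_set: set[str]
    minus_set: set[str]

    def __post_init__(self) -> None:
        if not (self.plus_set | self.minus_set) <= self.universe:
            raise ValidationError("differential sets must be subsets of the universe")
        if self.plus_set & self.minus_set:
            raise ValidationError("plus and minus sets must be disjoint")

    def direction(self, direction: str) -> set[str]:
        if direction not in ("plus", "minus"):
            raise ValidationError(f"unknown direction {direction!r}")
        return self.plus_set if direction == "plus" else self.minus_set


@dataclass
class DifferentialSetFamily:
    sets: dict[str, DatasetSets]

    def __getitem__(self, label: str) -> DatasetSets:
        try:
            return self.sets[label]
        except KeyError:
            raise KeyError(f"unknown dataset label {label!r}") from None

    @property
    def labels(self) -> list[str]:
        return list(self.sets)


@dataclass
class IntersectionReport:
    dataset_subset: tuple[str, ...]
    direction: str
    members: set[str]
    observed_size: int
    p_value: float
    p_value_corrected: float  # (count + 1) / (n + 1), auxiliary
    n_iterations: int
    seed: int


def intersect_sets(
    family: DifferentialSetFamily, subset: Sequence[str], direction: str
) -> set[str]:
    """Plain intersection of one direction's sets across >= 2 datasets."""
    if len(subset) < 2:
        raise ValidationError("need at least 2 datasets to intersect")
    sets = [family[label].direction(direction) for label in subset]
    return set.intersection(*sets)


def permutation_intersection_p(
    family: DifferentialSetFamily,
    subset: Sequence[str],
    direction: str,
    n_iterations: int = 1000,
    seed: int = 0,
) -> IntersectionReport:
    """Permutation significance of the observed intersection size.

    Each dataset's random subset is drawn from its own universe (universes
    may differ); the random intersection then lives on the shared universe
    exactly as the observed one does.
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    members = intersect_sets(family, subset, direction)
    observed = len(members)

    universes = [sorted(family[label].universe) for label in subset]
    set_sizes = [len(family[label].direction(direction)) for label in subset]
    union = sorted(set().union(*map(set, universes)))
    pos = {g: i for i, g in enumerate(union)}
    global_idx = [np.asarray([pos[g] for g in u], dtype=np.intp) for u in universes]

    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    while done < n_iterations:
        block = min(_CHUNK, n_iterations - done)
        inter = np.ones((block, len(union)), dtype=bool)
        for u_idx, k in zip(global_idx, set_sizes):
            mask = np.zeros((block, len(union)), dtype=bool)
            if k > 0:
                r = rng.random((block, len(u_idx)))
                sel = np.argpartition(r, k - 1, axis=1)[:, :k]
                rows = np.repeat(np.arange(block), k)
                mask[rows, u_idx[sel].ravel()] = True
            inter &= mask
        sizes = inter.sum(axis=1)
        count += int((sizes >= observed).sum())
        done += block
    return IntersectionReport(
        dataset_subset=tuple(subset),
        direction=direction,
        members=members,
        observed_size=observed,
        p_value=count / n_iterations,
        p_value_corrected=(count + 1) / (n_iterations + 1),
        n_iterations=n_iterations,
        seed=seed,
    )


def exact_two_set_p(
    universe_sizes: tuple[int, int],
    set_sizes: tuple[int, int],
    shared_universe_size: int,
    observed: int,
) -> float:
    """Closed-form P(overlap >= observed) for the two-dataset null.

    Set A is uniform over a universe of size U1, set B over U2, and the two
    universes share ``shared_universe_size`` features. Conditioning on how
    many members of each set fall in the shared region (hypergeometric),
    the overlap given those counts is hypergeometric on the shared region.
    Used as the independent oracle for :func:`permutation_intersection_p`.
    """
    u1, u2 = universe_sizes
    k1, k2 = set_sizes
    m = shared_universe_size
    if observed > min(k1, k2):
        raise ValidationError("observed overlap exceeds the smaller set size")
    if m > min(u1, u2) or k1 > u1 or k2 > u2:
        raise ValidationError("inconsistent sizes")
    if observed <= 0:
        return 1.0
    a_vals = np.arange(max(0, k1 - (u1 - m)), min(k1, m) + 1)
    b_vals = np.arange(max(0, k2 - (u2 - m)), min(k2, m) + 1)
    pa = stats.hypergeom.pmf(a_vals, u1, m, k1)
    pb = stats.hypergeom.pmf(b_vals, u2, m, k2)
    total = 0.0
    for a, wa in zip(a_vals, pa):
        # overlap | a, b ~ Hypergeom(M, a, b); tail at `observed`
        tails = stats.hypergeom.sf(observed - 1, m, a, b_vals)
        total += wa * float((pb * tails).sum())
    return float(min(total, 1.0))


def venn_counts(
    family: DifferentialSetFamily, direction: str
) -> dict[tuple[str, ...], int]:
    """Cardinality of every >= 2-way intersection (Venn table export)."""
    from itertools import combinations

    labels = family.labels
    out: dict[tuple[str, ...], int] = {}
    for r in range(2, len(labels) + 1):
        for combo in combinations(labels, r):
            out[combo] = len(intersect_sets(family, combo, direction))
    return out
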