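"""Pan-genome descriptive statistics.

Given a species x orthogroup count matrix these helpers compute the
universal families (present, i.e. count >= 1, in every species), the
single-copy core (exactly one copy in every species), per-species fractions
of predicted genes assigned to families, the family-size histogram (total
genes per family across all species) and its secondary mode, and simple
assignment-percentage arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

__all__ = [
    "CoreReport",
    "FamilySizeHistogram",
    "AssignmentStats",
    "core_report",
    "family_size_histogram",
    "assignment_stats",
]


@dataclass(frozen=True)
class CoreReport:
    universal_families: tuple
    single_copy_core: tuple
    per_species_assigned_fraction: Mapping[str, float] | None


@dataclass(frozen=True)
class FamilySizeHistogram:
    """Mapping family total size -> number of families with that total."""

    counts: Mapping[int, int]

    @property
    def n_families(self) -> int:
        return sum(self.counts.values())

    @property
    def total_genes(self) -> int:
        return sum(s * c for s, c in self.counts.items())

    def secondary_mode(self, min_size: int = 3) -> int | None:
        """Size bin with the largest family count among bins >= min_size.

        The restriction to sizes >= 3 keeps the bulk of tiny families (totals
        of 1-2 genes) from masking the core-genome peak at the number of
        species. Ties go to the smallest qualifying size. None when no bin
        qualifies.
        """
        eligible = {s: c for s, c in self.counts.items() if s >= min_size}
        if not eligible:
            return None
        best = max(eligible.values())
        return min(s for s, c in eligible.items() if c == best)

    def to_frame(self) -> pd.DataFrame:
        sizes = sorted(self.counts)
        return pd.DataFrame({"size": sizes,
                             "n_families": [self.counts[s] for s in sizes]})


@dataclass(frozen=True)
class AssignmentStats:
    unassigned: int
    percent_assigned: float
    percent_unassigned: float


def core_report(g: GenotypeMatrix,
                totals: Mapping[str, int] | None = None) -> CoreReport:
    """Universal families, single-copy core and assignment fractions.

    ``totals`` maps species to its total number of predicted genes; when
    given, the fraction of each species' genes assigned to families is the
    species' row sum divided by its total. A total smaller than the assigned
    row sum is an error.
    """
    counts = g.counts
    universal = counts.min(axis=0) >= 1
    single_copy = (counts == 1).all(axis=0)
    og = np.asarray(g.orthogroup_ids, dtype=object)
    fractions = None
    if totals is not None:
        row_sums = counts.sum(axis=1)
        fractions = {}
        for sp, assigned in zip(g.species_ids, row_sums):
            total = totals[sp]
            if total < assigned:
                raise ValueError(
                    f"species {sp!r}: total predicted genes ({total}) is "
                    f"smaller than genes assigned to families ({assigned})")
            fractions[sp] = float(assigned) / float(total)
    return CoreReport(tuple(og[universal]), tuple(og[single_copy]), fractions)


def family_size_histogram(g: GenotypeMatrix) -> FamilySizeHistogram:
    """Histogram of per-family total gene counts (summed over species)."""
    totals = g.counts.sum(axis=0)
    sizes, n = np.unique(totals, return_counts=True)
    return FamilySizeHistogram({int(s): int(c) for s, c in zip(sizes, n)})


def _pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal."""
    q = (Decimal(numerator) * 100) / Decimal(denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def assignment_stats(total_predicted: int, assigned: int) -> AssignmentStats:
    """Unassigned gene count and one-decimal assignment percentages."""
    if not 0 <= assigned <= total_predicted:
        raise ValueError(
            f"assigned ({assigned}) must lie in [0, total_predicted "
            f"({total_predicted})]")
    return AssignmentStats(
        unassigned=total_predicted - assigned,
        percent_assigned=_pct(assigned, total_predicted),
        percent_unassigned=_pct(total_predicted - assigned, total_predicted),
    )
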