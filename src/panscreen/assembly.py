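"""Best-assembly selection from a k-mer sweep by summed metric ranks.

Each candidate assembly (one per k-mer value) is ranked on three QUAST-style
metrics: N50 (higher is better), total genome length (direction configurable,
larger-is-better by default) and number of contigs (fewer is better). Tied
metric values share the best available rank (competition ranking). The
assembly with the lowest overall rank, the sum of the three individual ranks,
is selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AssemblyStats", "RankedAssembly", "rank_assemblies",
           "read_assembly_stats", "write_ranked_assemblies"]


@dataclass(frozen=True)
class AssemblyStats:
    label: str
    kmer: int
    n50: int
    total_length: int
    n_contigs: int

    def __post_init__(self):
        if min(self.n50, self.total_length, self.n_contigs) <= 0:
            raise ValueError(f"{self.label}: all metrics must be positive")
        if self.n50 > self.total_length:
            raise ValueError(
                f"{self.label}: N50 ({self.n50}) exceeds total length "
                f"({self.total_length})")


@dataclass(frozen=True)
class RankedAssembly:
    stats: AssemblyStats
    rank_n50: int
    rank_length: int
    rank_contigs: int

    @property
    def overall(self) -> int:
        return self.rank_n50 + self.rank_length + self.rank_contigs


def _competition_rank(values, higher_is_better: bool) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    return stats.rankdata(-a if higher_is_better else a, method="min").astype(int)


def rank_assemblies(candidates: list[AssemblyStats],
                    length_direction: str = "larger") -> list[RankedAssembly]:
    """Rank candidates and return them best-first.

    Rank 1 is best per metric: highest N50, best total length (per
    ``length_direction``), fewest contigs. Ties on the overall score are
    broken by higher N50, then fewer contigs, then label.
    """
    if not candidates:
        raise ValueError("need at least one candidate assembly")
    if length_direction not in ("larger", "smaller"):
        raise ValueError("length_direction must be 'larger' or 'smaller'")
    r_n50 = _competition_rank([c.n50 for c in candidates], True)
    r_len = _competition_rank([c.total_length for c in candidates],
                              length_direction == "larger")
    r_ctg = _competition_rank([c.n_contigs for c in candidates], False)
    ranked = [RankedAssembly(c, int(a), int(b), int(d))
              for c, a, b, d in zip(candidates, r_n50, r_len, r_ctg)]
    return sorted(ranked, key=lambda r: (r.overall, -r.stats.n50,
                                         r.stats.n_contigs, r.stats.label))


def read_assembly_stats(path) -> list[AssemblyStats]:
    """Read a distilled QUAST report: TSV with columns
    label, kmer, n50, total_length, n_contigs."""
    df = pd.read_csv(path, sep="\t")
    required = ["label", "kmer", "n50", "total_length", "n_contigs"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"assembly stats table missing columns: {missing}")
    return [AssemblyStats(str(r.label), int(r.kmer), int(r.n50),
                          int(r.total_length), int(r.n_contigs))
            for r in df.itertuples(index=False)]


def write_ranked_assemblies(ranked: list[RankedAssembly], path) -> None:
    pd.DataFrame([{
        "label": r.stats.label,
        "kmer": r.stats.kmer,
        "n50": r.stats.n50,
        "total_length": r.stats.total_length,
        "n_contigs": r.stats.n_contigs,
        "rank_n50": r.rank_n50,
        "rank_length": r.rank_length,
        "rank_contigs": r.rank_contigs,
        "overall": r.overall,
    } for r in ranked]).to_csv(path, sep="\t", index=False)
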