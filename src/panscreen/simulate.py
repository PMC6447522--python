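"""Synthetic genotype/phenotype datasets with planted associations.

The generator emulates the statistical structure a pan-genome association
screen faces in a set of lactic acid bacteria genomes: a species x family
count matrix dominated by zero-inflated low-count families, a block of
single-copy core families present once in every species, binary fermentation
phenotypes per substrate, a few substrates that no species ferments, and a
chosen set of (family, substrate) pairs in which metabolizing species carry
systematically more (or fewer) gene copies than non-metabolizing ones.

Family counts are Poisson: background families are all-zero with probability
``w`` and otherwise draw per-species counts from Poisson(background mean);
planted families draw Poisson(lambda_pos) for metabolizers of their paired
substrate and Poisson(lambda_null) for the rest. Species are exchangeable
(no phylogenetic autocorrelation); an optional clade-block mode shares a
family-specific baseline within clades to probe relatedness confounding.

Everything is reproducible from the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .assembly import AssemblyStats
from .association import TESTED, AssociationTable, significant
from .io import GenotypeMatrix, PhenotypeMatrix

__all__ = ["SimConfig", "SimTruth", "RecoveryMetrics", "simulate",
           "simulate_quast_stats", "evaluate", "DEFAULT_KMER_SWEEP"]

#: k-mer values of a 12-assembly sweep.
DEFAULT_KMER_SWEEP = (20, 32, 40, 50, 60, 65, 70, 75, 80, 85, 90, 96)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated dataset.

    Defaults mirror a 56-genome screen at a scaled-down family count: 600
    families (full scale is 5932), 219 single-copy core families, 49
    substrates of which 9 are fermented by no species, background families
    all-zero with probability 0.2 and otherwise Poisson(0.05) per species
    (family totals then peak at 1-3 genes with a secondary core peak at the
    number of species), and 5 planted (family, substrate) pairs with Poisson
    means 0.2 (non-metabolizers) vs 3.0 (metabolizers).
    """

    n_species: int = 56
    n_families: int = 600
    n_substrates: int = 49
    n_single_copy_core: int = 219
    n_planted: int = 5
    effect: tuple[float, float] = (0.2, 3.0)  # (lambda_null, lambda_pos)
    background: tuple[float, float] = (0.2, 0.05)  # (zero weight, Poisson mean)
    prevalence: float = 0.5
    n_degenerate_substrates: int = 9
    balanced_planted: bool = False
    n_clades: int = 0  # 0 = exchangeable species (no block relatedness)
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2 or self.n_families < 1 or self.n_substrates < 1:
            raise ValueError("dimensions must be positive (>= 2 species)")
        if self.n_single_copy_core + self.n_planted > self.n_families:
            raise ValueError("core plus planted families exceed n_families")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0 <= self.background[0] <= 1 or self.background[1] < 0:
            raise ValueError("invalid background mixture")
        if self.n_planted and self.effect[0] == self.effect[1]:
            raise ValueError("planted pairs require lambda_pos != lambda_null")
        if self.n_degenerate_substrates + self.n_planted > self.n_substrates:
            raise ValueError("too many degenerate substrates for the planted "
                             "pairs to fit")
        if min(self.effect) < 0:
            raise ValueError("Poisson means must be non-negative")


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth registry of the planted structure."""

    planted_pairs: Mapping[tuple[str, str], str]  # -> effect direction
    core_ids: frozenset
    degenerate_substrates: frozenset


@dataclass(frozen=True)
class RecoveryMetrics:
    power: float
    observed_fdr: float
    type1_uncorrected: float


def _species_ids(n):
    return [f"sp{i + 1:03d}" for i in range(n)]


def _family_ids(n):
    return [f"OG{i + 1:07d}" for i in range(n)]


def _substrate_ids(n):
    return [f"substrate_{i + 1:02d}" for i in range(n)]


def simulate(config: SimConfig) -> tuple[GenotypeMatrix, PhenotypeMatrix, SimTruth]:
    """Draw one dataset; bit-identical for identical config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    n_sp, n_fam, n_sub = (config.n_species, config.n_families,
                          config.n_substrates)
    species = _species_ids(n_sp)
    families = _family_ids(n_fam)
    substrates = _substrate_ids(n_sub)

    # --- phenotypes -------------------------------------------------------
    degenerate_idx = list(range(n_sub - config.n_degenerate_substrates, n_sub))
    non_degenerate = [s for s in range(n_sub) if s not in set(degenerate_idx)]
    planted_sub_idx = list(rng.choice(non_degenerate, size=config.n_planted,
                                      replace=False)) if config.n_planted else []

    calls = np.zeros((n_sp, n_sub), dtype=np.int64)
    for s in non_degenerate:
        if config.balanced_planted and s in planted_sub_idx:
            vec = np.zeros(n_sp, dtype=np.int64)
            vec[: n_sp // 2] = 1
            rng.shuffle(vec)
        else:
            while True:
                vec = (rng.random(n_sp) < config.prevalence).astype(np.int64)
                if 0 < vec.sum() < n_sp:
                    break
        calls[:, s] = vec

    # --- family counts ----------------------------------------------------
    lam_null, lam_pos = config.effect
    zero_w, bg_mean = config.background
    counts = np.zeros((n_sp, n_fam), dtype=np.int64)

    c = config.n_single_copy_core
    counts[:, :c] = 1

    planted_pairs = {}
    for k in range(config.n_planted):
        f = c + k
        s = planted_sub_idx[k]
        pos = calls[:, s] == 1
        col = np.empty(n_sp, dtype=np.int64)
        col[pos] = rng.poisson(lam_pos, pos.sum())
        col[~pos] = rng.poisson(lam_null, (~pos).sum())
        counts[:, f] = col
        direction = "expansion" if lam_pos > lam_null else "contraction"
        planted_pairs[(families[f], substrates[s])] = direction

    n_bg = n_fam - c - config.n_planted
    if n_bg:
        clade_of = (rng.integers(0, config.n_clades, n_sp)
                    if config.n_clades else None)
        nonzero = rng.random(n_bg) >= zero_w
        bg = np.zeros((n_sp, n_bg), dtype=np.int64)
        if config.n_clades:
            # clade-shared baseline: each (clade, family) draws its own mean
            clade_means = rng.gamma(2.0, bg_mean / 2.0,
                                    (config.n_clades, n_bg))
            lam = clade_means[clade_of, :] * nonzero[np.newaxis, :]
            bg = rng.poisson(lam)
        else:
            bg[:, nonzero] = rng.poisson(bg_mean, (n_sp, int(nonzero.sum())))
        counts[:, c + config.n_planted:] = bg

    g = GenotypeMatrix.from_arrays(species, families, counts)
    p = PhenotypeMatrix.from_arrays(species, substrates, calls)
    truth = SimTruth(
        planted_pairs=planted_pairs,
        core_ids=frozenset(families[:c]),
        degenerate_substrates=frozenset(substrates[s] for s in degenerate_idx),
    )
    return g, p, truth


def simulate_quast_stats(n_candidates: int, seed: int
                         ) -> tuple[list[AssemblyStats], str]:
    """Plausible correlated assembly metrics with a designated best candidate.

    Higher N50 goes with fewer contigs (both driven by a latent contiguity
    quality); the designated best candidate strictly dominates every other on
    N50, total length and contig count, so rank selection must recover it.
    Returns (candidates, label of the designated best).
    """
    if n_candidates < 1:
        raise ValueError("need at least one candidate")
    rng = np.random.default_rng(seed)
    if n_candidates == len(DEFAULT_KMER_SWEEP):
        kmers = list(DEFAULT_KMER_SWEEP)
    else:
        kmers = sorted(rng.choice(np.arange(20, 97), size=n_candidates,
                                  replace=False).tolist())
    genome = float(rng.uniform(1.6e6, 3.7e6))
    quality = rng.uniform(0.1, 1.0, n_candidates)
    n50 = (20_000 + quality * 400_000).astype(np.int64)
    n_contigs = np.maximum(2, (genome / n50 * rng.uniform(2.0, 3.0))
                           ).astype(np.int64)
    total = (genome * rng.uniform(0.95, 1.0, n_candidates)).astype(np.int64)

    best = int(rng.integers(n_candidates))
    if n_candidates > 1:
        others = np.arange(n_candidates) != best
        n50[best] = int(n50[others].max() * 1.1) + 1
        total[best] = int(total[others].max()) + 1000
        n_contigs[best] = max(1, int(n_contigs[others].min()) - 1)
    n50 = np.minimum(n50, total)  # N50 can never exceed assembly length
    stats = [AssemblyStats(f"k{k}", int(k), int(a), int(b), int(d))
             for k, a, b, d in zip(kmers, n50, total, n_contigs)]
    return stats, stats[best].label


def evaluate(table: AssociationTable, truth: SimTruth, method: str,
             alpha: float) -> RecoveryMetrics:
    """Recovery metrics of a screen against the planted ground truth.

    power: fraction of planted pairs declared significant (0 when nothing was
    planted); observed_fdr: fraction of significant pairs not planted (0 when
    nothing is significant); type1_uncorrected: fraction of tested,
    non-planted pairs with raw p below alpha.
    """
    df = table.df
    table_fams = set(df["orthogroup"])
    table_subs = set(df["substrate"])
    for fam, sub in truth.planted_pairs:
        if fam not in table_fams or sub not in table_subs:
            raise ValueError(f"planted pair ({fam}, {sub}) not present in the "
                             "association table; id mismatch")
    if not truth.degenerate_substrates <= table_subs:
        raise ValueError("degenerate substrate ids not present in the table")

    summary = significant(table, method, alpha)
    sig = {(og, sub) for og, sub, _ in summary.pairs}
    planted = set(truth.planted_pairs)

    power = len(sig & planted) / len(planted) if planted else 0.0
    observed_fdr = len(sig - planted) / len(sig) if sig else 0.0

    tested = df[df["status"] == TESTED]
    is_planted = [(og, sub) in planted for og, sub
                  in zip(tested["orthogroup"], tested["substrate"])]
    null = tested.loc[[not x for x in is_planted], "p_raw"].to_numpy()
    type1 = float((null < alpha).mean()) if null.size else 0.0
    return RecoveryMetrics(power, observed_fdr, type1)
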