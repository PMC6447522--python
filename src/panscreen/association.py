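"""Mass-univariate Wilcoxon rank-sum screening of gene-family sizes.

For every (orthogroup, substrate) pair the gene copy counts of the species
that metabolize the substrate are compared with those of the species that do
not, using the two-sided Wilcoxon rank-sum (Mann-Whitney) test on midranks
with tie-corrected variance. Raw p-values are corrected for multiple testing
with Bonferroni and with the Benjamini-Hochberg step-up (FDR), either over
all pairs (so degenerate, untestable pairs still count toward m, matching
the convention of reporting the full number of hypotheses screened) or over
tested pairs only.

Count data of this kind are heavily tied (most families are absent from most
species), so the tie-aware machinery is load-bearing, not a corner case:

* ``W`` is the rank-sum of the positive group computed on pooled midranks;
* null mean ``mu = n_pos (n+1) / 2``;
* null variance ``sigma^2 = n_pos n_neg (n+1)/12
  - n_pos n_neg sum(t^3 - t) / (12 n (n-1))`` with ``t`` the tied-group sizes;
* normal approximation: ``z = (W - mu -/+ 0.5) / sigma`` with the continuity
  term shrinking ``|W - mu|`` toward zero, ``p = 2 Phi(-|z|)`` capped at 1;
* exact method: enumeration of all ``C(n, n_pos)`` equally likely selections
  of positive-group midranks (valid under ties, bounded at n <= 14);
* ``sigma = 0`` (all counts identical) yields ``p = 1``: the pair is
  uninformative, not untestable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import GenotypeMatrix, PhenotypeMatrix

__all__ = [
    "TESTED",
    "SKIPPED",
    "EXACT_N_MAX",
    "ScreenConfig",
    "RankVector",
    "WilcoxonResult",
    "TestResult",
    "AssociationTable",
    "SignificanceSummary",
    "DegenerateGroupsError",
    "midrank",
    "wilcoxon_rank_sum",
    "wilcoxon_p_exact",
    "test_pair",
    "screen",
    "adjust",
    "significant",
    "WilcoxonAssociationScreen",
]

TESTED = "tested"
SKIPPED = "skipped_degenerate"

#: Largest pooled sample size for which the exact enumeration is attempted
#: (C(14, 7) = 3432 selections).
EXACT_N_MAX = 14

_CORRECTIONS = ("bonferroni", "bh")
_M_MODES = ("all-pairs", "tested-only")
_P_METHODS = ("normal", "exact", "auto")


class DegenerateGroupsError(ValueError):
    """One of the two phenotype classes is empty; the pair cannot be tested."""


@dataclass(frozen=True)
class ScreenConfig:
    """Configuration of the association screen.

    Parameters
    ----------
    alpha : significance threshold on adjusted values (0 < alpha < 1).
    correction : default correction used by reporting helpers.
    m_mode : ``"all-pairs"`` counts every (orthogroup, substrate) pair toward
        the number of hypotheses m; ``"tested-only"`` counts only
        non-degenerate pairs.
    p_method : ``"normal"``, ``"exact"``, or ``"auto"`` (exact when the pooled
        sample size is at most ``EXACT_N_MAX``, normal otherwise).
    continuity_correction : apply the 0.5 continuity term in the normal
        approximation.
    """

    alpha: float = 0.05
    correction: str = "bonferroni"
    m_mode: str = "all-pairs"
    p_method: str = "auto"
    continuity_correction: bool = True

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.correction not in _CORRECTIONS:
            raise ValueError(f"correction must be one of {_CORRECTIONS}")
        if self.m_mode not in _M_MODES:
            raise ValueError(f"m_mode must be one of {_M_MODES}")
        if self.p_method not in _P_METHODS:
            raise ValueError(f"p_method must be one of {_P_METHODS}")


@dataclass(frozen=True)
class RankVector:
    """Midranks of a sample plus the multiset of tied-group sizes."""

    midranks: np.ndarray
    tie_group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # rank-sum W of the positive group
    mu: float
    sigma: float
    p: float


@dataclass(frozen=True)
class TestResult:
    orthogroup_id: str
    substrate_id: str
    n_pos: int
    n_neg: int
    statistic: float | None
    p_raw: float | None
    p_bonferroni: float | None
    q_bh: float | None
    status: str


@dataclass(frozen=True)
class AssociationTable:
    """One record per (orthogroup, substrate) pair.

    ``df`` carries the columns of :data:`panscreen.io.ASSOCIATION_COLUMNS` in
    orthogroup-major order; ``m_total`` is the number of hypotheses used for
    correction; ``adjusted`` records which corrections have been applied.
    """

    df: pd.DataFrame
    m_total: int
    config: ScreenConfig
    adjusted: frozenset = field(default_factory=frozenset)

    @property
    def n_tested(self) -> int:
        return int((self.df["status"] == TESTED).sum())

    def records(self) -> list[TestResult]:
        def _opt(x):
            return None if pd.isna(x) else float(x)

        return [
            TestResult(row.orthogroup, row.substrate,
                       int(row.n_pos), int(row.n_neg),
                       _opt(row.statistic), _opt(row.p_raw),
                       _opt(row.p_bonferroni), _opt(row.q_bh), row.status)
            for row in self.df.itertuples(index=False)
        ]


@dataclass(frozen=True)
class SignificanceSummary:
    method: str
    alpha: float
    n_significant_pairs: int
    n_orthogroups: int
    n_substrates: int
    pairs: tuple  # (orthogroup_id, substrate_id, p_adjusted), sorted


def midrank(values: Sequence[float]) -> RankVector:
    """Ranks 1..n with ties averaged, plus tied-group sizes in value order."""
    a = np.asarray(values, dtype=float)
    if a.size == 0:
        raise ValueError("cannot rank an empty sample")
    ranks = stats.rankdata(a, method="average")
    _, counts = np.unique(a, return_counts=True)
    return RankVector(ranks, tuple(int(c) for c in counts))


def _tie_term(tie_group_sizes) -> float:
    return float(sum(t ** 3 - t for t in tie_group_sizes))


def wilcoxon_p_exact(pos_counts, neg_counts) -> float:
    """Two-sided exact p by full enumeration over midrank selections.

    Every one of the ``C(n, n_pos)`` ways of assigning the pooled midranks to
    the positive group is equally likely under the null; the p-value is the
    fraction of selections whose rank-sum deviates from the null mean at least
    as much as the observed one. Enumerating index subsets handles ties
    correctly because tied observations carry equal midranks.
    """
    pos = np.asarray(pos_counts, dtype=float)
    neg = np.asarray(neg_counts, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DegenerateGroupsError("both groups must be non-empty")
    n = pos.size + neg.size
    if n > EXACT_N_MAX:
        raise ValueError(
            f"exact enumeration supports n <= {EXACT_N_MAX} (got n = {n}); "
            "use the normal method")
    ranks = midrank(np.concatenate([pos, neg])).midranks
    n_pos = pos.size
    mu = n_pos * (n + 1) / 2.0
    d_obs = abs(float(ranks[:n_pos].sum()) - mu)
    hits = total = 0
    for combo in itertools.combinations(range(n), n_pos):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= d_obs - 1e-9:
            hits += 1
    return hits / total


def wilcoxon_rank_sum(pos_counts, neg_counts, p_method: str = "normal",
                      continuity_correction: bool = True) -> WilcoxonResult:
    """Tie-corrected two-sided Wilcoxon rank-sum test.

    Returns the rank-sum ``W`` of the positive group, the null mean and
    tie-corrected null standard deviation, and the two-sided p-value.
    """
    pos = np.asarray(pos_counts, dtype=float)
    neg = np.asarray(neg_counts, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DegenerateGroupsError("both groups must be non-empty")
    if p_method not in _P_METHODS:
        raise ValueError(f"p_method must be one of {_P_METHODS}")
    n_pos, n_neg = pos.size, neg.size
    n = n_pos + n_neg
    rv = midrank(np.concatenate([pos, neg]))
    w = float(rv.midranks[:n_pos].sum())
    mu = n_pos * (n + 1) / 2.0
    var = (n_pos * n_neg * (n + 1) / 12.0
           - n_pos * n_neg * _tie_term(rv.tie_group_sizes) / (12.0 * n * (n - 1)))
    sigma = math.sqrt(max(var, 0.0))
    if sigma == 0.0:
        p = 1.0
    elif p_method == "exact" or (p_method == "auto" and n <= EXACT_N_MAX):
        p = wilcoxon_p_exact(pos, neg)
    else:
        d = w - mu
        if continuity_correction:
            d = math.copysign(max(abs(d) - 0.5, 0.0), d)
        z = d / sigma
        p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return WilcoxonResult(w, mu, sigma, p)


def test_pair(counts_for_family, calls_for_substrate,
              config: ScreenConfig = ScreenConfig(),
              orthogroup_id: str = "", substrate_id: str = "") -> TestResult:
    """Test a single (family, substrate) pair in shared species order."""
    counts = np.asarray(counts_for_family)
    calls = np.asarray(calls_for_substrate)
    if counts.shape != calls.shape:
        raise ValueError("counts and calls must have equal length")
    pos = counts[calls == 1]
    neg = counts[calls == 0]
    n_pos, n_neg = int(pos.size), int(neg.size)
    if n_pos == 0 or n_neg == 0:
        return TestResult(orthogroup_id, substrate_id, n_pos, n_neg,
                          None, None, None, None, SKIPPED)
    res = wilcoxon_rank_sum(pos, neg, p_method=config.p_method,
                            continuity_correction=config.continuity_correction)
    return TestResult(orthogroup_id, substrate_id, n_pos, n_neg,
                      res.statistic, res.p, None, None, TESTED)


def _column_tie_terms(counts: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tied groups, per column of a species x family matrix."""
    n = counts.shape[0]
    s = np.sort(counts, axis=0)
    change = np.ones_like(s, dtype=bool)
    change[1:] = s[1:] != s[:-1]
    out = np.empty(counts.shape[1], dtype=float)
    for j in range(counts.shape[1]):
        starts = np.flatnonzero(change[:, j])
        sizes = np.diff(np.append(starts, n)).astype(float)
        out[j] = float(np.sum(sizes ** 3 - sizes))
    return out


def screen(g: GenotypeMatrix, p: PhenotypeMatrix,
           config: ScreenConfig = ScreenConfig()) -> AssociationTable:
    """Run the full screen: one test per (orthogroup, substrate) pair.

    The matrices must already be aligned on species (same ids, same order).
    Substrates with a one-class phenotype (all 0 or all 1) produce
    ``skipped_degenerate`` records with undefined p-values. Both corrections
    (Bonferroni, BH) are filled on the returned table. Output order is
    orthogroup-major and fully deterministic.
    """
    if list(g.species_ids) != list(p.species_ids):
        raise ValueError("matrices are not aligned on species; "
                         "call align_matrices first")
    counts = g.counts.astype(float)
    calls = p.calls
    n_sp, n_fam = counts.shape
    n_sub = calls.shape[1]
    if n_sp < 2:
        raise ValueError("need at least 2 species")

    n_pos = calls.sum(axis=0).astype(float)
    n_neg = n_sp - n_pos
    degenerate = (n_pos == 0) | (n_neg == 0)

    ranks = stats.rankdata(counts, axis=0) if n_fam else np.empty((n_sp, 0))
    w = ranks.T @ calls.astype(float)  # (n_fam, n_sub)

    use_normal = (config.p_method == "normal"
                  or (config.p_method == "auto" and n_sp > EXACT_N_MAX))
    if use_normal:
        tie_terms = _column_tie_terms(counts)
        mu = n_pos * (n_sp + 1) / 2.0
        var = (n_pos * n_neg * (n_sp + 1) / 12.0
               - np.outer(tie_terms, n_pos * n_neg) / (12.0 * n_sp * (n_sp - 1)))
        sigma = np.sqrt(np.clip(var, 0.0, None))
        d = w - mu[np.newaxis, :]
        if config.continuity_correction:
            d = np.sign(d) * np.maximum(np.abs(d) - 0.5, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sigma > 0, d / np.where(sigma > 0, sigma, 1.0), 0.0)
        p_raw = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z)))
        p_raw = np.where(sigma == 0, 1.0, p_raw)
    else:
        p_raw = np.full((n_fam, n_sub), np.nan)
        for s in range(n_sub):
            if degenerate[s]:
                continue
            mask = calls[:, s] == 1
            for f in range(n_fam):
                res = wilcoxon_rank_sum(
                    counts[mask, f], counts[~mask, f],
                    p_method=config.p_method,
                    continuity_correction=config.continuity_correction)
                p_raw[f, s] = res.p

    p_raw[:, degenerate] = np.nan
    statistic = w.copy()
    statistic[:, degenerate] = np.nan

    status = np.where(degenerate, SKIPPED, TESTED)
    df = pd.DataFrame({
        "orthogroup": np.repeat(g.orthogroup_ids, n_sub),
        "substrate": np.tile(p.substrate_ids, n_fam),
        "n_pos": np.tile(n_pos.astype(int), n_fam),
        "n_neg": np.tile(n_neg.astype(int), n_fam),
        "statistic": statistic.ravel(),
        "p_raw": p_raw.ravel(),
        "p_bonferroni": np.nan,
        "q_bh": np.nan,
        "status": np.tile(status, n_fam),
    })
    n_tested = int((df["status"] == TESTED).sum())
    m_total = len(df) if config.m_mode == "all-pairs" else n_tested
    table = AssociationTable(df, m_total, config)
    table = adjust(table, "bonferroni")
    table = adjust(table, "bh")
    return table


def adjust(table: AssociationTable, method: str) -> AssociationTable:
    """Fill one correction column; skipped records stay NA.

    Bonferroni: ``p_adj = min(1, p_raw * m_total)``. BH: step-up
    ``q_(i) = min_{j >= i} (p_(j) * m_total / j)`` capped at 1 over the tested
    p-values sorted ascending, with ``m_total`` taken from the table (it may
    exceed the number of tested records in all-pairs mode).
    """
    if method not in _CORRECTIONS:
        raise ValueError(f"method must be one of {_CORRECTIONS}")
    df = table.df.copy()
    tested = (df["status"] == TESTED).to_numpy()
    k = int(tested.sum())
    if table.m_total < k:
        raise ValueError(
            f"m_total ({table.m_total}) is smaller than the number of tested "
            f"records ({k})")
    if k:
        p = df.loc[tested, "p_raw"].to_numpy(dtype=float)
        if method == "bonferroni":
            df.loc[tested, "p_bonferroni"] = np.minimum(1.0, p * table.m_total)
        else:
            order = np.argsort(p, kind="mergesort")
            ranks = np.arange(1, k + 1, dtype=float)
            stepped = (p[order] * table.m_total) / ranks
            q_sorted = np.minimum(1.0,
                                  np.minimum.accumulate(stepped[::-1])[::-1])
            q = np.empty(k)
            q[order] = q_sorted
            df.loc[tested, "q_bh"] = q
    return replace(table, df=df, adjusted=table.adjusted | {method})


def significant(table: AssociationTable, method: str,
                alpha: float) -> SignificanceSummary:
    """Pairs whose adjusted value falls strictly below alpha.

    Ordered by adjusted value, then (orthogroup, substrate) lexicographically.
    """
    if method not in _CORRECTIONS:
        raise ValueError(f"method must be one of {_CORRECTIONS}")
    if method not in table.adjusted:
        raise ValueError(f"adjusted values for {method!r} have not been computed")
    col = "p_bonferroni" if method == "bonferroni" else "q_bh"
    df = table.df
    sel = df[(df["status"] == TESTED) & (df[col] < alpha)]
    sel = sel.sort_values([col, "orthogroup", "substrate"])
    pairs = tuple((row.orthogroup, row.substrate, float(getattr(row, col)))
                  for row in sel.itertuples(index=False))
    return SignificanceSummary(
        method=method, alpha=alpha,
        n_significant_pairs=len(pairs),
        n_orthogroups=int(sel["orthogroup"].nunique()),
        n_substrates=int(sel["substrate"].nunique()),
        pairs=pairs)


class WilcoxonAssociationScreen(BaseEstimator):
    """Scikit-learn style estimator wrapping the association screen.

    Parameters mirror :class:`ScreenConfig`. ``fit`` accepts a
    :class:`~panscreen.io.GenotypeMatrix` and a
    :class:`~panscreen.io.PhenotypeMatrix` (or labelled DataFrames) aligned on
    species, and exposes the fitted table and hypothesis count as ``table_``
    and ``m_total_``.
    """

    def __init__(self, alpha: float = 0.05, correction: str = "bonferroni",
                 m_mode: str = "all-pairs", p_method: str = "auto",
                 continuity_correction: bool = True):
        self.alpha = alpha
        self.correction = correction
        self.m_mode = m_mode
        self.p_method = p_method
        self.continuity_correction = continuity_correction

    def _config(self) -> ScreenConfig:
        return ScreenConfig(alpha=self.alpha, correction=self.correction,
                            m_mode=self.m_mode, p_method=self.p_method,
                            continuity_correction=self.continuity_correction)

    def fit(self, X, y):
        g = X if isinstance(X, GenotypeMatrix) else GenotypeMatrix(pd.DataFrame(X))
        p = y if isinstance(y, PhenotypeMatrix) else PhenotypeMatrix(pd.DataFrame(y))
        self.table_ = screen(g, p, self._config())
        self.m_total_ = self.table_.m_total
        self.n_tested_ = self.table_.n_tested
        return self

    def significant(self, method: str | None = None,
                    alpha: float | None = None) -> SignificanceSummary:
        if not hasattr(self, "table_"):
            raise ValueError("this WilcoxonAssociationScreen instance is not "
                             "fitted yet; call fit first")
        return significant(self.table_,
                           method or self.correction,
                           self.alpha if alpha is None else alpha)
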