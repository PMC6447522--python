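# Methods

Statistical model, parameter defaults, generator design and numerical choices
behind `panscreen`. Notation: `A` is the species × orthogroup count matrix
(`n` species, `F` families), `B` the species × substrate binary phenotype
matrix (`S` substrates).

## 1. Per-pair test: tie-corrected Wilcoxon rank-sum

For one (orthogroup, substrate) pair, split the `n` gene counts by phenotype
into a positive group of size `n⁺` and a negative group of size `n⁻`. Rank the
pooled counts with midranks (tied values share the average of the ranks they
occupy). The statistic is the rank sum of the positive group,

```
W = Σ_{i: y_i = 1} r_i .
```

Under the null that both groups draw from the same distribution,

```
μ = n⁺ (n + 1) / 2
σ² = n⁺ n⁻ (n + 1) / 12  −  n⁺ n⁻ Σ_g (t_g³ − t_g) / (12 n (n − 1)) ,
```

where `t_g` are the tied-group sizes. This is the standard tie correction;
gene-count data is dominated by ties (most counts are 0 or 1), so the
uncorrected variance would be badly inflated. The two-sided normal p-value is
`p = 2 Φ(−|z|)` with `z = (W − μ ∓ ½) / σ`, the ½ being a continuity
correction that shrinks `|W − μ|` toward zero (never past it). If `σ = 0`
(all pooled counts identical) the test carries no information and `p = 1`.

**Exact test.** For `n ≤ 14` (the `EXACT_N_MAX` constant) the exact two-sided
p is available: every one of the `C(n, n⁺)` assignments of the pooled midranks
to the positive group is equally likely under the null, and
`p = #{assignments with |W' − μ| ≥ |W − μ|} / C(n, n⁺)`. The comparison uses a
`1e-9` tolerance so ties in `|W' − μ|` caused by floating-point rank
arithmetic count as "at least as extreme", keeping the test conservative.
`C(14, 7) = 3432` keeps full enumeration trivial.

**Method selection.** `p_method="auto"` (the default) uses the exact test when
`n ≤ 14` and the normal approximation otherwise. The approximation is good
when both groups are reasonably sized: over exhaustive untied batteries with
both groups ≥ 4, the worst observed `|p_normal − p_exact|` is 0.0305. It is
**not** uniformly good for tiny groups — a 1-vs-13 split can disagree by 0.115
(singleton at midrank 11: exact 8/14 ≈ 0.571 vs normal ≈ 0.457) — which is
precisely why small `n` defaults to the exact test, and why the documented
accuracy claim is scoped to groups of size ≥ 4.

**Degenerate substrates.** A substrate fermented by no strain (or by every
strain) has an empty comparison group; its pairs are emitted with status
`skipped_degenerate` and NA p-fields rather than silently dropped, so the
output table always has exactly `F × S` rows.

## 2. Multiplicity control

Let `m` be the number of hypotheses charged. Two conventions are supported:

* `m_mode="all-pairs"` (default): `m = F × S`, counting skipped pairs. This is
  the conservative screen-everything bookkeeping — you planned every test, so
  you pay for every test. At a realistic scale (5,932 families × 49
  substrates) `m = 290,668`.
* `m_mode="tested"`: `m` = number of non-degenerate pairs actually tested.

Corrections (both always computed, stored per row):

* **Bonferroni**: `p_adj = min(1, p · m)`; controls the family-wise error rate.
* **Benjamini–Hochberg**: sort the `k` tested p-values ascending and set
  `q_(i) = min_{j ≥ i} ( p_(j) · m / j )`, capped at 1. Note `m`, not `k`, in
  the numerator: with `m_mode="all-pairs"` the skipped hypotheses still
  inflate the correction, making the q-values conservative relative to
  textbook BH over tested pairs only. With `m_mode="tested"` the procedure
  coincides with `statsmodels`' `fdr_bh` (verified in tests).

Significance is strict (`p_adj < α`), sorting of reported hits is by adjusted
p then lexicographic ids, fully deterministic.

## 3. Vectorised screen

Ranks are computed once per family column; for column rank matrix `R`
(n × F) and call matrix `C` (n × S), all rank sums fall out of one product
`W = Rᵀ C`, and `μ`, `σ²` follow from per-column tie terms and per-substrate
group sizes via outer products. A 56 × 5,932 × 49 screen (290,668 tests)
completes in ~1.5 s. The per-pair scalar path (used for the exact test and as
a cross-check) is tested to agree with the vectorised path exactly.

## 4. Pan-genome summaries

* **Universal families**: min count over species ≥ 1. **Single-copy core**:
  every species has exactly count 1.
* **Family-size histogram**: distribution of family total size
  (column sums). Its *secondary mode* is the size bin with the largest count
  among bins of size ≥ 3 (ties go to the smaller bin); in a collection of `n`
  species with a substantial single-copy core this sits at exactly `n`.
* **Assignment percentages**: given total predicted genes and genes assigned
  to families, percentages are rounded to one decimal with half-up rounding
  (`Decimal ROUND_HALF_UP`), matching how such numbers are conventionally
  reported; e.g. 118,555 / 123,255 → 96.2% assigned, 3.8% (4,700)
  unassigned.

## 5. Assembly selection

Each k-mer sweep candidate carries N50 (larger better), total length
(direction configurable, default larger better) and contig count (smaller
better). Each metric gets a **competition rank** (ties share the best rank:
1, 1, 3); the overall score is the sum of the three ranks, smaller wins.
Final ordering breaks overall-score ties by higher N50, then fewer contigs,
then label — deterministic for any input permutation. The default 12-point
k-mer sweep is (20, 32, 40, 50, 60, 65, 70, 75, 80, 85, 90, 96).

## 6. Clustering and heatmap ordering

Complete linkage (inter-cluster distance = max pairwise member distance) on
Euclidean distances, implemented as the explicit O(n³) agglomeration so
tie-breaking is fully specified: at each step merge the pair with minimal
height, ties broken by the smallest (i, j) cluster-index pair, new clusters
numbered `n, n+1, …` (the scipy id convention). Merge heights match
`scipy.cluster.hierarchy.linkage(..., 'complete')` on tie-free inputs and are
non-decreasing always. Leaf order puts the subtree containing the smallest
leaf index on the left, recursively, so the displayed order is unique.
Heatmap export clusters species rows on phenotype profiles and
orthogroup/substrate columns on their respective profiles, writing reordered
TSVs plus order sidecars (rendering to PNG is optional and off by default).

## 7. Synthetic-data generator

A zero-inflated Poisson model starting at the count-matrix level (no sequence
or assembly simulation). Defaults, chosen to mimic the shape of a real
56-strain fermentation study *before* any calibration experiments were run:

| parameter | default | rationale |
|---|---|---|
| `n_species` | 56 | typical collection size |
| `n_families` | 600 | large enough for multiplicity behaviour, fast |
| `n_substrates` | 49 | API 50 CHL panel size |
| `n_single_copy_core` | 219 | produces the histogram secondary mode at 56 |
| `n_planted` | 5 | planted true associations |
| `n_degenerate_substrates` | 9 | substrates fermented by no strain |
| `effect` | (0.2, 3.0) | Poisson means for planted families, negative vs positive strains |
| `background` | (0.2, 0.05) | zero-inflation weight; Poisson mean elsewhere |
| `prevalence` | 0.5 | Bernoulli phenotype probability |

Construction: core families are count 1 everywhere; each planted family is
paired with a distinct non-degenerate substrate and drawn
`Poisson(λ⁺)`/`Poisson(λ⁻)` by phenotype class; background families are 0
with probability 0.2 and `Poisson(0.05)` otherwise, giving the heavy-zero,
small-count bulk typical of accessory-genome count matrices. Non-degenerate
substrates are resampled until both classes are non-empty;
`balanced_planted=True` forces an exact `n/2` split on planted substrates for
power studies. Everything is driven by one `numpy` `default_rng(seed)`, so
output is bit-reproducible per seed.

**Realism limits.** Species are exchangeable — there is no phylogenetic
correlation, so confounding by population structure (the main practical
hazard of pan-genome association studies) is absent by construction; observed
false-positive rates on this generator are a best case. Families are
independent; linkage between families and operon structure are not modelled.
Phenotype noise (mis-scored wells) is not modelled. Within-species
strain-to-strain variation is not modelled.

## 8. Numerical and I/O choices

* All p-value machinery is deterministic; sorting uses stable mergesort so
  equal keys keep a reproducible order.
* Association tables are written with 17 significant digits (`%.17g`) and
  read back with round-trip float parsing, so write→read reproduces every
  float bit-exactly; undefined values are literal `NA`.
* Scale defaults (56 species, 49 substrates, 290,668-pair screens, 12-point
  k-mer sweeps) are this package's own benchmark configuration; nothing in
  the code depends on them.

## 9. Limitations

* The Wilcoxon screen tests marginal association only: no conditioning on
  phylogeny, no multivariate modelling, no effect-size estimation beyond the
  rank statistic. Treat hits as hypotheses for follow-up, not causal claims.
* The normal approximation accuracy bound (0.05) is established for untied
  configurations with both group sizes ≥ 4; highly unbalanced splits should
  rely on the exact test (automatic for n ≤ 14, otherwise set
  `p_method="exact"` is unavailable above `EXACT_N_MAX` by design — subsample
  or accept the approximation).
* BH q-values under `m_mode="all-pairs"` are deliberately conservative; use
  `m_mode="tested"` for textbook FDR control over performed tests.
* The exact test enumerates `C(n, n⁺)` assignments and is capped at `n = 14`.
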