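"""Deterministic hierarchical clustering for heatmap ordering.

Agglomerative clustering with Euclidean distances and complete linkage
(inter-cluster distance = maximum pairwise leaf distance), the combination
commonly used to order species and features in genotype-phenotype heatmaps.
The merge sequence is made fully deterministic by breaking distance ties on
the smallest (i, j) pair of cluster indices; newly formed clusters receive
indices n, n+1, ... in merge order (the scipy linkage convention).

``heatmap_export`` writes heatmap-ready artifacts: the count and phenotype
matrices restricted to significant orthogroups/substrates, with species rows
ordered by clustering on phenotype profiles and feature columns ordered by
clustering on their own profiles, plus order files and an annotation sidecar.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import (AnnotationMap, GenotypeMatrix, PhenotypeMatrix,
                 write_count_matrix, write_phenotype_matrix)

__all__ = ["MergeTree", "euclidean_distances", "complete_linkage",
           "leaf_order", "heatmap_export"]


@dataclass(frozen=True)
class MergeTree:
    """Sequence of (cluster_a, cluster_b, height) merges over n_leaves items."""

    n_leaves: int
    merges: tuple

    def __post_init__(self):
        if len(self.merges) != max(self.n_leaves - 1, 0):
            raise ValueError("a tree over n leaves must contain n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(h < 0 for h in heights):
            raise ValueError("merge heights must be non-negative")

    @property
    def heights(self) -> tuple:
        return tuple(h for _, _, h in self.merges)


def euclidean_distances(m, axis: str = "rows") -> np.ndarray:
    """Symmetric Euclidean distance matrix over rows or columns of ``m``."""
    a = np.asarray(m, dtype=float)
    if axis == "columns":
        a = a.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 items to compute distances")
    return squareform(pdist(a, metric="euclidean"))


def complete_linkage(d) -> MergeTree:
    """Agglomerate by minimal complete-linkage distance, deterministically.

    At each step the pair of active clusters with the smallest inter-cluster
    distance (maximum pairwise leaf distance) is merged; ties are broken by
    the lexicographically smallest (i, j) cluster-index pair.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    active: dict[int, tuple[int, ...]] = {i: (i,) for i in range(n)}
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            h = max(d[i, j] for i in active[a] for j in active[b])
            key = (h, a, b)
            if best is None or key < best:
                best = key
        h, a, b = best
        merges.append((a, b, float(h)))
        active[next_id] = active.pop(a) + active.pop(b)
        next_id += 1
    return MergeTree(n, tuple(merges))


def leaf_order(tree: MergeTree) -> list[int]:
    """Left-to-right dendrogram leaf order.

    At each merge the subtree containing the smallest original leaf index is
    placed on the left.
    """
    n = tree.n_leaves
    children = {n + k: (a, b) for k, (a, b, _) in enumerate(tree.merges)}
    min_leaf: dict[int, int] = {}

    def _min_leaf(c: int) -> int:
        if c not in min_leaf:
            if c < n:
                min_leaf[c] = c
            else:
                a, b = children[c]
                min_leaf[c] = min(_min_leaf(a), _min_leaf(b))
        return min_leaf[c]

    def _emit(c: int):
        if c < n:
            yield c
        else:
            a, b = children[c]
            left, right = sorted((a, b), key=_min_leaf)
            yield from _emit(left)
            yield from _emit(right)

    root = n + len(tree.merges) - 1 if tree.merges else 0
    return list(_emit(root))


def _axis_order(matrix: np.ndarray, axis: str) -> list[int]:
    n_items = matrix.shape[0] if axis == "rows" else matrix.shape[1]
    if n_items < 2:
        return list(range(n_items))
    return leaf_order(complete_linkage(euclidean_distances(matrix, axis)))


def heatmap_export(g: GenotypeMatrix, p: PhenotypeMatrix,
                   ann: AnnotationMap | None = None, outdir=".",
                   render: bool = False) -> dict[str, Path]:
    """Write heatmap-ready, cluster-ordered matrices and sidecars.

    Species rows are ordered by clustering on the phenotype profiles;
    orthogroup columns by clustering on their count profiles; substrate
    columns by clustering on their call profiles. ``ann`` supplies the
    functional-annotation sidecar (missing families are labelled
    "hypothetical protein"). With ``render=True`` a PNG is drawn when
    matplotlib is importable.
    """
    if list(g.species_ids) != list(p.species_ids):
        raise ValueError("matrices are not aligned on species")
    if g.counts.size == 0 or p.calls.size == 0:
        raise ValueError("empty selection: no significant orthogroups or "
                         "substrates at this threshold; relax alpha")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sp_order = _axis_order(p.calls, "rows")
    og_order = _axis_order(g.counts, "columns")
    sub_order = _axis_order(p.calls, "columns")

    species = [g.species_ids[i] for i in sp_order]
    orthogroups = [g.orthogroup_ids[j] for j in og_order]
    substrates = [p.substrate_ids[j] for j in sub_order]

    g_out = GenotypeMatrix(g.data.loc[species, orthogroups])
    p_out = PhenotypeMatrix(p.data.loc[species, substrates])

    paths = {
        "counts": outdir / "counts_ordered.tsv",
        "phenotypes": outdir / "phenotypes_ordered.tsv",
        "species_order": outdir / "species_order.txt",
        "orthogroup_order": outdir / "orthogroup_order.txt",
        "substrate_order": outdir / "substrate_order.txt",
        "annotations": outdir / "annotations.tsv",
    }
    write_count_matrix(g_out, paths["counts"])
    write_phenotype_matrix(p_out, paths["phenotypes"])
    paths["species_order"].write_text("\n".join(species) + "\n")
    paths["orthogroup_order"].write_text("\n".join(orthogroups) + "\n")
    paths["substrate_order"].write_text("\n".join(substrates) + "\n")
    ann = ann or AnnotationMap()
    with open(paths["annotations"], "w") as fh:
        for og in orthogroups:
            fh.write(f"{og}\t{ann.describe(og)}\n")
    if render:
        _render(g_out, p_out, outdir / "heatmap.png")
        paths["image"] = outdir / "heatmap.png"
    return paths


def _render(g: GenotypeMatrix, p: PhenotypeMatrix, path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # plotting support is optional
        return
    fig, axes = plt.subplots(
        1, 2, figsize=(2 + 0.25 * (g.shape[1] + p.shape[1]),
                       2 + 0.25 * g.shape[0]),
        gridspec_kw={"width_ratios": [max(g.shape[1], 1), max(p.shape[1], 1)]})
    for ax, m, title, cmap in ((axes[0], g.data, "gene copies", "RdYlGn"),
                               (axes[1], p.data, "phenotype", "cividis")):
        ax.imshow(m.to_numpy(), aspect="auto", cmap=cmap)
        ax.set_title(title)
        ax.set_xticks(range(m.shape[1]))
        ax.set_xticklabels(m.columns, rotation=90, fontsize=6)
    axes[0].set_yticks(range(g.shape[0]))
    axes[0].set_yticklabels(g.data.index, fontsize=6)
    axes[1].set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
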