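"""Core data containers and tab-separated readers/writers.

The two central objects mirror the inputs of a pan-genome association
screen: a species x orthogroup gene-count matrix (integer copy numbers
per multigene family, as produced by OrthoFinder's ``Orthogroups.GeneCount``
table) and a species x substrate binary phenotype matrix (e.g. API 50 CHL
fermentation calls, 1 = positive reaction, 0 = negative).

All files are UTF-8, tab-separated, with a header row of column ids and a
first column of species ids. Missing values are not permitted in inputs;
``NA`` is the sole missing-value token in outputs.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PhenotypeMatrix",
    "AnnotationMap",
    "MatrixParseError",
    "read_count_matrix",
    "read_phenotype_matrix",
    "read_annotation_map",
    "write_count_matrix",
    "write_phenotype_matrix",
    "align_matrices",
    "write_association_table",
    "read_association_table",
    "ASSOCIATION_COLUMNS",
]

ASSOCIATION_COLUMNS = (
    "orthogroup",
    "substrate",
    "n_pos",
    "n_neg",
    "statistic",
    "p_raw",
    "p_bonferroni",
    "q_bh",
    "status",
)


class MatrixParseError(ValueError):
    """A matrix file violated the expected layout or value domain."""


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dups = labels[labels.duplicated()].unique().tolist()
        raise MatrixParseError(f"duplicate {what} ids: {dups}")


class _LabelledMatrix:
    """Shared validation for species-by-feature integer matrices."""

    _feature_name = "feature"

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise TypeError("expected a pandas DataFrame")
        _check_unique(data.index, "species")
        _check_unique(data.columns, self._feature_name)
        values = data.to_numpy()
        if values.size:
            numeric = np.asarray(values, dtype=float)
            if np.isnan(numeric).any():
                raise MatrixParseError("matrix contains missing values")
            if (numeric < 0).any() or (numeric % 1 != 0).any():
                bad = np.argwhere((numeric < 0) | (numeric % 1 != 0))[0]
                raise MatrixParseError(
                    f"non-integer or negative value at species "
                    f"{data.index[bad[0]]!r}, {self._feature_name} "
                    f"{data.columns[bad[1]]!r}"
                )
        self.data = data.astype(np.int64)
        self._validate()

    def _validate(self) -> None:  # pragma: no cover - overridden
        pass

    @property
    def species_ids(self) -> list:
        return list(self.data.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def equals(self, other: "_LabelledMatrix") -> bool:
        return type(self) is type(other) and self.data.equals(other.data)

    def __repr__(self) -> str:
        n, m = self.data.shape
        return f"{type(self).__name__}({n} species x {m} {self._feature_name}s)"


class GenotypeMatrix(_LabelledMatrix):
    """Species x orthogroup matrix of non-negative gene copy counts."""

    _feature_name = "orthogroup"

    @property
    def orthogroup_ids(self) -> list:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @classmethod
    def from_arrays(cls, species_ids, orthogroup_ids, counts) -> "GenotypeMatrix":
        return cls(pd.DataFrame(np.asarray(counts), index=list(species_ids),
                                columns=list(orthogroup_ids)))


class PhenotypeMatrix(_LabelledMatrix):
    """Species x substrate matrix of binary fermentation calls (0/1)."""

    _feature_name = "substrate"

    def _validate(self) -> None:
        values = self.data.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise MatrixParseError(
                f"phenotype call not 0/1 at species {self.data.index[bad[0]]!r}, "
                f"substrate {self.data.columns[bad[1]]!r}"
            )

    @property
    def substrate_ids(self) -> list:
        return list(self.data.columns)

    @property
    def calls(self) -> np.ndarray:
        return self.data.to_numpy()

    @classmethod
    def from_arrays(cls, species_ids, substrate_ids, calls) -> "PhenotypeMatrix":
        return cls(pd.DataFrame(np.asarray(calls), index=list(species_ids),
                                columns=list(substrate_ids)))


class AnnotationMap(Mapping):
    """Orthogroup -> free-text functional description.

    Orthogroups absent from the map are reported as ``"hypothetical protein"``,
    the conventional label for functionally unannotated families.
    """

    HYPOTHETICAL = "hypothetical protein"

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map = dict(mapping or {})

    def describe(self, orthogroup_id: str) -> str:
        return self._map.get(orthogroup_id, self.HYPOTHETICAL)

    def check_against(self, orthogroup_ids: Sequence[str]) -> set:
        """Warn about map keys not present among the given orthogroups."""
        unmatched = set(self._map) - set(orthogroup_ids)
        if unmatched:
            logger.warning(
                "%d annotation keys match no orthogroup (e.g. %s)",
                len(unmatched), sorted(unmatched)[:3],
            )
        return unmatched

    def __getitem__(self, key: str) -> str:
        return self._map[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise MatrixParseError(f"ragged or malformed table {path}: {exc}") from exc
    _check_unique(df.index, "species")
    _check_unique(df.columns, "column")
    return df


def _cell_error(df: pd.DataFrame, mask: np.ndarray, path, reason: str) -> None:
    i, j = np.argwhere(mask)[0]
    raise MatrixParseError(
        f"{reason} at row {df.index[i]!r}, column {df.columns[j]!r} in {path}"
    )


def read_count_matrix(path) -> GenotypeMatrix:
    """Parse an OrthoFinder-style gene-count table.

    Layout: header row of orthogroup ids (first cell is a corner label),
    one row per species with integer copy counts. Row and column order are
    preserved.
    """
    df = _read_table(path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    values = numeric.to_numpy(dtype=float)
    if np.isnan(values).any():
        _cell_error(df, np.isnan(values), path, "non-numeric or missing cell")
    if ((values < 0) | (values % 1 != 0)).any():
        _cell_error(df, (values < 0) | (values % 1 != 0), path,
                    "non-integer or negative count")
    return GenotypeMatrix(numeric)


def read_phenotype_matrix(path) -> PhenotypeMatrix:
    """Parse a binary phenotype table; any token other than 0 or 1 is an error."""
    df = _read_table(path)
    stripped = df.apply(lambda col: col.str.strip())
    ok = stripped.isin(["0", "1"]).to_numpy()
    if not ok.all():
        _cell_error(df, ~ok, path, "phenotype call not 0/1")
    return PhenotypeMatrix(stripped.astype(np.int64))


def read_annotation_map(path) -> AnnotationMap:
    """Read a two-column (orthogroup_id <tab> description) file, no header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                     names=["orthogroup", "description"], keep_default_na=False)
    _check_unique(pd.Index(df["orthogroup"]), "orthogroup")
    return AnnotationMap(dict(zip(df["orthogroup"], df["description"])))


def write_count_matrix(g: GenotypeMatrix, path) -> None:
    g.data.to_csv(path, sep="\t", index_label="species")


def write_phenotype_matrix(p: PhenotypeMatrix, path) -> None:
    p.data.to_csv(path, sep="\t", index_label="species")


def align_matrices(g: GenotypeMatrix, p: PhenotypeMatrix
                   ) -> tuple[GenotypeMatrix, PhenotypeMatrix]:
    """Restrict both matrices to their shared species, in the genotype order.

    Dropped species are reported through the module logger. Raises if the
    species sets are disjoint. Idempotent.
    """
    shared = [s for s in g.species_ids if s in set(p.species_ids)]
    if not shared:
        raise ValueError("no species shared between genotype and phenotype matrices")
    dropped_g = sorted(set(g.species_ids) - set(shared))
    dropped_p = sorted(set(p.species_ids) - set(shared))
    if dropped_g or dropped_p:
        logger.info("align_matrices dropped %d genotype-only (%s) and %d "
                    "phenotype-only (%s) species",
                    len(dropped_g), dropped_g, len(dropped_p), dropped_p)
    if shared == g.species_ids and shared == p.species_ids:
        return g, p
    return (GenotypeMatrix(g.data.loc[shared]),
            PhenotypeMatrix(p.data.loc[shared]))


def write_association_table(table, path) -> None:
    """Write an association table as TSV.

    Columns follow :data:`ASSOCIATION_COLUMNS`; undefined values are ``NA``.
    Rows are sorted by raw p ascending, degenerate (skipped) rows last, ties
    broken lexicographically on (orthogroup, substrate). Floats carry full
    precision (17 significant digits) so a read-back reproduces them.
    """
    df = table.df.loc[:, list(ASSOCIATION_COLUMNS)].copy()
    df["_skip"] = (df["status"] != "tested").astype(int)
    df = df.sort_values(["_skip", "p_raw", "orthogroup", "substrate"],
                        na_position="last").drop(columns="_skip")
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_association_table(path) -> pd.DataFrame:
    """Read back a written association table as a DataFrame (NA -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                       float_precision="round_trip")
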