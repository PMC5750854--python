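"""Parsing, normalization and validation of multi-source gene evidence.

The prioritizer consumes a binary evidence matrix: one row per gene, one
0/1 column per evidence category (association study, linkage region,
expression profiling, literature search, ...), plus a curated "core" set
of genes known to be associated with the phenotype.  The upload format is
a plain CSV of gene lists: each column holds the symbols contributed by
one source and the last column holds the core gene set.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoreCoverageWarning",
    "EvidenceFormatError",
    "EvidenceMatrix",
    "normalize_symbol",
    "read_evidence_csv",
    "write_evidence_csv",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "matrix_summary",
]

_WS = re.compile(r"\s+")


class EvidenceFormatError(ValueError):
    """Raised when an evidence file violates the expected CSV/TSV layout."""


class CoreCoverageWarning(UserWarning):
    """A core gene appears in no evidence column (all-zero evidence row)."""


def normalize_symbol(raw: str) -> str:
    """Normalize a gene symbol token.

    Uppercases, strips leading/trailing whitespace and collapses internal
    whitespace runs to a single space, so that ``" drd2 "`` and ``"DRD2"``
    map to the same symbol.  Normalization is idempotent.

    Raises
    ------
    ValueError
        If ``raw`` is empty or whitespace-only.
    """
    if not isinstance(raw, str):
        raise TypeError(f"gene symbol must be a string, got {type(raw).__name__}")
    token = _WS.sub(" ", raw.strip()).upper()
    if not token:
        raise ValueError(f"empty gene symbol cell: {raw!r}")
    return token


@dataclass(frozen=True)
class EvidenceMatrix:
    """Genes x categories binary indicator matrix plus the core gene set.

    Attributes
    ----------
    categories : tuple of str
        Ordered evidence-source names (N >= 2), in upload-column order.
    genes : tuple of str
        Normalized gene symbols, sorted lexicographically.
    indicator : ndarray of shape (n_genes, n_categories)
        0/1 membership of each gene in each category.
    core : frozenset of str
        Gold-standard genes for the phenotype; may be empty for pure
        scoring, must be non-empty before weight optimization.
    """

    categories: tuple[str, ...]
    genes: tuple[str, ...]
    indicator: np.ndarray = field(repr=False)
    core: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise EvidenceFormatError(
                f"need at least 2 evidence categories, got {len(self.categories)}"
            )
        if len(set(self.categories)) != len(self.categories):
            raise EvidenceFormatError("duplicate category names")
        ind = np.asarray(self.indicator, dtype=np.int8)
        if ind.shape != (len(self.genes), len(self.categories)):
            raise ValueError(
                f"indicator shape {ind.shape} does not match "
                f"{len(self.genes)} genes x {len(self.categories)} categories"
            )
        if ind.size and not np.isin(ind, (0, 1)).all():
            raise ValueError("indicator entries must be exactly 0 or 1")
        if list(self.genes) != sorted(set(self.genes)):
            raise ValueError("genes must be unique and lexicographically sorted")
        unknown_core = self.core - set(self.genes)
        if unknown_core:
            raise ValueError(f"core genes missing from gene list: {sorted(unknown_core)}")
        # Genes with no supporting evidence are tolerated only for core
        # genes (kept with an all-zero row so the gold standard is not
        # silently truncated); any other all-zero row is a construction bug.
        if ind.size:
            zero_rows = np.flatnonzero(ind.sum(axis=1) == 0)
            bad = [self.genes[i] for i in zero_rows if self.genes[i] not in self.core]
            if bad:
                raise ValueError(f"non-core genes with all-zero evidence: {bad}")
        object.__setattr__(self, "indicator", ind)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def core_mask(self) -> np.ndarray:
        """Boolean array aligned with ``genes``: True for core genes."""
        return np.fromiter(
            (g in self.core for g in self.genes), dtype=bool, count=len(self.genes)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvidenceMatrix):
            return NotImplemented
        return (
            self.categories == other.categories
            and self.genes == other.genes
            and self.core == other.core
            and np.array_equal(self.indicator, other.indicator)
        )

    def __hash__(self) -> int:  # frozen dataclass with ndarray: hash on identity keys
        return hash((self.categories, self.genes, self.core))


def _build_matrix(
    categories: list[str],
    source_sets: list[set[str]],
    core: set[str],
    origin: str,
) -> EvidenceMatrix:
    genes = sorted(set().union(*source_sets, core))
    indicator = np.zeros((len(genes), len(categories)), dtype=np.int8)
    index = {g: i for i, g in enumerate(genes)}
    for j, members in enumerate(source_sets):
        for g in members:
            indicator[index[g], j] = 1
    orphans = sorted(g for g in core if indicator[index[g]].sum() == 0)
    if orphans:
        warnings.warn(
            f"{origin}: core gene(s) {orphans} appear in no evidence column; "
            "kept with an all-zero evidence row",
            CoreCoverageWarning,
            stacklevel=3,
        )
    return EvidenceMatrix(
        categories=tuple(categories),
        genes=tuple(genes),
        indicator=indicator,
        core=frozenset(core),
    )


def read_evidence_csv(path) -> EvidenceMatrix:
    """Read the gene-list upload CSV into an :class:`EvidenceMatrix`.

    Layout: a mandatory header row of column names; every column except
    the last lists the gene symbols contributed by one evidence source;
    the last column lists the core gene set.  Rows may be ragged (gene
    lists of unequal length); empty cells are ignored; duplicate symbols
    within a column collapse to one.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise EvidenceFormatError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    if len(header) < 3:
        raise EvidenceFormatError(
            f"{path}: need at least 3 columns (>=2 sources + core), got {len(header)}"
        )
    if any(not h for h in header):
        raise EvidenceFormatError(f"{path}: blank column name in header")
    ncol = len(header)
    columns: list[set[str]] = [set() for _ in range(ncol)]
    for r, row in enumerate(rows[1:], start=2):
        if len(row) > ncol:
            raise EvidenceFormatError(
                f"{path}: row {r} has {len(row)} cells but header has {ncol}"
            )
        for c, cell in enumerate(row):
            if cell.strip() == "":
                continue
            try:
                columns[c].add(normalize_symbol(cell))
            except ValueError as exc:
                raise EvidenceFormatError(f"{path}: row {r}, column {header[c]!r}: {exc}")
    return _build_matrix(header[:-1], columns[:-1], columns[-1], origin=str(path))


def write_evidence_csv(matrix: EvidenceMatrix, path) -> None:
    """Serialize a matrix back to the gene-list upload CSV (round-trips)."""
    lists = [
        sorted(g for i, g in enumerate(matrix.genes) if matrix.indicator[i, j])
        for j in range(matrix.n_categories)
    ]
    lists.append(sorted(matrix.core))
    depth = max((len(col) for col in lists), default=0)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(matrix.categories) + ["core"])
        for i in range(depth):
            writer.writerow([col[i] if i < len(col) else "" for col in lists])


def write_matrix_tsv(matrix: EvidenceMatrix, path) -> None:
    """Write the binary matrix as TSV: gene, one 0/1 column per category, is_core."""
    core = matrix.core_mask
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene", *matrix.categories, "is_core"])
        for i, g in enumerate(matrix.genes):
            writer.writerow([g, *matrix.indicator[i].tolist(), int(core[i])])


def read_matrix_tsv(path) -> EvidenceMatrix:
    """Companion reader for :func:`write_matrix_tsv` (lossless round-trip)."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows or rows[0][:1] != ["gene"] or rows[0][-1] != "is_core":
        raise EvidenceFormatError(f"{path}: not a matrix TSV (expected gene ... is_core header)")
    categories = rows[0][1:-1]
    genes, core, data = [], set(), []
    for row in rows[1:]:
        genes.append(normalize_symbol(row[0]))
        data.append([int(v) for v in row[1:-1]])
        if int(row[-1]):
            core.add(genes[-1])
    order = np.argsort(genes)
    genes_sorted = [genes[i] for i in order]
    indicator = np.asarray(data, dtype=np.int8)[order] if data else np.zeros((0, len(categories)), np.int8)
    return EvidenceMatrix(tuple(categories), tuple(genes_sorted), indicator, frozenset(core))


def matrix_summary(matrix: EvidenceMatrix) -> dict:
    """JSON-ready summary: sizes plus any core-coverage warnings."""
    uncovered = sorted(
        g
        for i, g in enumerate(matrix.genes)
        if g in matrix.core and matrix.indicator[i].sum() == 0
    )
    warns = (
        [f"core gene(s) with no evidence in any category: {', '.join(uncovered)}"]
        if uncovered
        else []
    )
    return {
        "n_genes": matrix.n_genes,
        "n_categories": matrix.n_categories,
        "n_core": len(matrix.core),
        "warnings": warns,
    }


def write_summary_json(matrix: EvidenceMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(matrix_summary(matrix), fh, indent=2, sort_keys=True)
        fh.write("\n")
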