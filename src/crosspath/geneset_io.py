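"""Reading, validation and filtering of gene-set collections and p-value matrices.

Gene-set collections come in GMT format (one tab-separated line per set:
id, description-or-URL, then gene symbols), the de-facto interchange format
for MSigDB-style pathway databases.  Human-readable pathway names and free-text
descriptions live in a separate three-column TSV (id, name, description) and
are attached to a parsed collection.  Differential-expression and enrichment
p-value matrices are plain TSVs with a header row of study labels and a first
column of gene or pathway ids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "read_description_table",
    "attach_descriptions",
    "filter_by_size",
    "read_pvalue_matrix",
    "write_pvalue_matrix",
]


@dataclass(frozen=True)
class GeneSet:
    """A named pathway: a set of gene symbols with id, short name and free text.

    The description may be empty (several public databases ship bare names);
    downstream keyword annotation then relies on the name alone.
    """

    id: str
    genes: frozenset[str]
    name: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("gene set id must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.id!r} has no genes")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered list of gene sets plus the background gene universe.

    The universe defaults to the union of all member sets but may be replaced
    by the measured gene list of the studies under analysis (over-representation
    tests must only count testable genes as background).
    """

    sets: tuple[GeneSet, ...]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sets]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene set ids: {dupes}")
        stray = set().union(*(s.genes for s in self.sets)) - self.universe if self.sets else set()
        if stray:
            raise ValueError(
                f"{len(stray)} genes appear in sets but not in the universe, "
                f"e.g. {sorted(stray)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sets]

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.id == set_id:
                return s
        raise KeyError(set_id)

    def with_universe(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Restrict to a new background universe, intersecting every set with it.

        Sets that become empty are dropped (they are untestable against this
        background).
        """
        uni = frozenset(g.upper() for g in universe)
        kept = []
        for s in self.sets:
            genes = s.genes & uni
            if genes:
                kept.append(replace(s, genes=frozenset(genes)))
        return GeneSetCollection(sets=tuple(kept), universe=uni)


def _normalize_symbol(gene: str) -> str:
    # Upper-casing makes cross-database joins robust (HGNC symbols are
    # conventionally upper-case; mouse-style mixed case collides otherwise).
    return gene.strip().upper()


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each line must have at least three tab-separated fields: set id, a
    description-or-URL field (stored as the description), and one or more gene
    symbols.  Gene symbols are upper-cased; duplicates within a line are
    dropped with a warning.  The background universe defaults to the union of
    all parsed sets.

    Raises
    ------
    ValueError
        On a malformed line (fewer than three fields, reported with its line
        number) or a duplicated set id.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    n_collisions = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: malformed GMT line "
                    f"({len(fields)} fields, need id, description and >=1 gene)"
                )
            set_id, desc = fields[0], fields[1]
            if set_id in seen:
                raise ValueError(f"{path.name}:{lineno}: duplicate gene set id {set_id!r}")
            seen.add(set_id)
            raw = [g for g in fields[2:] if g.strip()]
            genes = [_normalize_symbol(g) for g in raw]
            n_collisions += len(genes) - len(set(genes))
            if len(genes) != len(set(genes)):
                warnings.warn(
                    f"{path.name}:{lineno}: {len(genes) - len(set(genes))} duplicate "
                    f"gene(s) in set {set_id!r} dropped",
                    stacklevel=2,
                )
            sets.append(GeneSet(id=set_id, genes=frozenset(genes), description=desc))
    if n_collisions:
        logger.info("read_gmt: %d within-set gene symbol collisions after upper-casing", n_collisions)
    if universe is None:
        uni = frozenset().union(*(s.genes for s in sets)) if sets else frozenset()
    else:
        uni = frozenset(_normalize_symbol(g) for g in universe)
    return GeneSetCollection(sets=tuple(sets), universe=uni)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    """Write a collection to GMT (id, description, sorted genes)."""
    with Path(path).open("w") as fh:
        for s in coll.sets:
            fh.write("\t".join([s.id, s.description or s.name or "na", *sorted(s.genes)]) + "\n")


def read_description_table(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a 3-column TSV (id, name, description) into a mapping."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError("description table needs 3 columns: id, name, description")
    return {row.iloc[0]: (row.iloc[1], row.iloc[2]) for _, row in df.iterrows()}


def attach_descriptions(
    coll: GeneSetCollection, table: Mapping[str, tuple[str, str]]
) -> GeneSetCollection:
    """Attach (name, description) pairs to sets, matched by id.

    Sets without an entry keep an empty description and are counted in a log
    message (sparse annotation limits downstream keyword mining).

    Raises
    ------
    KeyError
        If the table contains ids not present in the collection.
    """
    known = set(coll.ids)
    stray = sorted(set(table) - known)
    if stray:
        raise KeyError(f"description table has {len(stray)} unknown pathway id(s): {stray[:10]}")
    out = []
    n_missing = 0
    for s in coll.sets:
        if s.id in table:
            name, desc = table[s.id]
            out.append(replace(s, name=name, description=desc))
        else:
            n_missing += 1
            out.append(s)
    if n_missing:
        logger.info("attach_descriptions: %d/%d sets have no description entry", n_missing, len(coll))
    return GeneSetCollection(sets=tuple(out), universe=coll.universe)


def filter_by_size(
    coll: GeneSetCollection,
    min_genes: int = 15,
    max_genes: int = 500,
    restrict_to: Iterable[str] | None = None,
) -> GeneSetCollection:
    """Keep sets with min_genes <= size <= max_genes (bounds inclusive).

    ``restrict_to``, if given, is a gene universe (e.g. the measured genes of
    the studies); sizes are then counted after intersecting each set with it,
    so that untestable genes do not inflate a pathway past the bounds.

    Raises
    ------
    ValueError
        If the bounds are invalid or no set survives.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    if min_genes > max_genes:
        raise ValueError("min_genes must be <= max_genes")
    restr = frozenset(_normalize_symbol(g) for g in restrict_to) if restrict_to is not None else None
    kept = []
    for s in coll.sets:
        n = len(s.genes & restr) if restr is not None else len(s.genes)
        if min_genes <= n <= max_genes:
            kept.append(s)
    if not kept:
        raise ValueError(
            f"no gene set has between {min_genes} and {max_genes} genes; loosen the bounds"
        )
    return GeneSetCollection(sets=tuple(kept), universe=coll.universe)


def read_pvalue_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV p-value matrix: first column row ids, header of study labels.

    Works for both gene-level DE p-values and pathway-level enrichment
    p-values.  Values must lie in (0, 1]; exact zeros are rejected here (they
    must be floored by the producer; downstream log-transforms cannot take 0).
    """
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in {path}: {dupes[:5]}")
    if df.isna().any().any():
        raise ValueError(f"missing values in p-value matrix {path}")
    vals = df.to_numpy()
    if (vals <= 0).any() or (vals > 1).any():
        raise ValueError(f"p-values in {path} must lie in (0, 1]")
    return df


def write_pvalue_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True)
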