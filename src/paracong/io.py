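"""Core domain containers and readers/writers for the standard formats.

All tabular formats are TSV (tab-separated, UTF-8) with a header row; the
first column holds row identifiers. Lines starting with ``#`` are treated
as comments (the CLI writes provenance headers this way) and ignored on
read. Trees are Newick, parsed through dendropy.

Containers
----------
CommunityTable   taxa x samples non-negative abundance matrix
MetaboliteTable  metabolites x samples non-negative intensity matrix
PhyloTree        rooted tree with non-negative branch lengths
TaxonomyMap      taxon -> ordered ranks (kingdom .. genus)
DistanceMatrix   symmetric sample x sample dissimilarities
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS: tuple[str, ...] = ("kingdom", "phylum", "class", "order", "family", "genus")
RANK_PREFIXES: tuple[str, ...] = ("k__", "p__", "c__", "o__", "f__", "g__")
UNASSIGNED = "unassigned"

__all__ = [
    "RANKS",
    "UNASSIGNED",
    "CommunityTable",
    "MetaboliteTable",
    "PhyloTree",
    "TaxonomyMap",
    "DistanceMatrix",
    "read_community_table",
    "write_community_table",
    "read_metabolite_table",
    "write_metabolite_table",
    "read_newick",
    "write_newick",
    "read_taxonomy",
    "write_taxonomy",
    "read_distance_matrix",
    "write_distance_matrix",
]


def _coerce_numeric(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Convert every cell to float, naming the first offending cell on failure."""
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy()][0]
            raise ValueError(
                f"{what}: non-numeric value {df.at[row, col]!r} at row {row!r}, "
                f"column {col!r}"
            )
        if converted.isna().any():
            row = df.index[converted.isna().to_numpy()][0]
            raise ValueError(f"{what}: missing value at row {row!r}, column {col!r}")
        out[col] = converted.astype(float)
    return pd.DataFrame(out, index=df.index)


def _check_ids(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"{what}: duplicate identifiers {dups}")
    if any(str(i).strip() == "" for i in ids):
        raise ValueError(f"{what}: empty identifier")


class _SampleMatrix:
    """Shared behaviour of taxa x samples and metabolites x samples matrices."""

    _row_kind = "feature"

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        data.index = data.index.astype(str)
        data.columns = data.columns.astype(str)
        _check_ids(data.index, f"{type(self).__name__} {self._row_kind} ids")
        _check_ids(data.columns, f"{type(self).__name__} sample ids")
        data = _coerce_numeric(data, type(self).__name__)
        values = data.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError(f"{type(self).__name__}: non-finite entries")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"{type(self).__name__}: negative entry at row "
                f"{data.index[r]!r}, column {data.columns[c]!r}"
            )
        self.data = data

    # -- basic introspection -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, type(self)) and self.data.equals(other.data)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"{type(self).__name__}({n} {self._row_kind}s x {m} samples)"

    # -- IO ------------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path, orientation: str = "taxa-rows"):
        if orientation not in ("taxa-rows", "samples-rows"):
            raise ValueError(f"unknown orientation {orientation!r}")
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
        if orientation == "samples-rows":
            df = df.T
        return cls(df)

    def to_tsv(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.data.to_csv(fh, sep="\t", index_label="id")


class CommunityTable(_SampleMatrix):
    """Taxa x samples table of read counts (or relative abundances)."""

    _row_kind = "taxon"

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def counts(self) -> np.ndarray:
        return self.values

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; errors on an all-zero sample."""
        totals = self.data.sum(axis=0)
        zero = totals[totals == 0].index.tolist()
        if zero:
            raise ValueError(f"all-zero sample(s): {zero}")
        return self.data / totals

    def drop_taxa(self, taxa: Iterable[str]) -> "CommunityTable":
        taxa = set(taxa)
        keep = [t for t in self.data.index if t not in taxa]
        return CommunityTable(self.data.loc[keep])

    def select_samples(self, sample_ids: Sequence[str]) -> "CommunityTable":
        return CommunityTable(self.data.loc[:, list(sample_ids)])


class MetaboliteTable(_SampleMatrix):
    """Metabolites x samples table of non-negative intensities."""

    _row_kind = "metabolite"

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.index)

    def select_samples(self, sample_ids: Sequence[str]) -> "MetaboliteTable":
        return MetaboliteTable(self.data.loc[:, list(sample_ids)])


def read_community_table(path: str | Path, orientation: str = "taxa-rows") -> CommunityTable:
    return CommunityTable.from_tsv(path, orientation=orientation)


def write_community_table(
    table: CommunityTable, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    table.to_tsv(path, header_lines=header_lines)


def read_metabolite_table(path: str | Path, orientation: str = "taxa-rows") -> MetaboliteTable:
    return MetaboliteTable.from_tsv(path, orientation=orientation)


def write_metabolite_table(
    table: MetaboliteTable, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    table.to_tsv(path, header_lines=header_lines)


# ---------------------------------------------------------------------------
# Phylogenetic tree
# ---------------------------------------------------------------------------


class PhyloTree:
    """Rooted phylogeny with non-negative branch lengths, leaves = taxon ids.

    Wraps a :class:`dendropy.Tree`. Missing branch lengths are set to 0
    with a warning so purely topological toy trees load. The edge set used
    throughout is "every node except the root": each such node contributes
    the edge above it, carrying its branch length and its descendant leaf
    set.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = []
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else leaf.label
            if label is None:
                raise ValueError("tree contains an unlabelled leaf")
            labels.append(str(label))
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dups}")
        self._leaf_labels = labels
        n_missing = 0
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            if node.edge.length is None:
                node.edge.length = 0.0
                n_missing += 1
            elif node.edge.length < 0:
                raise ValueError(f"negative branch length {node.edge.length}")
        if n_missing:
            logger.warning("%d branch length(s) missing; set to 0", n_missing)
        self._edge_table: list[tuple[float, frozenset[str]]] | None = None

    # -- construction --------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse-error types
            raise ValueError(f"invalid Newick: {exc}") from exc
        return cls(tree)

    # -- properties ----------------------------------------------------------
    @property
    def leaf_labels(self) -> list[str]:
        return list(self._leaf_labels)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_labels)

    @property
    def n_edges(self) -> int:
        return len(self.edge_table())

    def edge_table(self) -> list[tuple[float, frozenset[str]]]:
        """(branch length, descendant leaf set) for every non-root node."""
        if self._edge_table is None:
            leaf_sets: dict[int, frozenset[str]] = {}
            table = []
            for node in self._tree.postorder_node_iter():
                if node.is_leaf():
                    label = node.taxon.label if node.taxon is not None else node.label
                    leaf_sets[id(node)] = frozenset([str(label)])
                else:
                    merged: set[str] = set()
                    for child in node.child_nodes():
                        merged |= leaf_sets[id(child)]
                    leaf_sets[id(node)] = frozenset(merged)
                if node is not self._tree.seed_node:
                    table.append((float(node.edge.length), leaf_sets[id(node)]))
            self._edge_table = table
        return self._edge_table

    def edge_arrays(self, taxon_order: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Branch lengths and boolean descendant masks over ``taxon_order``.

        Taxa in ``taxon_order`` that are not tree leaves raise; tree leaves
        absent from ``taxon_order`` simply contribute no abundance.
        """
        missing = sorted(set(taxon_order) - set(self._leaf_labels))
        if missing:
            raise ValueError(f"taxa absent from tree: {missing}")
        idx = {t: i for i, t in enumerate(taxon_order)}
        edges = self.edge_table()
        lengths = np.array([b for b, _ in edges], dtype=float)
        masks = np.zeros((len(edges), len(taxon_order)), dtype=bool)
        for e, (_, leaves) in enumerate(edges):
            for leaf in leaves:
                j = idx.get(leaf)
                if j is not None:
                    masks[e, j] = True
        return lengths, masks

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def to_dendropy(self) -> dendropy.Tree:
        return self._tree


def read_newick(path: str | Path) -> PhyloTree:
    text = Path(path).read_text(encoding="utf-8")
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


class TaxonomyMap:
    """Mapping from taxon id to named ranks (kingdom..genus).

    Lookups for taxa without an entry, or with an empty rank, return
    ``"unassigned"`` so downstream grouping never KeyErrors.
    """

    def __init__(self, mapping: Mapping[str, Mapping[str, str | None]]):
        clean: dict[str, dict[str, str | None]] = {}
        for taxon, ranks in mapping.items():
            unknown = set(ranks) - set(RANKS)
            if unknown:
                raise ValueError(f"unknown rank(s) {sorted(unknown)} for taxon {taxon!r}")
            clean[str(taxon)] = {r: ranks.get(r) or None for r in RANKS}
        self._map = clean

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._map

    def __len__(self) -> int:
        return len(self._map)

    @property
    def taxa(self) -> list[str]:
        return list(self._map)

    def get(self, taxon: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        entry = self._map.get(taxon)
        if entry is None:
            return UNASSIGNED
        return entry[rank] or UNASSIGNED

    def groups_at_rank(self, rank: str, taxa: Iterable[str]) -> dict[str, list[str]]:
        """Partition ``taxa`` by their label at ``rank`` (incl. unassigned)."""
        groups: dict[str, list[str]] = {}
        for t in taxa:
            groups.setdefault(self.get(t, rank), []).append(t)
        return groups

    def lineage_string(self, taxon: str) -> str:
        entry = self._map.get(taxon, {})
        return ";".join(
            f"{p}{entry.get(r) or ''}" for p, r in zip(RANK_PREFIXES, RANKS)
        )


def _parse_lineage(lineage: str) -> dict[str, str | None]:
    ranks: dict[str, str | None] = {}
    for field in str(lineage).split(";"):
        field = field.strip()
        if not field:
            continue
        for prefix, rank in zip(RANK_PREFIXES, RANKS):
            if field.startswith(prefix):
                value = field[len(prefix):].strip()
                ranks[rank] = value or None
                break
        # fields without a recognised prefix are ignored (e.g. s__)
    return ranks


def read_taxonomy(path: str | Path, dialect: str = "lineage-string") -> TaxonomyMap:
    if dialect not in ("lineage-string", "rank-columns"):
        raise ValueError(f"unknown taxonomy dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    _check_ids(df.index.astype(str), "taxonomy taxon ids")
    mapping: dict[str, dict[str, str | None]] = {}
    if dialect == "lineage-string":
        if df.shape[1] < 1:
            raise ValueError("lineage-string taxonomy needs a lineage column")
        lineages = df.iloc[:, 0]
        for taxon, lineage in lineages.items():
            mapping[str(taxon)] = _parse_lineage("" if pd.isna(lineage) else lineage)
    else:
        cols = {c.lower(): c for c in df.columns}
        for taxon, row in df.iterrows():
            entry: dict[str, str | None] = {}
            for rank in RANKS:
                if rank in cols:
                    value = row[cols[rank]]
                    entry[rank] = None if pd.isna(value) else (str(value).strip() or None)
            mapping[str(taxon)] = entry
    return TaxonomyMap(mapping)


def write_taxonomy(
    taxonomy: TaxonomyMap, path: str | Path, dialect: str = "lineage-string"
) -> None:
    if dialect not in ("lineage-string", "rank-columns"):
        raise ValueError(f"unknown taxonomy dialect {dialect!r}")
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "lineage-string":
            fh.write("taxon_id\tlineage\n")
            for taxon in taxonomy.taxa:
                fh.write(f"{taxon}\t{taxonomy.lineage_string(taxon)}\n")
        else:
            fh.write("taxon_id\t" + "\t".join(RANKS) + "\n")
            for taxon in taxonomy.taxa:
                values = [taxonomy.get(taxon, r) for r in RANKS]
                values = ["" if v == UNASSIGNED else v for v in values]
                fh.write(taxon + "\t" + "\t".join(values) + "\n")


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric sample x sample dissimilarity matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        _check_ids(pd.Index(self.ids), "DistanceMatrix sample ids")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"DistanceMatrix: values shape {self.values.shape} != ({n}, {n})"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("DistanceMatrix: non-finite entries")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-10:
            raise ValueError("DistanceMatrix: not symmetric within 1e-10")
        if np.abs(np.diag(self.values)).max(initial=0.0) > 1e-10:
            raise ValueError("DistanceMatrix: non-zero diagonal")
        if (self.values < -1e-10).any():
            raise ValueError("DistanceMatrix: negative entries")
        # enforce exact invariants after tolerance checks
        self.values = np.maximum((self.values + self.values.T) / 2.0, 0.0)
        np.fill_diagonal(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValueError("distance matrix rows and columns disagree")
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    return DistanceMatrix.from_tsv(path)


def write_distance_matrix(
    dm: DistanceMatrix, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    dm.to_tsv(path, header_lines=header_lines)
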