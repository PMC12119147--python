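"""Dated trees, community matrices, and sampling-coverage tabulation.

The two central containers are :class:`DatedTree`, a thin wrapper around a
rooted :class:`dendropy.Tree` with nonnegative branch lengths in time units
(Ma), and :class:`CommunityMatrix`, a binary species x area occupancy table
backed by a pandas DataFrame.  Both validate their invariants on
construction, so downstream metric code can assume clean inputs.

Species names use underscores; spaces in labels are normalized to
underscores on input (newick convention), and comparison is case-sensitive
otherwise.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloendemismError",
    "NewickError",
    "MatrixError",
    "ReconcileError",
    "UltrametricityError",
    "DatedTree",
    "CommunityMatrix",
    "CoverageTable",
    "normalize_name",
    "read_newick",
    "write_newick",
    "read_community",
    "reconcile",
    "coverage_summary",
    "percent_1dp",
]


class PhyloendemismError(Exception):
    """Base class for all errors raised by this package."""


class NewickError(PhyloendemismError):
    """Malformed or incomplete newick input."""


class MatrixError(PhyloendemismError):
    """Invalid community-matrix input."""


class ReconcileError(PhyloendemismError):
    """Tree tips and matrix rows cannot be reconciled."""


class UltrametricityError(PhyloendemismError):
    """A tree required to be ultrametric is not, beyond tolerance."""


def normalize_name(name: str) -> str:
    """Normalize a species label: strip whitespace, spaces -> underscores."""
    return name.strip().replace(" ", "_")


# ---------------------------------------------------------------------------
# DatedTree
# ---------------------------------------------------------------------------


class DatedTree:
    """A rooted tree with branch lengths in time units (Ma).

    Wraps a :class:`dendropy.Tree`.  Every non-root node must carry a
    nonnegative branch length; tip labels must be unique.  Node ages are
    derived quantities: age(node) = root_age - depth(node), with the root
    age taken as the maximum root-to-tip path length.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._tree.is_rooted = True  # trees are rooted as read; no rerooting
        self._normalize_labels()
        self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, path: str | Path) -> "DatedTree":
        path = Path(path)
        try:
            tree = dendropy.Tree.get(
                path=str(path), schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickError(f"failed to parse newick file {path}: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_string(cls, newick: str) -> "DatedTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise NewickError(f"failed to parse newick string: {exc}") from exc
        return cls(tree)

    def _normalize_labels(self) -> None:
        for taxon in self._tree.taxon_namespace:
            if taxon.label is not None:
                taxon.label = normalize_name(taxon.label)

    def _validate(self) -> None:
        seen: set[str] = set()
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise NewickError("tree has an unlabeled tip")
            label = leaf.taxon.label
            if label in seen:
                raise NewickError(f"duplicate tip label: {label!r}")
            seen.add(label)
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            if node.edge.length is None:
                who = node.taxon.label if node.taxon else "an internal node"
                raise NewickError(
                    f"missing branch length on the edge above {who}; "
                    "dated analyses require branch lengths"
                )
            if node.edge.length < 0:
                raise NewickError(f"negative branch length: {node.edge.length}")

    # -- basic properties ---------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def total_length(self) -> float:
        return float(
            sum(
                node.edge.length
                for node in self._tree.preorder_node_iter()
                if node is not self._tree.seed_node
            )
        )

    def depths(self) -> dict[dendropy.Node, float]:
        """Root-to-node path length for every node (root depth 0)."""
        out: dict[dendropy.Node, float] = {self._tree.seed_node: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            out[node] = out[node.parent_node] + node.edge.length
        return out

    @property
    def root_age(self) -> float:
        """Crown age of the tree: the maximum root-to-tip path length."""
        depths = self.depths()
        return max(
            (depths[leaf] for leaf in self._tree.leaf_node_iter()), default=0.0
        )

    def node_ages(self) -> dict[dendropy.Node, float]:
        depths = self.depths()
        root_age = max(
            (depths[leaf] for leaf in self._tree.leaf_node_iter()), default=0.0
        )
        return {node: root_age - d for node, d in depths.items()}

    def ultrametric_spread(self) -> tuple[float, str]:
        """Max minus min root-to-tip depth, and the label of the worst tip.

        The "worst" tip is the one whose depth deviates most from the mean.
        """
        depths = self.depths()
        leaves = list(self._tree.leaf_node_iter())
        vals = np.array([depths[leaf] for leaf in leaves])
        if len(vals) == 0:
            return 0.0, ""
        spread = float(vals.max() - vals.min())
        worst = leaves[int(np.argmax(np.abs(vals - vals.mean())))]
        return spread, worst.taxon.label

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        spread, _ = self.ultrametric_spread()
        root_age = self.root_age
        if root_age == 0:
            return spread == 0
        return spread <= rel_tol * root_age

    # -- manipulation -------------------------------------------------------

    def clone(self) -> "DatedTree":
        return DatedTree(self._tree.clone(depth=1))

    def prune_to(self, keep: Iterable[str]) -> "DatedTree":
        """Restrict the tree to the given tip labels (others removed)."""
        keep = {normalize_name(k) for k in keep}
        present = set(self.tip_labels)
        missing = keep - present
        if missing:
            raise ReconcileError(
                f"cannot keep tips absent from tree: {sorted(missing)[:5]}"
            )
        if not keep:
            raise ReconcileError("cannot prune tree to an empty tip set")
        tree = self._tree.clone(depth=1)
        tree.retain_taxa_with_labels(sorted(keep))
        # dendropy may leave the (new) root with a dangling edge length after
        # suppressing unifurcations; PD code ignores the root edge anyway.
        return DatedTree(tree)

    # -- output -------------------------------------------------------------

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".17g",
        )

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DatedTree with {self.n_tips} tips, total length {self.total_length:.4g}>"


def read_newick(path: str | Path) -> DatedTree:
    """Read one newick tree (with branch lengths) from ``path``."""
    return DatedTree.from_newick(path)


def write_newick(tree: DatedTree, path: str | Path) -> None:
    tree.write_newick(path)


# ---------------------------------------------------------------------------
# CommunityMatrix
# ---------------------------------------------------------------------------


class CommunityMatrix:
    """Binary species x area presence/absence table.

    Rows are species, columns are area codes (e.g. the ten IAA areas).
    Cells must be exactly 0 or 1; abundances are rejected rather than
    thresholded.
    """

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        df.index = [normalize_name(str(s)) for s in df.index]
        df.columns = [str(c).strip() for c in df.columns]
        if df.index.duplicated().any():
            dups = sorted(set(df.index[df.index.duplicated()]))
            raise MatrixError(f"duplicate species rows: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = sorted(set(df.columns[df.columns.duplicated()]))
            raise MatrixError(f"duplicate area columns: {dups[:5]}")
        arr = df.to_numpy()
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixError(
                f"non-binary cell at species {df.index[i]!r}, area "
                f"{df.columns[j]!r}: {arr[i, j]!r} (presence/absence required)"
            )
        self._df = df.astype(np.int8)

    @classmethod
    def read_csv(cls, path: str | Path, sep: str | None = None) -> "CommunityMatrix":
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise MatrixError(f"failed to read community matrix {path}: {exc}") from exc
        return cls(df)

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self._df.to_csv(path, sep=sep)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def species(self) -> list[str]:
        return list(self._df.index)

    @property
    def areas(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        """Species x area int8 array."""
        return self._df.to_numpy()

    def area_species(self, area: str) -> list[str]:
        if area not in self._df.columns:
            raise MatrixError(f"unknown area: {area!r}")
        col = self._df[area]
        return list(col.index[col == 1])

    def row_sums(self) -> pd.Series:
        return self._df.sum(axis=1)

    def column_sums(self) -> pd.Series:
        return self._df.sum(axis=0)

    def restrict_species(self, keep: Iterable[str]) -> "CommunityMatrix":
        keep = [normalize_name(k) for k in keep]
        missing = set(keep) - set(self._df.index)
        if missing:
            raise ReconcileError(
                f"species not in matrix: {sorted(missing)[:5]}"
            )
        return CommunityMatrix(self._df.loc[keep])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityMatrix):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<CommunityMatrix {len(self.species)} species x {len(self.areas)} areas>"


def read_community(path: str | Path, sep: str | None = None) -> CommunityMatrix:
    """Read a species x area presence/absence CSV/TSV (first column species)."""
    return CommunityMatrix.read_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Reconciliation
# ---------------------------------------------------------------------------


@dataclass
class ReconcileResult:
    tree: DatedTree
    matrix: CommunityMatrix
    dropped_from_tree: list[str] = field(default_factory=list)
    dropped_from_matrix: list[str] = field(default_factory=list)


def reconcile(
    tree: DatedTree, matrix: CommunityMatrix, policy: str = "intersect"
) -> ReconcileResult:
    """Restrict a tree and matrix to a common species set.

    policy "intersect": prune both to the shared species, reporting what was
    dropped from each side.  policy "strict": raise if the sets differ at
    all.  Needed because checklist rows and tree tips routinely disagree
    after taxonomy updates.
    """
    if policy not in {"intersect", "strict"}:
        raise ValueError(f"unknown reconcile policy: {policy!r}")
    tips = set(tree.tip_labels)
    rows = set(matrix.species)
    shared = tips & rows
    if policy == "strict":
        if tips != rows:
            raise ReconcileError(
                f"species sets differ under strict policy: "
                f"{len(tips - rows)} tree-only, {len(rows - tips)} matrix-only"
            )
        return ReconcileResult(tree, matrix)
    if not shared:
        raise ReconcileError("tree tips and matrix species have empty intersection")
    dropped_tree = sorted(tips - shared)
    dropped_matrix = sorted(rows - shared)
    new_tree = tree.prune_to(shared) if dropped_tree else tree
    # keep matrix row order stable: original order restricted to shared
    order = [s for s in matrix.species if s in shared]
    new_matrix = matrix.restrict_species(order) if dropped_matrix else matrix
    return ReconcileResult(new_tree, new_matrix, dropped_tree, dropped_matrix)


# ---------------------------------------------------------------------------
# Sampling coverage
# ---------------------------------------------------------------------------


def percent_1dp(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to 1 decimal place."""
    if denominator == 0:
        return 0.0
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CoverageTable:
    """Per-area (plus global) genetic sampling coverage.

    ``table`` has index 'ALL' plus any areas, with columns n_recognized,
    n_sampled, pct_sampled.  ``unmatched`` lists sampled names absent from
    the recognized checklist — reported, never silently dropped.
    """

    table: pd.DataFrame
    unmatched: list[str] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path)


def coverage_summary(
    recognized: Sequence[str],
    sampled: Sequence[str],
    area_map: Mapping[str, Sequence[str]] | None = None,
) -> CoverageTable:
    """Tabulate how many recognized species have been genetically sampled.

    ``area_map`` optionally maps species -> areas of occurrence, in which
    case a per-area breakdown is appended below the global 'ALL' row.
    """
    rec = [normalize_name(s) for s in recognized]
    sam = [normalize_name(s) for s in sampled]
    rec_set = set(rec)
    if len(rec_set) != len(rec):
        raise MatrixError("duplicate names in recognized species list")
    sam_set = set(sam)
    unmatched = sorted(sam_set - rec_set)
    sam_in = sam_set & rec_set

    rows: dict[str, tuple[int, int]] = {"ALL": (len(rec_set), len(sam_in))}
    if area_map is not None:
        norm_map = {
            normalize_name(sp): list(areas) for sp, areas in area_map.items()
        }
        areas = sorted({a for ars in norm_map.values() for a in ars})
        for area in areas:
            in_area = {sp for sp, ars in norm_map.items() if area in ars} & rec_set
            rows[area] = (len(in_area), len(in_area & sam_in))

    table = pd.DataFrame(
        {
            "n_recognized": [v[0] for v in rows.values()],
            "n_sampled": [v[1] for v in rows.values()],
            "pct_sampled": [percent_1dp(v[1], v[0]) for v in rows.values()],
        },
        index=list(rows.keys()),
    )
    return CoverageTable(table, unmatched)
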