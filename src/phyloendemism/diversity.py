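"""Per-area species richness, Faith PD, Rosauer PE, and relative PD/PE.

PD here is *rooted*: the PD of a community is the summed length of every
branch on the union of root-to-tip paths of its members, root path
included.  PE divides each branch's length by its range size — the number
of areas whose spanning sets contain that branch — so that branch length is
partitioned exactly across areas: sum over areas of PE(area) equals PD of
the union of all occupied areas.

Relative PD (RPD) and relative PE (RPE) divide the observed metric by the
same metric computed on a comparison tree with identical topology but all
branch lengths equal (total length preserved).  High RPE concentrates long
range-restricted branches; low RPE, unusually short ones.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    CommunityMatrix,
    DatedTree,
    MatrixError,
    PhyloendemismError,
    normalize_name,
)

__all__ = [
    "species_richness",
    "faith_pd",
    "phylo_endemism",
    "make_equal_branch_tree",
    "diversity_table",
    "SpanningEngine",
]

METRIC_COLUMNS = ["SR", "PD", "PE", "PD_alt", "PE_alt", "RPD", "RPE"]


def species_richness(matrix: CommunityMatrix, area: str) -> int:
    """Number of species present in ``area`` (column sum)."""
    if area not in matrix.areas:
        raise MatrixError(f"unknown area: {area!r}")
    return int(matrix.df[area].sum())


def faith_pd(
    tree: DatedTree, community: Iterable[str], include_root: bool = True
) -> float:
    """Faith's phylogenetic diversity of a set of species.

    With ``include_root`` (default), sums branch lengths on the union of
    root-to-tip paths of the community.  With ``include_root=False`` the
    path between the root and the community's MRCA is excluded (the
    unrooted minimal-spanning-subtree convention).  Empty community -> 0.
    """
    comm = {normalize_name(s) for s in community}
    if not comm:
        return 0.0
    tips = set(tree.tip_labels)
    missing = comm - tips
    if missing:
        raise PhyloendemismError(
            f"species not on tree: {sorted(missing)[:5]}"
        )
    t = tree.dendropy_tree
    present: dict = {}
    total = 0.0
    for node in t.postorder_node_iter():
        if node.is_leaf():
            p = node.taxon.label in comm
        else:
            p = any(present[c] for c in node.child_nodes())
        present[node] = p
        if p and node is not t.seed_node:
            total += node.edge.length
    if not include_root:
        # walk down from the root while only one child subtends the community
        node = t.seed_node
        while True:
            hits = [c for c in node.child_nodes() if present.get(c)]
            if len(hits) != 1:
                break
            node = hits[0]
            total -= node.edge.length
            if node.is_leaf():
                break
    return float(total)


def make_equal_branch_tree(tree: DatedTree) -> DatedTree:
    """Same topology, every branch length = total length / branch count."""
    clone = tree.clone()
    t = clone.dendropy_tree
    edges = [
        n for n in t.preorder_node_iter() if n is not t.seed_node
    ]
    if not edges:
        return clone
    mean_len = sum(n.edge.length for n in edges) / len(edges)
    for n in edges:
        n.edge.length = mean_len
    return DatedTree(t)


class SpanningEngine:
    """Edge x species incidence machinery for fast PD/PE over many matrices.

    Precomputes, for a fixed tree and species ordering, which species sit
    below each branch.  Per-area metrics for any binary occupancy matrix
    with that row ordering then reduce to one boolean matrix product.
    Matrix species must all be tree tips (reconcile first).
    """

    def __init__(self, tree: DatedTree, species: Sequence[str]):
        self.species = [normalize_name(s) for s in species]
        sp_index = {s: i for i, s in enumerate(self.species)}
        if len(sp_index) != len(self.species):
            raise MatrixError("duplicate species in matrix ordering")
        tips = set(tree.tip_labels)
        missing = [s for s in self.species if s not in tips]
        if missing:
            raise PhyloendemismError(
                f"matrix species not on tree: {missing[:5]} (reconcile first)"
            )
        t = tree.dendropy_tree
        S = len(self.species)
        rows: list[np.ndarray] = []
        lengths: list[float] = []
        below: dict = {}
        for node in t.postorder_node_iter():
            if node.is_leaf():
                vec = np.zeros(S, dtype=bool)
                idx = sp_index.get(node.taxon.label)
                if idx is not None:
                    vec[idx] = True
            else:
                vec = np.zeros(S, dtype=bool)
                for c in node.child_nodes():
                    vec |= below[c]
            below[node] = vec
            if node is not t.seed_node:
                rows.append(vec)
                lengths.append(node.edge.length)
        self.incidence = np.array(rows, dtype=np.float64)  # E x S
        self.lengths = np.array(lengths, dtype=np.float64)  # E
        n_edges = len(lengths)
        self.alt_length = self.lengths.sum() / n_edges if n_edges else 0.0

    def metrics(self, occupancy: np.ndarray) -> dict[str, np.ndarray]:
        """Per-area SR, PD, PE, PD_alt, PE_alt, RPD, RPE.

        ``occupancy`` is the S x A binary array in this engine's species
        order.  RPD/RPE are NaN for empty areas.
        """
        M = occupancy.astype(np.float64, copy=False)
        spanned = self.incidence @ M > 0.5  # E x A: branch in area's set
        range_size = spanned.sum(axis=1)  # per-branch number of areas
        safe_range = np.maximum(range_size, 1)
        pe_weights = self.lengths / safe_range
        pd_vals = self.lengths @ spanned
        pe_vals = pe_weights @ spanned
        pd_alt = self.alt_length * spanned.sum(axis=0)
        pe_alt = (self.alt_length / safe_range) @ spanned
        with np.errstate(invalid="ignore", divide="ignore"):
            rpd = np.where(pd_alt > 0, pd_vals / pd_alt, np.nan)
            rpe = np.where(pe_alt > 0, pe_vals / pe_alt, np.nan)
        return {
            "SR": occupancy.sum(axis=0),
            "PD": pd_vals,
            "PE": pe_vals,
            "PD_alt": pd_alt,
            "PE_alt": pe_alt,
            "RPD": rpd,
            "RPE": rpe,
        }


def phylo_endemism(tree: DatedTree, matrix: CommunityMatrix, area: str) -> float:
    """Rosauer's phylogenetic endemism of one area.

    Sum over branches in the area's spanning set of branch length divided
    by the branch's range size (number of areas whose spanning sets contain
    it).  An empty area has PE 0.
    """
    if area not in matrix.areas:
        raise MatrixError(f"unknown area: {area!r}")
    engine = SpanningEngine(tree, matrix.species)
    vals = engine.metrics(matrix.values)
    return float(vals["PE"][matrix.areas.index(area)])


def diversity_table(
    tree: DatedTree, matrix: CommunityMatrix, include_root: bool = True
) -> pd.DataFrame:
    """One row per area: SR, PD, PE, PD_alt, PE_alt, RPD, RPE.

    ``include_root=False`` switches PD (and PD_alt, hence RPD) to the
    unrooted convention; PE stays rooted so that branch lengths partition
    exactly across areas.
    """
    engine = SpanningEngine(tree, matrix.species)
    vals = engine.metrics(matrix.values)
    table = pd.DataFrame(
        {k: vals[k] for k in METRIC_COLUMNS}, index=pd.Index(matrix.areas, name="area")
    )
    if not include_root:
        alt = make_equal_branch_tree(tree)
        for area in matrix.areas:
            comm = matrix.area_species(area)
            pd_val = faith_pd(tree, comm, include_root=False)
            pd_alt = faith_pd(alt, comm, include_root=False)
            table.loc[area, "PD"] = pd_val
            table.loc[area, "PD_alt"] = pd_alt
            table.loc[area, "RPD"] = pd_val / pd_alt if pd_alt > 0 else np.nan
    table["SR"] = table["SR"].astype(int)
    return table
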