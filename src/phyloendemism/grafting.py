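"""Grafting independently dated family subtrees onto a calibrated backbone.

The backbone carries one exemplar tip per family at a calibrated position.
Each family's dated subtree is linearly rescaled so that its crown age
matches the calibration target, then spliced in place of the exemplar tip;
the stem branch absorbs the difference between the attachment parent's age
and the target crown age.  Linear rescaling preserves relative branch
lengths exactly, which is what the grafted-vs-ungrafted concordance check
verifies (per-family Pearson correlation of matched branch lengths = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .core import (
    DatedTree,
    PhyloendemismError,
    UltrametricityError,
    normalize_name,
)

__all__ = [
    "GraftError",
    "GraftEntry",
    "GraftPlan",
    "rescale_subtree",
    "graft",
    "concordance",
    "ConcordanceReport",
]


class GraftError(PhyloendemismError):
    """Invalid graft plan or graft operation."""


@dataclass(frozen=True)
class GraftEntry:
    """One family's grafting instruction.

    attachment_label: the exemplar tip on the backbone to be replaced.
    target_age: the calibration age in Ma — the family crown age in
    "crown" mode, or the stem (attachment) age in "stem" mode.
    """

    family: str
    attachment_label: str
    target_age: float

    def __post_init__(self):
        if self.target_age <= 0:
            raise GraftError(
                f"family {self.family!r}: target age must be > 0, "
                f"got {self.target_age}"
            )


class GraftPlan:
    """A set of :class:`GraftEntry`, one per family."""

    def __init__(self, entries: Iterable[GraftEntry]):
        self.entries = list(entries)
        fams = [e.family for e in self.entries]
        if len(set(fams)) != len(fams):
            raise GraftError("duplicate family in graft plan")
        atts = [e.attachment_label for e in self.entries]
        if len(set(atts)) != len(atts):
            raise GraftError("duplicate attachment label in graft plan")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def by_family(self) -> dict[str, GraftEntry]:
        return {e.family: e for e in self.entries}

    @classmethod
    def read_csv(cls, path: str | Path) -> "GraftPlan":
        df = pd.read_csv(path)
        required = {"family", "attachment_label", "target_crown_age"}
        if not required.issubset(df.columns):
            raise GraftError(
                f"graft plan must have columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        return cls(
            GraftEntry(
                str(r.family),
                normalize_name(str(r.attachment_label)),
                float(r.target_crown_age),
            )
            for r in df.itertuples()
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "family": [e.family for e in self.entries],
                "attachment_label": [e.attachment_label for e in self.entries],
                "target_crown_age": [e.target_age for e in self.entries],
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Rescaling
# ---------------------------------------------------------------------------


def rescale_subtree(
    subtree: DatedTree, target_crown_age: float, ultrametric_rel_tol: float = 1e-6
) -> DatedTree:
    """Multiply every branch length by target_crown_age / current crown age.

    The subtree must be ultrametric (all root-to-tip paths equal within
    ``ultrametric_rel_tol`` x crown age) with at least two tips.  Topology
    and relative branch lengths are untouched; only the time scale changes.
    """
    if subtree.n_tips < 2:
        raise GraftError("rescaling requires a subtree with >= 2 tips")
    if target_crown_age <= 0:
        raise GraftError(f"target crown age must be > 0, got {target_crown_age}")
    crown = subtree.root_age
    if crown <= 0:
        raise GraftError("subtree crown age is zero; cannot rescale")
    if not subtree.is_ultrametric(ultrametric_rel_tol):
        spread, worst = subtree.ultrametric_spread()
        raise UltrametricityError(
            f"subtree is not ultrametric: root-to-tip spread {spread:.6g} "
            f"(crown age {crown:.6g}); worst tip {worst!r}"
        )
    k = target_crown_age / crown
    clone = subtree.clone()
    t = clone.dendropy_tree
    for node in t.preorder_node_iter():
        if node is not t.seed_node and node.edge.length is not None:
            node.edge.length *= k
    return DatedTree(t)


# ---------------------------------------------------------------------------
# Grafting
# ---------------------------------------------------------------------------


def graft(
    backbone: DatedTree,
    subtrees: Mapping[str, DatedTree],
    plan: GraftPlan,
    mode: str = "crown",
    outgroups: Mapping[str, Iterable[str]] | None = None,
    ultrametric_rel_tol: float = 1e-6,
) -> DatedTree:
    """Replace backbone exemplar tips by rescaled family subtrees.

    mode "crown" (default): each subtree is rescaled so its crown age
    equals the plan's target age; the stem branch is set to
    attachment-parent age minus target.  mode "stem": the target age is the
    stem age — a stem node is created at that age on the exemplar's branch
    and the subtree is grafted *without rescaling*, trusting its own crown
    age (which must be younger than the stem age).

    Families named in ``plan`` but missing from ``subtrees`` (e.g. one-tip
    families whose subtree was discarded) keep their backbone exemplar tip
    unchanged.  ``outgroups`` optionally lists, per family, dating-outgroup
    taxa to prune from the subtree before rescaling.
    """
    if mode not in {"crown", "stem"}:
        raise GraftError(f"unknown graft mode: {mode!r}")

    grafted = backbone.clone()
    gt = grafted.dendropy_tree
    depths = grafted.depths()
    root_age = grafted.root_age
    leaf_by_label = {
        leaf.taxon.label: leaf for leaf in gt.leaf_node_iter()
    }

    for entry in plan:
        sub = subtrees.get(entry.family)
        if sub is None:
            continue  # exemplar tip retained as-is
        if entry.attachment_label not in leaf_by_label:
            raise GraftError(
                f"attachment tip {entry.attachment_label!r} for family "
                f"{entry.family!r} not found on backbone"
            )
        if outgroups and entry.family in outgroups:
            drop = {normalize_name(s) for s in outgroups[entry.family]}
            keep = [t for t in sub.tip_labels if t not in drop]
            if not keep:
                raise GraftError(
                    f"family {entry.family!r}: all tips listed as outgroups"
                )
            sub = sub.prune_to(keep)
        if sub.n_tips < 2:
            # a one-tip "subtree" cannot carry a crown age; keep the exemplar
            continue

        leaf = leaf_by_label.pop(entry.attachment_label)
        parent = leaf.parent_node
        parent_age = root_age - depths[parent]

        if mode == "crown":
            if entry.target_age >= parent_age:
                raise GraftError(
                    f"family {entry.family!r}: target crown age "
                    f"{entry.target_age:.6g} >= attachment parent age "
                    f"{parent_age:.6g} (negative stem)"
                )
            scaled = rescale_subtree(sub, entry.target_age, ultrametric_rel_tol)
            stem = parent_age - entry.target_age
        else:  # stem mode: create the stem node at target_age, no rescale
            if entry.target_age >= parent_age:
                raise GraftError(
                    f"family {entry.family!r}: stem age {entry.target_age:.6g} "
                    f">= attachment parent age {parent_age:.6g}"
                )
            crown = sub.root_age
            if crown >= entry.target_age:
                raise GraftError(
                    f"family {entry.family!r}: subtree crown age {crown:.6g} "
                    f">= stem age {entry.target_age:.6g}; cannot graft "
                    "without rescaling in stem mode"
                )
            if not sub.is_ultrametric(ultrametric_rel_tol):
                spread, worst = sub.ultrametric_spread()
                raise UltrametricityError(
                    f"family {entry.family!r} subtree not ultrametric "
                    f"(spread {spread:.6g}, worst tip {worst!r})"
                )
            scaled = sub.clone()
            stem = parent_age - crown

        st = scaled.dendropy_tree
        st.migrate_taxon_namespace(gt.taxon_namespace)
        sub_root = st.seed_node
        parent.remove_child(leaf)
        parent.add_child(sub_root)
        sub_root.edge.length = stem

    labels = [leaf.taxon.label for leaf in gt.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise GraftError(f"duplicate tip labels after grafting: {dupes[:5]}")
    return DatedTree(gt)


# ---------------------------------------------------------------------------
# Concordance (grafted vs. ungrafted branch lengths)
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceReport:
    """Per-family Pearson correlation of grafted vs. original branch lengths.

    ``table`` has index family and columns correlation, scale_factor,
    n_branches.  correlation is NaN where undefined (< 3 branches, or zero
    variance in branch lengths).
    """

    table: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path)

    def all_unity(self, tol: float = 1e-9) -> bool:
        corr = self.table["correlation"].dropna()
        return bool(len(corr)) and bool((np.abs(corr - 1.0) <= tol).all())


def _branch_lengths_by_bipartition(
    tree: dendropy.Tree, top_node: dendropy.Node
) -> dict[frozenset[str], float]:
    """Edge length keyed by the tip set each edge subtends, below top_node."""
    out: dict[frozenset[str], float] = {}
    tipsets: dict[dendropy.Node, frozenset[str]] = {}
    for node in top_node.postorder_iter():
        if node.is_leaf():
            tipsets[node] = frozenset([node.taxon.label])
        else:
            tipsets[node] = frozenset().union(
                *(tipsets[c] for c in node.child_nodes())
            )
        if node is not top_node:
            out[tipsets[node]] = node.edge.length
    return out


def concordance(
    grafted: DatedTree, originals: Mapping[str, DatedTree]
) -> ConcordanceReport:
    """Compare each grafted family's branch lengths with its dated original.

    Branches are matched by the bipartition of family tips they subtend
    (the family clade on the grafted tree vs. the original subtree); the
    stem branch is excluded since grafting sets it independently.
    """
    gt = grafted.dendropy_tree
    rows = []
    for family, original in originals.items():
        tips = original.tip_labels
        present = set(grafted.tip_labels)
        missing = [t for t in tips if t not in present]
        if missing:
            raise GraftError(
                f"family {family!r}: tips missing from grafted tree: "
                f"{missing[:5]}"
            )
        mrca = gt.mrca(taxon_labels=tips)
        g_lens = _branch_lengths_by_bipartition(gt, mrca)
        o_lens = _branch_lengths_by_bipartition(
            original.dendropy_tree, original.dendropy_tree.seed_node
        )
        if set(g_lens) != set(o_lens):
            raise GraftError(
                f"family {family!r}: grafted clade topology does not match "
                "the original subtree"
            )
        keys = sorted(o_lens, key=sorted)
        g = np.array([g_lens[k] for k in keys])
        o = np.array([o_lens[k] for k in keys])
        scale = float(
            grafted_crown_age(gt, tips) / original.root_age
        ) if original.root_age > 0 else np.nan
        if len(keys) < 3 or np.std(g) == 0 or np.std(o) == 0:
            corr = np.nan
        else:
            corr = float(np.corrcoef(g, o)[0, 1])
        rows.append((family, corr, scale, len(keys)))
    table = pd.DataFrame(
        rows, columns=["family", "correlation", "scale_factor", "n_branches"]
    ).set_index("family")
    return ConcordanceReport(table)


def grafted_crown_age(gt: dendropy.Tree, family_tips: Iterable[str]) -> float:
    """Crown age of a family clade on a grafted tree (max depth below MRCA)."""
    mrca = gt.mrca(taxon_labels=list(family_tips))
    depths = {mrca: 0.0}
    best = 0.0
    for node in mrca.preorder_iter():
        if node is mrca:
            continue
        depths[node] = depths[node.parent_node] + node.edge.length
        if node.is_leaf():
            best = max(best, depths[node])
    return best
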