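"""Synthetic dated trees and occupancy matrices with known endemism regimes.

Everything the pipeline consumes can be generated here: ultrametric Yule
(pure-birth) trees, backbone/family-subtree pairs with deliberately
mismatched crown ages (so grafting has real work to do), and species x area
matrices whose areas carry a known endemism regime:

* ``paleo`` — old, phylogenetically isolated single-area lineages: long
  pendant branches attached deep in the tree, present in one area only.
* ``neo`` — young single-area radiations: shallow clades attached near the
  present, all tips endemic to the area.
* ``super`` — both constructions at once.
* ``none`` — only background species, which occupy every area
  independently with a fixed probability.

These are constructions with an analytically known truth, not claims about
real biogeographic history.  All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .core import CommunityMatrix, DatedTree, PhyloendemismError
from .grafting import GraftEntry, GraftPlan

__all__ = [
    "IAA_AREAS",
    "REGIMES",
    "ScenarioSpec",
    "simulate_dated_tree",
    "simulate_backbone_and_subtrees",
    "simulate_endemism_scenario",
]

#: The ten Indo-Australian Archipelago areas used as default area codes.
IAA_AREAS = ("AUS", "NG", "EMN", "MAU", "SUL", "LSU", "BOR", "JAV", "SUM", "SEA")

REGIMES = ("paleo", "neo", "super", "none")


# ---------------------------------------------------------------------------
# Yule trees
# ---------------------------------------------------------------------------


def _yule(
    n_tips: int,
    crown_age: float,
    rng: np.random.Generator,
    prefix: str,
    tns: dendropy.TaxonNamespace,
) -> dendropy.Tree:
    """Pure-birth tree conditioned on n_tips, scaled to the given crown age.

    Nodes carry an ``age`` attribute (root = crown_age, tips = 0).
    """
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    # active lineages: (parent node, birth time); time runs root -> tips
    active: list[tuple[dendropy.Node, float]] = [(root, 0.0), (root, 0.0)]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        parent, birth = active.pop(idx)
        node = dendropy.Node()
        parent.add_child(node)
        node.edge.length = t - birth
        active.append((node, t))
        active.append((node, t))
    total = t + rng.exponential(1.0 / n_tips)
    counter = 1
    for parent, birth in active:
        leaf = dendropy.Node(taxon=tns.new_taxon(f"{prefix}{counter}"))
        counter += 1
        parent.add_child(leaf)
        leaf.edge.length = total - birth
    scale = crown_age / total
    for node in tree.preorder_node_iter():
        if node is not root:
            node.edge.length *= scale
    _set_ages(tree, crown_age)
    return tree


def _set_ages(tree: dendropy.Tree, root_age: float) -> None:
    tree.seed_node.age = root_age
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            node.age = node.parent_node.age - node.edge.length


def simulate_dated_tree(
    n_tips: int,
    crown_age: float,
    model: str = "yule",
    seed: int | None = None,
    prefix: str = "t",
) -> DatedTree:
    """An ultrametric dated tree with ``n_tips`` leaves and the given crown age."""
    if n_tips < 2:
        raise PhyloendemismError(f"n_tips must be >= 2, got {n_tips}")
    if model != "yule":
        raise PhyloendemismError(f"unknown tree model: {model!r}")
    if crown_age <= 0:
        raise PhyloendemismError(f"crown_age must be > 0, got {crown_age}")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    return DatedTree(_yule(n_tips, crown_age, rng, prefix, tns))


# ---------------------------------------------------------------------------
# Backbone + family subtrees
# ---------------------------------------------------------------------------


def simulate_backbone_and_subtrees(
    n_families: int = 5,
    tips_per_family: int | Sequence[int] | None = None,
    seed: int | None = None,
    backbone_crown_age: float = 90.0,
) -> tuple[DatedTree, dict[str, DatedTree], GraftPlan]:
    """A calibrated family-level backbone plus one dated subtree per family.

    The backbone carries one exemplar tip per family ("Fam1"...).  Each
    family's graft target crown age is drawn below its attachment parent's
    age; subtree crown ages are drawn independently (deliberately
    mismatched with the targets) so that grafting must rescale.
    ``tips_per_family`` defaults to independent draws in [10, 40].
    """
    if n_families < 2:
        raise PhyloendemismError(f"n_families must be >= 2, got {n_families}")
    rng = np.random.default_rng(seed)
    backbone = simulate_dated_tree(
        n_families, backbone_crown_age, seed=int(rng.integers(2**31 - 1)), prefix="Fam"
    )
    if tips_per_family is None:
        sizes = [int(rng.integers(10, 41)) for _ in range(n_families)]
    elif isinstance(tips_per_family, int):
        sizes = [tips_per_family] * n_families
    else:
        sizes = list(tips_per_family)
        if len(sizes) != n_families:
            raise PhyloendemismError(
                "tips_per_family length must equal n_families"
            )
    ages = backbone.node_ages()
    parent_age = {
        leaf.taxon.label: ages[leaf.parent_node]
        for leaf in backbone.dendropy_tree.leaf_node_iter()
    }
    subtrees: dict[str, DatedTree] = {}
    entries = []
    for i, fam in enumerate(sorted(parent_age)):
        target = float(rng.uniform(0.25, 0.85) * parent_age[fam])
        mismatched_crown = float(rng.uniform(5.0, 40.0))
        subtrees[fam] = simulate_dated_tree(
            sizes[i],
            mismatched_crown,
            seed=int(rng.integers(2**31 - 1)),
            prefix=f"{fam}_sp",
        )
        entries.append(GraftEntry(fam, fam, target))
    return backbone, subtrees, GraftPlan(entries)


# ---------------------------------------------------------------------------
# Endemism scenarios
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSpec:
    """Study conditions for one synthetic endemism scenario.

    ``regimes`` maps area code -> regime; areas not mentioned get "none".
    Background species occupy each area independently with probability
    ``occupancy_p`` (species drawn in no area are assigned one at random,
    so every row has >= 1 presence).  Paleo areas receive ``n_relicts``
    single-area relict lineages with stem ages drawn in
    ``relict_stem_frac`` x crown age; neo areas receive ``n_radiations``
    endemic Yule clades of ``radiation_size`` tips with crown age
    ``radiation_crown_frac`` x crown age (stem at twice the crown age).
    """

    regimes: Mapping[str, str] = field(default_factory=dict)
    areas: Sequence[str] = IAA_AREAS
    n_background: int = 260
    occupancy_p: float = 0.35
    crown_age: float = 50.0
    n_relicts: int = 8
    relict_stem_frac: tuple[float, float] = (0.80, 0.92)
    n_radiations: int = 3
    radiation_size: int = 10
    radiation_crown_frac: float = 0.04
    seed: int = 0

    def __post_init__(self):
        if len(self.areas) < 2:
            raise PhyloendemismError("a scenario needs >= 2 areas")
        if len(set(self.areas)) != len(self.areas):
            raise PhyloendemismError("duplicate area codes")
        for area, regime in self.regimes.items():
            if area not in self.areas:
                raise PhyloendemismError(f"regime for unknown area: {area!r}")
            if regime not in REGIMES:
                raise PhyloendemismError(f"unknown regime: {regime!r}")
        if self.n_background < 2:
            raise PhyloendemismError("n_background must be >= 2")
        if not 0 < self.occupancy_p <= 1:
            raise PhyloendemismError("occupancy_p must be in (0, 1]")
        if self.crown_age <= 0:
            raise PhyloendemismError("crown_age must be > 0")
        if min(self.n_relicts, self.n_radiations, self.radiation_size) < 0:
            raise PhyloendemismError("counts must be >= 0")
        needs_relicts = any(r in ("paleo", "super") for r in self.regimes.values())
        if needs_relicts and self.n_relicts < 1:
            raise PhyloendemismError(
                "a paleo/super regime requires n_relicts >= 1"
            )
        needs_rad = any(r in ("neo", "super") for r in self.regimes.values())
        if needs_rad and (self.n_radiations < 1 or self.radiation_size < 2):
            raise PhyloendemismError(
                "a neo/super regime requires n_radiations >= 1 radiations "
                "of >= 2 tips"
            )

    def regime_of(self, area: str) -> str:
        return self.regimes.get(area, "none")


def _insert_at_stem(
    tree: dendropy.Tree,
    stem_age: float,
    new_child: dendropy.Node,
    child_crown_age: float,
    rng: np.random.Generator,
) -> None:
    """Split a background edge spanning ``stem_age`` and hang ``new_child``
    (with its own crown age) from the new node.  Marks inserted nodes
    special so later insertions avoid landing inside them."""
    candidates = [
        node
        for node in tree.preorder_node_iter()
        if node is not tree.seed_node
        and not getattr(node, "special", False)
        and node.parent_node.age > stem_age > node.age
    ]
    if not candidates:
        raise PhyloendemismError(
            f"no background branch spans stem age {stem_age:.4g}"
        )
    child = candidates[int(rng.integers(len(candidates)))]
    parent = child.parent_node
    mid = dendropy.Node()
    mid.age = stem_age
    parent.remove_child(child)
    parent.add_child(mid)
    mid.edge.length = parent.age - stem_age
    mid.add_child(child)
    child.edge.length = stem_age - child.age
    mid.add_child(new_child)
    new_child.edge.length = stem_age - child_crown_age
    new_child.special = True
    for node in new_child.preorder_iter():
        node.special = True


def simulate_endemism_scenario(
    spec: ScenarioSpec,
) -> tuple[DatedTree, CommunityMatrix, dict[str, str]]:
    """Build (tree, matrix, truth) for one scenario.

    Returns the dated tree, the binary occupancy matrix, and the true
    regime per area.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    tns = dendropy.TaxonNamespace()
    tree = _yule(spec.n_background, spec.crown_age, rng, "bg", tns)

    # one insertion record per relict / radiation: (stem age, area, kind, idx)
    insertions: list[tuple[float, str, str, int]] = []
    for area in spec.areas:
        regime = spec.regime_of(area)
        if regime in ("paleo", "super"):
            lo, hi = spec.relict_stem_frac
            for i in range(spec.n_relicts):
                stem = float(rng.uniform(lo, hi) * spec.crown_age)
                insertions.append((stem, area, "relict", i))
        if regime in ("neo", "super"):
            crown = spec.radiation_crown_frac * spec.crown_age
            for i in range(spec.n_radiations):
                insertions.append((2.0 * crown, area, "radiation", i))

    # deepest first, so shallower insertions can still find background edges
    members: dict[str, list[str]] = {}  # area -> endemic special species
    for stem, area, kind, i in sorted(insertions, key=lambda x: -x[0]):
        if kind == "relict":
            label = f"{area}_relict{i + 1}"
            node = dendropy.Node(taxon=tns.new_taxon(label))
            node.age = 0.0
            _insert_at_stem(tree, stem, node, 0.0, rng)
            members.setdefault(area, []).append(label)
        else:
            crown = spec.radiation_crown_frac * spec.crown_age
            clade = _yule(
                spec.radiation_size, crown, rng, f"{area}_rad{i + 1}_sp", tns
            )
            croot = clade.seed_node
            _insert_at_stem(tree, stem, croot, crown, rng)
            members.setdefault(area, []).extend(
                leaf.taxon.label for leaf in croot.leaf_iter()
            )

    dated = DatedTree(tree)
    species = dated.tip_labels
    special = {sp for names in members.values() for sp in names}
    occupancy = pd.DataFrame(
        0, index=species, columns=list(spec.areas), dtype=np.int8
    )
    for sp in species:
        if sp in special:
            continue
        draws = rng.random(len(spec.areas)) < spec.occupancy_p
        if not draws.any():
            draws[int(rng.integers(len(spec.areas)))] = True
        occupancy.loc[sp] = draws.astype(np.int8)
    for area, names in members.items():
        occupancy.loc[names, area] = 1

    truth = {area: spec.regime_of(area) for area in spec.areas}
    return dated, CommunityMatrix(occupancy), truth
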