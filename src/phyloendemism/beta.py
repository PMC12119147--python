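"""Pairwise taxonomic and phylogenetic beta diversity between areas.

Sorensen-family dissimilarities with the turnover/nestedness partition:
with a = shared, b and c = uniques (species counts for taxonomic beta,
spanning-branch lengths for phylogenetic beta),

    sor = (b + c) / (2a + b + c)        total dissimilarity
    sim = min(b, c) / (a + min(b, c))   turnover component
    sne = sor - sim                     nestedness component

Phylogenetic branch sets are the rooted spanning sets used for PD, so
shared deep branches count toward overlap — which is why phylogenetic beta
tends to sit below taxonomic beta when communities share deep lineages.
Jaccard variants are available behind the ``family`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan

import numpy as np
import pandas as pd

from .core import CommunityMatrix, DatedTree, MatrixError
from .diversity import SpanningEngine

__all__ = ["BetaPair", "taxonomic_beta_pair", "phylo_beta_pair", "beta_matrix",
           "square_matrix"]

TAXONOMIC_METRICS = ("beta_sor", "beta_sim", "beta_sne")
PHYLO_METRICS = ("phylo_sor", "phylo_sim", "phylo_sne")


@dataclass(frozen=True)
class BetaPair:
    """One area pair's dissimilarity components (NaN when undefined)."""

    area_a: str
    area_b: str
    sor: float
    sim: float
    sne: float


def _partition(a: float, b: float, c: float, family: str) -> tuple[float, float, float]:
    if a + b + c == 0:
        return nan, nan, nan
    lo = min(b, c)
    if family == "sorensen":
        sor = (b + c) / (2 * a + b + c)
        sim = lo / (a + lo) if (a + lo) > 0 else 0.0
    elif family == "jaccard":
        sor = (b + c) / (a + b + c)
        sim = 2 * lo / (a + 2 * lo) if (a + lo) > 0 else 0.0
    else:
        raise ValueError(f"unknown index family: {family!r}")
    return sor, sim, sor - sim


def taxonomic_beta_pair(
    matrix: CommunityMatrix, area_a: str, area_b: str, family: str = "sorensen"
) -> BetaPair:
    """Taxonomic (species-count) beta diversity between two areas."""
    for area in (area_a, area_b):
        if area not in matrix.areas:
            raise MatrixError(f"unknown area: {area!r}")
    sa = set(matrix.area_species(area_a))
    sb = set(matrix.area_species(area_b))
    if not sa or not sb:
        return BetaPair(area_a, area_b, nan, nan, nan)
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    return BetaPair(area_a, area_b, *_partition(a, b, c, family))


def phylo_beta_pair(
    tree: DatedTree,
    matrix: CommunityMatrix,
    area_a: str,
    area_b: str,
    family: str = "sorensen",
    engine: SpanningEngine | None = None,
) -> BetaPair:
    """Phylogenetic beta diversity: species counts replaced by the summed
    lengths of shared vs. unique branches of the two areas' spanning sets."""
    for area in (area_a, area_b):
        if area not in matrix.areas:
            raise MatrixError(f"unknown area: {area!r}")
    if engine is None:
        engine = SpanningEngine(tree, matrix.species)
    values = matrix.values
    ia, ib = matrix.areas.index(area_a), matrix.areas.index(area_b)
    in_a = engine.incidence @ values[:, ia] > 0.5
    in_b = engine.incidence @ values[:, ib] > 0.5
    if not in_a.any() or not in_b.any():
        return BetaPair(area_a, area_b, nan, nan, nan)
    a = float(engine.lengths[in_a & in_b].sum())
    b = float(engine.lengths[in_a & ~in_b].sum())
    c = float(engine.lengths[~in_a & in_b].sum())
    return BetaPair(area_a, area_b, *_partition(a, b, c, family))


def beta_matrix(
    tree: DatedTree, matrix: CommunityMatrix, family: str = "sorensen"
) -> pd.DataFrame:
    """All pairwise taxonomic and phylogenetic beta components, long format.

    Returns a DataFrame with columns area_a, area_b, metric, value covering
    every unordered pair once (and both orders implied by symmetry);
    metrics are beta_sor/beta_sim/beta_sne and phylo_sor/phylo_sim/
    phylo_sne.
    """
    areas = matrix.areas
    if len(areas) < 2:
        raise MatrixError("beta_matrix requires >= 2 areas")
    engine = SpanningEngine(tree, matrix.species)
    rows = []
    for i, area_a in enumerate(areas):
        for area_b in areas[i + 1:]:
            tb = taxonomic_beta_pair(matrix, area_a, area_b, family)
            pb = phylo_beta_pair(tree, matrix, area_a, area_b, family, engine)
            for metric, value in zip(TAXONOMIC_METRICS, (tb.sor, tb.sim, tb.sne)):
                rows.append((area_a, area_b, metric, value))
            for metric, value in zip(PHYLO_METRICS, (pb.sor, pb.sim, pb.sne)):
                rows.append((area_a, area_b, metric, value))
    return pd.DataFrame(rows, columns=["area_a", "area_b", "metric", "value"])


def square_matrix(long_df: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Pivot one metric of :func:`beta_matrix` output into a symmetric
    square matrix with zero diagonal."""
    sub = long_df[long_df["metric"] == metric]
    if sub.empty:
        raise ValueError(f"metric {metric!r} not present")
    areas = sorted(set(sub["area_a"]) | set(sub["area_b"]))
    out = pd.DataFrame(0.0, index=areas, columns=areas)
    for r in sub.itertuples():
        out.loc[r.area_a, r.area_b] = r.value
        out.loc[r.area_b, r.area_a] = r.value
    return out
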