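"""Null-model randomization and CANAPE endemism classification.

The null model randomizes the binary community matrix while holding every
row sum (species range size) and column sum (area richness) fixed.  Two
samplers are provided: curveball trades (default) and classic 2x2
checkerboard swaps, both as compiled kernels so that hundreds of thousands
of randomizations stay cheap.

Observed PE, PE on the equal-branch-length comparison tree (PE_alt), RPD
and RPE are ranked against their null distributions with the standard
(r+1)/(n+1) rank p-values, ties counted in both tails.  The two-step
classification: an area is a candidate for significant endemism when PE or
PE_alt is significantly high (one-tailed at alpha/2); candidates are then
split by RPE — significantly high -> paleo-endemic, significantly low ->
neo-endemic, neither -> mixed, and mixed escalates to super-endemic when
both PE and PE_alt are highly significant (alpha_high).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from numba import njit

from .core import CommunityMatrix, DatedTree, MatrixError, PhyloendemismError
from .diversity import SpanningEngine

__all__ = [
    "CATEGORIES",
    "NULL_METRICS",
    "randomize_matrix",
    "null_distribution",
    "classify_canape",
    "repeat_classification",
    "NullDistribution",
    "EndemismClassification",
]

CATEGORIES = ("paleo", "super", "neo", "mixed", "not_significant")
NULL_METRICS = ("PE", "PE_alt", "RPD", "RPE")

_MAX_SEED = 2**31 - 1


# ---------------------------------------------------------------------------
# Fixed-fixed randomization kernels
# ---------------------------------------------------------------------------


@njit(cache=False)
def _curveball_kernel(M, n_trades, seed):  # pragma: no cover - compiled
    np.random.seed(seed)
    R, C = M.shape
    diff_cols = np.empty(C, dtype=np.int64)
    for _ in range(n_trades):
        i = np.random.randint(0, R)
        j = np.random.randint(0, R)
        if i == j:
            continue
        k = 0
        ones_i = 0
        for c in range(C):
            if M[i, c] != M[j, c]:
                diff_cols[k] = c
                k += 1
                if M[i, c] == 1:
                    ones_i += 1
        if k < 2 or ones_i == 0 or ones_i == k:
            continue
        # redistribute row i's ones uniformly among the differing columns
        for t in range(k - 1):
            r = t + np.random.randint(0, k - t)
            tmp = diff_cols[t]
            diff_cols[t] = diff_cols[r]
            diff_cols[r] = tmp
        for t in range(k):
            c = diff_cols[t]
            if t < ones_i:
                M[i, c] = 1
                M[j, c] = 0
            else:
                M[i, c] = 0
                M[j, c] = 1
    return M


@njit(cache=False)
def _swap_kernel(M, n_attempts, seed):  # pragma: no cover - compiled
    np.random.seed(seed)
    R, C = M.shape
    for _ in range(n_attempts):
        r1 = np.random.randint(0, R)
        r2 = np.random.randint(0, R)
        c1 = np.random.randint(0, C)
        c2 = np.random.randint(0, C)
        if r1 == r2 or c1 == c2:
            continue
        a = M[r1, c1]
        b = M[r1, c2]
        c = M[r2, c1]
        d = M[r2, c2]
        if a == 1 and d == 1 and b == 0 and c == 0:
            M[r1, c1] = 0
            M[r2, c2] = 0
            M[r1, c2] = 1
            M[r2, c1] = 1
        elif a == 0 and d == 0 and b == 1 and c == 1:
            M[r1, c1] = 1
            M[r2, c2] = 1
            M[r1, c2] = 0
            M[r2, c1] = 0
    return M


def _randomized_values(
    values: np.ndarray, algorithm: str, n_swaps: int | None, seed: int
) -> np.ndarray:
    R, C = values.shape
    if n_swaps is None:
        n_swaps = 10 * max(R, C)
    out = values.astype(np.int8).copy()
    if algorithm == "curveball":
        _curveball_kernel(out, n_swaps, seed)
    elif algorithm == "swap":
        _swap_kernel(out, n_swaps, seed)
    else:
        raise ValueError(f"unknown randomization algorithm: {algorithm!r}")
    return out


def randomize_matrix(
    matrix: CommunityMatrix,
    algorithm: str = "curveball",
    n_swaps: int | None = None,
    seed: int = 0,
) -> CommunityMatrix:
    """A fixed-fixed randomization of the matrix (marginals preserved).

    ``n_swaps`` defaults to 10 x max(n_species, n_areas) trade (or swap)
    attempts.  A matrix admitting no rearrangement (e.g. all ones) is
    returned unchanged — the unique member of its marginal class.
    Reproducible given ``seed``.
    """
    out = _randomized_values(matrix.values, algorithm, n_swaps, int(seed))
    return CommunityMatrix(
        pd.DataFrame(out, index=matrix.species, columns=matrix.areas)
    )


# ---------------------------------------------------------------------------
# Null distributions and rank p-values
# ---------------------------------------------------------------------------


@dataclass
class NullDistribution:
    """Observed metrics, null samples, and rank p-values per area.

    ``observed``: areas x (PE, PE_alt, RPD, RPE).  ``nulls``: metric ->
    (n_rand x n_areas) array.  ``p_high``/``p_low``: one-tailed rank
    p-values (r_ge+1)/(n_rand+1) and (r_le+1)/(n_rand+1); ties count in
    both tails, so p_high + p_low >= 1 + 1/(n_rand+1).
    """

    areas: list[str]
    observed: pd.DataFrame
    nulls: dict[str, np.ndarray]
    p_high: pd.DataFrame
    p_low: pd.DataFrame
    n_rand: int

    def to_csv(self, path: str | Path) -> None:
        high = self.p_high.add_prefix("p_high_")
        low = self.p_low.add_prefix("p_low_")
        pd.concat([self.observed, high, low], axis=1).to_csv(path)


_TIE_TOL = 1e-12


def _rank_p_values(observed: np.ndarray, nulls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(r_ge+1)/(n+1), (r_le+1)/(n+1) columnwise; NaN null rows ignored."""
    n = nulls.shape[0]
    r_ge = np.nansum(nulls >= observed[None, :] - _TIE_TOL, axis=0)
    r_le = np.nansum(nulls <= observed[None, :] + _TIE_TOL, axis=0)
    return (r_ge + 1) / (n + 1), (r_le + 1) / (n + 1)


def null_distribution(
    tree: DatedTree,
    matrix: CommunityMatrix,
    n_rand: int = 999,
    seed: int = 0,
    algorithm: str = "curveball",
    n_swaps: int | None = None,
    engine: SpanningEngine | None = None,
) -> NullDistribution:
    """Null distributions of PE, PE_alt, RPD, RPE from matrix randomization.

    Draws ``n_rand`` fixed-fixed randomized matrices (seeded from ``seed``),
    recomputes the four metrics per area for each, and attaches rank
    p-values for the observed values.  A prebuilt :class:`SpanningEngine`
    may be passed to amortize tree preprocessing over many calls.
    """
    if n_rand < 1:
        raise ValueError(f"n_rand must be >= 1, got {n_rand}")
    if engine is None:
        engine = SpanningEngine(tree, matrix.species)
    values = matrix.values
    obs = engine.metrics(values)
    rng = np.random.default_rng(seed)
    sample_seeds = rng.integers(0, _MAX_SEED, size=n_rand)
    nulls = {m: np.empty((n_rand, len(matrix.areas))) for m in NULL_METRICS}
    for r in range(n_rand):
        rand_vals = _randomized_values(values, algorithm, n_swaps, int(sample_seeds[r]))
        vals = engine.metrics(rand_vals)
        for m in NULL_METRICS:
            nulls[m][r] = vals[m]

    distinct = len(np.unique(np.round(nulls["PE"], 10), axis=0))
    if n_rand >= 20 and distinct < max(2, n_rand // 20):
        warnings.warn(
            f"only {distinct} distinct null samples out of {n_rand}: the "
            "randomization space is small, ties will inflate p-values",
            stacklevel=2,
        )

    observed = pd.DataFrame(
        {m: obs[m] for m in NULL_METRICS}, index=pd.Index(matrix.areas, name="area")
    )
    p_high = {}
    p_low = {}
    for m in NULL_METRICS:
        hi, lo = _rank_p_values(observed[m].to_numpy(), nulls[m])
        p_high[m] = hi
        p_low[m] = lo
    return NullDistribution(
        areas=list(matrix.areas),
        observed=observed,
        nulls=nulls,
        p_high=pd.DataFrame(p_high, index=observed.index),
        p_low=pd.DataFrame(p_low, index=observed.index),
        n_rand=n_rand,
    )


# ---------------------------------------------------------------------------
# CANAPE classification
# ---------------------------------------------------------------------------


@dataclass
class EndemismClassification:
    """Per-area endemism category, and category frequencies over replicates.

    ``categories`` is the single-run (or last-run) area -> category Series;
    ``frequencies`` (areas x CATEGORIES counts) is populated by
    :func:`repeat_classification` and sums to ``n_reps`` per area.
    """

    categories: pd.Series
    frequencies: pd.DataFrame | None = None
    n_reps: int = 1

    def to_csv(self, path: str | Path) -> None:
        if self.frequencies is not None:
            self.frequencies.to_csv(path)
        else:
            self.categories.rename("category").to_csv(path)


def classify_canape(
    nulls: NullDistribution, alpha: float = 0.05, alpha_high: float = 0.01
) -> EndemismClassification:
    """Two-step endemism classification from null-model p-values.

    Step 1 (candidacy): an area is significant when PE or PE_alt is
    significantly high one-tailed at alpha/2; otherwise not_significant.
    Step 2: among candidates, RPE significantly high -> paleo, RPE
    significantly low -> neo, neither -> mixed; mixed becomes super when
    both PE and PE_alt are significantly high at alpha_high.
    """
    if not alpha > alpha_high:
        raise ValueError(
            f"alpha ({alpha}) must exceed alpha_high ({alpha_high})"
        )
    for m in NULL_METRICS:
        if m not in nulls.p_high.columns:
            raise PhyloendemismError(f"missing metric in null distribution: {m}")
    half = alpha / 2.0
    cats = {}
    for area in nulls.areas:
        ph = nulls.p_high.loc[area]
        pl = nulls.p_low.loc[area]
        if not (ph["PE"] < half or ph["PE_alt"] < half):
            cats[area] = "not_significant"
        elif ph["RPE"] < half:
            cats[area] = "paleo"
        elif pl["RPE"] < half:
            cats[area] = "neo"
        elif ph["PE"] < alpha_high and ph["PE_alt"] < alpha_high:
            cats[area] = "super"
        else:
            cats[area] = "mixed"
    return EndemismClassification(
        categories=pd.Series(cats, name="category").reindex(nulls.areas)
    )


def repeat_classification(
    tree: DatedTree,
    matrix: CommunityMatrix,
    n_reps: int = 100,
    n_rand: int = 999,
    base_seed: int = 0,
    alpha: float = 0.05,
    alpha_high: float = 0.01,
    algorithm: str = "curveball",
    n_swaps: int | None = None,
) -> EndemismClassification:
    """Classification frequencies over ``n_reps`` independent null runs.

    Replicate r uses seed base_seed + r; everything is reproducible from
    (base_seed, n_reps, n_rand).  Returns per-area counts of each category
    (rows sum to n_reps) plus the final replicate's categories.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    engine = SpanningEngine(tree, matrix.species)
    counts = pd.DataFrame(
        0, index=pd.Index(matrix.areas, name="area"), columns=list(CATEGORIES)
    )
    last = None
    for rep in range(n_reps):
        nd = null_distribution(
            tree,
            matrix,
            n_rand=n_rand,
            seed=(base_seed + rep) % _MAX_SEED,
            algorithm=algorithm,
            n_swaps=n_swaps,
            engine=engine,
        )
        last = classify_canape(nd, alpha=alpha, alpha_high=alpha_high)
        for area, cat in last.categories.items():
            counts.loc[area, cat] += 1
    return EndemismClassification(
        categories=last.categories, frequencies=counts, n_reps=n_reps
    )
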