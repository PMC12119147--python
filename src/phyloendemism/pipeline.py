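"""End-to-end orchestration: graft -> reconcile -> metrics -> CANAPE -> beta.

:func:`run_pipeline` takes a :class:`RunConfig` describing either real
inputs (backbone + subtrees + graft plan + matrix, or a pre-grafted tree +
matrix) or a synthetic scenario, runs every stage, and writes a bundle of
CSV/newick outputs plus a deterministic JSON manifest (parameters,
versions, SHA-256 checksums).  Identical configs yield byte-identical
bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .beta import beta_matrix, square_matrix
from .canape import repeat_classification, null_distribution
from .core import (
    CommunityMatrix,
    DatedTree,
    PhyloendemismError,
    read_community,
    read_newick,
    reconcile,
)
from .diversity import diversity_table
from .grafting import GraftPlan, graft, concordance
from .simulate import ScenarioSpec, simulate_endemism_scenario

__all__ = ["RunConfig", "run_pipeline", "compare_trees"]

logger = logging.getLogger("phyloendemism")

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    Exactly one input route must be set: either ``scenario`` (a synthetic
    :class:`ScenarioSpec`), or ``matrix`` together with ``tree`` (a
    pre-grafted dated tree) or with ``backbone`` + ``subtree_dir`` +
    ``graft_plan``.
    """

    # real inputs
    backbone: str | None = None
    subtree_dir: str | None = None
    graft_plan: str | None = None
    tree: str | None = None
    matrix: str | None = None
    # or a synthetic scenario
    scenario: ScenarioSpec | None = None
    # analysis parameters
    alpha: float = 0.05
    alpha_high: float = 0.01
    n_rand: int = 199
    n_reps: int = 100
    seed: int = 1
    algorithm: str = "curveball"
    graft_mode: str = "crown"
    include_root: bool = True
    beta_family: str = "sorensen"
    out_dir: str = "phyloendemism_out"

    def __post_init__(self):
        has_real = self.matrix is not None
        has_scenario = self.scenario is not None
        if has_real == has_scenario:
            raise PhyloendemismError(
                "config must provide exactly one of: a matrix with tree "
                "inputs, or a synthetic scenario"
            )
        if has_real and self.tree is None and not (
            self.backbone and self.subtree_dir and self.graft_plan
        ):
            raise PhyloendemismError(
                "real inputs need either a pre-grafted tree or "
                "backbone + subtree_dir + graft_plan"
            )
        if not (0 < self.alpha_high < self.alpha < 1):
            raise PhyloendemismError(
                f"need 0 < alpha_high < alpha < 1, got "
                f"{self.alpha_high}, {self.alpha}"
            )
        if self.n_rand < 1 or self.n_reps < 1:
            raise PhyloendemismError("n_rand and n_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        scenario = raw.pop("scenario", None)
        if scenario is not None:
            regimes = scenario.pop("regimes", {}) or {}
            scenario = ScenarioSpec(regimes=regimes, **scenario)
        return cls(scenario=scenario, **raw)

    def manifest_params(self) -> dict:
        d = {
            k: v
            for k, v in asdict(self).items()
            if k != "scenario"
        }
        if self.scenario is not None:
            sc = asdict(self.scenario)
            sc["regimes"] = dict(self.scenario.regimes)
            sc["areas"] = list(self.scenario.areas)
            d["scenario"] = sc
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, float_format=FLOAT_FORMAT, **kw)


def _load_subtrees(subtree_dir: Path) -> dict[str, DatedTree]:
    out = {}
    for p in sorted(subtree_dir.glob("*.nwk")) + sorted(subtree_dir.glob("*.tre")):
        out[p.stem] = read_newick(p)
    if not out:
        raise PhyloendemismError(f"no .nwk/.tre subtrees found in {subtree_dir}")
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the output bundle; returns the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage_times: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s ...", name)
        return time.perf_counter()

    def done(name, t0):
        stage_times[name] = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs", name, stage_times[name])

    # -- inputs -------------------------------------------------------------
    t0 = stage("inputs")
    truth = None
    if config.scenario is not None:
        tree, matrix, truth = simulate_endemism_scenario(config.scenario)
        tree.write_newick(out_dir / "tree.nwk")
        matrix.to_csv(out_dir / "matrix.csv")
        outputs["tree"] = out_dir / "tree.nwk"
        outputs["matrix"] = out_dir / "matrix.csv"
        pd.Series(truth, name="regime").rename_axis("area").to_csv(
            out_dir / "truth.csv"
        )
        outputs["truth"] = out_dir / "truth.csv"
    else:
        matrix = read_community(config.matrix)
        if config.tree is not None:
            tree = read_newick(config.tree)
        else:
            backbone = read_newick(config.backbone)
            subtrees = _load_subtrees(Path(config.subtree_dir))
            plan = GraftPlan.read_csv(config.graft_plan)
            tree = graft(backbone, subtrees, plan, mode=config.graft_mode)
            tree.write_newick(out_dir / "grafted.nwk")
            outputs["grafted_tree"] = out_dir / "grafted.nwk"
            report = concordance(tree, subtrees)
            _write_csv(report.table, out_dir / "concordance.csv")
            outputs["concordance"] = out_dir / "concordance.csv"
    done("inputs", t0)

    # -- reconcile ----------------------------------------------------------
    t0 = stage("reconcile")
    rec = reconcile(tree, matrix, policy="intersect")
    tree, matrix = rec.tree, rec.matrix
    if rec.dropped_from_tree or rec.dropped_from_matrix:
        logger.warning(
            "reconcile dropped %d tree tips, %d matrix rows",
            len(rec.dropped_from_tree),
            len(rec.dropped_from_matrix),
        )
    done("reconcile", t0)

    # -- diversity ----------------------------------------------------------
    t0 = stage("diversity")
    div = diversity_table(tree, matrix, include_root=config.include_root)
    _write_csv(div, out_dir / "diversity.csv")
    outputs["diversity"] = out_dir / "diversity.csv"
    done("diversity", t0)

    # -- canape -------------------------------------------------------------
    t0 = stage("canape")
    nd = null_distribution(
        tree, matrix, n_rand=config.n_rand, seed=config.seed,
        algorithm=config.algorithm,
    )
    nd.to_csv(out_dir / "pvalues.csv")
    outputs["pvalues"] = out_dir / "pvalues.csv"
    cls = repeat_classification(
        tree,
        matrix,
        n_reps=config.n_reps,
        n_rand=config.n_rand,
        base_seed=config.seed,
        alpha=config.alpha,
        alpha_high=config.alpha_high,
        algorithm=config.algorithm,
    )
    cls.to_csv(out_dir / "classification.csv")
    outputs["classification"] = out_dir / "classification.csv"
    done("canape", t0)

    # -- beta ---------------------------------------------------------------
    t0 = stage("beta")
    long_df = beta_matrix(tree, matrix, family=config.beta_family)
    _write_csv(long_df, out_dir / "beta_long.csv", index=False)
    outputs["beta_long"] = out_dir / "beta_long.csv"
    _write_csv(square_matrix(long_df, "beta_sor"), out_dir / "beta_taxonomic.csv")
    _write_csv(square_matrix(long_df, "phylo_sor"), out_dir / "beta_phylogenetic.csv")
    outputs["beta_taxonomic"] = out_dir / "beta_taxonomic.csv"
    outputs["beta_phylogenetic"] = out_dir / "beta_phylogenetic.csv"
    done("beta", t0)

    # -- manifest -----------------------------------------------------------
    manifest = {
        "package": "phyloendemism",
        "version": __version__,
        "parameters": config.manifest_params(),
        "n_species": len(matrix.species),
        "areas": matrix.areas,
        "outputs": {
            name: {"path": p.name, "sha256": _sha256(p)}
            for name, p in sorted(outputs.items())
        },
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    logger.info(
        "pipeline finished; stage times: %s",
        {k: round(v, 2) for k, v in stage_times.items()},
    )
    return manifest


def compare_trees(
    trees: Mapping[str, DatedTree],
    matrix: CommunityMatrix,
    n_rand: int = 199,
    n_reps: int = 100,
    seed: int = 1,
    alpha: float = 0.05,
    alpha_high: float = 0.01,
) -> dict[str, dict]:
    """Side-by-side diversity tables and classification frequencies per tree.

    Trees sharing no species with the matrix are excluded with a warning.
    """
    if len(trees) < 2:
        raise PhyloendemismError("compare_trees needs >= 2 trees")
    out: dict[str, dict] = {}
    for name, tree in trees.items():
        shared = set(tree.tip_labels) & set(matrix.species)
        if not shared:
            logger.warning("tree %r shares no species with matrix; excluded", name)
            continue
        rec = reconcile(tree, matrix, policy="intersect")
        div = diversity_table(rec.tree, rec.matrix)
        cls = repeat_classification(
            rec.tree,
            rec.matrix,
            n_reps=n_reps,
            n_rand=n_rand,
            base_seed=seed,
            alpha=alpha,
            alpha_high=alpha_high,
        )
        out[name] = {"diversity": div, "frequencies": cls.frequencies}
    return out
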