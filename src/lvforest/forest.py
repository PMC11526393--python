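"""Score-based trees and the LV Forest ensemble.

Each tree recursively splits the sample where the one-factor model's
parameters are unstable along a randomly drawn subset of covariates
(M-fluctuation test, Bonferroni-corrected), cutting at the point that
maximizes the score-based statistic.  Terminal nodes are then heavily pruned:
the node's rule is applied to the *full* sample, the model is re-fit with the
limited-information WLS estimator, and the node survives only if the re-fit
converges, its RMSEA clears the cutoff, and its parameters are stable with
respect to *every* covariate.  Surviving nodes are "relevant subgroups"; their
empirical-Bayes-modal scores are averaged per individual across the bagged
ensemble.  Individuals covered by no relevant subgroup receive no score (the
nonconvergence rate reports their share).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .fluctuation import (
    CovariateColumn,
    FluctuationResult,
    SplitCandidate,
    best_split,
    bonferroni_select,
    test_instability,
)
from .mlfit import casewise_scores, fit_ml_cfa
from .model import LatentScores, ModelSpec
from .polychoric import estimate_polychoric
from .wls import WLSFitResult, fit_wls, score_with_wls

__all__ = [
    "Condition",
    "SubgroupRule",
    "TreeNode",
    "RelevantSubgroup",
    "ForestConfig",
    "ForestResult",
    "build_covariates",
    "grow_tree",
    "prune_and_validate",
    "lv_forest",
    "score_coverage",
    "semtree_scores",
    "naive_scores",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Condition:
    """One atomic covariate condition: Z <= c, Z > c, Z in S or Z not in S."""

    covariate: str
    op: str  # 'le' | 'gt' | 'in' | 'notin'
    value: object  # float for le/gt, tuple of levels for in/notin

    def matches(self, cols: dict[str, CovariateColumn]) -> np.ndarray:
        col = cols[self.covariate]
        if self.op in ("le", "gt"):
            if col.kind == "ordinal":
                rank = col.ordinal_rank()
                cut = list(col.levels).index(self.value)
                mask = rank <= cut
            else:
                mask = col.values.astype(float) <= float(self.value)
            return mask if self.op == "le" else ~mask
        member = np.isin(col.values, np.asarray(self.value))
        return member if self.op == "in" else ~member

    def describe(self) -> str:
        if self.op == "le":
            return f"{self.covariate} <= {self.value}"
        if self.op == "gt":
            return f"{self.covariate} > {self.value}"
        sym = "in" if self.op == "in" else "not in"
        return f"{self.covariate} {sym} {set(self.value)}"

    def to_dict(self) -> dict:
        v = self.value
        if isinstance(v, tuple):
            v = list(v)
        return {"covariate": self.covariate, "op": self.op, "value": v}

    @classmethod
    def from_dict(cls, d: dict) -> "Condition":
        v = d["value"]
        if isinstance(v, list):
            v = tuple(v)
        return cls(d["covariate"], d["op"], v)


@dataclass(frozen=True)
class SubgroupRule:
    """Conjunction of atomic conditions defining a covariate-space region."""

    conditions: tuple[Condition, ...] = ()

    def matches(self, cols: dict[str, CovariateColumn]) -> np.ndarray:
        n = len(next(iter(cols.values())).values) if cols else 0
        mask = np.ones(n, dtype=bool)
        for c in self.conditions:
            mask &= c.matches(cols)
        return mask

    def extended(self, cond: Condition) -> "SubgroupRule":
        return SubgroupRule(self.conditions + (cond,))

    def describe(self) -> str:
        return " & ".join(c.describe() for c in self.conditions) or "<all rows>"

    def to_dict(self) -> dict:
        return {"conditions": [c.to_dict() for c in self.conditions]}

    @classmethod
    def from_dict(cls, d: dict) -> "SubgroupRule":
        return cls(tuple(Condition.from_dict(c) for c in d["conditions"]))


@dataclass
class TreeNode:
    node_id: int
    depth: int
    rule: SubgroupRule
    n: int
    terminal: bool = False
    reason: str = ""
    ml_converged: bool = False
    split: Optional[SplitCandidate] = None
    tests: list[FluctuationResult] = field(default_factory=list)
    children: list["TreeNode"] = field(default_factory=list)

    def terminal_nodes(self) -> list["TreeNode"]:
        if self.terminal:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.terminal_nodes())
        return out

    def n_splits(self) -> int:
        if self.terminal:
            return 0
        return 1 + sum(c.n_splits() for c in self.children)

    def to_dict(self) -> dict:
        d = {
            "node_id": self.node_id,
            "depth": self.depth,
            "rule": self.rule.to_dict(),
            "n": self.n,
            "terminal": self.terminal,
            "reason": self.reason,
        }
        if self.split is not None:
            d["split"] = {
                "covariate": self.split.covariate,
                "cut": self.split.cut,
                "subset": list(self.split.subset) if self.split.subset else None,
            }
            d["children"] = [c.to_dict() for c in self.children]
        return d


@dataclass
class RelevantSubgroup:
    """A validated terminal-node region: well-fitting, covariate-stable model."""

    rule: SubgroupRule
    wls: WLSFitResult
    stability: list[FluctuationResult]
    scores: LatentScores  # aligned with row_indices
    row_indices: np.ndarray
    tree_id: int = -1
    node_id: int = -1

    @property
    def n(self) -> int:
        return self.row_indices.size

    def to_dict(self) -> dict:
        return {
            "rule": self.rule.to_dict(),
            "rule_text": self.rule.describe(),
            "n": int(self.n),
            "tree_id": int(self.tree_id),
            "node_id": int(self.node_id),
            "wls": self.wls.to_dict(),
            "stability_pvalues": {r.covariate: r.pvalue for r in self.stability},
        }


@dataclass
class ForestConfig:
    """Ensemble hyperparameters.

    Per-tree resampling draws ``round(subsample * n)`` rows *without*
    replacement (subsample bagging).  With-replacement bootstrap resampling is
    deliberately not used: duplicated rows clump in the covariate ordering and
    inflate the fluctuation process relative to its information scaling, so
    every instability test would over-reject and homogeneous samples would be
    split spuriously.  ``subsample=1.0`` disables resampling.
    """

    n_trees: int = 100
    min_size: int = 200
    mtry: int = 2
    alpha: float = 0.05
    rmsea_cutoff: float = 0.05
    n_sim: int = 4999
    subsample: float = 0.632


@dataclass
class ForestResult:
    subgroups: list[RelevantSubgroup]
    scores: LatentScores  # per-individual aggregated score
    n_covering: np.ndarray
    nonconvergence_rate: float
    tree_summaries: list[dict]
    config: ForestConfig
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "nonconvergence_rate": self.nonconvergence_rate,
            "n_subgroups": len(self.subgroups),
            "config": dataclasses.asdict(self.config),
            "subgroups": [g.to_dict() for g in self.subgroups],
            "trees": self.tree_summaries,
        }


def build_covariates(
    df: pd.DataFrame, schema: dict[str, object]
) -> dict[str, CovariateColumn]:
    """Wrap DataFrame columns as typed covariates.

    ``schema`` maps column name to a kind string or to a dict
    {'kind': ..., 'levels': [...]}.
    """
    cols: dict[str, CovariateColumn] = {}
    for name, info in schema.items():
        if name not in df.columns:
            raise ValueError(f"covariate column {name!r} missing from the data")
        if isinstance(info, str):
            kind, levels = info, None
        else:
            kind = info["kind"]
            levels = info.get("levels")
        cols[name] = CovariateColumn(name, kind, df[name].to_numpy(), levels)
    return cols


def _subset_col(col: CovariateColumn, idx: np.ndarray) -> CovariateColumn:
    return CovariateColumn(col.name, col.kind, col.values[idx], col.levels)


def _split_conditions(cand: SplitCandidate) -> tuple[Condition, Condition]:
    if cand.kind in ("numeric", "ordinal"):
        return (
            Condition(cand.covariate, "le", cand.cut),
            Condition(cand.covariate, "gt", cand.cut),
        )
    return (
        Condition(cand.covariate, "in", cand.subset),
        Condition(cand.covariate, "notin", cand.subset),
    )


def grow_tree(
    responses: np.ndarray,
    cov_cols: dict[str, CovariateColumn],
    spec: ModelSpec,
    cfg: ForestConfig,
    rng: np.random.Generator,
) -> TreeNode:
    """Grow one score-based tree on the given (possibly bootstrapped) sample."""
    y = np.asarray(responses, dtype=float)
    names = list(cov_cols.keys())
    counter = [0]

    def recurse(idx: np.ndarray, rule: SubgroupRule, depth: int) -> TreeNode:
        node = TreeNode(node_id=counter[0], depth=depth, rule=rule, n=idx.size)
        counter[0] += 1
        if idx.size < 2 * cfg.min_size:
            node.terminal, node.reason = True, "no admissible cut"
            return node
        try:
            fit = fit_ml_cfa(y[idx], spec)
        except (ValueError, np.linalg.LinAlgError):
            node.terminal, node.reason = True, "ml failure"
            return node
        if not fit.converged:
            node.terminal, node.reason = True, "ml failure"
            return node
        # Heywood fits (clamped residual variance) may still be split further;
        # the validation stage bars them from becoming relevant subgroups.
        node.ml_converged = True
        scores = casewise_scores(fit, y[idx])
        mtry = min(cfg.mtry, len(names))
        chosen_idx = np.sort(rng.choice(len(names), size=mtry, replace=False))
        chosen = [names[i] for i in chosen_idx]
        node.tests = [
            test_instability(scores, fit.info, _subset_col(cov_cols[nm], idx), cfg.n_sim)
            for nm in chosen
        ]
        sel = bonferroni_select(node.tests, cfg.alpha)
        if sel is None:
            node.terminal, node.reason = True, "stable"
            return node
        cand = best_split(
            scores, fit.info, _subset_col(cov_cols[sel.covariate], idx), cfg.min_size
        )
        if cand is None:
            node.terminal, node.reason = True, "no admissible cut"
            return node
        node.split = cand
        cond_l, cond_r = _split_conditions(cand)
        sub_cols = {nm: _subset_col(cov_cols[nm], idx) for nm in (cand.covariate,)}
        mask_l = cond_l.matches(sub_cols)
        node.children = [
            recurse(idx[mask_l], rule.extended(cond_l), depth + 1),
            recurse(idx[~mask_l], rule.extended(cond_r), depth + 1),
        ]
        return node

    return recurse(np.arange(y.shape[0]), SubgroupRule(), 0)


def _validate_node(
    rule: SubgroupRule,
    y: np.ndarray,
    cov_cols: dict[str, CovariateColumn],
    spec: ModelSpec,
    cfg: ForestConfig,
) -> Optional[RelevantSubgroup]:
    """Re-fit and re-test one terminal-node region on the full sample."""
    mask = rule.matches(cov_cols)
    idx = np.flatnonzero(mask)
    if idx.size < cfg.min_size:
        return None
    y_sub = y[idx]
    try:
        ml = fit_ml_cfa(y_sub, spec)
    except (ValueError, np.linalg.LinAlgError):
        return None
    if not ml.converged or ml.heywood:
        return None
    try:
        stats = estimate_polychoric(y_sub, spec)
        wls = fit_wls(stats)
    except (ValueError, np.linalg.LinAlgError):
        logger.info("WLS failed for rule %s", rule.describe())
        return None
    if not wls.converged or wls.rmsea > cfg.rmsea_cutoff:
        return None
    scores = casewise_scores(ml, y_sub)
    stability = [
        test_instability(scores, ml.info, _subset_col(col, idx), cfg.n_sim)
        for col in cov_cols.values()
    ]
    bar = cfg.alpha / len(stability)
    if any(r.pvalue <= bar for r in stability):
        return None
    ebm = score_with_wls(wls, y_sub, spec)
    return RelevantSubgroup(
        rule=rule, wls=wls, stability=stability, scores=ebm, row_indices=idx
    )


def prune_and_validate(
    tree: TreeNode,
    responses: np.ndarray,
    cov_cols: dict[str, CovariateColumn],
    spec: ModelSpec,
    cfg: ForestConfig,
    cache: Optional[dict] = None,
) -> list[RelevantSubgroup]:
    """Keep the terminal nodes whose full-sample re-fit passes fit + stability.

    A split-less root counts as a terminal node.  ``cache`` (keyed by the
    node's full-sample row set) lets an ensemble skip re-validating a region
    that another tree already produced; validation is deterministic, so cached
    results are exact.
    """
    y = np.asarray(responses, dtype=float)
    out: list[RelevantSubgroup] = []
    for node in tree.terminal_nodes():
        key = None
        if cache is not None:
            key = np.packbits(node.rule.matches(cov_cols)).tobytes()
            if key in cache:
                hit = cache[key]
                if hit is not None:
                    out.append(dataclasses.replace(hit, node_id=node.node_id))
                continue
        sg = _validate_node(node.rule, y, cov_cols, spec, cfg)
        if cache is not None:
            cache[key] = sg
        if sg is not None:
            out.append(dataclasses.replace(sg, node_id=node.node_id))
    return out


def lv_forest(
    responses: np.ndarray,
    cov_cols: dict[str, CovariateColumn],
    spec: ModelSpec,
    cfg: ForestConfig,
    seed: int | np.random.SeedSequence = 0,
) -> ForestResult:
    """Bagged ensemble of score-based trees with pruned, validated subgroups.

    Per tree: draw a random subsample (without replacement), grow with random
    split selection, validate every terminal node against the full sample, and
    collect the surviving subgroups.  Scores are the unweighted mean of each
    individual's EBM scores over all relevant subgroups containing them.
    Fully deterministic for a fixed seed and config.
    """
    y = np.asarray(responses, dtype=float)
    n = y.shape[0]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(cfg.n_trees)
    subgroups: list[RelevantSubgroup] = []
    summaries: list[dict] = []
    cache: dict = {}
    n_bag = int(round(np.clip(cfg.subsample, 0.0, 1.0) * n))
    for t, child in enumerate(children):
        rng = np.random.default_rng(child)
        if n_bag < n:
            bag = np.sort(rng.choice(n, size=n_bag, replace=False))
        else:
            bag = np.arange(n)
        bag_cols = {nm: _subset_col(col, bag) for nm, col in cov_cols.items()}
        tree = grow_tree(y[bag], bag_cols, spec, cfg, rng)
        found = prune_and_validate(tree, y, cov_cols, spec, cfg, cache)
        for sg in found:
            sg.tree_id = t
        subgroups.extend(found)
        summaries.append(
            {
                "tree": t,
                "n_splits": tree.n_splits(),
                "n_terminal": len(tree.terminal_nodes()),
                "n_relevant": len(found),
            }
        )
    total = np.zeros(n)
    count = np.zeros(n, dtype=int)
    for sg in subgroups:
        ok = sg.scores.available
        rows = sg.row_indices[ok]
        total[rows] += sg.scores.values[ok]
        count[rows] += 1
    covered = count > 0
    values = np.full(n, np.nan)
    values[covered] = total[covered] / count[covered]
    if not subgroups:
        logger.warning("no relevant subgroups found; all scores unavailable")
    result = ForestResult(
        subgroups=subgroups,
        scores=LatentScores(values, covered),
        n_covering=count,
        nonconvergence_rate=float(np.mean(~covered)),
        tree_summaries=summaries,
        config=cfg,
        n=n,
    )
    _assert_invariants(result)
    return result


def _assert_invariants(result: ForestResult) -> None:
    cfg = result.config
    for sg in result.subgroups:
        assert sg.wls.converged
        assert sg.wls.rmsea <= cfg.rmsea_cutoff + 1e-12
        bar = cfg.alpha / max(len(sg.stability), 1)
        assert all(r.pvalue > bar for r in sg.stability)


def score_coverage(result: ForestResult) -> dict:
    """Coverage summary: nonconvergence rate, per-subgroup n, overlap histogram."""
    hist = np.bincount(result.n_covering)
    return {
        "nonconvergence_rate": result.nonconvergence_rate,
        "per_subgroup_n": [int(g.n) for g in result.subgroups],
        "overlap_histogram": {int(i): int(c) for i, c in enumerate(hist) if c > 0},
    }


def semtree_scores(
    responses: np.ndarray,
    cov_cols: dict[str, CovariateColumn],
    spec: ModelSpec,
    cfg: ForestConfig,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[TreeNode, LatentScores]:
    """Single score-based tree with all covariates; every terminal node scored.

    Unlike the forest there is no bootstrap, no random split selection and no
    pruning: each terminal node's subgroup gets a WLS re-fit and EBM scores
    (rows in nodes whose re-fit fails stay unscored).  This is the
    single-tree comparison method.
    """
    y = np.asarray(responses, dtype=float)
    n = y.shape[0]
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    full_cfg = dataclasses.replace(cfg, mtry=len(cov_cols))
    tree = grow_tree(y, cov_cols, spec, full_cfg, rng)
    values = np.full(n, np.nan)
    avail = np.zeros(n, dtype=bool)
    for node in tree.terminal_nodes():
        idx = np.flatnonzero(node.rule.matches(cov_cols))
        if idx.size < spec.n_items * 3:
            continue
        try:
            stats = estimate_polychoric(y[idx], spec)
            wls = fit_wls(stats)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not wls.converged:
            continue
        ebm = score_with_wls(wls, y[idx], spec)
        values[idx[ebm.available]] = ebm.values[ebm.available]
        avail[idx[ebm.available]] = True
    return tree, LatentScores(values, avail)


def naive_scores(responses: np.ndarray, spec: ModelSpec) -> tuple[WLSFitResult, LatentScores]:
    """One WLS model for the whole sample, EBM scores for every row."""
    y = np.asarray(responses, dtype=float)
    stats = estimate_polychoric(y, spec)
    wls = fit_wls(stats)
    return wls, score_with_wls(wls, y, spec)
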