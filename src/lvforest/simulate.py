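"""Built-in simulation designs with ground-truth latent scores and subgroup labels.

Three designs are provided.  The first draws ten model-compliant subgroups of
500 respondents each from a five-item, seven-category graded response model
whose thresholds, discriminations and factor moments differ per subgroup
(``SIM1_THRESHOLDS`` / ``SIM1_MOMENTS`` / ``SIM1_LOADINGS``), together with 30
partitioning covariates constructed so that each subgroup h is exactly the
region {num_h <= 50} & {cat_h in {1,3,5}} & {ord_h >= 4} — but no single
decision tree can carve out all ten regions at once.  The second is a smaller
three-subgroup, eight-item/five-category variant with six covariates.  The
third is a homogeneous control: one parameter set, covariates independent of
everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .grm import simulate_responses
from .model import GRMParameters, ModelSpec

__all__ = [
    "SubgroupDesign",
    "SimulatedDataset",
    "sim1_parameters",
    "simulate_sim1",
    "simulate_sim2",
    "simulate_homogeneous",
    "simulate_two_regime",
    "default_param_sampler",
]

# Generating thresholds per subgroup: SIM1_THRESHOLDS[h][i] is the increasing
# 6-vector of item i's category cuts (conditional-probit scale), kappa_{i1} of
# item 1 anchored at 0 in every subgroup.
SIM1_THRESHOLDS: list[np.ndarray] = [
    np.array([
        [0.00, 0.31, 0.90, 1.20, 1.47, 1.96],
        [1.54, 1.73, 2.08, 2.40, 2.51, 2.76],
        [0.27, 0.79, 0.86, 1.21, 1.31, 1.69],
        [-0.45, 0.13, 0.42, 0.84, 1.20, 1.37],
        [-1.24, -0.74, -0.09, 0.35, 1.13, 1.55],
    ]),
    np.array([
        [0.00, 0.25, 0.85, 1.20, 1.49, 2.00],
        [1.06, 1.69, 1.98, 2.24, 2.51, 3.25],
        [-0.43, -0.03, 0.11, 0.37, 0.69, 0.80],
        [-1.03, -0.40, 0.18, 0.94, 1.31, 1.80],
        [-0.14, 0.20, 0.40, 0.98, 1.29, 1.73],
    ]),
    np.array([
        [0.00, 0.56, 1.11, 1.74, 1.91, 2.59],
        [0.60, 1.22, 1.80, 2.15, 2.85, 3.43],
        [0.37, 0.78, 0.96, 1.30, 1.53, 1.92],
        [1.94, 2.16, 2.30, 2.54, 2.70, 2.95],
        [0.78, 1.27, 1.69, 2.34, 3.03, 3.63],
    ]),
    np.array([
        [0.00, 0.33, 0.54, 1.07, 1.41, 1.77],
        [-1.02, -0.49, -0.19, 0.38, 0.59, 1.19],
        [-0.43, -0.22, 0.13, 0.76, 1.08, 1.52],
        [0.33, 0.56, 0.84, 1.17, 1.34, 1.54],
        [0.30, 0.71, 1.23, 1.56, 1.85, 2.17],
    ]),
    np.array([
        [0.00, 0.32, 0.71, 1.14, 1.38, 1.91],
        [-1.85, -1.24, -0.99, -0.33, 0.30, 1.00],
        [1.45, 1.76, 1.96, 2.12, 2.22, 2.49],
        [-0.13, 0.30, 0.83, 1.27, 1.68, 2.17],
        [0.44, 1.00, 1.65, 2.14, 2.50, 3.21],
    ]),
    np.array([
        [0.00, 0.75, 1.34, 2.06, 2.33, 2.95],
        [1.50, 1.94, 2.06, 2.34, 2.47, 2.70],
        [-0.17, 0.43, 0.92, 1.47, 1.68, 2.17],
        [-1.56, -1.15, -0.58, 0.09, 0.73, 1.49],
        [-0.17, 0.10, 0.70, 1.66, 2.07, 2.78],
    ]),
    np.array([
        [0.00, 0.83, 1.49, 1.95, 2.46, 2.80],
        [0.99, 1.96, 2.65, 3.73, 4.33, 5.34],
        [1.98, 2.43, 2.52, 2.68, 2.94, 3.08],
        [-1.86, -0.68, -0.19, 0.23, 0.84, 1.43],
        [2.66, 3.89, 4.22, 5.14, 5.48, 6.04],
    ]),
    np.array([
        [0.00, 0.64, 1.03, 1.45, 1.87, 2.45],
        [0.20, 1.44, 1.63, 2.33, 3.16, 4.04],
        [-1.69, -1.23, -0.54, 0.23, 0.62, 1.48],
        [1.54, 1.98, 2.12, 2.37, 2.47, 2.64],
        [0.00, 0.71, 1.32, 1.84, 2.25, 2.76],
    ]),
    np.array([
        [0.00, 0.52, 0.78, 1.16, 1.54, 2.08],
        [-0.94, -0.89, -0.71, -0.58, -0.41, -0.17],
        [0.99, 1.76, 1.93, 2.60, 3.30, 3.60],
        [-0.93, -0.63, -0.07, 0.34, 0.94, 1.69],
        [-1.39, -0.74, -0.30, 0.50, 0.77, 1.63],
    ]),
    np.array([
        [0.00, 0.64, 0.96, 1.46, 1.84, 2.09],
        [1.28, 1.51, 1.81, 2.00, 2.30, 2.62],
        [1.52, 2.01, 2.37, 3.01, 3.40, 4.17],
        [0.51, 1.45, 1.77, 2.22, 2.54, 3.27],
        [-0.91, 0.22, 0.60, 1.47, 2.01, 2.43],
    ]),
]

# (Var(eta), E(eta)) per subgroup.
SIM1_MOMENTS: np.ndarray = np.array([
    [0.66, 0.99],
    [0.67, 0.95],
    [1.13, 1.21],
    [0.68, 0.77],
    [0.54, 0.80],
    [1.04, 1.76],
    [1.15, 1.67],
    [0.68, 1.21],
    [0.54, 1.03],
    [0.70, 1.25],
])

# Discriminations lambda_1..lambda_5 per subgroup (lambda_1 fixed to 1).
SIM1_LOADINGS: np.ndarray = np.array([
    [1.0, 0.67, 0.57, 0.80, 1.47],
    [1.0, 0.80, 0.58, 1.36, 0.89],
    [1.0, 1.20, 0.48, 0.37, 1.17],
    [1.0, 1.12, 1.12, 0.66, 0.97],
    [1.0, 1.51, 0.50, 1.54, 1.33],
    [1.0, 0.39, 0.90, 1.00, 1.19],
    [1.0, 1.46, 0.39, 1.23, 1.21],
    [1.0, 1.57, 1.46, 0.52, 1.36],
    [1.0, 0.40, 1.44, 1.32, 1.51],
    [1.0, 0.74, 1.30, 1.21, 1.50],
])

NUM_RANGE = 200  # numeric covariates take integer values 1..200
ORD_LEVELS = 5  # ordinal/categorical covariates are on a 5-point scale


@dataclass
class SubgroupDesign:
    """Generating configuration of one model-compliant subgroup."""

    label: int
    params: GRMParameters
    n: int


@dataclass
class SimulatedDataset:
    """Item responses plus covariates, with stored ground truth."""

    spec: ModelSpec
    items: pd.DataFrame
    covariates: pd.DataFrame
    eta: np.ndarray
    labels: np.ndarray
    designs: list[SubgroupDesign] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.items)

    def to_frame(self) -> pd.DataFrame:
        truth = pd.DataFrame({"true_eta": self.eta, "true_group": self.labels})
        return pd.concat(
            [self.items.reset_index(drop=True), self.covariates.reset_index(drop=True), truth],
            axis=1,
        )


def sim1_parameters(h: int) -> GRMParameters:
    """Generating parameters of subgroup h (0-based) of the first design."""
    var, mean = SIM1_MOMENTS[h]
    return GRMParameters(
        loadings=SIM1_LOADINGS[h].copy(),
        thresholds=[SIM1_THRESHOLDS[h][i].copy() for i in range(5)],
        factor_mean=float(mean),
        factor_variance=float(var),
    )


def _subgroup_covariates(
    rng: np.random.Generator, labels: np.ndarray, n_groups: int, with_cat: bool
) -> pd.DataFrame:
    """Build the overlapping covariate system of the heterogeneous designs.

    For rows of subgroup h: num_h in 1..50, cat_h in {1,3,5} (if present),
    ord_h in {4,5}.  For all other rows the three columns are uniform over
    their full ranges, except that ord_h is forced <= 3 wherever the row also
    satisfies the num/cat part of subgroup h's rule — so the full conjunction
    identifies subgroup h exactly, while partial rules overlap across groups.
    """
    n = labels.size
    cols: dict[str, np.ndarray] = {}
    for h in range(n_groups):
        member = labels == h
        num = rng.integers(1, NUM_RANGE + 1, size=n)
        num[member] = rng.integers(1, 51, size=int(member.sum()))
        ordv = rng.integers(1, ORD_LEVELS + 1, size=n)
        ordv[member] = rng.integers(4, 6, size=int(member.sum()))
        if with_cat:
            cat = rng.integers(1, ORD_LEVELS + 1, size=n)
            cat[member] = rng.choice([1, 3, 5], size=int(member.sum()))
            clash = ~member & (num <= 50) & np.isin(cat, [1, 3, 5])
        else:
            clash = ~member & (num <= 50)
        ordv[clash] = rng.integers(1, 4, size=int(clash.sum()))
        cols[f"num_{h + 1}"] = num
        if with_cat:
            cols[f"cat_{h + 1}"] = cat
        cols[f"ord_{h + 1}"] = ordv
    return pd.DataFrame(cols)


def _assemble(
    spec: ModelSpec,
    designs: list[SubgroupDesign],
    rng: np.random.Generator,
    with_cat: bool,
) -> SimulatedDataset:
    etas, labels, blocks = [], [], []
    for d in designs:
        eta = rng.normal(d.params.factor_mean, np.sqrt(d.params.factor_variance), d.n)
        blocks.append(simulate_responses(spec, d.params, eta, rng))
        etas.append(eta)
        labels.append(np.full(d.n, d.label))
    eta = np.concatenate(etas)
    labels = np.concatenate(labels)
    items = pd.DataFrame(np.vstack(blocks).astype(int), columns=spec.item_names)
    cov = _subgroup_covariates(rng, labels, len(designs), with_cat)
    return SimulatedDataset(spec, items, cov, eta, labels, designs)


def simulate_sim1(rng: np.random.Generator, n_per_group: int = 500) -> SimulatedDataset:
    """Ten heterogeneous subgroups, 5 items x 7 categories, 30 covariates."""
    spec = ModelSpec.ordinal(5, 7)
    designs = [SubgroupDesign(h, sim1_parameters(h), n_per_group) for h in range(10)]
    return _assemble(spec, designs, rng, with_cat=True)


def default_param_sampler(
    spec: ModelSpec, rng: np.random.Generator
) -> GRMParameters:
    """Random valid generating parameters spanning the ranges of the first design."""
    m = spec.n_items
    lam = rng.uniform(0.4, 1.6, size=m)
    lam[spec.reference_item] = 1.0
    thresholds = []
    for i, item in enumerate(spec.items):
        t = np.sort(rng.normal(0.0, 1.5, size=item.n_categories - 1))
        while np.any(np.diff(t) < 1e-3):  # keep cuts separated
            t = np.sort(rng.normal(0.0, 1.5, size=item.n_categories - 1))
        if i == 0:
            t = t - t[0]
        thresholds.append(t)
    return GRMParameters(
        loadings=lam,
        thresholds=thresholds,
        factor_mean=float(rng.uniform(-0.5, 1.5)),
        factor_variance=float(rng.uniform(0.5, 1.5)),
    )


def simulate_sim2(
    rng: np.random.Generator,
    param_sampler: Optional[Callable[[ModelSpec, np.random.Generator], GRMParameters]] = None,
    n_per_group: int = 500,
) -> SimulatedDataset:
    """Three heterogeneous subgroups, 8 items x 5 categories, 6 covariates."""
    spec = ModelSpec.ordinal(8, 5)
    sampler = param_sampler or default_param_sampler
    designs = [SubgroupDesign(h, sampler(spec, rng), n_per_group) for h in range(3)]
    return _assemble(spec, designs, rng, with_cat=False)


def simulate_homogeneous(
    rng: np.random.Generator,
    params: Optional[GRMParameters] = None,
    n: int = 5000,
    spec: Optional[ModelSpec] = None,
) -> SimulatedDataset:
    """One parameter set for the whole sample; covariates pure noise."""
    if spec is None:
        spec = ModelSpec.ordinal(5, 7)
    if params is None:
        params = sim1_parameters(0)
    eta = rng.normal(params.factor_mean, np.sqrt(params.factor_variance), n)
    items = pd.DataFrame(
        simulate_responses(spec, params, eta, rng).astype(int), columns=spec.item_names
    )
    cov = pd.DataFrame(
        {
            "num_1": rng.integers(1, NUM_RANGE + 1, size=n),
            "cat_1": rng.integers(1, ORD_LEVELS + 1, size=n),
            "ord_1": rng.integers(1, ORD_LEVELS + 1, size=n),
        }
    )
    return SimulatedDataset(
        spec, items, cov, eta, np.zeros(n, dtype=int),
        [SubgroupDesign(0, params, n)],
    )


def simulate_two_regime(
    rng: np.random.Generator,
    n: int = 1000,
    breakpoint: int = 50,
    loading_shift: float = 0.8,
    shifted_item: int = 1,
) -> SimulatedDataset:
    """Single numeric covariate with one true breakpoint; one loading differs.

    Rows with num_1 <= breakpoint follow the base parameter set; the rest get
    ``loading_shift`` added to one discrimination.  Used for split-recovery and
    power checks.
    """
    spec = ModelSpec.ordinal(5, 7)
    base = sim1_parameters(0)
    shifted = sim1_parameters(0)
    shifted.loadings[shifted_item] += loading_shift
    num = rng.integers(1, 101, size=n)
    labels = (num > breakpoint).astype(int)
    eta = rng.normal(base.factor_mean, np.sqrt(base.factor_variance), n)
    resp = np.empty((n, 5))
    for g, p in enumerate((base, shifted)):
        mask = labels == g
        resp[mask] = simulate_responses(spec, p, eta[mask], rng)
    items = pd.DataFrame(resp.astype(int), columns=spec.item_names)
    cov = pd.DataFrame({"num_1": num})
    return SimulatedDataset(
        spec, items, cov, eta, labels,
        [SubgroupDesign(0, base, int((labels == 0).sum())),
         SubgroupDesign(1, shifted, int((labels == 1).sum()))],
    )
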