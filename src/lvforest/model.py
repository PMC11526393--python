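"""Model specification and parameter containers for the one-factor graded response / CFA model.

The measurement model couples a single latent factor ``eta ~ N(mu_eta, phi)`` with
``m`` observed items.  An ordinal item ``i`` with ``K_i`` ordered categories follows
the conditional-probit graded response model

    P(Y_i >= k | eta) = Phi(lambda_i * eta - kappa_{i,k-1}),   k = 2, ..., K_i,

with strictly increasing thresholds ``kappa``.  A numeric item follows the linear
factor model ``Y_i = pi_i + lambda_i * eta + eps_i`` with ``eps_i ~ N(0, psi_i)``.
One reference item has its loading fixed to 1, and the first threshold of the
first ordinal item is fixed to 0, which identifies location and scale of ``eta``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["ItemSpec", "ModelSpec", "GRMParameters", "LatentScores"]

ORDINAL = "ordinal"
NUMERIC = "numeric"


@dataclass(frozen=True)
class ItemSpec:
    """One observed indicator: name, kind and (for ordinal items) category count."""

    name: str
    kind: str = ORDINAL
    n_categories: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in (ORDINAL, NUMERIC):
            raise ValueError(f"item {self.name!r}: kind must be 'ordinal' or 'numeric'")
        if self.kind == ORDINAL:
            if self.n_categories is None or self.n_categories < 2:
                raise ValueError(f"ordinal item {self.name!r} needs n_categories >= 2")
        elif self.n_categories is not None:
            raise ValueError(f"numeric item {self.name!r} must not declare categories")

    @property
    def is_ordinal(self) -> bool:
        return self.kind == ORDINAL


@dataclass(frozen=True)
class ModelSpec:
    """A one-factor measurement model: items plus the reference item.

    ``reference_item`` indexes the item whose loading is fixed to 1.
    """

    items: tuple[ItemSpec, ...]
    reference_item: int = 0
    n_factors: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if len(self.items) < 3:
            raise ValueError("a one-factor model needs at least 3 items")
        if not (0 <= self.reference_item < len(self.items)):
            raise ValueError("reference_item out of range")
        if self.n_factors != 1:
            raise ValueError("only a single latent factor is supported")
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate item names")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.items]

    @property
    def ordinal_indices(self) -> list[int]:
        return [i for i, it in enumerate(self.items) if it.is_ordinal]

    @property
    def numeric_indices(self) -> list[int]:
        return [i for i, it in enumerate(self.items) if not it.is_ordinal]

    @classmethod
    def ordinal(
        cls, n_items: int, n_categories: int, prefix: str = "item", reference_item: int = 0
    ) -> "ModelSpec":
        """Convenience constructor for an all-ordinal model with equal category counts."""
        items = tuple(
            ItemSpec(f"{prefix}{i + 1}", ORDINAL, n_categories) for i in range(n_items)
        )
        return cls(items=items, reference_item=reference_item)


@dataclass
class GRMParameters:
    """Parameter set of the one-factor model on the conditional-probit scale.

    ``thresholds[i]`` is an increasing array of length ``K_i - 1`` for ordinal
    item ``i`` and ``None`` for numeric items; ``intercepts``/``residual_variances``
    are set for numeric items only.  The reference loading must be exactly 1.
    """

    loadings: np.ndarray
    thresholds: list[Optional[np.ndarray]]
    factor_mean: float = 0.0
    factor_variance: float = 1.0
    intercepts: Optional[list[Optional[float]]] = None
    residual_variances: Optional[list[Optional[float]]] = None

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.thresholds = [
            None if t is None else np.asarray(t, dtype=float) for t in self.thresholds
        ]
        m = self.loadings.size
        if self.intercepts is None:
            self.intercepts = [None] * m
        if self.residual_variances is None:
            self.residual_variances = [None] * m

    def validate(self, spec: ModelSpec) -> None:
        m = spec.n_items
        if self.loadings.shape != (m,):
            raise ValueError("loadings length does not match the model spec")
        if not np.isclose(self.loadings[spec.reference_item], 1.0):
            raise ValueError("reference loading must be fixed to 1")
        if not np.isfinite(self.factor_variance) or self.factor_variance <= 0:
            raise ValueError("factor variance must be positive")
        for i, item in enumerate(spec.items):
            if item.is_ordinal:
                t = self.thresholds[i]
                if t is None or t.size != item.n_categories - 1:
                    raise ValueError(f"item {item.name}: expected {item.n_categories - 1} thresholds")
                if np.any(np.diff(t) <= 0):
                    raise ValueError(f"item {item.name}: thresholds must be strictly increasing")
            else:
                if self.intercepts[i] is None or self.residual_variances[i] is None:
                    raise ValueError(f"numeric item {item.name}: intercept/residual variance missing")
                if self.residual_variances[i] <= 0:
                    raise ValueError(f"numeric item {item.name}: residual variance must be positive")

    def to_dict(self) -> dict:
        return {
            "loadings": self.loadings.tolist(),
            "thresholds": [None if t is None else t.tolist() for t in self.thresholds],
            "factor_mean": float(self.factor_mean),
            "factor_variance": float(self.factor_variance),
            "intercepts": [None if v is None else float(v) for v in self.intercepts],
            "residual_variances": [
                None if v is None else float(v) for v in self.residual_variances
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "GRMParameters":
        return cls(
            loadings=np.asarray(d["loadings"], dtype=float),
            thresholds=[None if t is None else np.asarray(t, dtype=float) for t in d["thresholds"]],
            factor_mean=float(d["factor_mean"]),
            factor_variance=float(d["factor_variance"]),
            intercepts=d.get("intercepts"),
            residual_variances=d.get("residual_variances"),
        )

    @classmethod
    def from_json(cls, s: str) -> "GRMParameters":
        return cls.from_dict(json.loads(s))


@dataclass
class LatentScores:
    """Per-row latent score estimates with an availability flag.

    ``values[j]`` is meaningful only where ``available[j]`` is True; uncovered
    rows carry NaN.
    """

    values: np.ndarray
    available: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.available = np.asarray(self.available, dtype=bool)
        if self.values.shape != self.available.shape:
            raise ValueError("values and availability flags must align")
        if np.any(~np.isfinite(self.values[self.available])):
            raise ValueError("available scores must be finite")

    def __len__(self) -> int:
        return self.values.size
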