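"""Configuration parsing, dataset loading and result serialization.

The run configuration is a YAML (or JSON) document::

    items:
      - {name: item1, kind: ordinal, n_categories: 7}
      - ...
    reference_item: item1          # optional; defaults to the first item
    covariates:
      num_1: numeric
      cat_1: categorical
      ord_1: {kind: ordinal, levels: [1, 2, 3, 4, 5]}
    forest:
      n_trees: 100
      min_size: 200
      mtry: 2
      alpha: 0.05
      rmsea_cutoff: 0.05
      n_sim: 4999
      subsample: 0.8
    seed: 1

Unknown keys raise an error rather than being ignored — a typo in a
hyperparameter name must not silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .forest import ForestConfig, build_covariates
from .model import ItemSpec, ModelSpec

__all__ = ["RunConfig", "load_config", "load_dataset", "save_manifest"]

logger = logging.getLogger(__name__)

_FOREST_KEYS = {f.name for f in dataclasses.fields(ForestConfig)}
_TOP_KEYS = {"items", "reference_item", "covariates", "forest", "seed"}


@dataclass
class RunConfig:
    """Validated model + covariate schema + ensemble hyperparameters + seed."""

    spec: ModelSpec
    covariate_schema: dict[str, object]
    forest: ForestConfig = field(default_factory=ForestConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        unknown = set(doc) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "items" not in doc or "covariates" not in doc:
            raise ValueError("config must declare 'items' and 'covariates'")
        items = []
        for entry in doc["items"]:
            extra = set(entry) - {"name", "kind", "n_categories"}
            if extra:
                raise ValueError(f"unknown item keys: {sorted(extra)}")
            items.append(
                ItemSpec(
                    entry["name"],
                    entry.get("kind", "ordinal"),
                    entry.get("n_categories"),
                )
            )
        names = [it.name for it in items]
        ref = doc.get("reference_item", names[0])
        if ref not in names:
            raise ValueError(f"reference item {ref!r} is not a declared item")
        spec = ModelSpec(items=tuple(items), reference_item=names.index(ref))

        schema: dict[str, object] = {}
        for name, info in doc["covariates"].items():
            if isinstance(info, str):
                if info not in ("numeric", "ordinal", "categorical"):
                    raise ValueError(f"covariate {name!r}: unknown kind {info!r}")
                schema[name] = info
            else:
                extra = set(info) - {"kind", "levels"}
                if extra:
                    raise ValueError(f"covariate {name!r}: unknown keys {sorted(extra)}")
                schema[name] = dict(info)

        fdoc = doc.get("forest", {})
        unknown = set(fdoc) - _FOREST_KEYS
        if unknown:
            raise ValueError(f"unknown forest hyperparameters: {sorted(unknown)}")
        forest = ForestConfig(**fdoc)
        if not (0 < forest.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if forest.min_size < 3 * spec.n_items:
            raise ValueError("min_size too small to fit the model")
        if not (1 <= forest.mtry <= len(schema)):
            raise ValueError("mtry must be between 1 and the number of covariates")
        if forest.rmsea_cutoff <= 0 or forest.n_trees < 1 or forest.n_sim < 1:
            raise ValueError("invalid forest hyperparameters")
        if not (0 < forest.subsample <= 1):
            raise ValueError("subsample fraction must be in (0, 1]")
        return cls(spec=spec, covariate_schema=schema, forest=forest, seed=int(doc.get("seed", 0)))


def load_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError("config file must contain a mapping")
    return RunConfig.from_dict(doc)


def load_dataset(path: str | Path, config: RunConfig):
    """Read a CSV of item responses and covariates against a config's schema.

    Rows with missing values in any declared column are dropped (logged);
    ordinal codes outside the declared range are a hard error naming the cell.
    Returns (responses ndarray, covariate DataFrame, row index).
    """
    df = pd.read_csv(path)
    spec = config.spec
    declared = spec.item_names + list(config.covariate_schema)
    missing_cols = [c for c in declared if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing declared columns: {missing_cols}")
    sub = df[declared]
    keep = ~sub.isna().any(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d rows with missing declared values", n_drop)
    sub = sub[keep]
    for i, item in enumerate(spec.items):
        col = sub[item.name]
        if item.is_ordinal:
            vals = col.to_numpy()
            bad = (vals != np.floor(vals)) | (vals < 1) | (vals > item.n_categories)
            if bad.any():
                row = sub.index[np.argmax(bad)]
                raise ValueError(
                    f"invalid category code {col.loc[row]!r} in column {item.name!r}, "
                    f"row {row} (declared 1..{item.n_categories})"
                )
    responses = sub[spec.item_names].to_numpy(dtype=float)
    covariates = sub[list(config.covariate_schema)].reset_index(drop=True)
    return responses, covariates, sub.index.to_numpy()


def save_manifest(path: str | Path, config: RunConfig, extra: Optional[dict] = None) -> None:
    import lvforest

    doc = {
        "package_version": lvforest.__version__,
        "seed": config.seed,
        "forest": dataclasses.asdict(config.forest),
        "items": [
            {"name": it.name, "kind": it.kind, "n_categories": it.n_categories}
            for it in config.spec.items
        ],
        "reference_item": config.spec.items[config.spec.reference_item].name,
        "covariates": config.covariate_schema,
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))
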