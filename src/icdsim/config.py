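"""Run configuration: algorithm selection, weight scheme, Li parameters.

The config file is a small YAML (or JSON, which YAML subsumes) mapping:

.. code-block:: yaml

    algorithms: [steps, weights, wupalmer, lietal]
    weights:                # per level-transition edge weight
      root-chapter: 8
      chapter-group: 4
      group-category: 2
      category-code: 1
    alpha: 0.2              # Li et al. path-length decay
    beta: 0.6               # Li et al. depth saturation

Every key is optional; omitted keys fall back to the package defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .similarity import (
    Algorithm,
    DEFAULT_LI_PARAMETERS,
    DEFAULT_WEIGHTS,
    LiParameters,
    WeightScheme,
)
from .taxonomy import Level, TaxonomyError

__all__ = ["RunConfig", "load_config"]

_TRANSITION_KEYS = {
    "root-chapter": (Level.ROOT, Level.CHAPTER),
    "chapter-group": (Level.CHAPTER, Level.GROUP),
    "group-category": (Level.GROUP, Level.CATEGORY),
    "category-code": (Level.CATEGORY, Level.CODE),
}


@dataclass(frozen=True)
class RunConfig:
    algorithms: list[Algorithm] = field(default_factory=lambda: list(Algorithm))
    scheme: WeightScheme = DEFAULT_WEIGHTS
    li_params: LiParameters = DEFAULT_LI_PARAMETERS


def load_config(path: str | Path | None) -> RunConfig:
    """Parse a YAML config file into a :class:`RunConfig` (defaults if None)."""
    if path is None:
        return RunConfig()
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise TaxonomyError("config file must contain a mapping")

    algorithms = list(Algorithm)
    if "algorithms" in raw:
        try:
            algorithms = [Algorithm(a) for a in raw["algorithms"]]
        except ValueError as e:
            raise TaxonomyError(f"unknown algorithm in config: {e}") from None

    scheme = DEFAULT_WEIGHTS
    if "weights" in raw:
        table = dict(DEFAULT_WEIGHTS.weight_per_transition)
        for key, value in raw["weights"].items():
            if key not in _TRANSITION_KEYS:
                raise TaxonomyError(
                    f"unknown weight transition {key!r}; expected one of "
                    f"{sorted(_TRANSITION_KEYS)}"
                )
            table[_TRANSITION_KEYS[key]] = float(value)
        scheme = WeightScheme(table)

    li = LiParameters(
        alpha=float(raw.get("alpha", DEFAULT_LI_PARAMETERS.alpha)),
        beta=float(raw.get("beta", DEFAULT_LI_PARAMETERS.beta)),
    )
    return RunConfig(algorithms=algorithms, scheme=scheme, li_params=li)
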