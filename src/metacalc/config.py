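"""Pipeline configuration.

A flat key-value file (YAML mapping, dotted keys) configures every stage;
unknown keys are rejected so typos fail loudly.  Example::

    fdr.q: 0.01
    filter.min_razor_unique: 2
    stats.linkage: average
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .group_filtering import DEFAULT_EXCLUDED_PATTERNS
from .tables_io import (
    DEFAULT_DECOY_PREFIX,
    DEFAULT_RANK_LADDER,
    ValidationError,
)
from .taxonomy_lca import DEFAULT_HUMAN_TRIGGER_TAXA

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    fdr_q: float = 0.01
    fdr_decoy_prefix: str = DEFAULT_DECOY_PREFIX
    filter_min_razor_unique: int = 2
    filter_drop_whole_group: bool = False
    filter_excluded_patterns: tuple[str, ...] = DEFAULT_EXCLUDED_PATTERNS
    taxonomy_rank_ladder: tuple[str, ...] = DEFAULT_RANK_LADDER
    taxonomy_human_trigger_taxa: tuple[str, ...] = DEFAULT_HUMAN_TRIGGER_TAXA
    quant_rank: str = "genus"
    quant_top_n: int = 20
    stats_alpha: float = 0.05
    stats_test_variant: str = "student"  # or "welch"
    stats_linkage: str = "average"
    stats_k_groups: int = 2
    diet_max_missed: int = 2
    diet_len_min: int = 7
    diet_len_max: int = 30
    diet_deamidation_aware: bool = True
    diet_q_e: bool = False
    diet_cleave_before_proline: bool = True


_KEY_MAP = {
    "fdr.q": "fdr_q",
    "fdr.decoy_prefix": "fdr_decoy_prefix",
    "filter.min_razor_unique": "filter_min_razor_unique",
    "filter.drop_whole_group": "filter_drop_whole_group",
    "filter.excluded_patterns": "filter_excluded_patterns",
    "taxonomy.rank_ladder": "taxonomy_rank_ladder",
    "taxonomy.human_trigger_taxa": "taxonomy_human_trigger_taxa",
    "quant.rank": "quant_rank",
    "quant.top_n": "quant_top_n",
    "stats.alpha": "stats_alpha",
    "stats.test_variant": "stats_test_variant",
    "stats.linkage": "stats_linkage",
    "stats.k_groups": "stats_k_groups",
    "diet.max_missed": "diet_max_missed",
    "diet.len_min": "diet_len_min",
    "diet.len_max": "diet_len_max",
    "diet.deamidation_aware": "diet_deamidation_aware",
    "diet.q_e": "diet_q_e",
    "diet.cleave_before_proline": "diet_cleave_before_proline",
}

_TUPLE_FIELDS = {
    "filter_excluded_patterns",
    "taxonomy_rank_ladder",
    "taxonomy_human_trigger_taxa",
}


def load_config(path: str | Path | None) -> PipelineConfig:
    """Read a flat YAML config; missing file section defaults apply."""
    config = PipelineConfig()
    if path is None:
        return config
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a flat mapping")
    overrides = {}
    for key, value in data.items():
        if key not in _KEY_MAP:
            raise ValidationError(f"{path}: unknown config key {key!r}")
        name = _KEY_MAP[key]
        if name in _TUPLE_FIELDS:
            value = tuple(value)
        overrides[name] = value
    return replace(config, **overrides)
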