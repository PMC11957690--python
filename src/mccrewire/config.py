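"""Pipeline configuration: schema, defaults, validation.

Every printed analysis parameter appears here with its default: 500
signature genes per tail, top 1000 drug-perturbed genes, soft-threshold
power 16, minimum module size 30, eigengene merge height 0.25, 40 hubs per
module, top-quintile edge filter, the five-period time map, community size
filter 30, adjusted-p threshold 0.05, |log2FC| threshold 1 and message-
passing damping 0.1.
"""

from __future__ import annotations

import dataclasses
import difflib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import MalformedConfigError, OutOfDomainError, UnknownKeyError
from .synthetic import DEFAULT_PERIODS

_ALL_STAGES = ("simulate", "signature", "reversal", "coexpr", "regnet", "enrich")


@dataclass
class PipelineConfig:
    """Validated, fully defaulted pipeline settings."""

    stages: tuple[str, ...] = _ALL_STAGES
    seed: int = 0
    n_per_tail: int = 500
    top_k: int = 1000
    power: float = 16.0
    min_module_size: int = 30
    merge_height: float = 0.25
    n_hubs: int = 40
    edge_quantile: float = 0.80
    periods: dict = field(default_factory=lambda: dict(DEFAULT_PERIODS))
    community_min_size: int = 30
    padj_threshold: float = 0.05
    lfc_threshold: float = 1.0
    alpha: float = 0.1
    # synthetic-data sizes (study-shaped defaults; see the generators)
    cohort_n_genes: int = 5000
    reversal_fraction: float = 0.6
    regnet_n_tfs: int = 12
    regnet_n_genes: int = 120


_DOMAIN_CHECKS = {
    "seed": lambda v: isinstance(v, int) and 0 <= v < 2 ** 31,
    "n_per_tail": lambda v: isinstance(v, int) and v > 0,
    "top_k": lambda v: isinstance(v, int) and v > 0,
    "power": lambda v: isinstance(v, (int, float)) and v > 0,
    "min_module_size": lambda v: isinstance(v, int) and v > 0,
    "merge_height": lambda v: isinstance(v, (int, float)) and 0 <= v < 2,
    "n_hubs": lambda v: isinstance(v, int) and v > 0,
    "edge_quantile": lambda v: isinstance(v, (int, float)) and 0 < v < 1,
    "community_min_size": lambda v: isinstance(v, int) and v >= 0,
    "padj_threshold": lambda v: isinstance(v, (int, float)) and 0 < v <= 1,
    "lfc_threshold": lambda v: isinstance(v, (int, float)) and v >= 0,
    "alpha": lambda v: isinstance(v, (int, float)) and 0 <= v < 1,
    "cohort_n_genes": lambda v: isinstance(v, int) and v > 0,
    "reversal_fraction": lambda v: isinstance(v, (int, float)) and 0 <= v <= 1,
    "regnet_n_tfs": lambda v: isinstance(v, int) and v >= 2,
    "regnet_n_genes": lambda v: isinstance(v, int) and v >= 2,
}


def validate_config(raw) -> PipelineConfig:
    """Parse and validate a config document (dict, YAML text, or path).

    Defaults are injected for absent keys; unknown keys raise
    :class:`UnknownKeyError` with a nearest-valid-key suggestion; values
    outside their domain raise :class:`OutOfDomainError` naming the key.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, PipelineConfig):
        return raw
    if isinstance(raw, (str, Path)):
        text = Path(raw).read_text() if Path(str(raw)).exists() else str(raw)
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise MalformedConfigError(f"cannot parse config document: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise MalformedConfigError(
            f"config document must be a mapping, got {type(raw).__name__}")

    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    cleaned = {}
    for key, value in raw.items():
        if key not in known:
            hint = difflib.get_close_matches(str(key), sorted(known), n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise UnknownKeyError(f"unknown config key {key!r}{suffix}")
        cleaned[key] = value

    if "stages" in cleaned:
        stages = tuple(cleaned["stages"])
        bad = [s for s in stages if s not in _ALL_STAGES]
        if bad:
            raise OutOfDomainError(f"stages: unknown stage(s) {bad}")
        cleaned["stages"] = stages
    if "periods" in cleaned:
        periods = {int(k): int(v) for k, v in dict(cleaned["periods"]).items()}
        if not periods:
            raise OutOfDomainError("periods: empty time-period map")
        cleaned["periods"] = periods

    config = PipelineConfig(**{k: v for k, v in cleaned.items()})
    for key, check in _DOMAIN_CHECKS.items():
        if not check(getattr(config, key)):
            raise OutOfDomainError(
                f"{key}: value {getattr(config, key)!r} outside its domain")
    return config
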