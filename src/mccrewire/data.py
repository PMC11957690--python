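"""Core in-memory containers.

An :class:`ExpressionMatrix` couples a genes x samples matrix of log2-scale
expression with per-sample metadata (condition, time, replicate).  A
:class:`SyntheticTruth` records the structure planted by the synthetic
generators so downstream stages can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InconsistentFixtureError


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values with aligned sample metadata.

    Parameters
    ----------
    values:
        DataFrame of shape (genes, samples); the index holds gene
        identifiers and the columns sample identifiers, both unique.
    meta:
        DataFrame indexed by sample identifier with columns ``condition``
        (e.g. ``ER``/``CTRL`` or ``TUMOR``/``NORMAL``), ``time_hours``
        (nonnegative integer, or missing for cohorts) and ``replicate``
        (positive integer).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        if set(self.meta.index) != set(self.values.columns):
            raise ValueError("meta must cover every sample exactly once")
        if self.meta.index.has_duplicates:
            raise ValueError("duplicate sample metadata records")
        # keep metadata in column order of the value matrix
        self.meta = self.meta.loc[self.values.columns]

    # -- convenience accessors -------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(self.values[samples], self.meta.loc[samples])

    def for_condition(self, condition: str) -> "ExpressionMatrix":
        keep = self.meta.index[self.meta["condition"] == condition]
        return self.subset_samples(keep)

    def samples_at(self, condition: str | None = None,
                   time_hours: int | None = None) -> list[str]:
        mask = pd.Series(True, index=self.meta.index)
        if condition is not None:
            mask &= self.meta["condition"] == condition
        if time_hours is not None:
            mask &= self.meta["time_hours"] == time_hours
        return list(self.meta.index[mask])


@dataclass
class SyntheticTruth:
    """Ground truth planted by a synthetic generator.

    ``planted_module_labels`` maps gene -> integer block id (0 = background),
    ``planted_trends`` maps gene -> {condition: slope sign}, and
    ``planted_marker_assoc`` maps gene -> the true latent loading driving its
    mean correlation with the marker panel.  ``planted_reverser`` names the
    single perturbagen constructed to oppose the signature.
    """

    planted_module_labels: dict[str, int] = field(default_factory=dict)
    planted_trends: dict[str, dict[str, int]] = field(default_factory=dict)
    planted_marker_assoc: dict[str, float] = field(default_factory=dict)
    planted_reverser: str | None = None
    planted_enriched_terms: list[str] = field(default_factory=list)

    def check_consistent(self, genes: Sequence[str],
                         perturbagens: Sequence[str] = (),
                         terms: Sequence[str] = ()) -> None:
        """Raise if any truth record references an id absent from the fixture."""
        gene_set = set(genes)
        for name, mapping in (("planted_module_labels", self.planted_module_labels),
                              ("planted_trends", self.planted_trends),
                              ("planted_marker_assoc", self.planted_marker_assoc)):
            missing = set(mapping) - gene_set
            if missing:
                raise InconsistentFixtureError(
                    f"{name} references genes absent from the fixture: "
                    f"{sorted(missing)[:5]}")
        if self.planted_reverser is not None and perturbagens:
            if self.planted_reverser not in set(perturbagens):
                raise InconsistentFixtureError(
                    f"planted reverser {self.planted_reverser!r} not among profiles")
        if terms:
            missing = set(self.planted_enriched_terms) - set(terms)
            if missing:
                raise InconsistentFixtureError(
                    f"planted terms absent from annotation: {sorted(missing)}")
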