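"""Marker-anchored two-tail expression signature.

Each gene is scored by the arithmetic mean of its Pearson correlations with
a neuroendocrine marker panel across all cohort samples; the signature is
the two extremes of that ranking (default 500 genes per tail).  Marker genes
themselves are excluded from the ranking -- they would trivially top it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix
from .errors import (InsufficientGenesError, InsufficientSamplesError,
                     MissingMarkerError)


@dataclass
class MarkerPanel:
    """An ordered panel of marker genes anchoring the signature."""

    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("marker panel must be nonempty")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker panel contains duplicates")


@dataclass
class GeneSignature:
    """Ordered up/down gene tails plus the score table that produced them."""

    up: list[str]
    down: list[str]
    n_per_tail: int
    scores: pd.DataFrame  # index gene, column 'score'

    def __post_init__(self) -> None:
        if len(self.up) != self.n_per_tail or len(self.down) != self.n_per_tail:
            raise ValueError("tail sizes must equal n_per_tail")
        if set(self.up) & set(self.down):
            raise ValueError("signature tails overlap")

    @property
    def genes(self) -> list[str]:
        return list(self.up) + list(self.down)

    def direction(self) -> pd.Series:
        """+1 for up-tail genes, -1 for down-tail genes."""
        return pd.Series({g: 1.0 for g in self.up} | {g: -1.0 for g in self.down})


def marker_correlation_scores(expr: ExpressionMatrix,
                              panel: MarkerPanel | Sequence[str],
                              include_markers: bool = False,
                              samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Score every gene by its mean Pearson r with the marker panel.

    Correlations are computed across all cohort samples by default (tumor and
    normal pooled); pass ``samples`` to restrict (e.g. tumor-only).
    Zero-variance non-marker genes receive a missing (NaN) score and are
    excluded from downstream ranking.
    """
    markers = list(panel.markers if isinstance(panel, MarkerPanel) else panel)
    missing = [m for m in markers if m not in expr.values.index]
    if missing:
        raise MissingMarkerError(f"marker gene(s) not in expression matrix: {missing}")
    values = expr.values if samples is None else expr.values[list(samples)]
    if values.shape[1] < 3:
        raise InsufficientSamplesError(
            f"need at least 3 samples to correlate, got {values.shape[1]}")

    x = values.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    marker_pos = values.index.get_indexer(markers)
    if np.any(norms[marker_pos] == 0):
        bad = [m for m, p in zip(markers, marker_pos) if norms[p] == 0]
        raise MissingMarkerError(f"zero-variance marker gene(s): {bad}")

    with np.errstate(invalid="ignore", divide="ignore"):
        xn = x / norms[:, None]
    r = xn @ xn[marker_pos].T            # genes x markers
    score = r.mean(axis=1)               # NaN for zero-variance genes
    table = pd.DataFrame({"score": score}, index=values.index)
    if not include_markers:
        table = table.drop(index=markers)
    return table


def build_signature(scores: pd.DataFrame, n_per_tail: int = 500) -> GeneSignature:
    """Select the ``n_per_tail`` highest- and lowest-scoring genes.

    Ties are broken lexicographically by gene identifier: the ranking sorts
    on (score descending, gene ascending); the up tail is its head and the
    down tail its tail (reported in ascending-score order).
    """
    if n_per_tail <= 0:
        raise ValueError("n_per_tail must be positive")
    usable = scores.dropna(subset=["score"])
    if len(usable) < 2 * n_per_tail:
        raise InsufficientGenesError(
            f"{len(usable)} scored genes cannot fill two tails of {n_per_tail}")
    # mergesort is stable; pre-sort by gene id for the lexicographic tie-break
    ranked = usable.loc[sorted(usable.index)].sort_values(
        by=["score"], ascending=False, kind="mergesort")
    order = list(ranked.index)
    up = order[:n_per_tail]
    down = list(reversed(order[-n_per_tail:]))
    return GeneSignature(up=up, down=down, n_per_tail=n_per_tail,
                         scores=usable.copy())
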