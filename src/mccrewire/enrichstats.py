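"""Shared statistics: differential expression, set enrichment, inter-set
correlation dynamics and paired log2FC trajectories.

Differential expression is a Welch t test on log2 expression with
Benjamini-Hochberg adjustment and the study's thresholding conventions
(adjusted p <= 0.05, |log2FC| >= 1; the coexpression input variant drops the
fold-change threshold).  Enrichment is the hypergeometric upper tail with
Haldane-Anscombe-corrected odds ratios.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ExpressionMatrix
from .errors import (AlignmentError, InconsistentUniverseError,
                     InsufficientReplicatesError, InsufficientSamplesError)
from .regnet import PeriodMap

log = logging.getLogger(__name__)

DEFAULT_PADJ_THRESHOLD = 0.05
DEFAULT_LFC_THRESHOLD = 1.0


def de_test(expr: ExpressionMatrix, group_a: Sequence[str],
            group_b: Sequence[str],
            padj_thresh: float = DEFAULT_PADJ_THRESHOLD,
            lfc_thresh: float = DEFAULT_LFC_THRESHOLD
            ) -> tuple[pd.DataFrame, list[str]]:
    """Welch-t differential expression on log2 values, BH-adjusted.

    ``log2fc`` is mean(A) - mean(B) (inputs are already on log scale).
    Genes with zero variance in both groups are excluded.  Returns the full
    table and the genes passing ``p_adj <= padj_thresh`` and
    ``|log2fc| >= lfc_thresh`` (set ``lfc_thresh=0`` for the
    coexpression-input variant).
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise InsufficientReplicatesError("each group needs >= 2 samples")
    a = expr.values[group_a].to_numpy(dtype=float)
    b = expr.values[group_b].to_numpy(dtype=float)
    usable = ~((a.std(axis=1) == 0) & (b.std(axis=1) == 0))
    genes = expr.values.index[usable]
    a, b = a[usable], b[usable]

    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({"log2fc": lfc, "t": t, "p": p, "p_adj": p_adj},
                         index=genes)
    hits = list(table.index[(table["p_adj"] <= padj_thresh)
                            & (table["log2fc"].abs() >= lfc_thresh)])
    return table, hits


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> float:
    """Sample odds ratio with the 0.5 correction only on zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))


def set_enrichment(query: Iterable[str], universe: Iterable[str],
                   annotation: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term.

    Terms are intersected with the universe first; p is the upper tail
    P(overlap >= observed), BH-adjusted across terms; rows sorted by
    ascending adjusted p.
    """
    query = set(query)
    universe = set(universe)
    if query - universe:
        raise InconsistentUniverseError("query genes outside the universe")
    if not query:
        warnings.warn("empty query set; returning an empty enrichment table",
                      stacklevel=2)
        return pd.DataFrame(columns=["overlap", "set_size", "term_size",
                                     "universe_size", "odds_ratio", "p", "p_adj"])

    rows = []
    for term in sorted(annotation):
        members = set(annotation[term]) & universe
        k = len(query & members)
        m, n_t, n_q = len(universe), len(members), len(query)
        p = float(stats.hypergeom.sf(k - 1, m, n_t, n_q))
        orv = odds_ratio_2x2(k, n_q - k, n_t - k, m - n_q - n_t + k)
        rows.append({"term": term, "overlap": k, "set_size": n_q,
                     "term_size": n_t, "universe_size": m,
                     "odds_ratio": orv, "p": p})
    table = pd.DataFrame(rows).set_index("term")
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table.sort_values(["p_adj", "p"], kind="mergesort")


def interset_correlation(expr: ExpressionMatrix, set_a: Sequence[str],
                         set_b: Sequence[str],
                         groups: Mapping[object, Sequence[str]]
                         ) -> dict[object, dict]:
    """Pairwise Pearson r between two gene sets within each sample group.

    ``groups`` maps a group key (e.g. ``(condition, period)``) to its sample
    ids.  Returns per group the full signed r matrix (set_a x set_b) and the
    mean absolute correlation.  Genes constant within a group are skipped
    (and logged).
    """
    set_a, set_b = list(set_a), list(set_b)
    if set(set_a) & set(set_b):
        raise ValueError("gene sets must be disjoint")
    out = {}
    for key, samples in groups.items():
        samples = list(samples)
        if len(samples) < 3:
            raise InsufficientSamplesError(
                f"group {key!r} has {len(samples)} samples; need >= 3")
        sub = expr.values.loc[set_a + set_b, samples].to_numpy(dtype=float)
        sd = sub.std(axis=1)
        skip = sd == 0
        if skip.any():
            log.warning("group %r: skipping %d constant genes", key,
                        int(skip.sum()))
        centered = sub - sub.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = centered / np.linalg.norm(centered, axis=1, keepdims=True)
        r = norm[:len(set_a)] @ norm[len(set_a):].T
        r_df = pd.DataFrame(r, index=set_a, columns=set_b)
        valid = r_df.to_numpy()[np.isfinite(r_df.to_numpy())]
        out[key] = {"r": r_df, "mean_abs_r": float(np.abs(valid).mean())}
    return out


def period_groups(expr: ExpressionMatrix,
                  period_map: PeriodMap | None = None,
                  conditions: Sequence[str] | None = None
                  ) -> dict[tuple[str, int], list[str]]:
    """Sample groups keyed by (condition, period) from the metadata."""
    period_map = period_map or PeriodMap()
    meta = expr.meta
    conditions = conditions or sorted(meta["condition"].unique())
    groups: dict[tuple[str, int], list[str]] = {}
    for sample, row in meta.iterrows():
        if row["condition"] not in conditions:
            continue
        key = (row["condition"], period_map.period_of(row["time_hours"]))
        groups.setdefault(key, []).append(sample)
    return dict(sorted(groups.items()))


def relative_log2fc(expr_er: ExpressionMatrix, expr_ctrl: ExpressionMatrix,
                    pairing: Sequence[int] | None = None) -> pd.DataFrame:
    """Per-gene, per-time-point mean(ER) - mean(CTRL) on the log2 scale.

    Both matrices must share their gene set; every time point in the pairing
    must be present with at least one replicate in both conditions.
    Returns a genes x time DataFrame.
    """
    if list(expr_er.values.index) != list(expr_ctrl.values.index):
        common = expr_er.values.index.intersection(expr_ctrl.values.index)
        if len(common) == 0:
            raise AlignmentError("matrices share no genes")
        expr_er = ExpressionMatrix(expr_er.values.loc[common], expr_er.meta)
        expr_ctrl = ExpressionMatrix(expr_ctrl.values.loc[common], expr_ctrl.meta)
    times_er = set(expr_er.meta["time_hours"].dropna().astype(int))
    times_ctrl = set(expr_ctrl.meta["time_hours"].dropna().astype(int))
    times = sorted(times_er & times_ctrl) if pairing is None else list(pairing)
    missing = [t for t in times if t not in times_er or t not in times_ctrl]
    if missing or not times:
        raise AlignmentError(f"time points missing in one condition: {missing}")

    cols = {}
    for t in times:
        er_samples = expr_er.meta.index[expr_er.meta["time_hours"] == t]
        ctrl_samples = expr_ctrl.meta.index[expr_ctrl.meta["time_hours"] == t]
        cols[t] = (expr_er.values[list(er_samples)].mean(axis=1)
                   - expr_ctrl.values[list(ctrl_samples)].mean(axis=1))
    return pd.DataFrame(cols)
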