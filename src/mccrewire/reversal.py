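"""Perturbagen screening by signature reversal.

A drug "reverses" a two-tail signature when its top perturbed genes overlap
the signature with opposed direction: drug-downregulated genes hitting the
signature's up tail and vice versa.  The direction-aware overlap is scored
with a one-sided Fisher exact test and ranked across drugs after
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateProfileError, InconsistentUniverseError
from .signature import GeneSignature


@dataclass
class PerturbationProfile:
    """Per-gene log2 fold change (drug vs vehicle) for one perturbagen."""

    perturbagen: str
    log2fc: pd.Series  # index = gene universe covered

    def __post_init__(self) -> None:
        if self.log2fc.index.has_duplicates:
            raise ValueError("duplicate genes in profile")
        if not np.isfinite(self.log2fc.to_numpy(dtype=float)).all():
            raise ValueError("log2fc values must be finite")

    @property
    def universe(self) -> list[str]:
        return list(self.log2fc.index)


@dataclass
class ReversalResult:
    """Screening outcome for one perturbagen."""

    perturbagen: str
    table: tuple[int, int, int, int]  # (a, b, c, d)
    odds_ratio: float
    p: float
    p_adj: float = float("nan")
    rank: int | None = None


def _fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p: P(overlap >= a) with margins fixed.

    Computed from the hypergeometric tail; equivalent to
    ``fisher_exact(..., alternative='greater')``.
    """
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio; Haldane-Anscombe 0.5 applied only on zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
    return float((a * d) / (b * c))


def select_top_perturbed(profile: PerturbationProfile,
                         k: int = 1000) -> tuple[list[str], list[str]]:
    """Pick the ``k`` genes of largest |z-scored log2FC| and split by sign.

    Returns ``(drug_up, drug_down)``: selected genes with positive /
    negative raw log2FC (exact zeros fall in neither set).  Ties in |z| are
    broken lexicographically.
    """
    lfc = profile.log2fc
    if len(lfc) < k:
        raise ValueError(f"universe of {len(lfc)} smaller than k={k}")
    sd = float(lfc.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateProfileError(
            f"{profile.perturbagen}: log2fc has zero variance")
    z = (lfc - lfc.mean()) / sd
    ranked = z.abs().to_frame("absz")
    ranked["gene"] = ranked.index
    ranked = ranked.sort_values(by=["absz", "gene"], ascending=[False, True])
    selected = ranked.index[:k]
    vals = lfc[selected]
    return list(selected[vals > 0]), list(selected[vals < 0])


def reversal_enrichment(signature: GeneSignature,
                        selected: tuple[Sequence[str], Sequence[str]],
                        universe: Iterable[str],
                        perturbagen: str = "",
                        direction_aware: bool = True,
                        alternative: str = "greater") -> ReversalResult:
    """Fisher exact test of direction-opposed overlap with the signature.

    The concordant count ``a`` is |drug_down & signature_up| +
    |drug_up & signature_down| (or the plain intersection when
    ``direction_aware`` is off); the 2x2 table is completed from the selected
    and signature sizes against the universe.
    """
    universe = set(universe)
    drug_up, drug_down = (set(selected[0]), set(selected[1]))
    sig_up = set(signature.up) & universe
    sig_down = set(signature.down) & universe
    if (drug_up | drug_down) - universe:
        raise InconsistentUniverseError("selected genes outside the universe")
    if not (set(signature.up) | set(signature.down)) & universe:
        raise InconsistentUniverseError("signature does not intersect the universe")

    if direction_aware:
        a = len(drug_down & sig_up) + len(drug_up & sig_down)
    else:
        a = len((drug_up | drug_down) & (sig_up | sig_down))
    n_sel = len(drug_up | drug_down)
    n_sig = len(sig_up | sig_down)
    b = n_sel - a
    c = n_sig - a
    d = len(universe) - a - b - c
    if min(b, c, d) < 0:
        raise InconsistentUniverseError("universe smaller than the union of inputs")

    if alternative == "greater":
        p = _fisher_one_sided(a, b, c, d)
    else:
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])
    return ReversalResult(perturbagen=perturbagen, table=(a, b, c, d),
                          odds_ratio=_odds_ratio(a, b, c, d), p=p)


def reversal_screen(signature: GeneSignature,
                    profiles: Mapping[str, PerturbationProfile] | Sequence[PerturbationProfile],
                    k: int = 1000,
                    universe: Iterable[str] | None = None,
                    direction_aware: bool = True,
                    alternative: str = "greater") -> list[ReversalResult]:
    """Score all perturbagens, BH-adjust across them, and rank.

    The test universe defaults, per drug, to the intersection of the
    signature's score table and the drug's profile.  Ranking is by ascending
    adjusted p, ties by descending odds ratio then perturbagen identifier.
    """
    if not isinstance(profiles, Mapping):
        profiles = {p.perturbagen: p for p in profiles}
    if not profiles:
        raise ValueError("need at least one perturbation profile")

    scored = set(signature.scores.index)
    results = []
    for name in sorted(profiles):
        profile = profiles[name]
        if universe is None:
            uni = [g for g in profile.universe if g in scored]
        else:
            uni = list(universe)
        restricted = PerturbationProfile(name, profile.log2fc[profile.log2fc.index.isin(uni)])
        selected = select_top_perturbed(restricted, k=k)
        res = reversal_enrichment(signature, selected, uni, perturbagen=name,
                                  direction_aware=direction_aware,
                                  alternative=alternative)
        results.append(res)

    padj = multipletests([r.p for r in results], method="fdr_bh")[1]
    for r, q in zip(results, padj):
        r.p_adj = float(q)
    results.sort(key=lambda r: (r.p_adj, -r.odds_ratio, r.perturbagen))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results


def results_table(results: Sequence[ReversalResult]) -> pd.DataFrame:
    """Tidy per-perturbagen screening table."""
    return pd.DataFrame(
        [{"perturbagen": r.perturbagen, "a": r.table[0], "b": r.table[1],
          "c": r.table[2], "d": r.table[3], "odds_ratio": r.odds_ratio,
          "p": r.p, "p_adj": r.p_adj, "rank": r.rank} for r in results]
    ).set_index("perturbagen")
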