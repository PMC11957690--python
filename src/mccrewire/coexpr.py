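"""Signed weighted-coexpression core.

Implements the signed soft-thresholded adjacency
``a_ij = ((1 + r_ij)/2)^beta`` (default beta = 16), the topological overlap
matrix (TOM), scale-free-topology power scan, hierarchical module detection
with eigengene merging (minimum module size 30, merge height 0.25), module
eigengene / trait correlation, and hub plus leading-edge extraction (40 hubs
per module, top-quintile TOM edges).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data import ExpressionMatrix
from .errors import DegenerateInputError, UndefinedCorrelationError

log = logging.getLogger(__name__)

DEFAULT_POWER = 16.0
DEFAULT_POWER_GRID = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)


@dataclass
class CoexpressionNetwork:
    """Signed adjacency and TOM over a gene set, plus the expression used."""

    genes: list[str]
    samples: list[str]
    power: float
    adjacency: np.ndarray
    tom: np.ndarray
    expression: pd.DataFrame          # filtered genes x samples
    mode: str = "signed"
    dropped: list[str] = field(default_factory=list)


@dataclass
class ModulePartition:
    """Gene -> module labels (0 = unassigned) with eigengenes and hubs."""

    labels: pd.Series                  # index gene, int module id
    eigengenes: pd.DataFrame           # samples x module id
    hub_lists: dict[int, list[str]] = field(default_factory=dict)
    merge_height: float = 0.25
    min_size: int = 30

    def module_ids(self) -> list[int]:
        return sorted(m for m in self.labels.unique() if m != 0)

    def genes_of(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def _drop_zero_variance(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    sd = values.to_numpy().std(axis=1)
    dropped = list(values.index[sd == 0])
    if dropped:
        log.warning("dropping %d zero-variance genes before network "
                    "construction: %s%s", len(dropped), dropped[:5],
                    "..." if len(dropped) > 5 else "")
    return values.loc[sd > 0], dropped


def signed_adjacency(values: pd.DataFrame, power: float = DEFAULT_POWER) -> np.ndarray:
    """``((1 + r)/2)^power`` for the gene-gene Pearson correlation r."""
    r = np.corrcoef(values.to_numpy())
    a = np.power(np.clip((1.0 + r) / 2.0, 0.0, 1.0), power)
    np.fill_diagonal(a, 1.0)
    return a


def tom_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: shared-neighbor weight plus direct adjacency.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    the sum over u distinct from i and j, k the connectivity (row sum minus
    the diagonal), and unit diagonal.
    """
    a = np.asarray(adjacency, dtype=float)
    k = a.sum(axis=1) - np.diag(a)
    # (A @ A)_ij includes u = i and u = j; subtract their a_ii*a_ij + a_ij*a_jj
    shared = a @ a - a * (np.diag(a)[:, None] + np.diag(a)[None, :])
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom = np.clip(np.nan_to_num(tom, nan=0.0), 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def soft_threshold_scan(expr: ExpressionMatrix,
                        powers: tuple[float, ...] = DEFAULT_POWER_GRID,
                        n_bins: int = 10) -> pd.DataFrame:
    """Scale-free-topology fit per candidate soft-thresholding power.

    For each power: build the signed adjacency, compute connectivities
    ``k_i``, histogram them into ``n_bins`` equal-width bins, and regress
    ``log10(frequency)`` on ``log10(mean k per bin)`` over usable bins.
    Returns (power, scale_free_R2, slope, mean_connectivity).
    """
    values, dropped = _drop_zero_variance(expr.values)
    if values.shape[0] == 0:
        raise DegenerateInputError("all genes have zero variance")
    if values.shape[1] < 4 or values.shape[0] < 30:
        warnings.warn("soft-threshold scan on fewer than 4 samples / 30 genes "
                      "is unreliable", stacklevel=2)
    rows = []
    for power in powers:
        a = signed_adjacency(values, power)
        k = a.sum(axis=1) - 1.0
        edges = np.linspace(k.min(), k.max(), n_bins + 1)
        idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
        freq = np.bincount(idx, minlength=n_bins).astype(float)
        mean_k = np.array([k[idx == b].mean() if freq[b] else np.nan
                           for b in range(n_bins)])
        usable = (freq > 0) & (mean_k > 0)
        if usable.sum() >= 2:
            fit = stats.linregress(np.log10(mean_k[usable]), np.log10(freq[usable]))
            r2, slope = fit.rvalue ** 2, fit.slope
        else:
            r2, slope = np.nan, np.nan
        rows.append({"power": power, "scale_free_R2": r2, "slope": slope,
                     "mean_connectivity": k.mean()})
    return pd.DataFrame(rows)


def build_network(expr: ExpressionMatrix, power: float = DEFAULT_POWER,
                  mode: str = "signed") -> CoexpressionNetwork:
    """Signed adjacency plus TOM for the (variance-filtered) genes."""
    if mode != "signed":
        raise ValueError("only the signed network mode is implemented")
    values, dropped = _drop_zero_variance(expr.values)
    if values.shape[0] == 0:
        raise DegenerateInputError("all genes have zero variance")
    adjacency = signed_adjacency(values, power)
    return CoexpressionNetwork(genes=list(values.index),
                               samples=list(values.columns), power=power,
                               adjacency=adjacency, tom=tom_matrix(adjacency),
                               expression=values, dropped=dropped)


def _eigengene(values: pd.DataFrame) -> np.ndarray:
    """First principal component across samples of row-standardized genes.

    Unit norm; sign-oriented so it correlates nonnegatively with the module's
    mean expression profile.
    """
    x = values.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    sd[sd == 0] = 1.0
    x = x / sd[:, None]
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    e = vt[0]
    mean_profile = values.to_numpy().mean(axis=0)
    mp = mean_profile - mean_profile.mean()
    if float(e @ mp) < 0:
        e = -e
    return e


def _cut_static(dist_linkage: np.ndarray, n_genes: int,
                min_size: int) -> np.ndarray:
    """Static dendrogram cut at the height that yields the largest number of
    clusters of size >= min_size (ties resolved toward the largest height,
    i.e. fully agglomerated clusters)."""
    heights = np.unique(dist_linkage[:, 2])
    cuts = np.concatenate([[heights[0] / 2.0],
                           (heights[:-1] + heights[1:]) / 2.0,
                           [heights[-1] + 1.0]])
    best_labels, best_count, best_cut = None, -1, None
    for t in cuts:
        labels = fcluster(dist_linkage, t=t, criterion="distance")
        count = int(np.sum(np.bincount(labels) >= min_size))
        if count >= best_count:  # >= keeps the largest qualifying height
            best_labels, best_count, best_cut = labels, count, t
    return best_labels


def detect_modules(network: CoexpressionNetwork, min_size: int = 30,
                   merge_height: float = 0.25,
                   cut_height: float | None = None) -> ModulePartition:
    """Average-linkage clustering on 1 - TOM, size filter, eigengene merge.

    Initial clusters come from a static cut (at ``cut_height`` if given,
    otherwise the height that maximizes the number of clusters of size
    >= ``min_size``); clusters below ``min_size`` are left unassigned
    (label 0).  Modules whose eigengene dissimilarity ``1 - r`` falls below
    ``merge_height`` are merged iteratively, closest pair first, and
    eigengenes are recomputed after merging.
    """
    n = len(network.genes)
    genes = pd.Index(network.genes)
    if n < min_size:
        warnings.warn(f"only {n} genes (< min_size={min_size}); "
                      "returning a single unassigned pool", stacklevel=2)
        labels = pd.Series(0, index=genes, name="module")
        return ModulePartition(labels=labels,
                               eigengenes=pd.DataFrame(index=network.samples),
                               merge_height=merge_height, min_size=min_size)

    dist = 1.0 - network.tom
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    if cut_height is not None:
        raw = fcluster(z, t=cut_height, criterion="distance")
    else:
        raw = _cut_static(z, n, min_size)

    sizes = pd.Series(raw).value_counts()
    keep = sorted(sizes.index[sizes >= min_size])
    labels = pd.Series(0, index=genes, name="module")
    for new_id, old in enumerate(keep, start=1):
        labels[raw == old] = new_id

    labels = _merge_by_eigengene(network.expression, labels, merge_height)
    # relabel by decreasing size, recompute eigengenes
    order = labels[labels != 0].value_counts().sort_values(ascending=False)
    remap = {old: i for i, old in enumerate(order.index, start=1)}
    labels = labels.map(lambda m: remap.get(m, 0))
    eig = _module_eigengenes(network.expression, labels)
    return ModulePartition(labels=labels, eigengenes=eig,
                           merge_height=merge_height, min_size=min_size)


def _module_eigengenes(values: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    mods = sorted(m for m in labels.unique() if m != 0)
    eig = {m: _eigengene(values.loc[labels.index[labels == m]]) for m in mods}
    return pd.DataFrame(eig, index=values.columns)


def _merge_by_eigengene(values: pd.DataFrame, labels: pd.Series,
                        merge_height: float) -> pd.Series:
    """Merge modules whose eigengene dissimilarity (1 - r) < merge_height."""
    labels = labels.copy()
    while True:
        mods = sorted(m for m in labels.unique() if m != 0)
        if len(mods) < 2:
            return labels
        eig = _module_eigengenes(values, labels)
        best, best_d = None, np.inf
        for i, mi in enumerate(mods):
            for mj in mods[i + 1:]:
                r = float(np.corrcoef(eig[mi], eig[mj])[0, 1])
                d = 1.0 - r
                if d < best_d:
                    best, best_d = (mi, mj), d
        if best is None or best_d >= merge_height:
            return labels
        mi, mj = best
        labels[labels == mj] = mi


def module_trait_correlation(partition: ModulePartition,
                             trait) -> pd.DataFrame:
    """Pearson r (and two-sided t-based p) of each eigengene with a trait."""
    trait = np.asarray(trait, dtype=float)
    if len(trait) != partition.eigengenes.shape[0]:
        raise ValueError("trait length must equal the sample count")
    if np.std(trait) == 0:
        raise UndefinedCorrelationError("trait is constant")
    rows = []
    for m in partition.eigengenes.columns:
        e = partition.eigengenes[m].to_numpy()
        if np.std(e) == 0:
            raise UndefinedCorrelationError(f"module {m} eigengene is constant")
        r, p = stats.pearsonr(e, trait)
        rows.append({"module": m, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows).set_index("module")


def hub_and_leading_edges(network: CoexpressionNetwork,
                          partition: ModulePartition,
                          n_hubs: int = 40,
                          edge_quantile: float = 0.80
                          ) -> tuple[dict[int, list[str]], pd.DataFrame]:
    """Top-connectivity hubs per module and the top-quantile TOM edges.

    The hub score of a gene is its summed TOM edge weight (row sum minus the
    unit diagonal).  Per module the ``n_hubs`` highest-scoring genes are
    retained (the whole module if smaller); among edges between retained
    hubs, exactly the ceil((1 - edge_quantile) * E) heaviest are kept
    (weight ties at the threshold are all included).
    """
    if list(partition.labels.index) != list(network.genes):
        raise ValueError("partition is not aligned with the network")
    tom = network.tom
    score = tom.sum(axis=1) - 1.0
    genes = pd.Index(network.genes)
    hub_lists: dict[int, list[str]] = {}
    for m in partition.module_ids():
        members = np.where(partition.labels.to_numpy() == m)[0]
        ranked = sorted(members, key=lambda i: (-score[i], genes[i]))
        hub_lists[m] = [genes[i] for i in ranked[:n_hubs]]

    hub_idx = sorted({i for hubs in hub_lists.values()
                      for i in genes.get_indexer(hubs)})
    edges = []
    for ai, i in enumerate(hub_idx):
        for j in hub_idx[ai + 1:]:
            edges.append((genes[i], genes[j], float(tom[i, j])))
    edge_df = pd.DataFrame(edges, columns=["gene_i", "gene_j", "tom"])
    if len(edge_df):
        m_keep = int(np.ceil((1.0 - edge_quantile) * len(edge_df)))
        threshold = np.sort(edge_df["tom"].to_numpy())[::-1][m_keep - 1]
        edge_df = edge_df[edge_df["tom"] >= threshold].reset_index(drop=True)
    return hub_lists, edge_df
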