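"""Time-resolved bipartite regulatory-network comparison.

The pipeline is: message-passing inference of a TF x gene edge-weight matrix
from expression, a TF-motif prior and a TF-TF interaction matrix;
leave-one-out single-sample extraction; a nonnegative edge transform
(softplus by default) followed by averaging within five time periods; and
differential-community detection that maximizes the modularity of the
perturbed network against the base network's strength-product null, keeping
communities of more than ``min_size`` nodes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix
from .errors import AlignmentError, InsufficientSamplesError
from .synthetic import DEFAULT_PERIODS

log = logging.getLogger(__name__)


@dataclass
class BipartiteNetwork:
    """TF x gene edge-weight matrix with free-form provenance ``tag``."""

    tfs: list[str]
    genes: list[str]
    weights: np.ndarray
    tag: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.tfs), len(self.genes)):
            raise ValueError("weights shape must be (n_tfs, n_genes)")
        if not np.isfinite(self.weights).all():
            raise ValueError("edge weights must be finite")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=pd.Index(self.tfs, name="tf"),
                            columns=pd.Index(self.genes, name="gene"))


@dataclass
class PeriodMap:
    """Assignment of time points (hours) to analysis periods."""

    assignment: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_PERIODS))

    def period_of(self, time_hours: int) -> int:
        try:
            return self.assignment[int(time_hours)]
        except KeyError:
            raise AlignmentError(f"time point {time_hours} h not covered by "
                                 "the period map") from None

    def periods(self) -> list[int]:
        return sorted(set(self.assignment.values()))


@dataclass
class CommunityResult:
    """Node -> community membership with per-node differential-modularity
    contributions and the size-filtered community ids."""

    membership: dict[tuple[str, str], int]      # ("tf"|"gene", name) -> community
    diff_modularity: dict[tuple[str, str], float]
    sizes: dict[int, int]
    retained: list[int]
    modularity: float = float("nan")

    def nodes_of(self, community: int) -> list[tuple[str, str]]:
        return sorted(n for n, c in self.membership.items() if c == community)


# ---------------------------------------------------------------------------
# message-passing inference
# ---------------------------------------------------------------------------

def _zscore(m: np.ndarray) -> np.ndarray:
    sd = m.std()
    if sd == 0:
        return m - m.mean()
    return (m - m.mean()) / sd


def _tanimoto(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Continuous Tanimoto similarity of the rows of x with the columns of y.

    ``T_ij = (xy)_ij / sqrt(sum_k x_ik^2 + sum_k y_kj^2 - |(xy)_ij|)``.
    """
    num = x @ y
    denom2 = np.add.outer((x * x).sum(axis=1), (y * y).sum(axis=0)) - np.abs(num)
    denom = np.sqrt(np.clip(denom2, 1e-12, None))
    return num / denom


def infer_network(expr: ExpressionMatrix, motif: pd.DataFrame,
                  ppi: pd.DataFrame, alpha: float = 0.1,
                  max_iter: int = 300, tol: float = 1e-3) -> BipartiteNetwork:
    """Message-passing integration of expression, motif prior and PPI.

    All three inputs are z-score normalized; the regulatory matrix ``W``
    (initialized from the motif prior) is updated by damped message passing

    ``W <- (1 - alpha) W + alpha * (T(P, W) + T(W, C)) / 2``

    where ``C`` is the gene-gene coexpression, ``P`` the TF cooperativity,
    and ``T`` the continuous Tanimoto similarity; ``P`` and ``C`` are pulled
    toward the co-targeting / co-regulation similarity of ``W`` with the
    same damping and re-z-scored each step (a fixed normalization that keeps
    the similarity diagonal from inflating the iteration).  Iteration stops
    at ``max_iter`` or when ``max |dW| < tol``.
    """
    tfs = list(motif.index)
    genes = list(motif.columns)
    missing = set(genes) - set(expr.values.index)
    if missing:
        raise AlignmentError(f"motif genes absent from expression: "
                             f"{sorted(missing)[:5]}")
    if set(tfs) - set(expr.values.index):
        raise AlignmentError("TFs must be a subset of the expression genes")
    if expr.n_samples < 3:
        raise InsufficientSamplesError("network inference needs >= 3 samples")

    x = expr.values.loc[genes].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(x)
    c = np.nan_to_num(c, nan=0.0)

    w = _zscore(motif.to_numpy(dtype=float))
    p = _zscore(ppi.loc[tfs, tfs].to_numpy(dtype=float))
    p = (p + p.T) / 2.0
    c = _zscore(c)
    c = (c + c.T) / 2.0

    converged = False
    for iteration in range(max_iter):
        responsibility = _tanimoto(p, w)
        availability = _tanimoto(w, c)
        w_new = (1.0 - alpha) * w + alpha * (responsibility + availability) / 2.0
        delta = float(np.max(np.abs(w_new - w)))
        w = w_new
        if alpha > 0:
            p_hat = _tanimoto(w, w.T)
            p = (1.0 - alpha) * p + alpha * (p_hat + p_hat.T) / 2.0
            c_hat = _tanimoto(w.T, w)
            c = (1.0 - alpha) * c + alpha * (c_hat + c_hat.T) / 2.0
            # hold P and C on the z-scored scale; their co-targeting updates
            # otherwise inflate through the similarity diagonal and diverge
            p = _zscore(p)
            c = _zscore(c)
        if delta < tol:
            converged = True
            break
    if not converged:
        log.warning("message passing did not converge within %d iterations "
                    "(last max |dW| = %.3g)", max_iter, delta)
    return BipartiteNetwork(tfs=tfs, genes=genes, weights=w,
                            tag={"converged": converged,
                                 "iterations": iteration + 1,
                                 "samples": list(expr.samples)})


# ---------------------------------------------------------------------------
# single-sample extraction
# ---------------------------------------------------------------------------

def single_sample_networks(expr: ExpressionMatrix, motif: pd.DataFrame,
                           ppi: pd.DataFrame,
                           inference: Callable[[ExpressionMatrix], np.ndarray] | None = None,
                           recenter: bool = True,
                           **settings) -> list[BipartiteNetwork]:
    """Leave-one-out extraction of one network per sample.

    For sample q, ``e_q = N * e(all) - (N - 1) * e(all \\ q)`` edgewise.  With
    ``recenter`` (default) the constant matrix ``e(all) - mean_q e_q`` is
    added to every ``e_q`` so that the single-sample networks average exactly
    to the aggregate; this is a no-op whenever the inference function is
    linear in the sample set and otherwise removes the jackknife bias term.
    """
    n = expr.n_samples
    if n < 3:
        raise InsufficientSamplesError("single-sample extraction needs >= 3 samples")
    if inference is None:
        def inference(e: ExpressionMatrix) -> np.ndarray:
            return infer_network(e, motif, ppi, **settings).weights

    e_all = np.asarray(inference(expr), dtype=float)
    nets = []
    for q in expr.samples:
        rest = [s for s in expr.samples if s != q]
        e_loo = np.asarray(inference(expr.subset_samples(rest)), dtype=float)
        e_q = n * e_all - (n - 1) * e_loo
        meta = expr.meta.loc[q]
        tag = {"sample": q, "condition": meta.get("condition"),
               "time_hours": (int(meta["time_hours"])
                              if "time_hours" in meta and pd.notna(meta["time_hours"])
                              else None)}
        nets.append(BipartiteNetwork(tfs=list(motif.index),
                                     genes=list(motif.columns),
                                     weights=e_q, tag=tag))
    if recenter:
        correction = e_all - np.mean([net.weights for net in nets], axis=0)
        for net in nets:
            net.weights = net.weights + correction
    return nets


# ---------------------------------------------------------------------------
# edge transforms and period averaging
# ---------------------------------------------------------------------------

def _softplus(w: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, w)


TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "softplus": _softplus,
    "identity": lambda w: np.asarray(w, dtype=float),
    "abs": np.abs,
}


def register_transform(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register an edge transform (hook for alternative published forms)."""
    TRANSFORMS[name] = fn


def transform_and_average(networks: Sequence[BipartiteNetwork],
                          period_map: PeriodMap | None = None,
                          transform: str | Callable = "softplus"
                          ) -> dict[tuple[str, int], BipartiteNetwork]:
    """Edgewise transform each single-sample network, then average per period.

    Networks are grouped by (condition, period) read from their tags; every
    time annotation must be covered by the period map.  Returns one averaged
    network per group; with the softplus default all output weights are > 0.
    """
    period_map = period_map or PeriodMap()
    fn = TRANSFORMS[transform] if isinstance(transform, str) else transform

    groups: dict[tuple[str, int], list[np.ndarray]] = {}
    ref = None
    for net in networks:
        t = net.tag.get("time_hours")
        if t is None:
            raise AlignmentError(f"network {net.tag} lacks a time annotation")
        key = (net.tag.get("condition"), period_map.period_of(t))
        groups.setdefault(key, []).append(fn(net.weights))
        ref = net
    out = {}
    for key in sorted(groups, key=lambda k: (str(k[0]), k[1])):
        mean_w = np.mean(groups[key], axis=0)
        out[key] = BipartiteNetwork(tfs=list(ref.tfs), genes=list(ref.genes),
                                    weights=mean_w,
                                    tag={"condition": key[0], "period": key[1],
                                         "n_networks": len(groups[key])})
    return out


# ---------------------------------------------------------------------------
# bipartite / differential modularity
# ---------------------------------------------------------------------------

def bipartite_modularity(weights: np.ndarray, tf_labels: np.ndarray,
                         gene_labels: np.ndarray,
                         null_weights: np.ndarray | None = None,
                         null_total: float | None = None) -> float:
    """``Q = (1/m') sum_ij (A_ij - k_i d_j / m) [c_i == c_j]``.

    With ``null_weights``/``null_total`` unset this is the plain bipartite
    modularity of ``weights``; supplying a base network's weights as the null
    gives the differential modularity of ``weights`` against that base.
    """
    a = np.asarray(weights, dtype=float)
    null = a if null_weights is None else np.asarray(null_weights, dtype=float)
    m = null.sum() if null_total is None else null_total
    m_prime = a.sum()
    if m_prime == 0 or m == 0:
        return 0.0
    b = a - np.outer(null.sum(axis=1), null.sum(axis=0)) / m
    same = tf_labels[:, None] == gene_labels[None, :]
    return float((b * same).sum() / m_prime)


def _greedy_labels(b: np.ndarray, norm: float, tf_labels: np.ndarray,
                   gene_labels: np.ndarray, max_sweeps: int = 200
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Greedy label moves maximizing ``sum_in_community(b) / norm``.

    Nodes are visited in a fixed order (TFs then genes, index order); each
    node may join any existing label or open a fresh one; a move is accepted
    only when it strictly improves the objective (tolerance 1e-12).
    """
    n_tf, n_gene = b.shape
    tf_labels = tf_labels.copy()
    gene_labels = gene_labels.copy()
    next_label = int(max(tf_labels.max(initial=0), gene_labels.max(initial=0))) + 1
    for _ in range(max_sweeps):
        moved = False
        for i in range(n_tf):
            scores = np.bincount(gene_labels, weights=b[i],
                                 minlength=next_label + 1)
            current = scores[tf_labels[i]]
            best = int(np.argmax(scores))
            if scores[best] > current + 1e-12:
                tf_labels[i] = best if scores[best] > 1e-12 else next_label
                if tf_labels[i] == next_label:
                    next_label += 1
                moved = True
            elif current < -1e-12:
                tf_labels[i] = next_label  # isolate a node that hurts its group
                next_label += 1
                moved = True
        for j in range(n_gene):
            scores = np.bincount(tf_labels, weights=b[:, j],
                                 minlength=next_label + 1)
            current = scores[gene_labels[j]]
            best = int(np.argmax(scores))
            if scores[best] > current + 1e-12:
                gene_labels[j] = best if scores[best] > 1e-12 else next_label
                if gene_labels[j] == next_label:
                    next_label += 1
                moved = True
            elif current < -1e-12:
                gene_labels[j] = next_label
                next_label += 1
                moved = True
        if not moved:
            break
    return tf_labels, gene_labels


def _canonical(tf_labels: np.ndarray, gene_labels: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Relabel communities by first appearance in (TFs, genes) order."""
    remap: dict[int, int] = {}
    out_tf = np.empty_like(tf_labels)
    out_gene = np.empty_like(gene_labels)
    for arr, out in ((tf_labels, out_tf), (gene_labels, out_gene)):
        for i, lab in enumerate(arr):
            if lab not in remap:
                remap[lab] = len(remap)
            out[i] = remap[lab]
    return out_tf, out_gene


def detect_base_communities(base: BipartiteNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Greedy bipartite-modularity communities of the base network."""
    a = base.weights
    m = a.sum()
    if m == 0:
        n_tf, n_gene = a.shape
        return np.arange(n_tf), np.arange(n_tf, n_tf + n_gene)
    b = a - np.outer(a.sum(axis=1), a.sum(axis=0)) / m
    n_tf, n_gene = a.shape
    tf0 = np.arange(n_tf)
    gene0 = np.arange(n_tf, n_tf + n_gene)
    return _canonical(*_greedy_labels(b, m, tf0, gene0))


def differential_communities(base: BipartiteNetwork,
                             perturbed: BipartiteNetwork,
                             min_size: int = 30, seed: int = 0,
                             count: str = "both") -> CommunityResult:
    """Differentially regulated communities of ``perturbed`` vs ``base``.

    The base network is partitioned by greedy bipartite-modularity
    maximization; the differential modularity (perturbed edges against the
    base strength-product null) is then maximized by greedy label moves run
    from both the base-partition seed and an all-singleton seed, keeping the
    better optimum (ties keep the base-seeded one).  Communities with node
    count strictly greater than ``min_size`` are retained; ``count`` selects
    whether TFs and genes ("both") or genes only are counted.

    The procedure is deterministic (fixed node order); ``seed`` is accepted
    for interface uniformity.
    """
    del seed
    if base.tfs != perturbed.tfs or base.genes != perturbed.genes:
        raise AlignmentError("base and perturbed networks must share TF/gene spaces")
    if (base.weights < 0).any() or (perturbed.weights < 0).any():
        raise ValueError("community detection expects nonnegative edge weights")
    if perturbed.weights.sum() == 0:
        warnings.warn("perturbed network has no edge weight; empty result",
                      stacklevel=2)
        return CommunityResult(membership={}, diff_modularity={}, sizes={},
                               retained=[], modularity=0.0)

    k = base.weights.sum(axis=1)
    d = base.weights.sum(axis=0)
    m = base.weights.sum()
    m_prime = perturbed.weights.sum()
    b = perturbed.weights - np.outer(k, d) / m

    tf_base, gene_base = detect_base_communities(base)
    singleton = (np.arange(len(base.tfs)),
                 np.arange(len(base.tfs), len(base.tfs) + len(base.genes)))
    q, tf_l, gene_l = -np.inf, None, None
    for seed_labels in ((tf_base, gene_base), singleton):
        tf_c, gene_c = _greedy_labels(b, m_prime, *seed_labels)
        q_c = bipartite_modularity(perturbed.weights, tf_c, gene_c,
                                   null_weights=base.weights, null_total=m)
        if q_c > q:  # strict: ties keep the base-seeded optimum
            q, tf_l, gene_l = q_c, tf_c, gene_c
    tf_l, gene_l = _canonical(tf_l, gene_l)

    membership: dict[tuple[str, str], int] = {}
    contribution: dict[tuple[str, str], float] = {}
    same = tf_l[:, None] == gene_l[None, :]
    for i, tf in enumerate(base.tfs):
        membership[("tf", tf)] = int(tf_l[i])
        contribution[("tf", tf)] = float(0.5 * (b[i] * same[i]).sum() / m_prime)
    for j, gene in enumerate(base.genes):
        membership[("gene", gene)] = int(gene_l[j])
        contribution[("gene", gene)] = float(0.5 * (b[:, j] * same[:, j]).sum()
                                             / m_prime)

    sizes: dict[int, int] = {}
    for (ns, _), comm in membership.items():
        if count == "genes" and ns != "gene":
            continue
        sizes[comm] = sizes.get(comm, 0) + 1
    retained = sorted(c for c, s in sizes.items() if s > min_size)
    return CommunityResult(membership=membership, diff_modularity=contribution,
                           sizes=sizes, retained=retained, modularity=q)
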