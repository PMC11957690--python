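"""Synthetic fixtures with planted structure.

Every generator emulates one of the data shapes the analyses consume:

* :func:`gen_timecourse` -- a two-condition (virus early-region ``ER`` vs
  control ``CTRL``), 10-time-point, triplicate log2-expression time course
  with latent-factor gene blocks.  The ``canonical`` (Wnt) block trends up
  over time only under ``ER``, the ``noncanonical`` block trends down, and
  the ``ne`` (neuroendocrine-marker) block becomes progressively coupled to
  the canonical block under ``ER``.
* :func:`gen_cohort` -- a tumor/normal cohort in which an 8-gene
  neuroendocrine marker panel and configurable fractions of positively /
  negatively loaded genes ride a latent factor elevated in tumors.
* :func:`gen_perturbations` -- LINCS-L1000-like per-drug log2FC profiles
  with exactly one planted signature reverser among decoys.
* :func:`gen_network_priors` -- a binary TF x gene motif prior and a
  symmetric TF x TF interaction matrix.
* :func:`gen_annotation` -- a synthetic term -> gene-set annotation with one
  term planted to overlap a designated query set.
* :func:`planted_differential_pair` -- a base/perturbed bipartite network
  pair in which dense TF-gene blocks are added to a structureless base, the
  ground truth for differential-community detection.

All generators are deterministic in ``(config, seed)``: each one draws from
its own named pseudo-random stream derived from the single integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, SyntheticTruth
from .errors import InconsistentFixtureError, InvalidConfigError

#: The study's time grid, in hours.
TIME_GRID_HOURS: tuple[int, ...] = (0, 4, 8, 12, 16, 20, 24, 32, 40, 48)

#: Default assignment of time points to the five analysis periods.
DEFAULT_PERIODS: dict[int, int] = {0: 1, 4: 1, 8: 2, 12: 2, 16: 3, 20: 3,
                                   24: 4, 32: 4, 40: 5, 48: 5}

#: Default neuroendocrine / MCC marker panel.
DEFAULT_MARKERS: tuple[str, ...] = ("ENO2", "NEFM", "NEFH", "NMB",
                                    "HES6", "SOX2", "ATOH1", "CHGA")

#: The six Wnt perturbagens screened by default.
DEFAULT_PERTURBAGENS: tuple[str, ...] = (
    "pyrvinium-pamoate", "XAV-939", "IWR-1-ENDO",
    "mesalazine", "PRI-724", "indirubin")

_STREAMS = {"timecourse": 1, "cohort": 2, "perturbations": 3,
            "priors": 4, "annotation": 5, "diffnet": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """A named, seed-derived pseudo-random stream (one per generator)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2 ** 31),
                                                         _STREAMS[stream]]))


# ---------------------------------------------------------------------------
# time course
# ---------------------------------------------------------------------------

@dataclass
class TimecourseConfig:
    """Settings for the latent-factor time-course generator.

    Each gene in block *b* is ``baseline + loading * F_b(sample) + eps`` with
    ``eps ~ N(0, noise_sd^2)`` and block factor
    ``F_b(s) = slope_b(condition) * tau_s + factor_sd * z_{b,s}`` where
    ``tau = time/48`` and ``z`` is a per-sample standard normal draw.
    ``coupling`` plants, per analysis period, an exact realized correlation
    between two block factors that ramps linearly with time under ``ER``
    (the virus condition) and stays zero under ``CTRL``.
    """

    blocks: Mapping[str, int] = field(
        default_factory=lambda: {"canonical": 60, "noncanonical": 60, "ne": 50})
    n_noise_genes: int = 130
    replicates: int = 3
    conditions: tuple[str, str] = ("ER", "CTRL")
    time_grid: tuple[int, ...] = TIME_GRID_HOURS
    noise_sd: float = 0.3
    factor_sd: float = 0.6
    loading_range: tuple[float, float] = (0.8, 1.2)
    baseline: float = 8.0
    #: per-block slope of the factor trend vs scaled time, by condition
    trends: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"canonical": {"ER": 2.0, "CTRL": 0.0},
                                 "noncanonical": {"ER": -2.0, "CTRL": 0.0},
                                 "ne": {"ER": 0.0, "CTRL": 0.0}})
    #: (dependent_block, anchor_block) -> maximal planted factor correlation
    coupling: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("ne", "canonical"): 0.9})
    #: condition under which the coupling ramp is active
    coupled_condition: str = "ER"
    periods: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_PERIODS))

    def __post_init__(self) -> None:
        if not self.blocks or any(s <= 0 for s in self.blocks.values()):
            raise InvalidConfigError("block sizes must be positive")
        if self.n_noise_genes < 0:
            raise InvalidConfigError("n_noise_genes must be nonnegative")
        if self.replicates <= 0:
            raise InvalidConfigError("replicates must be positive")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be positive")
        if self.factor_sd <= 0:
            raise InvalidConfigError("factor_sd must be positive")
        for pair, w in self.coupling.items():
            if not 0.0 <= w <= 1.0:
                raise InvalidConfigError(f"coupling {pair} outside [0, 1]")
        # coupling entries for blocks absent from this config are ignored
        self.coupling = {pair: w for pair, w in self.coupling.items()
                         if pair[0] in self.blocks and pair[1] in self.blocks}

    @property
    def n_genes(self) -> int:
        return sum(self.blocks.values()) + self.n_noise_genes


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return v - v.mean()
    return (v - v.mean()) / sd


def gen_timecourse(config: TimecourseConfig | None = None,
                   seed: int = 0) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate the two-condition triplicate time course.

    Returns the expression matrix (genes x samples, log2 scale) and the
    planted truth: block membership, per-condition trend signs, and the
    coupling schedule is implied by the config.
    """
    config = config or TimecourseConfig()
    rng = _rng(seed, "timecourse")

    sample_ids, cond_col, time_col, rep_col = [], [], [], []
    for cond in config.conditions:
        for t in config.time_grid:
            for rep in range(1, config.replicates + 1):
                sample_ids.append(f"{cond}_t{t:02d}_r{rep}")
                cond_col.append(cond)
                time_col.append(t)
                rep_col.append(rep)
    meta = pd.DataFrame({"condition": cond_col, "time_hours": time_col,
                         "replicate": rep_col}, index=pd.Index(sample_ids, name="sample"))
    tau = np.asarray(time_col, dtype=float) / max(config.time_grid)

    # per-sample standard-normal factor draws, one stream per block
    z = {b: rng.standard_normal(len(sample_ids)) for b in config.blocks}

    # Within each (condition, period) group, make every block factor exactly
    # standard (mean 0, var 1) and exactly orthogonal to the within-period
    # time contrast.  Six-sample groups are too small for raw draws to
    # concentrate, so the planted per-period variances and correlations are
    # imposed on the realized draws, not just in expectation.
    time_arr = np.asarray(time_col, dtype=float)
    for b in config.blocks:
        for cond in config.conditions:
            cond_mask = np.asarray(cond_col) == cond
            for period in sorted(set(config.periods.values())):
                times = [t for t, p in config.periods.items() if p == period]
                idx = np.where(cond_mask & np.isin(time_col, times))[0]
                if len(idx) >= 3:
                    contrast = time_arr[idx] - time_arr[idx].mean()
                    zi = z[b][idx]
                    if contrast @ contrast > 0:
                        zi = zi - (zi @ contrast) / (contrast @ contrast) * contrast
                    z[b][idx] = _standardize(zi)

    # plant exact within-period factor correlations for coupled block pairs
    for (dep, anchor), w_max in config.coupling.items():
        for cond in config.conditions:
            cond_mask = np.asarray(cond_col) == cond
            for period in sorted(set(config.periods.values())):
                times = [t for t, p in config.periods.items() if p == period]
                idx = np.where(cond_mask & np.isin(time_col, times))[0]
                if len(idx) < 3:
                    continue
                za = _standardize(z[anchor][idx])
                zd = _standardize(z[dep][idx])
                # Gram-Schmidt: make the dependent draw exactly orthogonal
                # to the anchor within the period, then remix at weight w.
                zd = _standardize(zd - (zd @ za) / max(za @ za, 1e-12) * za)
                if cond == config.coupled_condition:
                    # fast-onset, saturating coupling: rewiring starts early
                    # after induction and levels off by the end of the course
                    t_mid = float(np.mean([t for t in times])) / max(config.time_grid)
                    w = w_max * np.sqrt(t_mid)
                else:
                    w = 0.0
                z[dep][idx] = w * za + np.sqrt(max(1.0 - w * w, 0.0)) * zd

    rows, gene_ids = [], []
    labels: dict[str, int] = {}
    trends: dict[str, dict[str, int]] = {}
    cond_arr = np.asarray(cond_col)
    for block_id, (block, size) in enumerate(config.blocks.items(), start=1):
        slope = {c: float(config.trends.get(block, {}).get(c, 0.0))
                 for c in config.conditions}
        trend = np.zeros(len(sample_ids))
        for c in config.conditions:
            trend[cond_arr == c] = slope[c] * tau[cond_arr == c]
        factor = trend + config.factor_sd * z[block]
        loadings = rng.uniform(*config.loading_range, size=size)
        noise = rng.normal(0.0, config.noise_sd, size=(size, len(sample_ids)))
        for g in range(size):
            gene = f"{block.upper()}_{g + 1:04d}"
            gene_ids.append(gene)
            labels[gene] = block_id
            trends[gene] = {c: int(np.sign(slope[c])) for c in config.conditions}
            rows.append(config.baseline + loadings[g] * factor + noise[g])
    for g in range(config.n_noise_genes):
        gene = f"NOISE_{g + 1:04d}"
        gene_ids.append(gene)
        labels[gene] = 0
        trends[gene] = {c: 0 for c in config.conditions}
        rows.append(config.baseline
                    + rng.normal(0.0, config.noise_sd, size=len(sample_ids)))

    values = pd.DataFrame(np.vstack(rows), index=pd.Index(gene_ids, name="gene"),
                          columns=meta.index)
    expr = ExpressionMatrix(values, meta)
    truth = SyntheticTruth(planted_module_labels=labels, planted_trends=trends)
    truth.check_consistent(expr.genes)
    return expr, truth


# ---------------------------------------------------------------------------
# tumor/normal cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Settings for the marker-anchored tumor/normal cohort generator.

    A latent neuroendocrine factor ``h ~ N(shift * 1[tumor], 1)`` drives the
    marker panel (loading ``marker_loading``) and the planted fractions of
    positively / negatively loaded genes (loading ``+-loading``); remaining
    genes are independent noise.
    """

    n_genes: int = 5000          # non-marker genes (L1000-like universe)
    n_tumor: int = 60
    n_normal: int = 40
    markers: tuple[str, ...] = DEFAULT_MARKERS
    frac_positive: float = 0.12
    frac_negative: float = 0.12
    loading: float = 0.8
    marker_loading: float = 1.0
    marker_noise_sd: float = 0.3
    noise_sd: float = 1.0
    tumor_shift: float = 2.0
    baseline: float = 8.0
    signature_size: int = 500    # intended n_per_tail downstream

    def __post_init__(self) -> None:
        if self.n_tumor < 10 or self.n_normal < 10:
            raise InvalidConfigError("need at least 10 tumor and 10 normal samples")
        if not self.markers:
            raise InvalidConfigError("marker panel must be nonempty")
        if self.n_genes < 2 * self.signature_size:
            raise InvalidConfigError(
                f"n_genes={self.n_genes} too small for a {self.signature_size}-per-tail "
                "signature")
        if not 0 <= self.frac_positive <= 1 or not 0 <= self.frac_negative <= 1 \
                or self.frac_positive + self.frac_negative > 1:
            raise InvalidConfigError("loading fractions must be in [0,1] and sum <= 1")
        if self.noise_sd <= 0 or self.marker_noise_sd <= 0:
            raise InvalidConfigError("noise sds must be positive")


def gen_cohort(config: CohortConfig | None = None,
               seed: int = 0) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a tumor/normal cohort anchored on a marker panel."""
    config = config or CohortConfig()
    rng = _rng(seed, "cohort")

    n = config.n_tumor + config.n_normal
    sample_ids = [f"TUMOR_{i + 1:03d}" for i in range(config.n_tumor)] + \
                 [f"NORMAL_{i + 1:03d}" for i in range(config.n_normal)]
    condition = ["TUMOR"] * config.n_tumor + ["NORMAL"] * config.n_normal
    meta = pd.DataFrame({"condition": condition,
                         "replicate": list(range(1, config.n_tumor + 1))
                         + list(range(1, config.n_normal + 1))},
                        index=pd.Index(sample_ids, name="sample"))

    h = rng.standard_normal(n)
    h[np.asarray(condition) == "TUMOR"] += config.tumor_shift

    n_pos = int(round(config.frac_positive * config.n_genes))
    n_neg = int(round(config.frac_negative * config.n_genes))
    assoc: dict[str, float] = {}
    gene_ids, rows = [], []
    for m in config.markers:
        gene_ids.append(m)
        assoc[m] = config.marker_loading
        rows.append(config.baseline + config.marker_loading * h
                    + rng.normal(0.0, config.marker_noise_sd, size=n))
    for g in range(config.n_genes):
        gene = f"G{g + 1:05d}"
        gene_ids.append(gene)
        if g < n_pos:
            lam = config.loading
        elif g < n_pos + n_neg:
            lam = -config.loading
        else:
            lam = 0.0
        assoc[gene] = lam
        rows.append(config.baseline + lam * h
                    + rng.normal(0.0, config.noise_sd, size=n))

    values = pd.DataFrame(np.vstack(rows), index=pd.Index(gene_ids, name="gene"),
                          columns=meta.index)
    expr = ExpressionMatrix(values, meta)
    truth = SyntheticTruth(planted_marker_assoc=assoc)
    truth.check_consistent(expr.genes)
    return expr, truth


# ---------------------------------------------------------------------------
# perturbagen profiles
# ---------------------------------------------------------------------------

@dataclass
class PerturbationConfig:
    """Settings for the per-drug log2FC profile generator."""

    perturbagens: tuple[str, ...] = DEFAULT_PERTURBAGENS
    reverser: str = "pyrvinium-pamoate"
    reversal_fraction: float = 0.6
    n_perturbed: int = 800
    effect_mean: float = 2.0
    effect_sd: float = 0.5
    background_sd: float = 0.2

    def __post_init__(self) -> None:
        if len(self.perturbagens) < 2:
            raise InvalidConfigError("need at least two perturbagens")
        if len(set(self.perturbagens)) != len(self.perturbagens):
            raise InvalidConfigError("duplicate perturbagen names")
        if self.reverser not in self.perturbagens:
            raise InvalidConfigError("reverser must be one of the perturbagens")
        if not 0.0 <= self.reversal_fraction <= 1.0:
            raise InvalidConfigError("reversal_fraction outside [0, 1]")
        if self.n_perturbed <= 0:
            raise InvalidConfigError("n_perturbed must be positive")
        if self.background_sd <= 0 or self.effect_sd <= 0:
            raise InvalidConfigError("effect/background sds must be positive")


def gen_perturbations(signature, config: PerturbationConfig | None = None,
                      seed: int = 0):
    """Simulate per-drug log2FC profiles with one planted reverser.

    ``signature`` is a :class:`~mccrewire.signature.GeneSignature`; the gene
    universe is its score table.  The planted reverser opposes the signature
    direction for ``reversal_fraction`` of the signature genes; decoys
    perturb genes drawn uniformly from the universe with random signs.

    Returns ``(profiles, truth)`` where ``profiles`` is a dict mapping
    perturbagen name to :class:`~mccrewire.reversal.PerturbationProfile`.
    """
    from .reversal import PerturbationProfile  # local import, avoids a cycle

    config = config or PerturbationConfig()
    rng = _rng(seed, "perturbations")

    universe = list(signature.scores.index)
    sig_genes = list(signature.up) + list(signature.down)
    if not sig_genes:
        raise InvalidConfigError("signature is empty")
    missing = set(sig_genes) - set(universe)
    if missing:
        raise InconsistentFixtureError(
            f"signature genes absent from universe: {sorted(missing)[:5]}")
    direction = pd.Series(
        {g: 1.0 for g in signature.up} | {g: -1.0 for g in signature.down})

    uni_index = pd.Index(universe)
    profiles = {}
    for drug in config.perturbagens:
        lfc = pd.Series(rng.normal(0.0, config.background_sd, size=len(universe)),
                        index=uni_index, name=drug)
        if drug == config.reverser:
            n_rev = int(round(config.reversal_fraction * len(sig_genes)))
            chosen = rng.choice(sig_genes, size=n_rev, replace=False)
            effects = np.abs(rng.normal(config.effect_mean, config.effect_sd,
                                        size=n_rev))
            lfc[chosen] = -direction[chosen].to_numpy() * effects
            n_rest = max(config.n_perturbed - n_rev, 0)
            pool = uni_index.difference(chosen)
            rest = rng.choice(pool, size=min(n_rest, len(pool)), replace=False)
            lfc[rest] = rng.choice([-1.0, 1.0], size=len(rest)) * np.abs(
                rng.normal(config.effect_mean, config.effect_sd, size=len(rest)))
        else:
            hit = rng.choice(uni_index, size=min(config.n_perturbed, len(universe)),
                             replace=False)
            lfc[hit] = rng.choice([-1.0, 1.0], size=len(hit)) * np.abs(
                rng.normal(config.effect_mean, config.effect_sd, size=len(hit)))
        profiles[drug] = PerturbationProfile(perturbagen=drug, log2fc=lfc)

    truth = SyntheticTruth(planted_reverser=config.reverser)
    truth.check_consistent([], perturbagens=list(profiles))
    return profiles, truth


# ---------------------------------------------------------------------------
# network priors
# ---------------------------------------------------------------------------

@dataclass
class PriorConfig:
    """Settings for the motif-prior / protein-interaction generator."""

    n_tfs: int = 20
    n_genes: int = 200
    motif_density: float = 0.2
    ppi_density: float = 0.3
    gene_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_tfs < 2:
            raise InvalidConfigError("need at least two TFs")
        if self.n_genes < self.n_tfs:
            raise InvalidConfigError("n_genes must be >= n_tfs")
        for key in ("motif_density", "ppi_density"):
            v = getattr(self, key)
            if not 0.0 < v <= 1.0:
                raise InvalidConfigError(f"{key}={v} outside (0, 1]")
        if self.gene_names is not None and len(self.gene_names) != self.n_genes:
            raise InvalidConfigError("gene_names length must equal n_genes")


def gen_network_priors(config: PriorConfig | None = None,
                       seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a binary TF x gene motif prior and a symmetric TF x TF PPI.

    TFs are the first ``n_tfs`` genes of the gene universe, so the TF set is
    a subset of the expression genes by construction.
    """
    config = config or PriorConfig()
    rng = _rng(seed, "priors")
    genes = list(config.gene_names) if config.gene_names is not None else \
        [f"G{i + 1:05d}" for i in range(config.n_genes)]
    tfs = genes[:config.n_tfs]

    motif = (rng.random((config.n_tfs, config.n_genes))
             < config.motif_density).astype(float)
    motif = pd.DataFrame(motif, index=pd.Index(tfs, name="tf"),
                         columns=pd.Index(genes, name="gene"))

    ppi = np.triu(rng.random((config.n_tfs, config.n_tfs))
                  * (rng.random((config.n_tfs, config.n_tfs))
                     < config.ppi_density), k=1)
    ppi = ppi + ppi.T
    np.fill_diagonal(ppi, 1.0)
    ppi = pd.DataFrame(ppi, index=pd.Index(tfs, name="tf"),
                       columns=pd.Index(tfs, name="tf"))
    return motif, ppi


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationConfig:
    """Settings for the synthetic term -> gene-set annotation generator."""

    n_terms: int = 50
    size_range: tuple[int, int] = (10, 100)
    query_set: tuple[str, ...] | None = None
    planted_overlap: float = 1.0
    planted_term: str = "TERM_PLANTED"

    def __post_init__(self) -> None:
        if self.n_terms <= 0:
            raise InvalidConfigError("n_terms must be positive")
        lo, hi = self.size_range
        if lo <= 0 or hi < lo:
            raise InvalidConfigError("invalid term size range")
        if not 0.0 <= self.planted_overlap <= 1.0:
            raise InvalidConfigError("planted_overlap outside [0, 1]")


def gen_annotation(universe: Sequence[str],
                   config: AnnotationConfig | None = None,
                   seed: int = 0) -> tuple[dict[str, list[str]], SyntheticTruth]:
    """Simulate a term -> gene-set annotation over ``universe``.

    One term (``planted_term``) is constructed to cover ``planted_overlap``
    of ``query_set`` (if given), the ground truth for enrichment tests.
    """
    config = config or AnnotationConfig()
    universe = list(universe)
    if not universe:
        raise InvalidConfigError("universe must be nonempty")
    lo, hi = config.size_range
    if hi > len(universe):
        raise InvalidConfigError(
            f"term size {hi} exceeds universe size {len(universe)}")
    rng = _rng(seed, "annotation")

    annotation: dict[str, list[str]] = {}
    for t in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        annotation[f"TERM_{t + 1:04d}"] = sorted(
            rng.choice(universe, size=size, replace=False))

    truth = SyntheticTruth()
    if config.query_set is not None:
        query = list(config.query_set)
        missing = set(query) - set(universe)
        if missing:
            raise InconsistentFixtureError(
                f"query genes absent from universe: {sorted(missing)[:5]}")
        n_in = int(round(config.planted_overlap * len(query)))
        inside = list(rng.choice(query, size=n_in, replace=False)) \
            if n_in < len(query) else list(query)
        pool = [g for g in universe if g not in set(query)]
        n_fill = max(min(hi, len(query)) - len(inside), 0)
        fill = list(rng.choice(pool, size=min(n_fill, len(pool)), replace=False))
        annotation[config.planted_term] = sorted(inside + fill)
        truth.planted_enriched_terms = [config.planted_term]
    truth.check_consistent([], terms=list(annotation))
    return annotation, truth


# ---------------------------------------------------------------------------
# differential-network fixture
# ---------------------------------------------------------------------------

@dataclass
class DiffNetConfig:
    """Settings for the planted base/perturbed bipartite network pair.

    The base network is complete bipartite with constant weight
    ``base_weight`` (hence no community structure: every edge matches its
    strength-product null exactly).  The perturbed copy adds ``delta`` to
    disjoint dense TF x gene blocks; ``blocks`` lists (n_tfs, n_genes) per
    planted block.
    """

    n_tfs: int = 40
    n_genes: int = 260
    base_weight: float = 0.5
    delta: float = 2.0
    blocks: tuple[tuple[int, int], ...] = ((2, 8), (8, 42), (30, 170))

    def __post_init__(self) -> None:
        if self.base_weight <= 0 or self.delta <= 0:
            raise InvalidConfigError("base_weight and delta must be positive")
        if sum(b[0] for b in self.blocks) > self.n_tfs:
            raise InvalidConfigError("planted blocks need more TFs than available")
        if sum(b[1] for b in self.blocks) > self.n_genes:
            raise InvalidConfigError("planted blocks need more genes than available")


def planted_differential_pair(config: DiffNetConfig | None = None, seed: int = 0):
    """Build a base/perturbed network pair with planted rewired blocks.

    Returns ``(base, perturbed, truth)`` where the networks are
    :class:`~mccrewire.regnet.BipartiteNetwork` objects and ``truth`` maps
    node ``(namespace, name)`` -> planted block id (0 = background) via
    ``planted_module_labels`` keyed by ``"tf::name"`` / ``"gene::name"``.
    """
    from .regnet import BipartiteNetwork  # local import, avoids a cycle

    config = config or DiffNetConfig()
    del seed  # the fixture is fully deterministic; kept for interface parity
    tfs = [f"TF{i + 1:03d}" for i in range(config.n_tfs)]
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]

    base_w = np.full((config.n_tfs, config.n_genes), config.base_weight)
    pert_w = base_w.copy()
    labels: dict[str, int] = {}
    ti, gi = 0, 0
    for block_id, (bt, bg) in enumerate(config.blocks, start=1):
        pert_w[ti:ti + bt, gi:gi + bg] += config.delta
        for t in tfs[ti:ti + bt]:
            labels[f"tf::{t}"] = block_id
        for g in genes[gi:gi + bg]:
            labels[f"gene::{g}"] = block_id
        ti += bt
        gi += bg
    for t in tfs[ti:]:
        labels[f"tf::{t}"] = 0
    for g in genes[gi:]:
        labels[f"gene::{g}"] = 0

    base = BipartiteNetwork(tfs=tfs, genes=genes, weights=base_w,
                            tag={"role": "base"})
    pert = BipartiteNetwork(tfs=tfs, genes=genes, weights=pert_w,
                            tag={"role": "perturbed"})
    truth = SyntheticTruth(planted_module_labels=labels)
    return base, pert, truth
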