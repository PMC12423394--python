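"""Correlation diagnostics: SASP concordance, co-senescence networks,
and concordance between deconvolved expression matrices.

All correlations are Spearman's rank correlation with average-tie ranks.
P-values use the t-approximation, except for n <= 9 where the exact
permutation distribution of the rank statistic is enumerated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    GroupSizeError,
    InsufficientOverlapError,
    UndefinedCorrelationError,
    ValidationError,
)
from .io import ExpressionMatrix, GeneList
from .scoring import ScoreVector

__all__ = [
    "CorrelationResult",
    "SaspConcordance",
    "CoSenNetwork",
    "spearman",
    "sasp_concordance",
    "cosenescence_network",
    "matrix_concordance",
]


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str = "spearman"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValidationError(f"|rho| > 1: {self.rho}")
        self.rho = float(np.clip(self.rho, -1.0, 1.0))


def spearman(x, y) -> CorrelationResult:
    """Spearman correlation with exact permutation p for n <= 9.

    Pairs with a missing value in either vector are removed first.  Zero
    variance in either ranked vector raises
    :class:`UndefinedCorrelationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman needs two equal-length 1-d vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise GroupSizeError(f"spearman needs >= 3 complete pairs, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError("zero variance in a ranked vector")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = _t_approx_p(rho, n)
    return CorrelationResult(rho, float(p), n)


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p over all n! pairings of the given ranks."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # n! x n
    rx_c = rx - rx.mean()
    denom = np.sqrt((rx_c**2).sum() * ((ry_perm - ry_perm.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
    rhos = (ry_perm - ry_perm.mean(axis=1, keepdims=True)) @ rx_c / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


@dataclass
class SaspConcordance:
    """Per-SASP-gene correlation with ICSS and the positive fraction."""

    per_gene: dict[str, CorrelationResult]
    positive_fraction: float
    n_expressed: int


def sasp_concordance(
    icss: ScoreVector,
    matrix: ExpressionMatrix,
    sasp: GeneList,
    expressed_min_fraction: float = 0.2,
    significant_only: bool = False,
    alpha: float = 0.05,
) -> SaspConcordance:
    """Correlate ICSS with SASP gene expression across units.

    A SASP gene is "expressed" when nonzero in at least
    ``expressed_min_fraction`` of units.  ``positive_fraction`` is the share
    of expressed SASP genes with rho > 0 (optionally restricted to p <=
    ``alpha`` when ``significant_only``).  Genes whose correlation is
    undefined (constant ranks) are excluded from the denominator with a
    warning.
    """
    unit_pos = {u: i for i, u in enumerate(matrix.unit_ids)}
    shared = [u for u in icss.unit_ids if u in unit_pos]
    if len(shared) < 3:
        raise GroupSizeError("fewer than 3 units shared between ICSS and matrix")
    cols = [unit_pos[u] for u in shared]
    score = icss.values[[icss.unit_ids.index(u) for u in shared]]
    present = [g for g in matrix.gene_ids if g in sasp.genes]
    if not present:
        raise InsufficientOverlapError("no SASP gene present in matrix")
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    per_gene: dict[str, CorrelationResult] = {}
    n_pos = 0
    n_expressed = 0
    for g in present:
        expr = matrix.values[gene_pos[g]][cols]
        if np.mean(expr != 0) < expressed_min_fraction:
            continue
        try:
            res = spearman(expr, score)
        except UndefinedCorrelationError:
            warnings.warn(f"SASP gene {g}: correlation undefined (constant ranks); excluded",
                          stacklevel=2)
            continue
        n_expressed += 1
        per_gene[g] = res
        if res.rho > 0 and (not significant_only or res.p_value <= alpha):
            n_pos += 1
    if n_expressed == 0:
        raise InsufficientOverlapError("no expressed SASP gene; positive fraction undefined")
    return SaspConcordance(per_gene, n_pos / n_expressed, n_expressed)


@dataclass
class CoSenEdge:
    cell_a: str
    cell_b: str
    weight: float  # |rho|
    rho: float
    p_value: float
    q_value: float | None = None
    context: str | None = None


@dataclass
class CoSenNetwork:
    """Undirected cell-type co-senescence network.

    Edge weight is the absolute Spearman correlation of the two cell types'
    ICSS across shared samples; node size is the cumulative weight of
    incident edges (0 for isolated nodes).
    """

    nodes: dict[str, float]
    edges: list[CoSenEdge] = field(default_factory=list)

    def node_size(self, cell_type: str) -> float:
        return self.nodes[cell_type]

    def recompute_node_sizes(self) -> None:
        sizes = {ct: 0.0 for ct in self.nodes}
        for e in self.edges:
            sizes[e.cell_a] += e.weight
            sizes[e.cell_b] += e.weight
        self.nodes = sizes

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for ct, size in self.nodes.items():
            g.add_node(ct, size=size)
        for e in self.edges:
            g.add_edge(e.cell_a, e.cell_b, weight=e.weight, rho=e.rho,
                       p=e.p_value, q=e.q_value, context=e.context)
        return g


def cosenescence_network(
    icss_by_celltype: dict[str, ScoreVector],
    p_threshold: float = 0.05,
    bh: bool = False,
    context: str | None = None,
) -> CoSenNetwork:
    """Build the co-senescence network over cell types.

    One candidate edge per cell-type pair with >= 3 shared samples; pairs
    with fewer are skipped with a warning.  Edges are retained when the
    Spearman p (or BH-adjusted q when ``bh``) is <= ``p_threshold``.
    """
    cts = list(icss_by_celltype)
    if len(cts) < 2:
        raise ValidationError("network needs >= 2 cell types")
    candidates = []
    for a, b in itertools.combinations(cts, 2):
        sa, sb = icss_by_celltype[a], icss_by_celltype[b]
        pos_b = {u: i for i, u in enumerate(sb.unit_ids)}
        shared = [(i, pos_b[u]) for i, u in enumerate(sa.unit_ids) if u in pos_b]
        if len(shared) < 3:
            warnings.warn(f"pair ({a}, {b}): fewer than 3 shared samples; skipped", stacklevel=2)
            continue
        ia, ib = zip(*shared)
        try:
            res = spearman(sa.values[list(ia)], sb.values[list(ib)])
        except UndefinedCorrelationError:
            warnings.warn(f"pair ({a}, {b}): constant ICSS; skipped", stacklevel=2)
            continue
        candidates.append(CoSenEdge(a, b, abs(res.rho), res.rho, res.p_value, context=context))
    if bh and candidates:
        from .diffexp import bh_adjust

        qs = bh_adjust([e.p_value for e in candidates])
        for e, q in zip(candidates, qs):
            e.q_value = float(q)
        kept = [e for e in candidates if e.q_value <= p_threshold]
    else:
        kept = [e for e in candidates if e.p_value <= p_threshold]
    net = CoSenNetwork(nodes={ct: 0.0 for ct in cts}, edges=kept)
    net.recompute_node_sizes()
    return net


def matrix_concordance(a: ExpressionMatrix, b: ExpressionMatrix) -> CorrelationResult:
    """Spearman concordance of per-gene mean expression between two matrices.

    Matrices are reduced to shared gene symbols (>= 3 required); each is
    summarised by its gene-wise mean across units, and the two mean vectors
    are rank-correlated.
    """
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if len(shared) < 3:
        raise InsufficientOverlapError(f"only {len(shared)} shared genes; need >= 3")
    mean_a = a.subset_genes(shared).values.mean(axis=1)
    mean_b = b.subset_genes(shared).values.mean(axis=1)
    return spearman(mean_a, mean_b)
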