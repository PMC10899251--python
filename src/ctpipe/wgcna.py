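"""Signed weighted gene co-expression networks and consensus modules.

A signed adjacency a_ij = ((1 + cor(x_i, x_j)) / 2)^beta maps strongly
anti-correlated genes near 0 and strongly co-expressed genes near 1; the
topological overlap matrix (TOM) then measures shared network
neighborhoods.  Consensus modules across several expression matrices come
from average-linkage hierarchical clustering of 1 - consensus TOM, where
the consensus TOM is the element-wise minimum of quantile-scaled inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "CoexpressionNetwork",
    "ConsensusModuleSet",
    "pick_soft_threshold",
    "signed_adjacency",
    "signed_tom",
    "consensus_modules",
    "module_eigengene",
]


@dataclass
class CoexpressionNetwork:
    genes: list
    adjacency: np.ndarray
    beta: float
    tom: np.ndarray

    def __post_init__(self):
        n = len(self.genes)
        if self.adjacency.shape != (n, n) or self.tom.shape != (n, n):
            raise ValueError("matrix shapes must match the gene list")


@dataclass
class ConsensusModuleSet:
    """Gene-to-module assignment (module 0 = unassigned) plus eigengenes."""

    genes: list
    labels: np.ndarray  # int per gene, 0 = unassigned
    module_sizes: dict = field(default_factory=dict)
    eigengenes: dict = field(default_factory=dict)  # matrix name -> samples x modules
    variance_explained: dict = field(default_factory=dict)

    def module_genes(self, module: int) -> list:
        return [g for g, m in zip(self.genes, self.labels) if m == module]

    @property
    def modules(self) -> list:
        return sorted(m for m in set(self.labels.tolist()) if m != 0)


def _validate_expr(expr: pd.DataFrame):
    x = expr.to_numpy(float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [expr.columns[i] for i in np.flatnonzero(sd == 0)][:5]
        raise ValueError(f"constant gene expression: {bad}")
    return x


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16),
    r2_target: float = 0.8,
    n_bins: int = 10,
    default_power: float = 12.0,
):
    """Smallest power giving approximate scale-free topology (R^2 >= target).

    For each candidate beta the connectivity distribution k_i = sum_j a_ij
    is binned and log10 p(k) is regressed on log10 k; the fit must have a
    negative slope.  If no candidate reaches the target the signed-network
    default of 12 is returned.  Returns ``(beta, fit_table)``.
    """
    x = _validate_expr(expr)
    candidate_powers = list(candidate_powers)
    cor = np.corrcoef(x.T)
    rows = []
    chosen = None
    for beta in candidate_powers:
        a = ((1 + cor) / 2.0) ** beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        pos = k[k > 0]
        if len(pos) < n_bins or np.ptp(pos) == 0:
            r2, slope = np.nan, np.nan
        else:
            hist, edges = np.histogram(pos, bins=n_bins)
            centers = 0.5 * (edges[:-1] + edges[1:])
            ok = hist > 0
            lk, lp = np.log10(centers[ok]), np.log10(hist[ok] / hist.sum())
            if ok.sum() < 3 or np.ptp(lk) == 0:
                r2, slope = np.nan, np.nan
            else:
                slope, icpt = np.polyfit(lk, lp, 1)
                pred = slope * lk + icpt
                ss_res = ((lp - pred) ** 2).sum()
                ss_tot = ((lp - lp.mean()) ** 2).sum()
                r2 = 1 - ss_res / ss_tot if ss_tot > 0 else np.nan
        rows.append(dict(power=beta, r2=r2, slope=slope))
        if chosen is None and np.isfinite(r2) and r2 >= r2_target and slope < 0:
            chosen = beta
    if len(candidate_powers) == 1:
        chosen = candidate_powers[0]
    if chosen is None:
        chosen = default_power
    return chosen, pd.DataFrame(rows)


def signed_adjacency(expr: pd.DataFrame, beta: float) -> np.ndarray:
    """a_ij = ((1 + cor(x_i, x_j)) / 2)^beta with unit diagonal."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    x = _validate_expr(expr)
    cor = np.corrcoef(x.T)
    if np.isnan(cor).any():
        bad = [expr.columns[i] for i in np.flatnonzero(np.isnan(cor).any(axis=0))][:5]
        raise ValueError(f"NaN correlations for genes: {bad}")
    return ((1 + cor) / 2.0) ** beta


def signed_tom(expr: pd.DataFrame, beta: float) -> CoexpressionNetwork:
    """Signed network with topological overlap.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    k_i the connectivity excluding the diagonal; TOM_ii = 1.
    """
    a = signed_adjacency(expr, beta)
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    num = a0 @ a0 + a0
    den = np.minimum.outer(k, k) + 1 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / den
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return CoexpressionNetwork(genes=list(expr.columns), adjacency=a, beta=beta, tom=tom)


def _scale_toms(toms, quantile: float = 0.95):
    """Quantile-match every TOM's off-diagonal distribution to the first."""
    ref = None
    out = []
    for tom in toms:
        off = tom[np.triu_indices(len(tom), k=1)]
        q = np.quantile(off, quantile)
        if ref is None:
            ref = q
            out.append(tom)
        else:
            scaled = tom * (ref / q) if q > 0 else tom
            out.append(np.clip(scaled, 0.0, 1.0))
    return out


def consensus_modules(
    networks,
    min_module_size: int = 50,
    cut_height: float = 0.99,
    scale_quantile: float = 0.95,
) -> ConsensusModuleSet:
    """Consensus modules across several co-expression networks.

    The consensus TOM is the element-wise minimum of the quantile-scaled
    TOMs; 1 - consensus TOM is clustered by average linkage and the tree is
    cut at ``cut_height`` times the maximum merge height (the fixed-height
    variant of dynamic tree cut).  Clusters smaller than
    ``min_module_size`` become unassigned (module 0); surviving modules are
    relabeled 1, 2, ... by decreasing size, with ties broken by the
    smallest member gene index for order stability.
    """
    networks = list(networks)
    genes = networks[0].genes
    for net in networks[1:]:
        if net.genes != genes:
            raise ValueError("gene lists differ across networks")
    toms = _scale_toms([net.tom for net in networks], quantile=scale_quantile)
    cons = np.minimum.reduce(toms)
    dissim = 1.0 - cons
    np.fill_diagonal(dissim, 0.0)
    dissim = 0.5 * (dissim + dissim.T)
    z = linkage(squareform(dissim, checks=False), method="average")
    height = cut_height * z[:, 2].max()
    raw = fcluster(z, t=height, criterion="distance")

    labels = np.zeros(len(genes), dtype=int)
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_module_size]
    kept.sort(key=lambda c: (-sizes[c], int(np.flatnonzero(raw == c)[0])))
    for new, c in enumerate(kept, start=1):
        labels[raw == c] = new
    return ConsensusModuleSet(
        genes=list(genes),
        labels=labels,
        module_sizes={m: int((labels == m).sum()) for m in range(1, len(kept) + 1)},
    )


def module_eigengene(expr: pd.DataFrame, module_genes):
    """First principal component of the standardized module submatrix.

    Returns ``(me, variance_explained)`` where ``me`` is a unit-norm
    samples-length vector sign-aligned so its average correlation with the
    member genes is positive.
    """
    module_genes = list(module_genes)
    if len(module_genes) < 2:
        raise ValueError("module must have at least 2 genes")
    x = expr[module_genes].to_numpy(float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant gene in module")
    xs = (x - x.mean(axis=0)) / sd
    u, s, _vt = np.linalg.svd(xs, full_matrices=False)
    if not s[0] > 0:
        raise ValueError("rank-0 module submatrix")
    me = u[:, 0]
    cors = np.array(
        [np.corrcoef(me, xs[:, j])[0, 1] for j in range(xs.shape[1])]
    )
    if cors.mean() < 0:
        me = -me
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return me, var_explained
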