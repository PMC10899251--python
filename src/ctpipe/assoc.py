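"""Transcription-neuroimaging association.

Tissue samples are linked to the connectome by averaging the MA map inside
spheres (default radii 4, 6, 8 mm) around each sample's MNI coordinate.
Module eigengenes are correlated with these sphere profiles; a module is
accepted only when its correlation survives BH-FDR at every radius with a
consistent sign.  Genes of accepted modules form signed (positive /
negative) gene sets which are intersected across parcellations and against
a disease gene list; highly intercorrelated members are flagged as key
genes, and a hypergeometric over-representation test scores annotation
terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bwas import MAMap

__all__ = [
    "GeneSetLedger",
    "sample_sphere_ma",
    "sphere_ma_profiles",
    "module_ma_association",
    "derive_signed_gene_sets",
    "intersect_disease_genes",
    "condition_overlap",
    "key_genes",
    "overrepresentation_test",
]

DEFAULT_RADII = (4.0, 6.0, 8.0)


def _voxel_mni(ma: MAMap) -> np.ndarray:
    homog = np.c_[ma.voxel_grid, np.ones(len(ma.voxel_grid))]
    return (homog @ ma.affine.T)[:, :3]


def sample_sphere_ma(ma: MAMap, coordinates: pd.DataFrame, radius_mm: float) -> pd.Series:
    """Mean MA over voxels within ``radius_mm`` of each sample coordinate.

    ``coordinates`` must carry x, y, z columns in MNI mm.  Samples whose
    sphere contains no voxel center get NaN.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    vox = _voxel_mni(ma)
    pts = coordinates[["x", "y", "z"]].to_numpy(float)
    d2 = ((pts[:, None, :] - vox[None, :, :]) ** 2).sum(axis=2)
    inside = d2 <= radius_mm**2
    out = np.full(len(pts), np.nan)
    any_in = inside.any(axis=1)
    vals = ma.values.astype(float)
    for i in np.flatnonzero(any_in):
        out[i] = vals[inside[i]].mean()
    return pd.Series(out, index=coordinates.index, name=f"ma_r{radius_mm:g}")


def sphere_ma_profiles(
    ma: MAMap, coordinates: pd.DataFrame, radii=DEFAULT_RADII
) -> pd.DataFrame:
    """Sphere-mean MA at every radius; one column per radius."""
    return pd.concat(
        [sample_sphere_ma(ma, coordinates, r) for r in radii], axis=1
    )


def module_ma_association(
    mes: pd.DataFrame,
    profiles: pd.DataFrame,
    q_threshold: float = 0.05,
    parcellation: str | None = None,
) -> pd.DataFrame:
    """Pearson ME-MA correlation per module and radius, BH across modules.

    ``mes`` is samples x modules, ``profiles`` samples x radii (same index).
    Samples with a missing sphere value are dropped pairwise per radius.
    BH-FDR runs across modules within each radius.  A module passes when
    q < ``q_threshold`` at every radius with one consistent correlation
    sign.
    """
    if not mes.index.equals(profiles.index):
        raise ValueError("ME rows and sphere profiles must share sample index")
    rows = []
    for radius_col in profiles.columns:
        prof = profiles[radius_col]
        for module in mes.columns:
            ok = prof.notna() & mes[module].notna()
            if ok.sum() < 4:
                raise ValueError("fewer than 4 complete samples")
            r, p = stats.pearsonr(mes.loc[ok, module], prof[ok])
            rows.append(dict(module=module, radius=radius_col, r=r, p=p))
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for radius_col in profiles.columns:
        m = out["radius"] == radius_col
        out.loc[m, "q"] = multipletests(out.loc[m, "p"], method="fdr_bh")[1]
    passed = {}
    for module in mes.columns:
        sub = out[out["module"] == module]
        ok = (sub["q"] < q_threshold).all() and (
            (sub["r"] > 0).all() or (sub["r"] < 0).all()
        )
        passed[module] = bool(ok)
    out["passes"] = out["module"].map(passed)
    if parcellation is not None:
        out.insert(0, "parcellation", parcellation)
    return out


@dataclass
class GeneSetLedger:
    """Signed gene sets for one condition, with derivation provenance."""

    condition: str
    positive: set = field(default_factory=set)
    negative: set = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positive = set(self.positive)
        self.negative = set(self.negative)
        if self.positive & self.negative:
            raise ValueError("a gene cannot be in both signed sets")

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "positive": sorted(self.positive),
            "negative": sorted(self.negative),
            "provenance": self.provenance,
        }


def derive_signed_gene_sets(
    module_gene_sets: dict,
    associations: dict,
    condition: str = "",
) -> GeneSetLedger:
    """Intersect per-parcellation signed module genes into one ledger.

    ``module_gene_sets`` maps parcellation -> module -> iterable of genes
    (the genes that parcellation contributes for that module);
    ``associations`` maps parcellation -> the association table from
    :func:`module_ma_association`.  Within each parcellation, genes of
    passing positive-sign modules form the positive set (negative
    analogous); the final signed sets are the strict intersection across
    all parcellations.  No passing module anywhere yields empty sets.
    """
    parcs = sorted(module_gene_sets)
    if sorted(associations) != parcs:
        raise ValueError("parcellation keys of gene sets and associations differ")
    pos_sets, neg_sets = [], []
    for parc in parcs:
        table = associations[parc]
        pos, neg = set(), set()
        for module, genes in module_gene_sets[parc].items():
            sub = table[table["module"] == module]
            if sub.empty or not sub["passes"].all():
                continue
            (pos if (sub["r"] > 0).all() else neg).update(genes)
        pos_sets.append(pos)
        neg_sets.append(neg)
    positive = set.intersection(*pos_sets) if pos_sets else set()
    negative = set.intersection(*neg_sets) if neg_sets else set()
    # a gene passing with opposite signs in different parcellations is
    # unassignable and excluded from both sets
    clash = positive & negative
    return GeneSetLedger(
        condition=condition,
        positive=positive - clash,
        negative=negative - clash,
        provenance={
            "parcellations": parcs,
            "per_parcellation_positive": {p: sorted(s) for p, s in zip(parcs, pos_sets)},
            "per_parcellation_negative": {p: sorted(s) for p, s in zip(parcs, neg_sets)},
        },
    )


def intersect_disease_genes(ledger: GeneSetLedger, disease_genes) -> GeneSetLedger:
    """Restrict both signed sets to a disease-associated gene list."""
    disease = set(disease_genes)
    if not disease:
        raise ValueError("disease gene list is empty")
    prov = dict(ledger.provenance)
    prov["disease_list_size"] = len(disease)
    prov["disease_intersected"] = True
    return GeneSetLedger(
        condition=ledger.condition,
        positive=ledger.positive & disease,
        negative=ledger.negative & disease,
        provenance=prov,
    )


def condition_overlap(a: GeneSetLedger, b: GeneSetLedger) -> dict:
    """Signed overlap between two conditions plus containment report."""
    return {
        "positive_overlap": sorted(a.positive & b.positive),
        "negative_overlap": sorted(a.negative & b.negative),
        f"{a.condition}_subset_of_{b.condition}": a.positive <= b.positive
        and a.negative <= b.negative,
        f"{b.condition}_subset_of_{a.condition}": b.positive <= a.positive
        and b.negative <= a.negative,
    }


def key_genes(
    expr: pd.DataFrame,
    gene_set,
    r_threshold: float = 0.7,
    use_abs: bool = False,
) -> set:
    """Genes with at least one co-expression partner above ``r_threshold``.

    Pairwise Pearson correlations are computed among set members across
    the rows (samples) of ``expr``; a gene is key when some partner's
    correlation exceeds the threshold strictly (on |r| when
    ``use_abs``).
    """
    genes = sorted(set(gene_set) & set(expr.columns))
    if len(set(gene_set) - set(expr.columns)):
        raise ValueError("gene set contains genes absent from the matrix")
    if len(genes) < 2:
        warnings.warn("gene set smaller than 2; no key genes")
        return set()
    if len(expr) < 4:
        raise ValueError("need at least 4 samples")
    cor = np.corrcoef(expr[genes].to_numpy(float).T)
    np.fill_diagonal(cor, -np.inf)
    if use_abs:
        cor = np.abs(cor)
    hit = (cor > r_threshold).any(axis=1)
    return {g for g, h in zip(genes, hit) if h}


def overrepresentation_test(
    query, annotations: dict, universe, fdr_q: float = 0.05
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per annotation term.

    For a term with K genes in a universe of N, a query of size n with k
    overlapping genes scores p = P(X >= k), X ~ Hypergeom(N, K, n); BH-FDR
    across terms.  The query must be a subset of the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for term, genes in annotations.items():
        term_genes = set(genes) & universe
        K = len(term_genes)
        k = len(query & term_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        # Haldane-corrected odds ratio of the 2x2 overlap table
        a, b_, c, d = k, n - k, K - k, N - K - (n - k)
        odds = ((a + 0.5) * (d + 0.5)) / ((b_ + 0.5) * (c + 0.5))
        rows.append(
            dict(term=term, term_size=K, overlap=k, odds_ratio=odds, p=min(p, 1.0))
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["q"] < fdr_q
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
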