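"""Donor microarray expression preprocessing.

Mirrors the standard multi-donor brain-expression workflow: probes are
filtered on above-background intensity and on concordance with companion
RNA-seq measurements, one representative probe per gene is chosen, values
are normalized per donor with a scaled robust sigmoid (SRS), samples are
aggregated into parcellation regions, and genes are filtered on
differential stability (DSS) — the mean cross-donor Spearman correlation
of their regional expression profile.

Filter order is fixed: intensity -> RNA-seq presence -> concordance ->
representative probe -> SRS -> region aggregation -> DSS, so gene counts
only shrink along the chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DonorExpressionBundle",
    "Parcellation",
    "AhbaResult",
    "intensity_filter",
    "probe_concordance",
    "rnaseq_concordance_filter",
    "select_representative_probe",
    "srs_normalize",
    "assign_samples_to_regions",
    "region_expression_matrix",
    "compute_dss",
    "dss_filter",
    "preprocess_bundles",
]


@dataclass
class DonorExpressionBundle:
    """All expression data for one donor.

    expression : probes x samples log2-intensity DataFrame
    probe_map : DataFrame indexed by probe_id with a ``gene`` column
    above_background : boolean DataFrame aligned with ``expression``
    rnaseq : genes x samples DataFrame (TPM-like), same sample columns
    coordinates : DataFrame indexed by sample id with x, y, z (MNI mm)
    """

    donor_id: str
    expression: pd.DataFrame
    probe_map: pd.DataFrame
    above_background: pd.DataFrame
    rnaseq: pd.DataFrame
    coordinates: pd.DataFrame

    def __post_init__(self):
        if self.probe_map.index.duplicated().any():
            raise ValueError("duplicated probe ids in probe map")
        if not self.expression.index.equals(self.above_background.index) or list(
            self.expression.columns
        ) != list(self.above_background.columns):
            raise ValueError("above_background must align with expression")
        missing = set(self.expression.index) - set(self.probe_map.index)
        if missing:
            raise ValueError(f"probes missing from probe map: {sorted(missing)[:5]}")
        if not set(self.expression.columns) <= set(self.coordinates.index):
            raise ValueError("sample coordinates missing for some samples")


@dataclass
class Parcellation:
    """Labeled volume partitioning the cortex into regions (0 = background)."""

    name: str
    volume: np.ndarray
    affine: np.ndarray

    def labeled_voxel_mni(self):
        """(labels, coords): region label and MNI-mm center per labeled voxel."""
        idx = np.argwhere(self.volume > 0)
        labels = self.volume[tuple(idx.T)]
        homog = np.c_[idx, np.ones(len(idx))]
        return labels, (homog @ self.affine.T)[:, :3]


# ---------------------------------------------------------------------------
# probe filtering and selection
# ---------------------------------------------------------------------------


def intensity_filter(bundles, min_fraction: float = 0.5, per_donor: bool = False):
    """Probes above background in at least ``min_fraction`` of samples.

    The fraction is pooled across all donors' samples by default
    (``per_donor=True`` instead requires the fraction within every donor).
    Retention uses >= (a probe above background in exactly half the samples
    is kept).
    """
    bundles = list(bundles)
    probes = bundles[0].expression.index
    for b in bundles:
        if b.above_background is None:
            raise ValueError("above-background indicators missing")
        if not b.expression.index.equals(probes):
            raise ValueError("bundles must share a probe set")
    if per_donor:
        keep = pd.Series(True, index=probes)
        for b in bundles:
            keep &= b.above_background.mean(axis=1) >= min_fraction
        return list(probes[keep])
    hits = sum(b.above_background.sum(axis=1) for b in bundles)
    total = sum(b.above_background.shape[1] for b in bundles)
    return list(probes[hits / total >= min_fraction])


def _pooled(bundles, probes):
    """Pooled probe expression and RNA-seq matrices across donors."""
    expr = pd.concat(
        [b.expression.loc[probes].add_suffix(f"@{b.donor_id}", axis=1) for b in bundles],
        axis=1,
    )
    rna = pd.concat(
        [b.rnaseq.add_suffix(f"@{b.donor_id}", axis=1) for b in bundles], axis=1
    )
    return expr, rna.reindex(columns=expr.columns)


def probe_concordance(bundles, probes=None) -> pd.Series:
    """Spearman rho between each probe and its gene's RNA-seq profile.

    Samples are pooled (matched within donor) across all donors; probes
    whose gene is absent from the RNA-seq companion get NaN, and probes
    with fewer than 3 matched samples get NaN with a warning.
    """
    bundles = list(bundles)
    if probes is None:
        probes = list(bundles[0].expression.index)
    gene_of = bundles[0].probe_map["gene"]
    expr, rna = _pooled(bundles, probes)
    rho = pd.Series(np.nan, index=pd.Index(probes, name="probe"))
    rna_genes = set(rna.index)
    for probe in probes:
        gene = gene_of[probe]
        if gene not in rna_genes:
            continue
        x = expr.loc[probe]
        y = rna.loc[gene]
        ok = x.notna() & y.notna()
        if ok.sum() < 3:
            warnings.warn(f"probe {probe}: fewer than 3 matched samples")
            continue
        rho[probe] = stats.spearmanr(x[ok], y[ok]).statistic
    return rho


def rnaseq_concordance_filter(bundles, probes=None, min_rho: float = 0.2):
    """Keep probes with pooled Spearman rho >= min_rho against RNA-seq.

    Probes whose gene is not measured by RNA-seq are excluded beforehand.
    Returns ``(retained_probes, rho)``.
    """
    rho = probe_concordance(bundles, probes)
    keep = rho[rho >= min_rho]
    return list(keep.index), rho


def select_representative_probe(bundles, probes, rho: pd.Series | None = None):
    """One probe per gene: highest RNA-seq concordance wins.

    Ties are broken by higher pooled mean expression, then lexicographic
    probe id.  Returns a ``gene -> probe`` dict.
    """
    bundles = list(bundles)
    if rho is None:
        rho = probe_concordance(bundles, probes)
    gene_of = bundles[0].probe_map["gene"]
    expr, _ = _pooled(bundles, list(probes))
    mean_expr = expr.mean(axis=1)
    best: dict = {}
    for probe in sorted(probes):
        gene = gene_of[probe]
        key = (rho.get(probe, np.nan), mean_expr[probe])
        if gene not in best:
            best[gene] = (key, probe)
            continue
        cur_key, _cur = best[gene]
        if (np.nan_to_num(key[0], nan=-2), key[1]) > (
            np.nan_to_num(cur_key[0], nan=-2),
            cur_key[1],
        ):
            best[gene] = (key, probe)
    return {g: probe for g, (_k, probe) in best.items()}


# ---------------------------------------------------------------------------
# normalization and aggregation
# ---------------------------------------------------------------------------


def srs_normalize(values):
    """Scaled robust sigmoid: outlier-robust map of a vector onto [0, 1].

    x' = 1 / (1 + exp(-(x - median) / (IQR / 1.35))), then linearly
    rescaled so min -> 0 and max -> 1.  Strictly monotone in x.  A zero
    IQR falls back to SD scaling; a zero SD (constant vector) returns 0.5
    everywhere.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("srs_normalize needs at least 2 values")
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    scale = (q75 - q25) / 1.35
    if scale == 0:
        scale = x.std()
        if scale == 0:
            return np.full_like(x, 0.5)
    s = 1.0 / (1.0 + np.exp(-(x - med) / scale))
    lo, hi = s.min(), s.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (s - lo) / (hi - lo)


def normalize_donor(bundle: DonorExpressionBundle, gene_probe: dict) -> pd.DataFrame:
    """Samples x genes SRS-normalized matrix for one donor."""
    genes = sorted(gene_probe)
    mat = bundle.expression.loc[[gene_probe[g] for g in genes]].to_numpy(float)
    out = np.vstack([srs_normalize(row) for row in mat])
    return pd.DataFrame(
        out.T, index=list(bundle.expression.columns), columns=genes
    )


def assign_samples_to_regions(
    coordinates: pd.DataFrame, parcellation: Parcellation, max_distance_mm: float = 4.0
) -> pd.Series:
    """Region of the nearest labeled voxel within ``max_distance_mm``.

    Samples farther than the cutoff from every labeled voxel are left
    unassigned (NaN).
    """
    labels, vox_mni = parcellation.labeled_voxel_mni()
    pts = coordinates[["x", "y", "z"]].to_numpy(float)
    d2 = ((pts[:, None, :] - vox_mni[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    dist = np.sqrt(d2[np.arange(len(pts)), nearest])
    region = labels[nearest].astype(float)
    region[dist > max_distance_mm] = np.nan
    return pd.Series(region, index=coordinates.index, name="region")


def region_expression_matrix(
    sample_expr: pd.DataFrame,
    coordinates: pd.DataFrame,
    parcellation: Parcellation,
    max_distance_mm: float = 4.0,
) -> pd.DataFrame:
    """Regions x genes matrix: mean of assigned samples' expression.

    ``sample_expr`` is samples x genes; regions with no assigned sample are
    omitted.  Raises if no sample is assigned anywhere.
    """
    assign = assign_samples_to_regions(
        coordinates.loc[sample_expr.index], parcellation, max_distance_mm
    )
    if assign.isna().all():
        raise ValueError("no sample assigned to any region")
    grouped = sample_expr.groupby(assign).mean()
    grouped.index = grouped.index.astype(int)
    grouped.index.name = "region"
    return grouped.sort_index()


# ---------------------------------------------------------------------------
# differential stability
# ---------------------------------------------------------------------------


def compute_dss(donor_region_matrices: dict, min_shared_regions: int = 3) -> pd.Series:
    """Differential stability: mean pairwise cross-donor Spearman rho.

    ``donor_region_matrices`` maps donor id to a regions x genes matrix.
    For every donor pair the genes' regional profiles are rank-correlated
    over the regions the pair shares (pairs sharing fewer than
    ``min_shared_regions`` are skipped); each gene's DSS is the mean over
    valid pairs, NaN when no pair is valid.
    """
    donors = sorted(donor_region_matrices)
    if len(donors) < 2:
        raise ValueError("DSS requires at least 2 donors")
    genes = donor_region_matrices[donors[0]].columns
    acc = np.zeros(len(genes))
    cnt = np.zeros(len(genes))
    for i in range(len(donors)):
        for j in range(i + 1, len(donors)):
            a = donor_region_matrices[donors[i]]
            b = donor_region_matrices[donors[j]]
            shared = a.index.intersection(b.index)
            if len(shared) < min_shared_regions:
                continue
            ra = stats.rankdata(a.loc[shared, genes].to_numpy(), axis=0)
            rb = stats.rankdata(b.loc[shared, genes].to_numpy(), axis=0)
            ra = ra - ra.mean(axis=0)
            rb = rb - rb.mean(axis=0)
            denom = np.sqrt((ra**2).sum(axis=0) * (rb**2).sum(axis=0))
            with np.errstate(invalid="ignore", divide="ignore"):
                rho = (ra * rb).sum(axis=0) / denom
            ok = np.isfinite(rho)
            acc[ok] += rho[ok]
            cnt[ok] += 1
    with np.errstate(invalid="ignore"):
        dss = acc / cnt
    dss[cnt == 0] = np.nan
    return pd.Series(dss, index=genes, name="dss")


def dss_filter(dss: pd.Series, threshold: float = 0.5):
    """Genes with DSS strictly above ``threshold``."""
    return list(dss[dss > threshold].index)


# ---------------------------------------------------------------------------
# end-to-end preprocessing
# ---------------------------------------------------------------------------


@dataclass
class AhbaResult:
    """Outputs of the donor-expression preprocessing chain."""

    sample_expr: pd.DataFrame  # pooled samples x genes, SRS normalized
    sample_coords: pd.DataFrame  # pooled sample coordinates
    sample_donor: pd.Series  # donor id per pooled sample
    donor_region_matrices: dict  # parcellation -> donor -> regions x genes
    region_matrices: dict  # parcellation -> regions x genes (donor mean)
    dss: dict  # parcellation -> per-gene DSS
    retained_genes: dict  # parcellation -> genes with DSS > threshold
    provenance: dict = field(default_factory=dict)


def preprocess_bundles(
    bundles,
    parcellations: dict,
    min_fraction: float = 0.5,
    min_rho: float = 0.2,
    max_distance_mm: float = 4.0,
    dss_threshold: float = 0.5,
) -> AhbaResult:
    """Run the full probe-to-region preprocessing chain.

    Returns pooled SRS-normalized sample x gene expression, per-donor and
    donor-averaged region x gene matrices for every parcellation, DSS
    vectors, and the per-parcellation DSS-retained gene lists, together
    with a provenance record of how many probes/genes survive each filter.
    """
    bundles = list(bundles)
    prov = {"n_probes": len(bundles[0].expression.index)}

    probes = intensity_filter(bundles, min_fraction=min_fraction)
    prov["after_intensity_filter"] = len(probes)

    probes, rho = rnaseq_concordance_filter(bundles, probes, min_rho=min_rho)
    prov["after_rnaseq_concordance"] = len(probes)

    gene_probe = select_representative_probe(bundles, probes, rho=rho)
    prov["n_genes"] = len(gene_probe)

    per_donor_norm = {b.donor_id: normalize_donor(b, gene_probe) for b in bundles}
    sample_expr = pd.concat(
        [df.set_axis([f"{s}@{d}" for s in df.index]) for d, df in per_donor_norm.items()]
    )
    sample_coords = pd.concat(
        [
            b.coordinates.loc[list(b.expression.columns)].set_axis(
                [f"{s}@{b.donor_id}" for s in b.expression.columns]
            )
            for b in bundles
        ]
    )
    sample_donor = pd.Series(
        {f"{s}@{b.donor_id}": b.donor_id for b in bundles for s in b.expression.columns}
    ).loc[sample_expr.index]

    donor_region, region_mats, dss, retained = {}, {}, {}, {}
    for name, parc in parcellations.items():
        per_donor = {}
        for b in bundles:
            per_donor[b.donor_id] = region_expression_matrix(
                per_donor_norm[b.donor_id],
                b.coordinates,
                parc,
                max_distance_mm=max_distance_mm,
            )
        donor_region[name] = per_donor
        region_mats[name] = (
            pd.concat(per_donor.values()).groupby(level=0).mean().sort_index()
        )
        dss[name] = compute_dss(per_donor)
        retained[name] = dss_filter(dss[name], threshold=dss_threshold)
        prov[f"genes_dss_retained[{name}]"] = len(retained[name])

    return AhbaResult(
        sample_expr=sample_expr,
        sample_coords=sample_coords,
        sample_donor=sample_donor,
        donor_region_matrices=donor_region,
        region_matrices=region_mats,
        dss=dss,
        retained_genes=retained,
        provenance=prov,
    )
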