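"""Synthetic study generator.

Produces seeded inputs with the statistical structure every downstream
stage assumes: a three-group BOLD cohort with link-wise connectivity
differences planted in the group correlation structure plus Table-1-style
nuisance covariates; clinical scores linearly coupled to planted-link
connectivity; and multi-donor spatially autocorrelated gene expression in
which chosen genes track a supplied MA map with a planted sign.

BOLD synthesis draws multivariate Gaussians with per-group target
correlation matrices (only second-order structure matters downstream);
spatial expression autocorrelation uses a squared-exponential kernel on
sample coordinates.  All randomness derives from a single master seed via
named substreams, so identical specs are bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .ahba import DonorExpressionBundle, Parcellation
from .bwas import MAMap, VoxelTimeSeriesSet

__all__ = [
    "PlantedLink",
    "CohortSpec",
    "DonorSpec",
    "generate_bold_cohort",
    "generate_clinical_scores",
    "generate_donor_expression",
    "generate_disease_gene_list",
    "make_parcellations",
    "DEFAULT_COVARIATE_MODEL",
    "DEFAULT_SCORE_MODEL",
]

GROUPS = ("CN", "NDS", "DS")

# per-group (mean, SD) of the four nuisance covariates, emulating a
# mid-life all-male clinical cohort
DEFAULT_COVARIATE_MODEL = {
    "CN": {"age": (50.76, 7.60), "education": (9.76, 2.82), "TIV": (1528.49, 117.50), "FD": (0.09, 0.04)},
    "NDS": {"age": (49.18, 7.96), "education": (8.91, 2.47), "TIV": (1443.71, 115.04), "FD": (0.09, 0.04)},
    "DS": {"age": (51.20, 8.31), "education": (8.49, 3.02), "TIV": (1471.35, 112.23), "FD": (0.08, 0.05)},
}

# per-scale, per-group (mean, SD) clinical scores; patients only
DEFAULT_SCORE_MODEL = {
    "SDS": {"NDS": (4.81, 2.251), "DS": (12.77, 2.976)},
    "BPRS": {"NDS": (27.26, 3.14), "DS": (31.39, 3.14)},
    "SANS": {"NDS": (33.89, 8.80), "DS": (55.58, 11.60)},
    "SAPS": {"NDS": (9.72, 4.54), "DS": (8.91, 3.64)},
}


@dataclass(frozen=True)
class PlantedLink:
    """One voxel pair whose group correlations differ from baseline.

    ``delta`` maps group name to the correlation offset added to the
    cohort-wide baseline for that group.
    """

    i: int
    j: int
    delta: dict


@dataclass
class CohortSpec:
    """Specification of the synthetic three-group BOLD cohort."""

    n_per_group: dict = field(default_factory=lambda: {g: 40 for g in GROUPS})
    n_voxels: int = 150
    n_timepoints: int = 240
    planted_links: list = field(default_factory=list)
    base_r: float = 0.2
    voxel_size_mm: float = 6.0
    covariate_model: dict = field(default_factory=lambda: DEFAULT_COVARIATE_MODEL)
    score_model: dict = field(default_factory=lambda: DEFAULT_SCORE_MODEL)
    primary_score: str = "SDS"
    score_coupling: float = -1.0
    score_noise_sd: float = 1.0
    include_sex_covariate: bool = False
    seed: int = 0

    def __post_init__(self):
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be positive")
        if self.n_voxels <= 1 or self.n_timepoints <= 1:
            raise ValueError("n_voxels and n_timepoints must exceed 1")
        for link in self.planted_links:
            if not (0 <= link.i < self.n_voxels and 0 <= link.j < self.n_voxels):
                raise ValueError(f"planted link ({link.i},{link.j}) outside voxel set")
            if link.i == link.j:
                raise ValueError("planted link must join two distinct voxels")
            for g, d in link.delta.items():
                if not abs(self.base_r + d) < 1:
                    raise ValueError(
                        f"target correlation for link ({link.i},{link.j}) group {g} "
                        "outside (-1, 1)"
                    )

    @property
    def groups(self):
        return tuple(self.n_per_group)


def _grid_geometry(n_voxels: int, voxel_size: float = 3.0):
    """Near-cubic grid holding ``n_voxels`` voxels, with an MNI-like affine."""
    a = int(np.ceil(n_voxels ** (1 / 3)))
    b = int(np.ceil(np.sqrt(n_voxels / a)))
    c = int(np.ceil(n_voxels / (a * b)))
    shape = (a, b, c)
    idx = np.argwhere(np.ones(shape, dtype=bool))[:n_voxels]
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = -voxel_size * (np.array(shape) - 1) / 2.0
    return shape, idx, affine


def _octant_labels(grid_idx: np.ndarray, shape) -> np.ndarray:
    half = np.array(shape) / 2.0
    bits = (grid_idx >= half).astype(int)
    return 1 + bits @ np.array([4, 2, 1])


def _group_correlation(spec: CohortSpec, group: str) -> np.ndarray:
    c = np.eye(spec.n_voxels)
    for link in spec.planted_links:
        r = spec.base_r + link.delta.get(group, 0.0)
        c[link.i, link.j] = c[link.j, link.i] = r
    eig = np.linalg.eigvalsh(c)
    if eig.min() < -1e-10:
        # nearest-PSD projection by eigenvalue clipping, diagonal renormalized
        w, v = np.linalg.eigh(c)
        w = np.clip(w, 1e-8, None)
        c2 = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(c2))
        c2 = c2 / np.outer(d, d)
        bad = [
            (l.i, l.j)
            for l in spec.planted_links
            if abs(c2[l.i, l.j] - c[l.i, l.j]) > 0.05
        ]
        if bad:
            raise ValueError(
                f"infeasible target correlation matrix for group {group}; "
                f"offending links: {bad}"
            )
        c = c2
    return c


def generate_bold_cohort(spec: CohortSpec) -> VoxelTimeSeriesSet:
    """Per-subject voxel time series plus a subject covariate table.

    Each subject's timepoints x voxels matrix is a multivariate Gaussian
    draw with the group's target correlation matrix, so group-wise link
    correlations converge to the planted targets as timepoints grow while
    non-planted links stay exchangeable between groups.
    """
    shape, grid_idx, affine = _grid_geometry(spec.n_voxels, spec.voxel_size_mm)
    labels = _octant_labels(grid_idx, shape)

    data, rows = [], []
    for group in spec.groups:
        chol = np.linalg.cholesky(_group_correlation(spec, group))
        cov_rng = substream(spec.seed, f"covariates/{group}")
        for s in range(spec.n_per_group[group]):
            rng = substream(spec.seed, f"bold/{group}/{s}")
            data.append(rng.standard_normal((spec.n_timepoints, spec.n_voxels)) @ chol.T)
            row = {"subject_id": f"{group}{s:03d}", "group": group}
            for cov, (mu, sd) in spec.covariate_model[group].items():
                row[cov] = mu + sd * cov_rng.standard_normal()
            if spec.include_sex_covariate:
                row["sex"] = int(cov_rng.random() < 0.5)
            rows.append(row)
    return VoxelTimeSeriesSet(
        data=np.stack(data),
        voxel_grid=grid_idx,
        grid_shape=shape,
        affine=affine,
        atlas_labels=labels,
        subjects=pd.DataFrame(rows),
    )


def generate_clinical_scores(spec: CohortSpec, subject_fc: pd.DataFrame) -> pd.DataFrame:
    """Clinical score table, primary score linearly coupled to planted FC.

    ``subject_fc`` must carry ``subject_id``, ``group``, and one or more
    numeric connectivity columns; their per-subject mean is the planted
    connectivity summary.  The primary score is the group mean plus
    ``score_coupling`` times that summary plus Gaussian noise with SD
    ``score_noise_sd``; all other scores are independent group-level
    noise.
    """
    fc_cols = [c for c in subject_fc.columns if c not in ("subject_id", "group")]
    if not fc_cols:
        raise ValueError("subject_fc must contain connectivity columns")
    expected = {
        f"{g}{s:03d}" for g in spec.groups for s in range(spec.n_per_group[g])
    }
    unknown = set(subject_fc["subject_id"]) - expected
    if unknown:
        raise ValueError(f"subject ids not in the cohort: {sorted(unknown)[:5]}")
    fc = subject_fc[fc_cols].mean(axis=1).to_numpy(float)
    rng = substream(spec.seed, "scores")
    rows = []
    for k, rec in enumerate(subject_fc.to_dict("records")):
        group = rec["group"]
        row = {"subject_id": rec["subject_id"], "group": group}
        for scale, per_group in spec.score_model.items():
            if group not in per_group:
                row[scale] = np.nan
                continue
            mu, sd = per_group[group]
            if scale == spec.primary_score:
                row[scale] = (
                    mu
                    + spec.score_coupling * fc[k]
                    + spec.score_noise_sd * rng.standard_normal()
                )
            else:
                row[scale] = mu + sd * rng.standard_normal()
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# donor expression
# ---------------------------------------------------------------------------


@dataclass
class DonorSpec:
    """Specification of the synthetic multi-donor expression dataset.

    ``n_pos_coupled`` / ``n_neg_coupled`` genes track the supplied MA map
    (sphere-averaged at ``ma_radius`` mm) with correlation ~``coupling``
    and the planted sign; all other genes are pure spatially
    autocorrelated fields.  A configurable fraction of probes is built to
    fail the intensity filter and another to fail RNA-seq concordance.
    """

    n_donors: int = 6
    n_samples_per_donor: int = 200
    n_probes: int = 360
    n_genes: int = 300
    spatial_field: float = 20.0  # squared-exponential length scale, mm
    n_pos_coupled: int = 60
    n_neg_coupled: int = 60
    coupling: float = 0.9
    noise_sd: float = 0.1
    ma_radius: float = 14.0
    frac_probe_low_intensity: float = 0.08
    frac_probe_discordant: float = 0.08
    frac_genes_missing_rnaseq: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_probes < self.n_genes:
            raise ValueError("need at least one probe per gene")
        if not np.isfinite(self.coupling) or abs(self.coupling) > 1:
            raise ValueError("coupling must be finite with |coupling| <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_pos_coupled + self.n_neg_coupled > self.n_genes:
            raise ValueError("more coupled genes than genes")
        if self.n_samples_per_donor < 10:
            raise ValueError("too few samples per donor for the spatial field")

    @property
    def genes(self):
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def positive_genes(self):
        return self.genes[: self.n_pos_coupled]

    @property
    def negative_genes(self):
        return self.genes[self.n_pos_coupled : self.n_pos_coupled + self.n_neg_coupled]


def _probe_layout(spec: DonorSpec):
    """Assign probes to genes: one primary probe per gene, extras round-robin."""
    genes = spec.genes
    probe_gene = list(genes)
    extra = spec.n_probes - spec.n_genes
    rng = substream(spec.seed, "probe_layout")
    extra_targets = rng.choice(spec.n_genes, size=extra, replace=extra > spec.n_genes)
    probe_gene += [genes[t] for t in extra_targets]
    probe_ids = [f"P{i:05d}" for i in range(spec.n_probes)]
    primary = {g: f"P{i:05d}" for i, g in enumerate(genes)}
    return probe_ids, probe_gene, primary


def _sphere_mean_ma(ma: MAMap, pts: np.ndarray, radius: float) -> np.ndarray:
    homog = np.c_[ma.voxel_grid, np.ones(len(ma.voxel_grid))]
    vox = (homog @ ma.affine.T)[:, :3]
    d2 = ((pts[:, None, :] - vox[None, :, :]) ** 2).sum(axis=2)
    inside = d2 <= radius**2
    vals = ma.values.astype(float)
    out = np.empty(len(pts))
    for i in range(len(pts)):
        out[i] = vals[inside[i]].mean() if inside[i].any() else vals[d2[i].argmin()]
    return out


def generate_donor_expression(spec: DonorSpec, ma: MAMap):
    """List of :class:`DonorExpressionBundle`, one per donor.

    Regional expression of MA-coupled genes correlates with the
    sphere-averaged MA map with the planted sign; non-coupled genes are
    independent smooth spatial fields.  Probe-level corruption (low
    intensity, scrambled RNA-seq concordance) only ever hits duplicate
    probes of coupled genes or probes of non-coupled genes, so every
    coupled gene keeps one clean probe.
    """
    if ma.n_voxels == 0:
        raise ValueError("MA map is empty")
    probe_ids, probe_gene, primary = _probe_layout(spec)
    genes = spec.genes
    gene_index = {g: i for i, g in enumerate(genes)}

    shared = substream(spec.seed, "shared_effects")
    gene_baseline = 8.0 + shared.standard_normal(spec.n_genes)
    probe_offset = 0.5 * shared.standard_normal(spec.n_probes)

    # probes eligible for planted failure: never the primary probe of a
    # coupled gene
    coupled = set(spec.positive_genes) | set(spec.negative_genes)
    eligible = [
        k
        for k, (pid, g) in enumerate(zip(probe_ids, probe_gene))
        if g not in coupled or pid != primary[g]
    ]
    fail_rng = substream(spec.seed, "probe_failures")
    n_low = int(round(spec.frac_probe_low_intensity * spec.n_probes))
    n_disc = int(round(spec.frac_probe_discordant * spec.n_probes))
    if n_low + n_disc > len(eligible):
        raise ValueError("failure fractions exceed eligible probe count")
    chosen = fail_rng.choice(eligible, size=n_low + n_disc, replace=False)
    low_probes = set(chosen[:n_low].tolist())
    disc_probes = set(chosen[n_low:].tolist())

    missing_pool = [g for g in genes if g not in coupled]
    n_missing = int(round(spec.frac_genes_missing_rnaseq * spec.n_genes))
    missing_rnaseq = set(
        fail_rng.choice(missing_pool, size=min(n_missing, len(missing_pool)), replace=False)
    )

    # bounding box of the MA voxel grid in mm
    homog = np.c_[ma.voxel_grid, np.ones(len(ma.voxel_grid))]
    vox_mni = (homog @ ma.affine.T)[:, :3]
    lo, hi = vox_mni.min(axis=0), vox_mni.max(axis=0)

    sign = np.zeros(spec.n_genes)
    sign[[gene_index[g] for g in spec.positive_genes]] = 1.0
    sign[[gene_index[g] for g in spec.negative_genes]] = -1.0

    bundles = []
    for d in range(spec.n_donors):
        donor = f"D{d + 1}"
        rng = substream(spec.seed, f"donor/{donor}")
        n_s = spec.n_samples_per_donor
        pts = lo + (hi - lo) * rng.random((n_s, 3))
        sample_ids = [f"{donor}_S{i:03d}" for i in range(n_s)]

        m = _sphere_mean_ma(ma, pts, spec.ma_radius)
        m = (m - m.mean()) / m.std() if m.std() > 0 else np.zeros_like(m)

        dist2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        kern = np.exp(-dist2 / (2 * spec.spatial_field**2)) + 1e-6 * np.eye(n_s)
        chol = np.linalg.cholesky(kern)
        fields = chol @ rng.standard_normal((n_s, spec.n_genes))

        c = spec.coupling
        signal = (
            sign[None, :] * c * m[:, None]
            + np.where(sign[None, :] != 0, np.sqrt(1 - c**2), 1.0) * fields
        )
        gene_expr = (
            gene_baseline[None, :]
            + signal
            + spec.noise_sd * rng.standard_normal((n_s, spec.n_genes))
        )  # samples x genes

        probe_expr = np.empty((spec.n_probes, n_s))
        for k, g in enumerate(probe_gene):
            probe_expr[k] = (
                gene_expr[:, gene_index[g]]
                + probe_offset[k]
                + 0.1 * rng.standard_normal(n_s)
            )
        # discordant probes: mirror deviations around the probe's expected
        # baseline so the pooled microarray/RNA-seq rank correlation is
        # strongly negative within and across donors
        for k in disc_probes:
            baseline = gene_baseline[gene_index[probe_gene[k]]] + probe_offset[k]
            probe_expr[k] = 2 * baseline - probe_expr[k]

        above = rng.random((spec.n_probes, n_s)) < 0.97
        for k in low_probes:
            above[k] = rng.random(n_s) < 0.2

        rna_genes = [g for g in genes if g not in missing_rnaseq]
        rnaseq = (
            gene_expr[:, [gene_index[g] for g in rna_genes]].T
            + 0.1 * rng.standard_normal((len(rna_genes), n_s))
        )

        bundles.append(
            DonorExpressionBundle(
                donor_id=donor,
                expression=pd.DataFrame(probe_expr, index=probe_ids, columns=sample_ids),
                probe_map=pd.DataFrame(
                    {"gene": probe_gene, "entrez": [gene_index[g] + 1 for g in probe_gene]},
                    index=pd.Index(probe_ids, name="probe_id"),
                ),
                above_background=pd.DataFrame(above, index=probe_ids, columns=sample_ids),
                rnaseq=pd.DataFrame(rnaseq, index=rna_genes, columns=sample_ids),
                coordinates=pd.DataFrame(
                    pts, index=pd.Index(sample_ids, name="sample_id"), columns=["x", "y", "z"]
                ),
            )
        )
    return bundles


def generate_disease_gene_list(
    all_genes,
    fraction: float,
    planted_genes=(),
    overlap_with_planted: float = 1.0,
    seed: int = 0,
):
    """Disease-associated gene list with a controlled planted-gene share.

    ``fraction`` of all genes is returned.  ``overlap_with_planted`` gives
    the share of the planted genes to include (an integer > 1 is read as an
    absolute count); the remainder is drawn from non-planted genes.
    """
    all_genes = list(all_genes)
    planted = [g for g in planted_genes if g in set(all_genes)]
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = int(round(fraction * len(all_genes)))
    if n == len(all_genes):
        return list(all_genes)
    if overlap_with_planted > 1:
        n_overlap = int(overlap_with_planted)
    else:
        n_overlap = int(round(overlap_with_planted * len(planted)))
    if n_overlap > len(planted):
        raise ValueError("overlap request exceeds planted-gene count")
    if n_overlap > n:
        raise ValueError("overlap request exceeds list size")
    rng = substream(seed, "disease_genes")
    chosen = list(rng.choice(planted, size=n_overlap, replace=False)) if n_overlap else []
    pool = [g for g in all_genes if g not in set(planted)]
    if n - n_overlap > len(pool):
        raise ValueError("not enough non-planted genes for the requested list")
    chosen += list(rng.choice(pool, size=n - n_overlap, replace=False))
    return sorted(chosen)


def make_parcellations(
    grid_shape, affine, n_regions_list=(12, 18, 24, 30), seed: int = 0
) -> dict:
    """Seeded Voronoi parcellations of a voxel grid.

    Each parcellation labels every grid voxel with the nearest of
    ``n_regions`` randomly placed region seeds (Euclidean distance in
    grid units), emulating multi-resolution cortical parcellations.
    """
    idx = np.argwhere(np.ones(grid_shape, dtype=bool))
    out = {}
    for n_regions in n_regions_list:
        rng = substream(seed, f"parcellation/{n_regions}")
        centers = idx[rng.choice(len(idx), size=n_regions, replace=False)]
        d2 = ((idx[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        vol = np.zeros(grid_shape, dtype=np.int32)
        vol[tuple(idx.T)] = d2.argmin(axis=1) + 1
        name = f"parc{n_regions}"
        out[name] = Parcellation(name=name, volume=vol, affine=np.asarray(affine))
    return out
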