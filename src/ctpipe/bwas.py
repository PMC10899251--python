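"""Voxel-wise brain-wide association (BWAS).

Given per-subject BOLD voxel time series, every unordered voxel pair defines
one functional-connectivity link: the Pearson correlation of the two series,
Fisher z-transformed.  Links are compared between two subject groups with a
pooled-variance two-sample t-test after nuisance covariates are residualized
out of the subject-level z values.  The per-voxel measure of association
MA(i) counts how many links of voxel i reach a corrected link-level
significance threshold, and regions of interest are connected clusters of
voxels with high MA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "VoxelTimeSeriesSet",
    "LinkTestResult",
    "MAMap",
    "ROI",
    "ROISet",
    "load_timeseries",
    "fisher_z",
    "link_count",
    "link_group_test",
    "fwe_threshold",
    "ma_map",
    "extract_roi_clusters",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VoxelTimeSeriesSet:
    """BOLD time series for a common voxel set across subjects.

    Parameters
    ----------
    data : ndarray, shape (n_subjects, n_timepoints, n_voxels)
        One timepoints x voxels matrix per subject, identical voxel order.
    voxel_grid : ndarray, shape (n_voxels, 3), int
        Grid index (i, j, k) of each voxel in the image volume.
    grid_shape : tuple of int
        Shape of the image volume.
    affine : ndarray, shape (4, 4)
        Voxel-to-MNI(mm) affine.
    atlas_labels : ndarray, shape (n_voxels,), int
        Atlas region label per voxel (0 = unlabeled).
    subjects : pandas.DataFrame
        One row per subject; must contain ``subject_id`` and ``group``
        columns plus any covariate columns.
    """

    data: np.ndarray
    voxel_grid: np.ndarray
    grid_shape: tuple
    affine: np.ndarray
    atlas_labels: np.ndarray
    subjects: pd.DataFrame

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_subjects, n_timepoints, n_voxels)")
        if len(self.subjects) != self.data.shape[0]:
            raise ValueError("subject table length does not match data")
        if self.voxel_grid.shape != (self.n_voxels, 3):
            raise ValueError("voxel_grid must be (n_voxels, 3)")
        sd = self.data.std(axis=1)
        if np.any(sd <= 0):
            subj, vox = np.argwhere(sd <= 0)[0]
            raise ValueError(
                f"zero-variance voxel series (subject index {subj}, voxel {vox})"
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[2]

    def voxel_mni(self) -> np.ndarray:
        """MNI-mm coordinates of all voxel centers, shape (n_voxels, 3)."""
        homog = np.c_[self.voxel_grid, np.ones(len(self.voxel_grid))]
        return (homog @ self.affine.T)[:, :3]


@dataclass
class LinkTestResult:
    """Group comparison of every unordered voxel-pair link.

    Arrays are stored in upper-triangular (i < j) order matching
    ``numpy.triu_indices(n_voxels, k=1)``.
    """

    n_voxels: int
    t: np.ndarray
    p: np.ndarray
    df: int
    mean_a: np.ndarray
    mean_b: np.ndarray
    group_a: str
    group_b: str
    covariates: tuple = ()
    alpha_link: float | None = None
    correction: str | None = None

    def __post_init__(self):
        n_links = link_count(self.n_voxels, "unique_pairs")
        for name in ("t", "p", "mean_a", "mean_b"):
            arr = getattr(self, name)
            if arr.shape != (n_links,):
                raise ValueError(f"{name} must have one entry per unique pair")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("non-finite t statistics")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p-values outside [0, 1]")

    def p_matrix(self) -> np.ndarray:
        """Symmetric p-value matrix with 1.0 on the diagonal."""
        m = np.ones((self.n_voxels, self.n_voxels))
        iu = np.triu_indices(self.n_voxels, k=1)
        m[iu] = self.p
        m[(iu[1], iu[0])] = self.p
        return m


@dataclass
class MAMap:
    """Per-voxel count of supra-threshold links (the MA statistic)."""

    values: np.ndarray
    alpha_link: float
    voxel_grid: np.ndarray
    grid_shape: tuple
    affine: np.ndarray
    atlas_labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if np.any(self.values < 0) or np.any(self.values > len(self.values) - 1):
            raise ValueError("MA values must lie in [0, n_voxels - 1]")

    @property
    def n_voxels(self) -> int:
        return len(self.values)

    def volume(self) -> np.ndarray:
        """Dense 3D int32 volume of MA values (-1 outside the voxel set)."""
        vol = np.full(self.grid_shape, -1, dtype=np.int32)
        vol[tuple(self.voxel_grid.T)] = self.values
        return vol

    def to_nifti(self):
        import nibabel as nib

        vol = self.volume()
        vol[vol < 0] = 0
        return nib.Nifti1Image(vol.astype(np.int32), self.affine)


@dataclass
class ROI:
    voxel_indices: np.ndarray  # indices into the voxel set
    size: int
    peak_ma: int
    peak_voxel: int
    peak_mni: np.ndarray
    atlas_label: int


@dataclass
class ROISet:
    rois: list = field(default_factory=list)
    ma_threshold: float = 40
    min_size: int = 100

    def __len__(self):
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, i):
        return self.rois[i]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "roi": i + 1,
                "region_label": r.atlas_label,
                "voxels": r.size,
                "peak_ma": r.peak_ma,
                "peak_x": r.peak_mni[0],
                "peak_y": r.peak_mni[1],
                "peak_z": r.peak_mni[2],
            }
            for i, r in enumerate(self.rois)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "roi",
                "region_label",
                "voxels",
                "peak_ma",
                "peak_x",
                "peak_y",
                "peak_z",
            ],
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def load_timeseries(bold_paths, atlas_path, subjects) -> VoxelTimeSeriesSet:
    """Build a :class:`VoxelTimeSeriesSet` from NIfTI files.

    ``bold_paths`` are per-subject 4D BOLD images (one per row of
    ``subjects``, in order); ``atlas_path`` is a 3D integer label image on
    the same grid defining the voxel set (labels > 0).  ``subjects`` is a
    DataFrame or a CSV path with ``subject_id``, ``group``, and covariate
    columns.
    """
    import nibabel as nib

    if not isinstance(subjects, pd.DataFrame):
        subjects = pd.read_csv(subjects)
    atlas_img = nib.load(str(atlas_path))
    atlas = np.asarray(atlas_img.dataobj)
    grid = np.argwhere(atlas > 0)
    if len(grid) == 0:
        raise ValueError("atlas contains no labeled voxels")
    data = []
    for path in bold_paths:
        img = nib.load(str(path))
        vol = np.asarray(img.dataobj)
        if vol.shape[:3] != atlas.shape:
            raise ValueError(f"{path}: BOLD grid does not match the atlas")
        data.append(vol[tuple(grid.T)].T)  # (timepoints, voxels)
    return VoxelTimeSeriesSet(
        data=np.stack(data),
        voxel_grid=grid,
        grid_shape=atlas.shape,
        affine=atlas_img.affine,
        atlas_labels=atlas[tuple(grid.T)].astype(int),
        subjects=subjects.reset_index(drop=True),
    )


def fisher_z(r):
    """Fisher z-transform, z = atanh(r).

    Raises ``ValueError`` for |r| >= 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return out.item() if out.ndim == 0 else out


def link_count(n_voxels: int, convention: str = "unique_pairs") -> int:
    """Number of voxel-pair links for a brain of ``n_voxels`` voxels.

    ``unique_pairs`` counts unordered distinct pairs, n(n-1)/2.
    ``paper_square_half`` is the n^2/2 convention sometimes quoted in BWAS
    reports (floor of half the full square count, self-pairs included).
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    n = int(n_voxels)
    if convention == "unique_pairs":
        return n * (n - 1) // 2
    if convention == "paper_square_half":
        return n * n // 2
    raise ValueError(f"unknown convention {convention!r}")


def _subject_link_z(data: np.ndarray) -> np.ndarray:
    """Fisher-z link vectors for each subject, shape (n_subjects, n_links)."""
    n_sub, _, n_vox = data.shape
    iu = np.triu_indices(n_vox, k=1)
    out = np.empty((n_sub, len(iu[0])))
    for s in range(n_sub):
        r = np.corrcoef(data[s].T)[iu]
        # guard against numerically-degenerate |r| = 1
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
        out[s] = np.arctanh(r)
    return out


def link_group_test(
    ts: VoxelTimeSeriesSet,
    group_a: str,
    group_b: str,
    covariates: tuple = (),
) -> LinkTestResult:
    """Two-sided pooled-variance two-sample t-test on every link.

    Per link, subject-level Fisher-z values are residualized against the
    covariate design (intercept included, fit jointly across both groups),
    then groups are compared on the residuals.  Degrees of freedom are
    n_a + n_b - 2 - n_covariates.
    """
    subj = ts.subjects
    in_a = (subj["group"] == group_a).to_numpy()
    in_b = (subj["group"] == group_b).to_numpy()
    if in_a.sum() < 3 or in_b.sum() < 3:
        raise ValueError("each group needs at least 3 subjects")
    keep = in_a | in_b
    for c in covariates:
        if c not in subj.columns:
            raise ValueError(f"covariate column {c!r} missing from subject table")

    z = _subject_link_z(ts.data[keep])
    in_a = in_a[keep]

    mean_a = z[in_a].mean(axis=0)
    mean_b = z[~in_a].mean(axis=0)

    n_cov = len(covariates)
    if n_cov:
        X = np.c_[np.ones(len(z)), subj.loc[keep, list(covariates)].to_numpy(float)]
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify collinear columns by incremental rank
            bad = []
            for j in range(1, X.shape[1]):
                if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(
                    X[:, :j]
                ):
                    bad.append(covariates[j - 1])
            raise ValueError(f"singular covariate design; collinear columns: {bad}")
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        resid = z - X @ beta
    else:
        resid = z

    na, nb = int(in_a.sum()), int((~in_a).sum())
    df = na + nb - 2 - n_cov
    if df < 1:
        raise ValueError("insufficient degrees of freedom after covariate removal")
    ra, rb = resid[in_a], resid[~in_a]
    da = ra - ra.mean(axis=0)
    db = rb - rb.mean(axis=0)
    sp2 = ((da**2).sum(axis=0) + (db**2).sum(axis=0)) / df
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ra.mean(axis=0) - rb.mean(axis=0)) / se
    t = np.where(se == 0, 0.0, t)
    p = 2 * stats.t.sf(np.abs(t), df)

    return LinkTestResult(
        n_voxels=ts.n_voxels,
        t=t,
        p=p,
        df=df,
        mean_a=mean_a,
        mean_b=mean_b,
        group_a=group_a,
        group_b=group_b,
        covariates=tuple(covariates),
    )


def fwe_threshold(
    result: LinkTestResult,
    method: str = "bonferroni",
    family_alpha: float = 0.01,
    fixed_p_value: float | None = None,
) -> float:
    """Link-level significance threshold under family-wise error control.

    ``bonferroni`` divides ``family_alpha`` by the unique-pair link count;
    ``fixed_p`` installs a user-supplied cluster-defining threshold directly
    (e.g. one derived externally from Gaussian-random-field theory).
    The chosen threshold is recorded on the result's metadata.
    """
    if method == "bonferroni":
        if not 0 < family_alpha < 1:
            raise ValueError("family_alpha must lie in (0, 1)")
        alpha = family_alpha / link_count(result.n_voxels, "unique_pairs")
    elif method == "fixed_p":
        if fixed_p_value is None or not 0 < fixed_p_value < 1:
            raise ValueError("fixed_p requires a fixed_p_value in (0, 1)")
        alpha = float(fixed_p_value)
    else:
        raise ValueError(f"unknown FWE method {method!r}")
    result.alpha_link = alpha
    result.correction = method
    return alpha


def ma_map(
    result: LinkTestResult,
    alpha_link: float,
    ts: VoxelTimeSeriesSet | None = None,
) -> MAMap:
    """MA(i) = number of links of voxel i with p < alpha_link (self excluded)."""
    iu = np.triu_indices(result.n_voxels, k=1)
    hit = result.p < alpha_link
    counts = np.zeros(result.n_voxels, dtype=np.int64)
    np.add.at(counts, iu[0][hit], 1)
    np.add.at(counts, iu[1][hit], 1)
    if ts is not None:
        return MAMap(
            values=counts,
            alpha_link=alpha_link,
            voxel_grid=ts.voxel_grid,
            grid_shape=ts.grid_shape,
            affine=ts.affine,
            atlas_labels=ts.atlas_labels,
        )
    # grid-less map: lay voxels out along a line (enough for counting uses)
    grid = np.c_[
        np.arange(result.n_voxels),
        np.zeros(result.n_voxels, int),
        np.zeros(result.n_voxels, int),
    ]
    return MAMap(
        values=counts,
        alpha_link=alpha_link,
        voxel_grid=grid,
        grid_shape=(result.n_voxels, 1, 1),
        affine=np.eye(4),
    )


_STRUCTURES = {
    26: np.ones((3, 3, 3), dtype=bool),
    6: ndimage.generate_binary_structure(3, 1),
}


def extract_roi_clusters(
    ma: MAMap,
    ma_threshold: float = 40,
    min_size: int = 100,
    connectivity: int = 26,
) -> ROISet:
    """Connected clusters of voxels with MA > ma_threshold and size > min_size.

    Both inequalities are strict.  Clusters are reported largest first, with
    per-cluster peak MA, peak MNI coordinate (ties broken at the lowest
    linear grid index), and majority atlas label (ties broken by the label
    of the peak voxel).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6 or 26")
    vol = np.full(ma.grid_shape, -1, dtype=np.int64)
    vol[tuple(ma.voxel_grid.T)] = ma.values
    mask = vol > ma_threshold
    labeled, n_comp = ndimage.label(mask, structure=_STRUCTURES[connectivity])

    # voxel-set index lookup per grid position
    index_vol = np.full(ma.grid_shape, -1, dtype=np.int64)
    index_vol[tuple(ma.voxel_grid.T)] = np.arange(ma.n_voxels)
    linear = np.ravel_multi_index(tuple(ma.voxel_grid.T), ma.grid_shape)

    rois = []
    comp_of_voxel = labeled[tuple(ma.voxel_grid.T)]
    for comp in range(1, n_comp + 1):
        members = np.flatnonzero(comp_of_voxel == comp)
        if len(members) <= min_size:
            continue
        vals = ma.values[members]
        peak_val = int(vals.max())
        at_peak = members[vals == peak_val]
        peak_voxel = int(at_peak[np.argmin(linear[at_peak])])
        peak_mni = (
            ma.affine @ np.r_[ma.voxel_grid[peak_voxel], 1.0]
        )[:3]
        if ma.atlas_labels is not None:
            labels = np.asarray(ma.atlas_labels)[members]
            uniq, cnt = np.unique(labels, return_counts=True)
            best = uniq[cnt == cnt.max()]
            label = (
                int(ma.atlas_labels[peak_voxel])
                if len(best) > 1 and ma.atlas_labels[peak_voxel] in best
                else int(best[0])
            )
        else:
            label = 0
        rois.append(
            ROI(
                voxel_indices=members,
                size=len(members),
                peak_ma=peak_val,
                peak_voxel=peak_voxel,
                peak_mni=peak_mni,
                atlas_label=label,
            )
        )
    rois.sort(key=lambda r: (-r.size, -r.peak_ma, r.peak_voxel))
    return ROISet(rois=rois, ma_threshold=ma_threshold, min_size=min_size)
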