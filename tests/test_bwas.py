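import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ctpipe import bwas, synth
from conftest import make_timeseries


class TestFisherZ:
    def test_closed_form(self):
        assert bwas.fisher_z(0.0) == 0.0
        assert bwas.fisher_z(0.5) == pytest.approx(0.5493061, abs=1e-7)

    @pytest.mark.parametrize("r", np.arange(0.1, 1.0, 0.1))
    def test_odd_function(self, r):
        assert bwas.fisher_z(-r) == -bwas.fisher_z(r)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
    def test_domain_error(self, r):
        with pytest.raises(ValueError):
            bwas.fisher_z(r)

    @given(st.floats(-0.99, 0.98))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, r):
        assert bwas.fisher_z(r + 0.01) > bwas.fisher_z(r)


class TestLinkCount:
    def test_full_brain_conventions(self):
        assert bwas.link_count(23178, "paper_square_half") == 268609842
        assert bwas.link_count(23178, "unique_pairs") == 23178 * 23177 // 2

    def test_edge_cases(self):
        assert bwas.link_count(1, "unique_pairs") == 0
        with pytest.raises(ValueError):
            bwas.link_count(0)


class TestLinkGroupTest:
    def test_identical_groups_give_zero_t(self):
        rng = np.random.default_rng(3)
        half = rng.standard_normal((3, 60, 8))
        ts = make_timeseries(data=np.concatenate([half, half]), groups=list("AAABBB"))
        res = bwas.link_group_test(ts, "A", "B")
        assert np.allclose(res.t, 0.0)
        assert res.df == 4

    def test_matches_textbook_pooled_t(self):
        """Independent oracle: per-subject Pearson r -> atanh -> scipy pooled t."""
        ts = make_timeseries(n_subjects=6, n_timepoints=50, n_voxels=5, seed=7)
        res = bwas.link_group_test(ts, "A", "B")
        iu = np.triu_indices(5, k=1)
        z = np.array([np.arctanh(np.corrcoef(ts.data[s].T)[iu]) for s in range(6)])
        for link in range(z.shape[1]):
            t_ref, p_ref = stats.ttest_ind(z[:3, link], z[3:, link], equal_var=True)
            assert res.t[link] == pytest.approx(t_ref, rel=1e-9)
            assert res.p[link] == pytest.approx(p_ref, rel=1e-9)

    def test_covariates_reduce_df_and_flag_collinear(self):
        cov = {"age": np.arange(8.0), "age2": 2 * np.arange(8.0)}
        ts = make_timeseries(
            n_subjects=8, n_voxels=4, groups=list("AAAABBBB"), covariates=cov
        )
        res = bwas.link_group_test(ts, "A", "B", covariates=("age",))
        assert res.df == 8 - 2 - 1
        with pytest.raises(ValueError, match="collinear"):
            bwas.link_group_test(ts, "A", "B", covariates=("age", "age2"))

    def test_planted_link_attains_max_t(self):
        """A strongly planted link dominates the |t| field."""
        for seed in range(3):
            spec = synth.CohortSpec(
                n_per_group={"CN": 30, "DS": 30},
                n_voxels=20,
                n_timepoints=200,
                planted_links=[synth.PlantedLink(2, 9, {"DS": 0.5})],
                base_r=0.1,
                covariate_model={
                    g: synth.DEFAULT_COVARIATE_MODEL[g] for g in ("CN", "DS")
                },
                seed=seed,
            )
            ts = synth.generate_bold_cohort(spec)
            res = bwas.link_group_test(ts, "CN", "DS")
            iu = np.triu_indices(20, k=1)
            best = np.argmax(np.abs(res.t))
            assert (iu[0][best], iu[1][best]) == (2, 9)


class TestFweThreshold:
    def test_bonferroni_and_fixed(self):
        res = _dummy_result(101)
        assert bwas.fwe_threshold(res, "bonferroni", 0.05) == pytest.approx(
            0.05 / 5050
        )
        assert bwas.fwe_threshold(
            res, "fixed_p", fixed_p_value=7.22e-48
        ) == pytest.approx(7.22e-48)
        assert res.correction == "fixed_p"

    def test_single_link_equals_family_alpha(self):
        res = _dummy_result(2)
        assert bwas.fwe_threshold(res, "bonferroni", 0.04) == pytest.approx(0.04)

    def test_invalid_inputs(self):
        res = _dummy_result(4)
        with pytest.raises(ValueError):
            bwas.fwe_threshold(res, "bonferroni", 1.5)
        with pytest.raises(ValueError):
            bwas.fwe_threshold(res, "fixed_p", fixed_p_value=0.0)


def _dummy_result(n_voxels, p=None, seed=0):
    n_links = n_voxels * (n_voxels - 1) // 2
    rng = np.random.default_rng(seed)
    if p is None:
        p = rng.uniform(size=n_links)
    zeros = np.zeros(n_links)
    return bwas.LinkTestResult(
        n_voxels=n_voxels,
        t=zeros,
        p=p,
        df=10,
        mean_a=zeros,
        mean_b=zeros,
        group_a="A",
        group_b="B",
    )


class TestMAMap:
    def test_degenerate_maps(self):
        res = _dummy_result(4, p=np.ones(6))
        assert bwas.ma_map(res, 0.5).values.tolist() == [0, 0, 0, 0]
        # exactly the pairs (0,1) and (0,2) below alpha
        p = np.ones(6)
        p[[0, 1]] = 1e-4  # triu order: (0,1), (0,2), ...
        res = _dummy_result(4, p=p)
        assert bwas.ma_map(res, 1e-3).values.tolist() == [2, 1, 1, 0]

    def test_brute_force_oracle(self):
        for trial in range(20):
            res = _dummy_result(30, seed=trial)
            alpha = 0.2
            ma = bwas.ma_map(res, alpha)
            pm = res.p_matrix()
            expected = [
                sum(1 for j in range(30) if j != i and pm[i, j] < alpha)
                for i in range(30)
            ]
            assert ma.values.tolist() == expected

    def test_sum_equals_twice_supra_links(self):
        res = _dummy_result(25, seed=5)
        alpha = 0.1
        ma = bwas.ma_map(res, alpha)
        assert ma.values.sum() == 2 * int((res.p < alpha).sum())


def _flood_fill(mask, conn26=True):
    """Brute-force connected components for the cluster oracle."""
    from collections import deque

    labels = np.zeros(mask.shape, int)
    nxt = 0
    offs = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
        and (conn26 or abs(a) + abs(b) + abs(c) == 1)
    ]
    for start in map(tuple, np.argwhere(mask)):
        if labels[start]:
            continue
        nxt += 1
        q = deque([start])
        labels[start] = nxt
        while q:
            x, y, z = q.popleft()
            for a, b, c in offs:
                n = (x + a, y + b, z + c)
                if all(0 <= n[k] < mask.shape[k] for k in range(3)) and mask[n] and not labels[n]:
                    labels[n] = nxt
                    q.append(n)
    return labels


def _ma_from_volume(vol, atlas=None):
    grid = np.argwhere(vol >= 0)
    values = vol[tuple(grid.T)]
    return bwas.MAMap(
        values=values,
        alpha_link=0.01,
        voxel_grid=grid,
        grid_shape=vol.shape,
        affine=np.diag([2.0, 2.0, 2.0, 1.0]),
        atlas_labels=atlas[tuple(grid.T)] if atlas is not None else None,
    )


class TestExtractRoiClusters:
    def test_straight_line_cluster(self):
        vol = np.zeros((5, 5, 5), int)
        vol[1, 1, 1:4] = 50
        rois = bwas.extract_roi_clusters(_ma_from_volume(vol), 40, min_size=2)
        assert len(rois) == 1
        assert rois[0].size == 3
        assert rois[0].peak_ma == 50

    def test_strict_size_threshold(self):
        vol = np.zeros((6, 6, 6), int)
        flat = np.argwhere(vol == 0)[:99]
        vol[tuple(flat.T)] = 60
        rois = bwas.extract_roi_clusters(_ma_from_volume(vol), 40, min_size=100)
        assert len(rois) == 0
        rois = bwas.extract_roi_clusters(_ma_from_volume(vol), 40, min_size=98)
        assert len(rois) == 1

    def test_flood_fill_oracle(self):
        rng = np.random.default_rng(11)
        vol = np.where(rng.random((20, 20, 20)) < 0.2, 50, 0)
        rois = bwas.extract_roi_clusters(_ma_from_volume(vol), 40, min_size=0)
        oracle = _flood_fill(vol > 40)
        n_oracle = {
            lbl: int((oracle == lbl).sum()) for lbl in range(1, oracle.max() + 1)
        }
        assert sorted(r.size for r in rois) == sorted(n_oracle.values())
        # membership agreement: each ROI maps onto exactly one oracle label
        grid = np.argwhere(vol >= 0)
        for roi in rois:
            labels = {oracle[tuple(grid[v])] for v in roi.voxel_indices}
            assert len(labels) == 1

    def test_voxel_order_invariance(self):
        rng = np.random.default_rng(4)
        vol = np.where(rng.random((8, 8, 8)) < 0.3, 45, 0)
        ma = _ma_from_volume(vol)
        perm = rng.permutation(ma.n_voxels)
        ma_perm = bwas.MAMap(
            values=ma.values[perm],
            alpha_link=ma.alpha_link,
            voxel_grid=ma.voxel_grid[perm],
            grid_shape=ma.grid_shape,
            affine=ma.affine,
        )
        a = bwas.extract_roi_clusters(ma, 40, min_size=1)
        b = bwas.extract_roi_clusters(ma_perm, 40, min_size=1)
        coords = lambda rs, m: sorted(
            tuple(sorted(map(tuple, m.voxel_grid[r.voxel_indices]))) for r in rs
        )
        assert coords(a, ma) == coords(b, ma_perm)

    def test_majority_atlas_label_and_peak(self):
        vol = np.zeros((4, 4, 4), int)
        vol[0, 0, 0:3] = [50, 60, 50]
        atlas = np.ones((4, 4, 4), int)
        atlas[0, 0, 1:3] = 7
        rois = bwas.extract_roi_clusters(_ma_from_volume(vol, atlas), 40, min_size=1)
        assert rois[0].atlas_label == 7
        assert rois[0].peak_ma == 60
        np.testing.assert_allclose(rois[0].peak_mni, [0, 0, 2])


def test_permuted_labels_leave_max_t_exchangeable():
    """Null-data max |t| is unexceptional among label permutations."""
    ts = make_timeseries(n_subjects=12, n_timepoints=60, n_voxels=8, seed=21,
                         groups=list("AAAAAABBBBBB"))
    obs = np.abs(bwas.link_group_test(ts, "A", "B").t).max()
    rng = np.random.default_rng(0)
    perm_stats = []
    for _ in range(19):
        subj = ts.subjects.copy()
        subj["group"] = rng.permutation(subj["group"].to_numpy())
        ts_p = make_timeseries(data=ts.data, groups=list(subj["group"]))
        perm_stats.append(np.abs(bwas.link_group_test(ts_p, "A", "B").t).max())
    assert obs <= max(perm_stats)


def test_nifti_round_trip(tmp_path):
    """BOLD + atlas NIfTI files load into the same arrays they were built from."""
    import nibabel as nib

    rng = np.random.default_rng(13)
    shape = (4, 4, 3)
    atlas = np.zeros(shape, np.int16)
    atlas[1:3, 1:3, :] = rng.integers(1, 4, (2, 2, 3))
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    nib.Nifti1Image(atlas, affine).to_filename(str(tmp_path / "atlas.nii.gz"))
    paths = []
    vols = []
    for s in range(4):
        vol = rng.standard_normal(shape + (30,))
        paths.append(tmp_path / f"sub{s}.nii.gz")
        nib.Nifti1Image(vol, affine).to_filename(str(paths[-1]))
        vols.append(vol)
    subjects = pd.DataFrame(
        {"subject_id": [f"s{k}" for k in range(4)], "group": ["A", "A", "B", "B"]}
    )
    ts = bwas.load_timeseries(paths, tmp_path / "atlas.nii.gz", subjects)
    assert ts.n_voxels == int((atlas > 0).sum())
    grid = np.argwhere(atlas > 0)
    np.testing.assert_allclose(ts.data[2], vols[2][tuple(grid.T)].T, rtol=1e-6)
    np.testing.assert_array_equal(ts.atlas_labels, atlas[tuple(grid.T)])
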