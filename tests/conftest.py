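import numpy as np
import pandas as pd
import pytest

from ctpipe import ahba, bwas


def make_timeseries(
    n_subjects=6,
    n_timepoints=80,
    n_voxels=12,
    groups=None,
    seed=0,
    data=None,
    covariates=None,
):
    """Hand-built VoxelTimeSeriesSet on a small 3D grid."""
    rng = np.random.default_rng(seed)
    if data is None:
        data = rng.standard_normal((n_subjects, n_timepoints, n_voxels))
    n_subjects = data.shape[0]
    n_voxels = data.shape[2]
    if groups is None:
        groups = ["A"] * (n_subjects // 2) + ["B"] * (n_subjects - n_subjects // 2)
    shape = (max(2, int(np.ceil(n_voxels ** (1 / 3)))),) * 3
    while np.prod(shape) < n_voxels:
        shape = (shape[0] + 1,) + shape[1:]
    grid = np.argwhere(np.ones(shape, bool))[:n_voxels]
    subjects = pd.DataFrame(
        {"subject_id": [f"s{i}" for i in range(n_subjects)], "group": groups}
    )
    if covariates is not None:
        for name, vals in covariates.items():
            subjects[name] = vals
    return bwas.VoxelTimeSeriesSet(
        data=data,
        voxel_grid=grid,
        grid_shape=shape,
        affine=np.diag([2.0, 2.0, 2.0, 1.0]),
        atlas_labels=np.ones(n_voxels, int),
        subjects=subjects,
    )


def make_bundle(
    donor_id="D1",
    expression=None,
    genes=("GA", "GB"),
    probes_per_gene=1,
    n_samples=8,
    seed=0,
    rnaseq=None,
    above=None,
    coords=None,
):
    """Small DonorExpressionBundle with one or more probes per gene."""
    rng = np.random.default_rng(seed)
    probe_ids, probe_gene = [], []
    for g in genes:
        for k in range(probes_per_gene):
            probe_ids.append(f"{g}_p{k}")
            probe_gene.append(g)
    samples = [f"{donor_id}_s{i}" for i in range(n_samples)]
    if expression is None:
        expression = pd.DataFrame(
            8 + rng.standard_normal((len(probe_ids), n_samples)),
            index=probe_ids,
            columns=samples,
        )
    else:
        expression = pd.DataFrame(expression, index=probe_ids, columns=samples)
    if rnaseq is None:
        rnaseq = pd.DataFrame(
            [expression.loc[[p for p, g2 in zip(probe_ids, probe_gene) if g2 == g]].mean()
             for g in genes],
            index=list(genes),
        )
    elif isinstance(rnaseq, dict):
        rnaseq = pd.DataFrame(
            np.vstack([rnaseq[g] for g in genes]), index=list(genes), columns=samples
        )
    else:
        rnaseq = pd.DataFrame(np.asarray(rnaseq), index=list(genes), columns=samples)
    if above is None:
        above = pd.DataFrame(True, index=probe_ids, columns=samples)
    else:
        above = pd.DataFrame(above, index=probe_ids, columns=samples)
    if coords is None:
        coords = pd.DataFrame(
            rng.uniform(0, 10, (n_samples, 3)),
            index=pd.Index(samples, name="sample_id"),
            columns=["x", "y", "z"],
        )
    return ahba.DonorExpressionBundle(
        donor_id=donor_id,
        expression=expression,
        probe_map=pd.DataFrame(
            {"gene": probe_gene}, index=pd.Index(probe_ids, name="probe_id")
        ),
        above_background=above,
        rnaseq=rnaseq,
        coordinates=coords,
    )


@pytest.fixture(scope="session")
def table1():
    """Published three-group demographic/clinical summaries."""
    from ctpipe.clinstats import GroupSummary as G

    return {
        "age": [G(118, 50.76, 7.60), G(89, 49.18, 7.96), G(66, 51.20, 8.31)],
        "TIV": [G(118, 1528.49, 117.50), G(89, 1443.71, 115.04), G(66, 1471.35, 112.23)],
        "SDS": (G(89, 4.81, 2.251), G(66, 12.77, 2.976)),
        "SANS": (G(89, 33.89, 8.80), G(66, 55.58, 11.60)),
        "SAPS": (G(89, 9.72, 4.54), G(66, 8.91, 3.64)),
        "CPZ": (G(89, 560.94, 210.67), G(66, 532.21, 213.39)),
    }
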