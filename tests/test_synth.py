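import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctpipe import ahba, bwas, synth
from ctpipe.assoc import sample_sphere_ma


def _two_group_spec(**kw):
    defaults = dict(
        n_per_group={"CN": 12, "DS": 12},
        n_voxels=21,
        n_timepoints=120,
        covariate_model={g: synth.DEFAULT_COVARIATE_MODEL[g] for g in ("CN", "DS")},
        seed=0,
    )
    defaults.update(kw)
    return synth.CohortSpec(**defaults)


class TestBoldCohort:
    def test_determinism(self):
        spec = _two_group_spec(seed=5)
        a = synth.generate_bold_cohort(spec)
        b = synth.generate_bold_cohort(_two_group_spec(seed=5))
        np.testing.assert_array_equal(a.data, b.data)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)

    def test_null_type_one_rate(self):
        """No planted links: uncorrected alpha=0.05 hits ~5% of links."""
        spec = _two_group_spec(
            n_per_group={"CN": 40, "DS": 40}, n_voxels=21, seed=1
        )
        ts = synth.generate_bold_cohort(spec)
        res = bwas.link_group_test(ts, "CN", "DS")
        n_links = len(res.p)  # 210
        hits = int((res.p < 0.05).sum())
        sd = np.sqrt(n_links * 0.05 * 0.95)
        assert abs(hits - 0.05 * n_links) <= 3 * sd

    def test_planted_link_correlations_converge(self):
        link = synth.PlantedLink(1, 4, {"DS": 0.5})
        gaps = []
        for t_len in (100, 2000):
            spec = _two_group_spec(
                n_per_group={"CN": 4, "DS": 4},
                n_timepoints=t_len,
                planted_links=[link],
                base_r=0.2,
                seed=3,
            )
            ts = synth.generate_bold_cohort(spec)
            ds = ts.subjects["group"] == "DS"
            rs = [np.corrcoef(ts.data[s][:, [1, 4]].T)[0, 1]
                  for s in np.flatnonzero(ds.to_numpy())]
            gaps.append(abs(np.mean(rs) - 0.7))
        assert gaps[1] < gaps[0]
        assert gaps[1] < 0.05

    def test_planted_power_exceeds_fwe_threshold(self):
        """A Delta-r = 0.5 link at n=60/group crosses the corrected threshold."""
        for seed in range(5):
            spec = _two_group_spec(
                n_per_group={"CN": 60, "DS": 60},
                n_voxels=15,
                n_timepoints=240,
                planted_links=[synth.PlantedLink(0, 7, {"DS": 0.5})],
                base_r=0.1,
                seed=seed,
            )
            ts = synth.generate_bold_cohort(spec)
            res = bwas.link_group_test(ts, "CN", "DS")
            alpha = bwas.fwe_threshold(res, "bonferroni", 0.01)
            iu = np.triu_indices(15, k=1)
            planted = np.flatnonzero((iu[0] == 0) & (iu[1] == 7))[0]
            assert res.p[planted] < alpha

    def test_infeasible_correlation_rejected(self):
        links = [
            synth.PlantedLink(0, 1, {"DS": 0.75}),
            synth.PlantedLink(1, 2, {"DS": 0.75}),
            synth.PlantedLink(0, 2, {"DS": -1.1}),
        ]
        spec = _two_group_spec(planted_links=links, base_r=0.2)
        with pytest.raises(ValueError, match="offending links"):
            synth.generate_bold_cohort(spec)

    def test_invalid_target_correlation(self):
        with pytest.raises(ValueError, match="outside"):
            _two_group_spec(planted_links=[synth.PlantedLink(0, 1, {"DS": 0.9})],
                            base_r=0.2)


class TestClinicalScores:
    def _fc(self, spec, values):
        ids = [f"{g}{i:03d}" for g in spec.groups for i in range(spec.n_per_group[g])]
        return pd.DataFrame(
            {"subject_id": ids, "group": [s[:2] for s in ids], "fc": values}
        )

    def test_noiseless_line_recovers_coupling(self):
        spec = _two_group_spec(
            n_per_group={"DS": 20}, score_coupling=-2.0, score_noise_sd=0.0
        )
        fc = self._fc(spec, np.linspace(-1, 1, 20))
        scores = synth.generate_clinical_scores(spec, fc)
        res = stats.linregress(fc["fc"], scores["SDS"])
        assert res.slope == pytest.approx(-2.0)
        assert res.rvalue == pytest.approx(-1.0)

    def test_null_coupling_slope_within_3se(self):
        spec = _two_group_spec(
            n_per_group={"DS": 80}, score_coupling=0.0, score_noise_sd=1.0, seed=4
        )
        fc = self._fc(spec, np.random.default_rng(1).standard_normal(80))
        scores = synth.generate_clinical_scores(spec, fc)
        res = stats.linregress(fc["fc"], scores["SDS"])
        assert abs(res.slope) < 3 * res.stderr

    def test_slope_recovered_within_sampling_error(self):
        hits = 0
        for seed in range(10):
            spec = _two_group_spec(
                n_per_group={"DS": 155}, score_coupling=-1.0,
                score_noise_sd=0.5, seed=seed,
            )
            fc = self._fc(spec, np.random.default_rng(seed).standard_normal(155))
            scores = synth.generate_clinical_scores(spec, fc)
            res = stats.linregress(fc["fc"], scores["SDS"])
            hits += abs(res.slope - (-1.0)) < 2 * res.stderr
        assert hits >= 9

    def test_unknown_subjects_rejected(self):
        spec = _two_group_spec()
        fc = pd.DataFrame({"subject_id": ["zz9"], "group": ["CN"], "fc": [0.1]})
        with pytest.raises(ValueError, match="subject ids"):
            synth.generate_clinical_scores(spec, fc)


def _small_ma(seed=0):
    spec = _two_group_spec(
        n_voxels=60,
        n_per_group={"CN": 20, "DS": 20},
        planted_links=[
            synth.PlantedLink(i, j, {"DS": 0.5})
            for i in range(10)
            for j in range(10)
            if i < j
        ],
        seed=seed,
    )
    ts = synth.generate_bold_cohort(spec)
    res = bwas.link_group_test(ts, "CN", "DS")
    alpha = bwas.fwe_threshold(res, "bonferroni", 0.01)
    return bwas.ma_map(res, alpha, ts)


class TestDonorExpression:
    def _spec(self, **kw):
        defaults = dict(
            n_donors=2, n_samples_per_donor=40, n_probes=30, n_genes=24,
            n_pos_coupled=5, n_neg_coupled=5, seed=0,
        )
        defaults.update(kw)
        return synth.DonorSpec(**defaults)

    def test_determinism(self):
        ma = _small_ma()
        a = synth.generate_donor_expression(self._spec(), ma)
        b = synth.generate_donor_expression(self._spec(), ma)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.expression, y.expression)
            pd.testing.assert_frame_equal(x.coordinates, y.coordinates)

    def test_coupled_genes_track_ma_with_planted_sign(self):
        ma = _small_ma()
        spec = self._spec(n_samples_per_donor=150, coupling=0.9, noise_sd=0.1)
        bundle = synth.generate_donor_expression(spec, ma)[0]
        m = sample_sphere_ma(ma, bundle.coordinates, spec.ma_radius)
        pos_probe = bundle.expression.loc["P00000"]  # primary probe, gene G0000
        neg_probe = bundle.expression.loc[f"P{spec.n_pos_coupled:05d}"]
        assert np.corrcoef(pos_probe, m)[0, 1] > 0.5
        assert np.corrcoef(neg_probe, m)[0, 1] < -0.5

    def test_planted_probe_failures_by_construction(self):
        ma = _small_ma()
        spec = self._spec(
            frac_probe_low_intensity=0.2, frac_probe_discordant=0.2, n_donors=3
        )
        bundles = synth.generate_donor_expression(spec, ma)
        kept = set(ahba.intensity_filter(bundles))
        n_low = round(0.2 * spec.n_probes)
        assert len(kept) == spec.n_probes - n_low
        kept2, rho = ahba.rnaseq_concordance_filter(bundles, sorted(kept))
        n_disc = round(0.2 * spec.n_probes)
        assert len(kept2) <= len(kept) - n_disc
        # every coupled gene keeps a clean probe through both filters
        gene_of = bundles[0].probe_map["gene"]
        surviving = {gene_of[p] for p in kept2}
        for g in spec.positive_genes + spec.negative_genes:
            assert g in surviving

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="few samples"):
            self._spec(n_samples_per_donor=5)

    def test_probe_gene_consistency(self):
        with pytest.raises(ValueError, match="probe per gene"):
            self._spec(n_probes=10, n_genes=24)


class TestDiseaseGeneList:
    def test_full_fraction_returns_all(self):
        genes = [f"G{i}" for i in range(30)]
        assert synth.generate_disease_gene_list(genes, 1.0) == genes

    def test_zero_overlap_is_disjoint(self):
        genes = [f"G{i}" for i in range(30)]
        planted = genes[:10]
        out = synth.generate_disease_gene_list(
            genes, 0.5, planted_genes=planted, overlap_with_planted=0.0, seed=1
        )
        assert len(out) == 15
        assert not set(out) & set(planted)

    def test_exact_count(self):
        genes = [f"G{i}" for i in range(500)]
        out = synth.generate_disease_gene_list(genes, 0.2, seed=2)
        assert len(out) == 100

    def test_overlap_exceeding_planted_rejected(self):
        genes = [f"G{i}" for i in range(30)]
        with pytest.raises(ValueError, match="planted-gene count"):
            synth.generate_disease_gene_list(
                genes, 0.5, planted_genes=genes[:3], overlap_with_planted=5, seed=0
            )


def test_parcellations_cover_grid_deterministically():
    parcs = synth.make_parcellations((6, 5, 5), np.eye(4), (8, 12), seed=3)
    again = synth.make_parcellations((6, 5, 5), np.eye(4), (8, 12), seed=3)
    for name in parcs:
        assert (parcs[name].volume > 0).all()
        assert len(np.unique(parcs[name].volume)) == int(name[4:])
        np.testing.assert_array_equal(parcs[name].volume, again[name].volume)
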