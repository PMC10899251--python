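"""End-to-end orchestration of the synthetic connectome-transcriptome study.

``run_pipeline`` executes the stage chain synth -> bwas -> classify ->
clinstats -> expression preprocessing -> consensus WGCNA -> association in
dependency order from a single config dict, stamps every artifact with the
config hash and seed, and is bit-identical on rerun with the same config.

The default config is the reduced-scale demo study: 150 voxels at 6 mm, 40
subjects per group, 300 genes, with connectivity differences planted in
spatially separated voxel blocks and expression of the coupled genes
tracking the NDS-contrast MA map.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import ahba, assoc, bwas, classify, clinstats, synth, wgcna

__all__ = ["DEFAULT_CONFIG", "demo_config", "run_pipeline"]


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {"classify": True, "clinstats": True, "expression": True},
    "cohort": {
        "n_per_group": {"CN": 40, "NDS": 40, "DS": 40},
        "n_voxels": 150,
        "n_timepoints": 240,
        "base_r": 0.2,
        "voxel_size_mm": 6.0,
        # equicorrelated voxel blocks, each spanning two spatially separate
        # ranges so the planted effect shows up in cross-ROI connectivity;
        # delta adds to base_r for the named group
        "blocks": [
            {"voxels": [[0, 10], [15, 25]], "delta": {"DS": 0.45, "NDS": 0.45}},
            {"voxels": [[50, 60], [65, 75]], "delta": {"DS": 0.45, "NDS": 0.45}},
            {"voxels": [[25, 35], [40, 50]], "delta": {"NDS": 0.45}},
        ],
        "score_coupling": -20.0,
        "score_noise_sd": 1.0,
    },
    "bwas": {
        "covariates": ["age", "education", "TIV", "FD"],
        "fwe_method": "bonferroni",
        "family_alpha": 0.01,
        "fixed_p_value": None,
        "ma_threshold": 5,
        "min_cluster_size": 5,
        "connectivity": 26,
        "contrasts": [["CN", "DS"], ["CN", "NDS"]],
    },
    "classify": {"model": "lda", "reducer": "pca", "dims": None},
    "clinstats": {"score": "SDS", "fdr_q": 0.05, "patient_group_only": True},
    "expression": {
        "coupled_to": "NDS",
        "donors": {
            "n_donors": 6,
            "n_samples_per_donor": 200,
            "n_probes": 360,
            "n_genes": 300,
            "spatial_field": 8.0,
            "n_pos_coupled": 60,
            "n_neg_coupled": 60,
            "coupling": 0.9,
            "noise_sd": 0.1,
            "ma_radius": 14.0,
        },
        "parcellations": [12, 18, 24, 30],
        "max_distance_mm": 8.0,
        "intensity_min_fraction": 0.5,
        "rnaseq_min_rho": 0.2,
        "dss_threshold": 0.5,
        "min_module_size": 30,
        "cut_height": 0.99,
        "radii": [4.0, 6.0, 8.0],
        "q_threshold": 0.05,
        "key_gene_r": 0.7,
        "disease_fraction": 0.5,
        "disease_overlap": 1.0,
    },
}


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _deep_update(base: dict, overrides: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (overrides or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def demo_config(seed: int = 0, overrides: dict | None = None) -> dict:
    cfg = _deep_update(DEFAULT_CONFIG, overrides or {})
    cfg["seed"] = int(seed)
    return cfg


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _cohort_spec(config: dict) -> synth.CohortSpec:
    c = config["cohort"]
    links = []
    for block in c["blocks"]:
        ranges = block["voxels"]
        if ranges and not isinstance(ranges[0], (list, tuple)):
            ranges = [ranges]
        members = [v for lo, hi in ranges for v in range(lo, hi)]
        links += [
            synth.PlantedLink(i, j, dict(block["delta"]))
            for i in members
            for j in members
            if i < j
        ]
    return synth.CohortSpec(
        n_per_group=dict(c["n_per_group"]),
        n_voxels=c["n_voxels"],
        n_timepoints=c["n_timepoints"],
        planted_links=links,
        base_r=c["base_r"],
        voxel_size_mm=c["voxel_size_mm"],
        score_coupling=c["score_coupling"],
        score_noise_sd=c["score_noise_sd"],
        seed=config["seed"],
    )


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Run the configured stage chain; return all stage results.

    When ``out_dir`` is given, artifacts (MA maps, ROI tables, feature and
    regression CSVs, module assignments, gene-set ledger JSON, and a
    provenance log with the config hash) are written there.
    """
    config = _deep_update(DEFAULT_CONFIG, config or {})
    seed = config["seed"]
    results: dict = {"config": config, "config_hash": _config_hash(config)}

    spec = _cohort_spec(config)
    ts = synth.generate_bold_cohort(spec)
    results["cohort"] = ts

    # --- brain-wide association per contrast -----------------------------
    bw = config["bwas"]
    contrasts = {}
    for group_a, group_b in bw["contrasts"]:
        res = bwas.link_group_test(ts, group_a, group_b, tuple(bw["covariates"]))
        alpha = bwas.fwe_threshold(
            res,
            method=bw["fwe_method"],
            family_alpha=bw["family_alpha"],
            fixed_p_value=bw["fixed_p_value"],
        )
        ma = bwas.ma_map(res, alpha, ts)
        rois = bwas.extract_roi_clusters(
            ma,
            ma_threshold=bw["ma_threshold"],
            min_size=bw["min_cluster_size"],
            connectivity=bw["connectivity"],
        )
        contrasts[group_b] = {"test": res, "alpha_link": alpha, "ma": ma, "rois": rois}
    results["bwas"] = contrasts

    # --- classification and clinical statistics --------------------------
    if config["stages"]["classify"]:
        cl = config["classify"]
        reports = {}
        for cond, c in contrasts.items():
            if len(c["rois"]) < 2:
                continue
            feats = classify.roi_pair_features(ts, c["rois"])
            mask = feats["group"].isin(["CN", cond])
            reports[cond] = classify.loocv_classify(
                feats[mask].reset_index(drop=True),
                model=cl["model"],
                reducer=cl["reducer"],
                dims=cl["dims"],
                seed=seed,
                pos_label=cond,
            )
            c["features"] = feats
        results["classify"] = reports

    if config["stages"]["clinstats"]:
        cs = config["clinstats"]
        regressions = {}
        scores = None
        for cond, c in contrasts.items():
            if "features" not in c:
                if len(c["rois"]) < 2:
                    continue
                c["features"] = classify.roi_pair_features(ts, c["rois"])
            feats = c["features"]
            if scores is None:
                scores = synth.generate_clinical_scores(
                    spec, feats[["subject_id", "group"]].join(feats.filter(like="ROI"))
                )
            sub = feats[feats["group"] == cond] if cs["patient_group_only"] else feats
            regressions[cond] = clinstats.fc_score_regression(
                sub.reset_index(drop=True),
                scores,
                cs["score"],
                fdr_q=cs["fdr_q"],
            )
        results["scores"] = scores
        results["clinstats"] = regressions

    # --- expression, consensus modules, association ----------------------
    if config["stages"]["expression"]:
        ex = config["expression"]
        dspec = synth.DonorSpec(seed=seed, **ex["donors"])
        ma_ref = contrasts[ex["coupled_to"]]["ma"]
        bundles = synth.generate_donor_expression(dspec, ma_ref)
        parcs = synth.make_parcellations(
            ts.grid_shape, ts.affine, ex["parcellations"], seed=seed
        )
        prep = ahba.preprocess_bundles(
            bundles,
            parcs,
            min_fraction=ex["intensity_min_fraction"],
            min_rho=ex["rnaseq_min_rho"],
            max_distance_mm=ex["max_distance_mm"],
            dss_threshold=ex["dss_threshold"],
        )
        results["bundles"] = bundles
        results["ahba"] = prep

        # consensus network over the union of per-parcellation retained genes
        union_genes = sorted(set().union(*prep.retained_genes.values()))
        if len(union_genes) < 20:
            raise RuntimeError("too few DSS-stable genes for network construction")
        mats = {
            name: m[ [g for g in union_genes if g in m.columns] ]
            for name, m in prep.region_matrices.items()
        }
        first = next(iter(mats.values()))
        beta, fit = wgcna.pick_soft_threshold(first)
        networks = [wgcna.signed_tom(mats[name][first.columns], beta) for name in mats]
        modules = wgcna.consensus_modules(
            networks,
            min_module_size=ex["min_module_size"],
            cut_height=ex["cut_height"],
        )
        results["wgcna"] = {"beta": beta, "fit": fit, "modules": modules}

        # per-parcellation module eigengenes on the pooled sample matrix,
        # restricted to that parcellation's DSS-stable genes
        ledgers = {}
        associations = {}
        module_gene_sets = {}
        mes_by_parc = {}
        for name in parcs:
            retained = set(prep.retained_genes[name])
            gene_sets = {}
            mes = {}
            for m in modules.modules:
                genes = [g for g in modules.module_genes(m) if g in retained]
                if len(genes) < 2:
                    continue
                me, _ve = wgcna.module_eigengene(prep.sample_expr, genes)
                gene_sets[m] = genes
                mes[m] = me
            if not mes:
                continue
            module_gene_sets[name] = gene_sets
            mes_by_parc[name] = pd.DataFrame(mes, index=prep.sample_expr.index)

        for cond in [c[1] for c in bw["contrasts"]]:
            profiles = assoc.sphere_ma_profiles(
                contrasts[cond]["ma"], prep.sample_coords, radii=ex["radii"]
            )
            per_parc = {
                name: assoc.module_ma_association(
                    mes_by_parc[name],
                    profiles,
                    q_threshold=ex["q_threshold"],
                    parcellation=name,
                )
                for name in mes_by_parc
            }
            associations[cond] = per_parc
            ledger = assoc.derive_signed_gene_sets(
                module_gene_sets, per_parc, condition=cond
            )
            disease = synth.generate_disease_gene_list(
                dspec.genes,
                fraction=ex["disease_fraction"],
                planted_genes=dspec.positive_genes + dspec.negative_genes,
                overlap_with_planted=ex["disease_overlap"],
                seed=seed,
            )
            ledger = assoc.intersect_disease_genes(ledger, disease)
            ledger.provenance["key_genes_positive"] = sorted(
                assoc.key_genes(prep.sample_expr, ledger.positive, ex["key_gene_r"])
            ) if len(ledger.positive) >= 2 else []
            ledger.provenance["key_genes_negative"] = sorted(
                assoc.key_genes(prep.sample_expr, ledger.negative, ex["key_gene_r"])
            ) if len(ledger.negative) >= 2 else []
            ledgers[cond] = ledger

        results["associations"] = associations
        results["ledgers"] = ledgers
        conds = list(ledgers)
        if len(conds) == 2:
            results["overlap"] = assoc.condition_overlap(
                ledgers[conds[0]], ledgers[conds[1]]
            )

    if out_dir is not None:
        _write_artifacts(results, Path(out_dir))
    return results


def _write_artifacts(results: dict, out_dir: Path) -> None:
    import h5py

    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = results["config"]
    ts = results["cohort"]
    ts.subjects.to_csv(out_dir / "subjects.csv", index=False)
    for cond, c in results["bwas"].items():
        c["ma"].to_nifti().to_filename(str(out_dir / f"ma_{cond}.nii.gz"))
        c["rois"].to_frame().to_csv(out_dir / f"rois_{cond}.csv", index=False)
        with h5py.File(out_dir / f"linktest_{cond}.h5", "w") as h5:
            h5.create_dataset("t", data=c["test"].t)
            h5.create_dataset("p", data=c["test"].p)
            h5.attrs["alpha_link"] = c["alpha_link"]
            h5.attrs["df"] = c["test"].df
        if "features" in c:
            c["features"].to_csv(out_dir / f"features_{cond}.csv", index=False)
    if results.get("scores") is not None:
        results["scores"].to_csv(out_dir / "scores.csv", index=False)
    for cond, rep in (results.get("classify") or {}).items():
        (out_dir / f"classifier_{cond}.json").write_text(
            json.dumps(
                {
                    "accuracy": rep.accuracy,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                    "auc": rep.auc,
                    "model": rep.model,
                    "reducer": rep.reducer,
                    "reducer_dim": rep.reducer_dim,
                },
                indent=2,
                sort_keys=True,
                default=_json_default,
            )
        )
    for cond, reg in (results.get("clinstats") or {}).items():
        reg.to_csv(out_dir / f"regression_{cond}.csv", index=False)
    if "ahba" in results:
        prep = results["ahba"]
        for name, mat in prep.region_matrices.items():
            mat.to_csv(out_dir / f"region_expression_{name}.tsv", sep="\t")
        modules = results["wgcna"]["modules"]
        pd.DataFrame({"gene": modules.genes, "module": modules.labels}).to_csv(
            out_dir / "modules.csv", index=False
        )
        ledger_doc = {
            cond: ledger.to_dict() for cond, ledger in results["ledgers"].items()
        }
        if "overlap" in results:
            ledger_doc["overlap"] = results["overlap"]
        (out_dir / "ledger.json").write_text(
            json.dumps(ledger_doc, indent=2, sort_keys=True, default=_json_default)
        )
        assoc_tables = [
            tbl
            for per_parc in results["associations"].values()
            for tbl in per_parc.values()
        ]
        if assoc_tables:
            pd.concat(
                [
                    tbl.assign(condition=cond)
                    for cond, per_parc in results["associations"].items()
                    for tbl in per_parc.values()
                ]
            ).to_csv(out_dir / "module_ma_association.csv", index=False)
    provenance = {
        "config": cfg,
        "config_hash": results["config_hash"],
        "seed": cfg["seed"],
        "ahba_provenance": results["ahba"].provenance if "ahba" in results else None,
        "wgcna_beta": results["wgcna"]["beta"] if "wgcna" in results else None,
    }
    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True, default=_json_default)
    )
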