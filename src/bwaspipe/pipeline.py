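"""Top-level orchestration: prep -> link tests -> MA -> ROIs -> cognition
-> reliability, with a JSON manifest of every output, parameter and seed."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

import bwaspipe
from bwaspipe import io
from bwaspipe.bwas import corrected_p, run_bwas
from bwaspipe.cognition import circuit_cognition_screen, compute_composites
from bwaspipe.config import PipelineConfig
from bwaspipe.errors import BwasError
from bwaspipe.prep import prep_subject
from bwaspipe.reliability import half_split_cross_validation, half_split_ma
from bwaspipe.roi import define_rois, roi_fc_matrix, roi_fc_table_test
from bwaspipe.types import ClusterSet, LinkTestTable, ROISet, VoxelCohort

log = logging.getLogger("bwaspipe")


def links_to_frame(links: LinkTestTable, cohort: VoxelCohort) -> pd.DataFrame:
    """Significant-link table with world coordinates and corrected p."""
    coords = cohort.voxel_coords
    world = cohort.world_coords(coords)
    wi, wj = world[links.i], world[links.j]
    return pd.DataFrame(
        {
            "i": links.i,
            "j": links.j,
            "x_i": wi[:, 0], "y_i": wi[:, 1], "z_i": wi[:, 2],
            "x_j": wj[:, 0], "y_j": wj[:, 1], "z_j": wj[:, 2],
            "t": links.t_stat,
            "p": links.p_value,
            "p_corrected": corrected_p(links.p_value, links.n_links),
        }
    )


def clusters_to_frame(clusters: ClusterSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "size": c.size,
                "peak_ma": c.peak_ma,
                "peak_x": c.peak_world[0],
                "peak_y": c.peak_world[1],
                "peak_z": c.peak_world[2],
            }
            for c in clusters
        ]
    )


def rois_to_frame(rois: ROISet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "region": r.name,
                "voxels_in_roi": r.n_voxels,
                "peak_ma": r.peak_ma,
                "peak_x": r.peak_world[0],
                "peak_y": r.peak_world[1],
                "peak_z": r.peak_world[2],
            }
            for r in rois
        ]
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages; write outputs and return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": bwaspipe.__version__,
        "parameters": {
            "alpha": config.bwas.alpha,
            "family_convention": config.bwas.family_convention,
            "ma_min": config.bwas.ma_min,
            "min_cluster_voxels": config.bwas.min_cluster_voxels,
            "connectivity": config.bwas.connectivity,
            "roi_min_voxels": config.bwas.roi_min_voxels,
            "q": config.roi.q,
            "n_boot": config.cognition.n_boot,
            "seed": config.cognition.seed,
            "covariates_link": list(config.bwas.covariates),
            "covariates_cognition": list(config.cognition.covariates),
        },
        "counts": {},
        "outputs": {},
    }

    stage = {"name": "init"}

    def _stage(name):
        stage["name"] = name
        log.info("stage: %s", name)

    try:
        _stage("load")
        cohort = io.read_cohort(config.cohort_dir, config.mask_path)
        phenotype = io.read_phenotype(config.phenotype_path)
        phenotype = phenotype.set_index("subject_id").loc[
            cohort.subject_ids
        ].reset_index()
        if config.run_prep:
            _stage("prep")
            prepped = np.empty_like(cohort.data)
            for s, sid in enumerate(cohort.subject_ids):
                motion = io.read_motion(Path(config.motion_dir) / f"{sid}_motion.txt")
                vol = np.zeros((*cohort.mask.shape, cohort.n_timepoints))
                vol[cohort.mask] = cohort.data[s]
                prepped[s] = prep_subject(
                    vol, motion, cohort.mask,
                    tr_seconds=config.prep.tr_seconds,
                    fwhm_mm=config.prep.fwhm_mm,
                    voxel_size_mm=config.prep.voxel_size_mm,
                    low_hz=config.prep.low_hz,
                    high_hz=config.prep.high_hz,
                )
            cohort = VoxelCohort(
                subject_ids=cohort.subject_ids, data=prepped,
                mask=cohort.mask, affine=cohort.affine,
            )

        _stage("bwas")
        links, ma, clusters = run_bwas(
            cohort, phenotype,
            alpha=config.bwas.alpha,
            covariates=config.bwas.covariates,
            family_convention=config.bwas.family_convention,
            ma_min=config.bwas.ma_min,
            min_cluster_voxels=config.bwas.min_cluster_voxels,
            connectivity=config.bwas.connectivity,
            method=config.bwas.method,
        )
        cutoff = config.bwas.alpha / links.n_links
        n_sig_links = int((links.p_value < cutoff).sum())
        manifest["counts"].update(
            n_voxels=cohort.n_voxels,
            n_links_family=links.n_links,
            n_links_retained=len(links),
            n_significant_links=n_sig_links,
            n_clusters=len(clusters),
        )
        io.write_ma_map(out / "ma.nii.gz", ma)
        sig = links.p_value < cutoff
        sig_links = LinkTestTable(
            i=links.i[sig], j=links.j[sig], t_stat=links.t_stat[sig],
            p_value=links.p_value[sig], n_links=links.n_links,
            n_voxels=links.n_voxels, alpha=links.alpha,
        )
        links_to_frame(sig_links, cohort).to_csv(
            out / "significant_links.tsv", sep="\t", index=False
        )
        clusters_to_frame(clusters).to_csv(
            out / "clusters.tsv", sep="\t", index=False
        )
        manifest["outputs"]["ma_map"] = str(out / "ma.nii.gz")
        manifest["outputs"]["significant_links"] = str(out / "significant_links.tsv")
        manifest["outputs"]["clusters"] = str(out / "clusters.tsv")

        roi_results = None
        if config.atlas_path is not None:
            _stage("roi_fc")
            atlas, _ = io.read_nifti(config.atlas_path)
            atlas = atlas.astype(int)
            labels = io.read_labels(config.labels_path)
            rois = define_rois(
                clusters.all_voxel_coords(), ma, atlas, labels,
                min_voxels=config.bwas.roi_min_voxels,
            )
            manifest["counts"]["n_rois"] = len(rois)
            rois_to_frame(rois).to_csv(out / "roi_table.tsv", sep="\t", index=False)
            manifest["outputs"]["roi_table"] = str(out / "roi_table.tsv")
            if len(rois) >= 2:
                fc = roi_fc_matrix(cohort, rois)
                fc.to_csv(out / "roi_fc.tsv", sep="\t", index=False)
                roi_results = roi_fc_table_test(
                    fc, phenotype,
                    covariates=config.bwas.covariates, q=config.roi.q,
                )
                roi_results.to_csv(
                    out / "roi_fc_tests.tsv", sep="\t", index=False
                )
                manifest["counts"]["n_significant_circuits"] = int(
                    roi_results["significant"].sum()
                )
                manifest["outputs"]["roi_fc"] = str(out / "roi_fc.tsv")
                manifest["outputs"]["roi_fc_tests"] = str(out / "roi_fc_tests.tsv")

        if roi_results is not None and config.manifest_path is not None:
            sig_circuits = roi_results[roi_results["significant"]]
            if len(sig_circuits):
                _stage("cognition")
                domains_manifest = io.read_yaml(config.manifest_path)
                phenotype = compute_composites(
                    phenotype,
                    {d: list(t) for d, t in domains_manifest.items()},
                )
                fc = pd.read_csv(out / "roi_fc.tsv", sep="\t")
                fc["circuit"] = fc["roi_a"] + "|" + fc["roi_b"]
                keys = sig_circuits["roi_a"] + "|" + sig_circuits["roi_b"]
                wide = fc[fc["circuit"].isin(set(keys))].pivot_table(
                    index="subject_id", columns="circuit", values="z",
                    sort=False,
                )
                screen = circuit_cognition_screen(
                    wide, phenotype,
                    covariates=config.cognition.covariates,
                    group=config.cognition.group,
                    n_boot=config.cognition.n_boot,
                    seed=config.cognition.seed,
                )
                screen.to_csv(out / "cognition.tsv", sep="\t", index=False)
                manifest["outputs"]["cognition"] = str(out / "cognition.tsv")

        if config.run_reliability:
            _stage("reliability")
            report = half_split_ma(
                cohort, phenotype,
                alpha=config.bwas.alpha,
                covariates=config.bwas.covariates,
                family_convention=config.bwas.family_convention,
                ma_min=config.bwas.ma_min,
                min_cluster_voxels=config.bwas.min_cluster_voxels,
                connectivity=config.bwas.connectivity,
                method=config.bwas.method,
            )
            rel = pd.DataFrame(
                [
                    {
                        "n_sig_first": report.n_sig_first,
                        "n_sig_second": report.n_sig_second,
                        "dice": report.dice,
                        "spearman_rho": report.spearman_rho,
                    }
                ]
            )
            rel.to_csv(out / "reliability.tsv", sep="\t", index=False)
            manifest["outputs"]["reliability"] = str(out / "reliability.tsv")
            if config.atlas_path is not None:
                atlas, _ = io.read_nifti(config.atlas_path)
                labels = io.read_labels(config.labels_path)
                cv = half_split_cross_validation(
                    cohort, phenotype, atlas.astype(int), labels,
                    roi_min_voxels=config.bwas.roi_min_voxels,
                    covariates=config.bwas.covariates, q=config.roi.q,
                    alpha=config.bwas.alpha,
                    family_convention=config.bwas.family_convention,
                    ma_min=config.bwas.ma_min,
                    min_cluster_voxels=config.bwas.min_cluster_voxels,
                    connectivity=config.bwas.connectivity,
                    method=config.bwas.method,
                )
                for key, table in cv.items():
                    path = out / f"reliability_{key}.tsv"
                    table.to_csv(path, sep="\t", index=False)
                    manifest["outputs"][f"reliability_{key}"] = str(path)
    except BwasError as exc:
        raise BwasError(
            f"pipeline halted in stage {stage['name']!r}: {exc}"
        ) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
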