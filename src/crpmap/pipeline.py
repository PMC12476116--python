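"""End-to-end orchestration with a hash manifest for resumability.

Stages: simulate -> falff -> glm-cluster -> tbss-infer -> spatial-assoc ->
transcriptome-assoc -> mediate.  Each stage records a hash of its inputs and
parameters in ``manifest.json``; re-running with unchanged inputs skips
completed stages.  All randomness flows through named per-stage seeds
spawned from the single config seed and recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import falff as falff_mod
from . import inference, spatial, stats, synthetic, transcriptomics
from .io import (read_region_table, read_subject_table, write_nifti,
                 write_subject_table)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ["simulate", "falff", "glm-cluster", "tbss-infer",
          "spatial-assoc", "transcriptome-assoc", "mediate"]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "crpmap_out"
    n_patients: int = 120
    n_controls: int = 118
    grid_shape: tuple = (24, 24, 24)
    n_timepoints: int = 200
    tr: float = 2.0
    band: tuple = (0.01, 0.1)
    n_regions: int = 60
    n_genes: int = 400
    n_annotation_maps: int = 27
    n_behavior_maps: int = 50
    cdt_p: float = 0.001
    n_perm: int = 1000
    n_surr: int = 1000
    n_boot: int = 5000
    fdr_q: float = 0.05
    adjust_bmi: bool = False
    a: float = 0.5
    b: float = 0.5
    c_prime: float = 0.0
    beta_crp_ad: float = -0.5

    def validate(self):
        for p in ("cdt_p", "fdr_q"):
            if not 0 < getattr(self, p) < 1:
                raise ValueError(f"{p} must be in (0, 1)")
        for p in ("n_perm", "n_surr", "n_boot"):
            if getattr(self, p) < 1:
                raise ValueError(f"{p} must be >= 1")


def _hash_obj(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, (str, bytes)):
            h.update(p if isinstance(p, bytes) else p.encode())
        elif isinstance(p, pathlib.Path):
            h.update(p.read_bytes())
        else:
            h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: pathlib.Path):
        self.path = path
        self.data = json.loads(path.read_text()) if path.exists() else {}

    def fresh(self, stage: str, key: str, outputs: list[pathlib.Path]) -> bool:
        rec = self.data.get(stage)
        return (rec is not None and rec["hash"] == key
                and all(pathlib.Path(o).exists() for o in rec["outputs"]))

    def record(self, stage: str, key: str, seed: int,
               outputs: list[pathlib.Path]):
        self.data[stage] = {"hash": key, "seed": seed,
                            "outputs": [str(o) for o in outputs]}
        self.path.write_text(json.dumps(self.data, indent=2))


def _stage_seed(cfg_seed: int, i: int) -> int:
    return int(np.random.SeedSequence(cfg_seed).spawn(len(STAGES))[i]
               .generate_state(1)[0] % (2 ** 31 - 1))


def run_pipeline(config: PipelineConfig | dict,
                 force: bool = False) -> dict:
    """Run every stage, skipping those whose inputs are unchanged.

    Returns a dict of key results (paths and summary objects).
    """
    if isinstance(config, dict):
        config = PipelineConfig(**config)
    config.validate()
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    cfg_dict = asdict(config)
    results: dict = {"out_dir": str(out)}

    # ---- simulate -------------------------------------------------------
    seed = _stage_seed(config.seed, 0)
    key = _hash_obj("simulate", cfg_dict)
    subj_path = out / "subjects.tsv"
    falff_raw_path = out / "falff_raw.nii.gz"
    skel_path = out / "skeleton_panel.tsv"
    expr_path = out / "expression.tsv"
    cat_path = out / "categories.tsv"
    nt_path = out / "annotation_neurotransmitter.tsv"
    bh_path = out / "annotation_behavior.tsv"
    atlas_path = out / "atlas_labels.nii.gz"
    gm_path = out / "gm_probability.tsv"
    sim_outputs = [subj_path, falff_raw_path, skel_path, expr_path, cat_path,
                   nt_path, bh_path, atlas_path, gm_path,
                   out / "mask.nii.gz", out / "skeleton_adjacency.tsv",
                   out / "atlas_centroids.tsv", out / "planted_cluster.nii.gz"]
    spec = synthetic.CohortSpec(
        n_patients=config.n_patients, n_controls=config.n_controls,
        seed=seed, a=config.a, b=config.b, c_prime=config.c_prime,
        beta_crp_ad=config.beta_crp_ad)
    grid = synthetic.GridSpec(shape=tuple(config.grid_shape),
                              tr=config.tr,
                              n_timepoints=config.n_timepoints)
    if force or not manifest.fresh("simulate", key, sim_outputs):
        logger.info("stage simulate (seed %d)", seed)
        subjects = synthetic.generate_subject_table(spec)
        write_subject_table(subjects, subj_path)
        # stream BOLD -> raw fALFF panel, one subject at a time
        nvox = int(grid.mask.sum())
        panel = np.empty((len(subjects), nvox))
        for i, (_, vol) in enumerate(
                synthetic.iter_bold(spec, grid, subjects)):
            series = vol[grid.mask]
            panel[i] = falff_mod.compute_falff(series, grid.tr, config.band)
        vol4 = np.zeros(grid.shape + (len(subjects),))
        vol4[grid.mask] = panel.T
        write_nifti(vol4, falff_raw_path, voxel_size=grid.voxel_size)
        write_nifti(grid.mask.astype(np.int16), out / "mask.nii.gz",
                    voxel_size=grid.voxel_size)
        write_nifti(grid.cluster_mask.astype(np.int16),
                    out / "planted_cluster.nii.gz",
                    voxel_size=grid.voxel_size)

        skel, edges, strip = synthetic.generate_skeleton_panel(spec, subjects)
        pd.DataFrame(skel, index=subjects["subject_id"]).to_csv(
            skel_path, sep="\t")
        (out / "skeleton_adjacency.tsv").write_text(
            "\n".join(f"{i}\t{j}" for i, j in edges) + "\n")
        (out / "skeleton_planted_strip.txt").write_text(
            f"{strip.start}\t{strip.stop}\n")

        atlas = synthetic.make_atlas(tuple(config.grid_shape),
                                     config.n_regions,
                                     voxel_size=grid.voxel_size, seed=seed)
        write_nifti(atlas.labels.astype(np.int16), atlas_path,
                    voxel_size=grid.voxel_size)
        np.savetxt(out / "atlas_centroids.tsv", atlas.centroids,
                   delimiter="\t", header="x\ty\tz", comments="")
        pd.DataFrame({"region_id": [f"R{r + 1:03d}"
                                    for r in range(atlas.n_regions)],
                      "gm_probability": atlas.gm_probability}
                     ).to_csv(gm_path, sep="\t", index=False)

        # phenotype pattern used to plant expression/annotation structure:
        # regional reduction of the planted cluster indicator smoothed into
        # a graded map
        pheno = _planted_phenotype(grid, atlas)
        expr, cats, _ = synthetic.generate_expression(
            atlas, n_genes=config.n_genes, phenotype=pheno, seed=seed)
        expr.index.name = "region_id"
        expr.to_csv(expr_path, sep="\t")
        cats.to_csv(cat_path, sep="\t", index=False)
        nt = synthetic.generate_annotation_maps(
            atlas, config.n_annotation_maps,
            planted={"planted_receptor": 0.6}, phenotype=pheno,
            prefix="receptor", seed=seed)
        nt.to_csv(nt_path, sep="\t")
        bh = synthetic.generate_annotation_maps(
            atlas, config.n_behavior_maps,
            planted={"planted_term": 0.6}, phenotype=pheno,
            prefix="term", seed=seed + 1)
        bh.to_csv(bh_path, sep="\t")
        manifest.record("simulate", key, seed, sim_outputs)
    else:
        logger.info("stage simulate up to date; skipping")
    results["subjects"] = str(subj_path)

    from .io import read_nifti  # local import to keep module load light

    subjects = read_subject_table(subj_path)
    panel4, _ = read_nifti(falff_raw_path)
    mask, _ = read_nifti(out / "mask.nii.gz")
    mask = mask.astype(bool)

    # ---- falff standardization -----------------------------------------
    key = _hash_obj("falff", cfg_dict)
    falff_std_path = out / "falff_std.nii.gz"
    if force or not manifest.fresh("falff", key, [falff_std_path]):
        logger.info("stage falff")
        vol4 = np.zeros_like(panel4, dtype=float)
        for i in range(panel4.shape[-1]):
            vol4[..., i] = falff_mod.standardize_global_mean(
                panel4[..., i], mask)
        write_nifti(vol4, falff_std_path, voxel_size=3.0)
        manifest.record("falff", key, 0, [falff_std_path])
    std4, _ = read_nifti(falff_std_path)

    # ---- glm-cluster ----------------------------------------------------
    seed = _stage_seed(config.seed, 2)
    key = _hash_obj("glm-cluster", cfg_dict)
    tmap_path = out / "crp_falff_tmap.nii.gz"
    clus_path = out / "clusters.tsv"
    roi_path = out / "roi_falff.tsv"
    if force or not manifest.fresh("glm-cluster", key,
                                   [tmap_path, clus_path, roi_path]):
        logger.info("stage glm-cluster (seed %d)", seed)
        pat = subjects[subjects["group"] == "MDD"].reset_index(drop=True)
        Y = std4[mask].T[subjects["group"].to_numpy() == "MDD"]
        covs = ["age", "sex", "education", "fd"]
        if config.adjust_bmi:
            covs.append("bmi")
        X, _, j = inference.build_design(pat, "crp_z", covs)
        table, label_vol3, tvol = inference.cluster_fwe(
            Y, X, mask.shape, mask, j, cdt_p=config.cdt_p,
            n_perm=config.n_perm, seed=seed)
        write_nifti(tvol, tmap_path, voxel_size=3.0)
        table.to_csv(clus_path, sep="\t", index=False)
        sig = table[table["p_fwe"] < 0.05]
        roi = pd.DataFrame({"subject_id": pat["subject_id"]})
        allY = std4[mask].T
        for cid in sig["cluster_id"]:
            members = (label_vol3[mask] == cid)
            roi[f"cluster{cid}"] = allY[
                subjects["group"].to_numpy() == "MDD"][:, members].mean(1)
        roi.to_csv(roi_path, sep="\t", index=False)
        write_nifti(label_vol3.astype(np.int16),
                    out / "cluster_labels.nii.gz", voxel_size=3.0)
        manifest.record("glm-cluster", key, seed,
                        [tmap_path, clus_path, roi_path])
    results["clusters"] = str(clus_path)

    # ---- tbss-infer -----------------------------------------------------
    seed = _stage_seed(config.seed, 3)
    key = _hash_obj("tbss-infer", cfg_dict)
    tbss_path = out / "tbss_corrp.tsv"
    roi_ad_path = out / "roi_ad.tsv"
    if force or not manifest.fresh("tbss-infer", key,
                                   [tbss_path, roi_ad_path]):
        logger.info("stage tbss-infer (seed %d)", seed)
        skel = pd.read_csv(skel_path, sep="\t", index_col=0)
        edges = np.loadtxt(out / "skeleton_adjacency.tsv", dtype=np.int64)
        is_pat = subjects["group"].to_numpy() == "MDD"
        pat = subjects[is_pat].reset_index(drop=True)
        Yk = skel.to_numpy()[is_pat]
        X, _, j = inference.build_design(pat, "crp_z",
                                         ("age", "sex", "education"))
        p_pos, p_neg, _, _, t_skel = inference.tfce_fwe(
            Yk, X, edges, j, n_perm=config.n_perm, seed=seed)
        pd.DataFrame({"voxel": np.arange(len(t_skel)), "t": t_skel,
                      "p_fwe_pos": p_pos, "p_fwe_neg": p_neg}).to_csv(
            tbss_path, sep="\t", index=False)
        sig = np.minimum(p_pos, p_neg) < 0.05
        roi = pd.DataFrame({"subject_id": pat["subject_id"]})
        if sig.any():
            roi["ad_sig"] = Yk[:, sig].mean(1)
        roi.to_csv(roi_ad_path, sep="\t", index=False)
        manifest.record("tbss-infer", key, seed, [tbss_path, roi_ad_path])
    results["tbss"] = str(tbss_path)

    # ---- spatial-assoc --------------------------------------------------
    seed = _stage_seed(config.seed, 4)
    key = _hash_obj("spatial-assoc", cfg_dict)
    assoc_path = out / "spatial_assoc.tsv"
    if force or not manifest.fresh("spatial-assoc", key, [assoc_path]):
        logger.info("stage spatial-assoc (seed %d)", seed)
        tvol, _ = read_nifti(tmap_path)
        labels, _ = read_nifti(atlas_path)
        atlas = _atlas_from_files(out, labels)
        x = spatial.parcellate(tvol, atlas)
        gm = read_region_table(gm_path)["gm_probability"].to_numpy()
        surr = spatial.surrogate_maps(x, atlas.centroids, config.n_surr,
                                      seed)
        frames = []
        for fam, path_ in (("neurotransmitter", nt_path),
                           ("behavior", bh_path)):
            fam_maps = read_region_table(path_)
            res = spatial.assoc_test(x, fam_maps, atlas.centroids, gm,
                                     surrogates=surr)
            res.insert(0, "family", fam)
            frames.append(res)
        pd.concat(frames, ignore_index=True).to_csv(assoc_path, sep="\t",
                                                    index=False)
        manifest.record("spatial-assoc", key, seed, [assoc_path])
    results["spatial_assoc"] = str(assoc_path)

    # ---- transcriptome-assoc -------------------------------------------
    seed = _stage_seed(config.seed, 5)
    key = _hash_obj("transcriptome-assoc", cfg_dict)
    gcea_path = out / "gcea.tsv"
    pls_path = out / "pls.tsv"
    if force or not manifest.fresh("transcriptome-assoc", key,
                                   [gcea_path, pls_path]):
        logger.info("stage transcriptome-assoc (seed %d)", seed)
        tvol, _ = read_nifti(tmap_path)
        labels, _ = read_nifti(atlas_path)
        atlas = _atlas_from_files(out, labels)
        x = spatial.parcellate(tvol, atlas)
        expr = read_region_table(expr_path)
        cats = pd.read_csv(cat_path, sep="\t")
        surr = spatial.surrogate_maps(x, atlas.centroids, config.n_surr,
                                      seed)
        gcea = transcriptomics.gcea_ensemble(expr, x, cats, surr)
        gcea.to_csv(gcea_path, sep="\t", index=False)
        pls = transcriptomics.pls_first_component(expr, x)
        p_perm, _ = transcriptomics.pls_permutation_p(expr, x, surr)
        pos, neg = transcriptomics.select_top_loadings(pls.loadings)
        df = pd.DataFrame({"gene_id": pls.loadings.index,
                           "loading": pls.loadings.to_numpy()})
        df["pls_pos"] = df["gene_id"].isin(pos)
        df["pls_neg"] = df["gene_id"].isin(neg)
        df.attrs["r"] = pls.r
        df.insert(0, "pls_r", pls.r)
        df.insert(1, "p_perm", p_perm)
        df.to_csv(pls_path, sep="\t", index=False)
        manifest.record("transcriptome-assoc", key, seed,
                        [gcea_path, pls_path])
    results["gcea"] = str(gcea_path)
    results["pls"] = str(pls_path)

    # ---- mediate --------------------------------------------------------
    seed = _stage_seed(config.seed, 6)
    key = _hash_obj("mediate", cfg_dict)
    med_path = out / "mediation.tsv"
    if force or not manifest.fresh("mediate", key, [med_path]):
        logger.info("stage mediate (seed %d)", seed)
        roi = pd.read_csv(roi_path, sep="\t")
        pat = subjects[subjects["group"] == "MDD"].reset_index(drop=True)
        rows = []
        covs = pat[["age", "sex", "education", "fd"]].to_numpy()
        for roi_col in [c for c in roi.columns if c != "subject_id"]:
            res = stats.mediate(pat["crp_z"], roi[roi_col], pat["cpt_ip"],
                                covs, n_boot=config.n_boot, seed=seed)
            rows.append({"roi": roi_col, "outcome": "cpt_ip",
                         **{k: getattr(res, k)
                            for k in ("a", "b", "c", "c_prime", "indirect",
                                      "ci_low", "ci_high", "n")},
                         "significant": res.significant})
        pd.DataFrame(rows).to_csv(med_path, sep="\t", index=False)
        manifest.record("mediate", key, seed, [med_path])
    results["mediation"] = str(med_path)
    results["manifest"] = str(out / "manifest.json")
    return results


def _planted_phenotype(grid: synthetic.GridSpec,
                       atlas: synthetic.RegionAtlas) -> np.ndarray:
    """Graded regional phenotype pattern centered on the planted cluster."""
    cm = grid.cluster_mask
    center = np.argwhere(cm).mean(0) * atlas.voxel_size
    d = np.linalg.norm(atlas.centroids - center, axis=1)
    return np.exp(-d / (d.max() / 3.0))


def _atlas_from_files(out: pathlib.Path,
                      labels: np.ndarray) -> synthetic.RegionAtlas:
    centroids = np.loadtxt(out / "atlas_centroids.tsv", skiprows=1)
    gm = pd.read_csv(out / "gm_probability.tsv",
                     sep="\t")["gm_probability"].to_numpy()
    return synthetic.RegionAtlas(labels=labels.astype(int),
                                 centroids=centroids, gm_probability=gm,
                                 voxel_size=3.0)
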