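"""End-to-end orchestration: config validation, stage execution, manifest.

``run_pipeline`` executes the stages in dependency order (qc -> demux ->
normalize -> de/signatures -> heterogeneity -> cnv -> tf activity ->
deconvolution) from a YAML config, records every output file with a
SHA-256 checksum in a run manifest, and validates all required inputs
before any stage runs (fail-fast).  ``make_demo`` writes a self-contained
synthetic worked example (MTX bundle, HTOs, labels, regulons, bulk table,
config) that exercises every stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cnv import infer_cnv, malignancy_sd
from .deconv import build_signature_matrix, cpm_normalize, deconvolve_nnls
from .errors import ConfigurationError
from .heterogeneity import (cosine_similarity_matrix, dendrogram_newick,
                            derive_emp_signatures, patient_cluster_profiles,
                            ward_order)
from .io import (QC_PROFILES, demultiplex_hto, filter_cells, read_mtx_bundle,
                 remove_doublets, write_mtx_bundle)
from .normalize import cluster_log2fc, filter_de_genes, log_normalize
from .synthetic import (SyntheticConfig, generate_bulk_mixtures,
                        generate_cohort, generate_hto_counts)
from .tf import (classify_tf_mode, cluster_activity_summary, read_regulons,
                 score_activity, write_regulons, Regulon)

log = logging.getLogger("empflow")

DEFAULT_STAGES = ("qc", "demux", "normalize", "de", "heterogeneity", "cnv",
                  "tf", "deconvolution")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError("config must be a YAML mapping")
    return cfg


def _required_inputs(cfg: dict) -> list[str]:
    stages = cfg.get("stages", {s: True for s in DEFAULT_STAGES})
    needed = ["matrix", "barcodes", "features"]
    if stages.get("demux", False):
        needed += ["hto_matrix", "hto_barcodes", "hto_features", "hto_thresholds"]
    if stages.get("de", False) or stages.get("heterogeneity", False) \
            or stages.get("cnv", False) or stages.get("deconvolution", False):
        needed.append("labels")
    if stages.get("tf", False):
        needed.append("regulons")
    if stages.get("deconvolution", False):
        needed.append("bulk")
    return needed


def validate_config(cfg: dict) -> None:
    """Fail-fast: every enabled stage's required input must resolve to an
    existing file before execution starts."""
    inputs = cfg.get("inputs", {})
    missing = []
    for key in _required_inputs(cfg):
        p = inputs.get(key)
        if p is None or not Path(p).exists():
            missing.append(f"{key} ({p})")
    if missing:
        raise ConfigurationError(f"missing required inputs: {missing}")
    if "seed" not in cfg:
        raise ConfigurationError("config must set a seed")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages and return the run manifest."""
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    validate_config(cfg)
    outdir = Path(outdir or cfg.get("outdir", "empflow_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = cfg.get("stages", {s: True for s in DEFAULT_STAGES})
    inputs = cfg["inputs"]
    manifest: dict = {"version": __version__, "seed": seed, "stages": {},
                      "outputs": {}, "parameters": {}}

    def record(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    adata = read_mtx_bundle(inputs["matrix"], inputs["barcodes"],
                            inputs["features"], inputs.get("gene_annotation"))
    labels = None
    if inputs.get("labels"):
        labels = pd.read_csv(inputs["labels"], sep="\t", index_col=0)

    if stages.get("qc", True):
        prof_name = cfg.get("qc", {}).get("profile", "default")
        profile = QC_PROFILES[prof_name]
        adata, report = filter_cells(adata, profile)
        p = outdir / "qc_report.tsv"
        report.to_csv(p, sep="\t")
        record("qc_report", p)
        manifest["parameters"]["qc"] = {"profile": prof_name}
        manifest["stages"]["qc"] = {"n_cells_pass": int(adata.n_obs)}
        log.info("qc: %d cells pass profile %s", adata.n_obs, prof_name)

    if stages.get("demux", False):
        hto = read_mtx_bundle(inputs["hto_matrix"], inputs["hto_barcodes"],
                              inputs["hto_features"])
        thr_path = inputs.get("hto_thresholds")
        if thr_path is None:
            raise ConfigurationError("demux stage needs hto_thresholds")
        with open(thr_path) as fh:
            thresholds = {k: float(v) for k, v in yaml.safe_load(fh).items()}
        hto = hto[hto.obs_names.isin(adata.obs_names)]
        assignment = demultiplex_hto(hto, thresholds)
        adata = adata[adata.obs_names.isin(assignment.index)].copy()
        adata = remove_doublets(adata, assignment,
                                keep_negatives=cfg.get("demux", {}).get(
                                    "keep_negatives", False))
        p = outdir / "demux_assignment.tsv"
        assignment.to_csv(p, sep="\t")
        record("demux_assignment", p)
        manifest["parameters"]["demux"] = {"thresholds": thresholds}
        manifest["stages"]["demux"] = {
            "n_singlet": int((assignment["call"] == "singlet").sum()),
            "n_doublet": int((assignment["call"] == "doublet").sum()),
            "n_negative": int((assignment["call"] == "negative").sum()),
        }

    norm = None
    if stages.get("normalize", True):
        sf = float(cfg.get("normalize", {}).get("scale_factor", 10_000.0))
        norm = log_normalize(adata, scale_factor=sf)
        manifest["parameters"]["normalize"] = {"scale_factor": sf}
        manifest["stages"]["normalize"] = {"n_cells": int(norm.n_obs)}

    if labels is not None:
        labels = labels.reindex(adata.obs_names)

    profiles = []
    if stages.get("de", True):
        de_cfg = cfg.get("de", {})
        min_fc = float(de_cfg.get("min_log2fc", 0.25))
        min_pct = float(de_cfg.get("min_pct", 0.10))
        cluster_col = de_cfg.get("cluster_column", "cluster")
        lab = labels[cluster_col].dropna()
        rows = []
        for cl in sorted(lab.unique()):
            in_cells = lab.index[lab == cl]
            out_cells = lab.index[lab != cl]
            if len(out_cells) == 0:
                continue
            prof = cluster_log2fc(norm, in_cells, out_cells, cluster_name=str(cl))
            profiles.append(prof)
            for g in filter_de_genes(prof, min_fc, min_pct):
                rows.append({"cluster": cl, "gene": g,
                             "log2fc": prof.table.loc[g, "log2fc"],
                             "pct_in": prof.table.loc[g, "pct_in"],
                             "pct_out": prof.table.loc[g, "pct_out"]})
        p = outdir / "de_genes.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        record("de_genes", p)
        manifest["parameters"]["de"] = {"min_log2fc": min_fc, "min_pct": min_pct}
        manifest["stages"]["de"] = {"n_clusters": len(profiles),
                                    "n_filtered_genes": len(rows)}

        # EMP signature derivation from the epi-vs-pEMT comparison when both
        # cluster labels are present
        sig_cfg = cfg.get("signatures", {})
        epi_name = sig_cfg.get("epi_cluster", "epi")
        pemt_name = sig_cfg.get("pemt_cluster", "pEMT")
        if {epi_name, pemt_name} <= set(lab.unique()):
            prof = cluster_log2fc(norm, lab.index[lab == epi_name],
                                  lab.index[lab == pemt_name],
                                  cluster_name=f"{epi_name}-vs-{pemt_name}")
            pair = derive_emp_signatures(prof)
            p = outdir / "emp_signatures.tsv"
            pd.DataFrame({
                "gene": pair.epithelial + pair.pemt,
                "signature": ["epithelial"] * len(pair.epithelial)
                             + ["pEMT"] * len(pair.pemt),
            }).to_csv(p, sep="\t", index=False)
            record("emp_signatures", p)

    if stages.get("heterogeneity", True):
        het_cfg = cfg.get("heterogeneity", {})
        min_cells = int(het_cfg.get("min_cells", 50))
        tumor_mask = labels["tumor"].astype(bool) if "tumor" in labels.columns \
            else pd.Series(True, index=labels.index)
        het_labels = labels.loc[tumor_mask, ["patient", "cluster"]].dropna()
        het_profiles = patient_cluster_profiles(norm, het_labels, min_cells=min_cells)
        if len(het_profiles) >= 2:
            sim = cosine_similarity_matrix(het_profiles)
            p = outdir / "cosine_similarity.tsv"
            sim.to_csv(p, sep="\t")
            record("cosine_similarity", p)
            order, Z = ward_order(sim)
            p = outdir / "similarity_dendrogram.nwk"
            p.write_text(dendrogram_newick(Z, sorted(sim.index)) + "\n")
            record("similarity_dendrogram", p)
            manifest["stages"]["heterogeneity"] = {"n_profiles": len(het_profiles)}
        else:
            warnings.warn("heterogeneity: fewer than 2 profiles, skipped")
            manifest["stages"]["heterogeneity"] = {"n_profiles": len(het_profiles)}
        manifest["parameters"]["heterogeneity"] = {"min_cells": min_cells}

    if stages.get("cnv", True):
        cnv_cfg = cfg.get("cnv", {})
        window = int(cnv_cfg.get("window_size", 101))
        clip = float(cnv_cfg.get("clip_bound", 3.0))
        ref_phen = cnv_cfg.get("reference_phenotypes", ["fibroblast", "immune"])
        phen_col = cnv_cfg.get("phenotype_column", "phenotype")
        ref_cells = labels.index[labels[phen_col].isin(ref_phen)]
        cnvm = infer_cnv(norm, ref_cells, window_size=window, clip_bound=clip)
        scores = malignancy_sd(cnvm)
        p = outdir / "cnv_scores.tsv"
        scores.to_frame().to_csv(p, sep="\t")
        record("cnv_scores", p)
        p = outdir / "cnv_gene_order.tsv"
        cnvm.gene_meta.to_csv(p, sep="\t")
        record("cnv_gene_order", p)
        manifest["parameters"]["cnv"] = {"window_size": window, "clip_bound": clip,
                                         "reference_phenotypes": list(ref_phen)}
        manifest["stages"]["cnv"] = {"n_reference": int(len(ref_cells))}

    if stages.get("tf", True):
        tf_cfg = cfg.get("tf", {})
        regulons = read_regulons(inputs["regulons"],
                                 min_confidence=tf_cfg.get("min_confidence"))
        activity = score_activity(norm, regulons,
                                  min_targets=int(tf_cfg.get("min_targets", 3)))
        p = outdir / "tf_activity.tsv"
        activity.to_csv(p, sep="\t")
        record("tf_activity", p)
        classes = pd.DataFrame([
            vars(classify_tf_mode(r)) for r in regulons if r.tf in activity.columns
        ])
        p = outdir / "tf_classes.tsv"
        classes.to_csv(p, sep="\t", index=False)
        record("tf_classes", p)
        cl_col = tf_cfg.get("cluster_column", "phenotype")
        summary = cluster_activity_summary(activity, labels[cl_col])
        p = outdir / "tf_summary.tsv"
        summary.to_csv(p, sep="\t", index=False)
        record("tf_summary", p)
        manifest["stages"]["tf"] = {"n_regulons": int(activity.shape[1])}

    if stages.get("deconvolution", True):
        dec_cfg = cfg.get("deconvolution", {})
        phen_col = dec_cfg.get("phenotype_column", "phenotype")
        sig = build_signature_matrix(
            adata, labels[phen_col],
            min_pct=float(dec_cfg.get("min_pct", 0.05)),
            subsample=dec_cfg.get("subsample"),
            seed=seed,
            filter_scope=dec_cfg.get("filter_scope", "all"),
        )
        p = outdir / "signature_matrix.tsv"
        sig.values.to_csv(p, sep="\t")
        record("signature_matrix", p)
        bulk = pd.read_csv(inputs["bulk"], sep="\t", index_col=0)
        est = deconvolve_nnls(cpm_normalize(bulk), sig)
        p = outdir / "bulk_fractions.tsv"
        est.fractions.to_csv(p, sep="\t")
        record("bulk_fractions", p)
        manifest["parameters"]["deconvolution"] = {
            "min_pct": sig.min_pct, "filter_scope": sig.filter_scope,
            "subsample": sig.subsample,
        }
        manifest["stages"]["deconvolution"] = {
            "n_signature_genes": int(sig.values.shape[0]),
            "n_samples": int(est.fractions.shape[0]),
        }

    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# --------------------------------------------------------------------------
# demo cohort
# --------------------------------------------------------------------------

def _demo_regulons(truth, seed: int) -> list[Regulon]:
    """Regulons wired to the implanted programs: an activator whose targets
    are the pEMT program genes, a repressor whose targets are the epi
    program genes (active where epi genes are down), and an ambiguous TF
    with mixed-mode random targets."""
    rng = np.random.default_rng(seed)
    genes = truth.genes
    pemt = list(genes.index[genes["program"] == "pEMT"])
    epi = list(genes.index[genes["program"] == "epi"])
    free = list(genes.index[(genes["program"] == "") & ~genes["mito"]])
    mixed = [free[i] for i in rng.choice(len(free), size=20, replace=False)]
    return [
        Regulon("TF-pEMT-act", pemt, np.ones(len(pemt)), np.ones(len(pemt))),
        Regulon("TF-epi-rep", epi, -np.ones(len(epi)), np.ones(len(epi))),
        Regulon("TF-ambiguous", mixed,
                np.where(np.arange(len(mixed)) % 2 == 0, 1.0, -1.0),
                np.full(len(mixed), 0.8)),
    ]


def make_demo(outdir: str | Path, seed: int = 0, scale: str = "tiny") -> Path:
    """Write a self-contained synthetic worked example and its pipeline
    config.  ``scale='tiny'`` (3 patients x 150 cells) runs end to end in
    well under a minute; ``'default'`` is 3 x 400."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells = {"tiny": 150, "default": 400}[scale]
    config = SyntheticConfig(cells_per_patient=cells, seed=seed)
    adata, truth = generate_cohort(config)
    hto = generate_hto_counts(truth, config)
    bulk, truth = generate_bulk_mixtures(adata, truth, n_mixtures=6,
                                         seed=seed + 1)

    cohort_dir = outdir / "cohort"
    paths = write_mtx_bundle(adata, cohort_dir)
    hto_dir = outdir / "hto"
    write_mtx_bundle(hto, hto_dir, write_annotation=False)

    truth.cells.to_csv(outdir / "ground_truth_cells.tsv", sep="\t")
    truth.genes.to_csv(outdir / "ground_truth_genes.tsv", sep="\t")
    truth.bulk_fractions.to_csv(outdir / "ground_truth_fractions.tsv", sep="\t")

    # labels emulate what clustering would assign: doublets that escape
    # hashtag detection (same-sample pairs) get their first parental type
    phenotype = truth.cells["cell_type"].str.split("+").str[0]
    is_tumor = phenotype.isin(("tumor-pEMT", "tumor-epi", "tumor-mix"))
    cluster = phenotype.map(
        {"tumor-pEMT": "pEMT", "tumor-epi": "epi", "tumor-mix": "mix"}
    ).fillna(phenotype)
    labels = pd.DataFrame({
        "patient": truth.cells["patient"],
        "cluster": cluster,
        "phenotype": phenotype,
        "tumor": is_tumor,
    }, index=truth.cells.index)
    labels.to_csv(outdir / "labels.tsv", sep="\t")

    write_regulons(_demo_regulons(truth, seed), outdir / "regulons.tsv")
    bulk.to_csv(outdir / "bulk_counts.tsv", sep="\t")

    thr = (config.hto_signal_mean + config.hto_background_mean) / 2
    thresholds = {h: thr for h in hto.var_names}
    with open(outdir / "hto_thresholds.yaml", "w") as fh:
        yaml.safe_dump(thresholds, fh)

    cfg = {
        "seed": seed,
        "outdir": str(outdir / "results"),
        "inputs": {
            "matrix": str(paths["matrix"]),
            "barcodes": str(paths["barcodes"]),
            "features": str(paths["features"]),
            "gene_annotation": str(paths["annotation"]),
            "hto_matrix": str(hto_dir / "matrix.mtx"),
            "hto_barcodes": str(hto_dir / "barcodes.tsv"),
            "hto_features": str(hto_dir / "features.tsv"),
            "hto_thresholds": str(outdir / "hto_thresholds.yaml"),
            "labels": str(outdir / "labels.tsv"),
            "regulons": str(outdir / "regulons.tsv"),
            "bulk": str(outdir / "bulk_counts.tsv"),
        },
        "stages": {s: True for s in DEFAULT_STAGES},
        "qc": {"profile": "default"},
        "cnv": {"window_size": 101, "clip_bound": 3.0,
                "reference_phenotypes": ["fibroblast", "immune"]},
        "tf": {"cluster_column": "phenotype"},
        "deconvolution": {"phenotype_column": "phenotype", "subsample": {}},
    }
    cfg_path = outdir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh)
    return cfg_path
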