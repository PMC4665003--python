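"""End-to-end orchestration: simulate -> cluster -> classify -> diff ->
repeats -> signature -> stratify -> clinical -> regulatory.

Each stage writes its tables under the output directory and is recorded in a
run manifest (config snapshot, input checksums, per-stage outputs, seed,
version). The whole run is deterministic under a fixed seed: re-running with
an unchanged configuration reproduces every output byte for byte, which is
what makes the manifest sufficient for reproducing any figure-analogue
table from its listed inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify_peaks
from .clustering import filter_working_set, paraclu_cluster, pool_ctss, quantify_peaks
from .config import PipelineConfig
from .diffexp import differential_expression
from .io_formats import (covariate_columns, write_ctss, write_gtf_genes,
                         write_matrix, write_narrowpeak, write_repeats_bed,
                         write_sample_sheet, write_state_bed)
from .regulatory import (call_active, chromatin_state_summary, cobinding_network,
                         tf_association)
from .repeats import (assign_repeat_overlap, enrichment_tables,
                      fdr_stratified_fractions, relative_position_profile,
                      subfamily_activation)
from .signature import (clinical_association, cluster_samples, forest_plot,
                        pca_embed, select_signature)
from .simulate import (SimulationPlan, add_silent_states, simulate_clinical,
                       simulate_ctss, simulate_genome_and_annotations,
                       simulate_regulatory_tracks)

logger = logging.getLogger(__name__)


def _config_hash(cfg: PipelineConfig, plan: SimulationPlan) -> str:
    payload = json.dumps({
        "config": dataclasses.asdict(cfg),
        "plan_seed": plan.seed,
        "plan": repr(plan),
        "version": __version__,
    }, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineRun:
    """Mutable run state; ``run_all`` drives the stages in order."""

    def __init__(self, outdir: str | Path, config: PipelineConfig,
                 plan: SimulationPlan | None = None):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.config = config.validate()
        self.plan = plan if plan is not None else SimulationPlan(seed=config.seed)
        self.manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "config_hash": _config_hash(config, self.plan),
            "stages": {},
            "input_checksums": {},
        }

    # -- manifest helpers ---------------------------------------------------
    def _manifest_path(self) -> Path:
        return self.outdir / "manifest.json"

    def _record(self, stage: str, outputs: list) -> None:
        self.manifest["stages"][stage] = {
            "outputs": [str(p) for p in outputs]}
        self._manifest_path().write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True, default=str))


def run_all(outdir: str | Path, config: PipelineConfig | None = None,
            simulate: bool = True,
            plan: SimulationPlan | None = None) -> dict:
    """Run the whole pipeline on a (simulated) cohort; returns the manifest.

    With ``simulate`` a synthetic cohort is generated from ``plan`` (the
    default plan seeded from the config); stage outputs land as TSV/BED
    under ``outdir``. The signature minimum-tumor-sample criterion is scaled
    to ceil(0.6 * n_tumor) when the cohort is smaller than the configured
    threshold allows.
    """
    cfg = (config or PipelineConfig()).validate()
    run = PipelineRun(outdir, cfg, plan)
    plan = run.plan
    out = run.outdir
    if not simulate:
        raise NotImplementedError(
            "external-input orchestration: run the stage functions directly; "
            "run_all drives the simulated cohort end to end")

    # stage 1: simulate ------------------------------------------------------
    genes, repeats_df, loci = simulate_genome_and_annotations(plan)
    tracks, sheet, truth = simulate_ctss(plan, genes, repeats_df, loci)
    sheet = simulate_clinical(plan, sheet, truth)
    tf_sets, open_chromatin, states, cell_ctss = simulate_regulatory_tracks(
        plan, truth)
    states = add_silent_states(states, repeats_df, loci)
    sim_dir = out / "simulated"
    sim_dir.mkdir(exist_ok=True)
    write_gtf_genes(genes, sim_dir / "genes.gtf")
    write_repeats_bed(repeats_df, sim_dir / "repeats.bed")
    write_sample_sheet(sheet, sim_dir / "samples.tsv")
    ctss_dir = sim_dir / "ctss"
    ctss_dir.mkdir(exist_ok=True)
    for sample, track in tracks.items():
        write_ctss(track, ctss_dir / f"{sample}.ctss.bed")
    write_ctss(cell_ctss, sim_dir / "cell.ctss.bed")
    write_narrowpeak(open_chromatin, sim_dir / "open_chromatin.narrowPeak")
    tf_dir = sim_dir / "tf"
    tf_dir.mkdir(exist_ok=True)
    for tf, feats in tf_sets.items():
        write_narrowpeak(feats, tf_dir / f"{tf}.narrowPeak")
    write_state_bed(states, sim_dir / "states.bed")
    loci.to_csv(sim_dir / "truth_loci.tsv", sep="\t")
    run.manifest["input_checksums"] = {
        p.name: _checksum(p) for p in sorted(sim_dir.glob("*.tsv"))}
    run._record("simulate", sorted(str(p) for p in sim_dir.rglob("*") if p.is_file()))

    # stage 2: cluster -------------------------------------------------------
    pooled = pool_ctss(tracks)
    peaks = paraclu_cluster(pooled, min_tags=cfg.cluster_min_tags,
                            min_fold=cfg.cluster_min_fold,
                            max_length=cfg.cluster_max_length)
    counts, tpm = quantify_peaks(peaks, tracks, sheet["library_size"])
    tumor_samples = sheet.index[sheet["group"] == "tumor"].tolist()
    nontumor_samples = sheet.index[sheet["group"] == "nontumor"].tolist()
    kept_ids, tallies = filter_working_set(
        tpm, counts, tumor_samples, min_tpm=cfg.working_min_tpm,
        min_samples=cfg.working_min_samples)
    peaks = peaks[peaks["peak_id"].isin(kept_ids)].reset_index(drop=True)
    counts = counts.loc[kept_ids]
    tpm = tpm.loc[kept_ids]
    peaks.to_csv(out / "peaks.tsv", sep="\t", index=False)
    write_matrix(counts, out / "counts.tsv")
    write_matrix(tpm.round(4), out / "tpm.tsv")
    run._record("cluster", [out / "peaks.tsv", out / "counts.tsv",
                            out / "tpm.tsv"])

    # stage 3: classify ------------------------------------------------------
    classified = classify_peaks(peaks, genes,
                                coding_window_bp=cfg.coding_window_bp,
                                proximal_bp=cfg.proximal_bp)
    classified.to_csv(out / "classified.tsv", sep="\t")
    run._record("classify", [out / "classified.tsv"])

    # stage 4: differential expression --------------------------------------
    diff = differential_expression(counts, tpm, tumor_samples,
                                   nontumor_samples, sheet["library_size"],
                                   alpha=cfg.de_alpha,
                                   fold_pseudocount=cfg.fold_pseudocount)
    diff.to_csv(out / "diff.tsv", sep="\t")
    run._record("diff", [out / "diff.tsv"])

    # stage 5: repeats -------------------------------------------------------
    distal_ids = classified.index[classified["label"] == "distal"]
    distal_peaks = peaks[peaks["peak_id"].isin(distal_ids)]
    overlaps = assign_repeat_overlap(distal_peaks, repeats_df,
                                     exclude_internal=cfg.exclude_internal)
    up_ids = diff.index[diff["up"]].intersection(distal_ids)
    nonup_ids = distal_ids.difference(up_ids)
    enrich = enrichment_tables(overlaps, up_ids, nonup_ids)
    strat = fdr_stratified_fractions(overlaps, diff, distal_ids)
    subfam = subfamily_activation(overlaps, up_ids, repeats_df)
    relpos = relative_position_profile(
        overlaps.loc[overlaps.index.intersection(up_ids)],
        plan.activated_subfamily)
    enrich.to_csv(out / "repeat_enrichment.tsv", sep="\t", index=False)
    strat.to_csv(out / "fdr_stratified.tsv", sep="\t", index=False)
    subfam.to_csv(out / "subfamily_activation.tsv", sep="\t", index=False)
    pd.DataFrame({"bin_start": relpos["edges"][:-1],
                  "count": relpos["hist"]}).to_csv(
        out / "relative_position.tsv", sep="\t", index=False)
    run._record("repeats", [out / "repeat_enrichment.tsv",
                            out / "fdr_stratified.tsv",
                            out / "subfamily_activation.tsv",
                            out / "relative_position.tsv"])

    # stage 6: signature -----------------------------------------------------
    min_tumor = min(cfg.signature_min_tumor_samples,
                    math.ceil(0.6 * len(tumor_samples)))
    if min_tumor < cfg.signature_min_tumor_samples:
        logger.info("scaling signature min_tumor_samples %d -> %d for a "
                    "%d-tumor cohort", cfg.signature_min_tumor_samples,
                    min_tumor, len(tumor_samples))
    ltr_flags = (overlaps["family"] == "LTR") & overlaps["sense_flag"]
    sig = select_signature(diff, counts, distal_ids, tumor_samples, ltr_flags,
                           fdr_max=cfg.signature_fdr_max,
                           fold_min=cfg.signature_fold_min,
                           min_tumor_samples=min_tumor,
                           prefix=cfg.signature_prefix)
    sig.to_csv(out / "signature.tsv", sep="\t")
    run._record("signature", [out / "signature.tsv"])

    # stage 7: stratify ------------------------------------------------------
    if len(sig):
        clus = cluster_samples(tpm, sig.index, k=cfg.cluster_k,
                               log_pseudocount=cfg.log_pseudocount)
        strata = clus["strata"]
        emb = pca_embed(tpm, sig.index, log_pseudocount=cfg.log_pseudocount)
        strata.to_frame().to_csv(out / "strata.tsv", sep="\t")
        emb["coords"].to_csv(out / "pca.tsv", sep="\t")
        run._record("stratify", [out / "strata.tsv", out / "pca.tsv"])
    else:
        strata = pd.Series(dtype=object)
        logger.warning("empty signature; stratification skipped")

    # stage 8: clinical ------------------------------------------------------
    clinical = None
    tumor_strata = strata.reindex(tumor_samples).dropna()
    if len(sig) and (tumor_strata == "high").sum() >= 2 \
            and (tumor_strata == "low").sum() >= 2:
        clinical = clinical_association(tumor_strata, sheet,
                                        covariate_columns(sheet))
        clinical["table"].to_csv(out / "clinical.tsv", sep="\t", index=False)
        forest_plot(clinical["table"], out / "forest.png")
        run._record("clinical", [out / "clinical.tsv", out / "forest.png"])
    else:
        logger.warning("clinical association skipped (insufficient strata)")

    # stage 9: regulatory ----------------------------------------------------
    up_distal_peaks = peaks[peaks["peak_id"].isin(up_ids)]
    activity = call_active(up_distal_peaks, cell_ctss, open_chromatin,
                           max_distance=cfg.open_chromatin_max_distance)
    state_labels = chromatin_state_summary(up_distal_peaks, states)
    active_up = up_distal_peaks[activity["active"].reindex(
        up_distal_peaks["peak_id"]).to_numpy()]
    nonup_peaks_df = peaks[peaks["peak_id"].isin(nonup_ids)]
    assoc = tf_association(active_up, nonup_peaks_df, tf_sets,
                           upstream=cfg.tf_window_upstream,
                           downstream=cfg.tf_window_downstream,
                           alpha=cfg.tf_alpha)
    activity.to_csv(out / "activity.tsv", sep="\t")
    state_labels.to_frame().to_csv(out / "states_summary.tsv", sep="\t")
    assoc.drop(columns="targets").to_csv(out / "tf_association.tsv", sep="\t")
    network = None
    if int(assoc["significant"].sum()) >= 2:
        network = cobinding_network(assoc, jaccard_min=cfg.jaccard_min)
        with open(out / "cobinding_edges.tsv", "w") as fh:
            fh.write("tf1\ttf2\tjaccard\n")
            for t1, t2, j in network["edges"]:
                fh.write(f"{t1}\t{t2}\t{j:.4f}\n")
        with open(out / "cliques.txt", "w") as fh:
            for c in network["cliques"]:
                fh.write(",".join(c) + "\n")
        run._record("regulatory", [out / "activity.tsv",
                                   out / "tf_association.tsv",
                                   out / "cobinding_edges.tsv",
                                   out / "cliques.txt"])
    else:
        logger.warning("fewer than two significant TFs; no cobinding network")

    run.manifest["n_stages"] = len(run.manifest["stages"])
    run._manifest_path().write_text(
        json.dumps(run.manifest, indent=1, sort_keys=True, default=str))
    return {
        "manifest": run.manifest,
        "peaks": peaks, "counts": counts, "tpm": tpm, "sheet": sheet,
        "classified": classified, "diff": diff, "overlaps": overlaps,
        "enrichment": enrich, "subfamily": subfam, "signature": sig,
        "strata": strata, "clinical": clinical, "tf_association": assoc,
        "network": network, "truth": truth, "relative_position": relpos,
    }
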