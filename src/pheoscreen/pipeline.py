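"""End-to-end pipeline runner.

Orders the stages of the screen analysis — simulate -> screen (normalize,
fit, classify, triage) -> enrich -> meta (cross-species correlation) ->
network -> synergy — over a shared output directory, and writes a manifest
listing every artifact with its SHA-256 hash, the seed and a config
snapshot, so reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, io, meta, network, qhts, simulate, synergy
from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A stage failed; partial outputs remain in the output directory."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    mix = {"1.1": 0.02, "1.2": 0.03, "2.1": 0.02, "2.2": 0.03,
           "3": 0.02, "4": 0.88}
    truth = simulate.gen_screen_library(cfg.screen.n_compounds, mix,
                                        seed=cfg.seed)
    plates, cmap = simulate.gen_plate_reads(
        truth, noise_sd=cfg.screen.noise_sd, seed=cfg.seed + 1)
    a, b, _ = simulate.gen_expression_pair(
        cfg.meta.n_genes, cfg.meta.n_samples_a, cfg.meta.n_samples_b,
        rho=cfg.meta.rho, seed=cfg.seed + 2,
        n_divergent=cfg.meta.n_divergent, private_frac=0.1)
    dtmap = simulate.gen_drug_target_map(
        cfg.meta.n_drugs, list(a.genes[: cfg.meta.n_genes]),
        seed=cfg.seed + 3)
    s = cfg.synergy
    combo = simulate.gen_combination_assay(
        simulate.SyntheticCombinationTruth(
            dm1=s.dm1, dm2=s.dm2, m1=s.m1, m2=s.m2, ratio=s.ratio,
            ci_true=s.ci_true, noise_sd=s.noise_sd),
        seed=cfg.seed + 4)
    files = {
        "library_truth.tsv": truth, "plates.tsv": plates,
        "compound_map.tsv": cmap, "drug_targets.tsv": dtmap,
        "combo_drug1.tsv": combo["drug1"], "combo_drug2.tsv": combo["drug2"],
        "combo_pairs.tsv": combo["combo"],
    }
    for name, df in files.items():
        io.write_table(df, out / name)
    io.write_expression(a, out / "expression_a.tsv")
    io.write_expression(b, out / "expression_b.tsv")
    return [out / n for n in [*files, "expression_a.tsv", "expression_b.tsv"]]


def _stage_screen(cfg: PipelineConfig, out: Path) -> list[Path]:
    plates = io.read_table(out / "plates.tsv", "plate")
    cmap = io.read_table(out / "compound_map.tsv", "compound_map")
    normalized = qhts.normalize_screen(plates)
    series = qhts.extract_titrations(normalized, cmap)
    ann = cmap[["compound_id", "category"]].drop_duplicates("compound_id")
    fits = qhts.fit_screen(series, cfg.screen.screen_config(), annotations=ann)
    io.write_table(fits, out / "fits.tsv")
    hits = qhts.rank_hits(fits, cfg.screen.top_n)
    io.write_table(hits, out / "hits.tsv")
    counts = fits["activity"].value_counts().reindex(
        ["active", "inactive", "inconclusive"], fill_value=0)
    io.write_table(counts.rename("n").reset_index(), out / "triage_counts.tsv")
    return [out / "fits.tsv", out / "hits.tsv", out / "triage_counts.tsv"]


def _stage_enrich(cfg: PipelineConfig, out: Path) -> list[Path]:
    fits = pd.read_csv(out / "fits.tsv", sep="\t")
    tab = qhts.category_enrichment(fits)
    io.write_table(tab, out / "enrichment.tsv")
    return [out / "enrichment.tsv"]


def _stage_meta(cfg: PipelineConfig, out: Path) -> list[Path]:
    a = io.read_expression(out / "expression_a.tsv", species="mouse",
                           normalized="cohort-zscore")
    b = io.read_expression(out / "expression_b.tsv", species="human",
                           normalized="cohort-zscore")
    dtmap = meta.DrugTargetMap.from_frame(
        io.read_table(out / "drug_targets.tsv", "drug_target"))
    merged = meta.merge_common_genes(a, b, restrict_to=dtmap.all_genes)
    survivors = meta.fold_change_filter(merged, cfg.meta.fold_threshold)
    table, overall = meta.drug_target_correlation(
        merged, dtmap, cfg.meta.min_targets)
    io.write_table(table, out / "drug_correlations.tsv")
    summary = pd.DataFrame([{
        "n_common_genes": len(merged.common_genes),
        "n_after_fold_filter": len(survivors),
        "overall_gene_correlation": meta.overall_correlation(merged, survivors),
        "mean_per_drug_r": overall,
    }])
    io.write_table(summary, out / "meta_summary.tsv")
    return [out / "drug_correlations.tsv", out / "meta_summary.tsv"]


def _stage_network(cfg: PipelineConfig, out: Path) -> list[Path]:
    dtmap = meta.DrugTargetMap.from_frame(
        io.read_table(out / "drug_targets.tsv", "drug_target"))
    net = network.build_drug_target_network(
        dtmap, cfg.network.connect_targets_to_all_drugs)
    scores = network.eccentricity_scores(net)
    hubs = network.top_hubs(scores, cfg.network.top_n)
    network.write_sif(net, out / "network.sif")
    network.write_node_attributes(scores, out / "node_scores.tsv")
    io.write_table(hubs, out / "top_hubs.tsv")
    return [out / "network.sif", out / "node_scores.tsv", out / "top_hubs.tsv"]


def _stage_synergy(cfg: PipelineConfig, out: Path) -> list[Path]:
    d1 = io.read_table(out / "combo_drug1.tsv", "dose_fa")
    d2 = io.read_table(out / "combo_drug2.tsv", "dose_fa")
    pairs = io.read_table(out / "combo_pairs.tsv", "combo")
    res = synergy.analyze_combination(
        d1, d2, pairs, ci_bands=(cfg.synergy.ci_lo, cfg.synergy.ci_hi))
    io.write_table(res.table, out / "synergy.tsv")
    io.write_table(res.fa_ci_curve(), out / "fa_ci_curve.tsv")
    return [out / "synergy.tsv", out / "fa_ci_curve.tsv"]


_STAGES = {
    "simulate": _stage_simulate,
    "screen": _stage_screen,
    "enrich": _stage_enrich,
    "meta": _stage_meta,
    "network": _stage_network,
    "synergy": _stage_synergy,
}


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the configured stages; returns (and writes) the manifest.

    Stage order is fixed (simulate -> screen -> enrich -> meta -> network
    -> synergy); stages absent from ``config.stages`` are skipped, and
    later stages read earlier stages' files from ``out_dir``, so a partial
    rerun over an existing directory works.  Any stage error raises
    :class:`PipelineStageError` naming the stage; files already written
    stay in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    logger.info("pipeline start: seed=%d stages=%s", config.seed, config.stages)
    for name, fn in _STAGES.items():
        if name not in config.stages:
            continue
        try:
            outputs = fn(config, out)
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise PipelineStageError(name, exc) from exc
        manifest["stages"][name] = {
            str(p.name): _sha256(p) for p in outputs}
        logger.info("stage %s: %d artifacts", name, len(outputs))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
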