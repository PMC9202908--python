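"""TAD-based prioritization of risk-locus candidate genes, and the
end-to-end pipeline runner.

The terminal stage of the analysis: for each susceptibility locus, find the
TAD(s) containing its risk SNP, collect the features whose TSS falls inside
those TADs (genes in a TAD share its cis-regulatory context), join the DE
results and apply the TAD-local screen (raw p < 0.05 and |log2FC| >= 1 by
default — deliberately looser than the genome-wide filters), yielding the
per-locus candidate table. Loci whose SNP hits no TAD are reported with an
explicit ``no_tad`` status; loci whose TAD contains no passing feature are
reported ``empty`` rather than dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import coexpress as cx
from . import diffexpr as dx
from . import enrichment as en
from . import hic as th
from . import io as tio
from . import network as nw
from . import simulate as sim
from .config import SimulationConfig, default_config

logger = logging.getLogger(__name__)

CANDIDATE_COLUMNS = [
    "locus", "chrom", "tad_start", "tad_end", "level",
    "feature_id", "rna_class", "log2fc", "p", "q", "direction",
]

TAD_LOCAL_P_CUT = 0.05
TAD_LOCAL_LFC_CUT = 1.0


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


# ----------------------------------------------------------------------
# per-locus screening


def features_in_tad(annotation: pd.DataFrame, tad: th.Tad, overlap: str = "tss") -> list[str]:
    """Features assigned to a TAD: TSS containment (default, half-open) or
    any gene-body overlap."""
    on_chrom = annotation[annotation["chrom"] == tad.chrom]
    if overlap == "tss":
        hit = (on_chrom["tss"] >= tad.start_bp) & (on_chrom["tss"] < tad.end_bp)
    elif overlap == "any":
        hit = (on_chrom["start"] < tad.end_bp) & (on_chrom["end"] > tad.start_bp)
    else:
        raise ValueError(f"unknown overlap mode {overlap!r}")
    return sorted(on_chrom.loc[hit, "feature_id"])


def prioritize(
    feature_ids,
    de: pd.DataFrame,
    p_cut: float = TAD_LOCAL_P_CUT,
    lfc_cut: float = TAD_LOCAL_LFC_CUT,
    p_field: str = "raw",
) -> pd.DataFrame:
    """Apply the TAD-local DE screen to a feature list.

    Keeps features with p_field < p_cut and |log2FC| >= lfc_cut; assigns
    up/down direction from the sign of log2FC. Features missing from the DE
    table are dropped with a logged count. Pure filter: idempotent.
    """
    col = "q" if p_field in ("adjusted", "q") else "p"
    present = [f for f in feature_ids if f in de.index]
    if len(present) < len(set(feature_ids)):
        logger.warning("prioritize: %d feature(s) absent from DE results", len(set(feature_ids)) - len(present))
    sub = de.loc[present]
    keep = (sub[col] < p_cut) & (sub["log2fc"].abs() >= lfc_cut)
    kept = sub[keep.fillna(False)].copy()
    kept["direction"] = np.where(kept["log2fc"] > 0, "up", "down")
    out = kept.reset_index().rename(columns={"index": "feature_id"})
    if "feature_id" not in out.columns:
        out = out.rename(columns={out.columns[0]: "feature_id"})
    return out[["feature_id", "rna_class", "log2fc", "p", "q", "direction"]]


def prioritize_loci(
    loci: pd.DataFrame,
    tads: th.TadSet,
    annotation: pd.DataFrame,
    de: pd.DataFrame,
    p_cut: float = TAD_LOCAL_P_CUT,
    lfc_cut: float = TAD_LOCAL_LFC_CUT,
    p_field: str = "raw",
    overlap: str = "tss",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate table over all loci plus a per-locus status table.

    A locus contributes one block of rows per containing TAD/sub-TAD (so
    sub-TAD hits are flagged separately via the level column). Status is
    ``no_tad`` (SNP in no TAD), ``empty`` (TAD(s) found, nothing passed) or
    ``ok``.
    """
    rows = []
    statuses = []
    for locus_row in loci.itertuples(index=False):
        locus = th.Locus(name=locus_row.name, chrom=locus_row.chrom, snp_pos=int(locus_row.snp_pos))
        containing = th.locate_tad(tads, locus)
        if not containing:
            statuses.append({"locus": locus.name, "status": "no_tad", "n_candidates": 0})
            continue
        locus_feats = set()
        for tad in containing:
            feats = features_in_tad(annotation, tad, overlap=overlap)
            table = prioritize(feats, de, p_cut=p_cut, lfc_cut=lfc_cut, p_field=p_field)
            for r in table.itertuples(index=False):
                rows.append(
                    {
                        "locus": locus.name,
                        "chrom": tad.chrom,
                        "tad_start": tad.start_bp,
                        "tad_end": tad.end_bp,
                        "level": tad.level,
                        "feature_id": r.feature_id,
                        "rna_class": r.rna_class,
                        "log2fc": r.log2fc,
                        "p": r.p,
                        "q": r.q,
                        "direction": r.direction,
                    }
                )
                locus_feats.add(r.feature_id)
        statuses.append(
            {
                "locus": locus.name,
                "status": "ok" if locus_feats else "empty",
                "n_candidates": len(locus_feats),
            }
        )
    table = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    if len(table):
        table = table.sort_values(
            ["locus", "p", "feature_id", "level"], kind="mergesort"
        ).reset_index(drop=True)
    status = pd.DataFrame(statuses, columns=["locus", "status", "n_candidates"])
    return table, status


# ----------------------------------------------------------------------
# the pipeline


DEFAULT_PIPELINE = {
    "seed": 0,
    "simulate": {},
    "inputs": {},
    "skip": [],
    "de": {"dispersion_mode": "pooled", "thresholds": None},
    "coexpress": {
        "r_min": 0.9, "use_abs": False, "min_size": 30, "cut_height": None,
        "top_k": 3, "adjust_condition": True, "soft_power": None,
    },
    "network": {"restrict_targets_to_de": False, "top_n": 20},
    "enrichment": {"p_cut": 0.01, "top_k": 8},
    "tads": {"window": 5, "delta": 0.5, "min_bins": 3, "sub": False, "tads_bed": None},
    "prioritize": {"p_cut": 0.05, "lfc_cut": 1.0, "p_field": "raw", "overlap": "tss"},
}


def _merge_config(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_PIPELINE))
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_pipeline(config: dict | str, outdir: str) -> dict:
    """Execute simulate? -> de -> coexpress -> network -> enrichment ->
    tads -> prioritize, writing every stage output plus run_manifest.json.

    ``config`` is a dict or a YAML path; see DEFAULT_PIPELINE for the
    schema. Stages in ``skip`` (coexpress/network/enrichment) are omitted;
    the TAD/prioritization arm is independent of them. Fully deterministic
    for a fixed config (including seed).
    """
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = _merge_config(config)
    skip = set(cfg.get("skip") or [])
    tio.ensure_dir(outdir)
    p = lambda name: os.path.join(outdir, name)
    manifest_rows: dict[str, int] = {}
    results: dict = {}

    # ---------------- simulate / load inputs
    stage = "simulate"
    try:
        if cfg.get("simulate") is not None:
            sim_overrides = dict(cfg["simulate"])
            sim_overrides.setdefault("seed", cfg["seed"])
            if sim_overrides.keys() <= {"seed"}:
                sim_cfg = default_config(sim_overrides["seed"])
            else:
                sim_cfg = SimulationConfig.from_dict(sim_overrides)
            study = sim.simulate_study(sim_cfg)
            sim.write_study(study, p("sim"))
            annotation, counts, design = study.annotation, study.counts, study.design
            targets, pathways_path = study.targets, study.files["pathways"]
            matrices = {
                c: th.ContactMatrix(c, sim_cfg.bin_size, m)
                for c, m in study.contact_matrices.items()
            }
            loci, bin_size = study.loci, sim_cfg.bin_size
            results["truth"] = study.truth
        else:
            inputs = cfg["inputs"]
            annotation = (
                tio.read_annotation_gtf(inputs["annotation"])
                if str(inputs["annotation"]).endswith(".gtf")
                else tio.read_annotation_bed(inputs["annotation"])
            )
            counts = tio.read_counts(inputs["counts"])
            design = tio.read_design(inputs["design"])
            targets = pd.read_csv(inputs["targets"], sep="\t") if inputs.get("targets") else None
            pathways_path = inputs.get("pathways")
            bin_size = int(inputs.get("bin_size", 40_000))
            matrices = {}
            for path in inputs.get("hic", []):
                chrom = os.path.basename(path).split(".")[0].replace("hic_", "")
                fmt = "coo" if path.endswith(".coo.tsv") else "dense"
                matrices[chrom] = th.read_contact_matrix(path, format=fmt, bin_size=bin_size, chrom=chrom)
            loci = tio.read_loci(inputs["loci"]) if inputs.get("loci") else pd.DataFrame(
                columns=["name", "chrom", "snp_pos"]
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    class_of = annotation.set_index("feature_id")["rna_class"]

    # ---------------- differential expression
    stage = "de"
    try:
        cm = dx.CountMatrix(counts, design, class_of)
        sf = dx.size_factors_median_of_ratios(cm)
        de = dx.run_de(cm, sf, dispersion_mode=cfg["de"]["dispersion_mode"])
        de.to_csv(p("de_results.tsv"), sep="\t", float_format="%.10g")
        manifest_rows["de_results.tsv"] = len(de)
        thresholds = cfg["de"]["thresholds"]
        if thresholds is not None:
            thresholds = {k: tuple(v) for k, v in thresholds.items()}
        de_sets = {c: dx.filter_de(de, c, thresholds) for c in ("mRNA", "lncRNA", "miRNA")}
        results["de"], results["de_sets"], results["size_factors"] = de, de_sets, sf
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    de_genes = sorted(set(de_sets["mRNA"][0]) | set(de_sets["mRNA"][1]))
    de_lncs = sorted(set(de_sets["lncRNA"][0]) | set(de_sets["lncRNA"][1]))
    de_mirs = sorted(set(de_sets["miRNA"][0]) | set(de_sets["miRNA"][1]))
    directions = {}
    for cls_sets in de_sets.values():
        directions.update({f: "up" for f in cls_sets[0]})
        directions.update({f: "down" for f in cls_sets[1]})
    expr = dx.log2_normalized(counts, sf)

    # ---------------- co-expression
    pairs = pd.DataFrame(columns=["lnc_id", "mrna_id", "r"])
    modules = None
    selected_modules: list[str] = []
    if "coexpress" not in skip:
        stage = "coexpress"
        try:
            ccfg = cfg["coexpress"]
            if de_lncs and de_genes:
                pairs = cx.pcc_pairs(
                    expr.loc[de_lncs], expr.loc[de_genes],
                    r_min=ccfg["r_min"], use_abs=ccfg["use_abs"],
                )
            pairs.to_csv(p("pcc_pairs.tsv"), sep="\t", index=False, float_format="%.10g")
            manifest_rows["pcc_pairs.tsv"] = len(pairs)
            union = sorted(set(de_genes) | set(de_lncs))
            if len(union) >= 30:
                sub_expr = expr.loc[union]
                if ccfg["adjust_condition"]:
                    sub_expr = cx.condition_adjust(sub_expr, design)
                if ccfg["soft_power"] is not None:
                    beta = int(ccfg["soft_power"])
                else:
                    beta, _ = cx.pick_soft_power(sub_expr)
                t = cx.tom(cx.adjacency(sub_expr, beta=beta))
                modules = cx.detect_modules(
                    t, union, min_size=ccfg["min_size"], cut_height=ccfg["cut_height"]
                )
                modules.eigengenes = cx.module_eigengenes(sub_expr, modules.labels)
                modules.significance, selected_modules = cx.module_significance(
                    modules.labels, de, top_k=ccfg["top_k"]
                )
                modules.labels.rename("module").to_csv(p("modules.tsv"), sep="\t", index_label="feature_id")
                modules.eigengenes.to_csv(p("eigengenes.tsv"), sep="\t", float_format="%.10g", index_label="module")
                modules.significance.rename("significance").to_csv(
                    p("module_significance.tsv"), sep="\t", index_label="module", float_format="%.10g"
                )
                manifest_rows["modules.tsv"] = len(modules.labels)
            else:
                logger.warning("coexpress: fewer than 30 DE mRNA/lncRNA features; modules skipped")
            results["pcc_pairs"], results["modules"] = pairs, modules
            results["selected_modules"] = selected_modules
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, e) from e

    # ---------------- regulatory network
    net = None
    if "network" not in skip:
        stage = "network"
        try:
            ncfg = cfg["network"]
            mirna_edges = set()
            if targets is not None:
                mirna_edges = nw.build_mirna_edges(
                    de_mirs, de_genes, targets, restrict_to_de=ncfg["restrict_targets_to_de"]
                )
            net = nw.merge_network(
                mirna_edges, pcc_pairs=pairs if len(pairs) else None,
                classes=class_of.to_dict(), directions=directions,
            )
            ranking = nw.degree_ranking(net, top_n=ncfg["top_n"])
            ranking.to_csv(p("degree_top.tsv"), sep="\t", index=False)
            nw.export_graph(net, p("network.graphml"), "graphml")
            nw.export_graph(net, p("network.sif"), "sif")
            manifest_rows["degree_top.tsv"] = len(ranking)
            manifest_rows["network.sif"] = net.n_edges
            results["network"], results["degree_top"] = net, ranking
            if modules is not None and selected_modules:
                subnet, comps = nw.extract_module_subnetwork(net, modules.labels, selected_modules)
                nw.export_graph(subnet, p("module_subnetwork.sif"), "sif")
                manifest_rows["module_subnetwork.sif"] = subnet.n_edges
                results["module_subnetwork"], results["components"] = subnet, comps
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, e) from e

    # ---------------- enrichment
    if "enrichment" not in skip and pathways_path:
        stage = "enrichment"
        try:
            ecfg = cfg["enrichment"]
            detected_mrna = de.index[(de["rna_class"] == "mRNA") & de["detected"]]
            gsc = en.GeneSetCollection.from_gmt(pathways_path).restrict_universe(detected_mrna)
            tables = {}
            if de_genes:
                tables["degs"] = en.fisher_enrich(de_genes, gsc, p_cut=ecfg["p_cut"])
            lnc_targets = en.lncrna_target_substitution(de_lncs, pairs)
            if lnc_targets:
                tables["lnc_targets"] = en.fisher_enrich(lnc_targets, gsc, p_cut=ecfg["p_cut"])
            if targets is not None and de_mirs:
                mir_targets = sorted(
                    set(targets[targets["miRNA_id"].isin(de_mirs)]["target_id"])
                )
                if mir_targets:
                    tables["mir_targets"] = en.fisher_enrich(mir_targets, gsc, p_cut=ecfg["p_cut"])
            for name, tab in tables.items():
                tab.to_csv(p(f"enrichment_{name}.tsv"), sep="\t", index=False, float_format="%.10g")
                manifest_rows[f"enrichment_{name}.tsv"] = len(tab)
            if modules is not None and selected_modules:
                module_genes = {
                    m: [f for f in modules.members(m) if class_of.get(f) == "mRNA"]
                    for m in selected_modules
                }
                module_genes = {m: g for m, g in module_genes.items() if g}
                if module_genes:
                    _, reported = en.enrich_modules(module_genes, gsc, top_k=ecfg["top_k"], p_cut=ecfg["p_cut"])
                    reported.to_csv(p("enrichment_modules.tsv"), sep="\t", index=False, float_format="%.10g")
                    manifest_rows["enrichment_modules.tsv"] = len(reported)
                    tables["modules"] = reported
            results["enrichment"] = tables
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, e) from e

    # ---------------- TADs
    stage = "tads"
    try:
        tcfg = cfg["tads"]
        if tcfg.get("tads_bed"):
            tads = th.load_tads_bed(tcfg["tads_bed"])
        else:
            all_tads = []
            for chrom in sorted(matrices):
                cm_hic = matrices[chrom]
                track = insulation_track = th.insulation(cm_hic, w=tcfg["window"])
                insulation_track.to_frame().to_csv(
                    p(f"insulation_{chrom}.tsv"), sep="\t", index=False, float_format="%.6g"
                )
                called = th.call_tads(
                    track, delta_min=tcfg["delta"], min_bins=tcfg["min_bins"],
                    cm=cm_hic, sub=tcfg["sub"],
                )
                all_tads.extend(called.tads)
            tads = th.TadSet(tads=all_tads)
            tads.validate()
        th.write_tads_bed(tads, p("tads.bed"))
        manifest_rows["tads.bed"] = len(tads)
        results["tads"] = tads
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # ---------------- locus prioritization
    stage = "prioritize"
    try:
        pcfg = cfg["prioritize"]
        table, status = prioritize_loci(
            loci, tads, annotation, de,
            p_cut=pcfg["p_cut"], lfc_cut=pcfg["lfc_cut"],
            p_field=pcfg["p_field"], overlap=pcfg["overlap"],
        )
        table.to_csv(p("candidates.tsv"), sep="\t", index=False, float_format="%.10g")
        status.to_csv(p("locus_status.tsv"), sep="\t", index=False)
        manifest_rows["candidates.tsv"] = len(table)
        for locus in status["locus"]:
            sub = table[table["locus"] == locus]
            sub.to_csv(p(f"candidates_{locus}.tsv"), sep="\t", index=False, float_format="%.10g")
        results["candidates"], results["locus_status"] = table, status
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # ---------------- manifest
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "package": "tadscope",
        "version": _version(),
        "seed": cfg["seed"],
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "stages_skipped": sorted(skip),
        "rows": manifest_rows,
    }
    with open(p("run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("tadscope")
    except Exception:  # noqa: BLE001
        return "unknown"
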