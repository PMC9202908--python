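"""Synthetic data generator with known ground truth.

Generates, under one seed, every input the pipeline consumes: a gene
annotation over a toy genome, paired negative-binomial RNA-seq counts with
planted differential expression and latent-factor co-expression modules,
binned Hi-C contact matrices with planted TADs (Poisson noise on a
distance-decaying expected matrix), a miRNA-target table with a designated
hub miRNA, pathway gene sets with one deliberately DE-enriched set, and risk
loci planted inside specific TADs. Ground truth for every planted structure
is returned as machine-readable tables.

Randomness comes from a single :class:`numpy.random.SeedSequence` forked
once per output (annotation, counts, Hi-C, targets), so adding outputs never
perturbs earlier ones and identical configs yield byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as tio
from .config import (
    CONDITIONS,
    RNA_CLASSES,
    ConfigError,
    PlantedTad,
    SimulationConfig,
)

_CLASS_PREFIX = {"mRNA": "mRNA", "lncRNA": "lncRNA", "miRNA": "miRNA"}
_MIRNA_LENGTH = 80


@dataclass
class TruthTables:
    """Machine-readable ground truth for one simulated study."""

    de_truth: pd.DataFrame  # feature_id, rna_class, is_de, true_log2fc, locus
    module_truth: pd.DataFrame  # feature_id, module
    tad_truth: pd.DataFrame  # chrom, start_bp, end_bp, level
    candidate_truth: pd.DataFrame  # locus, feature_id, rna_class, log2fc, in_sub
    hub_mirna: str = ""
    enriched_pathway: str = ""


@dataclass
class SimulatedStudy:
    cfg: SimulationConfig
    annotation: pd.DataFrame
    counts: pd.DataFrame
    design: pd.DataFrame
    targets: pd.DataFrame
    pathways: dict[str, list[str]]
    contact_matrices: dict[str, np.ndarray]
    loci: pd.DataFrame
    truth: TruthTables
    files: dict[str, str] = field(default_factory=dict)


def _rngs(cfg: SimulationConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(cfg.seed).spawn(4)
    names = ("annotation", "counts", "hic", "targets")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ----------------------------------------------------------------------
# annotation


def _draw_tss(rng, lo: int, hi: int, used: set, avoid: tuple[int, int] | None = None) -> int:
    for _ in range(10_000):
        pos = int(rng.integers(lo, hi))
        if pos in used:
            continue
        if avoid is not None and avoid[0] <= pos < avoid[1]:
            continue
        used.add(pos)
        return pos
    raise ConfigError("could not place a feature TSS without collision")


def generate_annotation(cfg: SimulationConfig, rng=None) -> pd.DataFrame:
    """Place features of all three classes with distinct TSS positions.

    Background features are uniform over the genome; planted locus
    candidates are placed inside their target TAD (or its sub-TAD), at least
    ``tad_margin_bins`` bins away from the domain edges. Candidates of a TAD
    that carries a sub-TAD but are not flagged ``in_sub`` are kept outside
    the sub-TAD span so the parent/sub distinction is meaningful.
    """
    cfg.validate()
    rng = rng or _rngs(cfg)["annotation"]
    lengths = cfg.chrom_lengths()
    chroms = [c for c, _ in cfg.genome]
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    margin = cfg.tad_margin_bins * cfg.bin_size

    used_tss: dict[str, set] = {c: set() for c in chroms}
    rows = []

    # planted candidates first so their positions never depend on background size
    for locus in cfg.loci_plan:
        tad = cfg.tad_plan[locus.target_tad]
        for cand in locus.planted_candidates:
            lo, hi = cfg.tad_span_bp(tad, sub=cand.in_sub)
            lo, hi = lo + margin, hi - margin
            avoid = None
            if not cand.in_sub and tad.nested_sub is not None:
                avoid = cfg.tad_span_bp(tad, sub=True)
            tss = _draw_tss(rng, lo, hi, used_tss[locus.chrom], avoid)
            rows.append(_make_feature(rng, cand.feature_id, cand.rna_class, locus.chrom, tss, lengths))

    counts_by_class = {"mRNA": cfg.n_mrna, "lncRNA": cfg.n_lnc, "miRNA": cfg.n_mir}
    for cls in RNA_CLASSES:
        for i in range(counts_by_class[cls]):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            tss = _draw_tss(rng, 0, lengths[chrom], used_tss[chrom])
            fid = f"{_CLASS_PREFIX[cls]}_{i:04d}"
            rows.append(_make_feature(rng, fid, cls, chrom, tss, lengths))

    ann = pd.DataFrame(rows, columns=tio.ANNOTATION_COLUMNS)
    order = {c: i for i, c in enumerate(chroms)}
    ann = ann.sort_values(
        ["chrom", "tss", "feature_id"], key=lambda s: s.map(order) if s.name == "chrom" else s
    ).reset_index(drop=True)
    return ann


def _make_feature(rng, fid: str, cls: str, chrom: str, tss: int, lengths: dict) -> dict:
    strand = "+" if rng.random() < 0.5 else "-"
    length = _MIRNA_LENGTH if cls == "miRNA" else int(rng.integers(1_000, 30_001))
    if strand == "+":
        start, end = tss, min(tss + length, lengths[chrom])
    else:
        start, end = max(tss + 1 - length, 0), tss + 1
    return {
        "feature_id": fid,
        "rna_class": cls,
        "chrom": chrom,
        "start": start,
        "end": end,
        "strand": strand,
        "tss": tss,
    }


# ----------------------------------------------------------------------
# counts


def _locus_tad_spans(cfg: SimulationConfig) -> list[tuple[str, int, int]]:
    """bp spans of locus target TADs, padded by the configured margin."""
    pad = cfg.tad_margin_bins * cfg.bin_size
    spans = []
    for locus in cfg.loci_plan:
        tad = cfg.tad_plan[locus.target_tad]
        lo, hi = cfg.tad_span_bp(tad)
        spans.append((locus.chrom, lo - pad, hi + pad))
    return spans


def generate_counts(
    cfg: SimulationConfig, annotation: pd.DataFrame, rng=None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired NB counts with planted DE and latent-factor modules.

    For feature g in sample i (patient p, condition c):
    ``count ~ NB(mean = s_i * exp(mu_g + eta_{g,p} + lambda_g*f_{m(g),i}
    + beta_g*ln2*[c == lesion]), dispersion alpha)`` where beta_g is the
    planted log2FC (0 for non-DE features). The patient effect eta is drawn
    independently per feature so it does not induce cross-feature
    correlation; module members share the per-sample factor f instead.

    Returns ``(counts, design, de_truth, module_truth)``.
    """
    cfg.validate()
    rng = rng or _rngs(cfg)["counts"]
    G = len(annotation)
    samples, patients, is_lesion = [], [], []
    for p in range(1, cfg.n_patients + 1):
        for cond in CONDITIONS:
            samples.append(f"P{p}_{cond}")
            patients.append(f"P{p}")
            is_lesion.append(1.0 if cond == "lesion" else 0.0)
    n = len(samples)
    design = pd.DataFrame(
        {"sample": samples, "patient": patients, "condition": [CONDITIONS[int(l)] for l in is_lesion]}
    )
    is_lesion = np.array(is_lesion)

    feats = annotation["feature_id"].to_numpy()
    classes = annotation["rna_class"].to_numpy()
    planted = {
        c.feature_id: (locus.name, c.log2fc)
        for locus in cfg.loci_plan
        for c in locus.planted_candidates
    }

    # eligibility for background DE: TSS outside every (padded) locus TAD
    spans = _locus_tad_spans(cfg)
    in_locus_tad = np.zeros(G, dtype=bool)
    for chrom, lo, hi in spans:
        in_locus_tad |= (
            (annotation["chrom"] == chrom)
            & (annotation["tss"] >= lo)
            & (annotation["tss"] < hi)
        ).to_numpy()

    beta = np.zeros(G)
    is_de = np.zeros(G, dtype=bool)
    locus_of = np.array([""] * G, dtype=object)
    for i, fid in enumerate(feats):
        if fid in planted:
            locus_of[i], beta[i] = planted[fid]
            is_de[i] = True

    for cls in RNA_CLASSES:
        cls_mask = classes == cls
        eligible = np.flatnonzero(cls_mask & ~in_locus_tad & ~is_de)
        n_de = int(round(cfg.de_fraction_per_class * cls_mask.sum()))
        n_de = min(n_de, eligible.size)
        if n_de > 0:
            chosen = rng.choice(eligible, size=n_de, replace=False)
            mag = cfg.de_log2fc_by_class.get(cls, 0.0)
            signs = rng.choice([-1.0, 1.0], size=n_de)
            beta[chosen] = mag * signs
            is_de[chosen] = True

    # co-expression modules among background DE mRNA/lncRNA features
    module_of = np.array([""] * G, dtype=object)
    loading = np.zeros(G)
    factors = np.zeros((max(cfg.n_modules, 1), n))
    if cfg.n_modules > 0:
        pool = np.flatnonzero(is_de & (locus_of == "") & np.isin(classes, ("mRNA", "lncRNA")))
        need = cfg.n_modules * cfg.module_size
        if pool.size < need:
            raise ConfigError(
                f"not enough background DE mRNA/lncRNA features for modules "
                f"({pool.size} < {need}); raise de_fraction_per_class or shrink modules"
            )
        members = rng.choice(pool, size=need, replace=False)
        factors = rng.normal(0.0, 1.0, size=(cfg.n_modules, n))
        # With a handful of samples, independently drawn factors are often
        # accidentally collinear with each other or with the lesion/normal
        # contrast, which would merge planted modules into one another or
        # into the global DE axis. Planted modules are meant to be distinct
        # expression programs, so realized factors are orthogonalized
        # against the condition contrast and each other, then rescaled to
        # the configured spread.
        cond = is_lesion - is_lesion.mean()
        basis = [cond / np.linalg.norm(cond)]
        for m in range(cfg.n_modules):
            f = factors[m] - factors[m].mean()
            for b_vec in basis:
                f = f - (f @ b_vec) * b_vec
            nrm = np.linalg.norm(f)
            if nrm > 1e-12 and len(basis) < n - 1:
                basis.append(f / nrm)
                f = f / f.std()
            factors[m] = f * cfg.module_factor_sd
        for m in range(cfg.n_modules):
            idx = members[m * cfg.module_size : (m + 1) * cfg.module_size]
            module_of[idx] = f"M{m + 1}"
            loading[idx] = rng.uniform(0.5, 1.0, size=idx.size)
            # a module moves coherently: members share one DE direction,
            # otherwise the condition effect would split it by sign
            beta[idx] = np.abs(beta[idx]) * (1.0 if m % 2 == 0 else -1.0)

    lo, hi = cfg.baseline_log_mean_range
    mu0 = rng.uniform(lo, hi, size=G)
    eta = rng.normal(0.0, cfg.patient_effect_sd, size=(G, cfg.n_patients))
    size_factors = np.exp(rng.normal(0.0, cfg.libsize_sd, size=n)) if cfg.libsize_sd > 0 else np.ones(n)

    patient_idx = np.repeat(np.arange(cfg.n_patients), len(CONDITIONS))
    log_mean = (
        mu0[:, None]
        + eta[:, patient_idx]
        + beta[:, None] * np.log(2.0) * is_lesion[None, :]
    )
    module_idx = {f"M{m + 1}": m for m in range(cfg.n_modules)}
    has_mod = module_of != ""
    if has_mod.any():
        mrows = np.array([module_idx[m] for m in module_of[has_mod]])
        log_mean[has_mod] += loading[has_mod, None] * factors[mrows]
    mean = size_factors[None, :] * np.exp(log_mean)

    # gamma-Poisson mixture == NB with var = mean + alpha * mean^2
    lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=cfg.dispersion * mean)
    counts = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=pd.Index(feats, name="feature_id"), columns=samples)
    de_truth = pd.DataFrame(
        {
            "feature_id": feats,
            "rna_class": classes,
            "is_de": is_de,
            "true_log2fc": beta,
            "locus": locus_of,
        }
    )
    module_truth = pd.DataFrame(
        {"feature_id": feats[has_mod], "module": module_of[has_mod]}
    ).sort_values(["module", "feature_id"]).reset_index(drop=True)
    return counts_df, design, de_truth, module_truth


# ----------------------------------------------------------------------
# Hi-C


def expected_contacts(cfg: SimulationConfig, chrom: str) -> np.ndarray:
    """Noise-free expected contact matrix: rate / (1 + |i - j|) with the
    intra-TAD rate inside planted TADs (sub-TAD rate inside nested subs)."""
    nb = cfg.n_bins(chrom)
    i = np.arange(nb)
    decay = 1.0 / (1.0 + np.abs(i[:, None] - i[None, :]))
    rate = np.full((nb, nb), cfg.inter_tad_rate)
    for tad in cfg.tad_plan:
        if tad.chrom != chrom:
            continue
        s, e = tad.start_bin, tad.end_bin
        rate[s:e, s:e] = cfg.intra_tad_rate
        if tad.nested_sub is not None:
            ss, se = tad.nested_sub
            rate[ss:se, ss:se] = cfg.effective_sub_tad_rate()
    return rate * decay


def generate_hic(cfg: SimulationConfig, rng=None) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Poisson-sampled symmetric contact matrices plus the planted-TAD truth."""
    cfg.validate()
    rng = rng or _rngs(cfg)["hic"]
    matrices = {}
    for chrom, _ in cfg.genome:
        exp = expected_contacts(cfg, chrom)
        upper = rng.poisson(np.triu(exp))
        m = upper + np.triu(upper, k=1).T
        matrices[chrom] = m.astype(np.int64)
    rows = []
    for tad in cfg.tad_plan:
        lo, hi = cfg.tad_span_bp(tad)
        rows.append({"chrom": tad.chrom, "start_bp": lo, "end_bp": hi, "level": "tad"})
        if tad.nested_sub is not None:
            lo, hi = cfg.tad_span_bp(tad, sub=True)
            rows.append({"chrom": tad.chrom, "start_bp": lo, "end_bp": hi, "level": "sub_tad"})
    tad_truth = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "level"])
    return matrices, tad_truth


# ----------------------------------------------------------------------
# miRNA targets and pathways


def generate_targets_and_pathways(
    cfg: SimulationConfig, annotation: pd.DataFrame, de_truth: pd.DataFrame, rng=None
) -> tuple[pd.DataFrame, dict[str, list[str]], str, str]:
    """miRNA-target edges, pathway gene sets, and their planted truth.

    One DE miRNA is designated the hub (strictly maximal out-degree,
    mirroring the dominant regulator observed in real keloid data); one
    pathway is deliberately enriched for planted DE mRNAs.

    Returns ``(targets, pathways, hub_mirna, enriched_pathway)``.
    """
    cfg.validate()
    rng = rng or _rngs(cfg)["targets"]
    mirna_ids = sorted(annotation.loc[annotation["rna_class"] == "miRNA", "feature_id"])
    mrna_ids = sorted(annotation.loc[annotation["rna_class"] == "mRNA", "feature_id"])
    if mirna_ids and not mrna_ids:
        raise ConfigError("cannot assign miRNA targets: no mRNA features")

    de_map = de_truth.set_index("feature_id")["is_de"]
    de_mirnas = [m for m in mirna_ids if bool(de_map.get(m, False))]
    hub = de_mirnas[0] if de_mirnas else (mirna_ids[0] if mirna_ids else "")

    rows = []
    degrees = {}
    for mid in mirna_ids:
        if mid == hub:
            continue
        d = int(rng.geometric(cfg.target_degree_p))
        degrees[mid] = min(max(d, 1), len(mrna_ids))
    max_other = max(degrees.values(), default=0)
    if hub:
        degrees[hub] = min(len(mrna_ids), max_other + max(5, max_other // 4))
        if degrees[hub] <= max_other:
            raise ConfigError("n_mrna too small for the hub miRNA to dominate out-degree")
    for mid in mirna_ids:
        targets = rng.choice(mrna_ids, size=degrees[mid], replace=False)
        for t in sorted(targets):
            rows.append({"miRNA_id": mid, "target_id": t})
    targets_df = pd.DataFrame(rows, columns=["miRNA_id", "target_id"])

    de_mrnas = sorted(de_truth.loc[(de_truth["rna_class"] == "mRNA") & de_truth["is_de"], "feature_id"])
    de_mrnas = [m for m in de_mrnas if m in set(mrna_ids)]
    pathways: dict[str, list[str]] = {}
    lo, hi = cfg.pathway_size_range
    if cfg.n_pathways > 0 and mrna_ids:
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(mrna_ids))
        n_de = min(int(round(cfg.enriched_pathway_frac * size)), len(de_mrnas))
        non_de_pool = sorted(set(mrna_ids) - set(de_mrnas))
        de_part = sorted(rng.choice(de_mrnas, size=n_de, replace=False)) if n_de else []
        rest = sorted(rng.choice(non_de_pool, size=min(size - n_de, len(non_de_pool)), replace=False))
        pathways["pathway_enriched"] = de_part + rest
        for i in range(1, cfg.n_pathways):
            size = min(int(rng.integers(lo, hi + 1)), len(mrna_ids))
            pathways[f"pathway_{i:02d}"] = sorted(rng.choice(mrna_ids, size=size, replace=False))
    enriched = "pathway_enriched" if pathways else ""
    return targets_df, pathways, hub, enriched


# ----------------------------------------------------------------------
# top level


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Run every generator under forked RNG streams; nothing written to disk."""
    cfg.validate()
    rngs = _rngs(cfg)
    ann = generate_annotation(cfg, rngs["annotation"])
    counts, design, de_truth, module_truth = generate_counts(cfg, ann, rngs["counts"])
    matrices, tad_truth = generate_hic(cfg, rngs["hic"])
    targets, pathways, hub, enriched = generate_targets_and_pathways(
        cfg, ann, de_truth, rngs["targets"]
    )
    cand_rows = [
        {
            "locus": locus.name,
            "feature_id": c.feature_id,
            "rna_class": c.rna_class,
            "log2fc": c.log2fc,
            "in_sub": c.in_sub,
        }
        for locus in cfg.loci_plan
        for c in locus.planted_candidates
    ]
    candidate_truth = pd.DataFrame(
        cand_rows, columns=["locus", "feature_id", "rna_class", "log2fc", "in_sub"]
    )
    loci = pd.DataFrame(
        [{"name": l.name, "chrom": l.chrom, "snp_pos": l.snp_pos} for l in cfg.loci_plan],
        columns=["name", "chrom", "snp_pos"],
    )
    truth = TruthTables(
        de_truth=de_truth,
        module_truth=module_truth,
        tad_truth=tad_truth,
        candidate_truth=candidate_truth,
        hub_mirna=hub,
        enriched_pathway=enriched,
    )
    return SimulatedStudy(
        cfg=cfg,
        annotation=ann,
        counts=counts,
        design=design,
        targets=targets,
        pathways=pathways,
        contact_matrices=matrices,
        loci=loci,
        truth=truth,
    )


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Write every generated input plus the truth tables; returns file paths."""
    from . import hic as thic

    tio.ensure_dir(outdir)
    p = lambda name: os.path.join(str(outdir), name)
    files = {}

    tio.write_annotation_gtf(study.annotation, p("annotation.gtf"))
    tio.write_annotation_bed(study.annotation, p("annotation.bed"))
    files["annotation_gtf"], files["annotation_bed"] = p("annotation.gtf"), p("annotation.bed")
    tio.write_counts(study.counts, p("counts.tsv"))
    files["counts"] = p("counts.tsv")
    tio.write_design(study.design, p("design.tsv"))
    files["design"] = p("design.tsv")
    study.targets.to_csv(p("targets.tsv"), sep="\t", index=False)
    files["targets"] = p("targets.tsv")
    tio.write_gmt(study.pathways, p("pathways.gmt"))
    files["pathways"] = p("pathways.gmt")
    for chrom, m in study.contact_matrices.items():
        thic.write_dense(m, p(f"hic_{chrom}.tsv"))
        thic.write_coo(m, p(f"hic_{chrom}.coo.tsv"))
        files[f"hic_{chrom}"] = p(f"hic_{chrom}.tsv")
        files[f"hic_{chrom}_coo"] = p(f"hic_{chrom}.coo.tsv")
    tio.write_loci_bed(study.loci, p("loci.bed"))
    files["loci"] = p("loci.bed")

    t = study.truth
    t.de_truth.to_csv(p("truth_de.tsv"), sep="\t", index=False, float_format="%.10g")
    t.module_truth.to_csv(p("truth_modules.tsv"), sep="\t", index=False)
    t.tad_truth.to_csv(p("truth_tads.tsv"), sep="\t", index=False)
    t.candidate_truth.to_csv(p("truth_candidates.tsv"), sep="\t", index=False, float_format="%.10g")
    with open(p("truth_misc.json"), "w") as fh:
        json.dump(
            {"hub_mirna": t.hub_mirna, "enriched_pathway": t.enriched_pathway},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    for k in ("de", "modules", "tads", "candidates"):
        files[f"truth_{k}"] = p(f"truth_{k}.tsv")
    files["truth_misc"] = p("truth_misc.json")
    study.files = files
    return files
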