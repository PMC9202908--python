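"""Simulation configuration for the synthetic keloid-style study design.

The generator emulates a paired lesion/normal RNA-seq design (three patients,
two conditions) over three RNA classes, together with binned Hi-C contact
maps carrying planted topologically associating domains (TADs) and risk loci
planted inside specific TADs. Every tunable of the generative model lives
here so that a single :class:`SimulationConfig` (including its seed) fully
determines every output file byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")

#: Condition labels, in the fixed order used for sample ids.
CONDITIONS = ("normal", "lesion")


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class PlantedTad:
    """A planted TAD in bin units (half-open), optionally with a nested sub-TAD."""

    chrom: str
    start_bin: int
    end_bin: int
    nested_sub: Optional[tuple[int, int]] = None

    def validate(self) -> None:
        if not self.start_bin < self.end_bin:
            raise ConfigError(
                f"TAD on {self.chrom}: start_bin {self.start_bin} must be < end_bin {self.end_bin}"
            )
        if self.nested_sub is not None:
            s, e = self.nested_sub
            if not (self.start_bin < s < e < self.end_bin):
                raise ConfigError(
                    f"nested sub-TAD ({s},{e}) must lie strictly inside ({self.start_bin},{self.end_bin})"
                )


@dataclass(frozen=True)
class PlantedCandidate:
    """A DE feature planted inside a risk locus's target TAD.

    ``in_sub`` places the TSS inside the TAD's nested sub-TAD (the
    "upregulated genes within the sub-TAD" situation).
    """

    feature_id: str
    rna_class: str
    log2fc: float
    in_sub: bool = False

    def validate(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ConfigError(f"unknown RNA class {self.rna_class!r}")
        if not math.isfinite(self.log2fc) or self.log2fc == 0.0:
            raise ConfigError(
                f"planted log2FC for {self.feature_id} must be finite and nonzero"
            )


@dataclass(frozen=True)
class PlantedLocus:
    """A susceptibility locus: one risk SNP inside a target TAD, plus the
    candidate features planted in that TAD (possibly none — an "empty" locus)."""

    name: str
    chrom: str
    snp_pos: int
    target_tad: int
    planted_candidates: tuple[PlantedCandidate, ...] = ()


@dataclass
class SimulationConfig:
    seed: int = 0
    n_patients: int = 3
    n_mrna: int = 1000
    n_lnc: int = 400
    n_mir: int = 80
    #: (chrom_name, length_bp) pairs; lengths must be multiples of bin_size.
    genome: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 12_000_000), ("chr2", 8_000_000)]
    )
    bin_size: int = 40_000
    #: Natural-log scale of per-feature baseline mean counts.
    baseline_log_mean_range: tuple[float, float] = (3.0, 8.0)
    dispersion: float = 0.05
    patient_effect_sd: float = 0.30
    libsize_sd: float = 0.15
    de_fraction_per_class: float = 0.15
    de_log2fc_by_class: dict[str, float] = field(
        default_factory=lambda: {"mRNA": 2.0, "lncRNA": 2.0, "miRNA": 1.0}
    )
    n_modules: int = 3
    module_size: int = 40
    module_factor_sd: float = 2.0
    tad_plan: list[PlantedTad] = field(default_factory=list)
    loci_plan: list[PlantedLocus] = field(default_factory=list)
    intra_tad_rate: float = 75.0
    inter_tad_rate: float = 25.0
    #: Contact rate inside a nested sub-TAD; default 2x the parent rate.
    sub_tad_rate: Optional[float] = None
    #: Candidate TSSs stay this many bins away from their TAD's edges, and
    #: background DE features stay this far outside every locus TAD.
    tad_margin_bins: int = 1
    # --- miRNA-target / pathway generator knobs ---
    target_degree_p: float = 0.05
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (20, 80)
    enriched_pathway_frac: float = 0.6

    # ------------------------------------------------------------------
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.genome)

    def n_bins(self, chrom: str) -> int:
        return self.chrom_lengths()[chrom] // self.bin_size

    def effective_sub_tad_rate(self) -> float:
        return 2.0 * self.intra_tad_rate if self.sub_tad_rate is None else self.sub_tad_rate

    def tad_span_bp(self, tad: PlantedTad, sub: bool = False) -> tuple[int, int]:
        if sub:
            if tad.nested_sub is None:
                raise ConfigError(f"TAD on {tad.chrom} has no nested sub-TAD")
            s, e = tad.nested_sub
        else:
            s, e = tad.start_bin, tad.end_bin
        return s * self.bin_size, e * self.bin_size

    def validate(self) -> None:
        lengths = self.chrom_lengths()
        if not self.genome:
            raise ConfigError("genome must be non-empty")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        if not self.intra_tad_rate > self.inter_tad_rate:
            raise ConfigError("intra_tad_rate must exceed inter_tad_rate")
        if not 0.0 <= self.de_fraction_per_class <= 1.0:
            raise ConfigError("de_fraction_per_class must be in [0, 1]")
        for name, length in self.genome:
            if length % self.bin_size != 0:
                raise ConfigError(f"bin_size must divide the length of {name}")
        for cls, lfc in self.de_log2fc_by_class.items():
            if cls not in RNA_CLASSES:
                raise ConfigError(f"unknown RNA class {cls!r} in de_log2fc_by_class")
            if not math.isfinite(lfc) or lfc == 0.0:
                raise ConfigError(f"de_log2fc for {cls} must be finite and nonzero")
        for tad in self.tad_plan:
            if tad.chrom not in lengths:
                raise ConfigError(f"TAD references unknown chrom {tad.chrom!r}")
            tad.validate()
            if tad.end_bin > self.n_bins(tad.chrom):
                raise ConfigError(f"TAD on {tad.chrom} extends past the chromosome")
        # same-chrom planted TADs must not overlap (nesting is declared inside)
        by_chrom: dict[str, list[PlantedTad]] = {}
        for tad in self.tad_plan:
            by_chrom.setdefault(tad.chrom, []).append(tad)
        for chrom, tads in by_chrom.items():
            spans = sorted((t.start_bin, t.end_bin) for t in tads)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ConfigError(f"planted TADs overlap on {chrom}")
        for locus in self.loci_plan:
            if locus.chrom not in lengths:
                raise ConfigError(f"locus {locus.name} references unknown chrom {locus.chrom!r}")
            if not 0 <= locus.target_tad < len(self.tad_plan):
                raise ConfigError(f"locus {locus.name}: target_tad out of range")
            tad = self.tad_plan[locus.target_tad]
            if tad.chrom != locus.chrom:
                raise ConfigError(f"locus {locus.name} and its target TAD are on different chroms")
            lo, hi = self.tad_span_bp(tad)
            if not lo <= locus.snp_pos < hi:
                raise ConfigError(f"locus {locus.name}: snp_pos outside its target TAD span")
            for cand in locus.planted_candidates:
                cand.validate()
                if cand.in_sub and tad.nested_sub is None:
                    raise ConfigError(
                        f"locus {locus.name}: candidate {cand.feature_id} requests a "
                        "sub-TAD but the target TAD has none"
                    )

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["genome"] = [tuple(g) for g in d.get("genome", [])] or None
        if d["genome"] is None:
            d.pop("genome")
        if "baseline_log_mean_range" in d:
            d["baseline_log_mean_range"] = tuple(d["baseline_log_mean_range"])
        if "pathway_size_range" in d:
            d["pathway_size_range"] = tuple(d["pathway_size_range"])
        if "tad_plan" in d:
            d["tad_plan"] = [
                t if isinstance(t, PlantedTad) else PlantedTad(
                    chrom=t["chrom"],
                    start_bin=t["start_bin"],
                    end_bin=t["end_bin"],
                    nested_sub=tuple(t["nested_sub"]) if t.get("nested_sub") else None,
                )
                for t in d["tad_plan"]
            ]
        if "loci_plan" in d:
            loci = []
            for l in d["loci_plan"]:
                if isinstance(l, PlantedLocus):
                    loci.append(l)
                    continue
                cands = tuple(
                    c if isinstance(c, PlantedCandidate) else PlantedCandidate(
                        feature_id=c["feature_id"],
                        rna_class=c["rna_class"],
                        log2fc=float(c["log2fc"]),
                        in_sub=bool(c.get("in_sub", False)),
                    )
                    for c in l.get("planted_candidates", ())
                )
                loci.append(
                    PlantedLocus(
                        name=l["name"],
                        chrom=l["chrom"],
                        snp_pos=int(l["snp_pos"]),
                        target_tad=int(l["target_tad"]),
                        planted_candidates=cands,
                    )
                )
            d["loci_plan"] = loci
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def default_config(seed: int = 0) -> SimulationConfig:
    """The default synthetic study: 3 patients x 2 conditions, two chromosomes,
    six planted TADs (one with a nested sub-TAD) and three risk loci.

    The loci mirror the published analysis layout: one locus with four
    upregulated candidates, one deliberately empty locus, and one locus whose
    TAD carries three downregulated candidates plus three upregulated
    candidates confined to its sub-TAD — ten planted candidates in total.
    """
    # TADs tile each chromosome, as in real genomes; boundaries between
    # adjacent domains are what the insulation caller recovers.
    chr1_edges = [0, 20, 40, 60, 80, 100, 120, 145, 170, 190, 215, 240, 260, 280, 300]
    chr2_edges = [0, 15, 30, 45, 65, 85, 100, 120, 140, 160, 180, 200]
    tads = [
        PlantedTad("chr1", s, e, nested_sub=(64, 72) if (s, e) == (60, 80) else None)
        for s, e in zip(chr1_edges, chr1_edges[1:])
    ] + [PlantedTad("chr2", s, e) for s, e in zip(chr2_edges, chr2_edges[1:])]
    tad_index = {(t.chrom, t.start_bin, t.end_bin): i for i, t in enumerate(tads)}
    loci = [
        PlantedLocus(
            name="locus_A",
            chrom="chr1",
            snp_pos=28 * 40_000 + 13_000,
            target_tad=tad_index[("chr1", 20, 40)],
            planted_candidates=(
                PlantedCandidate("candA_mRNA_up1", "mRNA", 2.5),
                PlantedCandidate("candA_lncRNA_up1", "lncRNA", 2.0),
                PlantedCandidate("candA_lncRNA_up2", "lncRNA", 3.0),
                PlantedCandidate("candA_lncRNA_up3", "lncRNA", 2.0),
            ),
        ),
        PlantedLocus(
            name="locus_B",
            chrom="chr2",
            snp_pos=37 * 40_000 + 5_000,
            target_tad=tad_index[("chr2", 30, 45)],
            planted_candidates=(),
        ),
        PlantedLocus(
            name="locus_C",
            chrom="chr1",
            snp_pos=66 * 40_000 + 20_000,
            target_tad=tad_index[("chr1", 60, 80)],
            planted_candidates=(
                PlantedCandidate("candC_mRNA_down1", "mRNA", -2.0),
                PlantedCandidate("candC_lncRNA_down1", "lncRNA", -2.5),
                PlantedCandidate("candC_lncRNA_down2", "lncRNA", -2.0),
                PlantedCandidate("candC_mRNA_up1", "mRNA", 2.0, in_sub=True),
                PlantedCandidate("candC_mRNA_up2", "mRNA", 2.5, in_sub=True),
                PlantedCandidate("candC_mRNA_up3", "mRNA", 2.0, in_sub=True),
            ),
        ),
    ]
    cfg = SimulationConfig(seed=seed, tad_plan=tads, loci_plan=loci)
    cfg.validate()
    return cfg
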