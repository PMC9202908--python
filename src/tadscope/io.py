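"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinate conventions: everything in memory is 0-based half-open. GTF is
written 1-based closed and BED 0-based half-open, the standard dialects of
each format. All writers produce deterministic, byte-stable output for a
given input (fixed column order, fixed float formatting, sorted rows where
the in-memory container is unordered).
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import pandas as pd

ANNOTATION_COLUMNS = ["feature_id", "rna_class", "chrom", "start", "end", "strand", "tss"]


# ----------------------------------------------------------------------
# annotation


def write_annotation_gtf(ann: pd.DataFrame, path) -> None:
    """Write one ``gene`` line per feature (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for row in ann.itertuples(index=False):
            attrs = f'gene_id "{row.feature_id}"; gene_biotype "{row.rna_class}";'
            fh.write(
                f"{row.chrom}\ttadscope\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def read_annotation_gtf(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in f[8].rstrip(";").split(";")
                if kv.strip()
            )
            start = int(f[3]) - 1
            end = int(f[4])
            strand = f[6]
            rows.append(
                {
                    "feature_id": attrs["gene_id"],
                    "rna_class": attrs.get("gene_biotype", "mRNA"),
                    "chrom": f[0],
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "tss": start if strand == "+" else end - 1,
                }
            )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotation_bed(ann: pd.DataFrame, path) -> None:
    """BED6 + rna_class column (0-based half-open)."""
    with open(path, "w") as fh:
        for row in ann.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.feature_id}\t0\t"
                f"{row.strand}\t{row.rna_class}\n"
            )


def read_annotation_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "feature_id", "score", "strand", "rna_class"],
    )
    df["tss"] = df["start"].where(df["strand"] == "+", df["end"] - 1)
    return df[ANNOTATION_COLUMNS]


# ----------------------------------------------------------------------
# counts / design


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "patient": str, "condition": str})
    return df


# ----------------------------------------------------------------------
# GMT gene sets


def write_gmt(sets: dict[str, Iterable[str]], path, descriptions: Optional[dict] = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Standard GMT dialect: name, description, then members (tab-separated).

    Duplicate members within a set are dropped, keeping first occurrence.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0]:
                continue
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            sets[fields[0]] = members
    return sets


# ----------------------------------------------------------------------
# loci


def write_loci_bed(loci: pd.DataFrame, path) -> None:
    """Loci as BED: chrom, snp_pos, snp_pos+1, name."""
    with open(path, "w") as fh:
        for row in loci.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_pos}\t{row.snp_pos + 1}\t{row.name}\n")


def read_loci(path) -> pd.DataFrame:
    """Read loci from BED (chrom, start, end, name) or a ``chrom:pos`` list.

    For interval rows the SNP position is taken as the interval start.
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                f = line.split("\t")
                name = f[3] if len(f) > 3 else f"locus_{i + 1}"
                rows.append({"name": name, "chrom": f[0], "snp_pos": int(f[1])})
            else:
                chrom, pos = line.split(":")
                rows.append({"name": line, "chrom": chrom, "snp_pos": int(pos)})
    return pd.DataFrame(rows, columns=["name", "chrom", "snp_pos"])


# ----------------------------------------------------------------------


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
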