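"""Readers and writers for the flat-text formats the pipeline exchanges.

Variant candidates travel as MAF-like TSV (one row per call, QC metrics
as columns) with an optional minimal VCFv4.2 rendering whose INFO field
carries the same metrics.  Copy-number segments use a SEG-like TSV,
expression a genes x samples TSV, gene sets GMT, and the cancer-gene
catalogue a three-column TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

VARIANT_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "variant_type", "gene", "effect",
    "quality_score", "depth", "vaf_tumor", "vaf_normal",
    "var_reads_fwd", "var_reads_rev", "avg_clipped_length", "avg_pos_as_fraction",
    "ref_mapq0", "ref_mapq1", "var_mapq0", "var_mapq1",
    "avg_read_len_ref", "avg_read_len_var", "context_5p", "context_3p",
]

SEG_COLUMNS = [
    "sample", "chrom", "start", "end", "n_snvs",
    "copy_number", "p_value", "log2_mbaf_adj",
]

#: INFO keys used in the minimal VCF rendering, in emission order
_VCF_INFO_KEYS = [
    ("VT", "variant_type", str),
    ("GENE", "gene", str),
    ("EFF", "effect", str),
    ("QS", "quality_score", float),
    ("DP", "depth", float),
    ("VAFT", "vaf_tumor", float),
    ("VAFN", "vaf_normal", float),
    ("VRF", "var_reads_fwd", int),
    ("VRR", "var_reads_rev", int),
    ("ACL", "avg_clipped_length", float),
    ("APF", "avg_pos_as_fraction", float),
    ("RM0", "ref_mapq0", int),
    ("RM1", "ref_mapq1", int),
    ("VM0", "var_mapq0", int),
    ("VM1", "var_mapq1", int),
    ("ARL", "avg_read_len_ref", float),
    ("AVL", "avg_read_len_var", float),
    ("C5", "context_5p", str),
    ("C3", "context_3p", str),
]


def read_variants_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in ("chrom", "pos", "ref", "alt", "variant_type") if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} lacks required columns: {missing}")
    return df


def write_variants_tsv(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in VARIANT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, sep="\t", index=False, columns=cols, lineterminator="\n")


def write_variants_vcf(df: pd.DataFrame, path: str | Path, sample: str = "TUMOR") -> None:
    """Minimal VCFv4.2 with QC metrics in INFO (no genotypes)."""
    lines = ["##fileformat=VCFv4.2", f"##source=hccsvr", f"##sample={sample}"]
    for key, col, typ in _VCF_INFO_KEYS:
        vtype = {str: "String", float: "Float", int: "Integer"}[typ]
        lines.append(f'##INFO=<ID={key},Number=1,Type={vtype},Description="{col}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for _, row in df.iterrows():
        info = []
        for key, col, typ in _VCF_INFO_KEYS:
            if col in row and pd.notna(row[col]) and str(row[col]) != "":
                val = row[col]
                if typ is int:
                    val = int(val)
                info.append(f"{key}={val}")
        qual = row.get("quality_score", ".")
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}"
            f"\t{qual}\t.\t{';'.join(info) if info else '.'}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_variants_vcf(path: str | Path) -> pd.DataFrame:
    """Parse the minimal VCF rendering back into the MAF-like table."""
    typemap = {key: (col, typ) for key, col, typ in _VCF_INFO_KEYS}
    records = []
    sample = ""
    for line in Path(path).read_text().splitlines():
        if line.startswith("##sample="):
            sample = line.split("=", 1)[1]
            continue
        if line.startswith("#"):
            continue
        chrom, pos, _id, ref, alt, _qual, _filt, info = line.split("\t")[:8]
        rec: dict = {"sample": sample, "chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt}
        if info != ".":
            for kv in info.split(";"):
                key, val = kv.split("=", 1)
                if key in typemap:
                    col, typ = typemap[key]
                    rec[col] = typ(val)
        records.append(rec)
    return pd.DataFrame(records)


def read_seg(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"segment table {path} lacks columns: {missing}")
    return df


def write_seg(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SEG_COLUMNS, lineterminator="\n")


def segments_to_bed(df: pd.DataFrame) -> pd.DataFrame:
    """SEG (1-based inclusive) to BED (0-based half-open) coordinates."""
    bed = df[["chrom", "start", "end", "sample"]].copy()
    bed["start"] = bed["start"] - 1
    return bed


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = parts[2:]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc] + list(genes)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples matrix; first column is the gene symbol index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene", lineterminator="\n", float_format="%.6g")


def read_catalogue_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "role"):
        if col not in df.columns:
            raise ValueError(f"catalogue {path} lacks column {col!r}")
    return df


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
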