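"""Readers and writers for the formats the pipeline touches.

VCF input goes through cyvcf2; only bi-allelic SNP records are retained (the
first step of the site-level quality ladder), and symbolic/indel/multi-allelic
records are skipped with a logged count.  VCF output is a minimal GT-only
VCF 4.2 writer.  Tabular inputs (gene models, depths, CDS alignment pairs,
skeleton markers, traits, metadata, windows) are TSV/CSV with a header and a
named schema.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, WindowTable

logger = logging.getLogger("hapweave.io")

__all__ = ["read_vcf", "write_vcf", "read_table", "write_table", "TABLE_SCHEMAS", "SchemaError"]

_BASES = {"A", "C", "G", "T"}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def read_vcf(path, panel_map: dict | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only bi-allelic SNP records are kept; multi-allelic, indel and symbolic
    ALT records are skipped (count logged).  Phased and unphased genotypes
    are both accepted; phase is not preserved.

    Parameters
    ----------
    path : str
        VCF file (plain text or bgzipped).
    panel_map : dict, optional
        Accession id -> panel label.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise ValueError(f"{path}: malformed VCF header ({exc})") from exc
    samples = list(vcf.samples)
    chroms, pos, ref, alt, rows = [], [], [], [], []
    n_skipped = 0
    for v in vcf:
        if (
            len(v.ALT) != 1
            or len(v.REF) != 1
            or len(v.ALT[0]) != 1
            or v.REF.upper() not in _BASES
            or v.ALT[0].upper() not in _BASES
        ):
            n_skipped += 1
            continue
        chroms.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF.upper())
        alt.append(v.ALT[0].upper())
        g = v.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g[g == 3] = MISSING
        rows.append(g)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-bi-allelic-SNP records in %s", n_skipped, path)
    calls = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    panel = dict(panel_map) if panel_map else {}
    return GenotypeMatrix(
        np.array(chroms, dtype=object),
        np.array(pos, dtype=np.int64),
        np.array(ref, dtype=object),
        np.array(alt, dtype=object),
        calls,
        samples,
        panel,
    )


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal GT-only VCF 4.2 file (missing calls as ``./.``)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in gm.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.accession_ids)
            + "\n"
        )
        for i in range(gm.n_sites):
            gts = "\t".join(_GT[int(c)] for c in gm.calls[i])
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# required columns and numeric columns per schema
TABLE_SCHEMAS = {
    "gene_models": {
        "required": ["gene", "chrom", "start", "end", "gc"],
        "numeric": ["start", "end", "gc"],
    },
    "gene_depths": {
        "required": ["gene", "accession", "depth"],
        "numeric": ["depth"],
    },
    "cds_pairs": {
        "required": ["gene_a", "gene_b", "gaps", "mismatches"],
        "numeric": ["gaps", "mismatches"],
    },
    "skeleton": {
        "required": ["marker", "chrom", "pos"],
        "numeric": ["pos"],
    },
    "traits": {
        "required": ["line", "environment", "replicate", "trait", "value"],
        "numeric": ["value"],
    },
    "metadata": {
        "required": ["accession", "panel", "latitude", "longitude"],
        "numeric": ["latitude", "longitude"],
    },
    "windows": {
        "required": ["chrom", "start", "end", "window"],
        "numeric": ["start", "end"],
    },
}


def read_table(path, schema: str):
    """Read a TSV/CSV table and validate it against a named schema.

    Required columns must be present (missing ones raise :class:`SchemaError`
    listing them); declared numeric columns are coerced; unknown columns are
    preserved untouched.  ``windows`` tables additionally validate interval
    sanity and return a :class:`WindowTable`.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}")
    schema_def = TABLE_SCHEMAS[schema]
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in schema_def["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: schema {schema!r} missing required columns {missing}")
    for c in schema_def["numeric"]:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: column {c!r} not numeric ({exc})") from exc
    if schema == "windows":
        return WindowTable(df)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a TSV with header (the package's uniform table output)."""
    df.to_csv(path, sep="\t", index=False)
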