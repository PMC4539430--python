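"""Readers and writers for the formats the pipeline touches.

Genotypes come in as VCF (biallelic SNPs, inbred calls) or as a tab-delimited
matrix of allele-pair calls (lines x markers, cells like ``GG``/``AA``/``NA``);
both are coded through :func:`qtsmap.core.code_genotypes` so the +1/-1
assignment by allele frequency is identical across formats. Phenotypes are a
long-format table (line_id, environment, value) which generalizes cleanly to
any number of environments. Positions are carried through unchanged (1-based
base pairs from VCF; whatever unit the map file declares otherwise).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GeneticMap, GenotypeMatrix, PhenotypeTable, code_genotypes, decode_genotypes

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "read_genotype_matrix",
    "read_vcf",
    "write_genotype_matrix",
    "read_phenotypes",
    "write_phenotypes",
]


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a coded genotype matrix.

    Multi-allelic and non-SNP records are skipped with a counted warning;
    positions stay 1-based as in the file. Calls are re-coded by allele
    frequency, so the VCF's own REF/ALT orientation does not affect the
    +1/-1 assignment.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: dict[str, list] = {}
    meta_rows = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        alleles = [rec.REF, rec.ALT[0]]
        col = []
        for g in rec.genotypes:  # [allele1, allele2, phased]
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                col.append("NA")
            else:
                col.append(alleles[a] + alleles[b])
        marker = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        calls[marker] = col
        meta_rows.append({"marker": marker, "chrom": str(rec.CHROM), "pos_cm": float(rec.POS)})
    if n_skipped:
        logger.warning("skipped %d non-biallelic-SNP record(s)", n_skipped)
    if not calls:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    raw = pd.DataFrame(calls, index=samples)
    return code_genotypes(raw, pd.DataFrame(meta_rows))


def read_genotype_matrix(path, map_path=None) -> GenotypeMatrix:
    """Read a tab-delimited call matrix (first column line_id, one column per marker).

    Cells are allele-pair strings (``GG``, ``G/A``) or ``NA``. An optional
    genetic-map file supplies chromosome and position metadata.
    """
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas names the offending line
        raise ValueError(f"malformed genotype matrix {path}: {exc}") from exc
    if raw.empty:
        raise ValueError(f"no usable markers in {path}")
    markers = None
    if map_path is not None:
        gmap = GeneticMap.read(map_path)
        meta = gmap.table.set_index("marker")
        missing = [m for m in raw.columns if m not in meta.index]
        if missing:
            raise ValueError(f"markers absent from map: {missing[:5]}")
        markers = meta.loc[raw.columns].reset_index()
    return code_genotypes(raw, markers)


def read_genotypes(path, format: str = "auto", map_path=None) -> GenotypeMatrix:
    """Dispatch on format: ``vcf``, ``matrix`` or ``auto`` (by extension)."""
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz") else "matrix"
    if format == "vcf":
        return read_vcf(path)
    if format == "matrix":
        return read_genotype_matrix(path, map_path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotype_matrix(G: GenotypeMatrix, path) -> None:
    """Write the decoded call matrix (tab-delimited, ``NA`` for missing)."""
    decode_genotypes(G).to_csv(path, sep="\t", index_label="line_id")


def read_phenotypes(path, genotypes: GenotypeMatrix | None = None) -> PhenotypeTable:
    """Read a long-format phenotype table: line_id, environment, value.

    ``NA`` values are retained as missing (downstream stages drop incomplete
    observations with a logged count). Duplicate (line, environment) rows are
    an error; so are line ids absent from the genotype matrix when one is
    given.
    """
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "environment": str})
    required = {"line_id", "environment", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype file needs columns {sorted(required)}")
    table = PhenotypeTable.from_long(df)
    n_missing = int(np.sum(~np.isfinite(table.values)))
    if n_missing:
        logger.warning("%d missing phenotype value(s) retained as NA", n_missing)
    if genotypes is not None:
        known = set(genotypes.line_ids)
        unknown = [l for l in table.line_ids if l not in known]
        if unknown:
            raise ValueError(f"phenotype lines absent from genotypes: {unknown[:10]}")
    return table


def write_phenotypes(y: PhenotypeTable, path) -> None:
    y.to_long().to_csv(path, sep="\t", index=False)
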