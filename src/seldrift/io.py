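"""Reading and writing genotype panels (TSV and VCF) and MAF tables.

The tabular format is TSV with header
``snp_id chrom pos allele_a allele_b <ind1> <ind2> ...`` and dosage
tokens ``0|1|2|NA`` counting allele_b.  An optional ``##candidates=``
comment line preserves the candidate-set flag across round trips.
VCF output is plain-text VCF 4.2 with GT-only calls; candidate SNPs
carry the ``CAND`` INFO flag.
"""

from __future__ import annotations

import os

import numpy as np
from cyvcf2 import VCF

from .cohort import CohortPanel, MafTable, SnpRecord

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_vcf",
    "write_vcf",
    "write_maf_tables",
]

_MISSING_TOKEN = "NA"
_DOSAGE_TOKENS = {"0": 0.0, "1": 1.0, "2": 2.0, _MISSING_TOKEN: np.nan}


class GenotypeParseError(ValueError):
    """Malformed genotype file content."""


def write_genotype_table(panel: CohortPanel, path: str | os.PathLike) -> None:
    """Write a panel as dosage TSV (see module docstring for the layout)."""
    candidates = [s.snp_id for s in panel.snps if s.is_candidate]
    with open(path, "w") as fh:
        if candidates:
            fh.write("##candidates=" + ",".join(candidates) + "\n")
        fh.write(
            "\t".join(["snp_id", "chrom", "pos", "allele_a", "allele_b"] + panel.individual_ids)
            + "\n"
        )
        for j, snp in enumerate(panel.snps):
            tokens = [
                _MISSING_TOKEN if np.isnan(v) else str(int(v)) for v in panel.dosages[:, j]
            ]
            fh.write(
                "\t".join([snp.snp_id, snp.chrom, str(snp.pos), snp.allele_a, snp.allele_b] + tokens)
                + "\n"
            )


def read_genotype_table(path: str | os.PathLike, cohort_id: str) -> CohortPanel:
    """Parse a dosage TSV into a :class:`CohortPanel`.

    SNP order is preserved from the file; ``NA`` entries become missing.

    Raises
    ------
    GenotypeParseError
        On a malformed dosage token (naming row and column) or a
        duplicate snp_id.
    """
    candidates: set[str] = set()
    header: list[str] | None = None
    snps: list[SnpRecord] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                if line.startswith("##candidates="):
                    candidates = set(line.split("=", 1)[1].split(","))
                continue
            fields = line.split("\t")
            if header is None:
                if fields[:5] != ["snp_id", "chrom", "pos", "allele_a", "allele_b"]:
                    raise GenotypeParseError(
                        f"{path}: unexpected header columns {fields[:5]}"
                    )
                header = fields[5:]
                continue
            if len(fields) != 5 + len(header):
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {5 + len(header)} fields, got {len(fields)}"
                )
            snp_id, chrom, pos, allele_a, allele_b = fields[:5]
            if any(s.snp_id == snp_id for s in snps):
                raise GenotypeParseError(f"{path}:{lineno}: duplicate snp_id {snp_id!r}")
            row = []
            for k, tok in enumerate(fields[5:]):
                if tok not in _DOSAGE_TOKENS:
                    raise GenotypeParseError(
                        f"{path}:{lineno}: bad dosage {tok!r} for SNP {snp_id!r}, "
                        f"individual {header[k]!r}"
                    )
                row.append(_DOSAGE_TOKENS[tok])
            snps.append(
                SnpRecord(
                    snp_id=snp_id,
                    chrom=chrom,
                    pos=int(pos),
                    allele_a=allele_a,
                    allele_b=allele_b,
                    is_candidate=snp_id in candidates,
                )
            )
            rows.append(row)
    if header is None:
        raise GenotypeParseError(f"{path}: missing header line")
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(header), 0))
    return CohortPanel(
        cohort_id=cohort_id, snps=snps, dosages=dosages, individual_ids=list(header)
    )


_GT_BY_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(panel: CohortPanel, path: str | os.PathLike) -> None:
    """Write a panel as plain-text VCF 4.2 (GT only, allele_a = REF)."""
    chroms = list(dict.fromkeys(s.chrom for s in panel.snps))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=seldrift\n")
        fh.write('##INFO=<ID=CAND,Number=0,Type=Flag,Description="Candidate SNP">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individual_ids)
            + "\n"
        )
        for j, snp in enumerate(panel.snps):
            gts = [
                "./." if np.isnan(v) else _GT_BY_DOSAGE[int(v)] for v in panel.dosages[:, j]
            ]
            info = "CAND" if snp.is_candidate else "."
            fh.write(
                "\t".join(
                    [snp.chrom, str(snp.pos), snp.snp_id, snp.allele_a, snp.allele_b,
                     ".", "PASS", info, "GT"] + gts
                )
                + "\n"
            )


def read_vcf(path: str | os.PathLike, cohort_id: str) -> CohortPanel:
    """Read a bi-allelic GT-only VCF into a :class:`CohortPanel`.

    Dosage counts the ALT allele; ``./.`` (or any partial call) becomes
    missing.  Multi-allelic records are rejected.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    snps: list[SnpRecord] = []
    cols: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic record {variant.ID or variant.POS} unsupported"
            )
        if "GT" not in (variant.FORMAT or []):
            raise ValueError(f"{path}: record {variant.ID or variant.POS} lacks GT")
        col = np.empty(len(samples))
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]
            col[i] = np.nan if any(a < 0 for a in alleles) else float(sum(alleles))
        snps.append(
            SnpRecord(
                snp_id=variant.ID or f"{variant.CHROM}:{variant.POS}",
                chrom=variant.CHROM,
                pos=variant.POS,
                allele_a=variant.REF,
                allele_b=variant.ALT[0],
                is_candidate=variant.INFO.get("CAND") is not None,
            )
        )
        cols.append(col)
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return CohortPanel(
        cohort_id=cohort_id, snps=snps, dosages=dosages, individual_ids=samples
    )


def write_maf_tables(tables: list[MafTable], minor_map, path: str | os.PathLike) -> None:
    """Export MAF tables as TSV: snp_id, cohort, minor_allele, maf, s2, n_geno, call_rate."""
    with open(path, "w") as fh:
        fh.write("snp_id\tcohort\tminor_allele\tmaf\ts2\tn_geno\tcall_rate\n")
        for table in tables:
            for snp_id, row in table.frame.iterrows():
                fh.write(
                    f"{snp_id}\t{table.cohort_id}\t{minor_map.minor_allele(snp_id)}\t"
                    f"{row['m']:.6g}\t{row['s2']:.6g}\t{int(row['n_geno'])}\t"
                    f"{row['call_rate']:.6g}\n"
                )
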