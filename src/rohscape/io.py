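"""Readers and writers for the package's text formats.

Supported formats:

* **PED/MAP** — white-space separated, six leading PED columns
  (FID, IID, father, mother, sex, phenotype) then two allele columns per
  marker; MAP with 3 or 4 columns (chrom, marker_id, [cM,] pos_bp).
  The missing-allele symbol is ``0``; half-missing genotypes collapse to
  missing.  PED/MAP carries no allele-order metadata, so on read the two
  observed alleles of each marker are oriented lexicographically
  (``allele1 < allele2``) and genotype codes follow that orientation.
* **VCF 4.2** — read through :mod:`cyvcf2`; only biallelic SNP records are
  kept (others are skipped and counted, or raise when ``strict=True``).
  ``REF`` maps to ``allele1`` and ``ALT`` to ``allele2``.
* **BED** intervals — written 0-based half-open, converted exactly from the
  internal 1-based inclusive convention on read/write.
* **Phenotype TSV** — header ``sample_id  trait  age  batch``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    FormatError,
    GenotypeMatrix,
    chrom_sort_key,
    make_markers,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

PED_MISSING_ALLELE = "0"


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------

def read_map(map_source: PathLike) -> pd.DataFrame:
    """Read a PLINK-style MAP file (3 or 4 columns) into a marker frame."""
    rows = []
    with open(map_source) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 4:
                chrom, mid, _cm, pos = fields
            elif len(fields) == 3:
                chrom, mid, pos = fields
            else:
                raise FormatError(
                    f"{map_source}:{lineno}: expected 3 or 4 MAP columns, got {len(fields)}"
                )
            rows.append((mid, str(chrom), int(pos)))
    frame = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp"])
    frame["allele1"] = "0"
    frame["allele2"] = "0"
    return frame


def read_ped_map(ped_source: PathLike, map_source: PathLike) -> GenotypeMatrix:
    """Read a PED/MAP pair into a :class:`GenotypeMatrix`.

    Sample metadata comes from PED columns 1-6 (FID is used as the
    population label).  Genotype codes count copies of ``allele2``, where the
    per-marker alleles are the observed non-missing allele labels in
    lexicographic order.
    """
    markers = read_map(map_source)
    n_markers = len(markers)
    sample_rows = []
    geno_rows = []
    seen_ids: set[str] = set()
    sex_map = {"1": "male", "2": "female"}
    with open(ped_source) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_source}:{lineno}: expected {6 + 2 * n_markers} columns "
                    f"({n_markers} markers), got {len(fields)}"
                )
            fid, iid, father, mother, sex, pheno = fields[:6]
            if iid in seen_ids:
                raise FormatError(f"{ped_source}:{lineno}: duplicate sample_id {iid!r}")
            seen_ids.add(iid)
            sample_rows.append(
                {
                    "sample_id": iid,
                    "population": fid,
                    "sex": sex_map.get(sex, "unknown"),
                    "father": father,
                    "mother": mother,
                    "phenotype": pheno,
                }
            )
            geno_rows.append(fields[6:])
    alleles = np.asarray(geno_rows, dtype=object).reshape(len(geno_rows), n_markers, 2)

    calls = np.full((len(geno_rows), n_markers), MISSING, dtype=np.int8)
    a1_list, a2_list = [], []
    for j in range(n_markers):
        col = alleles[:, j, :]
        ok = (col[:, 0] != PED_MISSING_ALLELE) & (col[:, 1] != PED_MISSING_ALLELE)
        observed = sorted(set(col[ok].ravel().tolist()))
        if len(observed) > 2:
            raise FormatError(
                f"marker {markers['marker_id'].iat[j]!r}: more than two alleles {observed}"
            )
        a1 = observed[0] if observed else "0"
        a2 = observed[1] if len(observed) == 2 else "0"
        a1_list.append(a1)
        a2_list.append(a2)
        dose = (col[:, 0] == a2).astype(np.int8) + (col[:, 1] == a2).astype(np.int8)
        calls[ok, j] = dose[ok]
    markers["allele1"] = a1_list
    markers["allele2"] = a2_list
    samples = pd.DataFrame(sample_rows)
    return GenotypeMatrix(calls, samples, markers)


def write_ped_map(
    matrix: GenotypeMatrix, ped_target: PathLike, map_target: PathLike
) -> None:
    """Write a PED/MAP pair (missing allele symbol ``0``, cM column zeroed)."""
    mk = matrix.markers
    with open(map_target, "w") as fh:
        for _, row in mk.iterrows():
            fh.write(f"{row.chrom}\t{row.marker_id}\t0\t{row.pos_bp}\n")
    sex_code = {"male": "1", "female": "2"}
    a1 = mk["allele1"].to_numpy(dtype=object)
    a2 = mk["allele2"].to_numpy(dtype=object)
    with open(ped_target, "w") as fh:
        for i in range(matrix.n_samples):
            s = matrix.samples.iloc[i]
            lead = [
                str(s.get("population", "pop1")),
                str(s["sample_id"]),
                str(s.get("father", "0")),
                str(s.get("mother", "0")),
                sex_code.get(str(s.get("sex", "unknown")), "0"),
                str(s.get("phenotype", "-9")),
            ]
            g = matrix.calls[i]
            pairs = np.empty((matrix.n_markers, 2), dtype=object)
            pairs[:, 0] = np.where(g >= 1, a2, a1)
            pairs[:, 1] = np.where(g == 2, a2, a1)
            miss = g == MISSING
            pairs[miss, :] = PED_MISSING_ALLELE
            fh.write(" ".join(lead + pairs.ravel().tolist()) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SNP_ALLELES = {"A", "C", "G", "T"}


def read_vcf(vcf_source: PathLike, *, strict: bool = False) -> GenotypeMatrix:
    """Read a VCF 4.x file of biallelic SNPs into a :class:`GenotypeMatrix`.

    ``GT`` codes ``0/0, 0/1|1/0, 1/1, ./.`` map to genotype codes
    ``0, 1, 2, MISSING``.  Non-SNP or multiallelic records are skipped with a
    logged count, or raise a :class:`FormatError` when ``strict`` is true.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_source))
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise FormatError(f"{vcf_source}: VCF has no sample/GT columns")
    rows = []
    calls_cols = []
    n_skipped = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1 or (
            rec.REF.upper() not in _SNP_ALLELES or alts[0].upper() not in _SNP_ALLELES
        ):
            if strict:
                raise FormatError(
                    f"{vcf_source}: non-biallelic-SNP record at {rec.CHROM}:{rec.POS}"
                )
            n_skipped += 1
            continue
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = rec.gt_types
        col = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING).astype(
            np.int8
        )
        mid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        rows.append((mid, str(rec.CHROM), int(rec.POS), rec.REF, alts[0]))
        calls_cols.append(col)
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    markers = pd.DataFrame(
        rows, columns=["marker_id", "chrom", "pos_bp", "allele1", "allele2"]
    )
    calls = (
        np.stack(calls_cols, axis=1)
        if calls_cols
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    samples = pd.DataFrame({"sample_id": sample_ids})
    return GenotypeMatrix(calls, samples, markers)


_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(matrix: GenotypeMatrix, vcf_target: PathLike) -> None:
    """Write an uncompressed VCF 4.2 with GT-only FORMAT."""
    with open(vcf_target, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohscape\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(matrix.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += [str(s) for s in matrix.sample_ids]
        fh.write("\t".join(header) + "\n")
        for j in range(matrix.n_markers):
            row = matrix.markers.iloc[j]
            alt = row.allele2 if row.allele2 not in ("0", ".") else "."
            fields = [
                str(row.chrom),
                str(row.pos_bp),
                str(row.marker_id),
                str(row.allele1),
                str(alt),
                ".",
                "PASS",
                ".",
                "GT",
            ]
            fields += [_GT_STRINGS[int(g)] for g in matrix.calls[:, j]]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Intervals (BED at the file boundary, 1-based inclusive internally)
# ---------------------------------------------------------------------------

def read_intervals(bed_source: PathLike) -> pd.DataFrame:
    """Read a BED-like file into an interval frame (1-based inclusive).

    Unsorted input is sorted on read with a logged notice.
    """
    rows = []
    with open(bed_source) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{bed_source}:{lineno}: fewer than 3 BED columns")
            chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else None
            rows.append((str(chrom), start0 + 1, end, name))
    frame = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "name"])
    keys = [(chrom_sort_key(c), s) for c, s in zip(frame["chrom"], frame["start_bp"])]
    order = sorted(range(len(frame)), key=lambda i: keys[i])
    if order != list(range(len(frame))):
        log.info("read_intervals: %s was unsorted; sorted on read", bed_source)
        frame = frame.iloc[order].reset_index(drop=True)
    return frame


def write_intervals(intervals: pd.DataFrame, bed_target: PathLike) -> None:
    """Write an interval frame as BED (0-based half-open); no header."""
    with open(bed_target, "w") as fh:
        for _, row in intervals.iterrows():
            fields = [str(row.chrom), str(int(row.start_bp) - 1), str(int(row.end_bp))]
            if "name" in intervals.columns and row.get("name") not in (None, np.nan):
                if not (isinstance(row["name"], float) and np.isnan(row["name"])):
                    fields.append(str(row["name"]))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

PHENO_COLUMNS = ["sample_id", "trait", "age", "batch"]


def read_phenotypes(tsv_source: PathLike) -> pd.DataFrame:
    """Read the phenotype table (TSV, header ``sample_id trait age batch``)."""
    frame = pd.read_csv(tsv_source, sep="\t", dtype={"sample_id": str, "batch": str})
    missing = [c for c in PHENO_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{tsv_source}: phenotype table lacks columns {missing}")
    if frame["sample_id"].duplicated().any():
        raise FormatError(f"{tsv_source}: duplicate sample_id in phenotype table")
    return frame


def write_phenotypes(phenotypes: pd.DataFrame, tsv_target: PathLike) -> None:
    phenotypes.to_csv(tsv_target, sep="\t", index=False, columns=PHENO_COLUMNS)
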