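"""Readers and writers for the external formats the pipeline touches.

TSV matrices: tab-separated, header ``feature_id<TAB>sample1...``, UTF-8,
no quoting, numeric cells printed with 12 significant digits so writer/reader
pairs round-trip at full useful precision.  Genotypes: VCF 4.2 with GT
(read through cyvcf2).  Annotations: BED6.  Coordinates are converted to the
internal 0-based half-open convention on read; VCF POS is 1-based on disk.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from nephroage.containers import (
    ANNOTATION_COLUMNS,
    OmicsMatrix,
    ValidationError,
    VariantSet,
)

_FLOAT_FORMAT = "%.12g"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# omics matrices (TSV)

def write_matrix(matrix: OmicsMatrix, path: str | os.PathLike) -> None:
    frame = matrix.data.copy()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT)


def read_matrix(path: str | os.PathLike, kind: str) -> OmicsMatrix:
    """Parse a features x samples TSV and validate it for ``kind``.

    Raises :class:`FormatError` naming the offending cell on non-numeric
    input or duplicated ids; methylation matrices are additionally range
    checked against [0, 1].
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {frame.iat[row, col]!r} at "
            f"feature {frame.index[row]!r}, sample {frame.columns[col]!r}"
        )
    try:
        return OmicsMatrix(numeric, kind)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# covariate / generic sample tables (TSV, sample ids in first column)

def write_sample_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    out = table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT)


def read_sample_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# BED6 annotations

def write_bed(annotations: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write feature annotations as BED6 (internal coordinates are already
    0-based half-open, so no conversion happens)."""
    bed = pd.DataFrame(
        {
            "chrom": annotations["chrom"],
            "start": annotations["start"],
            "end": annotations["end"],
            "name": annotations["feature_id"],
            "score": 0,
            "strand": annotations["strand"].replace(".", "."),
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | os.PathLike, kind: str = "gene") -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    frame = pd.DataFrame(
        {
            "feature_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int),
            "end": bed["end"].astype(int),
            "strand": bed["strand"].fillna("."),
            "kind": kind,
        }
    )[ANNOTATION_COLUMNS]
    if frame["feature_id"].duplicated().any():
        dup = frame.loc[frame["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    return frame


# ---------------------------------------------------------------------------
# VCF genotypes

_GT_FROM_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(variants: VariantSet, path: str | os.PathLike) -> None:
    """Emit a minimal VCF 4.2 with GT fields.

    Dosages must be integral (0/1/2) or NaN (written as ``./.``); POS is
    written 1-based from the internal 0-based start.
    """
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        handle.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(variants.sample_ids)
            + "\n"
        )
        ann = variants.annotations
        for i in range(variants.n_variants):
            calls = []
            for d in variants.dosage[i]:
                if np.isnan(d):
                    calls.append("./.")
                else:
                    if d != int(d):
                        raise ValidationError(
                            "write_vcf requires hard genotype calls (0/1/2)"
                        )
                    calls.append(_GT_FROM_DOSAGE[int(d)])
            handle.write(
                f"{ann['chrom'].iat[i]}\t{ann['start'].iat[i] + 1}\t"
                f"{ann['feature_id'].iat[i]}\t{variants.ref[i]}\t"
                f"{variants.alt[i]}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_genotypes(path: str | os.PathLike, split_multiallelic: bool = False) -> VariantSet:
    """Read a diploid VCF 4.2 into a :class:`VariantSet`.

    GT 0/0, 0/1, 1/1 map to dosages 0, 1, 2; missing GT (./.) is masked as
    NaN.  Multi-allelic records are rejected unless ``split_multiallelic``
    is set, in which case each alternate allele becomes its own record with
    an ``:<n>`` id suffix.
    """
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, dosages, refs, alts = [], [], [], []
    for record in vcf:
        record_alts = record.ALT
        if len(record_alts) > 1 and not split_multiallelic:
            raise FormatError(
                f"multi-allelic record at {record.CHROM}:{record.POS} "
                f"({record.ID}); enable split_multiallelic to split"
            )
        gts = record.genotype.array()
        if gts.shape[1] - 1 != 2:  # last column is the phase flag
            raise FormatError(
                f"non-diploid GT at {record.CHROM}:{record.POS}"
            )
        alleles = gts[:, :2].astype(float)
        alleles[alleles < 0] = np.nan
        for alt_index, alt in enumerate(record_alts, start=1):
            dose = np.nansum(alleles == alt_index, axis=1).astype(float)
            dose[np.isnan(alleles).any(axis=1)] = np.nan
            vid = record.ID or f"{record.CHROM}:{record.POS}"
            if len(record_alts) > 1:
                vid = f"{vid}:{alt_index}"
            rows.append(
                (vid, record.CHROM, record.POS - 1, record.POS, ".", "variant")
            )
            dosages.append(dose)
            refs.append(record.REF)
            alts.append(alt)
    annotations = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return VariantSet(
        annotations, np.array(dosages, dtype=float), sample_ids, ref=refs, alt=alts
    )
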