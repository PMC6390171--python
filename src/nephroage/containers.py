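"""In-memory containers shared by every pipeline stage.

Coordinates are stored 0-based half-open (BED convention) throughout; the
1-based convention appears only at the VCF boundary (see :mod:`nephroage.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MATRIX_KINDS = (
    "expression_tpm",
    "expression_log",
    "methylation_beta",
    "methylation_mvalue",
    "normalized",
)

ANNOTATION_COLUMNS = ["feature_id", "chrom", "start", "end", "strand", "kind"]


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass(frozen=True)
class FeatureAnnotation:
    """A genomic feature: gene span, CpG site or variant position.

    ``start``/``end`` are 0-based half-open.  Point features (CpG sites,
    variants) must satisfy ``end == start + 1``.
    """

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.kind == "gene":
            if not self.start < self.end:
                raise ValidationError(
                    f"gene {self.feature_id}: start must be < end "
                    f"(got {self.start}, {self.end})"
                )
        elif self.kind in ("cpg", "variant"):
            if self.end != self.start + 1:
                raise ValidationError(
                    f"{self.kind} {self.feature_id} is a point feature; "
                    f"end must equal start + 1"
                )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")


def annotations_to_frame(annotations: list[FeatureAnnotation]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            (a.feature_id, a.chrom, a.start, a.end, a.strand, a.kind)
            for a in annotations
        ],
        columns=ANNOTATION_COLUMNS,
    )
    for kind, group in frame.groupby("kind"):
        if group["feature_id"].duplicated().any():
            dup = group.loc[group["feature_id"].duplicated(), "feature_id"].iloc[0]
            raise ValidationError(f"duplicate {kind} id {dup!r}")
    return frame


class OmicsMatrix:
    """Features x samples numeric matrix with a declared measurement kind.

    Parameters
    ----------
    data:
        DataFrame with feature ids as index, sample ids as columns.
    kind:
        One of ``expression_tpm``, ``expression_log``, ``methylation_beta``,
        ``methylation_mvalue``, ``normalized``.
    """

    def __init__(self, data: pd.DataFrame, kind: str):
        if kind not in MATRIX_KINDS:
            raise ValidationError(f"unknown matrix kind {kind!r}")
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id {dup!r}")
        if data.columns.duplicated().any():
            dup = data.columns[data.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("matrix contains non-numeric values")
        if kind == "methylation_beta":
            finite = values[np.isfinite(values)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                bad = finite[(finite < 0) | (finite > 1)][0]
                raise ValidationError(
                    f"methylation beta value {bad} outside [0, 1]"
                )
        self.data = data.astype(float)
        self.kind = kind

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[:, list(sample_ids)], self.kind)

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "OmicsMatrix":
        """Same ids, new value matrix (and optionally new kind)."""
        frame = pd.DataFrame(
            values, index=self.data.index, columns=self.data.columns
        )
        return OmicsMatrix(frame, kind or self.kind)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"OmicsMatrix(kind={self.kind!r}, "
            f"{self.n_features} features x {self.n_samples} samples)"
        )


class VariantSet:
    """Variant annotations plus a diploid dosage matrix in [0, 2].

    Missing genotypes are NaN in ``dosage``; downstream regressions use
    pairwise-complete samples per variant.
    """

    def __init__(
        self,
        annotations: pd.DataFrame,
        dosage: np.ndarray,
        sample_ids: list[str],
        ref: list[str] | None = None,
        alt: list[str] | None = None,
    ):
        annotations = annotations.reset_index(drop=True)
        if annotations["feature_id"].duplicated().any():
            dup = annotations.loc[
                annotations["feature_id"].duplicated(), "feature_id"
            ].iloc[0]
            raise ValidationError(f"duplicate variant id {dup!r}")
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(annotations), len(sample_ids)):
            raise ValidationError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(annotations)} variants x {len(sample_ids)} samples"
            )
        observed = dosage[np.isfinite(dosage)]
        if observed.size and (observed.min() < 0.0 or observed.max() > 2.0):
            raise ValidationError("dosage outside [0, 2]")
        self.annotations = annotations
        self.dosage = dosage
        self.sample_ids = list(sample_ids)
        n = len(annotations)
        self.ref = list(ref) if ref is not None else ["A"] * n
        self.alt = list(alt) if alt is not None else ["G"] * n

    @property
    def variant_ids(self) -> list[str]:
        return list(self.annotations["feature_id"])

    @property
    def n_variants(self) -> int:
        return len(self.annotations)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency over non-missing samples."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosage, axis=1) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset_samples(self, sample_ids: list[str]) -> "VariantSet":
        index = [self.sample_ids.index(s) for s in sample_ids]
        return VariantSet(
            self.annotations,
            self.dosage[:, index],
            list(sample_ids),
            ref=self.ref,
            alt=self.alt,
        )

    def subset_variants(self, variant_ids: list[str]) -> "VariantSet":
        lookup = {v: i for i, v in enumerate(self.annotations["feature_id"])}
        rows = [lookup[v] for v in variant_ids]
        return VariantSet(
            self.annotations.iloc[rows],
            self.dosage[rows],
            self.sample_ids,
            ref=[self.ref[i] for i in rows],
            alt=[self.alt[i] for i in rows],
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"VariantSet({self.n_variants} variants x {self.n_samples} samples)"


@dataclass
class AlignmentReport:
    """Outcome of sample alignment: kept order and per-component drops."""

    sample_ids: list[str]
    dropped: dict[int, list[str]] = field(default_factory=dict)


def align_samples(*components):
    """Reorder components to their shared samples.

    The intersection of sample ids is taken in the order of the first
    component.  Components may be :class:`OmicsMatrix`, :class:`VariantSet`
    or a DataFrame indexed by sample id.

    Returns ``(aligned_components, AlignmentReport)``; raises
    :class:`ValidationError` on an empty intersection.
    """

    def ids_of(c):
        if isinstance(c, pd.DataFrame):
            return list(c.index)
        return list(c.sample_ids)

    if not components:
        raise ValidationError("no components to align")
    shared = set(ids_of(components[0]))
    for c in components[1:]:
        shared &= set(ids_of(c))
    if not shared:
        raise ValidationError("sample intersection is empty")
    kept = [s for s in ids_of(components[0]) if s in shared]
    report = AlignmentReport(sample_ids=kept)
    aligned = []
    for i, c in enumerate(components):
        dropped = sorted(set(ids_of(c)) - shared)
        if dropped:
            report.dropped[i] = dropped
        if isinstance(c, pd.DataFrame):
            aligned.append(c.loc[kept])
        else:
            aligned.append(c.subset_samples(kept))
    return aligned, report
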