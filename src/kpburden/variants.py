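"""Core variant domain types.

Coordinates are 1-based inclusive on hg19-style contigs, normalised to the
``chr``-prefixed spelling. Prediction cells follow the dbNSFP convention that
``.`` means missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from ._util import DataError, normalize_chrom

#: The 12 missense predictors contributing to the consensus score.
MISSENSE_TOOLS: tuple[str, ...] = (
    "SIFT",
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "PROVEAN",
    "MetaSVM",
    "MetaLR",
    "M-CAP",
    "CADD",
)

ZYGOSITIES = ("het", "hom", "hemi")


@dataclass(frozen=True, order=True)
class VariantKey:
    """chrom / 1-based position / ref / alt identity of a variant call."""

    chromosome: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chrom(self.chromosome))
        if self.position < 1:
            raise DataError(f"position must be >= 1, got {self.position}")
        if not self.ref or not self.alt:
            raise DataError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise DataError(f"ref == alt ({self.ref}) at {self.chromosome}:{self.position}")

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.position}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class CaseObservation:
    """One genotype call in a case individual with the QC-relevant fields."""

    sample_id: str
    zygosity: str
    depth: int
    alt_reads: int
    gq: int
    evaluable: bool = True  # False when DP/AD/GQ could not be read from the call

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise DataError(f"zygosity must be one of {ZYGOSITIES}, got {self.zygosity!r}")
        if self.evaluable:
            if not (0 <= self.alt_reads <= self.depth):
                raise DataError(
                    f"alt_reads {self.alt_reads} outside [0, depth={self.depth}] "
                    f"for sample {self.sample_id}"
                )
            if not (0 <= self.gq <= 99):
                raise DataError(f"GQ {self.gq} outside [0, 99] for sample {self.sample_id}")


@dataclass(frozen=True)
class PredictionProfile:
    """Raw per-tool predictions for one variant.

    ``tools`` holds the 12 missense predictors (categorical letters, or a
    float for CADD phred); ``splice`` holds splice-capable tool verdicts
    (HSF verdict strings). A ``None`` slot is explicitly missing.
    """

    tools: Mapping[str, str | float | None] = field(default_factory=dict)
    revel: float | None = None
    bayesdel: float | None = None
    splice: Mapping[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.revel is not None and not (0.0 <= self.revel <= 1.0):
            raise DataError(f"REVEL score {self.revel} outside [0, 1]")


@dataclass
class AnnotatedVariant:
    """One annotated variant with gene assignment and case observations.

    ``observations`` may be empty for sites annotated from the union of case
    and control discoveries (control-only sites still contribute to control
    burden counts); case-cohort records carry at least one observation.
    ``off_target`` marks rows whose gene does not resolve in the active panel.
    """

    key: VariantKey
    gene: str
    transcript: str
    consequence: str  # a ConsequenceClass value, see kpburden.filtering
    cdna_change: str = ""
    protein_change: str = ""
    profile: PredictionProfile = field(default_factory=PredictionProfile)
    observations: tuple[CaseObservation, ...] = ()
    dbsnp_id: str = ""
    off_target: bool = False


@dataclass(frozen=True)
class ControlFrequencyRecord:
    """Carrier / allele counts for one variant in one control dataset."""

    dataset_id: str
    key: VariantKey
    carrier_count: int | None
    allele_count: int | None
    sample_size: int
    absent: bool = False

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise DataError(f"sample_size must be >= 1, got {self.sample_size}")
        if self.carrier_count is not None:
            if self.carrier_count < 0:
                raise DataError("negative carrier_count")
            if self.carrier_count > self.sample_size:
                raise DataError(
                    f"carrier_count {self.carrier_count} exceeds sample size "
                    f"{self.sample_size} ({self.dataset_id} {self.key})"
                )
        if self.allele_count is not None:
            if self.allele_count < 0:
                raise DataError("negative allele_count")
            if self.allele_count > 2 * self.sample_size:
                raise DataError(
                    f"allele_count {self.allele_count} exceeds 2 x sample size "
                    f"{2 * self.sample_size} ({self.dataset_id} {self.key})"
                )

    @property
    def maf(self) -> float:
        """Minor allele frequency; allele counts preferred, carrier counts an
        approximation (one allele per carrier) when alleles are unavailable."""
        if self.allele_count is not None:
            return self.allele_count / (2 * self.sample_size)
        if self.carrier_count is not None:
            return self.carrier_count / (2 * self.sample_size)
        return 0.0

    @property
    def carriers(self) -> int:
        """Best available count of carrier individuals (rare-variant regime:
        each allele assumed in a distinct individual when only AC is known)."""
        if self.carrier_count is not None:
            return self.carrier_count
        if self.allele_count is not None:
            return min(self.allele_count, self.sample_size)
        return 0


class ControlFrequencyTable:
    """Per-dataset variant frequency summary with total lookup.

    Lookup of an absent key never raises: it returns an explicit absent
    record with zero counts (maf exactly 0). ``covered_genes``, when given,
    declares which panel genes the dataset can assess; genes outside it are
    reported as insufficient-data in burden reports.
    """

    def __init__(
        self,
        dataset_id: str,
        sample_size: int,
        records: Mapping[VariantKey, ControlFrequencyRecord] | None = None,
        covered_genes: frozenset[str] | None = None,
    ):
        if sample_size < 1:
            raise DataError(f"sample_size must be >= 1, got {sample_size}")
        self.dataset_id = dataset_id
        self.sample_size = sample_size
        self.records: dict[VariantKey, ControlFrequencyRecord] = dict(records or {})
        self.covered_genes = covered_genes
        for rec in self.records.values():
            if rec.dataset_id != dataset_id:
                raise DataError(
                    f"record dataset {rec.dataset_id!r} != table dataset {dataset_id!r}"
                )

    def add(self, rec: ControlFrequencyRecord) -> None:
        if rec.dataset_id != self.dataset_id:
            raise DataError(
                f"record dataset {rec.dataset_id!r} != table dataset {self.dataset_id!r}"
            )
        self.records[rec.key] = rec

    def lookup(self, key: VariantKey) -> ControlFrequencyRecord:
        rec = self.records.get(key)
        if rec is not None:
            return rec
        return ControlFrequencyRecord(
            dataset_id=self.dataset_id,
            key=key,
            carrier_count=None,
            allele_count=None,
            sample_size=self.sample_size,
            absent=True,
        )

    def covers_gene(self, symbol: str) -> bool:
        return self.covered_genes is None or symbol in self.covered_genes

    def __len__(self) -> int:
        return len(self.records)
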