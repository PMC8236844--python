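"""Qualifying-variant filter: consequence classification and rarity gating.

A qualifying variant alters the protein sequence (missense, indel, splicing,
stop gain/loss) and is rare in every control dataset under that dataset's MAF
threshold (default 0.005; 0.0001 for very large cohorts such as gnomAD nNFE).
Both thresholds are inclusive, so a variant absent from a dataset (MAF 0) is
always rare there. Zygosity never disqualifies a variant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from ._util import ConfigError, DataError, data_path
from .variants import AnnotatedVariant, ControlFrequencyTable, VariantKey


class ConsequenceClass(str, enum.Enum):
    MISSENSE = "missense"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SPLICING = "splicing"
    SYNONYMOUS = "synonymous"
    UTR5 = "utr5"
    UTR3 = "utr3"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    OTHER = "other"


#: Classes that alter the protein sequence and can qualify for burden testing.
PROTEIN_ALTERING: frozenset[ConsequenceClass] = frozenset(
    {
        ConsequenceClass.MISSENSE,
        ConsequenceClass.STOPGAIN,
        ConsequenceClass.STOPLOSS,
        ConsequenceClass.FRAMESHIFT_INDEL,
        ConsequenceClass.INFRAME_INDEL,
        ConsequenceClass.SPLICING,
    }
)

#: Severity order used to resolve multi-transcript annotations (most severe first).
SEVERITY_ORDER: tuple[ConsequenceClass, ...] = (
    ConsequenceClass.STOPGAIN,
    ConsequenceClass.FRAMESHIFT_INDEL,
    ConsequenceClass.STOPLOSS,
    ConsequenceClass.SPLICING,
    ConsequenceClass.MISSENSE,
    ConsequenceClass.INFRAME_INDEL,
    ConsequenceClass.SYNONYMOUS,
    ConsequenceClass.UTR5,
    ConsequenceClass.UTR3,
    ConsequenceClass.INTRONIC,
    ConsequenceClass.INTERGENIC,
    ConsequenceClass.OTHER,
)


def _load_vocab(path: str | Path | None = None) -> dict[str, ConsequenceClass]:
    source = Path(path) if path is not None else data_path("consequence_map.yaml")
    raw = yaml.safe_load(Path(source).read_text())
    vocab: dict[str, ConsequenceClass] = {}
    for cls_name, strings in raw.items():
        try:
            cls = ConsequenceClass(cls_name)
        except ValueError as exc:
            raise ConfigError(f"unknown consequence class {cls_name!r} in vocab") from exc
        for s in strings or []:
            vocab[str(s).strip().lower()] = cls
    return vocab


_DEFAULT_VOCAB = _load_vocab()


def classify_consequence(
    raw_consequence: str, vocab: Mapping[str, ConsequenceClass] | None = None
) -> ConsequenceClass:
    """Map an annotation-dialect consequence string to a ConsequenceClass.

    Total function: unknown vocabulary maps to OTHER. Multi-transcript cells
    joined with ';' resolve to the most severe class present.
    """
    table = vocab if vocab is not None else _DEFAULT_VOCAB
    s = str(raw_consequence).strip().lower()
    if s in table:
        return table[s]
    if ";" in s:
        classes = [table.get(part.strip(), ConsequenceClass.OTHER) for part in s.split(";")]
        return most_severe(classes)
    return ConsequenceClass.OTHER


def most_severe(classes: Iterable[ConsequenceClass]) -> ConsequenceClass:
    """The most severe class under the fixed severity order."""
    rank = {c: i for i, c in enumerate(SEVERITY_ORDER)}
    chosen = sorted(classes, key=lambda c: rank[c])
    if not chosen:
        return ConsequenceClass.OTHER
    return chosen[0]


def is_protein_altering(c: ConsequenceClass) -> bool:
    return c in PROTEIN_ALTERING


def resolve_transcript_consequence(
    per_transcript: Mapping[str, str], canonical: str
) -> ConsequenceClass:
    """Pick the class for a variant annotated on several transcripts.

    The panel's canonical accession wins when annotated; otherwise the most
    severe class across transcripts is used.
    """
    if canonical in per_transcript:
        return classify_consequence(per_transcript[canonical])
    return most_severe(classify_consequence(v) for v in per_transcript.values())


@dataclass(frozen=True)
class MafPolicy:
    """Per-dataset inclusive MAF rarity thresholds.

    The default threshold is 0.005; very large cohorts get stricter
    overrides (gnomAD nNFE: 0.0001).
    """

    default_threshold: float = 0.005
    overrides: Mapping[str, float] = field(default_factory=lambda: {"nNFE": 0.0001})

    def __post_init__(self) -> None:
        for t in (self.default_threshold, *self.overrides.values()):
            if not (0.0 < t <= 0.5):
                raise ConfigError(f"MAF threshold {t} outside (0, 0.5]")

    def threshold(self, dataset_id: str) -> float:
        return self.overrides.get(dataset_id, self.default_threshold)


@dataclass(frozen=True)
class QualifyingStatus:
    """Outcome of the qualifying filter with per-clause reasons.

    ``qualifies`` is the conjunction of protein_altering and rarity in every
    dataset; ``reasons`` is non-empty exactly when the variant fails.
    """

    qualifies: bool
    protein_altering: bool
    rare_in: Mapping[str, bool]
    reasons: tuple[str, ...]


def is_rare(
    key: VariantKey,
    tables: Iterable[ControlFrequencyTable],
    policy: MafPolicy | None = None,
) -> dict[str, bool]:
    """Per-dataset rarity: MAF <= the dataset threshold (inclusive).

    A variant absent from a dataset has MAF exactly 0 and is therefore rare
    there (absence is maximal rarity).
    """
    policy = policy or MafPolicy()
    out: dict[str, bool] = {}
    for table in tables:
        rec = table.lookup(key)
        out[table.dataset_id] = rec.maf <= policy.threshold(table.dataset_id)
    return out


def qualify(
    variant: AnnotatedVariant,
    tables: Iterable[ControlFrequencyTable],
    policy: MafPolicy | None = None,
) -> QualifyingStatus:
    """Apply the full qualifying-variant filter to an on-panel variant.

    Zygosity is irrelevant: heterozygous and homozygous carriers both count.
    """
    if variant.off_target:
        raise DataError(f"cannot qualify off-target variant {variant.key} ({variant.gene})")
    cls = ConsequenceClass(variant.consequence)
    pa = is_protein_altering(cls)
    rare = is_rare(variant.key, tables, policy)
    reasons: list[str] = []
    if not pa:
        reasons.append(f"consequence_not_protein_altering:{cls.value}")
    for ds, ok in rare.items():
        if not ok:
            reasons.append(f"common_in:{ds}")
    qualifies = pa and all(rare.values())
    return QualifyingStatus(
        qualifies=qualifies,
        protein_altering=pa,
        rare_in=rare,
        reasons=tuple(reasons),
    )
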