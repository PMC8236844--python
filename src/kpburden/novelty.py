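"""Novel-variant definition and sequencing-accuracy QC.

A case variant is novel when it is absent from, or carried by at most one
individual across, all control datasets (dbSNP presence is tracked
separately: an rs identifier without frequency evidence does not by itself
veto novelty unless the strict mode is enabled). Novel calls are trusted
only when the underlying genotype passes accuracy QC: depth >= 25x,
heterozygous allele balance within 0.50 +/- 0.15 (inclusive) and GQ >= 99;
the balance window is not applied to hom/hemi calls, where 50:50 has no
meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import DataError
from .filtering import ConsequenceClass, MafPolicy, qualify
from .pathogenicity import MISSING, score_variant
from .variants import AnnotatedVariant, CaseObservation, ControlFrequencyTable, VariantKey


@dataclass(frozen=True)
class NoveltyEvidence:
    """Control-side observations of one variant."""

    per_dataset: Mapping[str, int]
    in_dbsnp: bool = False

    @property
    def total_control_carriers(self) -> int:
        return sum(self.per_dataset.values())


@dataclass(frozen=True)
class QcThresholds:
    """Accuracy thresholds for novel calls (all boundaries inclusive)."""

    min_depth: int = 25
    allele_balance_window: tuple[float, float] = (0.35, 0.65)
    required_gq: int = 99

    def __post_init__(self) -> None:
        low, high = self.allele_balance_window
        if not (0.0 < low < 0.5 < high < 1.0):
            raise DataError(
                f"allele balance window {self.allele_balance_window} must straddle 0.5 "
                "within (0, 1)"
            )


def build_novelty_evidence(
    key: VariantKey,
    tables: Iterable[ControlFrequencyTable],
    dbsnp_ids: Mapping[VariantKey, str] | None = None,
) -> NoveltyEvidence:
    """Collect per-dataset carrier counts and the dbSNP presence flag."""
    per_dataset = {t.dataset_id: t.lookup(key).carriers for t in tables}
    in_dbsnp = bool(dbsnp_ids and key in dbsnp_ids)
    return NoveltyEvidence(per_dataset=per_dataset, in_dbsnp=in_dbsnp)


def is_novel(
    key: VariantKey,
    evidence: NoveltyEvidence,
    mode: str = "total",
    dbsnp_vetoes: bool = False,
) -> bool:
    """Novelty: at most one control carrier, summed across datasets.

    ``mode='per_dataset'`` relaxes the sum to a per-dataset <= 1 rule;
    ``dbsnp_vetoes=True`` additionally rejects any variant with a dbSNP
    entry regardless of carrier counts.
    """
    if mode not in ("total", "per_dataset"):
        raise DataError(f"unknown novelty mode {mode!r}")
    if dbsnp_vetoes and evidence.in_dbsnp:
        return False
    if mode == "total":
        return evidence.total_control_carriers <= 1
    return all(n <= 1 for n in evidence.per_dataset.values())


def passes_sequencing_qc(
    obs: CaseObservation, thresholds: QcThresholds | None = None
) -> tuple[bool | None, tuple[str, ...]]:
    """Accuracy QC for one genotype call.

    Returns (True, ()) on pass, (False, reasons) on fail, and (None,
    ('unevaluable',)) when DP/AD/GQ were not available for the call.
    """
    t = thresholds or QcThresholds()
    if not obs.evaluable:
        return None, ("unevaluable",)
    reasons: list[str] = []
    if obs.depth < t.min_depth:
        reasons.append(f"depth:{obs.depth}<{t.min_depth}")
    if obs.zygosity == "het":
        balance = obs.alt_reads / obs.depth if obs.depth else 0.0
        low, high = t.allele_balance_window
        if not (low <= balance <= high):
            reasons.append(f"balance:{balance:.3f} outside [{low}, {high}]")
    if obs.gq < t.required_gq:
        reasons.append(f"gq:{obs.gq}<{t.required_gq}")
    return (not reasons), tuple(reasons)


def novel_variant_report(
    variants: Sequence[AnnotatedVariant],
    tables: Iterable[ControlFrequencyTable],
    dbsnp_ids: Mapping[VariantKey, str] | None = None,
    thresholds: QcThresholds | None = None,
    policy: MafPolicy | None = None,
    novelty_mode: str = "total",
    dbsnp_vetoes: bool = False,
) -> tuple[pd.DataFrame, list[tuple[AnnotatedVariant, tuple[str, ...]]]]:
    """Table of novel, QC-passing qualifying variants with consensus scores.

    Returns (report, excluded): the report has one row per retained variant
    mirroring the novel-variant table layout (gene, position, type,
    accession, cDNA/protein change, consensus score with denominator,
    REVEL/BayesDel verdicts, and a manual-inspection placeholder column);
    ``excluded`` lists novel qualifying variants rejected by QC with their
    reasons.
    """
    tables = list(tables)
    rows: list[dict] = []
    excluded: list[tuple[AnnotatedVariant, tuple[str, ...]]] = []
    for v in variants:
        if v.off_target or not v.observations:
            continue
        if not qualify(v, tables, policy).qualifies:
            continue
        evidence = build_novelty_evidence(v.key, tables, dbsnp_ids)
        if not is_novel(v.key, evidence, novelty_mode, dbsnp_vetoes):
            continue
        qc_results = [passes_sequencing_qc(o, thresholds) for o in v.observations]
        if not any(ok is True for ok, _ in qc_results):
            reasons = tuple(r for _, rs in qc_results for r in rs)
            excluded.append((v, reasons))
            continue
        try:
            score = score_variant(v.profile, v.consequence)
            score_display = str(score)
            revel, bayesdel = score.revel_call, score.bayesdel_call
        except Exception:
            score_display, revel, bayesdel = "n/a", MISSING, MISSING
        rows.append(
            {
                "gene": v.gene,
                "position": f"{v.key.chromosome}:{v.key.position}",
                "type": "splicing"
                if v.consequence == ConsequenceClass.SPLICING.value
                else "exonic",
                "accession": v.transcript,
                "cdna_change": v.cdna_change or ".",
                "protein_change": v.protein_change or ".",
                "score": score_display,
                "revel": "n/a" if revel == MISSING else revel,
                "bayesdel": "n/a" if bayesdel == MISSING else bayesdel,
                "inspect": "",  # manual IGV review placeholder, never automated
            }
        )
    columns = [
        "gene", "position", "type", "accession", "cdna_change", "protein_change",
        "score", "revel", "bayesdel", "inspect",
    ]
    return pd.DataFrame(rows, columns=columns), excluded
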