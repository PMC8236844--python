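"""Readers and writers for the pipeline's file formats.

* annotation TSV — a versioned tab-separated dialect with a header row and
  ``.`` for missing cells (dbNSFP convention); a column-mapping dict adapts
  the reader to real ANNOVAR multianno headers;
* case VCF 4.2 fixtures with GT/AD/DP/GQ, read through pysam;
* control frequency TSV — dataset_id, chrom, pos, ref, alt, carrier_count,
  allele_count, sample_size;
* dbSNP presence TSV — variant key, rs identifier;
* gene-set YAML (see :mod:`kpburden.genes`).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping

import pysam

from ._util import DataError
from .filtering import classify_consequence
from .genes import GeneSet
from .variants import (
    MISSENSE_TOOLS,
    AnnotatedVariant,
    CaseObservation,
    ControlFrequencyRecord,
    ControlFrequencyTable,
    PredictionProfile,
    VariantKey,
)

MISSING_CELL = "."

#: Annotation TSV dialect v1 column order.
ANNOTATION_COLUMNS: tuple[str, ...] = (
    "chrom", "pos", "ref", "alt", "gene", "transcript", "consequence",
    "cdna_change", "protein_change", "dbsnp_id",
    *MISSENSE_TOOLS, "REVEL", "BayesDel", "HSF", "observations",
)

_MANDATORY = ("chrom", "pos", "ref", "alt", "gene", "consequence")
_NUMERIC_TOOLS = ("CADD",)


def parse_variant_key(text: str) -> VariantKey:
    """Parse the ``chrom:pos:ref>alt`` spelling of a variant key."""
    try:
        chrom, pos, alleles = text.strip().split(":")
        ref, alt = alleles.split(">")
        return VariantKey(chrom, int(pos), ref, alt)
    except (ValueError, TypeError) as exc:
        raise DataError(f"malformed variant key {text!r}") from exc


def _cell(value: str | None) -> str | None:
    if value is None:
        return None
    v = value.strip()
    return None if v in ("", MISSING_CELL) else v


def _float_cell(value: str | None) -> float | None:
    v = _cell(value)
    if v is None:
        return None
    try:
        return float(v)
    except ValueError:
        return None  # unparseable prediction cells are missing, not fatal


def _format_observation(o: CaseObservation) -> str:
    if not o.evaluable:
        return f"{o.sample_id}:{o.zygosity}:.:.:."
    return f"{o.sample_id}:{o.zygosity}:{o.depth}:{o.alt_reads}:{o.gq}"


def _parse_observation(text: str) -> CaseObservation:
    parts = text.split(":")
    if len(parts) != 5:
        raise DataError(f"malformed observation cell {text!r}")
    sid, zyg, dp, alt, gq = parts
    if MISSING_CELL in (dp, alt, gq):
        return CaseObservation(sid, zyg, 0, 0, 0, evaluable=False)
    return CaseObservation(sid, zyg, int(dp), int(alt), int(gq))


def read_annotated_variants(
    path: str | Path,
    gene_set: GeneSet,
    column_map: Mapping[str, str] | None = None,
) -> list[AnnotatedVariant]:
    """Read the annotation TSV into AnnotatedVariant records.

    Gene resolution is total: rows whose gene resolves (directly or via an
    alias) get the panel symbol and canonical transcript fallback; other
    rows are retained with ``off_target=True``. No silent drops — the output
    length equals the number of data rows.
    """
    colmap = dict(column_map or {})

    def col(row: Mapping[str, str], name: str) -> str | None:
        return row.get(colmap.get(name, name))

    out: list[AnnotatedVariant] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for name in _MANDATORY:
            if colmap.get(name, name) not in header:
                raise DataError(f"annotation file missing mandatory column {name!r}")
        for row in reader:
            try:
                pos = int(str(col(row, "pos")).strip())
            except (TypeError, ValueError) as exc:
                raise DataError(f"malformed coordinate in row {row!r}") from exc
            key = VariantKey(str(col(row, "chrom")), pos,
                             str(col(row, "ref")).strip(), str(col(row, "alt")).strip())
            raw_gene = (_cell(col(row, "gene")) or "")
            gene_def = gene_set.lookup(raw_gene)
            profile = PredictionProfile(
                tools={
                    tool: (_float_cell(col(row, tool)) if tool in _NUMERIC_TOOLS
                           else _cell(col(row, tool)))
                    for tool in MISSENSE_TOOLS
                },
                revel=_float_cell(col(row, "REVEL")),
                bayesdel=_float_cell(col(row, "BayesDel")),
                splice={"HSF": _cell(col(row, "HSF"))} if _cell(col(row, "HSF")) else {},
            )
            obs_cell = _cell(col(row, "observations"))
            observations = tuple(
                _parse_observation(tok) for tok in obs_cell.split(";")
            ) if obs_cell else ()
            transcript = _cell(col(row, "transcript")) or (
                gene_def.transcript if gene_def else ""
            )
            out.append(
                AnnotatedVariant(
                    key=key,
                    gene=gene_def.symbol if gene_def else raw_gene,
                    transcript=transcript,
                    consequence=classify_consequence(str(col(row, "consequence"))).value,
                    cdna_change=_cell(col(row, "cdna_change")) or "",
                    protein_change=_cell(col(row, "protein_change")) or "",
                    profile=profile,
                    observations=observations,
                    dbsnp_id=_cell(col(row, "dbsnp_id")) or "",
                    off_target=gene_def is None,
                )
            )
    return out


def write_annotated_variants(variants: list[AnnotatedVariant], path: str | Path) -> None:
    """Write AnnotatedVariant records in the dialect-v1 TSV (round-trip safe)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for v in variants:
            row = [
                v.key.chromosome, v.key.position, v.key.ref, v.key.alt,
                v.gene, v.transcript or MISSING_CELL, v.consequence,
                v.cdna_change or MISSING_CELL, v.protein_change or MISSING_CELL,
                v.dbsnp_id or MISSING_CELL,
            ]
            for tool in MISSENSE_TOOLS:
                val = v.profile.tools.get(tool)
                row.append(MISSING_CELL if val is None else val)
            row.append(MISSING_CELL if v.profile.revel is None else v.profile.revel)
            row.append(MISSING_CELL if v.profile.bayesdel is None else v.profile.bayesdel)
            hsf = v.profile.splice.get("HSF") if v.profile.splice else None
            row.append(hsf if hsf is not None else MISSING_CELL)
            row.append(
                ";".join(_format_observation(o) for o in v.observations) or MISSING_CELL
            )
            writer.writerow(row)


def read_case_vcf(
    path: str | Path,
    sex: Mapping[str, str] | None = None,
) -> dict[VariantKey, list[CaseObservation]]:
    """Read per-sample genotype observations from a VCF 4.2 fixture.

    Zygosity is derived from GT; a single-allele call on chrX in a male (per
    the optional sex sidecar) is hemizygous, otherwise calls are treated as
    diploid. Calls whose DP/AD/GQ cannot be read are flagged unevaluable
    rather than dropped.
    """
    out: dict[VariantKey, list[CaseObservation]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt_idx, alt in enumerate(rec.alts or (), start=1):
                key = VariantKey(rec.chrom, rec.pos, rec.ref, alt)
                for sample_name, call in rec.samples.items():
                    gt = tuple(a for a in (call.get("GT") or ()) if a is not None)
                    if alt_idx not in gt:
                        continue
                    if len(gt) == 1:
                        is_male = bool(sex) and sex.get(sample_name, "").lower() in ("m", "male")
                        on_x = key.chromosome == "chrX"
                        zyg = "hemi" if (is_male and on_x) else "hom"
                    elif all(a == alt_idx for a in gt):
                        zyg = "hom"
                    else:
                        zyg = "het"
                    dp, ad, gq = call.get("DP"), call.get("AD"), call.get("GQ")
                    alt_reads = ad[alt_idx] if ad is not None and len(ad) > alt_idx else None
                    if dp is None and ad is not None:
                        dp = sum(x for x in ad if x is not None)
                    if dp is None or alt_reads is None or gq is None:
                        obs = CaseObservation(sample_name, zyg, 0, 0, 0, evaluable=False)
                    else:
                        obs = CaseObservation(sample_name, zyg, int(dp), int(alt_reads), int(gq))
                    out.setdefault(key, []).append(obs)
    return out


def read_control_frequencies(
    path: str | Path,
    dataset_id: str | None = None,
    sample_size: int | None = None,
    covered_genes: frozenset[str] | None = None,
) -> ControlFrequencyTable:
    """Read a control frequency TSV into a ControlFrequencyTable.

    ``dataset_id`` / ``sample_size`` default to the (uniform) values found in
    the file. MAF is derived from allele counts when present, else from
    carrier counts.
    """
    records: dict[VariantKey, ControlFrequencyRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for name in ("chrom", "pos", "ref", "alt"):
            if name not in (reader.fieldnames or []):
                raise DataError(f"control table missing mandatory column {name!r}")
        for row in reader:
            ds = _cell(row.get("dataset_id")) or dataset_id
            if ds is None:
                raise DataError("control table rows carry no dataset_id and none was given")
            if dataset_id is not None and ds != dataset_id:
                raise DataError(f"dataset_id mismatch: file {ds!r} vs requested {dataset_id!r}")
            dataset_id = ds
            n_cell = _cell(row.get("sample_size"))
            n = int(n_cell) if n_cell is not None else sample_size
            if n is None:
                raise DataError("control table rows carry no sample_size and none was given")
            if sample_size is not None and n != sample_size:
                raise DataError(
                    f"sample_size mismatch: file {n} vs requested {sample_size}"
                )
            sample_size = n
            key = VariantKey(str(row["chrom"]), int(row["pos"]),
                             row["ref"].strip(), row["alt"].strip())
            cc, ac = _cell(row.get("carrier_count")), _cell(row.get("allele_count"))
            records[key] = ControlFrequencyRecord(
                dataset_id=ds,
                key=key,
                carrier_count=int(cc) if cc is not None else None,
                allele_count=int(ac) if ac is not None else None,
                sample_size=n,
            )
    if dataset_id is None or sample_size is None:
        raise DataError("empty control table requires explicit dataset_id and sample_size")
    return ControlFrequencyTable(dataset_id, sample_size, records, covered_genes)


def write_control_frequencies(table: ControlFrequencyTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["dataset_id", "chrom", "pos", "ref", "alt",
             "carrier_count", "allele_count", "sample_size"]
        )
        for key in sorted(table.records):
            r = table.records[key]
            writer.writerow(
                [r.dataset_id, key.chromosome, key.position, key.ref, key.alt,
                 MISSING_CELL if r.carrier_count is None else r.carrier_count,
                 MISSING_CELL if r.allele_count is None else r.allele_count,
                 r.sample_size]
            )


def read_dbsnp(path: str | Path) -> dict[VariantKey, str]:
    """Read the two-column (variant key, rs id) dbSNP presence TSV."""
    out: dict[VariantKey, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                key_text, rsid = line.split("\t")
            except ValueError as exc:
                raise DataError(f"malformed dbSNP line {line!r}") from exc
            out[parse_variant_key(key_text)] = rsid
    return out


def write_dbsnp(mapping: Mapping[VariantKey, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#variant_key\trs_id\n")
        for key in sorted(mapping):
            fh.write(f"{key}\t{mapping[key]}\n")
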