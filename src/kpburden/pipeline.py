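"""End-to-end orchestration: ingest -> qualify -> novelty/QC -> score -> burden.

A run is configured by :class:`PipelineConfig` (constructed directly or from
YAML), executes the stages in order, and returns burden and novel-variant
reports plus a manifest (input checksums, parameters and per-stage record
counts) sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from ._util import ConfigError, DataError
from .burden import GeneBurdenModel, GeneBurdenResults, TestConfig
from .filtering import ConsequenceClass, MafPolicy, qualify
from .genes import GeneSet, load_gene_set
from .io import (
    read_annotated_variants,
    read_case_vcf,
    read_control_frequencies,
    read_dbsnp,
)
from .novelty import QcThresholds, novel_variant_report
from .variants import AnnotatedVariant

log = logging.getLogger("kpburden")


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    annotation_path: str
    control_paths: Mapping[str, str]            # dataset_id -> TSV path
    vcf_path: str | None = None
    dbsnp_path: str | None = None
    sex_path: str | None = None
    gene_set_path: str | None = None            # None = packaged 18-gene default
    maf_default: float = 0.005
    maf_overrides: Mapping[str, float] = field(default_factory=lambda: {"nNFE": 0.0001})
    min_depth: int = 25
    allele_balance_window: tuple[float, float] = (0.35, 0.65)
    required_gq: int = 99
    two_sided_method: str = "central"
    alpha: float = 0.05
    count_mode: str = "observations"
    table_unit: str = "individuals"
    novelty_mode: str = "total"
    dbsnp_vetoes: bool = False
    out_dir: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"config does not parse: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "allele_balance_window" in raw:
            raw["allele_balance_window"] = tuple(raw["allele_balance_window"])
        return cls(**raw)

    def maf_policy(self) -> MafPolicy:
        return MafPolicy(self.maf_default, dict(self.maf_overrides))

    def qc_thresholds(self) -> QcThresholds:
        return QcThresholds(self.min_depth, tuple(self.allele_balance_window),
                            self.required_gq)


@dataclass
class PipelineRun:
    """Outputs of one pipeline execution."""

    burden: GeneBurdenResults
    novel_report: pd.DataFrame
    inventory: dict[str, int]
    manifest: dict


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_sex(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, sx = line.split("\t")
            out[sid] = sx
    return out


def variant_inventory(
    variants: list[AnnotatedVariant], gene_set: GeneSet
) -> dict[str, int]:
    """Distinct on-panel variant sites per consequence class.

    Every on-panel site lands in exactly one class (conservation: the counts
    sum to the number of distinct on-panel sites).
    """
    seen: dict = {}
    for v in variants:
        if v.off_target:
            continue
        seen.setdefault(v.key, v.consequence)
    counts = {c.value: 0 for c in ConsequenceClass}
    for consequence in seen.values():
        counts[consequence] += 1
    return counts


def run_pipeline(config: PipelineConfig, case_n: int | None = None) -> PipelineRun:
    """Execute the full pipeline for one configured input set.

    ``case_n`` (the case-cohort denominator) defaults to the number of
    distinct samples seen in the VCF; it must be given when genotype
    observations come packed in the annotation table instead.

    Deterministic and idempotent: rerunning on the same inputs reproduces
    identical reports.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(name)s %(levelname)s %(message)s")

    def stage_error(stage: str, exc: Exception) -> DataError:
        return DataError(f"[{stage}] {exc}")

    # ingest
    try:
        gene_set = load_gene_set(config.gene_set_path)
        variants = read_annotated_variants(config.annotation_path, gene_set)
        sex = _read_sex(config.sex_path) if config.sex_path else None
        if config.vcf_path:
            observations = read_case_vcf(config.vcf_path, sex)
            samples = {o.sample_id for obs in observations.values() for o in obs}
            by_key = {v.key: v for v in variants}
            for key, obs in observations.items():
                if key in by_key:
                    by_key[key].observations = tuple(obs)
            if case_n is None:
                case_n = len(samples)
        tables = [
            read_control_frequencies(path, dataset_id=ds)
            for ds, path in config.control_paths.items()
        ]
        dbsnp_ids = read_dbsnp(config.dbsnp_path) if config.dbsnp_path else {}
    except (OSError, DataError, ConfigError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise stage_error("ingest", exc) from exc
    if case_n is None or case_n < 1:
        raise ConfigError("case cohort size unknown: give a VCF or an explicit case_n")
    log.info("[ingest] %d annotated rows, %d control datasets", len(variants), len(tables))

    # qualify
    policy = config.maf_policy()
    try:
        on_target = [v for v in variants if not v.off_target]
        statuses = {v.key: qualify(v, tables, policy) for v in on_target}
    except DataError as exc:
        raise stage_error("qualify", exc) from exc
    n_qual = sum(s.qualifies for s in statuses.values())
    log.info("[qualify] %d of %d on-panel variants qualify", n_qual, len(on_target))

    # novelty + scoring
    try:
        novel_df, excluded = novel_variant_report(
            on_target, tables, dbsnp_ids, config.qc_thresholds(), policy,
            config.novelty_mode, config.dbsnp_vetoes,
        )
    except DataError as exc:
        raise stage_error("novelty", exc) from exc
    for v, reasons in excluded:
        log.info("[novelty] excluded %s (%s): %s", v.key, v.gene, "; ".join(reasons))
    log.info("[novelty] %d novel QC-passing variants", len(novel_df))

    # burden
    try:
        test_config = TestConfig(
            two_sided_method=config.two_sided_method,
            alpha=config.alpha,
            n_tests=gene_set.n_genes,
            count_mode=config.count_mode,
            table_unit=config.table_unit,
        )
        burden = GeneBurdenModel.from_cohort(
            on_target, statuses, tables, case_n, gene_set, test_config
        ).fit()
    except DataError as exc:
        raise stage_error("burden", exc) from exc

    inventory = variant_inventory(variants, gene_set)
    manifest = {
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in {
                "annotation": config.annotation_path,
                "vcf": config.vcf_path,
                "dbsnp": config.dbsnp_path,
                "sex": config.sex_path,
                "gene_set": config.gene_set_path,
                **{f"controls_{ds}": p for ds, p in config.control_paths.items()},
            }.items()
            if p
        },
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("out_dir", "log_level")
        },
        "case_n": case_n,
        "stage_counts": {
            "ingested": len(variants),
            "on_target": len(on_target),
            "qualifying": int(n_qual),
            "novel_reported": int(len(novel_df)),
            "novel_qc_excluded": len(excluded),
            "burden_rows": len(burden.results),
        },
    }
    run = PipelineRun(burden, novel_df, inventory, manifest)
    if config.out_dir:
        write_reports(run, config.out_dir)
    return run


def write_reports(run: PipelineRun, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "burden_tsv": out / "burden.tsv",
        "burden_json": out / "burden.json",
        "novel_tsv": out / "novel_variants.tsv",
        "inventory_tsv": out / "inventory.tsv",
        "manifest": out / "manifest.json",
    }
    frame = run.burden.frame
    frame.to_csv(paths["burden_tsv"], sep="\t", index=False)
    paths["burden_json"].write_text(frame.to_json(orient="records", indent=1) + "\n")
    run.novel_report.to_csv(paths["novel_tsv"], sep="\t", index=False)
    with open(paths["inventory_tsv"], "w") as fh:
        fh.write("consequence\tn_sites\n")
        for cls, n in run.inventory.items():
            fh.write(f"{cls}\t{n}\n")
    paths["manifest"].write_text(json.dumps(run.manifest, indent=1, sort_keys=True) + "\n")
    return paths
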