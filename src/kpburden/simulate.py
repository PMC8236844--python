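"""Synthetic case/control cohort generator with planted ground truth.

The generator emulates the study geometry the burden analysis assumes: a
case cohort of 614 whole-genome-sequenced individuals screened over the
18-gene panel, and three control frequency resources (gnomAD nNFE n=51,592;
AOGC n=967; MGRB n=1,144). Variant sites are drawn per gene with a
rare/common frequency spectrum; control allele counts are binomial draws
from each site's frequency, and case carrier counts are binomial draws at
the odds-ratio-adjusted carrier probability, so the case/control odds ratio
per qualifying site equals the configured per-gene enrichment. Per-tool
predictions are drawn from a class-conditional sensitivity/specificity/
missingness model. Ground truth (qualifying, novel, latent deleterious) is
recorded for every emitted variant from the realized draws, so pipeline
recovery can be checked exactly.

Everything is driven by one numpy Generator; identical parameters and seed
give byte-identical fixture files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from ._util import DataError
from .filtering import ConsequenceClass, MafPolicy
from .genes import GeneSet, default_gene_set
from .io import (
    write_annotated_variants,
    write_control_frequencies,
    write_dbsnp,
)
from .variants import (
    MISSENSE_TOOLS,
    AnnotatedVariant,
    CaseObservation,
    ControlFrequencyRecord,
    ControlFrequencyTable,
    PredictionProfile,
    VariantKey,
)

#: Default control resources: (dataset_id, n individuals).
DEFAULT_CONTROLS: tuple[tuple[str, int], ...] = (
    ("nNFE", 51592),
    ("AOGC", 967),
    ("MGRB", 1144),
)

_CATEGORICAL_TOKENS = {
    "SIFT": ("D", "T"),
    "Polyphen2_HDIV": ("D", "B"),
    "Polyphen2_HVAR": ("P", "B"),
    "LRT": ("D", "N"),
    "MutationTaster": ("D", "N"),
    "MutationAssessor": ("M", "L"),
    "FATHMM": ("D", "T"),
    "PROVEAN": ("D", "N"),
    "MetaSVM": ("D", "T"),
    "MetaLR": ("D", "T"),
    "M-CAP": ("D", "T"),
}

_NONCODING_CLASSES = (
    ConsequenceClass.SYNONYMOUS,
    ConsequenceClass.UTR3,
    ConsequenceClass.UTR5,
    ConsequenceClass.INTRONIC,
)


@dataclass(frozen=True)
class PredictionModelParams:
    """Class-conditional behaviour of the in-silico predictors."""

    sensitivity: float = 0.9      # P(deleterious call | latent deleterious)
    specificity: float = 0.95     # P(benign call | latent benign)
    missingness: float = 0.08     # P(no result), independent per tool
    revel_deleterious: tuple[float, float] = (8.0, 2.0)   # Beta(a, b)
    revel_benign: tuple[float, float] = (2.0, 8.0)
    bayesdel_deleterious: tuple[float, float] = (0.3, 0.15)  # Normal(mu, sd)
    bayesdel_benign: tuple[float, float] = (-0.3, 0.15)


@dataclass(frozen=True)
class PlannedNovelVariant:
    """A variant planted to appear in exactly one case with chosen QC fields."""

    gene: str
    control_carriers: int = 0        # 0 or 1, placed in one control dataset
    in_dbsnp: bool = False
    depth: int = 40
    alt_fraction: float = 0.5
    gq: int = 99
    zygosity: str = "het"
    consequence: str = ConsequenceClass.MISSENSE.value
    deleterious: bool = True


@dataclass
class SimulationParams:
    """Study-condition knobs for the synthetic cohort.

    Defaults mirror the analysed cohort geometry (614 cases; nNFE/AOGC/MGRB
    controls; 18 genes) with a rare-dominated frequency spectrum so that
    most protein-altering sites pass the MAF gates and per-gene case counts
    land in the single-digit range seen in candidate-gene panels.
    """

    seed: int = 0
    n_cases: int = 614
    controls: tuple[tuple[str, int], ...] = DEFAULT_CONTROLS
    n_sites_per_gene: int = 8
    fraction_protein_altering: float = 0.5
    fraction_splicing: float = 0.06   # share of protein-altering sites that are splice
    fraction_rare: float = 0.8
    rare_freq_range: tuple[float, float] = (2e-6, 5e-5)     # allele frequency, loguniform
    common_freq_range: tuple[float, float] = (3e-4, 5e-3)
    p_deleterious: float = 0.3        # latent deleterious share of protein-altering sites
    enrichment_or: Mapping[str, float] = field(default_factory=dict)
    novel_plan: tuple[PlannedNovelVariant, ...] = ()
    dbsnp_rate: float = 0.8           # P(rs id | seen in any control dataset)
    prediction: PredictionModelParams = field(default_factory=PredictionModelParams)
    maf_policy: MafPolicy = field(default_factory=MafPolicy)


@dataclass
class GroundTruth:
    """Realized per-variant flags and per-gene enrichment."""

    variants: dict[str, dict]                 # str(VariantKey) -> flags
    gene_enrichment: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(
            {"variants": self.variants, "gene_enrichment": self.gene_enrichment},
            indent=1, sort_keys=True,
        )


@dataclass
class CohortFixtures:
    """In-memory fixture set produced by :func:`simulate_cohort`."""

    variants: list[AnnotatedVariant]
    control_tables: dict[str, ControlFrequencyTable]
    dbsnp_ids: dict[VariantKey, str]
    sex: dict[str, str]
    truth: GroundTruth
    gene_set: GeneSet
    params: SimulationParams


def _loguniform(rng: np.random.Generator, low: float, high: float) -> float:
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))


def simulate_predictions(
    latent_deleterious: bool,
    params: SimulationParams | PredictionModelParams,
    rng: np.random.Generator,
    consequence: str = ConsequenceClass.MISSENSE.value,
) -> PredictionProfile:
    """Draw a per-tool prediction profile for one variant.

    Each tool is independently missing with the configured rate; otherwise
    it calls deleterious with probability ``sensitivity`` for latent
    deleterious variants and ``1 - specificity`` for benign ones. REVEL and
    BayesDel are drawn from class-conditional Beta resp. Normal
    distributions; splicing variants get splice-tool verdicts instead of
    missense categories.
    """
    pm = params.prediction if isinstance(params, SimulationParams) else params
    p_del = pm.sensitivity if latent_deleterious else 1.0 - pm.specificity

    def one_call() -> bool | None:
        if rng.random() < pm.missingness:
            return None
        return bool(rng.random() < p_del)

    tools: dict[str, str | float | None] = {}
    splice: dict[str, str | None] = {}
    is_splice = consequence == ConsequenceClass.SPLICING.value
    for tool in MISSENSE_TOOLS:
        if is_splice and tool not in ("MutationTaster", "CADD"):
            tools[tool] = None
            continue
        call = one_call()
        if call is None:
            tools[tool] = None
        elif tool == "CADD":
            tools[tool] = round(float(rng.uniform(20.0, 40.0) if call
                                      else rng.uniform(0.0, 19.5)), 2)
        else:
            d_tok, b_tok = _CATEGORICAL_TOKENS[tool]
            tools[tool] = d_tok if call else b_tok
    if is_splice:
        call = one_call()
        splice["HSF"] = None if call is None else ("affected" if call else "no_impact")
    a, b = pm.revel_deleterious if latent_deleterious else pm.revel_benign
    revel = None if is_splice else float(np.clip(rng.beta(a, b), 0.0, 1.0))
    mu, sd = pm.bayesdel_deleterious if latent_deleterious else pm.bayesdel_benign
    bayesdel = round(float(rng.normal(mu, sd)), 4)
    return PredictionProfile(
        tools=tools,
        revel=None if revel is None else round(revel, 4),
        bayesdel=bayesdel,
        splice=splice,
    )


def _case_observation(
    rng: np.random.Generator,
    sample_id: str,
    zygosity: str,
    depth: int | None = None,
    alt_fraction: float | None = None,
    gq: int | None = None,
) -> CaseObservation:
    dp = int(depth) if depth is not None else max(10, int(rng.poisson(40)))
    if alt_fraction is not None:
        alt = int(round(dp * alt_fraction))
    elif zygosity == "het":
        alt = int(rng.binomial(dp, 0.5))
    else:
        alt = dp - int(rng.binomial(dp, 0.01))
    alt = min(max(alt, 0), dp)
    q = int(gq) if gq is not None else (99 if rng.random() < 0.97 else int(rng.integers(30, 99)))
    return CaseObservation(sample_id, zygosity, dp, alt, q)


def _qualifies(consequence: str, records: Mapping[str, ControlFrequencyRecord],
               policy: MafPolicy) -> bool:
    pa = ConsequenceClass(consequence) in {
        ConsequenceClass.MISSENSE, ConsequenceClass.STOPGAIN, ConsequenceClass.STOPLOSS,
        ConsequenceClass.FRAMESHIFT_INDEL, ConsequenceClass.INFRAME_INDEL,
        ConsequenceClass.SPLICING,
    }
    rare = all(rec.maf <= policy.threshold(ds) for ds, rec in records.items())
    return pa and rare


def simulate_cohort(
    params: SimulationParams | None = None,
    gene_set: GeneSet | None = None,
) -> CohortFixtures:
    """Generate a full synthetic cohort with planted ground truth.

    Sites with neither case carriers nor control alleles are unobservable
    and therefore not emitted. Planted novel variants appear in exactly one
    case; their control carriers (at most one) are placed in one dataset.
    """
    params = params or SimulationParams()
    gene_set = gene_set or default_gene_set()
    if params.n_cases < 1:
        raise DataError("n_cases must be >= 1")
    if params.n_sites_per_gene < 1:
        raise DataError("n_sites_per_gene must be >= 1")
    for gene, or_ in params.enrichment_or.items():
        if gene not in gene_set:
            raise DataError(f"enrichment configured for off-panel gene {gene!r}")
        if or_ <= 0:
            raise DataError(f"odds ratio for {gene} must be > 0, got {or_}")
    rng = np.random.default_rng(params.seed)
    sample_ids = [f"S{i:04d}" for i in range(params.n_cases)]
    sex = {s: ("male" if rng.random() < 0.5 else "female") for s in sample_ids}
    control_records: dict[str, dict[VariantKey, ControlFrequencyRecord]] = {
        ds: {} for ds, _ in params.controls
    }
    variants: list[AnnotatedVariant] = []
    truth_variants: dict[str, dict] = {}
    dbsnp_ids: dict[VariantKey, str] = {}
    bases = "ACGT"

    def emit_site(
        gene_def, position: int, consequence: str, freq: float, latent: bool,
        or_: float, planned: PlannedNovelVariant | None = None,
    ) -> None:
        ref = bases[rng.integers(0, 4)]
        alt = ([b for b in bases if b != ref])[rng.integers(0, 3)]
        key = VariantKey(gene_def.chromosome, position, ref, alt)
        recs: dict[str, ControlFrequencyRecord] = {}
        for ds, n_d in params.controls:
            if planned is not None:
                ac = 0
            else:
                ac = int(rng.binomial(2 * n_d, freq))
            recs[ds] = ControlFrequencyRecord(ds, key, None, ac, n_d)
        if planned is not None and planned.control_carriers:
            ds_pick = params.controls[int(rng.integers(0, len(params.controls)))][0]
            n_d = dict(params.controls)[ds_pick]
            recs[ds_pick] = ControlFrequencyRecord(
                ds_pick, key, None, int(planned.control_carriers), n_d
            )
        q0 = 1.0 - (1.0 - freq) ** 2
        q1 = or_ * q0 / (1.0 - q0 + or_ * q0)
        if q1 * 1.05 > 1.0:
            raise DataError(
                f"infeasible enrichment for {gene_def.symbol}: carrier probability {q1:.3f}"
            )
        if planned is not None:
            n_car = 1
        else:
            n_car = int(rng.binomial(params.n_cases, q1))
        obs: list[CaseObservation] = []
        if n_car:
            picks = rng.choice(params.n_cases, size=n_car, replace=False)
            for idx in np.sort(picks):
                sid = sample_ids[int(idx)]
                if planned is not None:
                    zyg = planned.zygosity
                    o = _case_observation(rng, sid, zyg, planned.depth,
                                          planned.alt_fraction, planned.gq)
                else:
                    on_x = gene_def.chromosome == "chrX"
                    if on_x and sex[sid] == "male":
                        zyg = "hemi"
                    else:
                        zyg = "hom" if rng.random() < freq else "het"
                    o = _case_observation(rng, sid, zyg)
                obs.append(o)
        total_control = sum(r.carriers for r in recs.values())
        if not obs and total_control == 0:
            return  # unobservable site
        in_dbsnp = (planned.in_dbsnp if planned is not None
                    else total_control > 0 and rng.random() < params.dbsnp_rate)
        rsid = f"rs{900000000 + len(truth_variants)}" if in_dbsnp else ""
        profile = simulate_predictions(latent, params, rng, consequence)
        aa = int(rng.integers(1, 400))
        is_splice = consequence == ConsequenceClass.SPLICING.value
        variant = AnnotatedVariant(
            key=key,
            gene=gene_def.symbol,
            transcript=gene_def.transcript,
            consequence=consequence,
            cdna_change=f"c.{key.ref}{aa * 3}{key.alt}",
            protein_change="" if is_splice or ConsequenceClass(consequence)
            in _NONCODING_CLASSES else f"p.X{aa}Y",
            profile=profile,
            observations=tuple(obs),
            dbsnp_id=rsid,
        )
        for ds in control_records:
            control_records[ds][key] = recs[ds]
        if rsid:
            dbsnp_ids[key] = rsid
        qual = _qualifies(consequence, recs, params.maf_policy)
        truth_variants[str(key)] = {
            "gene": gene_def.symbol,
            "consequence": consequence,
            "qualifying": qual,
            "novel": bool(obs) and total_control <= 1,
            "deleterious": bool(latent),
            "case_carriers": len(obs),
            "control_carriers": int(total_control),
            "planted_novel": planned is not None,
        }
        variants.append(variant)

    for g_idx, gene_def in enumerate(gene_set):
        or_ = float(params.enrichment_or.get(gene_def.symbol, 1.0))
        base_pos = 1_000_000 * (g_idx + 1)
        offsets = np.sort(rng.choice(500_000, size=params.n_sites_per_gene, replace=False))
        for off in offsets:
            pa = rng.random() < params.fraction_protein_altering
            if pa:
                consequence = (
                    ConsequenceClass.SPLICING.value
                    if rng.random() < params.fraction_splicing
                    else ConsequenceClass.MISSENSE.value
                )
            else:
                consequence = _NONCODING_CLASSES[rng.integers(0, len(_NONCODING_CLASSES))].value
            rare = rng.random() < params.fraction_rare
            lo, hi = params.rare_freq_range if rare else params.common_freq_range
            freq = _loguniform(rng, lo, hi)
            latent = pa and rng.random() < params.p_deleterious
            emit_site(gene_def, base_pos + int(off), consequence, freq,
                      latent, or_ if pa else 1.0)

    for plan in params.novel_plan:
        gene_def = gene_set.lookup(plan.gene)
        if gene_def is None:
            raise DataError(f"planted novel variant names off-panel gene {plan.gene!r}")
        position = 2_000_000_000 + int(rng.integers(0, 1_000_000))
        emit_site(gene_def, position, plan.consequence, 1e-7, plan.deleterious,
                  1.0, planned=plan)

    tables = {
        ds: ControlFrequencyTable(ds, n_d, control_records[ds])
        for ds, n_d in params.controls
    }
    truth = GroundTruth(
        variants=truth_variants,
        gene_enrichment={g.symbol: float(params.enrichment_or.get(g.symbol, 1.0))
                         for g in gene_set},
    )
    return CohortFixtures(variants, tables, dbsnp_ids, sex, truth, gene_set, params)


def simulate_burden_counts(
    baseline_carrier_prob: float,
    odds_ratio: float,
    n_cases: int,
    control_sizes: Mapping[str, int],
    rng: np.random.Generator,
    n_reps: int,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Count-level replicate generator for calibration and power studies.

    Controls carry a binomial count at the baseline per-gene carrier
    probability; cases at the odds-ratio-adjusted probability — the exact
    2x2 model the burden test assumes, without the fixture-file machinery.
    Returns (case_counts[n_reps], {dataset: control_counts[n_reps]}).
    """
    if not (0.0 < baseline_carrier_prob < 1.0):
        raise DataError("baseline carrier probability must be in (0, 1)")
    if odds_ratio <= 0:
        raise DataError("odds ratio must be > 0")
    p0 = baseline_carrier_prob
    p1 = odds_ratio * p0 / (1.0 - p0 + odds_ratio * p0)
    case_counts = rng.binomial(n_cases, p1, size=n_reps)
    control_counts = {
        ds: rng.binomial(n_d, p0, size=n_reps) for ds, n_d in control_sizes.items()
    }
    return case_counts, control_counts


def _write_vcf(fixtures: CohortFixtures, path: Path) -> None:
    """Emit the case genotypes as a plain-text VCF 4.2 fixture."""
    sample_ids = [f"S{i:04d}" for i in range(fixtures.params.n_cases)]
    carried: dict[VariantKey, dict[str, CaseObservation]] = {}
    for v in fixtures.variants:
        if v.observations:
            carried[v.key] = {o.sample_id: o for o in v.observations}
    contigs = sorted({k.chromosome for k in carried},
                     key=lambda c: (len(c), c))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for key in sorted(carried, key=lambda k: (contigs.index(k.chromosome), k.position)):
            cells = []
            for sid in sample_ids:
                o = carried[key].get(sid)
                if o is None:
                    cells.append("0/0:.:.:.")
                    continue
                gt = {"het": "0/1", "hom": "1/1", "hemi": "1"}[o.zygosity]
                ref_reads = max(o.depth - o.alt_reads, 0)
                cells.append(f"{gt}:{ref_reads},{o.alt_reads}:{o.depth}:{o.gq}")
            fh.write(
                f"{key.chromosome}\t{key.position}\t.\t{key.ref}\t{key.alt}\t.\t.\t.\t"
                "GT:AD:DP:GQ\t" + "\t".join(cells) + "\n"
            )


def write_fixtures(fixtures: CohortFixtures, out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture file set; everything is re-readable by the IO layer.

    Emits annotation.tsv (without observation cells — genotypes live in the
    VCF), cases.vcf, controls_<dataset>.tsv, dbsnp.tsv, sex.tsv and
    truth.json. Returns the path of each artefact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    stripped = [
        AnnotatedVariant(
            key=v.key, gene=v.gene, transcript=v.transcript, consequence=v.consequence,
            cdna_change=v.cdna_change, protein_change=v.protein_change,
            profile=v.profile, observations=(), dbsnp_id=v.dbsnp_id,
            off_target=v.off_target,
        )
        for v in sorted(fixtures.variants, key=lambda v: v.key)
    ]
    paths["annotation"] = out / "annotation.tsv"
    write_annotated_variants(stripped, paths["annotation"])
    paths["vcf"] = out / "cases.vcf"
    _write_vcf(fixtures, paths["vcf"])
    for ds, table in fixtures.control_tables.items():
        p = out / f"controls_{ds}.tsv"
        write_control_frequencies(table, p)
        paths[f"controls_{ds}"] = p
    paths["dbsnp"] = out / "dbsnp.tsv"
    write_dbsnp(fixtures.dbsnp_ids, paths["dbsnp"])
    paths["sex"] = out / "sex.tsv"
    with open(paths["sex"], "w") as fh:
        fh.write("#sample_id\tsex\n")
        for sid in sorted(fixtures.sex):
            fh.write(f"{sid}\t{fixtures.sex[sid]}\n")
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(fixtures.truth.to_json() + "\n")
    return paths
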