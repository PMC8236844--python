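"""Per-gene case/control burden testing.

For each panel gene and each control dataset separately, the number of
qualifying-variant observations in cases is compared with the control count
by an exact conditional test on the 2x2 table

    [[count_cases, n_cases - count_cases],
     [count_controls, n_controls - count_controls]]

with Bonferroni correction over the number of genes tested (alpha/n_genes;
0.05/18 = 0.00278). The modelling surface is statsmodels-style:
``GeneBurdenModel(...).fit()`` returns a ``GeneBurdenResults`` carrying the
per-(gene, dataset) results, with ``summary()`` rendering the report table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import DataError, round_half_up
from .exact_tests import TWO_SIDED_METHODS, fisher_exact_2x2
from .filtering import QualifyingStatus
from .genes import GeneSet, default_gene_set
from .variants import AnnotatedVariant, ControlFrequencyTable


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Individuals-as-units 2x2 table: (with, without) x (cases, controls)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name, v in (("a", self.a), ("b", self.b), ("c", self.c), ("d", self.d)):
            if int(v) != v or v < 0:
                raise DataError(f"2x2 cell {name} must be a non-negative integer, got {v!r}")

    @classmethod
    def from_counts(
        cls, case_count: int, case_n: int, control_count: int, control_n: int,
        unit: str = "individuals",
    ) -> "ContingencyTable2x2":
        """Build from counts and denominators; ``unit='alleles'`` doubles the
        denominators for allele-count control summaries."""
        if unit not in ("individuals", "alleles"):
            raise DataError(f"unknown table unit {unit!r}")
        mult = 2 if unit == "alleles" else 1
        if case_count > mult * case_n or control_count > mult * control_n:
            raise DataError("count exceeds denominator in 2x2 construction")
        return cls(case_count, mult * case_n - case_count,
                   control_count, mult * control_n - control_count)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class TestConfig:
    """Burden test configuration: two-sided method, alpha, Bonferroni n."""

    __test__ = False  # not a pytest collectable despite the name

    two_sided_method: str = "central"
    alpha: float = 0.05
    n_tests: int = 18
    count_mode: str = "observations"  # or "carriers"
    table_unit: str = "individuals"   # or "alleles"

    def __post_init__(self) -> None:
        if self.two_sided_method not in TWO_SIDED_METHODS:
            raise DataError(f"unknown two-sided method {self.two_sided_method!r}")
        if not (0.0 < self.alpha < 1.0):
            raise DataError(f"alpha {self.alpha} outside (0, 1)")
        if self.n_tests < 1:
            raise DataError("n_tests must be >= 1")
        if self.count_mode not in ("observations", "carriers"):
            raise DataError(f"unknown count mode {self.count_mode!r}")


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise DataError("n_tests must be >= 1")
    return alpha / n_tests


def count_qualifying(
    variants: Sequence[AnnotatedVariant],
    statuses: Mapping,
    gene: str,
    mode: str = "observations",
) -> int:
    """Count qualifying-variant load for one gene in the case cohort.

    ``observations`` counts distinct (variant, individual) pairs — a
    homozygote counts once per variant; ``carriers`` counts distinct
    individuals carrying at least one qualifying variant. ``statuses`` maps
    VariantKey -> QualifyingStatus.
    """
    if mode not in ("observations", "carriers"):
        raise DataError(f"unknown count mode {mode!r}")
    hits = [
        v for v in variants
        if v.gene == gene and not v.off_target
        and statuses[v.key].qualifies
    ]
    if mode == "observations":
        return sum(len({o.sample_id for o in v.observations}) for v in hits)
    return len({o.sample_id for v in hits for o in v.observations})


@dataclass(frozen=True)
class BurdenResult:
    """One gene x dataset burden comparison.

    ``p_value`` and ``significant`` are None when the dataset cannot assess
    the gene (insufficient data).
    """

    gene: str
    dataset_id: str
    case_count: int
    case_n: int
    control_count: int | None
    control_n: int
    p_value: float | None
    significant: bool | None
    method: str
    threshold: float

    @property
    def case_pct(self) -> float:
        return round_half_up(100.0 * self.case_count / self.case_n, 2)

    @property
    def control_pct(self) -> float | None:
        if self.control_count is None:
            return None
        return round_half_up(100.0 * self.control_count / self.control_n, 2)


class GeneBurdenResults:
    """Fitted burden results with frame/summary accessors."""

    def __init__(self, results: list[BurdenResult], config: TestConfig, case_n: int):
        self.results = results
        self.config = config
        self.case_n = case_n
        self.bonferroni = bonferroni_threshold(config.alpha, config.n_tests)

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "gene": r.gene,
                    "dataset": r.dataset_id,
                    "case_count": r.case_count,
                    "case_pct": r.case_pct,
                    "control_count": r.control_count,
                    "control_pct": r.control_pct,
                    "p_value": r.p_value,
                    "p_display": "n/a" if r.p_value is None else f"{r.p_value:.4f}",
                    "significant": r.significant,
                }
            )
        return pd.DataFrame(rows)

    @property
    def significant_genes(self) -> dict[str, list[str]]:
        """dataset -> genes significant after Bonferroni."""
        out: dict[str, list[str]] = {}
        for r in self.results:
            if r.significant:
                out.setdefault(r.dataset_id, []).append(r.gene)
        return out

    def summary(self) -> str:
        """Report-style table: one row per gene, one count/%/p block per dataset."""
        datasets = list(dict.fromkeys(r.dataset_id for r in self.results))
        by_gene: dict[str, dict[str, BurdenResult]] = {}
        for r in self.results:
            by_gene.setdefault(r.gene, {})[r.dataset_id] = r
        header = ["Gene", f"Cases (n={self.case_n})"]
        for ds in datasets:
            header += [f"{ds} (%)", f"{ds} p"]
        lines = [
            "Gene burden of qualifying variants "
            f"(method={self.config.two_sided_method}, "
            f"Bonferroni threshold={self.bonferroni:.3g})",
            "\t".join(header),
        ]
        for gene, per_ds in by_gene.items():
            any_r = next(iter(per_ds.values()))
            row = [gene, f"{any_r.case_count} ({any_r.case_pct:.2f})"]
            for ds in datasets:
                r = per_ds.get(ds)
                if r is None or r.control_count is None:
                    row += ["n/a", "n/a"]
                else:
                    star = "*" if r.significant else ""
                    row += [f"{r.control_count} ({r.control_pct:.2f})", f"{r.p_value:.4f}{star}"]
            lines.append("\t".join(row))
        return "\n".join(lines)


class GeneBurdenModel:
    """Exact-test burden model over per-gene case/control counts.

    Construct either directly from counts or with :meth:`from_cohort`, which
    derives counts from annotated variants, their qualifying statuses and the
    control frequency tables. ``fit`` runs one exact conditional test per
    (gene, dataset) and applies the Bonferroni threshold.
    """

    def __init__(
        self,
        case_counts: Mapping[str, int],
        case_n: int,
        control_counts: Mapping[str, Mapping[str, int | None]],
        control_ns: Mapping[str, int],
        config: TestConfig | None = None,
        gene_set: GeneSet | None = None,
    ):
        if case_n < 1:
            raise DataError("case_n must be >= 1")
        self.gene_set = gene_set or default_gene_set()
        self.case_counts = dict(case_counts)
        self.case_n = case_n
        self.control_counts = {ds: dict(cc) for ds, cc in control_counts.items()}
        self.control_ns = dict(control_ns)
        self.config = config or TestConfig(n_tests=self.gene_set.n_genes)
        for ds in self.control_counts:
            if ds not in self.control_ns:
                raise DataError(f"no sample size for control dataset {ds!r}")

    @classmethod
    def from_cohort(
        cls,
        variants: Sequence[AnnotatedVariant],
        statuses: Mapping,
        control_tables: Iterable[ControlFrequencyTable],
        case_n: int,
        gene_set: GeneSet | None = None,
        config: TestConfig | None = None,
    ) -> "GeneBurdenModel":
        """Derive per-gene counts from a qualified cohort.

        Case counts follow the configured counting mode over case
        observations. Control counts sum each dataset's carrier counts over
        that gene's annotated qualifying sites (annotation rows without case
        observations still contribute their control carriers).
        """
        gene_set = gene_set or default_gene_set()
        config = config or TestConfig(n_tests=gene_set.n_genes)
        tables = list(control_tables)
        case_counts: dict[str, int] = {}
        control_counts: dict[str, dict[str, int | None]] = {t.dataset_id: {} for t in tables}
        for gene in gene_set.symbols:
            case_counts[gene] = count_qualifying(variants, statuses, gene, config.count_mode)
            gene_keys = [
                v.key for v in variants
                if v.gene == gene and not v.off_target and statuses[v.key].qualifies
            ]
            for t in tables:
                if not t.covers_gene(gene):
                    control_counts[t.dataset_id][gene] = None
                    continue
                total = sum(t.lookup(k).carriers for k in gene_keys)
                control_counts[t.dataset_id][gene] = min(total, t.sample_size)
        return cls(
            case_counts,
            case_n,
            control_counts,
            {t.dataset_id: t.sample_size for t in tables},
            config=config,
            gene_set=gene_set,
        )

    def fit(self) -> GeneBurdenResults:
        cfg = self.config
        threshold = bonferroni_threshold(cfg.alpha, cfg.n_tests)
        results: list[BurdenResult] = []
        for gene in self.gene_set.symbols:
            a = self.case_counts.get(gene, 0)
            for ds, per_gene in self.control_counts.items():
                n_d = self.control_ns[ds]
                c = per_gene.get(gene, 0)
                if c is None:
                    results.append(
                        BurdenResult(gene, ds, a, self.case_n, None, n_d,
                                     None, None, cfg.two_sided_method, threshold)
                    )
                    continue
                tab = ContingencyTable2x2.from_counts(a, self.case_n, c, n_d, cfg.table_unit)
                p = fisher_exact_2x2(tab.as_tuple(), cfg.two_sided_method)
                results.append(
                    BurdenResult(gene, ds, a, self.case_n, c, n_d,
                                 p, p < threshold, cfg.two_sided_method, threshold)
                )
        return GeneBurdenResults(results, cfg, self.case_n)


def burden_report(
    variants: Sequence[AnnotatedVariant],
    statuses: Mapping,
    control_tables: Iterable[ControlFrequencyTable],
    case_n: int,
    gene_set: GeneSet | None = None,
    config: TestConfig | None = None,
) -> GeneBurdenResults:
    """One-call burden report: build the model from a cohort and fit it."""
    model = GeneBurdenModel.from_cohort(
        variants, statuses, control_tables, case_n, gene_set, config
    )
    return model.fit()
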