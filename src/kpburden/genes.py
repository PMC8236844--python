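"""Gene panel definition: the candidate genes, their canonical transcripts and
pathway membership.

The default panel is the 18-gene tryptophan-metabolism set: the cytoplasmic
tryptophanyl-tRNA synthetase (protein synthesis), four serotonin-synthesis
genes and thirteen kynurenine-pathway genes, each pinned to one RefSeq
accession.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import yaml

from ._util import ConfigError, data_path

PATHWAY_GROUPS = ("protein_synthesis", "serotonin", "kynurenine")


@dataclass(frozen=True)
class GeneDef:
    """One panel gene: HGNC-style symbol, aliases, canonical transcript."""

    symbol: str
    transcript: str
    chromosome: str
    pathway_group: str
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ConfigError("gene symbol must be non-empty")
        if self.pathway_group not in PATHWAY_GROUPS:
            raise ConfigError(
                f"unknown pathway_group {self.pathway_group!r} for {self.symbol}; "
                f"expected one of {PATHWAY_GROUPS}"
            )


class GeneSet:
    """Ordered collection of GeneDef with total symbol/alias resolution.

    Lookup accepts either the primary symbol or any alias (e.g. ``CCBL1``
    resolves to ``KYAT1``). Symbols and aliases must be globally unique.
    """

    def __init__(self, genes: list[GeneDef]):
        if not genes:
            raise ConfigError("gene set must contain at least one gene")
        self.genes: tuple[GeneDef, ...] = tuple(genes)
        self._index: dict[str, GeneDef] = {}
        for g in self.genes:
            for name in (g.symbol, *g.aliases):
                if name in self._index:
                    raise ConfigError(f"duplicate gene symbol or alias: {name}")
                self._index[name] = g

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(g.symbol for g in self.genes)

    def lookup(self, name: str) -> GeneDef | None:
        """Resolve a symbol or alias; None if the gene is off-panel."""
        return self._index.get(name)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __iter__(self) -> Iterator[GeneDef]:
        return iter(self.genes)

    def __len__(self) -> int:
        return self.n_genes


def load_gene_set(config_path: str | Path | None = None) -> GeneSet:
    """Load a gene panel from YAML; with no path, the packaged 18-gene default.

    The YAML layout is ``genes: [{symbol, aliases, transcript, chromosome,
    pathway_group}, ...]``.
    """
    source = Path(config_path) if config_path is not None else data_path("gene_set.yaml")
    try:
        raw = yaml.safe_load(Path(source).read_text())
    except FileNotFoundError as exc:
        raise ConfigError(f"gene set config not found: {source}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"gene set config does not parse: {exc}") from exc
    if not isinstance(raw, dict) or "genes" not in raw:
        raise ConfigError("gene set config must contain a top-level 'genes' list")
    entries = raw["genes"]
    if not entries:
        raise ConfigError("gene set config lists no genes")
    genes = []
    for e in entries:
        try:
            genes.append(
                GeneDef(
                    symbol=str(e["symbol"]),
                    transcript=str(e["transcript"]),
                    chromosome=str(e["chromosome"]),
                    pathway_group=str(e["pathway_group"]),
                    aliases=tuple(str(a) for a in e.get("aliases", [])),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"gene entry missing field {exc}: {e}") from exc
    return GeneSet(genes)


def default_gene_set() -> GeneSet:
    """The packaged 18-gene tryptophan / kynurenine panel."""
    return load_gene_set(None)
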