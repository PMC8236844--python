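"""Consensus in-silico pathogenicity scoring.

The consensus score is the fraction of predictors returning a deleterious
call among predictors that returned any call, rounded half-away-from-zero to
two decimals; a score of 1 means every tool with a result called the variant
deleterious. Missense variants are scored over the 12 dbNSFP tools; splicing
variants over the splice-capable set (MutationTaster/NNSplice, CADD,
BayesDel, plus an imported Human Splicing Finder verdict when present). The
meta-predictors REVEL and BayesDel are reported alongside with inclusive
published cutoffs (0.5 and -0.057).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from ._util import ConfigError, DataError, UndefinedScoreError, data_path, round_half_up
from .variants import MISSENSE_TOOLS, PredictionProfile

DELETERIOUS = "deleterious"
BENIGN = "benign"
MISSING = "missing"


def _load_mapping(path: str | Path | None = None) -> dict:
    source = Path(path) if path is not None else data_path("tool_calls.yaml")
    return yaml.safe_load(Path(source).read_text())


_DEFAULT_MAPPING = _load_mapping()

REVEL_CUTOFF: float = float(_DEFAULT_MAPPING["meta"]["REVEL"]["cutoff"])
BAYESDEL_CUTOFF: float = float(_DEFAULT_MAPPING["meta"]["BayesDel"]["cutoff"])


def _classify(spec: Mapping, raw: str | float | None) -> str:
    if raw is None:
        return MISSING
    if spec["kind"] == "numeric":
        try:
            value = float(raw)
        except (TypeError, ValueError):
            return MISSING
        return DELETERIOUS if value >= float(spec["cutoff"]) else BENIGN
    token = str(raw).strip()
    if token in ("", "."):
        return MISSING
    if token in {str(x) for x in spec.get("deleterious", [])}:
        return DELETERIOUS
    if token in {str(x) for x in spec.get("benign", [])}:
        return BENIGN
    return MISSING


def classify_tool_prediction(
    tool: str,
    raw: str | float | None,
    mapping: Mapping | None = None,
    splice: bool = False,
) -> str:
    """Classify one tool's raw annotation cell as deleterious/benign/missing."""
    table = (mapping or _DEFAULT_MAPPING)["splice" if splice else "tools"]
    if tool not in table:
        raise ConfigError(f"unknown prediction tool {tool!r}")
    return _classify(table[tool], raw)


class ToolCallTable:
    """Per-tool deleterious/benign/missing calls with derived counts."""

    def __init__(self, calls: Mapping[str, str]):
        for tool, call in calls.items():
            if call not in (DELETERIOUS, BENIGN, MISSING):
                raise DataError(f"invalid call {call!r} for tool {tool}")
        self.calls = dict(calls)

    @property
    def n_with_results(self) -> int:
        return sum(1 for c in self.calls.values() if c != MISSING)

    @property
    def n_deleterious(self) -> int:
        return sum(1 for c in self.calls.values() if c == DELETERIOUS)

    @classmethod
    def from_profile(
        cls, profile: PredictionProfile, mapping: Mapping | None = None
    ) -> "ToolCallTable":
        """Calls for the 12 missense predictors; tools absent from the profile
        are missing."""
        calls = {
            tool: classify_tool_prediction(tool, profile.tools.get(tool), mapping)
            for tool in MISSENSE_TOOLS
        }
        return cls(calls)


@dataclass(frozen=True)
class ConsensusScore:
    """Fraction-of-tools-deleterious score with its denominator.

    ``value`` is the 2-decimal display value (half-away-from-zero);
    ``raw_value`` keeps full precision. REVEL/BayesDel verdicts ride along
    ('missing' when the underlying score is unavailable).
    """

    value: float
    raw_value: float
    n_with_results: int
    revel_call: str = MISSING
    bayesdel_call: str = MISSING

    def __str__(self) -> str:  # Table-style display, e.g. "0.83 (12)"
        v = f"{self.value:g}"
        return f"{v} ({self.n_with_results})"


def call_revel(score: float, cutoff: float = REVEL_CUTOFF) -> str:
    """REVEL verdict: Pathogenic iff score >= cutoff (inclusive)."""
    if not (0.0 <= score <= 1.0):
        raise DataError(f"REVEL score {score} outside [0, 1]")
    return "Pathogenic" if score >= cutoff else "Benign"


def call_bayesdel(score: float, cutoff: float = BAYESDEL_CUTOFF) -> str:
    """BayesDel verdict: Damaging iff score >= cutoff (inclusive)."""
    return "Damaging" if float(score) >= cutoff else "Tolerated"


def _meta_calls(profile: PredictionProfile) -> tuple[str, str]:
    revel = MISSING if profile.revel is None else call_revel(profile.revel)
    bayesdel = MISSING if profile.bayesdel is None else call_bayesdel(profile.bayesdel)
    return revel, bayesdel


def consensus_score(
    table: ToolCallTable, revel_call: str = MISSING, bayesdel_call: str = MISSING
) -> ConsensusScore:
    """Consensus score = n_deleterious / n_with_results, 2-dp display rounding.

    Undefined (raises) when no tool returned a result.
    """
    n = table.n_with_results
    if n == 0:
        raise UndefinedScoreError("no prediction tool returned a result")
    raw = table.n_deleterious / n
    return ConsensusScore(
        value=round_half_up(raw, 2),
        raw_value=raw,
        n_with_results=n,
        revel_call=revel_call,
        bayesdel_call=bayesdel_call,
    )


def score_missense(profile: PredictionProfile, mapping: Mapping | None = None) -> ConsensusScore:
    """Consensus over the 12 missense predictors plus REVEL/BayesDel verdicts."""
    revel, bayesdel = _meta_calls(profile)
    return consensus_score(ToolCallTable.from_profile(profile, mapping), revel, bayesdel)


def score_splicing(profile: PredictionProfile, mapping: Mapping | None = None) -> ConsensusScore:
    """Consensus over the splice-capable tools.

    Default set: MutationTaster (carrying NNSplice), CADD, BayesDel, and an
    imported HSF verdict; any tool without a result drops out of the
    denominator (an absent HSF column simply shrinks it). REVEL is not
    splice-capable, so its verdict is missing here unless a score is present
    in the profile.
    """
    table = (mapping or _DEFAULT_MAPPING)["splice"]
    calls: dict[str, str] = {}
    for tool, spec in table.items():
        if tool == "BayesDel":
            raw: str | float | None = profile.bayesdel
        elif tool in profile.splice:
            raw = profile.splice.get(tool)
        else:
            raw = profile.tools.get(tool)
        calls[tool] = _classify(spec, raw)
    revel, bayesdel = _meta_calls(profile)
    return consensus_score(ToolCallTable(calls), revel, bayesdel)


def score_variant(
    profile: PredictionProfile, consequence: str, mapping: Mapping | None = None
) -> ConsensusScore:
    """Dispatch on consequence: splicing variants use the splice tool set."""
    if consequence == "splicing":
        return score_splicing(profile, mapping)
    return score_missense(profile, mapping)
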