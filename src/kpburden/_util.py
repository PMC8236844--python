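"""Shared helpers: rounding, chromosome normalisation, error types."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from importlib import resources


class KpBurdenError(Exception):
    """Base class for package errors."""


class ConfigError(KpBurdenError):
    """Invalid configuration or gene-set definition (CLI exit code 2)."""


class DataError(KpBurdenError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


class UndefinedScoreError(KpBurdenError):
    """Consensus score requested when no predictor returned a result."""


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching printed report conventions.

    Python's builtin round() is banker's rounding; report tables round
    0.005 -> 0.01.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def normalize_chrom(chrom: str) -> str:
    """Normalise contig names to the 'chr'-prefixed hg19 convention."""
    c = str(chrom).strip()
    if not c:
        raise DataError("empty chromosome name")
    if c.upper() in ("MT", "CHRMT"):
        return "chrM"
    return c if c.startswith("chr") else f"chr{c}"


def data_path(name: str):
    """Path to a packaged data file (YAML tables shipped with the package)."""
    return resources.files("kpburden.data").joinpath(name)
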