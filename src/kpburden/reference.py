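"""Packaged reference counts from the published 614-case sporadic ALS screen
of this panel, for worked examples and regression checks."""

from __future__ import annotations

from pathlib import Path

import yaml

from ._util import data_path


def load_reference_counts() -> dict:
    """Cohort sizes, per-gene qualifying-variant counts with printed
    percentages, and the printed novel-variant (score, n-tools) pairs."""
    return yaml.safe_load(Path(data_path("sals_reference_counts.yaml")).read_text())


def reference_burden_model(two_sided_method: str = "central"):
    """GeneBurdenModel preloaded with the published per-gene counts."""
    from .burden import GeneBurdenModel, TestConfig

    ref = load_reference_counts()
    cohorts = ref["cohorts"]
    case_counts = {g: v["counts"]["SALS"] for g, v in ref["genes"].items()}
    control_counts = {
        ds: {g: v["counts"][ds] for g, v in ref["genes"].items()}
        for ds in ("nNFE", "AOGC", "MGRB")
    }
    control_ns = {ds: cohorts[ds] for ds in ("nNFE", "AOGC", "MGRB")}
    return GeneBurdenModel(
        case_counts,
        cohorts["SALS"],
        control_counts,
        control_ns,
        config=TestConfig(two_sided_method=two_sided_method, n_tests=18),
    )
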