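import itertools

import pytest
from hypothesis import given, settings, strategies as st

from kpburden import (
    AnnotatedVariant,
    ConsequenceClass,
    ControlFrequencyTable,
    DataError,
    MafPolicy,
    VariantKey,
    classify_consequence,
    is_protein_altering,
    is_rare,
    qualify,
)
from kpburden.filtering import resolve_transcript_consequence
from kpburden.variants import ControlFrequencyRecord

KEY = VariantKey("chr2", 143799665, "A", "G")


def table_with_maf(dataset_id: str, sample_size: int, maf: float | None) -> ControlFrequencyTable:
    """Control table carrying KEY at the requested MAF (None = absent)."""
    records = {}
    if maf is not None:
        ac = round(maf * 2 * sample_size)
        records[KEY] = ControlFrequencyRecord(dataset_id, KEY, None, ac, sample_size)
    return ControlFrequencyTable(dataset_id, sample_size, records)


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("nonsynonymous SNV", ConsequenceClass.MISSENSE),
        ("stopgain", ConsequenceClass.STOPGAIN),
        ("stoploss", ConsequenceClass.STOPLOSS),
        ("frameshift insertion", ConsequenceClass.FRAMESHIFT_INDEL),
        ("nonframeshift deletion", ConsequenceClass.INFRAME_INDEL),
        ("splicing", ConsequenceClass.SPLICING),
        ("synonymous SNV", ConsequenceClass.SYNONYMOUS),
        ("UTR3", ConsequenceClass.UTR3),
        ("UTR5", ConsequenceClass.UTR5),
        ("intronic", ConsequenceClass.INTRONIC),
        ("banana", ConsequenceClass.OTHER),
        ("exonic;splicing", ConsequenceClass.SPLICING),
    ],
)
def test_classify_consequence(raw, expected):
    assert classify_consequence(raw) is expected


def test_protein_altering_classes_exactly():
    altering = {c for c in ConsequenceClass if is_protein_altering(c)}
    assert altering == {
        ConsequenceClass.MISSENSE,
        ConsequenceClass.STOPGAIN,
        ConsequenceClass.STOPLOSS,
        ConsequenceClass.FRAMESHIFT_INDEL,
        ConsequenceClass.INFRAME_INDEL,
        ConsequenceClass.SPLICING,
    }


def test_canonical_transcript_wins_else_most_severe():
    per_tx = {"NM_003937": "synonymous SNV", "NM_999": "stopgain"}
    assert resolve_transcript_consequence(per_tx, "NM_003937") is ConsequenceClass.SYNONYMOUS
    assert resolve_transcript_consequence(per_tx, "NM_other") is ConsequenceClass.STOPGAIN


class TestIsRare:
    def test_large_cohort_stricter_threshold(self):
        tables = [table_with_maf("nNFE", 51592, 2e-4)]
        assert is_rare(KEY, tables)["nNFE"] is False

    def test_default_threshold_inclusive(self):
        tables = [table_with_maf("AOGC", 967, 0.004)]
        assert is_rare(KEY, tables)["AOGC"] is True

    def test_boundary_exact_threshold_is_rare(self):
        # MAF exactly at the threshold passes (inclusive <=)
        aogc = table_with_maf("AOGC", 1000, 0.005)
        assert aogc.lookup(KEY).maf == 0.005
        assert is_rare(KEY, [aogc])["AOGC"] is True
        nnfe = table_with_maf("nNFE", 50000, 0.0001)
        assert nnfe.lookup(KEY).maf == 0.0001
        assert is_rare(KEY, [nnfe])["nNFE"] is True

    def test_absent_everywhere_is_rare_everywhere(self):
        tables = [table_with_maf(ds, n, None)
                  for ds, n in (("nNFE", 51592), ("AOGC", 967), ("MGRB", 1144))]
        assert all(is_rare(KEY, tables).values())


def make_variant(consequence: str, off_target: bool = False) -> AnnotatedVariant:
    return AnnotatedVariant(
        key=KEY, gene="KYNU", transcript="NM_003937",
        consequence=consequence, off_target=off_target,
    )


class TestQualify:
    def test_missense_absent_from_controls_qualifies(self):
        tables = [table_with_maf("nNFE", 51592, None)]
        status = qualify(make_variant("missense"), tables)
        assert status.qualifies
        assert status.reasons == ()

    def test_common_in_one_dataset_disqualifies_with_reason(self):
        tables = [table_with_maf("nNFE", 51592, 0.002), table_with_maf("AOGC", 967, None)]
        status = qualify(make_variant("missense"), tables)
        assert not status.qualifies
        assert status.rare_in == {"nNFE": False, "AOGC": True}
        assert "common_in:nNFE" in status.reasons

    def test_synonymous_never_qualifies_even_when_absent(self):
        tables = [table_with_maf("nNFE", 51592, None)]
        for consequence in ("synonymous", "utr5", "utr3", "intronic", "intergenic"):
            status = qualify(make_variant(consequence), tables)
            assert not status.qualifies
            assert status.reasons

    def test_off_target_rejected(self):
        with pytest.raises(DataError):
            qualify(make_variant("missense", off_target=True), [])

    def test_conjunction_law_brute_force(self):
        """qualifies <=> protein_altering AND rare in every dataset, checked
        over every combination of consequence class and per-dataset rarity."""
        for cls, rare_nnfe, rare_aogc in itertools.product(
            ConsequenceClass, [True, False], [True, False]
        ):
            if cls is ConsequenceClass.OTHER:
                continue
            tables = [
                table_with_maf("nNFE", 51592, None if rare_nnfe else 2e-3),
                table_with_maf("AOGC", 967, None if rare_aogc else 2e-1),
            ]
            status = qualify(make_variant(cls.value), tables)
            expected = is_protein_altering(cls) and rare_nnfe and rare_aogc
            assert status.qualifies == expected
            assert bool(status.reasons) == (not expected)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    maf=st.floats(0.0, 0.02),
    thr_high=st.floats(1e-5, 0.01),
    thr_low=st.floats(1e-6, 0.01),
)
def test_lowering_threshold_never_creates_qualifiers(maf, thr_high, thr_low):
    """Monotonicity: a variant not qualifying at some threshold cannot
    qualify at any lower threshold."""
    thr_low = min(thr_low, thr_high)
    table = table_with_maf("DS", 100000, maf)
    v = make_variant("missense")
    high = qualify(v, [table], MafPolicy(thr_high, {}))
    low = qualify(v, [table], MafPolicy(thr_low, {}))
    if not high.qualifies:
        assert not low.qualifies
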