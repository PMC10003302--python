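"""ACMG/AMP clause combination, oracle equivalence, and auto-assignment."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from cdcurate.acmg import (
    ALL_CODES,
    auto_assign,
    classify_table,
    combine,
    parse_evidence,
    strength_class,
)
from cdcurate.cf_threshold import PrevalenceModel, gene_threshold, subset_threshold
from cdcurate.core_model import GeneModel, PopulationFrequency, build_variant

# ---------------------------------------------------------------------------
# Independent clause-enumeration oracle: a table of minimum-count requirements
# checked by explicit iteration, written without reference to the engine.

_P_CLAUSES = [
    {"PVS": 1, "PS": 1}, {"PVS": 1, "PM": 2}, {"PVS": 1, "PM": 1, "PP": 1},
    {"PVS": 1, "PP": 2}, {"PS": 2}, {"PS": 1, "PM": 3},
    {"PS": 1, "PM": 2, "PP": 2}, {"PS": 1, "PM": 1, "PP": 4},
]
_LP_CLAUSES = [
    {"PVS": 1, "PM": 1}, {"PS": 1, "PM": 1}, {"PS": 1, "PP": 2},
    {"PM": 3}, {"PM": 2, "PP": 2}, {"PM": 1, "PP": 4},
]
_B_CLAUSES = [{"BA": 1}, {"BS": 2}]
_LB_CLAUSES = [{"BS": 1, "BP": 1}, {"BP": 2}]


def _oracle(codes):
    tally = {"PVS": 0, "PS": 0, "PM": 0, "PP": 0, "BA": 0, "BS": 0, "BP": 0}
    for c in codes:
        for prefix in ("PVS", "BA", "BS", "BP", "PS", "PM", "PP"):
            if c.startswith(prefix):
                tally[prefix] += 1
                break
    def satisfied(clauses):
        for clause in clauses:
            if all(tally[k] >= v for k, v in clause.items()):
                return True
        return False
    p = satisfied(_P_CLAUSES)
    lp = satisfied(_LP_CLAUSES)
    b = satisfied(_B_CLAUSES)
    lb = satisfied(_LB_CLAUSES)
    if (p or lp) and (b or lb):
        return "VUS"
    if p:
        return "Pathogenic"
    if lp:
        return "Likely_pathogenic"
    if b:
        return "Benign"
    if lb:
        return "Likely_benign"
    return "VUS"


@pytest.mark.parametrize(
    "codes,rank",
    [
        ({"PVS1", "PS4", "PM4"}, "Pathogenic"),
        ({"PS4", "PP1", "PP2", "PP3", "PP4"}, "Likely_pathogenic"),
        ({"PM3", "PP1", "PP2", "PP3", "PP4"}, "Likely_pathogenic"),
        (set(), "VUS"),
        ({"BA1"}, "Benign"),
        ({"BS1", "BS2"}, "Benign"),
        ({"BS1", "BP4"}, "Likely_benign"),
        ({"BP4", "BP7"}, "Likely_benign"),
        ({"PVS1", "PS3", "BA1"}, "VUS"),  # contradictory evidence
    ],
)
def test_combine_examples(codes, rank):
    assert combine(codes).rank == rank


def test_exhaustive_oracle_equivalence_up_to_four_codes():
    """combine matches the independent oracle for every code set of size <= 4."""
    codes = sorted(ALL_CODES)
    for r in range(5):
        for subset in itertools.combinations(codes, r):
            assert combine(frozenset(subset)).rank == _oracle(subset), subset


@settings(max_examples=300, deadline=None)
@given(st.sets(st.sampled_from(sorted(ALL_CODES)), max_size=8))
def test_combine_order_invariant_and_matches_oracle(codes):
    ranks = {combine(frozenset(perm)).rank for perm in [list(codes), sorted(codes)]}
    assert len(ranks) == 1
    assert ranks.pop() == _oracle(codes)


_RANK_ORDER = {"Benign": 0, "Likely_benign": 1, "VUS": 2, "Likely_pathogenic": 3, "Pathogenic": 4}
_P_SIDE = sorted(c for c in ALL_CODES if c[0] == "P")


@settings(max_examples=300, deadline=None)
@given(
    st.sets(st.sampled_from(sorted(ALL_CODES)), max_size=5),
    st.sampled_from(_P_SIDE),
)
def test_adding_pathogenic_code_never_moves_toward_benign(codes, extra):
    before = combine(frozenset(codes)).rank
    after = combine(frozenset(codes | {extra})).rank
    if after != "VUS":  # conflicting-evidence transitions into VUS are allowed
        assert _RANK_ORDER[after] >= _RANK_ORDER[before]


def test_strength_class_and_unknown_codes():
    assert strength_class("PVS1") == "very_strong"
    assert strength_class("PM4") == "moderate"
    assert strength_class("BA1") == "stand_alone_benign"
    with pytest.raises(ValueError, match="PX9"):
        strength_class("PX9")
    with pytest.raises(ValueError, match="NOPE"):
        combine({"NOPE"})


def test_parse_evidence_dialect():
    assert parse_evidence("PVS1+PS4+PM4") == frozenset({"PVS1", "PS4", "PM4"})
    assert parse_evidence(".") == frozenset()
    with pytest.raises(ValueError):
        parse_evidence("PVS1+PVS1")


def test_cohort_table_ranks_reproduced(cohort_variants):
    """All printed cohort evidence sets combine to their printed ranks."""
    result = classify_table(cohort_variants)
    short = result["rank"].map({"Pathogenic": "P", "Likely_pathogenic": "LP"})
    assert list(short) == list(cohort_variants["rank"])
    assert (short == "P").sum() == 14 and (short == "LP").sum() == 3


def test_classify_table_empty_and_bad_rows(cohort_variants):
    import pandas as pd
    empty = classify_table(pd.DataFrame({"evidence": []}))
    assert empty.empty
    bad = pd.DataFrame({"evidence": ["PVS1+WAT"]})
    with pytest.raises(ValueError, match="row 0"):
        classify_table(bad)


# ---------------------------------------------------------------------------
# auto-assignment of frequency-linked codes

_AD_LOF = GeneModel(
    symbol="ZEB1", transcript="NM_0", chromosome="10", inheritance="AD",
    family_count=76, share=76 / 2933, lof_mechanism=True,
)
_AD_TGFBI = GeneModel(
    symbol="TGFBI", transcript="NM_0", chromosome="5", inheritance="AD",
    hotspot_codons=frozenset({124, 555, 626}), family_count=1850, share=0.6308,
)
_PREV = PrevalenceModel()


def test_auto_assign_flagged_variant_reclassifies_benign():
    v = build_variant("TGFBI", "c.1501C>A", "p.(Pro501Thr)")
    t = subset_threshold(_AD_TGFBI, _PREV, 0.1314, printed_budget_per_100k=6.0)
    codes = auto_assign(v, PopulationFrequency(85, 279_506), t, cross_check=83, gene=_AD_TGFBI)
    assert codes == {"BS1", "BS2"}
    assert combine(codes).rank == "Benign"


def test_auto_assign_absent_truncating_gets_pm2_pvs1():
    v = build_variant("ZEB1", "c.1481_1482insTTTT", "p.(Lys494Asnfs*12)")
    t = gene_threshold(_AD_LOF, _PREV)
    codes = auto_assign(v, PopulationFrequency(0, 250_000), t, gene=_AD_LOF)
    assert codes == {"PM2", "PVS1"}


def test_auto_assign_common_variant_is_ba1_only():
    v = build_variant("TGFBI", "c.999A>G", "p.(Lys333Arg)")
    t = gene_threshold(_AD_TGFBI, _PREV)
    codes = auto_assign(v, PopulationFrequency(15_000, 250_000), t, gene=_AD_TGFBI)
    assert codes == {"BA1"}  # BA1 wins; PM2/BS1 suppressed
    assert combine(codes).rank == "Benign"


def test_auto_assign_never_emits_curator_codes():
    v = build_variant("TGFBI", "c.370C>T", "p.(Arg124Cys)")
    t = gene_threshold(_AD_TGFBI, _PREV)
    codes = auto_assign(v, PopulationFrequency(2, 280_458), t, gene=_AD_TGFBI)
    curator = {"PS1", "PS2", "PS3", "PS4", "PM1", "PM3", "PM5", "PM6",
               "PP1", "PP2", "PP3", "PP4", "PP5"}
    assert not codes & curator
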