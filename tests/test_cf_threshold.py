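"""Carrier-frequency budgets, the rounding rule, and the frequency screen."""

import pytest
from hypothesis import given, settings, strategies as st

from cdcurate import reference
from cdcurate.cf_threshold import (
    PrevalenceModel,
    ThresholdPolicy,
    carrier_frequency,
    flag_variants,
    frequency_check,
    gene_threshold,
    round_threshold_per_100k,
    subset_threshold,
)
from cdcurate.core_model import (
    CohortFamilyRecord,
    FamilyMember,
    GeneModel,
    PopulationFrequency,
    build_variant,
)
from cdcurate.cf_threshold import phenotype_cross_check


def _gene(symbol="ZEB1", share=76 / 2933, inheritance="AD", hotspots=()):
    return GeneModel(
        symbol=symbol, transcript="NM_0", chromosome="1", inheritance=inheritance,
        hotspot_codons=frozenset(hotspots), family_count=1, share=share,
    )


def test_prevalence_model_product():
    prev = PrevalenceModel()
    assert prev.monogenic_prevalence == pytest.approx(897e-6 / 2)
    with pytest.raises(ValueError):
        PrevalenceModel(total_prevalence=0.0)


@pytest.mark.parametrize(
    "raw,expected",
    [
        (0.0, 0.0),
        (1.1622e-5, 1.0),   # rounds to nearest integer at >= 1 per 100k
        (1.5e-5, 2.0),
        (0.474e-5, 0.5),    # nearest 0.1 below 1 per 100k
        (0.0612e-5, 0.1),   # floor of 0.1
        (0.035e-5, 0.1),
        (0.35e-5, 0.4),     # half-up at the midpoint
    ],
)
def test_rounding_rule(raw, expected):
    assert round_threshold_per_100k(raw) == expected


def test_gene_threshold_product(prevalence):
    t = gene_threshold(_gene(), prevalence)
    assert t.raw_cf == pytest.approx((76 / 2933) * 448.5e-6)
    assert t.reported_per_100k == 1.0
    zero = gene_threshold(_gene(share=0.0), prevalence)
    assert zero.raw_cf == 0.0 and zero.reported_per_100k == 0.0


def test_ar_gene_has_no_threshold(prevalence):
    t = gene_threshold(_gene(inheritance="AR"), prevalence)
    assert not t.applicable
    assert t.budget is None and t.reported_per_100k is None


def test_subset_threshold_identity_and_zero(prevalence):
    g = _gene(symbol="TGFBI", share=0.6315, hotspots=(124, 555, 626))
    full = gene_threshold(g, prevalence)
    assert subset_threshold(g, prevalence, 1.0).raw_cf == pytest.approx(full.raw_cf)
    assert subset_threshold(g, prevalence, 0.0).raw_cf == 0.0
    sub = subset_threshold(g, prevalence, 0.1314, printed_budget_per_100k=6.0)
    assert sub.raw_cf == pytest.approx(0.6315 * 0.1314 * 448.5e-6)
    assert sub.budget == pytest.approx(6e-5)  # printed budget is operative


def test_carrier_frequency_values():
    assert carrier_frequency(PopulationFrequency(13, 249_042)) == pytest.approx(
        2 * (13 / 249_042) * (1 - 13 / 249_042)
    )
    assert carrier_frequency(PopulationFrequency(85, 279_506)) == pytest.approx(6.08e-4, rel=1e-3)
    assert carrier_frequency(PopulationFrequency(0, 1000)) == 0.0


def test_frequency_check_boundaries(prevalence):
    g = _gene()
    t = gene_threshold(g, prevalence)
    v = build_variant("ZEB1", "c.100A>G", "p.(Ala34Val)")
    assert frequency_check(v, PopulationFrequency(0, 250_000), t) is False
    assert frequency_check(v, None, t) is None  # not evaluable, never a pass
    big = PopulationFrequency(5000, 250_000)
    assert frequency_check(v, big, t) is True


def test_budget_conservation(panel, prevalence):
    """Sum of AD-gene budgets never exceeds the monogenic prevalence."""
    total = sum(
        gene_threshold(g, prevalence).raw_cf
        for g in panel.values()
        if g.inheritance == "AD"
    )
    assert total <= prevalence.monogenic_prevalence + 1e-15


@settings(max_examples=200, deadline=None)
@given(
    ac=st.integers(min_value=0, max_value=10_000),
    bump=st.integers(min_value=1, max_value=1_000),
)
def test_monotonic_in_allele_count(ac, bump):
    """Raising AC never converts a fail into a pass."""
    prev = PrevalenceModel()
    t = gene_threshold(_gene(), prev)
    v = build_variant("ZEB1", "c.100A>G", "p.(Ala34Val)")
    low = frequency_check(v, PopulationFrequency(ac, 250_000), t)
    high = frequency_check(v, PopulationFrequency(ac + bump, 250_000), t)
    assert not (low and not high)


@settings(max_examples=100, deadline=None)
@given(
    share=st.floats(min_value=1e-4, max_value=0.9),
    bump=st.floats(min_value=1e-4, max_value=0.09),
    ac=st.integers(min_value=0, max_value=2_000),
)
def test_monotonic_in_share(share, bump, ac):
    """Raising a gene's share never converts a pass into a fail."""
    prev = PrevalenceModel()
    v = build_variant("G1", "c.100A>G", "p.(Ala34Val)")
    pf = PopulationFrequency(ac, 250_000)
    low = frequency_check(v, pf, gene_threshold(_gene("G1", share), prev))
    high = frequency_check(v, pf, gene_threshold(_gene("G1", share + bump), prev))
    assert not (not low and high)


def test_policy_routes_hotspot_to_gene_budget(policy):
    hot = build_variant("TGFBI", "c.370C>T", "p.(Arg124Cys)")
    non = build_variant("TGFBI", "c.1501C>A", "p.(Pro501Thr)")
    assert policy.threshold_for(hot).subset == "all"
    t_non = policy.threshold_for(non)
    assert t_non.subset == "non_hotspot" and t_non.budget == pytest.approx(6e-5)


def test_phenotype_cross_check_counts_planted_carriers():
    key = ("TGFBI", "c.1501C>A")
    fams = []
    for i in range(5):
        m = FamilyMember(f"m{i}", False, {key: "ref/alt"})
        fams.append(CohortFamilyRecord(f"f{i}", (m,), "non_CD", f"m{i}"))
    cd = FamilyMember("cd1", True, {key: "ref/alt"})
    fams.append(CohortFamilyRecord("fcd", (cd,), "LCD", "cd1"))
    assert phenotype_cross_check(key, fams) == 5
    assert phenotype_cross_check(("TGFBI", "c.1A>G"), fams) == 0


def _brute_force_flags(rows, prevalence_mono):
    """Independent recomputation with explicit loops (no shared code).

    Each row: (gene, share, inheritance, hotspot_codons, codon, ac, an,
    subset_fraction, printed_budget_per_100k).
    """
    flagged = []
    for gene, share, inh, hotspots, codon, ac, an, frac, printed in rows:
        if inh != "AD":
            continue
        af = ac / an
        cf = 2.0 * af * (1.0 - af)
        if hotspots and codon not in hotspots and frac is not None:
            budget = printed * 1e-5 if printed is not None else share * frac * prevalence_mono
        else:
            budget = share * prevalence_mono
        if cf > budget:
            flagged.append((gene, codon))
    return flagged


def test_flagger_agrees_with_brute_force(policy, panel):
    """On a small table the flagger matches an independent loop recomputation."""
    cases = [
        ("TGFBI", 124, 2, 280_458),     # hotspot, modest AC -> pass
        ("TGFBI", 501, 85, 279_506),    # non-hotspot, high AC -> fail
        ("TGFBI", 544, 13, 249_042),    # fails only under the CF convention
        ("TGFBI", 200, 0, 250_000),
        ("ZEB1", 100, 0, 250_000),
        ("ZEB1", 101, 900, 250_000),    # cf ~7.2e-3 > 1.16e-5 -> fail
        ("CHST6", 268, 5_000, 250_000), # AR -> never flagged
        ("DCN", 50, 2, 250_000),        # cf 1.6e-5 > 0.0765e-5 -> fail
    ]
    variants, freqs, rows = [], {}, []
    for gene, codon, ac, an in cases:
        v = build_variant(gene, f"c.{3 * codon - 1}C>T", f"p.(Ala{codon}Val)")
        variants.append(v)
        freqs[v.key] = PopulationFrequency(ac, an)
        g = panel[gene]
        frac, printed = (0.1314, 6.0) if gene == "TGFBI" else (None, None)
        rows.append((gene, g.share, g.inheritance, set(g.hotspot_codons), codon, ac, an, frac, printed))
    decisions, _ = flag_variants(variants, freqs, policy)
    got = {(d.variant.gene, d.variant.protein_change.codon) for d in decisions if d.flagged}
    expected = set(_brute_force_flags(rows, 448.5e-6))
    assert got == expected
    assert ("TGFBI", 501) in got and ("CHST6", 268) not in got


def test_reference_screen_flags_twelve_of_sixty_one(policy, pop_freqs):
    decisions, summary = flag_variants(
        reference.reference_literature_variants(), pop_freqs, policy,
        cohort=reference.synthetic_inhouse_noncd_families(),
        family_counts=reference.reference_family_counts(),
    )
    assert summary["n_flagged"] == 12
    assert summary["n_families_attributed"] == 61
    by_key = {d.variant.key: d for d in decisions}
    assert by_key[("TGFBI", "c.1501C>A")].inhouse_noncd_families == 83
    assert by_key[("TGFBI", "c.367G>C")].inhouse_noncd_families == 51
    for d in decisions:  # flagged implies frequency_fail; phenotype corroborates
        if d.flagged:
            assert d.frequency_fail
        if d.phenotype_fail:
            assert d.inhouse_noncd_families > 0
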