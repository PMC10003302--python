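"""Multi-step cohort filter: stage boundaries, segregation, and the pipeline."""

import pytest

from cdcurate import reference
from cdcurate.cohort_filter import (
    PredictionProfile,
    filter_common,
    filter_quality,
    prediction_consensus,
    run_cohort,
    run_family_pipeline,
    segregation_check,
    solved_families_by_gene,
)
from cdcurate.core_model import (
    CohortFamilyRecord,
    FamilyMember,
    PopulationFrequency,
    build_variant,
)
from cdcurate.simulate import simulate_cohort


V1 = build_variant("TGFBI", "c.370C>T", "p.(Arg124Cys)")
V2 = build_variant("CHST6", "c.803A>G", "p.(Tyr268Cys)")
V3 = build_variant("CHST6", "c.1096G>T", "p.(Glu366*)")


@pytest.mark.parametrize("cov,kept", [(4, False), (5, True), (125, True)])
def test_quality_boundary(cov, kept):
    retained, dropped = filter_quality([V1], {V1.key: cov})
    assert (V1 in retained) is kept
    assert len(retained) + len(dropped) == 1


def test_quality_missing_coverage_retained():
    retained, _ = filter_quality([V1], {})
    assert retained == [V1]


@pytest.mark.parametrize(
    "ac,an,kept",
    [(2500, 250_000, False),  # af 0.01 -> boundary excluded
     (2475, 250_000, True),   # af 0.0099
     (20, 275_774, True)],
)
def test_common_af_boundary(ac, an, kept):
    retained, dropped = filter_common([V1], {V1.key: PopulationFrequency(ac, an)})
    assert (V1 in retained) is kept


def test_common_absent_from_population_retained():
    retained, _ = filter_common([V1], {})
    assert retained == [V1]


FULL_DELETERIOUS = PredictionProfile(revel=0.9, cadd=30, sift=0.0, polyphen2=0.99, provean=-7)


@pytest.mark.parametrize(
    "profile,consequence,expected",
    [
        (FULL_DELETERIOUS, "missense", "supported"),
        (PredictionProfile(), "frameshift", "supported"),          # truncating bypass
        (PredictionProfile(), "nonsense", "supported"),
        (PredictionProfile(revel=0.9, cadd=30, sift=0.9, polyphen2=0.1, provean=0.0),
         "missense", "unsupported"),                               # 2 of 5 < majority
        (PredictionProfile(revel=0.9, cadd=30, sift=0.01, polyphen2=0.1, provean=0.0),
         "missense", "supported"),                                 # 3 of 5
        (None, "missense", "not_evaluable"),
        (PredictionProfile(splice_calls={"varSEAK": "damaging"}), "splicing", "supported"),
        (PredictionProfile(splice_calls={"BDGP": "benign", "HSF": "benign"}),
         "splicing", "unsupported"),
        (None, "splicing", "not_evaluable"),
        (PredictionProfile(splice_calls={"HSF": "damaging"}), "synonymous", "supported"),
        (None, "inframe_indel", "not_evaluable"),
    ],
)
def test_prediction_consensus(profile, consequence, expected):
    assert prediction_consensus(profile, consequence) == expected


def _family(members, candidates, proband="II:1", phenotype="MCD"):
    return CohortFamilyRecord(
        family_id="F", members=tuple(members), phenotype=phenotype,
        proband_id=proband, candidate_variants=tuple(candidates),
    )


def test_segregation_compound_het_siblings_consistent():
    """Two affected sibs sharing both alleles of a recessive gene segregate."""
    gt = {V2.key: "ref/alt", V3.key: "ref/alt"}
    fam = _family(
        [FamilyMember("II:1", True, dict(gt)), FamilyMember("II:3", True, dict(gt))],
        [V2, V3],
    )
    assert segregation_check(fam, V2, "AR") == "consistent"
    assert segregation_check(fam, V3, "AR") == "consistent"


def test_segregation_unaffected_carrier_inconsistent_ad():
    fam = _family(
        [FamilyMember("II:1", True, {V1.key: "ref/alt"}),
         FamilyMember("I:2", False, {V1.key: "ref/alt"})],
        [V1], phenotype="LCD",
    )
    assert segregation_check(fam, V1, "AD") == "inconsistent"


def test_segregation_sporadic_uninformative():
    fam = _family([FamilyMember("II:1", True, {V1.key: "ref/alt"})], [V1])
    assert segregation_check(fam, V1, "AD") == "uninformative"


def test_segregation_unaffected_biallelic_inconsistent_ar():
    fam = _family(
        [FamilyMember("II:1", True, {V2.key: "alt/alt"}),
         FamilyMember("II:2", False, {V2.key: "alt/alt"})],
        [V2],
    )
    assert segregation_check(fam, V2, "AR") == "inconsistent"


def test_segregation_missing_proband_genotype_errors():
    fam = _family([FamilyMember("II:1", True, {}), FamilyMember("I:1", False, {V1.key: "ref/ref"})], [V1])
    with pytest.raises(ValueError, match="proband"):
        segregation_check(fam, V1, "AD")


def test_pipeline_stages_idempotent(panel, policy):
    """Re-applying a filter to its own output changes nothing."""
    pop = {V1.key: PopulationFrequency(2, 280_458)}
    retained, _ = filter_common([V1, V2], pop)
    again, dropped = filter_common(retained, pop)
    assert again == retained and not dropped
    kept, _ = filter_quality([V1], {V1.key: 100})
    kept2, _ = filter_quality(kept, {V1.key: 100})
    assert kept2 == kept


def test_simulated_cohort_solved_split(panel, policy):
    """The simulated study cohort resolves 30 of 37 families, 21/6/2/1 by gene."""
    families, pop, profiles, evidence, truth = simulate_cohort(11, panel)
    reports, ledger = run_cohort(
        families, panel, pop, profiles, policy=policy, curator_evidence=evidence
    )
    solved = {r.family_id for r in reports if r.solved}
    expected = {fid for fid, t in truth.items() if t["solvable"]}
    assert solved == expected and len(solved) == 30
    assert solved_families_by_gene(reports) == {
        "TGFBI": 21, "CHST6": 6, "SLC4A11": 2, "ZEB1": 1,
    }
    # ledger accounting: every input candidate is either retained or ledgered
    for r in reports:
        assert len(r.ledger) + len(r.classified) == r.n_input_candidates


def test_family_with_only_common_variant_unsolved(panel, policy):
    common = build_variant("TGFBI", "c.999A>G", "p.(Lys333Arg)")
    fam = CohortFamilyRecord(
        family_id="FX",
        members=(FamilyMember("II:1", True, {common.key: "ref/alt"}),),
        phenotype="LCD", proband_id="II:1",
        candidate_variants=(common,), coverage={common.key: 100},
    )
    report = run_family_pipeline(
        fam, panel, {common.key: PopulationFrequency(5000, 250_000)}, {}, policy=policy
    )
    assert not report.solved
    assert report.ledger == [(common.key, "common", "common: af 0.02 >= 0.01")]
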