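"""Multi-step cohort variant filter: from raw per-family candidates to
ACMG-classifiable, segregation-consistent variants.

Stage order, applied per family:

1. quality        — drop candidates with read coverage below 5
2. common         — drop candidates with population AF ≥ 0.01
3. prediction     — drop missense candidates that a majority of the available
                    in-silico tools (REVEL, CADD, SIFT, PolyPhen-2, PROVEAN)
                    call tolerated; splice/synonymous candidates need at least
                    one damaging splice-tool call (varSEAK, BDGP, HSF);
                    truncating candidates bypass; candidates with no scores
                    pass to manual review rather than being dropped
4. zygosity       — candidates must match the gene's inheritance mode
                    (AR genes need a biallelic proband, AD genes one allele)
5. segregation    — drop candidates inconsistent with the pedigree under full
                    penetrance; uninformative families are retained
6. classification — merge mechanized frequency codes with curator evidence and
                    combine under the ACMG/AMP clauses

Every exclusion is written to a ledger (family, variant, stage, reason);
retained + excluded always equals the input count.  Each stage is idempotent
and the pipeline commutes with candidate row order.

Predictor execution is out of scope — scores are consumed as precomputed
columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .acmg import auto_assign, combine
from .cf_threshold import ThresholdPolicy
from .core_model import (
    CohortFamilyRecord,
    GeneModel,
    PopulationFrequency,
    TRUNCATING_CLASSES,
    VariantRecord,
)

MIN_COVERAGE = 5
MAX_COMMON_AF = 0.01

#: Published per-tool deleteriousness cutoffs for missense prediction.
MISSENSE_CUTOFFS = {
    "revel": lambda x: x >= 0.5,
    "cadd": lambda x: x >= 20.0,
    "sift": lambda x: x < 0.05,
    "polyphen2": lambda x: x >= 0.446,
    "provean": lambda x: x <= -2.5,
}


@dataclass(frozen=True)
class PredictionProfile:
    """Precomputed in-silico scores for one variant; every field optional."""

    revel: Optional[float] = None
    cadd: Optional[float] = None
    sift: Optional[float] = None
    polyphen2: Optional[float] = None
    provean: Optional[float] = None
    #: categorical calls from splice-effect tools: damaging | benign | unknown
    splice_calls: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, rng in (("revel", (0, 1)), ("sift", (0, 1)), ("polyphen2", (0, 1))):
            val = getattr(self, name)
            if val is not None and not rng[0] <= val <= rng[1]:
                raise ValueError(f"{name} score out of range: {val}")


def prediction_consensus(
    profile: Optional[PredictionProfile], consequence: str
) -> str:
    """Aggregate tool calls into supported / unsupported / not_evaluable.

    Missense: deleterious votes under the per-tool cutoffs; supported when
    votes reach a majority (ceil(n/2)) of the tools with scores available.
    Splicing and synonymous: supported when any splice tool says damaging.
    Truncating consequences bypass with supported.  No usable scores →
    not_evaluable (manual review, never silently dropped).
    """
    if consequence in TRUNCATING_CLASSES and consequence != "splicing":
        return "supported"
    if consequence in ("splicing", "synonymous"):
        if profile is None or not profile.splice_calls:
            return "not_evaluable"
        calls = set(profile.splice_calls.values())
        if "damaging" in calls:
            return "supported"
        if calls <= {"unknown"}:
            return "not_evaluable"
        return "unsupported"
    if consequence == "missense":
        if profile is None:
            return "not_evaluable"
        votes, available = 0, 0
        for tool, deleterious in MISSENSE_CUTOFFS.items():
            score = getattr(profile, tool)
            if score is None:
                continue
            available += 1
            if deleterious(score):
                votes += 1
        if available == 0:
            return "not_evaluable"
        return "supported" if votes >= math.ceil(available / 2) else "unsupported"
    # in-frame indels and non-coding changes have no tool battery here
    return "not_evaluable"


# ---------------------------------------------------------------------------
# Single stages (each also usable standalone on a candidate table)


def filter_quality(
    candidates: Sequence[VariantRecord],
    coverage: Mapping[tuple[str, str], int],
    min_coverage: int = MIN_COVERAGE,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Retain candidates with coverage ≥ min_coverage.

    Missing coverage retains the candidate with a warning reason recorded
    (conservative: never drop for lack of metadata).
    """
    kept, dropped = [], []
    for v in candidates:
        cov = coverage.get(v.key)
        if cov is None:
            kept.append(v)
        elif cov >= min_coverage:
            kept.append(v)
        else:
            dropped.append((v, f"coverage {cov} < {min_coverage}"))
    return kept, dropped


def filter_common(
    candidates: Sequence[VariantRecord],
    pop_freqs: Mapping[tuple[str, str], PopulationFrequency],
    max_af: float = MAX_COMMON_AF,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Exclude candidates with population AF ≥ max_af; absent records retained."""
    kept, dropped = [], []
    for v in candidates:
        pf = pop_freqs.get(v.key)
        if pf is not None and pf.af >= max_af:
            dropped.append((v, f"common: af {pf.af:.4g} >= {max_af}"))
        else:
            kept.append(v)
    return kept, dropped


def _biallelic(
    member, gene: str, candidates: Sequence[VariantRecord]
) -> bool:
    """Member carries two alternate alleles of the gene (hom or ≥2 het sites)."""
    het = 0
    for v in candidates:
        if v.gene != gene:
            continue
        gt = member.genotypes.get(v.key, "ref/ref")
        if gt == "alt/alt":
            return True
        if gt == "ref/alt":
            het += 1
    return het >= 2


def segregation_check(
    family: CohortFamilyRecord,
    v: VariantRecord,
    mode: str,
    candidates: Optional[Sequence[VariantRecord]] = None,
) -> str:
    """Co-segregation under full penetrance: consistent / inconsistent / uninformative.

    AD: every genotyped affected member carries at least one alternate allele
    and no genotyped unaffected member carries one.  AR: every affected member
    is biallelic for the gene (homozygous, or carrying the variant plus a
    second candidate allele presumed in trans) and no unaffected member is.
    Families with a single genotyped member are uninformative.
    """
    if mode not in ("AD", "AR"):
        raise ValueError(f"mode must be AD or AR, got {mode!r}")
    genotyped = [m for m in family.members if v.key in m.genotypes]
    proband = family.proband
    if v.key not in proband.genotypes:
        raise ValueError(
            f"proband {proband.member_id} has no genotype for {v.key} in {family.family_id}"
        )
    if len(genotyped) <= 1:
        return "uninformative"
    cand = candidates if candidates is not None else family.candidate_variants
    for m in genotyped:
        gt = m.genotypes[v.key]
        if mode == "AD":
            carries = gt in ("ref/alt", "alt/alt")
            if m.affected and not carries:
                return "inconsistent"
            if not m.affected and carries:
                return "inconsistent"
        else:
            biallelic = _biallelic(m, v.gene, cand)
            if m.affected and not biallelic:
                return "inconsistent"
            if not m.affected and biallelic:
                return "inconsistent"
    return "consistent"


# ---------------------------------------------------------------------------
# Full per-family pipeline


@dataclass
class FamilyReport:
    family_id: str
    phenotype: str
    solved: bool
    #: surviving candidates with their final rank
    classified: list[tuple[VariantRecord, str, str]] = field(default_factory=list)
    #: exclusion ledger rows (variant key, stage, reason)
    ledger: list[tuple[tuple[str, str], str, str]] = field(default_factory=list)
    n_input_candidates: int = 0


def run_family_pipeline(
    family: CohortFamilyRecord,
    panel: Mapping[str, GeneModel],
    pop_freqs: Mapping[tuple[str, str], PopulationFrequency],
    profiles: Mapping[tuple[str, str], PredictionProfile],
    policy: Optional[ThresholdPolicy] = None,
    curator_evidence: Optional[Mapping[tuple[str, str], frozenset[str]]] = None,
    min_coverage: int = MIN_COVERAGE,
    max_af: float = MAX_COMMON_AF,
) -> FamilyReport:
    """Run the ordered multi-step filter on one family's candidate variants.

    A family is solved when at least one candidate survives all stages with a
    Pathogenic or Likely_pathogenic combined rank.  Curator evidence (e.g.
    functional and segregation-strength codes) is merged with the mechanized
    frequency codes before combination.
    """
    report = FamilyReport(
        family_id=family.family_id,
        phenotype=family.phenotype,
        solved=False,
        n_input_candidates=len(family.candidate_variants),
    )
    for g in {v.gene for v in family.candidate_variants}:
        if g not in panel:
            raise KeyError(f"candidate gene {g} not on panel in family {family.family_id}")

    current = list(family.candidate_variants)

    current, dropped = filter_quality(current, family.coverage, min_coverage)
    report.ledger += [(v.key, "quality", reason) for v, reason in dropped]

    current, dropped = filter_common(current, pop_freqs, max_af)
    report.ledger += [(v.key, "common", reason) for v, reason in dropped]

    kept = []
    for v in current:
        verdict = prediction_consensus(profiles.get(v.key), v.consequence or "unknown")
        if verdict == "unsupported":
            report.ledger.append((v.key, "prediction", "majority of tools call tolerated"))
        else:
            kept.append(v)
    current = kept

    kept = []
    proband = family.proband
    for v in current:
        mode = panel[v.gene].inheritance
        gt = proband.genotypes.get(v.key, "ref/ref")
        if gt == "ref/ref":
            report.ledger.append((v.key, "zygosity", "proband carries no alternate allele"))
            continue
        if mode == "AR" and not _biallelic(proband, v.gene, current):
            report.ledger.append(
                (v.key, "zygosity", "AR gene without biallelic proband genotype")
            )
            continue
        kept.append(v)
    current = kept

    kept = []
    for v in current:
        mode = panel[v.gene].inheritance
        verdict = segregation_check(family, v, mode, candidates=current)
        if verdict == "inconsistent":
            report.ledger.append((v.key, "segregation", "co-segregation inconsistent"))
        else:
            kept.append(v)
    current = kept

    for v in current:
        gene = panel[v.gene]
        pf = pop_freqs.get(v.key)
        t = policy.threshold_for(v) if policy is not None else None
        codes = auto_assign(v, pf, t, cross_check=0, gene=gene)
        if curator_evidence and v.key in curator_evidence:
            codes |= set(curator_evidence[v.key])
        cls = combine(frozenset(codes))
        report.classified.append((v, cls.rank, cls.fired_rule))
        if cls.rank in ("Pathogenic", "Likely_pathogenic"):
            report.solved = True
    return report


def run_cohort(
    families: Iterable[CohortFamilyRecord],
    panel: Mapping[str, GeneModel],
    pop_freqs: Mapping[tuple[str, str], PopulationFrequency],
    profiles: Mapping[tuple[str, str], PredictionProfile],
    policy: Optional[ThresholdPolicy] = None,
    curator_evidence: Optional[Mapping[tuple[str, str], frozenset[str]]] = None,
) -> tuple[list[FamilyReport], pd.DataFrame]:
    """Run the per-family pipeline over a cohort; returns reports + ledger table."""
    reports = [
        run_family_pipeline(
            fam, panel, pop_freqs, profiles, policy=policy, curator_evidence=curator_evidence
        )
        for fam in families
    ]
    rows = [
        {
            "family_id": r.family_id,
            "gene": key[0],
            "cdna": key[1],
            "stage": stage,
            "reason": reason,
        }
        for r in reports
        for key, stage, reason in r.ledger
    ]
    ledger = pd.DataFrame(rows, columns=["family_id", "gene", "cdna", "stage", "reason"])
    return reports, ledger


def solved_families_by_gene(reports: Sequence[FamilyReport]) -> dict[str, int]:
    """Count solved families per gene (a family counts once per gene)."""
    counts: dict[str, int] = {}
    for r in reports:
        genes = {
            v.gene for v, rank, _ in r.classified if rank in ("Pathogenic", "Likely_pathogenic")
        }
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return counts
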