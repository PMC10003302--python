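"""Prevalence-partitioned carrier-frequency (CF) budgets and variant flagging.

The core statistic of the pipeline.  For a dominant disease gene g with share
s_g of disease-attributed families, the aggregate carrier frequency of all
pathogenic alleles of g cannot exceed

    T_g = s_g × P_mono,

where P_mono is the prevalence of the monogenic form of the disease (total
prevalence × monogenic fraction).  Any single reported variant whose
population carrier frequency 2·AF·(1−AF) exceeds T_g is inconsistent with the
gene's total contribution and is therefore an implausible monogenic cause.
For a gene with mutational hotspots, the budget can be split: variants outside
the hotspot codons are tested against the non-hotspot fraction of the gene's
budget.

The comparison convention is carrier frequency (not raw allele frequency)
against the CF budget; with thresholds this low the two differ by a factor of
almost exactly 2, and the convention decides borderline calls.

Thresholds are derived for autosomal-dominant genes only.  For recessive
genes a single-allele population frequency does not bound disease prevalence
the same way (Hardy–Weinberg biallelic calculus would be needed), so AR genes
pass through explicitly unflagged.

This module is fully deterministic; all stochastic behavior lives in
:mod:`cdcurate.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core_model import (
    GeneModel,
    PopulationFrequency,
    VariantRecord,
    is_hotspot,
)

PER_100K = 1e-5


@dataclass(frozen=True)
class PrevalenceModel:
    """Disease prevalence split into monogenic and non-monogenic fractions.

    Defaults: total prevalence 897 per million with half of cases monogenic,
    i.e. a monogenic prevalence of about 450 per million.
    """

    total_prevalence: float = 897e-6
    monogenic_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.total_prevalence < 1.0:
            raise ValueError("total_prevalence must be in (0,1)")
        if not 0.0 < self.monogenic_fraction <= 1.0:
            raise ValueError("monogenic_fraction must be in (0,1]")

    @property
    def monogenic_prevalence(self) -> float:
        return self.total_prevalence * self.monogenic_fraction


def round_threshold_per_100k(raw_cf: float) -> float:
    """Reporting rule for printed thresholds, in units of per-100,000.

    Values ≥ 1/100,000 round half-up to the nearest integer; smaller values
    round half-up to the nearest 0.1 with a floor of 0.1.  The raw value is
    always retained alongside; the rounded figure is presentation only.
    """
    if raw_cf < 0:
        raise ValueError("raw_cf must be non-negative")
    if raw_cf == 0:
        return 0.0
    per_100k = Decimal(str(raw_cf)) / Decimal(str(PER_100K))
    if per_100k >= 1:
        return float(per_100k.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    rounded = float(per_100k.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return max(rounded, 0.1)


@dataclass(frozen=True)
class ThresholdResult:
    """Per-gene (or per-gene-subset) CF budget.

    ``applicable`` is False for AR genes, for which no dominant-model
    threshold is defined; such a result never carries a number.
    ``printed_budget_per_100k`` is an externally configured published budget
    (for example a hotspot-split budget quoted as a round figure); when set it
    is the operative budget for flagging, and the computed raw value is kept
    beside it.
    """

    gene: str
    subset: str = "all"  # "all" | "non_hotspot"
    raw_cf: Optional[float] = None
    basis_share: Optional[float] = None
    applicable: bool = True
    printed_budget_per_100k: Optional[float] = None

    @property
    def reported_per_100k(self) -> Optional[float]:
        if not self.applicable or self.raw_cf is None:
            return None
        return round_threshold_per_100k(self.raw_cf)

    @property
    def budget(self) -> Optional[float]:
        """Operative CF budget as a fraction; None when not applicable."""
        if not self.applicable:
            return None
        if self.printed_budget_per_100k is not None:
            return self.printed_budget_per_100k * PER_100K
        return self.raw_cf


def gene_threshold(g: GeneModel, prev: PrevalenceModel) -> ThresholdResult:
    """Whole-gene CF budget T_g = share × monogenic prevalence.

    AR genes yield an explicit not-applicable result rather than a number.
    """
    if g.inheritance != "AD":
        return ThresholdResult(gene=g.symbol, subset="all", applicable=False)
    return ThresholdResult(
        gene=g.symbol,
        subset="all",
        raw_cf=g.share * prev.monogenic_prevalence,
        basis_share=g.share,
    )


def subset_threshold(
    g: GeneModel,
    prev: PrevalenceModel,
    subset_fraction: float,
    printed_budget_per_100k: Optional[float] = None,
    subset: str = "non_hotspot",
) -> ThresholdResult:
    """Budget for a subset of a gene's alleles (e.g. non-hotspot variants).

    ``subset_fraction`` is the fraction of the gene's families attributed to
    the subset; the raw budget is share × subset_fraction × monogenic
    prevalence.  A published round-figure budget can be configured and is then
    used for flagging, with the computed value stored alongside.
    """
    if not 0.0 <= subset_fraction <= 1.0:
        raise ValueError("subset_fraction must be in [0,1]")
    if g.inheritance != "AD":
        return ThresholdResult(gene=g.symbol, subset=subset, applicable=False)
    return ThresholdResult(
        gene=g.symbol,
        subset=subset,
        raw_cf=g.share * subset_fraction * prev.monogenic_prevalence,
        basis_share=g.share * subset_fraction,
        printed_budget_per_100k=printed_budget_per_100k,
    )


def carrier_frequency(pf: PopulationFrequency) -> float:
    """Population carrier frequency 2·AF·(1−AF) from an AC/AN pair."""
    return pf.carrier_freq


@dataclass
class ThresholdPolicy:
    """Maps each variant to the budget it must be tested against.

    Holds the whole-gene threshold per AD gene plus optional subset budgets
    for genes with hotspot splits; hotspot variants of such genes are tested
    against the whole-gene budget, all other variants against the subset
    budget.
    """

    panel: Mapping[str, GeneModel]
    prevalence: PrevalenceModel = field(default_factory=PrevalenceModel)
    #: per-gene non-hotspot subset: gene -> (subset_fraction, printed budget per 100k or None)
    subset_budgets: Mapping[str, tuple[float, Optional[float]]] = field(default_factory=dict)

    def gene_thresholds(self) -> dict[str, ThresholdResult]:
        return {g: gene_threshold(m, self.prevalence) for g, m in self.panel.items()}

    def threshold_for(self, v: VariantRecord) -> ThresholdResult:
        g = self.panel[v.gene]
        if g.symbol in self.subset_budgets and g.hotspot_codons and not is_hotspot(v, g):
            frac, printed = self.subset_budgets[g.symbol]
            return subset_threshold(g, self.prevalence, frac, printed)
        return gene_threshold(g, self.prevalence)


def frequency_check(
    v: VariantRecord,
    pf: Optional[PopulationFrequency],
    t: ThresholdResult,
) -> Optional[bool]:
    """True when the variant's population CF exceeds its budget.

    Returns None ("not evaluable" — never a pass) when no population record
    exists, and None for non-applicable (AR) thresholds.
    """
    if not t.applicable:
        return None
    if pf is None:
        return None
    return carrier_frequency(pf) > t.budget


def phenotype_cross_check(
    variant_key: tuple[str, str],
    cohort: Iterable,
    cd_phenotypes: Optional[frozenset[str]] = None,
) -> int:
    """Count distinct in-house carrier families whose phenotype is not a CD.

    ``cohort`` yields CohortFamilyRecord objects; a family counts when any
    member carries at least one alternate allele of the variant and the
    family's phenotype label is outside the CD subtype set.
    """
    from .core_model import CD_PHENOTYPES

    cd = cd_phenotypes if cd_phenotypes is not None else CD_PHENOTYPES
    n = 0
    for fam in cohort:
        if fam.phenotype in cd:
            continue
        carries = any(
            m.genotypes.get(variant_key, "ref/ref") in ("ref/alt", "alt/alt")
            for m in fam.members
        )
        if carries:
            n += 1
    return n


@dataclass
class FlagDecision:
    """Outcome of the frequency (and phenotype) checks for one variant."""

    variant: VariantRecord
    population: Optional[PopulationFrequency]
    threshold: ThresholdResult
    frequency_fail: Optional[bool]
    inhouse_noncd_families: int = 0
    n_families_attributed: int = 0

    @property
    def carrier_freq(self) -> Optional[float]:
        return None if self.population is None else self.population.carrier_freq

    @property
    def phenotype_fail(self) -> bool:
        return self.inhouse_noncd_families > 0

    @property
    def flagged(self) -> bool:
        # phenotype evidence corroborates but never flags on its own
        return bool(self.frequency_fail)


def flag_variants(
    variants: Sequence[VariantRecord],
    pop_freqs: Mapping[tuple[str, str], PopulationFrequency],
    policy: ThresholdPolicy,
    cohort: Optional[Sequence] = None,
    family_counts: Optional[Mapping[tuple[str, str], int]] = None,
) -> tuple[list[FlagDecision], dict]:
    """Run the frequency screen over a variant table.

    Returns per-variant decisions plus a summary with the number of flagged
    variants, the literature families they account for, and the keys that
    could not be joined to a population record (listed, never dropped).
    """
    decisions: list[FlagDecision] = []
    unjoined: list[tuple[str, str]] = []
    cohort_list = list(cohort) if cohort is not None else []
    for v in variants:
        if v.gene not in policy.panel:
            raise KeyError(f"variant gene {v.gene} not on the panel")
        t = policy.threshold_for(v)
        pf = pop_freqs.get(v.key)
        fail = frequency_check(v, pf, t)
        if pf is None and t.applicable:
            unjoined.append(v.key)
        cross = 0
        if cohort_list and fail:
            cross = phenotype_cross_check(v.key, cohort_list)
        decisions.append(
            FlagDecision(
                variant=v,
                population=pf,
                threshold=t,
                frequency_fail=fail,
                inhouse_noncd_families=cross,
                n_families_attributed=(
                    family_counts.get(v.key, 0) if family_counts else 0
                ),
            )
        )
    flagged = [d for d in decisions if d.flagged]
    summary = {
        "n_variants": len(decisions),
        "n_flagged": len(flagged),
        "n_families_attributed": sum(d.n_families_attributed for d in flagged),
        "unjoined": unjoined,
    }
    return decisions, summary


def decisions_to_frame(decisions: Sequence[FlagDecision]) -> pd.DataFrame:
    """Tidy flags table (one row per variant) for report writing."""
    rows = []
    for d in decisions:
        rows.append(
            {
                "gene": d.variant.gene,
                "cdna": d.variant.cdna,
                "protein": d.variant.protein,
                "af": None if d.population is None else d.population.af,
                "carrier_freq": d.carrier_freq,
                "threshold_subset": d.threshold.subset,
                "threshold_budget": d.threshold.budget,
                "frequency_fail": d.frequency_fail,
                "inhouse_noncd_families": d.inhouse_noncd_families,
                "phenotype_fail": d.phenotype_fail,
                "flagged": d.flagged,
                "n_families_attributed": d.n_families_attributed,
            }
        )
    return pd.DataFrame(rows)
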