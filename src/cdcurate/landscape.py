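"""Gene-contribution landscape summaries.

Aggregates literature family reports (and optionally cohort-solved families)
into the per-gene contribution table, ethnicity and consequence-class
distributions, and phenotype × variant contingencies.  Families — not probands
or alleles — are the counting unit throughout: a family contributes once per
gene even when it carries two variants of that gene (compound heterozygotes
count once).

Two modes exist: ``raw`` (literature reports as published) and ``curated``
(families attributed to flagged, frequency-implausible variants removed and
cohort-solved families added).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core_model import (
    CONSEQUENCE_CLASSES,
    ETHNICITY_GROUPS,
    GeneModel,
    LiteratureFamilyRecord,
    VariantRecord,
    is_hotspot,
)

LITERATURE_COLUMNS = [
    "gene", "cdna", "protein", "consequence", "n_families", "ethnicity",
    "phenotype", "zygosity", "ethnicity_provenance",
]


def pct(numerator: float, denominator: float) -> float:
    """Percentage with half-up rounding to two decimals."""
    if denominator == 0:
        raise ZeroDivisionError("undefined percentage: zero denominator")
    value = Decimal(str(100.0 * numerator / denominator))
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def records_to_frame(records: Iterable[LiteratureFamilyRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene": r.variant.gene,
            "cdna": r.variant.cdna,
            "protein": r.variant.protein,
            "consequence": r.variant.consequence,
            "n_families": r.n_families,
            "ethnicity": r.ethnicity,
            "phenotype": r.phenotype,
            "zygosity": r.zygosity,
            "ethnicity_provenance": r.ethnicity_provenance,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=LITERATURE_COLUMNS)


@dataclass
class LandscapeSummary:
    """Per-gene landscape facets plus the totals they were computed from."""

    mode: str                       # "raw" | "combined" | "curated"
    gene_summary: pd.DataFrame      # gene, n_families, n_variants, share, percent
    ethnicity: pd.DataFrame         # gene × ethnicity family counts
    consequence: pd.DataFrame       # gene × consequence-class family counts
    phenotype_variant: pd.DataFrame # phenotype, gene, cdna, n_families
    total_families: int
    total_variants: int

    def share_percent(self, gene: str) -> float:
        row = self.gene_summary.loc[self.gene_summary["gene"] == gene]
        if row.empty:
            raise KeyError(f"gene {gene} absent from summary")
        return float(row["percent"].iloc[0])


def _coerce(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = records_to_frame(records)
    df["n_families"] = df["n_families"].astype(int)
    return df


def aggregate_contributions(
    records,
    cohort: Optional[pd.DataFrame] = None,
    panel: Optional[dict[str, GeneModel]] = None,
    mode: Optional[str] = None,
) -> LandscapeSummary:
    """Aggregate family reports into the landscape summary.

    Parameters
    ----------
    records
        Literature table (DataFrame in the dialect of ``LITERATURE_COLUMNS``
        or an iterable of LiteratureFamilyRecord).
    cohort
        Optional cohort-solved families, columns family_id/gene/cdna; each
        family counts once per gene, and cohort variants absent from the
        literature add to the variant tally (combined mode).
    panel
        When given, rows whose gene is not on the panel are rejected into
        the summary's side report instead of silently aggregated.
    """
    df = _coerce(records)
    if panel is not None:
        unknown = df.loc[~df["gene"].isin(panel)]
        if not unknown.empty:
            raise ValueError(
                f"records reference genes outside the panel: {sorted(unknown['gene'].unique())}"
            )

    per_gene_fam = df.groupby("gene")["n_families"].sum() if not df.empty else pd.Series(dtype=int)
    per_gene_var = (
        df.groupby("gene")["cdna"].nunique() if not df.empty else pd.Series(dtype=int)
    )

    cohort_fam = pd.Series(dtype=int)
    cohort_new_var = pd.Series(dtype=int)
    if cohort is not None and not cohort.empty:
        cohort_fam = cohort.groupby("gene")["family_id"].nunique()
        lit_keys = set(zip(df["gene"], df["cdna"])) if not df.empty else set()
        novel = cohort.loc[
            ~cohort.apply(lambda r: (r["gene"], r["cdna"]) in lit_keys, axis=1)
        ]
        cohort_new_var = novel.groupby("gene")["cdna"].nunique()

    fam = per_gene_fam.add(cohort_fam, fill_value=0).astype(int)
    var = per_gene_var.add(cohort_new_var, fill_value=0).astype(int)
    total_fam = int(fam.sum())
    total_var = int(var.sum())

    gene_summary = pd.DataFrame(
        {
            "gene": fam.index,
            "n_families": fam.values,
            "n_variants": var.reindex(fam.index).fillna(0).astype(int).values,
        }
    )
    if total_fam > 0:
        gene_summary["share"] = gene_summary["n_families"] / total_fam
        gene_summary["percent"] = [
            pct(n, total_fam) for n in gene_summary["n_families"]
        ]
    else:
        gene_summary["share"] = []
        gene_summary["percent"] = []
    gene_summary = gene_summary.sort_values(
        "n_families", ascending=False, kind="stable"
    ).reset_index(drop=True)

    if df.empty:
        ethnicity = pd.DataFrame(columns=list(ETHNICITY_GROUPS))
        consequence = pd.DataFrame(columns=list(CONSEQUENCE_CLASSES))
        phen = pd.DataFrame(columns=["phenotype", "gene", "cdna", "n_families"])
    else:
        ethnicity = (
            df.pivot_table(
                index="gene", columns="ethnicity", values="n_families",
                aggfunc="sum", fill_value=0,
            )
            .reindex(columns=list(ETHNICITY_GROUPS), fill_value=0)
        )
        consequence = df.pivot_table(
            index="gene", columns="consequence", values="n_families",
            aggfunc="sum", fill_value=0,
        )
        phen = (
            df.groupby(["phenotype", "gene", "cdna"], as_index=False)["n_families"]
            .sum()
        )

    resolved_mode = mode or ("combined" if cohort is not None else "raw")
    return LandscapeSummary(
        mode=resolved_mode,
        gene_summary=gene_summary,
        ethnicity=ethnicity,
        consequence=consequence,
        phenotype_variant=phen,
        total_families=total_fam,
        total_variants=total_var,
    )


def curate(
    records,
    flagged: Sequence[tuple[str, str]],
    cohort: Optional[pd.DataFrame] = None,
    panel: Optional[dict[str, GeneModel]] = None,
) -> LandscapeSummary:
    """Curated landscape: drop families attributed to flagged variants, add cohort.

    ``flagged`` is a sequence of (gene, cdna) keys of frequency-implausible
    variants; every key must resolve into the literature table, otherwise the
    missing keys are reported in the raised error.  The curated totals obey
    the conservation law: curated families = raw − flagged-attributed +
    cohort-solved.
    """
    df = _coerce(records)
    keys = set(zip(df["gene"], df["cdna"])) if not df.empty else set()
    missing = [k for k in flagged if k not in keys]
    if missing:
        raise ValueError(f"flagged variants absent from the literature table: {missing}")
    flagged_set = set(flagged)
    if flagged_set:
        mask = df.apply(lambda r: (r["gene"], r["cdna"]) in flagged_set, axis=1)
        df = df.loc[~mask]
    return aggregate_contributions(df, cohort=cohort, panel=panel, mode="curated")


def phenotype_allele_fraction(records, phenotype: str, gene: str, cdna: str) -> float:
    """Percent of families of a phenotype carrying one specific variant.

    Undefined (ZeroDivisionError) when no family of that phenotype exists.
    """
    df = _coerce(records)
    stratum = df.loc[df["phenotype"] == phenotype]
    denom = int(stratum["n_families"].sum())
    if denom == 0:
        raise ZeroDivisionError(f"no families with phenotype {phenotype!r}")
    num = int(
        stratum.loc[(stratum["gene"] == gene) & (stratum["cdna"] == cdna), "n_families"].sum()
    )
    return pct(num, denom)


def hotspot_fraction(records, gene_model: GeneModel, variants: dict[tuple[str, str], VariantRecord]) -> float:
    """Percent of a gene's families whose variant hits a hotspot codon.

    ``variants`` maps (gene, cdna) keys to parsed VariantRecord objects so
    codon membership can be evaluated.  A gene with an empty hotspot set
    yields 0.  A gene with no families is undefined.
    """
    df = _coerce(records)
    sub = df.loc[df["gene"] == gene_model.symbol]
    denom = int(sub["n_families"].sum())
    if denom == 0:
        raise ZeroDivisionError(f"no families attributed to {gene_model.symbol}")
    if not gene_model.hotspot_codons:
        return 0.0
    num = 0
    for _, row in sub.iterrows():
        v = variants.get((row["gene"], row["cdna"]))
        if v is not None and is_hotspot(v, gene_model):
            num += int(row["n_families"])
    return pct(num, denom)
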