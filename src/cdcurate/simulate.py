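"""Synthetic-data generation for every pipeline stage.

Emulates the structure of the study's data: per-gene literature family tables
with configured gene shares, gnomAD-like allele counts binomially sampled at a
quarter-million alleles, planted high-frequency "misinterpreted" variants, and
small autosomal-dominant/recessive pedigrees with noise candidates the cohort
filter must remove.

One global seed feeds a named-stream splitter, so regenerating one fixture
never shifts another.  AN is treated as constant per variant (no per-site
call-rate variation) — sufficient for threshold testing.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .acmg import parse_evidence
from .cf_threshold import ThresholdPolicy
from .cohort_filter import PredictionProfile
from .core_model import (
    CohortFamilyRecord,
    FamilyMember,
    GeneModel,
    PopulationFrequency,
    VariantRecord,
    build_variant,
)
from .landscape import LITERATURE_COLUMNS

#: Default per-gene literature family counts (the study landscape); shares
#: are these counts over their total of 2933.
DEFAULT_GENE_FAMILY_COUNTS = {
    "TGFBI": 1850, "CHST6": 477, "SLC4A11": 199, "TACSTD2": 128, "ZEB1": 76,
    "UBIAD1": 74, "KRT12": 31, "COL8A2": 28, "OVOL2": 23, "PIKFYVE": 12,
    "COL17A1": 12, "GRHL2": 6, "AGBL1": 8, "DCN": 5, "KRT3": 4,
}

DEFAULT_AN = 250_000

#: Ethnicity mix used when simulating literature rows (Asian, Caucasian, African).
DEFAULT_ETHNICITY_P = (0.55, 0.42, 0.03)

#: Consequence mix for simulated literature variants.
DEFAULT_CONSEQUENCE_P = {
    "missense": 0.62, "nonsense": 0.10, "frameshift": 0.12,
    "splicing": 0.10, "inframe_indel": 0.04, "synonymous": 0.02,
}


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Named random stream derived from the global seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic generators."""

    seed: int = 0
    n_families: int = 2933
    gene_shares: Mapping[str, float] = field(
        default_factory=lambda: {
            g: n / sum(DEFAULT_GENE_FAMILY_COUNTS.values())
            for g, n in DEFAULT_GENE_FAMILY_COUNTS.items()
        }
    )
    n_variants_per_gene: int = 20
    an_population: int = DEFAULT_AN
    #: planted frequency-implausible variants: (gene, true CF as multiple of budget)
    planted_benign: Sequence[tuple[str, float]] = ()

    def __post_init__(self) -> None:
        if sum(self.gene_shares.values()) > 1.0 + 1e-9:
            raise ValueError("gene shares must sum to at most 1")


# ---------------------------------------------------------------------------
# Literature table


def _phenotype_for(gene: str) -> str:
    defaults = {
        "TGFBI": "LCD", "CHST6": "MCD", "SLC4A11": "CHED", "TACSTD2": "GDLD",
        "ZEB1": "PPCD", "UBIAD1": "SCD", "KRT12": "MECD", "COL8A2": "FECD",
        "OVOL2": "PPCD", "PIKFYVE": "FCD", "COL17A1": "ERED", "GRHL2": "PPCD",
        "AGBL1": "FECD", "DCN": "CSCD", "KRT3": "MECD",
    }
    return defaults.get(gene, "other_CD")


def _synthetic_variant(gene: str, index: int, consequence: str) -> tuple[str, Optional[str]]:
    codon = 100 + index
    if consequence == "missense":
        return f"c.{3 * codon - 1}C>T", f"p.(Ala{codon}Val)"
    if consequence == "nonsense":
        return f"c.{3 * codon - 2}C>T", f"p.(Gln{codon}*)"
    if consequence == "frameshift":
        return f"c.{3 * codon}del", f"p.(Gly{codon}Valfs*10)"
    if consequence == "splicing":
        return f"c.{3 * codon}+1G>A", None
    if consequence == "inframe_indel":
        return f"c.{3 * codon - 2}_{3 * codon}del", f"p.(Ala{codon}del)"
    return f"c.{3 * codon}G>A", f"p.(Ala{codon}=)"


def simulate_literature_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Multinomial family allocation over genes, then over per-gene variants.

    Returns the literature table dialect.  Identical config (including seed)
    yields an identical table.
    """
    rng = rng_for(cfg.seed, "literature")
    genes = list(cfg.gene_shares)
    if cfg.n_families == 0 or not genes:
        return pd.DataFrame(columns=LITERATURE_COLUMNS)
    probs = np.array([cfg.gene_shares[g] for g in genes], dtype=float)
    probs = probs / probs.sum()
    fam_per_gene = rng.multinomial(cfg.n_families, probs)

    cons_names = list(DEFAULT_CONSEQUENCE_P)
    cons_p = np.array([DEFAULT_CONSEQUENCE_P[c] for c in cons_names])
    cons_p = cons_p / cons_p.sum()

    rows = []
    for gene, n_fam in zip(genes, fam_per_gene):
        if n_fam == 0:
            continue
        n_var = min(cfg.n_variants_per_gene, n_fam)
        var_alloc = rng.multinomial(n_fam - n_var, np.full(n_var, 1.0 / n_var)) + 1
        for i, n in enumerate(var_alloc):
            consequence = cons_names[rng.choice(len(cons_names), p=cons_p)]
            cdna, protein = _synthetic_variant(gene, i, consequence)
            eth_counts = rng.multinomial(n, DEFAULT_ETHNICITY_P)
            for eth, count in zip(("Asian", "Caucasian", "African"), eth_counts):
                if count == 0:
                    continue
                rows.append(
                    {
                        "gene": gene, "cdna": cdna, "protein": protein,
                        "consequence": consequence, "n_families": int(count),
                        "ethnicity": eth, "phenotype": _phenotype_for(gene),
                        "zygosity": "unknown", "ethnicity_provenance": "inferred",
                    }
                )
    return pd.DataFrame(rows, columns=LITERATURE_COLUMNS)


# ---------------------------------------------------------------------------
# Population counts


def simulate_population_counts(
    true_af: Mapping[tuple[str, str], float],
    an: int,
    seed: int,
) -> dict[tuple[str, str], PopulationFrequency]:
    """AC ~ Binomial(AN, true AF) per variant, under the named-stream seed."""
    rng = rng_for(seed, "population")
    out = {}
    for key in sorted(true_af):
        af = true_af[key]
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"true AF out of [0,1] for {key}: {af}")
        out[key] = PopulationFrequency(ac=int(rng.binomial(an, af)), an=an)
    return out


def simulate_misinterpretation_screen(
    seed: int,
    n_planted: int,
    n_background: int,
    policy: ThresholdPolicy,
    gene: str = "TGFBI",
    planted_multiple: float = 10.0,
    background_multiple: float = 0.1,
    an: int = DEFAULT_AN,
) -> tuple[list[VariantRecord], dict, set]:
    """Variant table with planted frequency-implausible alleles.

    Plants ``n_planted`` non-hotspot variants of ``gene`` whose true carrier
    frequency is ``planted_multiple`` times the operative budget, against
    ``n_background`` variants at ``background_multiple`` times the budget.
    Returns (variants, population frequencies, set of planted keys); the
    ground truth is sufficient for a confusion matrix.
    """
    variants: list[VariantRecord] = []
    true_af: dict[tuple[str, str], float] = {}
    planted: set[tuple[str, str]] = set()
    for i in range(n_planted + n_background):
        cdna, protein = _synthetic_variant(gene, 1000 + i, "missense")
        v = build_variant(gene, cdna, protein)
        variants.append(v)
        budget = policy.threshold_for(v).budget
        mult = planted_multiple if i < n_planted else background_multiple
        # invert cf = 2 af (1-af) for the target carrier frequency
        cf = budget * mult
        af = (1.0 - np.sqrt(max(0.0, 1.0 - 2.0 * cf))) / 2.0
        true_af[v.key] = af
        if i < n_planted:
            planted.add(v.key)
    freqs = simulate_population_counts(true_af, an, seed)
    return variants, freqs, planted


# ---------------------------------------------------------------------------
# Cohort pedigrees

_NOISE_COMMON = ("TGFBI", "c.999A>G", "p.(Lys333Arg)")       # af 0.02 in population
_NOISE_LOWCOV = ("CHST6", "c.1202C>T", "p.(Ala401Val)")      # coverage 4
_NOISE_UNSUPPORTED = ("TGFBI", "c.1300G>A", "p.(Ala434Thr)") # 1/5 tools deleterious
_NOISE_NONSEG = ("TGFBI", "c.1400C>T", "p.(Ala467Val)")      # carried by unaffected parent
_NOISE_VUS = ("TGFBI", "c.1499C>T", "p.(Thr500Ile)")         # survives to VUS


def simulate_cohort(
    seed: int,
    panel: Mapping[str, GeneModel],
    solved_families: Optional[pd.DataFrame] = None,
    cohort_variants: Optional[pd.DataFrame] = None,
    n_unsolved: int = 7,
) -> tuple[
    list[CohortFamilyRecord],
    dict[tuple[str, str], PopulationFrequency],
    dict[tuple[str, str], PredictionProfile],
    dict[tuple[str, str], frozenset],
    dict,
]:
    """Cohort with causal genotypes planted per inheritance mode, plus noise.

    ``solved_families`` (family_id, gene, allele1, allele2, phenotype) and
    ``cohort_variants`` (the causal-variant table with curator evidence) default
    to the packaged study reconstruction: 30 solved families split 21/6/2/1
    across TGFBI/CHST6/SLC4A11/ZEB1 and 7 families left unsolved.

    Every family carries noise candidates the filter must remove: a common
    variant (AF 0.02), a low-coverage call, a prediction-unsupported missense
    and a non-segregating missense; unsolved families additionally carry a
    rare candidate that survives to VUS.  Returns families, population
    frequencies, prediction profiles, curator evidence and a ground-truth
    sidecar mapping each family to its planted causal keys.
    """
    from . import reference

    rng = rng_for(seed, "cohort")
    fams_df = solved_families if solved_families is not None else reference.cohort_family_table()
    var_df = cohort_variants if cohort_variants is not None else reference.cohort_variant_table()

    causal: dict[tuple[str, str], VariantRecord] = {}
    evidence: dict[tuple[str, str], frozenset] = {}
    pop: dict[tuple[str, str], PopulationFrequency] = {}
    profiles: dict[tuple[str, str], PredictionProfile] = {}
    deleterious = PredictionProfile(
        revel=0.92, cadd=28.0, sift=0.001, polyphen2=0.99, provean=-6.2,
        splice_calls={"varSEAK": "damaging"},
    )
    for _, r in var_df.iterrows():
        v = build_variant(r["gene"], r["cdna"], r["protein"], position=r["position"])
        causal[v.key] = v
        evidence[v.key] = parse_evidence(r["evidence"])
        if r["gnomad_ac"] not in (".", None):
            pop[v.key] = PopulationFrequency(int(r["gnomad_ac"]), int(r["gnomad_an"]))
        else:
            pop[v.key] = PopulationFrequency(0, DEFAULT_AN)
        profiles[v.key] = deleterious

    noise_variants = {}
    for gene, cdna, protein in (
        _NOISE_COMMON, _NOISE_LOWCOV, _NOISE_UNSUPPORTED, _NOISE_NONSEG, _NOISE_VUS,
    ):
        noise_variants[(gene, cdna)] = build_variant(gene, cdna, protein)
    pop[_NOISE_COMMON[:2]] = PopulationFrequency(ac=5000, an=DEFAULT_AN)       # af 0.02
    pop[_NOISE_LOWCOV[:2]] = PopulationFrequency(ac=0, an=DEFAULT_AN)
    pop[_NOISE_UNSUPPORTED[:2]] = PopulationFrequency(ac=0, an=DEFAULT_AN)
    pop[_NOISE_NONSEG[:2]] = PopulationFrequency(ac=0, an=DEFAULT_AN)
    pop[_NOISE_VUS[:2]] = PopulationFrequency(ac=0, an=DEFAULT_AN)
    profiles[_NOISE_COMMON[:2]] = deleterious
    profiles[_NOISE_UNSUPPORTED[:2]] = PredictionProfile(
        revel=0.1, cadd=24.0, sift=0.6, polyphen2=0.1, provean=0.5,
    )
    profiles[_NOISE_NONSEG[:2]] = deleterious
    profiles[_NOISE_VUS[:2]] = deleterious
    # low-coverage candidate never reaches prediction, leave profile absent

    families: list[CohortFamilyRecord] = []
    truth: dict[str, dict] = {}

    def build_family(
        fid: str, phenotype: str, causal_keys: list[tuple[str, str]], mode: Optional[str]
    ) -> CohortFamilyRecord:
        noise_keys = [_NOISE_COMMON[:2], _NOISE_LOWCOV[:2], _NOISE_UNSUPPORTED[:2],
                      _NOISE_NONSEG[:2]]
        if not causal_keys:
            noise_keys.append(_NOISE_VUS[:2])
        candidates = [causal[k] for k in causal_keys] + [noise_variants[k] for k in noise_keys]
        coverage = {v.key: int(rng.integers(80, 160)) for v in candidates}
        coverage[_NOISE_LOWCOV[:2]] = 4

        proband_gt = {k: "ref/alt" for k in noise_keys}
        father_gt = {k: "ref/ref" for k in noise_keys}
        mother_gt = {k: "ref/ref" for k in noise_keys}
        mother_gt[_NOISE_NONSEG[:2]] = "ref/alt"  # unaffected carrier -> inconsistent
        father_affected = False
        if causal_keys:
            if mode == "AD":
                k = causal_keys[0]
                proband_gt[k] = "ref/alt"
                father_gt[k] = "ref/alt"
                father_affected = True
            else:  # AR
                if len(causal_keys) == 1:  # homozygous
                    k = causal_keys[0]
                    proband_gt[k] = "alt/alt"
                    father_gt[k] = "ref/alt"
                    mother_gt[k] = "ref/alt"
                else:  # compound het, one allele per parent (trans)
                    k1, k2 = causal_keys[0], causal_keys[1]
                    proband_gt[k1] = "ref/alt"
                    proband_gt[k2] = "ref/alt"
                    father_gt[k1] = "ref/alt"
                    mother_gt[k2] = "ref/alt"
        all_keys = [v.key for v in candidates]
        members = (
            FamilyMember(f"{fid}-II:1", True, {k: proband_gt.get(k, "ref/ref") for k in all_keys}),
            FamilyMember(f"{fid}-I:1", father_affected, {k: father_gt.get(k, "ref/ref") for k in all_keys}),
            FamilyMember(f"{fid}-I:2", False, {k: mother_gt.get(k, "ref/ref") for k in all_keys}),
        )
        return CohortFamilyRecord(
            family_id=fid, members=members, phenotype=phenotype,
            proband_id=f"{fid}-II:1", candidate_variants=tuple(candidates),
            coverage=coverage,
        )

    for _, r in fams_df.iterrows():
        gene = r["gene"]
        keys = [(gene, r["allele1"])]
        if r["allele2"] not in (".", None) and r["allele2"] != r["allele1"]:
            keys.append((gene, r["allele2"]))
        mode = panel[gene].inheritance
        fam = build_family(r["family_id"], r["phenotype"], keys, mode)
        families.append(fam)
        truth[r["family_id"]] = {"causal": keys, "solvable": True}

    for i in range(n_unsolved):
        fid = f"U{i + 1}"
        fam = build_family(fid, "CD", [], None)
        families.append(fam)
        truth[fid] = {"causal": [], "solvable": False}

    return families, pop, profiles, evidence, truth
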