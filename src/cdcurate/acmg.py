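"""ACMG/AMP evidence combination and frequency-derived code assignment.

Implements the published clause logic combining the 28 standardized evidence
codes (PVS1, PS1–PS4, PM1–PM6, PP1–PP5 on the pathogenic side; BA1, BS1–BS4,
BP1–BP7 on the benign side) into a five-tier rank: Pathogenic, Likely
pathogenic, VUS, Likely benign, Benign.  When both a pathogenic and a benign
clause fire, the evidence is contradictory and the variant is a VUS; both
fired clauses are reported.

Only the frequency-linked subset of codes is mechanized (``auto_assign``):
BA1 (stand-alone common), BS1 (carrier frequency above the gene's CF budget),
BS2 (observed in unaffected in-house families for a dominant, fully penetrant
gene), PM2 (absent/rare in population databases), and PVS1 (null variant in a
gene where loss of function is the disease mechanism).  All judgement codes
(functional, segregation, de novo, computational, phenotype-specificity) are
curator-supplied inputs and are never second-guessed.

No Bayesian point-scale refinement is applied — clause logic only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Set

import pandas as pd

from .core_model import GeneModel, PopulationFrequency, TRUNCATING_CLASSES, VariantRecord
from .cf_threshold import ThresholdResult, carrier_frequency

PATHOGENIC_CODES = frozenset(
    {"PVS1", "PS1", "PS2", "PS3", "PS4"}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
)
BENIGN_CODES = frozenset({"BA1", "BS1", "BS2", "BS3", "BS4"} | {f"BP{i}" for i in range(1, 8)})
ALL_CODES = PATHOGENIC_CODES | BENIGN_CODES

_STRENGTH = {
    "PVS": "very_strong",
    "PS": "strong",
    "PM": "moderate",
    "PP": "supporting",
    "BA": "stand_alone_benign",
    "BS": "strong_benign",
    "BP": "supporting_benign",
}

RANKS = ("Benign", "Likely_benign", "VUS", "Likely_pathogenic", "Pathogenic")


def strength_class(code: str) -> str:
    """Strength class of an evidence code (pure function of its prefix)."""
    if code not in ALL_CODES:
        raise ValueError(f"unknown ACMG/AMP code: {code!r}")
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if code.startswith(prefix):
            return _STRENGTH[prefix]
    raise AssertionError  # pragma: no cover


def parse_evidence(text: str) -> frozenset[str]:
    """Parse a "+"-joined evidence string (e.g. ``PVS1+PS4+PM4``)."""
    if text is None or text == "" or text == ".":
        return frozenset()
    codes = [tok.strip() for tok in str(text).split("+") if tok.strip()]
    for c in codes:
        if c not in ALL_CODES:
            raise ValueError(f"unknown ACMG/AMP code: {c!r}")
    if len(codes) != len(set(codes)):
        raise ValueError(f"duplicate codes in evidence string {text!r}")
    return frozenset(codes)


@dataclass(frozen=True)
class Classification:
    rank: str
    fired_rule: str


def _counts(ev: frozenset[str]) -> tuple[int, int, int, int, int, int, int]:
    pvs = sum(1 for c in ev if c == "PVS1")
    ps = sum(1 for c in ev if c.startswith("PS"))
    pm = sum(1 for c in ev if c.startswith("PM"))
    pp = sum(1 for c in ev if c.startswith("PP"))
    ba = sum(1 for c in ev if c == "BA1")
    bs = sum(1 for c in ev if c.startswith("BS"))
    bp = sum(1 for c in ev if c.startswith("BP"))
    return pvs, ps, pm, pp, ba, bs, bp


def _pathogenic_clause(pvs: int, ps: int, pm: int, pp: int) -> Optional[str]:
    if pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2):
        return "P_PVS1_combo"
    if ps >= 2:
        return "P_2PS"
    if ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)):
        return "P_PS_combo"
    return None


def _likely_pathogenic_clause(pvs: int, ps: int, pm: int, pp: int) -> Optional[str]:
    if pvs >= 1 and pm >= 1:
        return "LP_PVS1_PM"
    if ps >= 1 and pm >= 1:
        return "LP_PS_PM"
    if ps >= 1 and pp >= 2:
        return "LP_PS_2PP"
    if pm >= 3:
        return "LP_3PM"
    if pm >= 2 and pp >= 2:
        return "LP_2PM_2PP"
    if pm >= 1 and pp >= 4:
        return "LP_PM_4PP"
    return None


def _benign_clause(ba: int, bs: int, bp: int) -> Optional[str]:
    if ba >= 1:
        return "B_BA1"
    if bs >= 2:
        return "B_2BS"
    return None


def _likely_benign_clause(bs: int, bp: int) -> Optional[str]:
    if bs >= 1 and bp >= 1:
        return "LB_BS_BP"
    if bp >= 2:
        return "LB_2BP"
    return None


def combine(ev: Iterable[str]) -> Classification:
    """Combine an evidence set into its five-tier rank.

    Order-invariant and deterministic.  Contradictory evidence — any
    pathogenic clause and any benign clause satisfied simultaneously —
    yields VUS with both fired clauses named.
    """
    evidence = frozenset(ev) if not isinstance(ev, frozenset) else ev
    for c in evidence:
        if c not in ALL_CODES:
            raise ValueError(f"unknown ACMG/AMP code: {c!r}")
    pvs, ps, pm, pp, ba, bs, bp = _counts(evidence)

    p_rule = _pathogenic_clause(pvs, ps, pm, pp) or _likely_pathogenic_clause(pvs, ps, pm, pp)
    b_rule = _benign_clause(ba, bs, bp) or _likely_benign_clause(bs, bp)

    if p_rule and b_rule:
        return Classification("VUS", f"conflict:{p_rule}|{b_rule}")
    if p_rule:
        rank = "Pathogenic" if p_rule.startswith("P_") else "Likely_pathogenic"
        return Classification(rank, p_rule)
    if b_rule:
        rank = "Benign" if b_rule.startswith("B_") else "Likely_benign"
        return Classification(rank, b_rule)
    return Classification("VUS", "no_clause")


#: AF above which BA1 (stand-alone benign) applies.
BA1_AF = 0.05
#: AF below which PM2 (absent/rare) applies by default.
PM2_RARE_AF = 1e-5


def auto_assign(
    v: VariantRecord,
    pf: Optional[PopulationFrequency],
    t: Optional[ThresholdResult],
    cross_check: int = 0,
    gene: Optional[GeneModel] = None,
    rare_af: float = PM2_RARE_AF,
) -> set[str]:
    """Mechanized assignment of the frequency-linked evidence codes.

    BA1 when AF > 0.05; BS1 when the carrier frequency exceeds the gene's CF
    budget (suppressed under BA1, which subsumes it); BS2 when the variant was
    observed in families without the disease phenotype for a dominant gene
    treated as fully penetrant; PM2 when AF is zero/absent or below the rare
    threshold; PVS1 for truncating consequences in a gene whose stated disease
    mechanism is loss of function.  BA1 and PM2 cannot co-fire: BA1 wins.

    Curator-judgement codes are never assigned here.
    """
    codes: set[str] = set()
    af = pf.af if pf is not None else 0.0
    if pf is not None and af > BA1_AF:
        codes.add("BA1")
    elif t is not None and t.applicable and pf is not None and carrier_frequency(pf) > t.budget:
        codes.add("BS1")
    if cross_check > 0 and gene is not None and gene.inheritance == "AD":
        codes.add("BS2")
    if "BA1" not in codes and af < rare_af:
        codes.add("PM2")
    if (
        gene is not None
        and gene.lof_mechanism
        and v.consequence in TRUNCATING_CLASSES
    ):
        codes.add("PVS1")
    return codes


def classify_table(df: pd.DataFrame, evidence_column: str = "evidence") -> pd.DataFrame:
    """Classify every row of a table carrying a "+"-joined evidence column.

    Returns a copy with ``rank`` and ``fired_rule`` columns added.  An
    unparseable evidence string raises with the offending row index.
    """
    if evidence_column not in df.columns:
        raise ValueError(f"missing evidence column {evidence_column!r}")
    ranks, rules = [], []
    for idx, text in df[evidence_column].items():
        try:
            cls = combine(parse_evidence(text))
        except ValueError as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
        ranks.append(cls.rank)
        rules.append(cls.fired_rule)
    out = df.copy()
    out["rank"] = ranks
    out["fired_rule"] = rules
    return out
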