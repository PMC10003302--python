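"""Domain types and variant-notation handling shared by all pipeline stages.

The corneal dystrophy (CD) curation pipeline works on four kinds of objects:
gene models (transcript, inheritance mode, mutational hotspot codons, and the
gene's share of disease-attributed families), variant records described in
HGVS c./p. notation, population allele-frequency records (AC/AN pairs in the
gnomAD style), and family-level observations from either the literature or an
in-house cohort.

HGVS handling is deliberately light: the pipeline only needs the protein-level
components that drive consequence classification and hotspot membership
(reference residue, codon number or range, and the effect class), so a small
grammar covering substitutions, stop gains, frameshifts, in-frame
deletions/duplications/insertions/delins and synonymous changes is implemented
here rather than pulling in a full nomenclature stack.  Coordinates are
1-based and fully closed; strand handling is delegated to the c. description.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger("cdcurate")

# ---------------------------------------------------------------------------
# Constants

#: The seven mutually exclusive consequence classes used throughout.
CONSEQUENCE_CLASSES = (
    "missense",
    "nonsense",
    "frameshift",
    "splicing",
    "inframe_indel",
    "synonymous",
    "noncoding",
)

#: Reporting group: consequences that truncate or abolish the product.
TRUNCATING_CLASSES = frozenset({"splicing", "frameshift", "nonsense"})

#: CD subtype codes accepted as disease phenotypes.
CD_PHENOTYPES = frozenset(
    {
        "LCD", "GCD1", "GCD2", "MCD", "GDLD", "SCD", "MECD", "FCD", "PPCD",
        "FECD", "CSCD", "CHED", "ERED", "EBMD", "RBCD", "TBCD", "CD", "other_CD",
    }
)

ETHNICITY_GROUPS = ("Asian", "Caucasian", "African")

AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp "
    "Tyr Val Sec Ter".split()
)
AA1_TO_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "U": "Sec", "X": "Ter", "*": "Ter",
}
_AA3_SET = frozenset(AA3)


class HgvsParseError(ValueError):
    """Raised when an HGVS description cannot be parsed; names the bad token."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class GeneModel:
    """One CD gene of the panel.

    ``family_count`` is the number of disease-attributed families from the
    literature landscape; ``share`` is that count over the panel total and is
    the basis of the gene's carrier-frequency budget.  ``lof_mechanism``
    states whether loss of function is an established disease mechanism for
    the gene (drives automatic PVS1 assignment).
    """

    symbol: str
    transcript: str
    chromosome: str
    inheritance: str  # "AD" | "AR"
    pli: Optional[float] = None
    hotspot_codons: frozenset[int] = frozenset()
    family_count: int = 0
    share: float = 0.0
    lof_mechanism: bool = False

    def __post_init__(self) -> None:
        if self.inheritance not in ("AD", "AR"):
            raise ValueError(f"inheritance must be AD or AR, got {self.inheritance!r}")
        if not 0.0 <= self.share <= 1.0:
            raise ValueError(f"share out of [0,1]: {self.share}")
        if self.family_count < 0:
            raise ValueError("family_count must be non-negative")


@dataclass(frozen=True)
class ProteinChange:
    """Parsed protein-level HGVS description."""

    ref: str                       # reference residue, 3-letter
    codon: int                     # first affected codon
    effect: str                    # substitution | ter | frameshift | deletion |
                                   # duplication | insertion | delins | synonymous
    alt: Optional[str] = None      # alternate residue(s), 3-letter, if any
    ref_end: Optional[str] = None  # closing residue of a range
    codon_end: Optional[int] = None
    fs_ter: Optional[int] = None   # new stop offset for frameshifts (fs*N)

    @property
    def codons(self) -> range:
        """Affected codon numbers as an inclusive range."""
        end = self.codon_end if self.codon_end is not None else self.codon
        return range(self.codon, end + 1)

    def format(self) -> str:
        """Canonical ``p.(...)`` rendering of the change."""
        left = f"{self.ref}{self.codon}"
        if self.codon_end is not None:
            left += f"_{self.ref_end}{self.codon_end}"
        if self.effect == "substitution":
            body = f"{left}{self.alt}"
        elif self.effect == "synonymous":
            body = f"{left}="
        elif self.effect == "ter":
            body = f"{left}*"
        elif self.effect == "frameshift":
            body = f"{left}{self.alt or ''}fs"
            if self.fs_ter is not None:
                body += f"*{self.fs_ter}"
        elif self.effect in ("deletion", "duplication"):
            body = f"{left}{'del' if self.effect == 'deletion' else 'dup'}"
        elif self.effect == "insertion":
            body = f"{left}ins{self.alt}"
        elif self.effect == "delins":
            body = f"{left}delins{self.alt}"
        else:  # pragma: no cover - constructor restricts effects
            raise ValueError(f"unknown effect {self.effect}")
        return f"p.({body})"


@dataclass(frozen=True)
class VariantRecord:
    """One variant on a panel gene, keyed by (gene, cdna)."""

    gene: str
    cdna: str
    protein: Optional[str] = None
    consequence: Optional[str] = None
    position: Optional[str] = None
    reported_class: Optional[str] = None
    protein_change: Optional[ProteinChange] = field(default=None, compare=False)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene, self.cdna)

    @property
    def affected_codons(self) -> Optional[range]:
        if self.protein_change is None:
            return None
        return self.protein_change.codons


@dataclass(frozen=True)
class PopulationFrequency:
    """AC/AN pair from a population database or in-house cohort."""

    ac: int
    an: int
    source: str = "gnomad"  # "gnomad" | "inhouse"

    def __post_init__(self) -> None:
        if self.an <= 0:
            raise ValueError("an must be positive")
        if not 0 <= self.ac <= self.an:
            raise ValueError(f"ac must be in [0, an]; got {self.ac}/{self.an}")

    @property
    def af(self) -> float:
        return self.ac / self.an

    @property
    def carrier_freq(self) -> float:
        """Carrier frequency 2·AF·(1−AF) under Hardy–Weinberg."""
        return 2.0 * self.af * (1.0 - self.af)


@dataclass(frozen=True)
class LiteratureFamilyRecord:
    """Families reported with one variant, one ethnicity group, one phenotype."""

    variant: VariantRecord
    n_families: int
    ethnicity: str
    phenotype: str
    zygosity: str = "unknown"          # het | hom | compound_het | unknown
    ethnicity_provenance: str = "stated"  # stated | inferred

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.ethnicity not in ETHNICITY_GROUPS:
            raise ValueError(f"ethnicity must be one of {ETHNICITY_GROUPS}")


@dataclass(frozen=True)
class FamilyMember:
    member_id: str
    affected: bool
    #: genotype per candidate variant key (gene, cdna): ref/ref, ref/alt, alt/alt
    genotypes: Mapping[tuple[str, str], str] = field(default_factory=dict)


@dataclass(frozen=True)
class CohortFamilyRecord:
    """One cohort family: members with per-candidate genotypes and coverage."""

    family_id: str
    members: tuple[FamilyMember, ...]
    phenotype: str
    proband_id: str
    candidate_variants: tuple[VariantRecord, ...] = ()
    coverage: Mapping[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("family must have at least one member")
        if self.proband_id not in {m.member_id for m in self.members}:
            raise ValueError("proband must be a family member")

    @property
    def proband(self) -> FamilyMember:
        return next(m for m in self.members if m.member_id == self.proband_id)

    @property
    def is_cd(self) -> bool:
        return self.phenotype in CD_PHENOTYPES


# ---------------------------------------------------------------------------
# Protein HGVS parsing

_RES = r"(?:[A-Z][a-z]{2}|[A-Z*])"
_RE_LEFT = re.compile(rf"^({_RES})(\d+)(?:_({_RES})(\d+))?")
_RE_FS = re.compile(rf"^({_RES})?fs(?:\*(\d+)|Ter(\d+))?$")


def _to_aa3(token: str) -> str:
    if token in _AA3_SET:
        return token
    if token in AA1_TO_AA3:
        return AA1_TO_AA3[token]
    raise HgvsParseError(f"unknown amino-acid token {token!r}")


def _to_aa3_seq(token: str) -> str:
    """Convert a run of residues (3-letter concatenated or 1-letter) to 3-letter."""
    if len(token) % 3 == 0 and all(
        token[i : i + 3] in _AA3_SET for i in range(0, len(token), 3)
    ):
        return token
    return "".join(_to_aa3(ch) for ch in token)


def parse_protein_hgvs(p: str) -> ProteinChange:
    """Parse a protein-level HGVS string into its components.

    Accepts predicted (``p.(Arg124Cys)``) and asserted (``p.Arg124Cys``)
    forms, three-letter or one-letter residue codes (one-letter is converted),
    stop gains written ``*`` or ``Ter``, frameshifts with or without a new
    stop offset, and residue ranges for in-frame events.

    Raises
    ------
    HgvsParseError
        If the string is not a parseable protein description; the message
        names the offending token.
    """
    if not isinstance(p, str):
        raise HgvsParseError(f"not a string: {p!r}")
    s = p.strip()
    if not s.startswith("p."):
        raise HgvsParseError(f"protein HGVS must start with 'p.': {p!r}")
    body = s[2:]
    if body.startswith("(") :
        if not body.endswith(")"):
            raise HgvsParseError(f"unbalanced parenthesis in {p!r}")
        body = body[1:-1]
    if not body:
        raise HgvsParseError(f"empty protein description in {p!r}")

    m = _RE_LEFT.match(body)
    if not m:
        raise HgvsParseError(f"cannot read residue/position at {body!r}")
    ref = _to_aa3(m.group(1))
    codon = int(m.group(2))
    ref_end = _to_aa3(m.group(3)) if m.group(3) else None
    codon_end = int(m.group(4)) if m.group(4) else None
    if codon_end is not None and codon_end < codon:
        raise HgvsParseError(f"inverted codon range in {p!r}")
    rest = body[m.end():]

    common = dict(ref=ref, codon=codon, ref_end=ref_end, codon_end=codon_end)

    if rest == "=":
        return ProteinChange(effect="synonymous", **common)
    if rest in ("*", "Ter"):
        return ProteinChange(effect="ter", **common)
    if rest == "del":
        return ProteinChange(effect="deletion", **common)
    if rest == "dup":
        return ProteinChange(effect="duplication", **common)
    if rest.startswith("delins"):
        alt = rest[len("delins"):]
        if not alt:
            raise HgvsParseError(f"delins without inserted residues in {p!r}")
        return ProteinChange(effect="delins", alt=_to_aa3_seq(alt), **common)
    if rest.startswith("ins"):
        alt = rest[len("ins"):]
        if not alt:
            raise HgvsParseError(f"ins without inserted residues in {p!r}")
        return ProteinChange(effect="insertion", alt=_to_aa3_seq(alt), **common)
    fs = _RE_FS.match(rest)
    if fs:
        alt = _to_aa3(fs.group(1)) if fs.group(1) else None
        ter = fs.group(2) or fs.group(3)
        return ProteinChange(
            effect="frameshift", alt=alt, fs_ter=int(ter) if ter else None, **common
        )
    # plain substitution: the remainder must be a single residue
    if rest:
        try:
            alt = _to_aa3(rest)
        except HgvsParseError:
            raise HgvsParseError(f"unrecognized trailing token {rest!r} in {p!r}")
        if alt == "Ter":
            return ProteinChange(effect="ter", **common)
        return ProteinChange(effect="substitution", alt=alt, **common)
    raise HgvsParseError(f"incomplete protein description {p!r}")


# ---------------------------------------------------------------------------
# cDNA inspection and consequence classification

_RE_INTRON_OFFSET = re.compile(r"\d+[+-]\d+")
_RE_CDNA_RANGE = re.compile(r"^c\.(\d+)(?:_(\d+))?")
_RE_INS_SEQ = re.compile(r"ins([ACGT]+)$")


def _cdna_is_noncoding(cdna: str) -> bool:
    body = cdna[2:] if cdna.startswith("c.") else cdna
    return cdna.startswith("n.") or body.startswith("-") or body.startswith("*")


def _cdna_is_splicing(cdna: str) -> bool:
    return bool(_RE_INTRON_OFFSET.search(cdna))


def _cdna_indel_frame(cdna: str) -> Optional[str]:
    """Classify a coding del/dup/ins cdna by length modulo 3, if computable."""
    if "delins" in cdna or "del" in cdna or "dup" in cdna:
        m = _RE_CDNA_RANGE.match(cdna)
        if not m:
            return None
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        span = end - start + 1
        ins = _RE_INS_SEQ.search(cdna)
        net = (len(ins.group(1)) if ins else 0) - span if "delins" in cdna else span
        return "inframe_indel" if net % 3 == 0 else "frameshift"
    if "ins" in cdna:
        ins = _RE_INS_SEQ.search(cdna)
        if not ins:
            return None
        return "inframe_indel" if len(ins.group(1)) % 3 == 0 else "frameshift"
    return None


def classify_consequence(
    cdna: str, protein_change: Optional[ProteinChange] = None
) -> str:
    """Assign exactly one of the seven consequence classes (or ``unknown``).

    The protein description takes precedence when present (it reflects the
    observed effect); otherwise the cdna syntax decides.  Unclassifiable
    records land in an explicit ``unknown`` bucket rather than being dropped.
    """
    if not isinstance(cdna, str) or not (cdna.startswith("c.") or cdna.startswith("n.")):
        return "unknown"
    if _cdna_is_noncoding(cdna):
        return "noncoding"
    if _cdna_is_splicing(cdna):
        return "splicing"
    if protein_change is not None:
        effect = protein_change.effect
        if effect == "frameshift":
            return "frameshift"
        if effect == "ter":
            return "nonsense"
        if effect == "synonymous":
            return "synonymous"
        if effect == "substitution":
            return "missense"
        if effect in ("deletion", "duplication", "insertion", "delins"):
            return "inframe_indel"
    frame = _cdna_indel_frame(cdna)
    if frame is not None:
        return frame
    return "unknown"


def is_hotspot(v: VariantRecord, g: GeneModel) -> bool:
    """True iff the variant's affected codon(s) intersect the gene's hotspots.

    A change spanning a codon range counts as hotspot when the range overlaps
    any hotspot codon.  Variants without protein notation cannot be placed
    and return False (logged).
    """
    if not g.hotspot_codons:
        return False
    codons = v.affected_codons
    if codons is None:
        logger.info("no protein notation for %s %s; hotspot check is False", v.gene, v.cdna)
        return False
    return any(c in g.hotspot_codons for c in codons)


# ---------------------------------------------------------------------------
# Table ingest and normalization

REQUIRED_VARIANT_COLUMNS = ("gene", "cdna")


def build_variant(
    gene: str,
    cdna: str,
    protein: Optional[str] = None,
    consequence: Optional[str] = None,
    position: Optional[str] = None,
    reported_class: Optional[str] = None,
) -> VariantRecord:
    """Construct a validated VariantRecord, parsing protein HGVS when present."""
    if not isinstance(cdna, str) or not (cdna.startswith("c.") or cdna.startswith("n.")):
        raise HgvsParseError(f"cdna does not parse under HGVS c. grammar: {cdna!r}")
    pc = None
    if protein not in (None, "", "."):
        pc = parse_protein_hgvs(protein)
    cons = consequence or classify_consequence(cdna, pc)
    return VariantRecord(
        gene=gene,
        cdna=cdna,
        protein=pc.format() if pc is not None else None,
        consequence=cons,
        position=position,
        reported_class=reported_class,
        protein_change=pc,
    )


def read_variant_table(
    path: str | Path | pd.DataFrame,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Read a variant TSV (columns gene, cdna[, protein, consequence, position]).

    Returns the accepted records plus a rejected-row report (row, reason).
    Duplicate (gene, cdna) rows are merged to the first occurrence — the
    transcript-level normalization used throughout is tag validation plus
    duplicate merging on that key.
    """
    df = path if isinstance(path, pd.DataFrame) else pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing required columns: {missing}")
    records: list[VariantRecord] = []
    seen: set[tuple[str, str]] = set()
    rejected: list[dict] = []
    for idx, row in df.iterrows():
        try:
            v = build_variant(
                gene=row["gene"],
                cdna=row["cdna"],
                protein=row.get("protein"),
                consequence=_none_if_missing(row.get("consequence")),
                position=_none_if_missing(row.get("position")),
                reported_class=_none_if_missing(row.get("reported_class")),
            )
        except (HgvsParseError, ValueError) as exc:
            rejected.append({"row": idx, "reason": str(exc)})
            continue
        if v.key in seen:
            continue
        seen.add(v.key)
        records.append(v)
    return records, pd.DataFrame(rejected, columns=["row", "reason"])


def _none_if_missing(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value in ("", "."):
        return None
    return value


def load_gene_panel(path: str | Path) -> dict[str, GeneModel]:
    """Load a gene panel TSV into GeneModel objects keyed by symbol.

    Shares are derived from the family_count column over its total.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    total = df["family_count"].astype(int).sum()
    panel: dict[str, GeneModel] = {}
    for _, row in df.iterrows():
        hotspots = frozenset(
            int(c) for c in str(row["hotspot_codons"]).split(",") if c not in (".", "nan", "")
        )
        count = int(row["family_count"])
        panel[row["symbol"]] = GeneModel(
            symbol=row["symbol"],
            transcript=row["transcript"],
            chromosome=str(row["chromosome"]),
            inheritance=row["inheritance"],
            pli=None if row["pli"] in (".", None) else float(row["pli"]),
            hotspot_codons=hotspots,
            family_count=count,
            share=count / total if total else 0.0,
            lof_mechanism=str(row.get("lof_mechanism", "no")).lower() in ("yes", "true", "1"),
        )
    return panel
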