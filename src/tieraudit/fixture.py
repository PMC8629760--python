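"""The audited craniosynostosis cohort, embedded as data.

Thirty-six diagnosed cases from a 114-family genome-sequencing cohort:
22 researcher-submitted candidate diagnoses transcribed field-for-field
(cases 1-22), 12 pipeline/clinic-identified diagnoses known only through
aggregate counts (cases 23-34; placeholder gene symbols except the named
ZBTB20 case 34), and two diagnoses made outside both routes (case 35, an
X-linked GPC3 exon deletion; case 36, a segregating 11.5 kb non-coding
duplication on 1p31.3 validated as causative by mouse modelling).

Schematic fields for cases 23-36 (inheritance of case 35, the Exomiser rank
of case 34, which two diagnoses are non-syndromic) are constrained by the
cohort's aggregate counts rather than printed per-case; they are marked by
``schematic=True``. Two of the 36 cases are variants of uncertain
significance (cases 4 and 13) and are excluded from the 34 confirmed
diagnoses that every sensitivity denominator uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["FixtureCase", "CohortTotals", "load_fixture", "case_attributes", "fixture_frame"]

VARIANT_CLASSES = ("snv", "indel", "cnv", "sv", "noncoding")
INHERITANCES = (
    "de_novo",
    "biallelic",
    "dominant",
    "parents_unavailable",
    "de_novo_mosaic_parent",
)
PATHOGENICITIES = ("pathogenic", "likely_pathogenic", "vus")


@dataclass(frozen=True)
class FixtureCase:
    case_id: int
    gene: str
    variant_class: str
    tier_original: str  # printed tier string, "Untiered" when none
    exomiser_rank: int | None
    inheritance: str
    green_original: bool
    green_updated: bool
    known_dd_gene: bool
    pathogenicity: str
    found_by_gmc: bool
    researcher_category: str | None  # printed number-letter code(s)
    nhse_identifiable: bool | None  # None where not applicable (VUS)
    syndromic: bool
    legacy_filter_dropped: bool
    classification: str  # clinical | research
    n_variants: int = 1
    discordant_sibship: bool = False
    schematic: bool = False

    def __post_init__(self) -> None:
        assert self.variant_class in VARIANT_CLASSES
        assert self.inheritance in INHERITANCES
        assert self.pathogenicity in PATHOGENICITIES
        assert self.classification in ("clinical", "research")

    @property
    def is_vus(self) -> bool:
        return self.pathogenicity == "vus"

    @property
    def tiered_mandatory(self) -> bool:
        """Whether any variant of the case reached Tier 1, Tier 2 or Tier A
        (the tiers whose clinical review was mandated)."""
        return any(t in self.tier_original for t in ("Tier 1", "Tier 2", "Tier A"))

    @property
    def untiered(self) -> bool:
        return "ntiered" in self.tier_original


@dataclass(frozen=True)
class CohortTotals:
    n_families: int = 114
    n_trios: int = 72
    n_multiplex: int = 15
    n_syndromic: int = 82
    n_multisuture: int = 53

    @property
    def n_nonsyndromic(self) -> int:
        return self.n_families - self.n_syndromic


def _c(*args, **kwargs) -> FixtureCase:
    return FixtureCase(*args, **kwargs)


# cases 1-22: the researcher-submitted candidate diagnoses, field-for-field
_RESEARCHER_CASES = [
    # case, gene, class, tier, rank, inheritance, green_orig, green_upd,
    # known_dd, pathogenicity, gmc, category, nhse, syndromic, dropped, cls
    _c(1, "MAN2B1", "snv", "Tier 1;Tier 2", 2, "biallelic", True, True, True,
       "pathogenic", True, None, True, True, False, "clinical", n_variants=2),
    _c(2, "3.4 Mb Chr 6 del", "cnv", "Tier A", None, "de_novo", True, True, True,
       "pathogenic", True, None, True, True, False, "clinical"),
    _c(3, "KMT5B", "snv", "Tier 3", 1, "de_novo", False, False, True,
       "pathogenic", True, None, True, True, False, "clinical"),
    _c(4, "SMAD2", "snv", "Tier 3", 2, "de_novo", False, False, True,
       "vus", False, "2A", None, True, False, "clinical"),
    _c(5, "SMAD6", "snv", "Tier 3", 1, "de_novo", False, True, True,
       "likely_pathogenic", False, "2A", True, True, False, "clinical"),
    _c(6, "CDK13", "snv", "Tier 3", 2, "de_novo", False, False, True,
       "likely_pathogenic", False, "2A", True, True, False, "clinical"),
    _c(7, "HNRNPK", "snv", "Tier 3", 1, "de_novo", False, True, True,
       "pathogenic", False, "2A", True, True, False, "clinical"),
    _c(8, "FBXO11", "indel", "Tier 3", 3, "de_novo", False, True, True,
       "likely_pathogenic", False, "2A", True, True, False, "clinical"),
    _c(9, "SOX6", "snv", "Tier 3", 2, "de_novo", False, False, False,
       "pathogenic", False, "4A", True, True, False, "research"),
    _c(10, "SOX6", "snv", "Tier 3", 63, "parents_unavailable", False, False, False,
       "likely_pathogenic", False, "4C", False, True, False, "research"),
    _c(11, "BRWD3", "snv", "Tier 3", 1, "de_novo", False, False, True,
       "pathogenic", False, "2A", True, True, False, "clinical"),
    _c(12, "PTCH1", "indel", "Tier 3", 1, "de_novo", False, False, True,
       "pathogenic", False, "2A", True, True, False, "clinical"),
    _c(13, "ALX1", "snv", "Tier 3", 5, "de_novo", False, False, True,
       "vus", False, "2A", None, True, False, "clinical"),
    _c(14, "MEGF8", "indel", "Both untiered", 96, "biallelic", True, True, True,
       "likely_pathogenic", False, "1B;1B", False, True, True, "clinical", n_variants=2),
    _c(15, "MMP21", "indel", "Untiered;Tier 3", None, "biallelic", True, True, True,
       "pathogenic", False, "1B;1B", True, True, True, "clinical", n_variants=2),
    _c(16, "ARID1B", "indel", "Untiered", None, "de_novo", True, True, True,
       "pathogenic", False, "1A", True, True, True, "clinical"),
    _c(17, "TRAF7", "snv", "Untiered", 3, "de_novo", False, True, True,
       "likely_pathogenic", False, "2A", True, True, True, "clinical"),
    _c(18, "TCF12", "snv", "Untiered", None, "de_novo", True, True, True,
       "pathogenic", False, "1E", True, True, True, "clinical",
       discordant_sibship=True),
    _c(19, "OGT", "snv", "Untiered", 1, "de_novo", False, True, True,
       "pathogenic", True, None, True, True, False, "clinical"),
    _c(20, "TWIST1", "sv", "Untiered", None, "dominant", True, True, True,
       "pathogenic", False, "3D", False, True, False, "clinical"),
    _c(21, "ERF", "cnv", "Untiered", None, "de_novo_mosaic_parent", True, True, True,
       "pathogenic", False, "3A", True, True, False, "clinical"),
    _c(22, "HOXC cluster", "cnv", "Untiered", None, "dominant", False, False, False,
       "likely_pathogenic", False, "3D", False, True, False, "research"),
]

# cases 23-34: pipeline/clinic-identified diagnoses encoded schematically
# (11 from mandated tiers, plus the untiered case 34 found through the
# phenotype-driven ranker); two are recorded as non-syndromic so that
# exactly 32 of the 34 confirmed diagnoses are syndromic
_GMC_TIERS = ["Tier 1"] * 6 + ["Tier 2"] * 4 + ["Tier A"]
_GMC_CASES = [
    _c(23 + i, f"GMC_GENE{23 + i}", "cnv" if t == "Tier A" else "snv", t, None,
       "de_novo" if i % 2 == 0 else "biallelic", True, True, True,
       "pathogenic", True, None, True, 23 + i not in (23, 24), False, "clinical",
       schematic=True)
    for i, t in enumerate(_GMC_TIERS)
] + [
    _c(34, "ZBTB20", "snv", "Untiered", 1, "de_novo", False, False, True,
       "pathogenic", True, None, True, True, False, "clinical", schematic=True),
]

# cases 35-36: diagnoses made outside both the pipeline and researcher routes
_ADDITIONAL_CASES = [
    _c(35, "GPC3", "cnv", "Untiered", None, "parents_unavailable", False, False, True,
       "pathogenic", False, "3C", True, True, False, "clinical", schematic=True),
    _c(36, "1p31.3 non-coding dup", "noncoding", "Untiered", None, "dominant",
       False, False, False, "pathogenic", False, "3D", False, True, False,
       "research", schematic=True),
]

_ALL_CASES = tuple(_RESEARCHER_CASES + _GMC_CASES + _ADDITIONAL_CASES)


def load_fixture() -> tuple[list[FixtureCase], CohortTotals]:
    """The 36 audited cases and the cohort composition totals."""
    return list(_ALL_CASES), CohortTotals()


def case_attributes(case_id: int) -> FixtureCase:
    if not 1 <= case_id <= len(_ALL_CASES):
        raise ValueError(f"case_id must be in 1..{len(_ALL_CASES)}, got {case_id}")
    return _ALL_CASES[case_id - 1]


def fixture_frame() -> pd.DataFrame:
    """The fixture as a table, one row per case."""
    cases, _ = load_fixture()
    return pd.DataFrame([vars(c) for c in cases]).set_index("case_id")
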