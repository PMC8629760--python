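"""Small-variant tiering: frequency, consequence, segregation and panel rules.

The engine reproduces a panel-based trio prioritization pipeline. A variant
is placed into one of four categories: Tier 1 and Tier 2 (mandatory clinical
review; diagnostic-grade gene with a compatible mode of inheritance), Tier 3
(plausibly pathogenic but outside the diagnostic-grade gene set; review is
discretionary) and Tier null (not reported). Two operating points are
modelled:

* ``LEGACY_CONFIG`` — the original production behaviour: multinucleotide
  indels in low-complexity regions are dropped by quality settings, a single
  alternate-allele read in a parent vetoes a de novo call, and multiplex
  sibships are forced to share one causal variant.
* ``IMPROVED_CONFIG`` — the remediated behaviour: the indel filter is off,
  parents may carry a small fraction of (presumed artefactual) alternate
  reads, and each affected individual is analysed in its own right.

Relaxing any of these knobs can only promote a variant, never demote it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .io import GenotypeCall, Pedigree, SmallVariantRecord
from .panels import PanelAssignment, PanelRegistry

__all__ = [
    "TIER1",
    "TIER2",
    "TIER3",
    "TIER_A",
    "TIER_NULL",
    "SMALL_TIER_RANK",
    "TierConfig",
    "LEGACY_CONFIG",
    "IMPROVED_CONFIG",
    "SegregationCall",
    "TierResult",
    "consequence_class",
    "frequency_pass",
    "parental_support_check",
    "legacy_quality_filter",
    "segregation_pattern",
    "assign_small_tier",
    "tier_variants",
    "exomiser_rank_review",
]

TIER1 = "TIER1"
TIER2 = "TIER2"
TIER3 = "TIER3"
TIER_A = "TIER_A"
TIER_NULL = "TIER_NULL"

#: Small-variant tiers ordered from unreported to highest priority.
SMALL_TIER_RANK = {TIER_NULL: 0, TIER3: 1, TIER2: 2, TIER1: 3}

_X_CHROMS = {"X", "chrX"}


@dataclass(frozen=True)
class TierConfig:
    """Tunable pipeline behaviour.

    ``af_max_monoallelic`` / ``af_max_biallelic`` are the population
    allele-frequency ceilings for dominant/X-linked and recessive candidates
    respectively. ``parental_alt_fraction_max`` applies only when
    ``legacy_mode`` is off: a parent may carry up to this fraction of
    alternate reads without vetoing a de novo call (0.05 admits the
    archetypal 1-in-32 artefactual read).
    """

    penetrance: str = "complete"  # or "incomplete"
    af_max_monoallelic: float = 0.001
    af_max_biallelic: float = 0.01
    legacy_mode: bool = True
    parental_alt_fraction_max: float = 0.05
    sibship_model: str = "shared_variant"  # or "per_individual"

    def __post_init__(self) -> None:
        if self.penetrance not in ("complete", "incomplete"):
            raise ValueError(f"unknown penetrance mode {self.penetrance!r}")
        if self.sibship_model not in ("shared_variant", "per_individual"):
            raise ValueError(f"unknown sibship model {self.sibship_model!r}")


LEGACY_CONFIG = TierConfig()
IMPROVED_CONFIG = TierConfig(legacy_mode=False, sibship_model="per_individual")


@dataclass(frozen=True)
class SegregationCall:
    pattern: str  # de_novo | dominant_inherited | biallelic | x_linked |
    #               parents_unavailable | fails_segregation
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class TierResult:
    tier: str
    reasons: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# individual rules
# ---------------------------------------------------------------------------


def consequence_class(record: SmallVariantRecord) -> str:
    if record.consequence == "lof":
        return "high_impact"
    if record.consequence in ("missense", "inframe_indel"):
        return "moderate_impact"
    return "other"


def frequency_pass(record: SmallVariantRecord, moi: str, config: TierConfig) -> bool:
    ceiling = config.af_max_biallelic if moi == "biallelic" else config.af_max_monoallelic
    return record.pop_af <= ceiling


def parental_support_check(
    child_call: GenotypeCall,
    parent_calls: tuple[GenotypeCall, ...],
    config: TierConfig,
) -> tuple[bool, tuple[str, ...]]:
    """Accept or veto a candidate de novo given parental read support.

    Legacy behaviour rejects on any parental alternate read; improved
    behaviour tolerates an alternate-read fraction up to
    ``parental_alt_fraction_max``. A parent with no coverage cannot exclude
    inheritance, so the call is rejected with ``no_parental_coverage``.
    """
    for pc in parent_calls:
        if pc.total_reads == 0:
            return False, ("no_parental_coverage",)
    for pc in parent_calls:
        if config.legacy_mode:
            if pc.alt_reads > 0:
                return False, ("parental_support",)
        elif pc.alt_fraction > config.parental_alt_fraction_max:
            return False, ("parental_support",)
    return True, ()


def legacy_quality_filter(record: SmallVariantRecord, config: TierConfig) -> str:
    """``drop`` for multinucleotide indel calls in flagged low-complexity
    regions under the legacy quality settings; ``keep`` otherwise."""
    if not config.legacy_mode:
        return "keep"
    if "low_complexity_region" not in record.flags:
        return "keep"
    if record.is_delins:
        return "drop"
    if record.is_indel and abs(len(record.ref) - len(record.alt)) >= 3:
        return "drop"
    return "keep"


# ---------------------------------------------------------------------------
# segregation
# ---------------------------------------------------------------------------


def segregation_pattern(
    record: SmallVariantRecord,
    pedigree: Pedigree,
    config: TierConfig,
    compound_het: bool = False,
) -> SegregationCall:
    """Classify how the variant segregates in the family.

    Under the ``shared_variant`` sibship model every affected member must
    carry the variant, so a genuine de novo event in one of several affected
    siblings fails segregation — the legacy blind spot for discordant
    multiplex families. ``compound_het`` marks the variant as one allele of
    a trans pair established at the cohort level, which routes it through
    the biallelic path.
    """
    proband = pedigree.proband
    try:
        pg = record.genotype(proband.sample_id)
    except KeyError:
        raise ValueError(f"no genotype for proband {proband.sample_id!r}") from None

    if pg.allele_count == 0:
        return SegregationCall("fails_segregation", ("absent_from_proband",))

    if config.sibship_model == "shared_variant":
        for m in pedigree.affected_members:
            try:
                if record.genotype(m.sample_id).allele_count == 0:
                    return SegregationCall("fails_segregation", ("sibship_discordant",))
            except KeyError:
                raise ValueError(f"no genotype for affected member {m.sample_id!r}") from None

    father, mother = pedigree.parents_of(proband)
    have_parents = father is not None and mother is not None
    if have_parents:
        try:
            fg = record.genotype(father.sample_id)
            mg = record.genotype(mother.sample_id)
        except KeyError:
            have_parents = False
    if not have_parents:
        return SegregationCall("parents_unavailable")

    if compound_het:
        return SegregationCall("biallelic", ("compound_het",))

    if fg.allele_count == 0 and mg.allele_count == 0:
        ok, reasons = parental_support_check(pg, (fg, mg), config)
        if ok:
            return SegregationCall("de_novo")
        return SegregationCall("fails_segregation", reasons)

    if pg.allele_count == 2:
        return SegregationCall("biallelic")

    if (
        record.chrom in _X_CHROMS
        and proband.sex == "male"
        and pg.allele_count == 1
        and fg.allele_count == 0
    ):
        return SegregationCall("x_linked", ("carrier_mother",))

    # inherited heterozygote: dominant segregation
    for m in pedigree.affected_members:
        try:
            if record.genotype(m.sample_id).allele_count == 0:
                return SegregationCall("fails_segregation", ("affected_noncarrier",))
        except KeyError:
            raise ValueError(f"no genotype for affected member {m.sample_id!r}") from None
    if config.penetrance == "complete":
        for m in pedigree.members:
            if m.affected == "unaffected":
                try:
                    carrier = record.genotype(m.sample_id).allele_count > 0
                except KeyError:
                    continue
                if carrier:
                    return SegregationCall("fails_segregation", ("unaffected_carrier",))
    return SegregationCall("dominant_inherited")


# ---------------------------------------------------------------------------
# tier assignment
# ---------------------------------------------------------------------------


def _moi_compatible(moi: str | None, pattern: str, chrom: str) -> bool:
    if moi in (None, "both"):
        return True
    if moi == "monoallelic":
        return pattern in ("de_novo", "dominant_inherited", "parents_unavailable")
    if moi == "biallelic":
        return pattern == "biallelic"
    if moi == "x_linked":
        return chrom in _X_CHROMS and pattern in ("x_linked", "de_novo", "parents_unavailable")
    return False


def assign_small_tier(
    record: SmallVariantRecord,
    pedigree: Pedigree,
    registry: PanelRegistry,
    assignment: PanelAssignment,
    panel_version: str,
    config: TierConfig,
    compound_het: bool = False,
) -> TierResult:
    """Assign the prioritization tier for one surviving small variant.

    Tier null when the variant is too common for its inheritance context,
    not protein-altering, or fails family segregation. Otherwise Tier 1/2
    when the gene is diagnostic grade (Green) on an applied panel with a
    compatible mode of inheritance — Tier 1 for loss-of-function or de novo
    protein-altering variants, Tier 2 for inherited moderate-impact ones —
    and Tier 3 for plausibly pathogenic variants outside that set. A lone
    surviving allele in a Green recessive gene (its trans partner lost
    upstream) is capped at Tier 3: without the pair there is no proven
    biallelic genotype.
    """
    if config.legacy_mode and legacy_quality_filter(record, config) == "drop":
        return TierResult(TIER_NULL, ("legacy_indel_filter",))

    cls = consequence_class(record)
    seg = segregation_pattern(record, pedigree, config, compound_het=compound_het)

    recessive_singleton = False
    if seg.pattern == "fails_segregation" and "unaffected_carrier" in seg.reasons:
        try:
            gene_moi = registry.moi(assignment, panel_version, record.gene)
        except ValueError:
            gene_moi = None
        if gene_moi == "biallelic":
            recessive_singleton = True
            seg = SegregationCall("biallelic", ("recessive_singleton",))

    moi_ctx = "biallelic" if seg.pattern == "biallelic" else "monoallelic"

    failures = []
    if not frequency_pass(record, moi_ctx, config):
        failures.append("frequency_fail")
    if cls == "other":
        failures.append("non_protein_altering")
    if seg.pattern == "fails_segregation":
        failures.extend(seg.reasons)
    if failures:
        return TierResult(TIER_NULL, tuple(failures))

    reasons = [f"segregation:{seg.pattern}", f"consequence:{cls}"]
    reasons.extend(seg.reasons)

    if record.gene:
        status = registry.gene_status(assignment, panel_version, record.gene)
        gene_moi = registry.moi(assignment, panel_version, record.gene)
    else:
        status, gene_moi = "not_listed", None

    if status == "green" and _moi_compatible(gene_moi, seg.pattern, record.chrom):
        reasons.append("green_panel_gene")
        if recessive_singleton:
            return TierResult(TIER3, tuple(reasons))
        if cls == "high_impact" or seg.pattern == "de_novo":
            return TierResult(TIER1, tuple(reasons))
        return TierResult(TIER2, tuple(reasons))

    reasons.append("moi_incompatible" if status == "green" else "not_diagnostic_grade")
    return TierResult(TIER3, tuple(reasons))


def _detect_compound_het(
    records: list[SmallVariantRecord],
    pedigree: Pedigree,
    config: TierConfig,
) -> set[str]:
    """Variant keys participating in a candidate trans pair within a gene."""
    proband = pedigree.proband
    father, mother = pedigree.parents_of(proband)
    by_gene: dict[str, list[SmallVariantRecord]] = {}
    for r in records:
        if not r.gene or consequence_class(r) == "other":
            continue
        if not frequency_pass(r, "biallelic", config):
            continue
        try:
            if r.genotype(proband.sample_id).allele_count != 1:
                continue
        except KeyError:
            continue
        by_gene.setdefault(r.gene, []).append(r)

    marked: set[str] = set()
    for gene, cands in by_gene.items():
        if len(cands) < 2:
            continue
        if father is None or mother is None:
            # unphaseable: a pair of rare heterozygotes is a trans candidate
            marked.update(r.key for r in cands)
            continue
        origins = {}
        for r in cands:
            try:
                from_f = r.genotype(father.sample_id).allele_count > 0
                from_m = r.genotype(mother.sample_id).allele_count > 0
            except KeyError:
                continue
            origins[r.key] = "father" if from_f and not from_m else (
                "mother" if from_m and not from_f else ("de_novo" if not from_f else "ambiguous")
            )
        if len({o for o in origins.values() if o != "ambiguous"}) >= 2:
            marked.update(origins)
    return marked


def tier_variants(
    records: list[SmallVariantRecord],
    pedigree: Pedigree,
    registry: PanelRegistry,
    assignment: PanelAssignment,
    panel_version: str,
    config: TierConfig,
) -> list[TierResult]:
    """Run the full small-variant pipeline over one family's records.

    Applies the legacy quality filter, establishes compound-heterozygous
    context among the survivors (a trans pair of rare protein-altering
    heterozygotes in one gene), then assigns a tier to every input record.
    Both alleles of a pair must survive the filters for the pair to exist —
    losing one demotes the survivor to a singleton.
    """
    survivors = [r for r in records if legacy_quality_filter(r, config) == "keep"]
    comp_het = _detect_compound_het(survivors, pedigree, config)
    results = []
    for r in records:
        if legacy_quality_filter(r, config) == "drop":
            results.append(TierResult(TIER_NULL, ("legacy_indel_filter",)))
        else:
            results.append(
                assign_small_tier(
                    r, pedigree, registry, assignment, panel_version, config,
                    compound_het=r.key in comp_het,
                )
            )
    return results


def exomiser_rank_review(case_rank: int | None, k: int) -> bool:
    """True when a phenotype-driven rank exists and falls within the top k."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    return case_rank is not None and case_rank <= k
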