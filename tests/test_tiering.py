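import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tieraudit.io import GenotypeCall, Pedigree, PedigreeMember, parse_ped, parse_small_vcf
from tieraudit.panels import PanelAssignment
from tieraudit.tiering import (
    IMPROVED_CONFIG,
    LEGACY_CONFIG,
    SMALL_TIER_RANK,
    TierConfig,
    assign_small_tier,
    consequence_class,
    exomiser_rank_review,
    frequency_pass,
    legacy_quality_filter,
    parental_support_check,
    segregation_pattern,
    tier_variants,
)

from conftest import HET, HOM, REF, make_record


# ---------------------------------------------------------------------------
# single rules
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "csq,expected",
    [
        ("lof", "high_impact"),  # e.g. a stop-gain
        ("missense", "moderate_impact"),
        ("inframe_indel", "moderate_impact"),
        ("synonymous", "other"),
        ("noncoding", "other"),
        ("other", "other"),
    ],
)
def test_consequence_class(trio, csq, expected):
    assert consequence_class(make_record(trio, consequence=csq, child=HET)) == expected


@pytest.mark.parametrize(
    "af,moi,expected",
    [
        (0.0, "monoallelic", True),
        (0.005, "monoallelic", False),  # above the 0.1% dominant ceiling
        (0.005, "biallelic", True),  # within the 1% recessive ceiling
        (0.005, "x_linked", False),
        (0.001, "monoallelic", True),  # ceiling is inclusive
    ],
)
def test_frequency_pass(trio, af, moi, expected):
    rec = make_record(trio, pop_af=af, child=HET)
    assert frequency_pass(rec, moi, LEGACY_CONFIG) is expected


class TestParentalSupport:
    child = GenotypeCall(1, 30, 15)

    def test_single_parental_read_vetoes_in_legacy_mode(self):
        mum = GenotypeCall(0, 32, 1)
        ok, reasons = parental_support_check(self.child, (REF, mum), LEGACY_CONFIG)
        assert not ok and "parental_support" in reasons

    def test_low_fraction_tolerated_in_improved_mode(self):
        mum = GenotypeCall(0, 32, 1)  # 3.1% < 5% ceiling
        ok, _ = parental_support_check(self.child, (REF, mum), IMPROVED_CONFIG)
        assert ok

    def test_clean_parents_accepted_in_both_modes(self):
        for config in (LEGACY_CONFIG, IMPROVED_CONFIG):
            ok, _ = parental_support_check(self.child, (REF, REF), config)
            assert ok

    def test_uncovered_parent_rejected(self):
        empty = GenotypeCall(0, 0, 0)
        ok, reasons = parental_support_check(self.child, (REF, empty), IMPROVED_CONFIG)
        assert not ok and reasons == ("no_parental_coverage",)


class TestLegacyQualityFilter:
    def test_multinucleotide_deletion_in_lcr_dropped(self, trio):
        rec = make_record(trio, ref="CTGTGTGTGTGTGTG", alt="C",
                          flags=("low_complexity_region",), child=HET)
        assert legacy_quality_filter(rec, LEGACY_CONFIG) == "drop"

    def test_delins_in_lcr_dropped(self, trio):
        # 1 nt deleted, 6 nt inserted
        rec = make_record(trio, ref="TG", alt="TCCCCCA",
                          flags=("low_complexity_region",), child=HET)
        assert legacy_quality_filter(rec, LEGACY_CONFIG) == "drop"

    def test_snv_in_lcr_kept(self, trio):
        rec = make_record(trio, flags=("low_complexity_region",), child=HET)
        assert legacy_quality_filter(rec, LEGACY_CONFIG) == "keep"

    def test_short_indel_outside_lcr_kept(self, trio):
        rec = make_record(trio, ref="CT", alt="C", child=HET)
        assert legacy_quality_filter(rec, LEGACY_CONFIG) == "keep"

    def test_improved_mode_keeps_everything(self, trio):
        rec = make_record(trio, ref="CTGTGTGTGTGTGTG", alt="C",
                          flags=("low_complexity_region",), child=HET)
        assert legacy_quality_filter(rec, IMPROVED_CONFIG) == "keep"


# ---------------------------------------------------------------------------
# segregation
# ---------------------------------------------------------------------------


def multiplex_pedigree():
    return Pedigree(
        "FM",
        (
            PedigreeMember("s1", "dad", "mum", "male", "affected", is_proband=True),
            PedigreeMember("s2", "dad", "mum", "male", "affected"),
            PedigreeMember("s3", "dad", "mum", "male", "affected"),
            PedigreeMember("dad", sex="male", affected="unaffected"),
            PedigreeMember("mum", sex="female", affected="unaffected"),
        ),
    )


def singleton_pedigree():
    return Pedigree(
        "FS", (PedigreeMember("p", sex="female", affected="affected", is_proband=True),)
    )


class TestSegregation:
    def test_trio_de_novo(self, trio):
        rec = make_record(trio, child=HET)
        assert segregation_pattern(rec, trio, LEGACY_CONFIG).pattern == "de_novo"

    def test_discordant_sibship_fails_shared_model(self):
        ped = multiplex_pedigree()
        rec = make_record(ped, s1=HET)  # only one affected brother carries it
        call = segregation_pattern(rec, ped, LEGACY_CONFIG)
        assert call.pattern == "fails_segregation"
        assert "sibship_discordant" in call.reasons

    def test_discordant_sibship_de_novo_under_per_individual_model(self):
        ped = multiplex_pedigree()
        rec = make_record(ped, s1=HET)
        assert segregation_pattern(rec, ped, IMPROVED_CONFIG).pattern == "de_novo"

    def test_singleton_is_parents_unavailable(self):
        ped = singleton_pedigree()
        rec = make_record(ped, p=HET)
        assert segregation_pattern(rec, ped, LEGACY_CONFIG).pattern == "parents_unavailable"

    def test_unaffected_carrier_fails_complete_penetrance(self, trio):
        rec = make_record(trio, child=HET, mum=HET)
        assert segregation_pattern(rec, trio, LEGACY_CONFIG).pattern == "fails_segregation"

    def test_unaffected_carrier_allowed_incomplete_penetrance(self, trio):
        rec = make_record(trio, child=HET, mum=HET)
        config = TierConfig(penetrance="incomplete")
        assert segregation_pattern(rec, trio, config).pattern == "dominant_inherited"

    def test_homozygote_from_carrier_parents_is_biallelic(self, trio):
        rec = make_record(trio, child=HOM, dad=HET, mum=HET)
        assert segregation_pattern(rec, trio, LEGACY_CONFIG).pattern == "biallelic"

    def test_hemizygous_x_from_carrier_mother(self):
        ped = Pedigree(
            "FX",
            (
                PedigreeMember("boy", "dad", "mum", "male", "affected", is_proband=True),
                PedigreeMember("dad", sex="male", affected="unaffected"),
                PedigreeMember("mum", sex="female", affected="unaffected"),
            ),
        )
        rec = make_record(ped, gene="OGT", chrom="chrX", boy=HET, mum=HET)
        assert segregation_pattern(rec, ped, LEGACY_CONFIG).pattern == "x_linked"

    def test_parental_read_blocks_de_novo_in_legacy_mode(self, trio):
        rec = make_record(trio, child=HET, mum=GenotypeCall(0, 32, 1))
        assert segregation_pattern(rec, trio, LEGACY_CONFIG).pattern == "fails_segregation"
        assert segregation_pattern(rec, trio, IMPROVED_CONFIG).pattern == "de_novo"


# ---------------------------------------------------------------------------
# tier assignment
# ---------------------------------------------------------------------------


class TestAssignSmallTier:
    def test_de_novo_lof_in_green_gene_is_tier1(self, trio, registry, assignment):
        rec = make_record(trio, gene="TWIST1", consequence="lof", child=HET)
        res = assign_small_tier(rec, trio, registry, assignment, "original", LEGACY_CONFIG)
        assert res.tier == "TIER1"
        assert "green_panel_gene" in res.reasons

    def test_de_novo_lof_in_nonpanel_gene_is_tier3(self, trio, registry, assignment):
        rec = make_record(trio, gene="KMT5B", chrom="chr11", consequence="lof", child=HET)
        res = assign_small_tier(rec, trio, registry, assignment, "original", LEGACY_CONFIG)
        assert res.tier == "TIER3"
        assert "not_diagnostic_grade" in res.reasons

    def test_parental_read_untiers_de_novo_in_legacy_mode(self, trio, registry, assignment):
        rec = make_record(trio, gene="TRAF7", chrom="chr16", consequence="missense",
                          child=HET, mum=GenotypeCall(0, 32, 1))
        res = assign_small_tier(rec, trio, registry, assignment, "original", LEGACY_CONFIG)
        assert res.tier == "TIER_NULL"
        assert "parental_support" in res.reasons
        res2 = assign_small_tier(rec, trio, registry, assignment, "updated", IMPROVED_CONFIG)
        assert res2.tier == "TIER1"

    def test_newly_green_gene_promotes_on_updated_panels(self, trio, registry, assignment):
        rec = make_record(trio, gene="SMAD6", chrom="chr15", consequence="missense", child=HET)
        legacy = assign_small_tier(rec, trio, registry, assignment, "original", LEGACY_CONFIG)
        updated = assign_small_tier(rec, trio, registry, assignment, "updated", LEGACY_CONFIG)
        assert (legacy.tier, updated.tier) == ("TIER3", "TIER1")

    def test_common_variant_is_tier_null(self, trio, registry, assignment):
        rec = make_record(trio, gene="TWIST1", consequence="missense", pop_af=0.02,
                          child=HET)
        res = assign_small_tier(rec, trio, registry, assignment, "original", LEGACY_CONFIG)
        assert res.tier == "TIER_NULL" and "frequency_fail" in res.reasons

    def test_compound_het_pair_in_green_recessive_gene(self, trio, registry, assignment):
        """A trans pair of a splice-equivalent LoF and a missense in a
        recessive diagnostic-grade gene reaches Tier 1 and Tier 2."""
        lof = make_record(trio, gene="MAN2B1", chrom="chr19", pos=1_001_000,
                          consequence="lof", child=HET, dad=HET)
        mis = make_record(trio, gene="MAN2B1", chrom="chr19", pos=1_002_000,
                          consequence="missense", child=HET, mum=HET)
        tiers = [r.tier for r in tier_variants(
            [lof, mis], trio, registry, assignment, "original", LEGACY_CONFIG)]
        assert tiers == ["TIER1", "TIER2"]

    def test_filtered_indel_demotes_partner_to_singleton_tier3(self, trio, registry, assignment):
        """When the indel allele of a recessive pair is lost to the legacy
        quality filter, the surviving missense is at best Tier 3."""
        indel = make_record(trio, gene="MMP21", chrom="chr10", pos=1_001_000,
                            ref="CTGTGTGTGTGTGTG", alt="C", consequence="lof",
                            flags=("low_complexity_region",), child=HET, dad=HET)
        mis = make_record(trio, gene="MMP21", chrom="chr10", pos=1_002_000,
                          consequence="missense", child=HET, mum=HET)
        legacy = [r.tier for r in tier_variants(
            [indel, mis], trio, registry, assignment, "original", LEGACY_CONFIG)]
        improved = [r.tier for r in tier_variants(
            [indel, mis], trio, registry, assignment, "updated", IMPROVED_CONFIG)]
        assert legacy == ["TIER_NULL", "TIER3"]
        assert improved == ["TIER1", "TIER2"]


@pytest.mark.parametrize(
    "rank,k,expected",
    [(1, 3, True), (3, 3, True), (63, 3, False), (None, 3, False), (4, 3, False)],
)
def test_exomiser_rank_review(rank, k, expected):
    assert exomiser_rank_review(rank, k) is expected


def test_exomiser_rank_review_rejects_nonpositive_k():
    with pytest.raises(ValueError):
        exomiser_rank_review(1, 0)


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

_GT_CONFIGS = [
    {"child": HET},
    {"child": HET, "mum": HET},
    {"child": HET, "dad": HET},
    {"child": HOM, "dad": HET, "mum": HET},
    {"child": HET, "mum": GenotypeCall(0, 32, 1)},
    {"child": HET, "mum": GenotypeCall(0, 0, 0)},
    {},
]

_rec_strategy = st.builds(
    dict,
    gene=st.sampled_from(["TWIST1", "SMAD6", "KMT5B", "MMP21", "MAN2B1", "GENE001"]),
    consequence=st.sampled_from(["lof", "missense", "inframe_indel", "synonymous"]),
    pop_af=st.sampled_from([0.0, 5e-4, 5e-3, 0.05]),
    flags=st.sampled_from([(), ("low_complexity_region",)]),
    ref=st.sampled_from(["C", "CTGTGTGTGTGTGTG", "TG"]),
    alt=st.sampled_from(["T", "TCCCCCA"]),
    genotypes=st.sampled_from(_GT_CONFIGS),
)


from tieraudit.panels import bundled_registry as _bundled_registry

_REGISTRY = _bundled_registry()
_TRIO = Pedigree(
    "FAM1",
    (
        PedigreeMember("child", "dad", "mum", "female", "affected", is_proband=True),
        PedigreeMember("dad", sex="male", affected="unaffected"),
        PedigreeMember("mum", sex="female", affected="unaffected"),
    ),
)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(params=_rec_strategy)
def test_relaxing_configuration_never_demotes(params):
    """Moving from the legacy operating point (original panels) to the
    improved one (updated panels) can promote a variant but never demote it,
    and identical inputs always produce identical results."""
    trio, registry = _TRIO, _REGISTRY
    assignment = PanelAssignment("case", ("craniosynostosis", "dd_syndromes"))
    genotypes = params.pop("genotypes")
    if params["ref"][0] != params["alt"][0]:
        params["alt"] = params["ref"][0] + params["alt"][1:]
    rec = make_record(trio, **params, **genotypes)

    legacy = tier_variants([rec], trio, registry, assignment, "original", LEGACY_CONFIG)[0]
    improved = tier_variants([rec], trio, registry, assignment, "updated", IMPROVED_CONFIG)[0]
    assert SMALL_TIER_RANK[improved.tier] >= SMALL_TIER_RANK[legacy.tier]
    again = tier_variants([rec], trio, registry, assignment, "original", LEGACY_CONFIG)[0]
    assert again == legacy


# ---------------------------------------------------------------------------
# oracle equivalence: independent flat rule evaluator
# ---------------------------------------------------------------------------

_X = ("X", "chrX")


def _reference_comp_het(records, ped, cfg):
    """Independently derive compound-het candidate keys."""
    pro = ped.proband
    father, mother = ped.parents_of(pro)
    by_gene = {}
    for r in records:
        if not r.gene or r.consequence in ("synonymous", "noncoding", "other"):
            continue
        if r.pop_af > cfg.af_max_biallelic:
            continue
        if cfg.legacy_mode and "low_complexity_region" in r.flags and (
            (len(r.ref) > 1 and len(r.alt) > 1) or abs(len(r.ref) - len(r.alt)) >= 3
        ):
            continue
        if dict(r.genotypes)[pro.sample_id].allele_count != 1:
            continue
        by_gene.setdefault(r.gene, []).append(r)
    marked = set()
    for gene, cands in by_gene.items():
        if len(cands) < 2:
            continue
        if father is None or mother is None:
            marked.update(r.key for r in cands)
            continue
        origin = {}
        for r in cands:
            g = dict(r.genotypes)
            ff = g[father.sample_id].allele_count > 0
            mm = g[mother.sample_id].allele_count > 0
            origin[r.key] = (
                "father" if ff and not mm
                else "mother" if mm and not ff
                else "de_novo" if not ff and not mm
                else "ambiguous"
            )
        if len({o for o in origin.values() if o != "ambiguous"}) >= 2:
            marked.update(origin)
    return marked


def _reference_tier(rec, ped, reg, asn, ver, cfg, comp):
    """Flat re-derivation of the tiering decision table, rule by rule."""
    pro = ped.proband
    g = dict(rec.genotypes)
    pg = g[pro.sample_id]
    if cfg.legacy_mode and "low_complexity_region" in rec.flags and (
        (len(rec.ref) > 1 and len(rec.alt) > 1)
        or abs(len(rec.ref) - len(rec.alt)) >= 3
    ):
        return "TIER_NULL"
    if pg.allele_count == 0:
        return "TIER_NULL"
    affected = [m for m in ped.members if m.affected == "affected"]
    if cfg.sibship_model == "shared_variant" and any(
        g[m.sample_id].allele_count == 0 for m in affected
    ):
        return "TIER_NULL"
    father, mother = ped.parents_of(pro)
    moi = reg.moi(asn, ver, rec.gene) if rec.gene else None
    if father is None or mother is None:
        pattern = "parents_unavailable"
    elif comp:
        pattern = "biallelic"
    else:
        fg, mg = g[father.sample_id], g[mother.sample_id]
        if fg.allele_count == 0 and mg.allele_count == 0:
            for parent in (fg, mg):
                if parent.total_reads == 0:
                    return "TIER_NULL"
                bad = parent.alt_reads > 0 if cfg.legacy_mode else (
                    parent.alt_reads / parent.total_reads > cfg.parental_alt_fraction_max
                )
                if bad:
                    return "TIER_NULL"
            pattern = "de_novo"
        elif pg.allele_count == 2:
            pattern = "biallelic"
        elif (rec.chrom in _X and pro.sex == "male" and pg.allele_count == 1
              and fg.allele_count == 0):
            pattern = "x_linked"
        else:
            if any(g[m.sample_id].allele_count == 0 for m in affected):
                return "TIER_NULL"
            carrier = cfg.penetrance == "complete" and any(
                g[m.sample_id].allele_count > 0
                for m in ped.members if m.affected == "unaffected"
            )
            if carrier:
                if moi == "biallelic":
                    pattern = "recessive_singleton"
                else:
                    return "TIER_NULL"
            else:
                pattern = "dominant_inherited"
    ceiling = (cfg.af_max_biallelic if pattern in ("biallelic", "recessive_singleton")
               else cfg.af_max_monoallelic)
    if rec.pop_af > ceiling:
        return "TIER_NULL"
    if rec.consequence in ("synonymous", "noncoding", "other"):
        return "TIER_NULL"
    green = bool(rec.gene) and reg.gene_status(asn, ver, rec.gene) == "green"
    compatible = (
        moi in (None, "both")
        or (moi == "monoallelic"
            and pattern in ("de_novo", "dominant_inherited", "parents_unavailable"))
        or (moi == "biallelic" and pattern in ("biallelic", "recessive_singleton"))
        or (moi == "x_linked" and rec.chrom in _X
            and pattern in ("x_linked", "de_novo", "parents_unavailable"))
    )
    if green and compatible:
        if pattern == "recessive_singleton":
            return "TIER3"
        if rec.consequence == "lof" or pattern == "de_novo":
            return "TIER1"
        return "TIER2"
    return "TIER3"


@pytest.mark.parametrize("mode", ["legacy", "improved"])
def test_engine_matches_flat_rule_evaluator(small_cohort, registry, mode):
    """On generated cohorts the engine agrees variant-for-variant with an
    independent flat evaluation of every rule."""
    config, version = (
        (LEGACY_CONFIG, "original") if mode == "legacy" else (IMPROVED_CONFIG, "updated")
    )
    pedigrees = {p.family_id: p for p in parse_ped(small_cohort.ped_path)}
    checked = 0
    for fam, ped in sorted(pedigrees.items()):
        assignment = PanelAssignment(fam, ("craniosynostosis", "dd_syndromes"))
        records = parse_small_vcf(small_cohort.small_vcf_paths[fam], ped)
        comp = _reference_comp_het(records, ped, config)
        results = tier_variants(records, ped, registry, assignment, version, config)
        for rec, res in zip(records, results):
            expected = _reference_tier(
                rec, ped, registry, assignment, version, config, rec.key in comp
            )
            assert res.tier == expected, (fam, rec.key, res.reasons)
            checked += 1
        if checked >= 150:
            break
    assert checked >= 50
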