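"""Synthetic trio-cohort generator with planted causal-variant archetypes.

The generator emulates the composition of a rare-disease genome-sequencing
cohort recruited for craniosynostosis: 114 families by default, of which 72
are sporadic proband-parent trios and 15 are multiplex sibships, with the
remainder split into parent-child duos and singleton probands; 72% of
probands carry a syndromic presentation. Each planted causal archetype
reproduces one documented success or failure mechanism of a panel-based
tiering pipeline — a de novo loss-of-function variant in a diagnostic-grade
gene, a compound-heterozygous pair whose indel allele is lost to a quality
filter, a de novo call shadowed by a single artefactual parental read, a
discordant de novo event inside a multiplex sibship, a reportable deletion
over a Green gene, a balanced inversion whose breakpoints flank one, and so
on — embedded with exactly the annotations the mechanism needs (low-
complexity flags, parental read counts, mosaic flags, panel membership).

Everything is driven by one seeded random stream in a fixed order, so a
given configuration and seed always produce byte-identical output files.
The per-archetype expected tiers (:func:`expected_tier`) form an oracle
that is a plain lookup table, deliberately independent of the tiering
engine it is used to check.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import GeneIndex, GeneSpan, tier_structural_calls, write_gene_bed
from .io import (
    GenotypeCall,
    Pedigree,
    PedigreeMember,
    SmallVariantRecord,
    StructuralCall,
    parse_ped,
    parse_small_vcf,
    parse_sv_vcf,
    write_ped,
    write_small_vcf,
    write_sv_vcf,
)
from .panels import PanelAssignment, PanelRegistry, bundled_registry
from .tiering import (
    IMPROVED_CONFIG,
    LEGACY_CONFIG,
    TIER1,
    TIER2,
    TIER3,
    TIER_A,
    TIER_NULL,
    TierConfig,
    tier_variants,
)

__all__ = [
    "ARCHETYPE_IDS",
    "ArchetypeSpec",
    "CohortConfig",
    "GeneratedCohort",
    "synthetic_gene_table",
    "expected_tier",
    "generate_cohort",
    "tier_cohort_files",
]

_PANEL_IDS = ("craniosynostosis", "dd_syndromes")

# genes carried by the audited-cohort archetypes, pinned to their real
# chromosomes on toy contigs; fillers host only benign background variation
_PINNED_GENES = {
    "chr2": ["FBXO11"],
    "chr3": ["ZBTB20"],
    "chr4": ["FGFR3"],
    "chr6": ["ARID1B"],
    "chr7": ["TWIST1", "CDK13"],
    "chr9": ["HNRNPK", "PTCH1"],
    "chr10": ["MMP21", "FGFR2"],
    "chr11": ["KMT5B", "SOX6"],
    "chr12": ["ALX1", "HOXC13"],
    "chr15": ["TCF12", "SMAD6"],
    "chr16": ["TRAF7"],
    "chr18": ["SMAD2"],
    "chr19": ["MAN2B1", "MEGF8", "ERF"],
    "chrX": ["BRWD3", "OGT", "GPC3"],
}

_N_GENES = 200
_SLOT = 200_000
_GENE_LEN = 60_000
_FIRST_START = 1_000_001


def synthetic_gene_table() -> list[GeneSpan]:
    """~200 non-overlapping gene spans on toy contigs (deterministic).

    Archetype genes keep their real names and chromosomes; invented fillers
    (GENE001...) are spread round-robin over the autosomes.
    """
    spans = []
    next_slot = {f"chr{c}": 0 for c in list(range(1, 23)) + ["X"]}

    def place(gene: str, chrom: str) -> None:
        start = _FIRST_START + next_slot[chrom] * _SLOT
        next_slot[chrom] += 1
        spans.append(GeneSpan(gene, chrom, start, start + _GENE_LEN - 1))

    for chrom in sorted(_PINNED_GENES, key=lambda c: (len(c), c)):
        for gene in _PINNED_GENES[chrom]:
            place(gene, chrom)
    n_fillers = _N_GENES - len(spans)
    autosomes = [f"chr{c}" for c in range(1, 23)]
    for i in range(n_fillers):
        place(f"GENE{i + 1:03d}", autosomes[i % len(autosomes)])
    return spans


@dataclass(frozen=True)
class ArchetypeSpec:
    """One planted causal mechanism and the tier an ideal pipeline assigns
    to its primary variant under each operating point."""

    archetype_id: str
    structure: str  # trio | multiplex | singleton
    expected_tier_legacy: str
    expected_tier_improved: str
    gene: str
    variant_class: str
    inheritance: str
    green_original: bool
    green_updated: bool
    known_dd_gene: bool
    legacy_filter_dropped: bool = False
    exomiser_rank: int | None = None


_ARCHETYPES = {
    a.archetype_id: a
    for a in [
        ArchetypeSpec("green_gene_denovo_lof", "trio", TIER1, TIER1,
                      "TWIST1", "snv", "de_novo", True, True, True, exomiser_rank=1),
        ArchetypeSpec("green_gene_biallelic", "trio", TIER2, TIER2,
                      "MAN2B1", "snv", "biallelic", True, True, True, exomiser_rank=2),
        ArchetypeSpec("nonpanel_denovo", "trio", TIER3, TIER3,
                      "KMT5B", "snv", "de_novo", False, False, True, exomiser_rank=1),
        ArchetypeSpec("updated_panel_denovo", "trio", TIER3, TIER1,
                      "SMAD6", "snv", "de_novo", False, True, True, exomiser_rank=1),
        ArchetypeSpec("filtered_indel_compound_het", "trio", TIER_NULL, TIER1,
                      "MMP21", "indel", "biallelic", True, True, True,
                      legacy_filter_dropped=True),
        ArchetypeSpec("parental_read_denovo", "trio", TIER_NULL, TIER1,
                      "TRAF7", "snv", "de_novo", False, True, True,
                      legacy_filter_dropped=True, exomiser_rank=3),
        ArchetypeSpec("discordant_sibship_denovo", "multiplex", TIER_NULL, TIER1,
                      "TCF12", "snv", "de_novo", True, True, True,
                      legacy_filter_dropped=True),
        ArchetypeSpec("green_cnv_del", "trio", TIER_A, TIER_A,
                      "ERF", "cnv", "de_novo", True, True, True),
        ArchetypeSpec("flanking_inversion", "trio", TIER_NULL, TIER_NULL,
                      "FGFR2", "sv", "dominant", True, True, True),
        ArchetypeSpec("nonpanel_dup_mosaic", "trio", TIER_NULL, TIER_NULL,
                      "HOXC13", "cnv", "dominant", False, False, False),
        ArchetypeSpec("noncoding_duplication", "trio", TIER_NULL, TIER_NULL,
                      "", "noncoding", "dominant", False, False, False),
        ArchetypeSpec("parents_unavailable_lof", "singleton", TIER3, TIER3,
                      "SOX6", "snv", "parents_unavailable", False, False, False,
                      exomiser_rank=63),
    ]
}

ARCHETYPE_IDS = tuple(_ARCHETYPES)


def expected_tier(archetype_id: str, mode: str) -> str:
    """Oracle: the tier the stated rules must produce for the archetype's
    primary variant. ``legacy`` pairs the legacy configuration with the
    original panels; ``improved`` pairs the remediated configuration with
    the updated panels. Implemented as a direct lookup, not via the engine.
    """
    try:
        spec = _ARCHETYPES[archetype_id]
    except KeyError:
        raise ValueError(f"unknown archetype {archetype_id!r}") from None
    if mode == "legacy":
        return spec.expected_tier_legacy
    if mode == "improved":
        return spec.expected_tier_improved
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition. Defaults emulate the audited recruitment: 114
    families, 72 analysed as trios, 15 multiplex, 72% syndromic probands,
    one family per archetype, and 50 rare/benign background variants per
    genome (only filter-surviving candidate variation is modelled — real
    genomes carry millions of calls, but the audit only ever sees the
    candidates)."""

    n_families: int = 114
    trio_fraction: float = 72 / 114
    multiplex_count: int = 15
    syndromic_fraction: float = 82 / 114
    archetype_counts: dict = field(default_factory=lambda: {a: 1 for a in ARCHETYPE_IDS})
    background_variants_per_genome: int = 50
    seed: int = 0


@dataclass
class GeneratedCohort:
    out_dir: Path
    ped_path: Path
    small_vcf_paths: dict[str, Path]
    sv_vcf_paths: dict[str, Path]
    panel_path: Path
    gene_bed_path: Path
    truth_path: Path
    truth: pd.DataFrame
    families_path: Path
    families: pd.DataFrame


# ---------------------------------------------------------------------------
# family construction
# ---------------------------------------------------------------------------


def _plan_structures(config: CohortConfig) -> list[str]:
    n = config.n_families
    n_trio = round(config.trio_fraction * n)
    n_multi = config.multiplex_count
    if n_multi + n_trio > n:
        raise ValueError("multiplex_count plus trio quota exceeds n_families")
    rest = n - n_trio - n_multi
    n_duo = rest // 2
    n_single = rest - n_duo

    counts = dict(config.archetype_counts)
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative archetype count")
    unknown = set(counts) - set(ARCHETYPE_IDS)
    if unknown:
        raise ValueError(f"unknown archetypes {sorted(unknown)}")
    if sum(counts.values()) > n:
        raise ValueError("more planted archetypes than families")
    need = {"trio": 0, "multiplex": 0, "singleton": 0}
    for aid, c in counts.items():
        need[_ARCHETYPES[aid].structure] += c
    if need["multiplex"] > n_multi:
        raise ValueError("not enough multiplex families for the requested archetypes")
    if need["singleton"] > n_single:
        raise ValueError("not enough singleton families for the requested archetypes")
    if need["trio"] > n_trio:
        raise ValueError("not enough trio families for the requested archetypes")

    return ["multiplex"] * n_multi + ["trio"] * n_trio + ["duo"] * n_duo + ["singleton"] * n_single


def _make_family(family_id: str, structure: str, rng: np.random.Generator) -> Pedigree:
    pid, fid, mid = f"{family_id}_P", f"{family_id}_F", f"{family_id}_M"
    proband_sex = "male" if rng.random() < 0.5 else "female"
    if structure == "multiplex":
        # parents plus three affected brothers; the first is the proband
        sibs = [
            PedigreeMember(f"{family_id}_S{i}", fid, mid, "male", "affected",
                           is_proband=(i == 1))
            for i in (1, 2, 3)
        ]
        members = sibs + [
            PedigreeMember(fid, sex="male", affected="unaffected"),
            PedigreeMember(mid, sex="female", affected="unaffected"),
        ]
    elif structure == "trio":
        members = [
            PedigreeMember(pid, fid, mid, proband_sex, "affected", is_proband=True),
            PedigreeMember(fid, sex="male", affected="unaffected"),
            PedigreeMember(mid, sex="female", affected="unaffected"),
        ]
    elif structure == "duo":
        members = [
            PedigreeMember(pid, None, mid, proband_sex, "affected", is_proband=True),
            PedigreeMember(mid, sex="female", affected="unaffected"),
        ]
    elif structure == "singleton":
        members = [PedigreeMember(pid, sex=proband_sex, affected="affected", is_proband=True)]
    else:  # pragma: no cover
        raise ValueError(structure)
    return Pedigree(family_id, tuple(members))


# ---------------------------------------------------------------------------
# genotype helpers
# ---------------------------------------------------------------------------

_HET = GenotypeCall(1, 30, 15)
_HOM = GenotypeCall(2, 30, 30)
_REF = GenotypeCall(0, 30, 0)


def _genotypes(ped: Pedigree, carriers: dict[str, GenotypeCall]) -> tuple:
    return tuple((sid, carriers.get(sid, _REF)) for sid in ped.sample_ids)


# ---------------------------------------------------------------------------
# archetype builders
# ---------------------------------------------------------------------------


def _plant_archetype(
    aid: str, ped: Pedigree, genes: dict[str, GeneSpan]
) -> tuple[list[SmallVariantRecord], list[StructuralCall], list[str]]:
    """Embed the archetype's variant(s) in the family; returns the records,
    SV calls and the primary-variant keys (one per truth row variant)."""
    spec = _ARCHETYPES[aid]
    p = ped.proband.sample_id
    f = ped.proband.father_id
    m = ped.proband.mother_id
    span = genes.get(spec.gene)

    def snv(offset, csq, gts, ref="C", alt="T", flags=(), gene=None, sp=None):
        sp = sp or span
        return SmallVariantRecord(
            chrom=sp.chrom, pos=sp.start + offset, ref=ref, alt=alt,
            gene=spec.gene if gene is None else gene, consequence=csq,
            pop_af=0.0, qual=100.0, genotypes=_genotypes(ped, gts),
            flags=frozenset(flags),
        )

    small: list[SmallVariantRecord] = []
    svs: list[StructuralCall] = []

    if aid in ("green_gene_denovo_lof", "nonpanel_denovo", "updated_panel_denovo"):
        csq = "lof" if aid != "updated_panel_denovo" else "missense"
        small.append(snv(1000, csq, {p: _HET, f: _REF, m: _REF}))
    elif aid == "green_gene_biallelic":
        small.append(snv(1000, "missense", {p: _HOM, f: _HET, m: _HET}, ref="G", alt="A"))
    elif aid == "filtered_indel_compound_het":
        # 14-nt frameshift deletion in a low-complexity region (paternal)
        # plus a rare missense (maternal)
        small.append(
            snv(1000, "lof", {p: _HET, f: _HET, m: _REF},
                ref="CTGTGTGTGTGTGTG", alt="C", flags=("low_complexity_region",))
        )
        small.append(snv(2000, "missense", {p: _HET, f: _REF, m: _HET}, ref="G", alt="A"))
    elif aid == "parental_read_denovo":
        small.append(
            snv(1000, "missense",
                {p: _HET, f: _REF, m: GenotypeCall(0, 32, 1)}, ref="A", alt="G")
        )
    elif aid == "discordant_sibship_denovo":
        small.append(snv(1000, "lof", {p: _HET}))  # other sibs and parents reference
    elif aid == "parents_unavailable_lof":
        small.append(snv(1000, "lof", {p: _HET}))
    elif aid == "green_cnv_del":
        svs.append(
            StructuralCall(span.chrom, span.start - 10_000,
                           span.start - 10_000 + 314_000 - 1, "DEL",
                           qual_score=50.0, carriers=frozenset({p}))
        )
    elif aid == "flanking_inversion":
        svs.append(
            StructuralCall(span.chrom, span.start - 400_000, span.end + 400_000,
                           "INV", qual_score=40.0, carriers=frozenset({p}),
                           breakpoints_only=True)
        )
    elif aid == "nonpanel_dup_mosaic":
        svs.append(
            StructuralCall(span.chrom, span.start - 10_000,
                           span.start - 10_000 + 285_000 - 1, "DUP",
                           qual_score=35.0, carriers=frozenset({p}),
                           mosaic_carriers=frozenset({f}) if f else frozenset())
        )
    elif aid == "noncoding_duplication":
        # 11.5 kb duplication in a gene desert: reportable but overlaps nothing
        svs.append(
            StructuralCall("chr22", 15_000_001, 15_000_001 + 11_500 - 1, "DUP",
                           qual_score=30.0, carriers=frozenset({p}))
        )
    else:  # pragma: no cover
        raise ValueError(aid)

    keys = [r.key for r in small] + [c.key for c in svs]
    return small, svs, keys


def _background_variants(
    ped: Pedigree,
    fillers: list[GeneSpan],
    n: int,
    rng: np.random.Generator,
    config: TierConfig = LEGACY_CONFIG,
) -> list[SmallVariantRecord]:
    """Rare and common benign variation on filler genes only."""
    p = ped.proband.sample_id
    f = ped.proband.father_id
    m = ped.proband.mother_id
    have_parents = f is not None and m is not None
    bases = ["A", "C", "G", "T"]
    used = set()
    out = []
    for _ in range(n):
        span = fillers[rng.integers(len(fillers))]
        while True:
            pos = int(rng.integers(span.start, span.end + 1))
            if (span.chrom, pos) not in used:
                used.add((span.chrom, pos))
                break
        ref = bases[rng.integers(4)]
        alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
        csq = rng.choice(
            ["synonymous", "missense", "noncoding", "lof", "inframe_indel"],
            p=[0.40, 0.30, 0.20, 0.05, 0.05],
        )
        common = rng.random() < 0.5
        af = float(rng.uniform(0.02, 0.5)) if common else float(10 ** rng.uniform(-6, -2.5))
        u = rng.random()
        gts: dict[str, GenotypeCall] = {}
        if have_parents:
            if u < 0.60:  # inherited heterozygote
                parent = f if rng.random() < 0.5 else m
                gts = {p: _HET, parent: _HET}
            elif u < 0.80:  # parent-only
                parent = f if rng.random() < 0.5 else m
                gts = {parent: _HET}
            elif u < 0.98 and common:  # common homozygote
                gts = {p: _HOM, f: _HET, m: _HET}
            else:  # occasional benign de novo
                gts = {p: _HET}
        else:
            gts = {p: _HET}
        out.append(
            SmallVariantRecord(
                chrom=span.chrom, pos=pos, ref=ref, alt=str(alt), gene=span.gene,
                consequence=str(csq), pop_af=af, qual=float(rng.uniform(40, 100)),
                genotypes=_genotypes(ped, gts),
            )
        )
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(config: CohortConfig, out_dir: str | os.PathLike) -> GeneratedCohort:
    """Generate the cohort files and truth table under ``out_dir``.

    Deterministic for a given config: the random stream is consumed in a
    fixed order (family structures, then per family its sex draw, syndromic
    draw and background variants).
    """
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    (out / "small").mkdir(parents=True, exist_ok=True)
    (out / "sv").mkdir(parents=True, exist_ok=True)

    structures = _plan_structures(config)
    rng.shuffle(structures)

    # queue archetypes onto compatible families in declaration order
    pending: dict[str, list[str]] = {"trio": [], "multiplex": [], "singleton": []}
    for aid in ARCHETYPE_IDS:
        pending[_ARCHETYPES[aid].structure].extend(
            [aid] * config.archetype_counts.get(aid, 0)
        )

    spans = synthetic_gene_table()
    genes = {s.gene: s for s in spans}
    fillers = [s for s in spans if s.gene.startswith("GENE")]

    width = len(str(config.n_families))
    pedigrees, truth_rows, family_rows = [], [], []
    small_paths: dict[str, Path] = {}
    sv_paths: dict[str, Path] = {}

    for i, structure in enumerate(structures, start=1):
        fam = f"FAM{i:0{width}d}"
        ped = _make_family(fam, structure, rng)
        pedigrees.append(ped)
        syndromic = bool(rng.random() < config.syndromic_fraction)
        family_rows.append(
            {"family_id": fam, "structure": structure, "syndromic": syndromic}
        )

        small: list[SmallVariantRecord] = []
        svs: list[StructuralCall] = []
        aid = pending[structure].pop(0) if pending.get(structure) else None
        if aid is not None:
            spec = _ARCHETYPES[aid]
            a_small, a_svs, keys = _plant_archetype(aid, ped, genes)
            small.extend(a_small)
            svs.extend(a_svs)
            baseline = spec.expected_tier_legacy in (TIER1, TIER2, TIER_A)
            truth_rows.append(
                {
                    "case_id": fam,
                    "archetype_id": aid,
                    "variant_keys": ";".join(keys),
                    "gene": spec.gene,
                    "structure": structure,
                    "syndromic": syndromic,
                    "expected_tier_legacy": spec.expected_tier_legacy,
                    "expected_tier_improved": spec.expected_tier_improved,
                    "variant_class": spec.variant_class,
                    "inheritance": spec.inheritance,
                    "green_original": spec.green_original,
                    "green_updated": spec.green_updated,
                    "known_dd_gene": spec.known_dd_gene,
                    "legacy_filter_dropped": spec.legacy_filter_dropped,
                    "exomiser_rank": spec.exomiser_rank,
                    "pathogenicity": "pathogenic",
                    "found_by_gmc": baseline,
                    "nhse_identifiable": bool(
                        baseline
                        or (spec.inheritance == "de_novo"
                            and spec.variant_class in ("snv", "indel"))
                        or (spec.green_updated and not spec.green_original)
                        or (spec.exomiser_rank is not None and spec.exomiser_rank <= 3)
                    ),
                }
            )
        small.extend(
            _background_variants(ped, fillers, config.background_variants_per_genome, rng)
        )

        small_paths[fam] = Path(write_small_vcf(small, ped, out / "small" / f"{fam}.vcf"))
        if svs:
            sv_paths[fam] = Path(write_sv_vcf(svs, ped, out / "sv" / f"{fam}.vcf"))

    ped_path = Path(write_ped(pedigrees, out / "cohort.ped"))
    panel_path = Path(bundled_registry().write(out / "panels.json"))
    gene_bed_path = Path(write_gene_bed(spans, out / "genes.bed"))

    truth = pd.DataFrame(truth_rows)
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    families = pd.DataFrame(family_rows)
    families_path = out / "families.tsv"
    families.to_csv(families_path, sep="\t", index=False)

    return GeneratedCohort(
        out_dir=out,
        ped_path=ped_path,
        small_vcf_paths=small_paths,
        sv_vcf_paths=sv_paths,
        panel_path=panel_path,
        gene_bed_path=gene_bed_path,
        truth_path=truth_path,
        truth=truth,
        families_path=families_path,
        families=families,
    )


def tier_cohort_files(
    cohort: GeneratedCohort,
    mode: str = "legacy",
) -> pd.DataFrame:
    """Re-read a generated cohort from its files and tier every variant.

    ``legacy`` runs the legacy configuration against the original panels,
    ``improved`` the remediated configuration against the updated panels.
    Returns one row per variant: case_id, variant_key, tier, reasons.
    """
    if mode == "legacy":
        config, version = LEGACY_CONFIG, "original"
    elif mode == "improved":
        config, version = IMPROVED_CONFIG, "updated"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    registry = PanelRegistry.load(cohort.panel_path)
    from .cnv import read_gene_bed

    genes = GeneIndex(read_gene_bed(cohort.gene_bed_path))
    pedigrees = {p.family_id: p for p in parse_ped(cohort.ped_path)}

    rows = []
    for fam, ped in pedigrees.items():
        assignment = PanelAssignment(fam, _PANEL_IDS)
        records = parse_small_vcf(cohort.small_vcf_paths[fam], ped)
        for rec, res in zip(records, tier_variants(records, ped, registry, assignment, version, config)):
            rows.append(
                {"case_id": fam, "variant_key": rec.key, "kind": "small",
                 "tier": res.tier, "reasons": ";".join(res.reasons)}
            )
        if fam in cohort.sv_vcf_paths:
            calls = parse_sv_vcf(cohort.sv_vcf_paths[fam], ped)
            for call, res, reviewed in tier_structural_calls(
                calls, registry, assignment, version, genes
            ):
                rows.append(
                    {"case_id": fam, "variant_key": call.key, "kind": "sv",
                     "tier": res.tier,
                     "reasons": ";".join(res.reasons)
                     + (";breakpoint_review_flagged" if reviewed else "")}
                )
    return pd.DataFrame(rows)
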