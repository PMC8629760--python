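"""Cohort file I/O: PED pedigrees, small-variant VCF and structural-variant VCF.

All external coordinates are VCF-style 1-based inclusive. The narrow VCF
dialect used throughout the package is:

* small variants — INFO ``GENE`` (symbol), ``CSQCLASS`` (consequence class),
  ``POPAF`` (population allele frequency), ``LCR`` (flag, low-complexity
  region); FORMAT ``GT``, ``DP``, ``AD``.
* structural variants — INFO ``SVTYPE`` (DEL/DUP/INV), ``END``, ``QS`` (call
  quality score); FORMAT ``GT``, ``MOSAIC`` (1 when the sample carries the
  rearrangement in mosaic state, which plain GT cannot express).

Multi-allelic small-variant sites are decomposed into one record per ALT
allele on parsing. Parsing a written file recovers the records bit-exactly
for every supported field.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import pysam

__all__ = [
    "ParseError",
    "ValidationError",
    "PedigreeMember",
    "Pedigree",
    "GenotypeCall",
    "SmallVariantRecord",
    "StructuralCall",
    "CONSEQUENCES",
    "SV_TYPES",
    "parse_ped",
    "write_ped",
    "parse_small_vcf",
    "write_small_vcf",
    "parse_sv_vcf",
    "write_sv_vcf",
]

CONSEQUENCES = ("lof", "missense", "inframe_indel", "synonymous", "noncoding", "other")
SV_TYPES = ("DEL", "DUP", "INV")

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown", "-9": "unknown"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}
_AFF_CODES = {"1": "unaffected", "2": "affected", "0": "unknown", "-9": "unknown"}
_AFF_OUT = {"unaffected": "1", "affected": "2", "unknown": "0"}
_MISSING = {"0", "-9"}


def _f(value: float) -> float:
    """Normalize a VCF float (stored as 32-bit) to 6 significant figures so
    that write/parse cycles are exact."""
    return float(f"{float(value):.6g}")


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Structurally valid input that violates a cohort invariant."""


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    affected: str = "unknown"
    is_proband: bool = False


@dataclass(frozen=True)
class Pedigree:
    """One family; exactly one member is flagged as the proband."""

    family_id: str
    members: tuple[PedigreeMember, ...]

    def __post_init__(self) -> None:
        ids = {m.sample_id for m in self.members}
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in ids:
                    raise ValidationError(
                        f"family {self.family_id}: parent {parent!r} of "
                        f"{m.sample_id!r} is not a member of the family"
                    )
        n_prob = sum(m.is_proband for m in self.members)
        if n_prob != 1:
            raise ValidationError(
                f"family {self.family_id}: expected exactly one proband, found {n_prob}"
            )

    @property
    def proband(self) -> PedigreeMember:
        return next(m for m in self.members if m.is_proband)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(m.sample_id for m in self.members)

    def member(self, sample_id: str) -> PedigreeMember:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    @property
    def affected_members(self) -> tuple[PedigreeMember, ...]:
        return tuple(m for m in self.members if m.affected == "affected")

    def parents_of(self, member: PedigreeMember) -> tuple[PedigreeMember | None, PedigreeMember | None]:
        father = self.member(member.father_id) if member.father_id else None
        mother = self.member(member.mother_id) if member.mother_id else None
        return father, mother


def parse_ped(path: str | os.PathLike) -> list[Pedigree]:
    """Parse a 6-column PED file (optional 7th column: proband flag).

    Columns: family, sample, father, mother, sex (1/2, 0/-9 missing),
    phenotype (1 unaffected, 2 affected, 0/-9 missing). Within each family
    the proband is the member flagged in column 7 when present, otherwise
    the first affected member. A family with no affected member is rejected.
    """
    rows: dict[str, list[tuple[PedigreeMember, bool]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) not in (6, 7):
                raise ParseError(
                    f"{path}: line {lineno}: expected 6 or 7 columns, found {len(cols)}"
                )
            fam, sid, fid, mid, sex, aff = cols[:6]
            if sex not in _SEX_CODES or aff not in _AFF_CODES:
                raise ParseError(f"{path}: line {lineno}: bad sex/phenotype code")
            explicit = len(cols) == 7 and cols[6] == "1"
            member = PedigreeMember(
                sample_id=sid,
                father_id=None if fid in _MISSING else fid,
                mother_id=None if mid in _MISSING else mid,
                sex=_SEX_CODES[sex],
                affected=_AFF_CODES[aff],
            )
            rows.setdefault(fam, []).append((member, explicit))

    pedigrees = []
    for fam, members in rows.items():
        if any(flag for _, flag in members):
            chosen = next(m.sample_id for m, flag in members if flag)
        else:
            affected = [m.sample_id for m, _ in members if m.affected == "affected"]
            if not affected:
                raise ValidationError(f"family {fam}: no affected member")
            chosen = affected[0]
        pedigrees.append(
            Pedigree(
                family_id=fam,
                members=tuple(
                    replace(m, is_proband=(m.sample_id == chosen)) for m, _ in members
                ),
            )
        )
    return pedigrees


def write_ped(pedigrees: list[Pedigree], path: str | os.PathLike) -> str:
    with open(path, "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            m.sample_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            _SEX_OUT[m.sex],
                            _AFF_OUT[m.affected],
                            "1" if m.is_proband else "0",
                        ]
                    )
                    + "\n"
                )
    return str(path)


# ---------------------------------------------------------------------------
# small variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeCall:
    """Per-sample genotype with read support for one ALT allele."""

    allele_count: int
    total_reads: int = 0
    alt_reads: int = 0

    def __post_init__(self) -> None:
        if self.allele_count not in (0, 1, 2):
            raise ValidationError(f"allele_count must be 0/1/2, got {self.allele_count}")
        if self.alt_reads > self.total_reads:
            raise ValidationError("alt_reads exceeds total_reads")
        if min(self.total_reads, self.alt_reads) < 0:
            raise ValidationError("negative read counts")

    @property
    def alt_fraction(self) -> float:
        return self.alt_reads / self.total_reads if self.total_reads else 0.0


@dataclass(frozen=True)
class SmallVariantRecord:
    """One decomposed small variant (a single ALT allele) in one family."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    pop_af: float = 0.0
    qual: float = 0.0
    genotypes: tuple[tuple[str, GenotypeCall], ...] = ()
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(f"unknown consequence {self.consequence!r}")
        if not 0.0 <= self.pop_af <= 1.0:
            raise ValidationError("pop_af outside [0, 1]")

    def genotype(self, sample_id: str) -> GenotypeCall:
        for sid, call in self.genotypes:
            if sid == sample_id:
                return call
        raise KeyError(sample_id)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def is_delins(self) -> bool:
        return len(self.ref) > 1 and len(self.alt) > 1

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def _check_samples(vcf_samples: list[str], pedigree: Pedigree, path) -> None:
    vset, pset = set(vcf_samples), set(pedigree.sample_ids)
    if vset != pset:
        raise ValidationError(
            f"{path}: VCF samples {sorted(vset)} do not match pedigree "
            f"{pedigree.family_id} members {sorted(pset)}"
        )


def parse_small_vcf(path: str | os.PathLike, pedigree: Pedigree) -> list[SmallVariantRecord]:
    """Parse small variants, decomposing multi-allelic sites.

    Yields one record per ALT allele with genotypes for every pedigree
    member. A sample's allele_count counts copies of that specific ALT
    allele, so hemizygous X genotypes in males come out as 0 or 1. A
    missing POPAF is treated as 0 (novel variants must never be
    frequency-filtered by omission).
    """
    records = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        _check_samples(list(vcf.header.samples), pedigree, path)
        for rec in vcf:
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                genotypes = []
                for sid in pedigree.sample_ids:
                    s = rec.samples[sid]
                    alleles = tuple(a for a in (s.get("GT") or ()) if a is not None)
                    ad = s.get("AD")
                    alt_reads = int(ad[alt_index]) if ad and ad[alt_index] is not None else 0
                    dp = s.get("DP")
                    total = int(dp) if dp is not None else int(sum(a or 0 for a in (ad or ())))
                    genotypes.append(
                        (sid, GenotypeCall(alleles.count(alt_index), total, alt_reads))
                    )
                info = rec.info
                pop_af = info.get("POPAF")
                if isinstance(pop_af, tuple):
                    pop_af = pop_af[alt_index - 1]
                records.append(
                    SmallVariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=info.get("GENE", ""),
                        consequence=info.get("CSQCLASS", "other"),
                        pop_af=_f(pop_af) if pop_af is not None else 0.0,
                        qual=_f(rec.qual) if rec.qual is not None else 0.0,
                        genotypes=tuple(genotypes),
                        flags=frozenset({"low_complexity_region"} if info.get("LCR") else ()),
                    )
                )
    return records


_SMALL_HEADER_LINES = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Consequence class">',
    '##INFO=<ID=POPAF,Number=1,Type=Float,Description="Population allele frequency">',
    '##INFO=<ID=LCR,Number=0,Type=Flag,Description="Low-complexity region">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
]

_GT_BY_COUNT = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def _make_header(extra_lines: list[str], chroms: list[str], samples: tuple[str, ...]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in chroms:
        header.add_line(f"##contig=<ID={chrom},length=536870911>")
    for line in extra_lines:
        header.add_line(line)
    for sid in samples:
        header.add_sample(sid)
    return header


def _sorted_chroms(records) -> list[str]:
    return sorted({r.chrom for r in records})


def write_small_vcf(
    records: list[SmallVariantRecord], pedigree: Pedigree, path: str | os.PathLike
) -> str:
    """Write decomposed small-variant records; inverse of :func:`parse_small_vcf`."""
    header = _make_header(_SMALL_HEADER_LINES, _sorted_chroms(records), pedigree.sample_ids)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt), qual=r.qual
            )
            rec.info["GENE"] = r.gene
            rec.info["CSQCLASS"] = r.consequence
            rec.info["POPAF"] = r.pop_af
            if "low_complexity_region" in r.flags:
                rec.info["LCR"] = True
            for sid, call in r.genotypes:
                s = rec.samples[sid]
                s["GT"] = _GT_BY_COUNT[call.allele_count]
                s["DP"] = call.total_reads
                s["AD"] = (call.total_reads - call.alt_reads, call.alt_reads)
            out.write(rec)
    return str(path)


# ---------------------------------------------------------------------------
# structural variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructuralCall:
    """One SV/CNV call. Coordinates are 1-based inclusive; length = end-start+1.

    ``breakpoints_only`` marks rearrangements without a copy-number change
    (all inversions); such calls never enter the copy-number reporting path.
    Mosaic carriage, which GT cannot express, is carried separately.
    """

    chrom: str
    start: int
    end: int
    sv_type: str
    qual_score: float = 0.0
    carriers: frozenset[str] = frozenset()
    mosaic_carriers: frozenset[str] = frozenset()
    breakpoints_only: bool = False

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValidationError(f"unknown SV type {self.sv_type!r}")
        if self.end < self.start:
            raise ValidationError("end < start")
        if self.sv_type == "INV" and not self.breakpoints_only:
            object.__setattr__(self, "breakpoints_only", True)
        if self.qual_score < 0:
            raise ValidationError("negative quality score")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.sv_type}"


def parse_sv_vcf(path: str | os.PathLike, pedigree: Pedigree) -> list[StructuralCall]:
    """Parse SV calls (SVTYPE/END/QS dialect).

    Carriers are the samples with a non-reference GT; mosaic carriers come
    from the MOSAIC FORMAT key. Records with an SVTYPE outside DEL/DUP/INV
    are skipped; DEL/DUP without END are rejected.
    """
    calls = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        _check_samples(list(vcf.header.samples), pedigree, path)
        for rec in vcf:
            sv_type = rec.info.get("SVTYPE")
            if sv_type not in SV_TYPES:
                import warnings

                warnings.warn(f"{path}: skipping unsupported SVTYPE {sv_type!r}")
                continue
            # pysam surfaces INFO/END as rec.stop (1-based inclusive end)
            end = rec.stop
            if end <= rec.pos and sv_type in ("DEL", "DUP"):
                raise ParseError(f"{path}: {sv_type} at {rec.chrom}:{rec.pos} lacks END")
            carriers, mosaic = set(), set()
            for sid in pedigree.sample_ids:
                s = rec.samples[sid]
                if any(a for a in (s.get("GT") or ()) if a):
                    carriers.add(sid)
                if s.get("MOSAIC"):
                    mosaic.add(sid)
            qs = rec.info.get("QS")
            calls.append(
                StructuralCall(
                    chrom=rec.chrom,
                    start=rec.pos,
                    end=int(end),
                    sv_type=sv_type,
                    qual_score=_f(qs if qs is not None else (rec.qual or 0.0)),
                    carriers=frozenset(carriers),
                    mosaic_carriers=frozenset(mosaic),
                    breakpoints_only=sv_type == "INV",
                )
            )
    return calls


_SV_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">',
    '##INFO=<ID=QS,Number=1,Type=Float,Description="Call quality score">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=MOSAIC,Number=1,Type=Integer,Description="Mosaic carrier flag">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=DUP,Description="Duplication">',
    '##ALT=<ID=INV,Description="Inversion">',
]


def write_sv_vcf(
    calls: list[StructuralCall], pedigree: Pedigree, path: str | os.PathLike
) -> str:
    """Write SV calls; inverse of :func:`parse_sv_vcf`."""
    header = _make_header(_SV_HEADER_LINES, _sorted_chroms(calls), pedigree.sample_ids)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.sv_type)):
            rec = out.new_record(
                contig=c.chrom, start=c.start - 1, stop=c.end,
                alleles=("N", f"<{c.sv_type}>"),
            )
            rec.info["SVTYPE"] = c.sv_type
            rec.info["QS"] = c.qual_score
            for sid in pedigree.sample_ids:
                s = rec.samples[sid]
                s["GT"] = (0, 1) if sid in c.carriers else (0, 0)
                s["MOSAIC"] = 1 if sid in c.mosaic_carriers else 0
            out.write(rec)
    return str(path)
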