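"""CNV reporting and Tier A assignment, plus breakpoint-aware SV review.

The production copy-number path only considers DEL/DUP calls longer than
10 kb with a call quality score above 10 (both strictly), and assigns
Tier A when the call overlaps a Green gene on a panel applied to the case —
by at least one base, with mode of inheritance deliberately ignored (a
heterozygous CNV over a recessive gene is still tiered). Balanced
inversions produce no copy-number change and therefore never enter this
path at all; :func:`sv_breakpoint_review` models the researcher-grade
analysis that inspects the full rearrangement interval between the
outermost breakpoints, which does catch an inversion whose breakpoints
flank a gene.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .io import StructuralCall
from .panels import PanelAssignment, PanelRegistry
from .tiering import TIER_A, TIER_NULL, TierResult

__all__ = [
    "MIN_CNV_LENGTH",
    "MIN_CNV_QUALITY",
    "GeneSpan",
    "GeneIndex",
    "cnv_reportable",
    "assign_cnv_tier",
    "sv_breakpoint_review",
    "tier_structural_calls",
    "read_gene_bed",
    "write_gene_bed",
]

MIN_CNV_LENGTH = 10_000  # strict: length must exceed this
MIN_CNV_QUALITY = 10.0  # strict: quality score must exceed this


@dataclass(frozen=True)
class GeneSpan:
    """Coding span of one gene, 1-based inclusive."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene}: end < start")


class GeneIndex:
    """Interval lookup over gene spans (internally 0-based half-open)."""

    def __init__(self, spans: list[GeneSpan]):
        self._trees: dict[str, IntervalTree] = {}
        self._spans = {s.gene: s for s in spans}
        for s in spans:
            self._trees.setdefault(s.chrom, IntervalTree()).addi(s.start - 1, s.end, s)

    def span(self, gene: str) -> GeneSpan | None:
        return self._spans.get(gene)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneSpan]:
        """Genes intersecting the 1-based inclusive interval by >= 1 base."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start - 1, end)), key=lambda s: s.gene)


def read_gene_bed(path) -> list[GeneSpan]:
    """Read gene spans from BED (0-based half-open, converted here)."""
    spans = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name = line.split("\t")[:4]
            spans.append(GeneSpan(name, chrom, int(start) + 1, int(end)))
    return spans


def write_gene_bed(spans: list[GeneSpan], path) -> str:
    with open(path, "w") as fh:
        for s in sorted(spans, key=lambda s: (s.chrom, s.start)):
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.gene}\n")
    return str(path)


def cnv_reportable(call: StructuralCall) -> bool:
    """Whether a copy-number call enters the reporting path at all."""
    if call.sv_type == "INV":
        raise ValueError("inversions are not copy-number calls")
    return call.length > MIN_CNV_LENGTH and call.qual_score > MIN_CNV_QUALITY


def _green_overlaps(
    call: StructuralCall,
    registry: PanelRegistry,
    assignment: PanelAssignment,
    panel_version: str,
    genes: GeneIndex,
) -> list[str]:
    hits = []
    for span in genes.overlapping(call.chrom, call.start, call.end):
        if registry.is_diagnostic_grade(assignment, panel_version, span.gene):
            hits.append(span.gene)
    return hits


def assign_cnv_tier(
    call: StructuralCall,
    registry: PanelRegistry,
    assignment: PanelAssignment,
    panel_version: str,
    genes: GeneIndex,
) -> TierResult:
    """Tier A iff the reportable DEL/DUP intersects a Green gene span."""
    if not cnv_reportable(call):
        raise ValueError("call does not meet the reporting thresholds")
    hits = _green_overlaps(call, registry, assignment, panel_version, genes)
    if hits:
        return TierResult(TIER_A, tuple(f"green_gene_overlap:{g}" for g in hits))
    return TierResult(TIER_NULL, ("no_green_gene_overlap",))


def sv_breakpoint_review(
    call: StructuralCall,
    registry: PanelRegistry,
    assignment: PanelAssignment,
    panel_version: str,
    genes: GeneIndex,
) -> bool:
    """Breakpoint-aware review of any rearrangement (researcher grade).

    True when the interval between the outermost breakpoints contains or
    intersects a Green-gene span. This is a strict superset of the Tier A
    detector: every Tier A call is flagged, and so are balanced inversions
    whose breakpoints flank a Green gene.
    """
    return bool(_green_overlaps(call, registry, assignment, panel_version, genes))


def tier_structural_calls(
    calls: list[StructuralCall],
    registry: PanelRegistry,
    assignment: PanelAssignment,
    panel_version: str,
    genes: GeneIndex,
) -> list[tuple[StructuralCall, TierResult, bool]]:
    """Run the production CNV path and the breakpoint review over all calls.

    Inversions and sub-threshold calls never reach tier assignment: they
    come back Tier null with the reason recorded. The third element is the
    breakpoint-review flag, which is computed for every call.
    """
    out = []
    for call in calls:
        reviewed = sv_breakpoint_review(call, registry, assignment, panel_version, genes)
        if call.sv_type == "INV" or call.breakpoints_only:
            result = TierResult(TIER_NULL, ("no_copy_number_change",))
        elif not cnv_reportable(call):
            result = TierResult(TIER_NULL, ("below_reporting_threshold",))
        else:
            result = assign_cnv_tier(call, registry, assignment, panel_version, genes)
        out.append((call, result, reviewed))
    return out
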