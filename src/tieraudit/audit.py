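"""Cohort-level audit: diagnostic rate, syndromic contrast, missed-diagnosis
classification and loss attribution.

Missed diagnoses are classified with a number-letter code: the number gives
the reason the pipeline missed the variant (1 lost to filtering/calling,
2 gene not diagnostic grade on the applied panels, 3 untiered SV/CNV,
4 research/novel gene) and the letter the variant's inheritance (A de novo,
B biallelic, C parents unavailable, D dominant, E de novo within a
discordant multiplex sibship). A case with two contributing variants gets
one code per variant (e.g. ``1B;1B`` for a compound heterozygote with both
alleles missed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from scipy.stats import fisher_exact as _scipy_fisher

from .fixture import CohortTotals, FixtureCase
from .strategies import combine, evaluate_all, found_set, sensitivity_pct

__all__ = [
    "Box2Code",
    "AuditReport",
    "classify_missed",
    "diagnostic_rate",
    "syndromic_split",
    "fisher_exact_one_tailed",
    "loss_attribution",
    "audit_cohort",
    "render_report",
]

_SV_LIKE = ("cnv", "sv", "noncoding")
_LETTER = {
    "de_novo": "A",
    "de_novo_mosaic_parent": "A",
    "biallelic": "B",
    "parents_unavailable": "C",
    "dominant": "D",
}


@dataclass(frozen=True)
class Box2Code:
    reason: int  # 1 filtering/calling, 2 not green, 3 SV/CNV, 4 research gene
    inheritance_letter: str

    def __str__(self) -> str:
        return f"{self.reason}{self.inheritance_letter}"


def classify_missed(case: FixtureCase) -> str:
    """Number-letter code(s) for a diagnosis the baseline pipeline missed.

    Reason precedence: untiered SV/CNV first (the calling route, not the
    gene, is what failed), then research/novel gene, then a green-gene
    variant lost to filtering or calling, and otherwise a gene that was not
    diagnostic grade on the applied panels.
    """
    if case.found_by_gmc:
        raise ValueError(f"case {case.case_id} was found by the baseline pipeline")
    if case.variant_class in _SV_LIKE:
        reason = 3
    elif not case.known_dd_gene:
        reason = 4
    elif case.green_original and case.legacy_filter_dropped:
        reason = 1
    else:
        reason = 2
    letter = "E" if case.discordant_sibship else _LETTER[case.inheritance]
    code = str(Box2Code(reason, letter))
    return ";".join([code] * case.n_variants)


def diagnostic_rate(cases, totals: CohortTotals) -> float:
    """Confirmed diagnoses per recruited family, one-decimal percent."""
    if totals.n_families <= 0:
        raise ValueError("n_families must be positive")
    n = sum(1 for c in cases if c.pathogenicity != "vus")
    return round(100 * n / totals.n_families, 1)


def syndromic_split(cases, totals: CohortTotals):
    """Diagnostic rates by presentation and the 2x2 contingency table.

    Returns ``(syndromic_pct, nonsyndromic_pct, table)`` where the table is
    ``[[diagnosed_syndromic, undiagnosed_syndromic], [diagnosed_nonsyndromic,
    undiagnosed_nonsyndromic]]``. Percentages are quoted to one decimal, or
    two when below 10.
    """
    confirmed = [c for c in cases if c.pathogenicity != "vus"]
    dx_syn = sum(1 for c in confirmed if c.syndromic)
    dx_non = len(confirmed) - dx_syn
    table = [
        [dx_syn, totals.n_syndromic - dx_syn],
        [dx_non, totals.n_nonsyndromic - dx_non],
    ]

    def pct(num, den):
        x = 100 * num / den
        return round(x, 2) if x < 10 else round(x, 1)

    return pct(dx_syn, totals.n_syndromic), pct(dx_non, totals.n_nonsyndromic), table


def fisher_exact_one_tailed(table) -> float:
    """One-tailed Fisher exact p, direction fixed as "the first row is
    diagnosed more often": the hypergeometric tail over tables at least as
    extreme with margins fixed."""
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("contingency entries must be non-negative")
    return float(_scipy_fisher([[a, b], [c, d]], alternative="greater").pvalue)


def loss_attribution(cases) -> tuple[int, int]:
    """Confirmed diagnoses lost to (small-variant filtering/calling errors,
    SV/CNV prioritization failures)."""
    confirmed = [c for c in cases if c.pathogenicity != "vus"]
    loss_filtering = sum(
        1
        for c in confirmed
        if c.variant_class in ("snv", "indel") and c.legacy_filter_dropped
    )
    loss_cnv_sv = sum(
        1 for c in confirmed if c.variant_class in _SV_LIKE and c.untiered
    )
    return loss_filtering, loss_cnv_sv


@dataclass(frozen=True)
class AuditReport:
    diagnostic_rate_pct: float
    syndromic_rate_pct: float
    nonsyndromic_rate_pct: float
    fisher_p_one_tailed: float
    loss_filtering: int
    loss_cnv_sv: int
    box2_table: tuple[tuple[int, str], ...]  # (case_id, code)


def audit_cohort(cases, totals: CohortTotals) -> AuditReport:
    syn_pct, non_pct, table = syndromic_split(cases, totals)
    lf, lc = loss_attribution(cases)
    box2 = tuple(
        (c.case_id, classify_missed(c)) for c in cases if not c.found_by_gmc
    )
    return AuditReport(
        diagnostic_rate_pct=diagnostic_rate(cases, totals),
        syndromic_rate_pct=syn_pct,
        nonsyndromic_rate_pct=non_pct,
        fisher_p_one_tailed=fisher_exact_one_tailed(table),
        loss_filtering=lf,
        loss_cnv_sv=lc,
        box2_table=box2,
    )


def render_report(cases, totals: CohortTotals, strategy_ids=None) -> tuple[str, str]:
    """Deterministic JSON and human-readable renderings of the full audit.

    ``strategy_ids`` restricts the strategy table; by default every
    strategy and the printed combinations are evaluated. An empty list
    yields a baseline-only report.
    """
    report = audit_cohort(cases, totals)
    total = sum(1 for c in cases if c.pathogenicity != "vus")
    baseline = found_set("baseline_gmc", cases)

    strat_rows = []
    if strategy_ids is None:
        table = evaluate_all(cases)
        strat_rows = [
            {k: (int(v) if hasattr(v, "item") else v) for k, v in row.items()}
            for row in table.to_dict(orient="records")
        ]
    else:
        for sid in strategy_ids:
            res = combine([sid], cases)
            strat_rows.append(
                {
                    "strategy": sid,
                    "n_found": len(found_set(sid, cases)),
                    "n_union_baseline": len(res.found_case_ids),
                    "sensitivity_pct": res.sensitivity_pct,
                    "increment_pts": res.increment_pts,
                }
            )

    payload = {
        "n_confirmed_diagnoses": total,
        "baseline_sensitivity_pct": sensitivity_pct(len(baseline), total),
        "diagnostic_rate_pct": report.diagnostic_rate_pct,
        "syndromic_rate_pct": report.syndromic_rate_pct,
        "nonsyndromic_rate_pct": report.nonsyndromic_rate_pct,
        "fisher_p_one_tailed": report.fisher_p_one_tailed,
        "loss_filtering": report.loss_filtering,
        "loss_cnv_sv": report.loss_cnv_sv,
        "loss_combined_pct": sensitivity_pct(report.loss_filtering + report.loss_cnv_sv, total),
        "strategies": strat_rows,
        "box2": {str(cid): code for cid, code in report.box2_table},
    }
    as_json = json.dumps(payload, indent=1, sort_keys=True)

    lines = [
        "Diagnostic audit",
        "================",
        f"Confirmed diagnoses: {total} "
        f"({report.diagnostic_rate_pct}% of {totals.n_families} families)",
        f"Baseline sensitivity: {payload['baseline_sensitivity_pct']}% "
        f"({len(baseline)}/{total})",
        f"Syndromic rate {report.syndromic_rate_pct}% vs "
        f"non-syndromic {report.nonsyndromic_rate_pct}% "
        f"(one-tailed Fisher p = {report.fisher_p_one_tailed:.2g})",
        f"Losses: filtering/calling {report.loss_filtering}, "
        f"SV/CNV {report.loss_cnv_sv} "
        f"({payload['loss_combined_pct']}% of diagnoses combined)",
        "",
        "strategy  n_found  union  sensitivity%  +pts",
    ]
    for row in strat_rows:
        lines.append(
            f"{row['strategy']:<45s} {row['n_found']:>3d} "
            f"{row['n_union_baseline']:>5d} {row['sensitivity_pct']:>5d} "
            f"{row['increment_pts']:>+5d}"
        )
    return as_json, "\n".join(lines) + "\n"
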