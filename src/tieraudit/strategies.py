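"""Detection strategies and the diagnostic-sensitivity decomposition.

Each strategy is a predicate over case attributes describing one way a
confirmed diagnosis could have been identified: the baseline panel pipeline
plus clinic review, re-analysis on updated panels, improved calling of
genes already diagnostic grade, systematic scrutiny of de novo small
variants, review of top phenotype-driven ranks, comprehensive CNV/SV
analysis, widening the candidate set to all validated developmental-
disorder genes, and the combined national-guidance strategy. Diagnostic
sensitivity is the fraction of all confirmed (non-VUS) diagnoses a strategy
finds; combinations are unions that always include the baseline, so
sensitivity is monotone under combination. Increments are quoted for each
strategy alone against the baseline and therefore need not sum to a
combined increment (a case can be found by several strategies).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "STRATEGY_IDS",
    "StrategyResult",
    "found_set",
    "sensitivity_pct",
    "combine",
    "evaluate_all",
]

STRATEGY_IDS = (
    "baseline_gmc",
    "updated_panels",
    "improved_calling",
    "dnm_scrutiny",
    "exomiser_top3",
    "cnv_comprehensive",
    "ddg2p_wide",
    "nhse_combined",
)

_DE_NOVO = ("de_novo", "de_novo_mosaic_parent")
_SV_CLASSES = ("cnv", "sv")


def _confirmed(cases) -> list:
    return [c for c in cases if c.pathogenicity != "vus"]


def _rank_le(case, k: int) -> bool:
    return case.exomiser_rank is not None and case.exomiser_rank <= k


def found_set(strategy_id: str, cases) -> set:
    """Case ids of confirmed diagnoses the strategy identifies.

    Non-baseline strategies describe *additional* routes, so they exclude
    the baseline finds; the combined national-guidance strategy is driven
    by the per-case flag (its rule set is external guidance, recorded as
    data rather than re-derived).
    """
    confirmed = _confirmed(cases)
    if strategy_id == "baseline_gmc":
        return {c.case_id for c in confirmed if c.found_by_gmc}
    if strategy_id == "nhse_combined":
        return {c.case_id for c in confirmed if c.nhse_identifiable}
    extra = [c for c in confirmed if not c.found_by_gmc]
    if strategy_id == "updated_panels":
        return {c.case_id for c in extra if c.green_updated and not c.green_original}
    if strategy_id == "improved_calling":
        return {
            c.case_id
            for c in extra
            if c.green_original
            and (c.legacy_filter_dropped or c.variant_class in _SV_CLASSES)
        }
    if strategy_id == "dnm_scrutiny":
        return {
            c.case_id
            for c in extra
            if c.inheritance in _DE_NOVO and c.variant_class in ("snv", "indel")
        }
    if strategy_id == "exomiser_top3":
        return {c.case_id for c in extra if _rank_le(c, 3)}
    if strategy_id == "cnv_comprehensive":
        return {
            c.case_id
            for c in extra
            if c.variant_class in _SV_CLASSES and c.known_dd_gene
        }
    if strategy_id == "ddg2p_wide":
        return {c.case_id for c in extra if c.known_dd_gene}
    raise ValueError(f"unknown strategy {strategy_id!r}")


def sensitivity_pct(found: int, total: int) -> int:
    """Nearest-integer percent, rounding halves away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    x = 100 * found / total
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


@dataclass(frozen=True)
class StrategyResult:
    strategy_id: str
    found_case_ids: frozenset
    sensitivity_pct: int
    increment_pts: int


def combine(strategy_ids, cases) -> StrategyResult:
    """Union of the strategies' found-sets, always including the baseline."""
    ids = list(strategy_ids)
    if not ids:
        raise ValueError("empty strategy list")
    total = len(_confirmed(cases))
    baseline = found_set("baseline_gmc", cases)
    found = set(baseline)
    for sid in ids:
        found |= found_set(sid, cases)
    sens = sensitivity_pct(len(found), total)
    base_sens = sensitivity_pct(len(baseline), total)
    return StrategyResult(
        strategy_id="+".join(ids),
        found_case_ids=frozenset(found),
        sensitivity_pct=sens,
        increment_pts=sens - base_sens,
    )


def evaluate_all(cases) -> pd.DataFrame:
    """Each strategy alone (union with baseline) plus the printed
    combinations, as a table of found counts, sensitivities and increments."""
    rows = []
    for sid in STRATEGY_IDS:
        res = combine([sid], cases)
        rows.append(
            {
                "strategy": sid,
                "n_found": len(found_set(sid, cases)),
                "n_union_baseline": len(res.found_case_ids),
                "sensitivity_pct": res.sensitivity_pct,
                "increment_pts": res.increment_pts,
            }
        )
    for combo in (
        ("updated_panels", "improved_calling"),
        ("updated_panels", "improved_calling", "dnm_scrutiny"),
    ):
        res = combine(list(combo), cases)
        rows.append(
            {
                "strategy": "+".join(combo),
                "n_found": len(res.found_case_ids),
                "n_union_baseline": len(res.found_case_ids),
                "sensitivity_pct": res.sensitivity_pct,
                "increment_pts": res.increment_pts,
            }
        )
    return pd.DataFrame(rows)
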