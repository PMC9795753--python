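"""Headline benchmark metrics recomputed from an adjudicated cohort.

Every value here is derived at run time from pipeline outputs (categories,
scores, yield tables) — nothing is looked up. Used by the acceptance
report and its tests.
"""

from __future__ import annotations

from .adjudication import AdjudicatedProband
from .stats import (
    pct_round,
    yield_by_ancestry,
    yield_by_feature_combination,
    yield_by_score,
)

__all__ = ["compute_benchmark_metrics"]


def _metric(numerator: int, denominator: int) -> dict:
    return {"value": pct_round(numerator, denominator), "n": denominator}


def compute_benchmark_metrics(adjudicated: list[AdjudicatedProband]) -> dict[str, dict]:
    """Integer-percentage headline metrics keyed t1..t12."""
    included = [a for a in adjudicated if not a.category.startswith("excluded")]
    n = len(included)

    unsolved = [a for a in included if a.category.startswith("unsolved")]
    likely_monogenic = [
        a for a in unsolved if a.category == "unsolved_likely_monogenic"
    ]

    score_table = yield_by_score(included)
    s0 = score_table.row("0|total")
    s4 = score_table.row(">=4|total")

    feature_table = yield_by_feature_combination(included)
    fh_severe = feature_table.row("FH_severe")
    fh_young = feature_table.row("FH_young")

    uncertain = [a for a in included if a.proband.diagnosis_certainty == "uncertain"]

    tier2_pool = [
        a
        for a in included
        if a.proband.testing_provenance == "research_tier2"
        and a.category != "solved_baseline"
    ]
    tier2_solved = [a for a in tier2_pool if a.category == "solved_on_review"]

    carriers = [a for a in included if a.has_lp_p or a.has_suspicious_vus]
    diagnosis_informed = [
        a for a in carriers if a.diagnosis_change in ("changed", "clarified")
    ]

    ancestry_table, _ = yield_by_ancestry(included)
    european = ancestry_table.row("European")
    mena = ancestry_table.row("MiddleEasternNorthAfrican")

    return {
        "t1": _metric(sum(a.has_lp_p for a in included), n),
        "t2": _metric(sum(a.has_suspicious_vus for a in included), n),
        "t3": _metric(len(likely_monogenic), len(unsolved)),
        "t4": _metric(s0.n_LPP, s0.n),
        "t5": _metric(s4.n_LPP, s4.n),
        "t6": _metric(fh_severe.n_LPP, fh_severe.n),
        "t7": _metric(fh_young.n_LPP, fh_young.n),
        "t8": _metric(sum(a.has_lp_p for a in uncertain), len(uncertain)),
        "t9": _metric(len(tier2_solved), len(tier2_pool)),
        "t10": _metric(len(diagnosis_informed), len(carriers)),
        "t11": _metric(european.n_suspicious_VUS, european.n),
        "t12": _metric(mena.n_LPP, mena.n),
    }
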