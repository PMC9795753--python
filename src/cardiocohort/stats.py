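"""Stratified diagnostic-yield tables and test statistics.

Percentages are integer-rounded half-away-from-zero by default (matching
how the clinical tables are printed); both the raw count fraction and the
rounded percentage are carried so rounding never hides a mismatch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats as sps

from .adjudication import AdjudicatedProband
from .model import ANCESTRIES, SchemaError
from .score import BUCKETS

__all__ = [
    "YieldRow",
    "YieldTable",
    "TestResult",
    "pct_round",
    "yield_by_score",
    "yield_by_feature_combination",
    "yield_by_ancestry",
    "chi_squared_2x2",
    "t_test_two_sample",
    "t_test_from_summary",
    "flow_counts",
    "render_report",
]

BUCKET_LABELS = {"s0": "0", "s1": "1", "s2": "2", "s3": "3", "s4plus": ">=4"}

FEATURE_COMBOS = (
    "FH_only",
    "severe_only",
    "young_only",
    "FH_severe",
    "FH_young",
    "severe_young",
    "FH_severe_young",
)

EMPTY_PCT = "—"


def pct_round(numerator: int, denominator: int, rule: str = "half_away") -> int | None:
    """Integer percentage under the declared rounding rule; None when the
    denominator is 0."""
    if denominator == 0:
        return None
    x = 100.0 * numerator / denominator
    if rule == "half_away":
        return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
    if rule == "half_even":
        return int(round(x))
    raise SchemaError(f"unknown rounding rule {rule!r}")


@dataclass(frozen=True)
class YieldRow:
    stratum: str
    n: int
    n_LPP: int
    n_suspicious_VUS: int

    def __post_init__(self) -> None:
        if self.n_LPP + self.n_suspicious_VUS > self.n:
            raise SchemaError(
                f"stratum {self.stratum}: LP/P + suspicious VUS exceed n"
            )

    def pct_LPP(self, rule: str = "half_away") -> int | None:
        return pct_round(self.n_LPP, self.n, rule)

    def pct_suspicious_VUS(self, rule: str = "half_away") -> int | None:
        return pct_round(self.n_suspicious_VUS, self.n, rule)


@dataclass
class YieldTable:
    name: str
    rows: list[YieldRow]
    rounding: str = "half_away"
    metadata: dict = field(default_factory=dict)

    def row(self, stratum: str) -> YieldRow:
        for r in self.rows:
            if r.stratum == stratum:
                return r
        raise KeyError(stratum)

    def to_frame(self) -> pd.DataFrame:
        def render_pct(v: int | None) -> str:
            return EMPTY_PCT if v is None else str(v)

        return pd.DataFrame(
            {
                "stratum": [r.stratum for r in self.rows],
                "n": [r.n for r in self.rows],
                "n_LPP": [r.n_LPP for r in self.rows],
                "n_suspicious_VUS": [r.n_suspicious_VUS for r in self.rows],
                "pct_LPP": [render_pct(r.pct_LPP(self.rounding)) for r in self.rows],
                "pct_suspicious_VUS": [
                    render_pct(r.pct_suspicious_VUS(self.rounding)) for r in self.rows
                ],
            }
        )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    test: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise SchemaError("p_value must lie in [0, 1]")
        if self.df < 1:
            raise SchemaError("df must be >= 1")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
        }


# --------------------------------------------------------------------------
# Cohort tabulations
# --------------------------------------------------------------------------


def _included(cohort: Iterable[AdjudicatedProband]) -> list[AdjudicatedProband]:
    return [a for a in cohort if not a.category.startswith("excluded")]


def _make_row(stratum: str, members: Sequence[AdjudicatedProband]) -> YieldRow:
    return YieldRow(
        stratum=stratum,
        n=len(members),
        n_LPP=sum(1 for a in members if a.has_lp_p),
        n_suspicious_VUS=sum(1 for a in members if a.has_suspicious_vus),
    )


def yield_by_score(
    cohort: Iterable[AdjudicatedProband], rounding: str = "half_away"
) -> YieldTable:
    """One row per score bucket x {definite, uncertain, total}; stratum keys
    are e.g. ``0|total`` and ``>=4|definite``."""
    included = _included(cohort)
    rows: list[YieldRow] = []
    for bucket in BUCKETS:
        label = BUCKET_LABELS[bucket]
        in_bucket = [a for a in included if a.score.bucket == bucket]
        for certainty in ("definite", "uncertain", "total"):
            members = (
                in_bucket
                if certainty == "total"
                else [
                    a
                    for a in in_bucket
                    if a.proband.diagnosis_certainty == certainty
                ]
            )
            rows.append(_make_row(f"{label}|{certainty}", members))
    table = YieldTable("yield_by_score", rows, rounding)
    _assert_partition(table, len(included), suffix="|total")
    return table


def _combo_key(a: AdjudicatedProband) -> str | None:
    fh = a.score.family_history_points > 0
    severe = a.score.severe_points > 0
    young = a.score.age_points > 0
    parts = [name for name, flag in (("FH", fh), ("severe", severe), ("young", young)) if flag]
    return "_".join(parts) + ("_only" if len(parts) == 1 else "") if parts else None


def yield_by_feature_combination(
    cohort: Iterable[AdjudicatedProband], rounding: str = "half_away"
) -> YieldTable:
    """Yields over the seven non-empty combinations of
    {family history, severe phenotype, young onset}."""
    included = _included(cohort)
    groups: dict[str, list[AdjudicatedProband]] = {c: [] for c in FEATURE_COMBOS}
    n_none = 0
    for a in included:
        key = _combo_key(a)
        if key is None:
            n_none += 1
        else:
            groups[key].append(a)
    rows = [_make_row(combo, groups[combo]) for combo in FEATURE_COMBOS]
    table = YieldTable(
        "yield_by_feature", rows, rounding, metadata={"n_no_features": n_none}
    )
    _assert_partition(table, len(included) - n_none)
    return table


def yield_by_ancestry(
    cohort: Iterable[AdjudicatedProband], rounding: str = "half_away"
) -> tuple[YieldTable, dict[str, TestResult]]:
    """Per-ancestry yields (Unknown excluded, counted in metadata) plus a
    2x2 chi-squared of suspicious-VUS proportion for each non-European
    group against Europeans."""
    included = _included(cohort)
    known = [a for a in included if a.proband.ancestry != "Unknown"]
    n_unknown = len(included) - len(known)
    groups = {
        anc: [a for a in known if a.proband.ancestry == anc]
        for anc in ANCESTRIES
        if anc != "Unknown"
    }
    rows = [_make_row(anc, members) for anc, members in groups.items() if members]
    table = YieldTable(
        "yield_by_ancestry",
        rows,
        rounding,
        metadata={"n_unknown_ancestry": n_unknown},
    )
    _assert_partition(table, len(known))

    tests: dict[str, TestResult] = {}
    eur = groups.get("European", [])
    if eur:
        eur_svus = sum(1 for a in eur if a.has_suspicious_vus)
        for anc, members in groups.items():
            if anc == "European" or not members:
                continue
            svus = sum(1 for a in members if a.has_suspicious_vus)
            try:
                tests[f"suspicious_vus_{anc}_vs_European"] = chi_squared_2x2(
                    svus, len(members) - svus, eur_svus, len(eur) - eur_svus
                )
            except SchemaError:
                pass  # degenerate margin (e.g. no suspicious VUS anywhere)
    return table, tests


def _assert_partition(table: YieldTable, expected_n: int, suffix: str = "") -> None:
    total = sum(r.n for r in table.rows if r.stratum.endswith(suffix))
    if total != expected_n:
        raise AssertionError(
            f"{table.name}: stratum counts sum to {total}, expected {expected_n}"
        )


def flow_counts(cohort: Iterable[AdjudicatedProband]) -> dict[str, int]:
    """Flow-diagram node counts: inclusion, genetic-cause rollups and the
    unsolved split, plus per-category tallies."""
    cohort = list(cohort)
    included = _included(cohort)
    counts = {
        "total": len(cohort),
        "included": len(included),
        "lp_p": sum(1 for a in included if a.has_lp_p),
        "suspicious_vus": sum(1 for a in included if a.has_suspicious_vus),
        "unsolved": sum(1 for a in included if a.category.startswith("unsolved")),
    }
    counts["genetic_cause"] = counts["lp_p"] + counts["suspicious_vus"]
    for a in cohort:
        key = f"category_{a.category}"
        counts[key] = counts.get(key, 0) + 1
    return counts


# --------------------------------------------------------------------------
# Test statistics
# --------------------------------------------------------------------------


def chi_squared_2x2(
    a: int, b: int, c: int, d: int, continuity_correction: bool = False
) -> TestResult:
    """Pearson chi-squared for the 2x2 table [[a, b], [c, d]], df = 1.

    Continuity correction is off by default. Any zero marginal is an error.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise SchemaError("cell counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise SchemaError("empty table")
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise SchemaError("zero marginal in 2x2 table")
    delta = abs(a * d - b * c)
    if continuity_correction:
        delta = max(delta - n / 2.0, 0.0)
    statistic = n * delta * delta / (margins[0] * margins[1] * margins[2] * margins[3])
    return TestResult(
        statistic=float(statistic),
        df=1,
        p_value=float(sps.chi2.sf(statistic, 1)),
        test="chi_squared",
    )


def t_test_two_sample(
    xs: Sequence[float], ys: Sequence[float], pooled: bool = True
) -> TestResult:
    """Two-sample t-test; Student's pooled-variance form by default, Welch
    with ``pooled=False``."""
    if len(xs) < 2 or len(ys) < 2:
        raise SchemaError("each sample must have n >= 2")
    res = sps.ttest_ind(xs, ys, equal_var=pooled)
    df = (
        len(xs) + len(ys) - 2
        if pooled
        else max(1, int(math.floor(float(res.df))))
    )
    return TestResult(
        statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        test="t_test",
    )


def t_test_from_summary(
    n1: int,
    mean1: float,
    sd1: float,
    n2: int,
    mean2: float,
    sd2: float,
    pooled: bool = True,
) -> TestResult:
    """t-test from (n, mean, sd) summaries; reproduces the raw-data result
    exactly when fed that data's own summaries."""
    if n1 < 2 or n2 < 2:
        raise SchemaError("each sample must have n >= 2")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=pooled)
    if pooled:
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = max(
            1,
            int(
                math.floor(
                    (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
                )
            ),
        )
    return TestResult(
        statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        test="t_test",
    )


# --------------------------------------------------------------------------
# Report rendering
# --------------------------------------------------------------------------


def render_report(
    tables: Iterable[YieldTable],
    tests: dict[str, TestResult],
    flow: dict[str, int],
    out_dir: str | Path,
    metadata: dict | None = None,
) -> list[Path]:
    """Write deterministic TSV + JSON artefacts; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for table in tables:
        path = out_dir / f"{table.name}.tsv"
        table.to_frame().to_csv(path, sep="\t", index=False)
        written.append(path)
    tests_path = out_dir / "tests.json"
    tests_path.write_text(
        json.dumps(
            {name: t.to_dict() for name, t in sorted(tests.items())}, indent=2
        )
        + "\n",
        encoding="utf-8",
    )
    written.append(tests_path)
    flow_path = out_dir / "flow_counts.json"
    flow_path.write_text(
        json.dumps(dict(sorted(flow.items())), indent=2) + "\n", encoding="utf-8"
    )
    written.append(flow_path)
    meta = {"rounding": "half_away", "p_values": "nominal, uncorrected"}
    meta.update(metadata or {})
    meta_path = out_dir / "report_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")
    written.append(meta_path)
    return written
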