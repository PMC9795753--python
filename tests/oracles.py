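"""Independent brute-force oracles used only by the test suite.

The combiner oracle enumerates the published categorical combining table
literally as minimal qualifying patterns and asks whether any pattern is a
sub-multiset of the applied evidence — a different mechanism from the
package's threshold logic, so agreement is meaningful.
"""

from collections import Counter

from cardiocohort import EvidenceCriterion, Strength

# Minimal qualifying patterns keyed by (very_strong, strong, moderate,
# supporting) counts for the pathogenic side and (stand_alone, strong,
# supporting) for the benign side.
_PATHOGENIC_PATTERNS = [
    (1, 1, 0, 0),
    (1, 0, 2, 0),
    (1, 0, 1, 1),
    (1, 0, 0, 2),
    (2, 0, 0, 0),
    (0, 2, 0, 0),
    (0, 1, 3, 0),
    (0, 1, 2, 2),
    (0, 1, 1, 4),
]
_LIKELY_PATHOGENIC_PATTERNS = [
    (1, 0, 1, 0),
    (0, 1, 1, 0),
    (0, 1, 0, 2),
    (0, 0, 3, 0),
    (0, 0, 2, 2),
    (0, 0, 1, 4),
]
_BENIGN_PATTERNS = [(1, 0, 0), (0, 2, 0)]
_LIKELY_BENIGN_PATTERNS = [(0, 1, 1), (0, 0, 2)]


def _fits(pattern, counts):
    return all(need <= have for need, have in zip(pattern, counts))


def oracle_combine(criteria) -> str:
    """Literal-pattern implementation of the combining table."""
    path = Counter()
    benign = Counter()
    for c in criteria:
        if c.is_pathogenic_direction:
            path[c.strength] += 1
        else:
            benign[c.strength] += 1
    p_counts = (
        path[Strength.very_strong] + path[Strength.stand_alone],
        path[Strength.strong],
        path[Strength.moderate],
        path[Strength.supporting],
    )
    b_counts = (
        benign[Strength.stand_alone],
        benign[Strength.strong] + benign[Strength.very_strong],
        benign[Strength.supporting] + benign[Strength.moderate],
    )

    if any(_fits(p, p_counts) for p in _PATHOGENIC_PATTERNS):
        p_tier = "pathogenic"
    elif any(_fits(p, p_counts) for p in _LIKELY_PATHOGENIC_PATTERNS):
        p_tier = "likely_pathogenic"
    else:
        p_tier = None

    if any(_fits(p, b_counts) for p in _BENIGN_PATTERNS):
        b_tier = "benign"
    elif any(_fits(p, b_counts) for p in _LIKELY_BENIGN_PATTERNS):
        b_tier = "likely_benign"
    else:
        b_tier = None

    if p_tier and b_tier:
        return "VUS"
    return p_tier or b_tier or "VUS"


def naive_yield_tabulation(adjudicated, key):
    """Group-by tabulation with plain dicts; independent of YieldTable."""
    out = {}
    for a in adjudicated:
        if a.category.startswith("excluded"):
            continue
        k = key(a)
        if k is None:
            continue
        n, lpp, svus = out.get(k, (0, 0, 0))
        out[k] = (n + 1, lpp + int(a.has_lp_p), svus + int(a.has_suspicious_vus))
    return out


#: Evidence codes observed in suspicious-VUS and LP/P reporting, at their
#: reported strengths; the exhaustive combiner-equivalence test draws
#: multisets of distinct base codes from this pool.
OBSERVED_CODE_POOL = [
    EvidenceCriterion("PVS1", Strength.very_strong),
    EvidenceCriterion("PS1", Strength.strong),
    EvidenceCriterion("PS3", Strength.supporting),
    EvidenceCriterion("PS4", Strength.moderate),
    EvidenceCriterion("PM1", Strength.moderate),
    EvidenceCriterion("PM2", Strength.moderate),
    EvidenceCriterion("PM6", Strength.moderate),
    EvidenceCriterion("PP1", Strength.supporting),
    EvidenceCriterion("PP3", Strength.supporting),
    EvidenceCriterion("BA1", Strength.stand_alone),
    EvidenceCriterion("BS1", Strength.strong),
    EvidenceCriterion("BP4", Strength.supporting),
]
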