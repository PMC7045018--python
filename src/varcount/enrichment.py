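"""Per-locus case/control enrichment: Fisher's exact test and adjustments.

The test universe is every locus with at least one carrier in either cohort;
its size m is the number of tests for Bonferroni and Benjamini–Hochberg
adjustment. The two-sided p-value follows the probability-mass rule (sum of
the hypergeometric probabilities of all tables with the observed margins that
are no more probable than the observed one), computed in exact integer
arithmetic so tables with thousands of samples lose no precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import pandas as pd

from .counting import TranscriptCarrierSet
from .errors import ValidationError

__all__ = [
    "EnrichmentResult",
    "fisher_exact_2x2",
    "build_test_universe",
    "adjust",
    "run_enrichment",
    "results_frame",
    "write_results",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One locus's 2x2 carrier table and test results.

    Table layout: a/b = case carriers/non-carriers, c/d = control
    carriers/non-carriers. The odds ratio is the unconditional cross-product
    ratio (a*d)/(b*c), infinite when b*c = 0.
    """

    locus_id: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    p_bonferroni: float
    p_bh: float
    m: int


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple:
    """Two-sided Fisher exact test on one 2x2 table, by the probability-mass rule.

    Returns ``(odds_ratio, p)``. The p-value sums the hypergeometric
    probabilities of every table with the same margins whose probability does
    not exceed the observed table's, compared exactly on integer numerators
    over the common denominator C(n, a+b).
    """
    import operator

    try:
        a, b, c, d = (operator.index(x) for x in (a, b, c, d))
    except TypeError as exc:
        raise ValidationError("table entries must be integers") from exc
    if min(a, b, c, d) < 0:
        raise ValidationError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    if r1 == 0 or r2 == 0:
        raise ValidationError("each cohort margin must be positive")
    c1 = a + c  # carrier column margin
    n = r1 + r2
    odds_ratio = math.inf if b * c == 0 else (a * d) / (b * c)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # numerator of P(A = k) with common denominator C(n, c1)
    numers = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    observed = numers[a]
    total = sum(num for num in numers.values() if num <= observed)
    p = float(Fraction(total, math.comb(n, c1)))
    return odds_ratio, min(p, 1.0)


def build_test_universe(
    case_sets: Sequence[TranscriptCarrierSet],
    control_sets: Sequence[TranscriptCarrierSet],
) -> list:
    """Loci with >=1 carrier in either cohort, sorted; len() is the test count m."""
    loci = {cs.locus_id for cs in case_sets if cs.count > 0}
    loci |= {cs.locus_id for cs in control_sets if cs.count > 0}
    return sorted(loci)


def adjust(pvalues: Sequence[float], m: int) -> tuple:
    """Bonferroni and Benjamini–Hochberg adjusted p-values, in input order.

    Bonferroni: min(1, m*p). BH (step-up): rank p ascending, q_i = p_i * m / i,
    enforce monotone non-decreasing from the largest rank downward, cap at 1.
    ``m`` may exceed the number of supplied p-values (loci tested elsewhere in
    the universe) but not be smaller.
    """
    k = len(pvalues)
    if m < k:
        raise ValidationError(f"m = {m} is smaller than the number of p-values ({k})")
    bonferroni = [min(1.0, m * p) for p in pvalues]
    order = sorted(range(k), key=lambda i: pvalues[i])
    q = [0.0] * k
    running = 1.0
    for rank in range(k, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return bonferroni, q


def run_enrichment(
    case_sets: Sequence[TranscriptCarrierSet],
    control_sets: Sequence[TranscriptCarrierSet],
    n_cases: int,
    n_controls: int,
) -> list:
    """Fisher-test every universe locus and adjust over the universe.

    Loci carried in only one cohort get a zero in the other (they remain in
    the universe, never dropped). Results are sorted by (p, locus id).
    """
    case_counts = {cs.locus_id: cs.count for cs in case_sets}
    control_counts = {cs.locus_id: cs.count for cs in control_sets}
    universe = build_test_universe(case_sets, control_sets)
    m = len(universe)
    rows = []
    for locus in universe:
        a = case_counts.get(locus, 0)
        c = control_counts.get(locus, 0)
        if a > n_cases or c > n_controls:
            raise ValidationError(
                f"carrier count exceeds cohort size at locus {locus!r}"
            )
        odds_ratio, p = fisher_exact_2x2(a, n_cases - a, c, n_controls - c)
        rows.append((locus, a, n_cases - a, c, n_controls - c, odds_ratio, p))
    bonf, bh = adjust([r[6] for r in rows], m)
    results = [
        EnrichmentResult(locus, a, b, c, d, or_, p, pb, q, m)
        for (locus, a, b, c, d, or_, p), pb, q in zip(rows, bonf, bh)
    ]
    results.sort(key=lambda r: (r.p, r.locus_id))
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": r.locus_id,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "OR": r.odds_ratio,
                "p": r.p,
                "p_bonferroni": r.p_bonferroni,
                "p_bh": r.p_bh,
                "m": r.m,
            }
            for r in results
        ]
    )


def write_results(dest, results: Sequence[EnrichmentResult]) -> None:
    frame = results_frame(results)
    if not frame.empty:
        frame["OR"] = frame["OR"].map(
            lambda v: "Inf" if math.isinf(v) else f"{v:.6g}"
        )
    frame.to_csv(dest, sep="\t", index=False)
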