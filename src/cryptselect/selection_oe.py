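"""Observed/expected selection readout: O/E ratios, chi-square and proportion tests.

For each mutation class (an amino-acid change, a domain bin, or a bin
combination) the observed count O is compared with the count expected from
the mutational signature alone, E = p * N.  O/E > 1 indicates positive
selection, O/E < 1 negative selection.  Each class is tested class-vs-rest by
a 1-d.f. chi-square without continuity correction; the two-sample equality of
proportions uses either Fisher's exact test or the continuity-corrected
chi-square, as in the cohort comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy import stats


class OEError(ValueError):
    pass


def significance_tier(p: float) -> str:
    """Star tiers at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class OEResult:
    """Observed vs expected for one mutation class."""

    label: str
    observed: int
    n_total: int
    expected_prob: float
    expected_count: float
    oe: float | None  # None when expected is 0 (undefined, flagged)
    chi2: float | None
    p: float | None
    flags: tuple[str, ...] = ()

    @property
    def tier(self) -> str:
        return significance_tier(self.p) if self.p is not None else "ns"


def oe_table(
    observed: Mapping[str, int], expected: Mapping[str, float]
) -> list[OEResult]:
    """One O/E result per class, chi-square class-vs-rest with 1 d.f.

    chi2 = (O-E)^2/E + ((N-O)-(N-E))^2/(N-E); no continuity correction.
    Classes with zero expected probability but nonzero observed have an
    undefined O/E and are flagged 'X' (as are zero-observed classes), never
    silently dropped.
    """
    total_p = sum(expected.values())
    if abs(total_p - 1.0) > 1e-9:
        raise OEError(f"expected probabilities must sum to 1 (got {total_p})")
    n = sum(observed.values())
    if n <= 0:
        raise OEError("no observed mutations")
    results = []
    for label, p_exp in expected.items():
        o = int(observed.get(label, 0))
        e = p_exp * n
        flags = []
        if o == 0:
            flags.append("zero_observed")
        if p_exp == 0:
            flags.append("zero_expected")
            oe = None if o > 0 else 0.0
            chi2 = p = None
        else:
            oe = o / e
            rest_o, rest_e = n - o, n - e
            chi2 = (o - e) ** 2 / e
            if rest_e > 0:
                chi2 += (rest_o - rest_e) ** 2 / rest_e
            p = float(stats.chi2.sf(chi2, df=1))
        results.append(
            OEResult(
                label=label,
                observed=o,
                n_total=n,
                expected_prob=p_exp,
                expected_count=e,
                oe=oe,
                chi2=chi2,
                p=p,
                flags=tuple(flags),
            )
        )
    return results


def oe_frame(results: list[OEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class": [r.label for r in results],
            "observed": [r.observed for r in results],
            "expected_prob": [r.expected_prob for r in results],
            "expected_count": [r.expected_count for r in results],
            "oe": [r.oe for r in results],
            "chi2": [r.chi2 for r in results],
            "p": [r.p for r in results],
            "tier": [r.tier for r in results],
            "flags": [";".join(r.flags) for r in results],
        }
    )


def recurrence_filter(observed: Mapping[str, int], min_n: int) -> dict[str, int]:
    """Keep classes observed strictly more than ``min_n`` times (n > min_n)."""
    if min_n < 0:
        raise OEError("min_n must be >= 0")
    return {k: v for k, v in observed.items() if v > min_n}


def proportion_test(
    x1: int, n1: int, x2: int, n2: int, kind: str = "fisher"
) -> tuple[float, float, float]:
    """Two-sided test of equality of two proportions.

    Returns (p1, p2, p-value).  ``kind='fisher'`` uses Fisher's exact test on
    the 2x2 table; ``kind='two-proportion-continuity'`` the 1-d.f. chi-square
    with Yates continuity correction (R's prop.test).
    """
    if n1 <= 0 or n2 <= 0:
        raise OEError("sample sizes must be positive")
    if x1 > n1 or x2 > n2:
        raise OEError("successes cannot exceed trials")
    table = [[x1, n1 - x1], [x2, n2 - x2]]
    if kind == "fisher":
        _, p = stats.fisher_exact(table, alternative="two-sided")
    elif kind == "two-proportion-continuity":
        if x1 / n1 == x2 / n2:
            p = 1.0
        else:
            _, p, _, _ = stats.chi2_contingency(table, correction=True)
    else:
        raise OEError(f"unknown test kind {kind!r}")
    return x1 / n1, x2 / n2, float(p)


def log2_fc(oe: float) -> float:
    """Signed log2 fold change of an O/E ratio; 0 maps to -inf (depleted)."""
    if oe is None or oe < 0:
        raise OEError("O/E must be defined and non-negative")
    if oe == 0:
        return -math.inf
    return math.log2(oe)
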