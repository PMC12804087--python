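"""Cohort-level tumour bookkeeping and decay tests against the neutral null.

Driver-class tumour numbers are the product of the sequencing-derived class
proportions and the cohort's mean tumour count; the fraction of those tumours
remaining after a rescue protocol (relative to the priming baseline) is then
compared with the neutral crypt-drift survival fraction by a 1-d.f.
chi-square over (remaining, lost) tumour counts.  Small closed-form summaries
used throughout the cohort analyses live here too: percent reduction, lineage
clone width and the VAF-based cellularity estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats


class CohortError(ValueError):
    pass


@dataclass
class CohortSummary:
    """One cohort x protocol: tumour burden and driver-class proportions.

    Protocols: TE = priming (induce the field, then mutagenize), ET10/ET30 =
    rescue (mutagenize, induce the field 10 or 30 days later).
    """

    label: str
    protocol: str  # TE | ET10 | ET30
    mean_count: float
    sd: float = 0.0
    proportions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mean_count < 0:
            raise CohortError("mean tumour count must be >= 0")
        total = sum(self.proportions.values())
        if any(not 0 <= p <= 1 for p in self.proportions.values()) or total > 1 + 1e-9:
            raise CohortError("proportions must lie in [0,1] and sum to <= 1")


def driver_counts(summary: CohortSummary) -> dict[str, float]:
    """Per-class tumour numbers: proportion x mean tumour count."""
    return {c: p * summary.mean_count for c, p in summary.proportions.items()}


def remaining_proportion(
    te: CohortSummary, et: CohortSummary, driver: str
) -> float:
    """Fraction of a driver class remaining in the rescue protocol relative
    to the priming (TE) baseline."""
    baseline = driver_counts(te).get(driver, 0.0)
    if baseline == 0:
        raise CohortError(f"zero TE baseline for driver class {driver!r}")
    return driver_counts(et).get(driver, 0.0) / baseline


def decay_test(
    observed_count: float, te_count: float, neutral_fraction: float
) -> tuple[float, float]:
    """Chi-square (1 d.f.) of observed vs neutral-expected remaining tumours.

    Two categories (remaining, lost) so expected counts sum to the TE
    baseline: E = (f*te, (1-f)*te) against O = (obs, te-obs).
    """
    if te_count <= 0:
        raise CohortError("TE baseline count must be positive")
    if not 0 < neutral_fraction < 1:
        raise CohortError("neutral fraction must be in (0,1)")
    e_remaining = neutral_fraction * te_count
    e_lost = te_count - e_remaining
    o_remaining = observed_count
    o_lost = te_count - observed_count
    chi2 = (o_remaining - e_remaining) ** 2 / e_remaining
    chi2 += (o_lost - e_lost) ** 2 / e_lost
    return chi2, float(stats.chi2.sf(chi2, df=1))


def fold_change_vs_control(
    cohort: CohortSummary, control: CohortSummary, driver: str
) -> float:
    """Fold change in driver-class tumour numbers relative to a control."""
    base = driver_counts(control).get(driver, 0.0)
    if base <= 0:
        raise CohortError(f"control has no {driver!r}-driven tumours")
    return driver_counts(cohort).get(driver, 0.0) / base


def percent_reduction(
    rescued_mean: float, primed_mean: float, nearest_ten: bool = False
) -> int:
    """Percent reduction of tumour burden, 100*(1 - rescued/primed), rounded
    to the nearest integer (or nearest ten) percent."""
    if primed_mean <= 0:
        raise CohortError("primed mean must be positive")
    pct = 100.0 * (1.0 - rescued_mean / primed_mean)
    if nearest_ten:
        return int(round(pct / 10.0) * 10)
    return int(round(pct))


def classify_clonality(drivers: Sequence[tuple[str, str]]) -> str:
    """Classify a tumour from its driver mutations as monoclonal/polyclonal.

    ``drivers`` is a list of (gene, class) pairs.  Monoclonal: one or two
    Apc-truncating mutations (and no Ctnnb1 exon-3 hit), or exactly one
    Ctnnb1 exon-3 mutation (and no Apc truncation).  Anything else with at
    least one driver is polyclonal; no drivers is undetermined.
    """
    truncating = {"nonsense", "splice", "frameshift", "truncating"}
    apc = sum(
        1
        for g, c in drivers
        if g.lower() == "apc" and c.lower() in truncating
    )
    ctnnb1 = sum(
        1
        for g, c in drivers
        if g.lower() == "ctnnb1" and c.lower() in ("exon3", "missense")
    )
    if apc == 0 and ctnnb1 == 0:
        return "undetermined"
    if 1 <= apc <= 2 and ctnnb1 == 0:
        return "monoclonal"
    if ctnnb1 == 1 and apc == 0:
        return "monoclonal"
    return "polyclonal"


def clone_width(size_counts: Mapping[int, int]) -> float:
    """Mean lineage-tracing clone width in crypt eighths.

    ``size_counts`` maps clone size (1..8 eighths of the crypt circumference)
    to the number of clones of that size; the mean is sum(count*size)/total.
    """
    if not size_counts or sum(size_counts.values()) == 0:
        raise CohortError("no clones counted")
    if any(not 1 <= s <= 8 for s in size_counts):
        raise CohortError("clone sizes must be in 1..8 crypt eighths")
    total = sum(size_counts.values())
    return sum(s * n for s, n in size_counts.items()) / total


def cellularity(vafs: Sequence[float]) -> float:
    """Tumour cellularity estimate: 2 x mean VAF, capped at 1."""
    if len(vafs) == 0:
        raise CohortError("no VAFs supplied")
    if any(not 0 <= v <= 1 for v in vafs):
        raise CohortError("VAFs must lie in [0,1]")
    return min(1.0, 2.0 * sum(vafs) / len(vafs))
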