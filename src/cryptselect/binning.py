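"""APC truncation binning and 20-amino-acid-repeat retention scoring.

Truncating mutations of APC are classified by where they fall along the
protein: consecutive residue intervals (domain bins A..H, with B spanning the
Armadillo repeats and E the 20-amino-acid beta-catenin-binding repeats) for
the mouse analysis, and a 0-7 retention score — the number of full-length
20-amino-acid repeats preserved upstream of the truncation — for the human
analysis.  Tumours carrying two truncating hits are summarized as an
unordered bin combination; a single hit with loss of heterozygosity counts as
a homotypic pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Mapping, Sequence

import pandas as pd


class BinningError(ValueError):
    pass


@dataclass(frozen=True)
class BinInterval:
    label: str
    start: int  # 1-based inclusive
    end: int  # inclusive


@dataclass
class DomainBinScheme:
    """Ordered, contiguous, non-overlapping residue intervals."""

    intervals: tuple[BinInterval, ...]

    def __post_init__(self) -> None:
        ivs = tuple(self.intervals)
        if not ivs:
            raise BinningError("empty bin scheme")
        prev_end = 0
        for iv in ivs:
            if iv.start != prev_end + 1:
                raise BinningError(
                    f"bin {iv.label} starts at {iv.start}, expected {prev_end + 1} "
                    "(bins must be contiguous and ordered)"
                )
            if iv.end < iv.start:
                raise BinningError(f"bin {iv.label} has end < start")
            prev_end = iv.end
        self.intervals = ivs

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(iv.label for iv in self.intervals)

    def assign(self, residue: int) -> str:
        """Bin label containing the residue; 'unbinned' beyond coverage."""
        if residue < 1:
            raise BinningError("residue positions are 1-based")
        for iv in self.intervals:
            if iv.start <= residue <= iv.end:
                return iv.label
        return "unbinned"

    @classmethod
    def from_tsv(cls, path) -> "DomainBinScheme":
        df = pd.read_csv(path, sep="\t")
        return cls(
            intervals=tuple(
                BinInterval(str(r["bin"]), int(r["start"]), int(r["end"]))
                for _, r in df.iterrows()
            )
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "bin": [iv.label for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
            }
        ).to_csv(path, sep="\t", index=False)


def assign_bin(residue: int, scheme: DomainBinScheme) -> str:
    return scheme.assign(residue)


def combo_of(bin_labels: Sequence[str], loh: bool = False) -> str:
    """Unordered bin combination for a tumour's truncating hits.

    Two hits give the sorted pair; one hit with LOH is a homotypic pair; one
    hit without LOH cannot be resolved to a combination.
    """
    labels = sorted(bin_labels)
    if len(labels) == 2:
        return "".join(labels)
    if len(labels) == 1:
        if loh:
            return labels[0] * 2
        return "incomplete"
    raise BinningError("a tumour contributes 1 or 2 truncating mutations")


def combo_labels(bins: Sequence[str]) -> list[str]:
    """All unordered pairs (with repetition) over the given bins."""
    return ["".join(pair) for pair in combinations_with_replacement(sorted(bins), 2)]


def combo_expected(
    bin_probs: Mapping[str, float], multinomial_factor: bool = True
) -> dict[str, float]:
    """Expected probability of each unordered bin combination.

    Heterotypic pair XY gets 2*p(X)*p(Y) (the unordered-pair probability of a
    multinomial draw of two independent hits), homotypic XX gets p(X)^2, so
    the combinations sum to 1.  ``multinomial_factor=False`` gives the bare
    product for both.
    """
    total = sum(bin_probs.values())
    if abs(total - 1.0) > 1e-9:
        raise BinningError(f"bin probabilities must sum to 1 (got {total})")
    out = {}
    for x, y in combinations_with_replacement(sorted(bin_probs), 2):
        p = bin_probs[x] * bin_probs[y]
        if x != y and multinomial_factor:
            p *= 2
        out[x + y] = p
    return out


@dataclass
class RepeatAnnotation:
    """The seven 20-amino-acid repeats of APC as ordered residue intervals."""

    intervals: tuple[BinInterval, ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for iv in self.intervals:
            if iv.start <= prev_end:
                raise BinningError("repeat intervals must be ordered, non-overlapping")
            if iv.end < iv.start:
                raise BinningError(f"repeat {iv.label} has end < start")
            prev_end = iv.end
        if len(self.intervals) != 7:
            raise BinningError("expected exactly 7 repeat intervals")

    @classmethod
    def from_tsv(cls, path) -> "RepeatAnnotation":
        df = pd.read_csv(path, sep="\t")
        return cls(
            intervals=tuple(
                BinInterval(str(r["repeat"]), int(r["start"]), int(r["end"]))
                for _, r in df.iterrows()
            )
        )


def retention_score(residue: int, repeats: RepeatAnnotation) -> int:
    """Number of full-length 20-AA repeats wholly upstream of a truncation.

    A repeat counts only if it ends before the truncated residue; the score is
    monotone non-decreasing in the truncation position, from 0 (before repeat
    1) to 7 (downstream of all repeats).
    """
    if residue < 1:
        raise BinningError("residue positions are 1-based")
    return sum(1 for iv in repeats.intervals if iv.end < residue)


def sample_retention(residues: Sequence[int], repeats: RepeatAnnotation) -> int:
    """Retention score of a sample: the single hit, or the most C-terminal of
    two hits (the later, more downstream truncation governs)."""
    if not residues:
        raise BinningError("sample has no truncating mutation")
    if len(residues) > 2:
        raise BinningError("samples with more than two truncating hits are excluded")
    return retention_score(max(residues), repeats)
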