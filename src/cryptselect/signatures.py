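"""Trinucleotide (SBS96) mutational-signature estimation with opportunity normalization.

A single-base substitution is classed by its pyrimidine-centric substitution
(C>A, C>G, C>T, T>A, T>C, T>G) and the two flanking bases, giving the 96
COSMIC-convention channels written ``"A[C>T]G"``.  Purine-centred inputs are
reverse-complemented onto the pyrimidine strand before classing.

The per-channel mutation *rate* depends on how often the channel's source
trinucleotide occurs in the sequenced territory, so raw channel counts are
divided by trinucleotide *opportunity* counts and renormalized to sum to one.
Expected probabilities for a restricted outcome set (e.g. the substitutions
able to generate a particular set of driver changes) are obtained by
renormalizing the signature over that set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 channels in COSMIC order: substitution, then 5' flank, then 3' flank.
CHANNELS_96: tuple[str, ...] = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTIONS for f5 in BASES for f3 in BASES
)

#: The 32 pyrimidine-centric trinucleotides (centre C or T).
PYRIMIDINE_TRINUCS: tuple[str, ...] = tuple(
    f"{f5}{c}{f3}" for c in PYRIMIDINES for f5 in BASES for f3 in BASES
)


class SignatureError(ValueError):
    """Raised for inconsistent signature/opportunity inputs."""


def revcomp(seq: str) -> str:
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise SignatureError(f"non-ACGT base in {seq!r}") from exc


def fold_context(ref: str, alt: str, flank5: str, flank3: str) -> str:
    """Fold one substitution-in-context onto its pyrimidine-centric channel.

    Purine-centred inputs (ref A or G) are reverse-complemented; already
    pyrimidine-centred inputs pass through unchanged, so folding is idempotent.
    """
    ref, alt, flank5, flank3 = (b.upper() for b in (ref, alt, flank5, flank3))
    for b in (ref, alt, flank5, flank3):
        if b not in COMPLEMENT:
            raise SignatureError(f"non-ACGT base {b!r}")
    if ref == alt:
        raise SignatureError("ref and alt must differ")
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        flank5, flank3 = COMPLEMENT[flank3], COMPLEMENT[flank5]
    return f"{flank5}[{ref}>{alt}]{flank3}"


def fold_trinuc(trinuc: str) -> str:
    """Fold a trinucleotide onto the pyrimidine-centred strand."""
    trinuc = trinuc.upper()
    if len(trinuc) != 3:
        raise SignatureError(f"not a trinucleotide: {trinuc!r}")
    if trinuc[1] not in PYRIMIDINES:
        return revcomp(trinuc)
    return trinuc


def channel_trinuc(channel: str) -> str:
    """Source trinucleotide of a channel: ``"A[C>T]G" -> "ACG"``."""
    return channel[0] + channel[2] + channel[6]


def channel_parts(channel: str) -> tuple[str, str, str, str]:
    """Split a channel into (flank5, ref, alt, flank3)."""
    return channel[0], channel[2], channel[4], channel[6]


def count_opportunities(territory: Iterable[str]) -> dict[str, int]:
    """Count pyrimidine-folded trinucleotides over a set of sequences.

    Every interior position of every sequence contributes exactly one window;
    counts are additive over sequences.
    """
    counts: dict[str, int] = {}
    n_seqs = 0
    for seq in territory:
        n_seqs += 1
        seq = seq.upper()
        for i in range(len(seq) - 2):
            tri = fold_trinuc(seq[i : i + 3])
            counts[tri] = counts.get(tri, 0) + 1
    if n_seqs == 0:
        raise SignatureError("empty territory")
    return counts


@dataclass
class TrinucleotideSpectrum:
    """96-channel counts plus opportunity-normalized frequencies.

    frequency(channel) = count(channel) / opportunity(trinuc(channel)),
    renormalized to sum to 1 over channels whose trinucleotide occurs in the
    territory.  Channels with zero opportunity are dropped from normalization
    (their rate is undefined) and carry frequency 0.
    """

    counts: dict[str, float]
    opportunities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(CHANNELS_96)
        if bad:
            raise SignatureError(f"unknown channels: {sorted(bad)}")
        for ch, n in self.counts.items():
            if n < 0:
                raise SignatureError(f"negative count for {ch}")
            tri = channel_trinuc(ch)
            if n > 0 and self.opportunities and self.opportunities.get(tri, 0) <= 0:
                raise SignatureError(
                    f"channel {ch} observed but trinucleotide {tri} absent "
                    "from the territory (inconsistent opportunity table)"
                )

    @property
    def frequencies(self) -> dict[str, float]:
        raw = {}
        for ch in CHANNELS_96:
            n = self.counts.get(ch, 0.0)
            if self.opportunities:
                opp = self.opportunities.get(channel_trinuc(ch), 0.0)
                raw[ch] = n / opp if opp > 0 else 0.0
            else:
                raw[ch] = float(n)
        total = sum(raw.values())
        if total == 0:
            return {ch: 0.0 for ch in CHANNELS_96}
        return {ch: v / total for ch, v in raw.items()}

    def frequency(self, channel: str) -> float:
        return self.frequencies.get(channel, 0.0)

    def to_frame(self) -> pd.DataFrame:
        freqs = self.frequencies
        return pd.DataFrame(
            {
                "channel": CHANNELS_96,
                "count": [self.counts.get(ch, 0) for ch in CHANNELS_96],
                "opportunity": [
                    self.opportunities.get(channel_trinuc(ch), 0) for ch in CHANNELS_96
                ],
                "frequency": [freqs[ch] for ch in CHANNELS_96],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TrinucleotideSpectrum":
        df = pd.read_csv(path, sep="\t")
        counts = dict(zip(df["channel"], df["count"].astype(float)))
        opps: dict[str, float] = {}
        if "opportunity" in df.columns:
            for ch, o in zip(df["channel"], df["opportunity"].astype(float)):
                opps[channel_trinuc(ch)] = o
            if all(v == 0 for v in opps.values()):
                opps = {}
        return cls(counts={k: v for k, v in counts.items() if v > 0}, opportunities=opps)

    @classmethod
    def from_frequencies(cls, freqs: Mapping[str, float]) -> "TrinucleotideSpectrum":
        """Build a spectrum directly from (possibly unnormalized) frequencies."""
        return cls(counts={ch: float(f) for ch, f in freqs.items() if f > 0})

    @classmethod
    def uniform(cls) -> "TrinucleotideSpectrum":
        return cls(counts={ch: 1.0 for ch in CHANNELS_96})


@dataclass(frozen=True)
class ExclusionRule:
    """Exclude catalog rows by gene and (optionally) consequence class."""

    gene: str
    classes: tuple[str, ...] | None = None  # None = every consequence

    def matches(self, gene: str, mclass: str | None) -> bool:
        if str(gene).lower() != self.gene.lower():
            return False
        if self.classes is None:
            return True
        return mclass is not None and str(mclass).lower() in self.classes


#: Study defaults: high-impact Apc SNVs plus everything in the three genes with
#: evidence of selection are held out of the passenger catalog.
DEFAULT_EXCLUSIONS: tuple[ExclusionRule, ...] = (
    ExclusionRule("Apc", ("nonsense", "splice", "frameshift")),
    ExclusionRule("Ctnnb1"),
    ExclusionRule("Ros1"),
    ExclusionRule("Ntrk3"),
)


def estimate_signature(
    passengers: pd.DataFrame,
    opportunities: Mapping[str, float],
    exclusions: Sequence[ExclusionRule] = DEFAULT_EXCLUSIONS,
) -> tuple[TrinucleotideSpectrum, pd.DataFrame]:
    """Estimate the SBS96 signature from a passenger SNV catalog.

    The catalog needs either a ``channel`` column or ``ref``/``alt``/
    ``flank5``/``flank3`` columns to fold.  Rows matching an exclusion rule
    (on ``gene``/``consequence`` columns when present) are removed and
    returned alongside the spectrum.  Invariant to row order and to splitting
    the catalog into batches.
    """
    df = passengers.copy()
    if "channel" not in df.columns:
        needed = {"ref", "alt", "flank5", "flank3"}
        if not needed.issubset(df.columns):
            raise SignatureError(
                "catalog needs a 'channel' column or ref/alt/flank5/flank3 columns"
            )
        df["channel"] = [
            fold_context(r, a, f5, f3)
            for r, a, f5, f3 in zip(df["ref"], df["alt"], df["flank5"], df["flank3"])
        ]
    excluded_mask = pd.Series(False, index=df.index)
    if exclusions and "gene" in df.columns:
        cls_col = df["consequence"] if "consequence" in df.columns else None
        for idx in df.index:
            gene = df.at[idx, "gene"]
            mclass = None if cls_col is None else cls_col.at[idx]
            if any(rule.matches(gene, mclass) for rule in exclusions):
                excluded_mask.at[idx] = True
    excluded = df[excluded_mask]
    kept = df[~excluded_mask]
    counts = kept["channel"].value_counts().to_dict()
    spectrum = TrinucleotideSpectrum(
        counts={k: float(v) for k, v in counts.items()},
        opportunities=dict(opportunities),
    )
    return spectrum, excluded


def rescale_to_outcome_set(
    sig: TrinucleotideSpectrum,
    outcomes: Mapping[str, Sequence[str] | str],
) -> dict[str, float]:
    """Renormalize signature frequencies over a restricted outcome set.

    ``outcomes`` maps an outcome label to the channel (or channels) able to
    generate it.  The expected probability of each outcome is its summed
    channel frequency divided by the total over the outcome set, so results
    sum to 1 and restricting twice equals restricting once.
    """
    if not outcomes:
        raise SignatureError("empty outcome set")
    freqs = sig.frequencies
    raw = {}
    for label, chans in outcomes.items():
        if isinstance(chans, str):
            chans = [chans]
        raw[label] = sum(freqs.get(ch, 0.0) for ch in chans)
    total = sum(raw.values())
    if total == 0:
        raise SignatureError("all outcome frequencies are zero")
    return {label: v / total for label, v in raw.items()}
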