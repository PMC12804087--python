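"""Exhaustive single-nucleotide mutation enumeration with protein consequences.

Every position of a coding sequence admits three single-base substitutions;
enumerating all of them, translating the mutant codon and folding the local
trinucleotide context onto its SBS96 channel links a mutational signature to
the expected probability of any protein-level outcome — a missense driver
change or a truncation falling in a given domain bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .binning import DomainBinScheme
from .io_formats import CdsFasta
from .signatures import (
    BASES,
    SignatureError,
    TrinucleotideSpectrum,
    fold_context,
    rescale_to_outcome_set,
)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_TO_AA[_stop] = "*"


class ConsequenceError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinConsequence:
    """One possible SNV over a CDS and its protein-level effect."""

    cds_pos: int  # 1-based position on the coding strand
    ref: str
    alt: str
    residue: int  # 1-based; ceil(cds_pos / 3)
    ref_aa: str
    alt_aa: str
    mclass: str  # synonymous | missense | nonsense | other
    channel: str | None  # None when flanking context is unavailable

    @property
    def aa_change(self) -> str:
        return f"{self.ref_aa}{self.residue}{self.alt_aa}"


def _classify(residue: int, ref_aa: str, alt_aa: str) -> str:
    if ref_aa == "*":
        return "other"  # stop-loss: outside the truncation/missense analysis
    if alt_aa == "*":
        return "nonsense"
    if ref_aa == alt_aa:
        return "synonymous"
    if residue == 1:
        return "other"  # start-loss
    return "missense"


def enumerate_snvs(
    cds: CdsFasta, pad5: str = "", pad3: str = ""
) -> list[ProteinConsequence]:
    """Enumerate all 3 x len(cds) single-base substitutions over a CDS.

    Flanking bases for channel assignment come from the CDS itself; the
    terminal positions use ``pad5``/``pad3`` (genomic context adjacent to the
    CDS) when supplied and otherwise carry no channel, so no context is ever
    fabricated.
    """
    seq = cds.seq
    out: list[ProteinConsequence] = []
    for i, ref in enumerate(seq):  # i is 0-based CDS index
        cds_pos = i + 1
        residue = (i // 3) + 1
        codon_start = (residue - 1) * 3
        codon = seq[codon_start : codon_start + 3]
        within = i - codon_start
        ref_aa = _CODON_TO_AA[codon]
        flank5 = seq[i - 1] if i > 0 else (pad5[-1].upper() if pad5 else None)
        flank3 = seq[i + 1] if i < len(seq) - 1 else (pad3[0].upper() if pad3 else None)
        for alt in BASES:
            if alt == ref:
                continue
            mut_codon = codon[:within] + alt + codon[within + 1 :]
            alt_aa = _CODON_TO_AA[mut_codon]
            channel = (
                fold_context(ref, alt, flank5, flank3)
                if flank5 is not None and flank3 is not None
                else None
            )
            out.append(
                ProteinConsequence(
                    cds_pos=cds_pos,
                    ref=ref,
                    alt=alt,
                    residue=residue,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    mclass=_classify(residue, ref_aa, alt_aa),
                    channel=channel,
                )
            )
    return out


def enumeration_frame(records: Sequence[ProteinConsequence]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cds_pos": [r.cds_pos for r in records],
            "ref": [r.ref for r in records],
            "alt": [r.alt for r in records],
            "channel": [r.channel for r in records],
            "residue": [r.residue for r in records],
            "ref_aa": [r.ref_aa for r in records],
            "alt_aa": [r.alt_aa for r in records],
            "class": [r.mclass for r in records],
        }
    )


def expected_missense_probs(
    cds: CdsFasta,
    sig: TrinucleotideSpectrum,
    codons: Sequence[int],
    pad5: str = "",
    pad3: str = "",
) -> dict[str, float]:
    """Expected probability of each missense amino-acid change reachable by
    one SNV within the given codon set, under the signature.

    Each distinct change is weighted by the summed frequency of its generating
    channels, then renormalized over the reachable outcome set.
    """
    codon_set = set(codons)
    if max(codon_set, default=0) > cds.protein_length:
        raise ConsequenceError("codon set extends beyond the protein")
    outcomes: dict[str, list[str]] = {}
    for rec in enumerate_snvs(cds, pad5=pad5, pad3=pad3):
        if rec.mclass != "missense" or rec.residue not in codon_set:
            continue
        if rec.channel is None:
            continue
        outcomes.setdefault(rec.aa_change, []).append(rec.channel)
    if not outcomes:
        raise ConsequenceError("no missense outcome reachable in the codon set")
    return rescale_to_outcome_set(sig, outcomes)


def stop_mass_by_bin(
    cds: CdsFasta,
    sig: TrinucleotideSpectrum,
    bins: DomainBinScheme,
    pad5: str = "",
    pad3: str = "",
) -> dict[str, float]:
    """Unnormalized per-bin stop-gain signature mass (additive over bins)."""
    if bins.intervals[-1].end > cds.protein_length:
        # bins may legitimately end before the protein does, never after
        raise ConsequenceError(
            f"bin {bins.intervals[-1].label} extends beyond protein length "
            f"{cds.protein_length}"
        )
    freqs = sig.frequencies
    mass = {iv.label: 0.0 for iv in bins.intervals}
    for rec in enumerate_snvs(cds, pad5=pad5, pad3=pad3):
        if rec.mclass != "nonsense" or rec.channel is None:
            continue
        label = bins.assign(rec.residue)
        if label in mass:
            mass[label] += freqs.get(rec.channel, 0.0)
    return mass


def expected_stop_probs_by_bin(
    cds: CdsFasta,
    sig: TrinucleotideSpectrum,
    bins: DomainBinScheme,
    analyzed: Sequence[str] | None = None,
    pad5: str = "",
    pad3: str = "",
) -> dict[str, float]:
    """Expected probability that a signature-drawn truncating SNV lands in
    each domain bin, renormalized over the analyzed bins."""
    mass = stop_mass_by_bin(cds, sig, bins, pad5=pad5, pad3=pad3)
    if analyzed is not None:
        mass = {b: mass[b] for b in analyzed}
    total = sum(mass.values())
    if total == 0:
        raise SignatureError("no stop-generating signature mass in the analyzed bins")
    return {b: v / total for b, v in mass.items()}
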