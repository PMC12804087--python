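"""Human colorectal arm: registry filtering, repeat retention and chronology.

Registry-style tumour samples (one per donor, carrying APC-truncating
mutations) are filtered on co-occurring driver burden, stratified by KRAS
driver status, and scored for 20-amino-acid-repeat retention.  For polyp
cohorts with per-mutation read support, the order in which APC and KRAS were
mutated is inferred from VAFs: the earlier mutation occupies a larger cell
fraction, so a chronology is called when the two binomial VAF confidence
intervals are disjoint.  A supplied normal-colon trinucleotide signature
gives the expected stop-codon profile along APC against which the observed
truncation spectrum is compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .binning import RepeatAnnotation, sample_retention
from .consequence import enumerate_snvs
from .io_formats import CdsFasta
from .selection_oe import proportion_test
from .signatures import TrinucleotideSpectrum

#: Genes whose driver mutations (beyond APC and KRAS) mark hypermutant or
#: alternatively driven tumours and trigger exclusion when more than two.
DRIVER_EXCLUSION_GENES = (
    "ATM", "ARID1A", "AMER1", "BRAF", "FBXW7",
    "PTEN", "PIK3CA", "SMAD4", "SOX9", "TCF7L2",
)


class HumanApcError(ValueError):
    pass


@dataclass
class ApcMutation:
    residue: int
    mclass: str = "nonsense"
    vaf: float | None = None
    alt_reads: int | None = None
    depth: int | None = None


@dataclass
class RegistrySample:
    """One donor's tumour/polyp: APC hits, KRAS status, other drivers."""

    sample_id: str
    apc_mutations: list[ApcMutation] = field(default_factory=list)
    kras_mutant: bool = False
    kras_vaf: float | None = None
    kras_alt_reads: int | None = None
    kras_depth: int | None = None
    other_driver_genes: list[str] = field(default_factory=list)
    side: str | None = None  # right | left | rectum


@dataclass
class ChronologyCall:
    verdict: str  # APC-first | KRAS-first | unresolved
    confidence: float
    vaf_ratio: float | None  # KRAS VAF / APC VAF
    reason: str = ""


def registry_filter(
    samples: Sequence[RegistrySample],
    exclusion_genes: Sequence[str] = DRIVER_EXCLUSION_GENES,
    max_other_drivers: int = 2,
    max_apc: int = 2,
) -> tuple[list[RegistrySample], dict[str, int]]:
    """Drop samples with too many co-occurring drivers or APC hits.

    Order-independent and idempotent; returns kept samples plus per-rule
    exclusion counts (a sample may violate both rules).
    """
    gene_set = {g.upper() for g in exclusion_genes}
    counts = {"too_many_other_drivers": 0, "too_many_apc": 0, "no_apc_truncation": 0}
    kept = []
    for s in samples:
        n_other = sum(1 for g in s.other_driver_genes if g.upper() in gene_set)
        bad = False
        if n_other > max_other_drivers:
            counts["too_many_other_drivers"] += 1
            bad = True
        if len(s.apc_mutations) > max_apc:
            counts["too_many_apc"] += 1
            bad = True
        if len(s.apc_mutations) == 0:
            counts["no_apc_truncation"] += 1
            bad = True
        if not bad:
            kept.append(s)
    return kept, counts


def retention_by_kras(
    samples: Sequence[RegistrySample],
    repeats: RepeatAnnotation,
    group_by_side: bool = False,
) -> pd.DataFrame:
    """Retention-score distribution stratified by KRAS status.

    Returns one row per (stratum[, side], score 0..7) with counts and
    percentages (summing to 100 per stratum) plus the two-sided Fisher
    p-value comparing the strata at each score.
    """
    rows = []
    for s in samples:
        if not s.apc_mutations:
            continue
        score = sample_retention([m.residue for m in s.apc_mutations], repeats)
        rows.append(
            {
                "sample": s.sample_id,
                "kras": "KRAS-mutant" if s.kras_mutant else "KRAS-WT",
                "side": s.side or "all",
                "score": score,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise HumanApcError("no scorable samples")
    keys = ["side"] if group_by_side else []
    out = []
    for side_vals, sub in df.groupby(keys) if keys else [((), df)]:
        n = {k: int((sub["kras"] == k).sum()) for k in ("KRAS-mutant", "KRAS-WT")}
        for score in range(8):
            x = {
                k: int(((sub["kras"] == k) & (sub["score"] == score)).sum())
                for k in n
            }
            if n["KRAS-mutant"] > 0 and n["KRAS-WT"] > 0:
                _, _, p = proportion_test(
                    x["KRAS-mutant"], n["KRAS-mutant"], x["KRAS-WT"], n["KRAS-WT"],
                    kind="fisher",
                )
            else:
                p = float("nan")
            rec = {
                "score": score,
                "n_kras_mutant": x["KRAS-mutant"],
                "n_kras_wt": x["KRAS-WT"],
                "pct_kras_mutant": 100.0 * x["KRAS-mutant"] / n["KRAS-mutant"]
                if n["KRAS-mutant"]
                else float("nan"),
                "pct_kras_wt": 100.0 * x["KRAS-WT"] / n["KRAS-WT"]
                if n["KRAS-WT"]
                else float("nan"),
                "fisher_p": p,
            }
            if keys:
                rec["side"] = side_vals[0] if isinstance(side_vals, tuple) else side_vals
            out.append(rec)
    return pd.DataFrame(out)


def halve_loh_vaf(mutations: Sequence[ApcMutation]) -> list[ApcMutation]:
    """LOH adjustment: the highest-ranked APC mutation's VAF is halved when
    strictly above 0.5 (a hit present on both alleles reads out at twice its
    cell fraction); other mutations are untouched.

    Ranking is by VAF descending; at equal VAFs the more N-terminal mutation
    ranks first.
    """
    if not mutations:
        return []
    ranked = sorted(
        mutations,
        key=lambda m: (-(m.vaf if m.vaf is not None else -1.0), m.residue),
    )
    out = []
    for i, m in enumerate(ranked):
        vaf = m.vaf
        if i == 0 and vaf is not None and vaf > 0.5:
            vaf = vaf / 2.0
        out.append(
            ApcMutation(
                residue=m.residue,
                mclass=m.mclass,
                vaf=vaf,
                alt_reads=m.alt_reads,
                depth=m.depth,
            )
        )
    return out


def chronology_call(
    apc_vaf: float,
    apc_depth: int | None,
    kras_vaf: float,
    kras_depth: int | None,
    alpha: float = 0.05,
    method: str = "wilson",
) -> ChronologyCall:
    """Order APC and KRAS mutations from their VAFs with (1-alpha) confidence.

    Binomial confidence intervals are built from (VAF x depth, depth); the
    APC VAF must already be LOH-adjusted.  APC-first iff the APC lower bound
    exceeds the KRAS upper bound; KRAS-first for the reverse; otherwise
    unresolved.  ``method`` is 'wilson' (default) or 'beta' (Clopper-Pearson).
    """
    conf = 1 - alpha
    ratio = kras_vaf / apc_vaf if apc_vaf else None
    if apc_depth is None or kras_depth is None or apc_depth <= 0 or kras_depth <= 0:
        return ChronologyCall("unresolved", conf, ratio, reason="missing depth")
    lo_a, hi_a = proportion_confint(apc_vaf * apc_depth, apc_depth, alpha, method)
    lo_k, hi_k = proportion_confint(kras_vaf * kras_depth, kras_depth, alpha, method)
    if lo_a > hi_k:
        return ChronologyCall("APC-first", conf, ratio)
    if lo_k > hi_a:
        return ChronologyCall("KRAS-first", conf, ratio)
    return ChronologyCall("unresolved", conf, ratio, reason="overlapping intervals")


def sample_chronology(
    sample: RegistrySample, alpha: float = 0.05, method: str = "wilson"
) -> ChronologyCall:
    """Chronology call for one polyp: LOH-adjust APC VAFs, then compare the
    highest-ranked APC mutation against the KRAS mutation."""
    if not sample.apc_mutations or not sample.kras_mutant:
        return ChronologyCall("unresolved", 1 - alpha, None, reason="missing driver")
    adjusted = halve_loh_vaf(sample.apc_mutations)
    top = adjusted[0]
    if top.vaf is None or sample.kras_vaf is None:
        return ChronologyCall("unresolved", 1 - alpha, None, reason="missing VAF")
    return chronology_call(
        top.vaf, top.depth, sample.kras_vaf, sample.kras_depth, alpha, method
    )


def expected_stop_profile(
    cds: CdsFasta,
    sig: TrinucleotideSpectrum,
    n_terminal_limit: int | None = None,
    pad5: str = "",
    pad3: str = "",
) -> pd.DataFrame:
    """Expected stop-gain frequency per residue under a signature.

    Each residue's value is the summed signature frequency over the SNVs that
    convert its codon to a stop, normalized so the highest residue equals 1.
    """
    limit = n_terminal_limit or cds.protein_length
    if limit > cds.protein_length:
        raise HumanApcError("limit beyond protein length")
    freqs = sig.frequencies
    mass = np.zeros(limit)
    for rec in enumerate_snvs(cds, pad5=pad5, pad3=pad3):
        if rec.mclass != "nonsense" or rec.residue > limit or rec.channel is None:
            continue
        mass[rec.residue - 1] += freqs.get(rec.channel, 0.0)
    top = mass.max()
    return pd.DataFrame(
        {
            "residue": np.arange(1, limit + 1),
            "expected": mass / top if top > 0 else mass,
        }
    )
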