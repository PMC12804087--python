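"""Synthetic inputs with the statistical structure the analyses assume.

Every input the pipeline consumes can be generated here: SNV catalogs drawn
from a 96-channel signature over a coding sequence with injected per-outcome
selection multipliers; per-mouse tumour counts with driver-class mixtures for
the priming (TE) and rescue (ET) protocols, with rescue decay applied through
the crypt-drift model; and polyp APC/KRAS VAF read counts consistent with a
configured mutation chronology.  Generators are deterministic under their
seed and emit tables that pass the corresponding readers' invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import RepeatAnnotation
from .cohort_decay import CohortSummary
from .consequence import ProteinConsequence, enumerate_snvs
from .crypt_drift import DriftParams, neutral_fraction_at
from .human_apc import ApcMutation, RegistrySample
from .io_formats import CdsFasta, MutationTable
from .signatures import CHANNELS_96, SUBSTITUTIONS, TrinucleotideSpectrum

_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def gen_random_cds(rng: np.random.Generator, n_codons: int, gene: str = "synth") -> CdsFasta:
    """A random valid CDS: ATG, n_codons-1 random non-stop codons, one stop."""
    if n_codons < 2:
        raise ValueError("need at least 2 codons (start + one more)")
    body = rng.choice(_NONSTOP_CODONS, size=n_codons - 1)
    stop = rng.choice(sorted(_STOPS))
    return CdsFasta(gene=gene, seq="ATG" + "".join(body) + str(stop))


def enu_like_signature(rng: np.random.Generator | None = None) -> TrinucleotideSpectrum:
    """A broad alkylating-mutagen-like signature enriched for C>T, T>A and
    T>C substitutions, with mild random channel-level variation."""
    weights = {"C>A": 0.5, "C>G": 0.5, "C>T": 2.0, "T>A": 1.5, "T>C": 1.5, "T>G": 0.5}
    freqs = {}
    for ch in CHANNELS_96:
        sub = ch[2:5]
        w = weights[sub]
        if rng is not None:
            w *= rng.uniform(0.5, 1.5)
        freqs[ch] = w
    return TrinucleotideSpectrum.from_frequencies(freqs)


@dataclass
class SyntheticSpec:
    """Study conditions for the generators.

    Defaults mirror the study's shapes: a few hundred codons of coding
    sequence, thousands of signature-drawn SNVs, overdispersed tumour counts
    per mouse (negative binomial), drift decay at the small-intestinal
    parameters, and amplicon-scale polyp read depths.
    """

    seed: int = 0
    n_codons: int = 200
    n_mutations: int = 5000
    selection: dict[str, float] = field(default_factory=dict)  # aa change -> multiplier
    drift: DriftParams = field(default_factory=DriftParams)
    mean_depth: int = 500
    cohorts: list[dict] = field(default_factory=list)
    n_polyps: int = 250
    chronology_mixture: dict[str, float] = field(
        default_factory=lambda: {"APC-first": 0.35, "KRAS-first": 0.05, "synchronous": 0.60}
    )


def _outcome_weights(
    records: Sequence[ProteinConsequence],
    sig: TrinucleotideSpectrum,
    selection: Mapping[str, float],
) -> np.ndarray:
    freqs = sig.frequencies
    w = np.zeros(len(records))
    for i, rec in enumerate(records):
        if rec.channel is None:
            continue
        mult = selection.get(rec.aa_change, 1.0)
        if mult <= 0:
            raise ValueError("selection multipliers must be positive")
        w[i] = freqs.get(rec.channel, 0.0) * mult
    return w


def gen_mutation_catalog(
    cds: CdsFasta,
    sig: TrinucleotideSpectrum,
    n_mutations: int,
    seed: int,
    selection: Mapping[str, float] | None = None,
    restrict_codons: Sequence[int] | None = None,
    restrict_classes: Sequence[str] | None = None,
    gene: str = "synth",
    mutations_per_tumour: int = 10,
    dialect: str = "capture",
    mean_depth: int = 500,
) -> MutationTable:
    """Draw an SNV catalog over a CDS from a signature with injected selection.

    Each possible SNV is weighted by the signature frequency of its folded
    channel times the selection multiplier of its amino-acid change; the
    catalog is a multinomial draw over those weights.  Support fields (read
    depths, alt counts, amplicon counts, normal-panel annotations) are drawn
    so the resulting table passes the corresponding post-caller filter.
    """
    rng = np.random.default_rng(seed)
    records = enumerate_snvs(cds)
    if restrict_codons is not None:
        codon_set = set(restrict_codons)
        records = [r for r in records if r.residue in codon_set]
    if restrict_classes is not None:
        cls = set(restrict_classes)
        records = [r for r in records if r.mclass in cls]
    weights = _outcome_weights(records, sig, selection or {})
    if weights.sum() == 0:
        raise ValueError("no outcome has positive weight")
    probs = weights / weights.sum()
    draws = rng.multinomial(n_mutations, probs)
    rows = []
    i_mut = 0
    for rec, count in zip(records, draws):
        for _ in range(count):
            tumour = i_mut // mutations_per_tumour
            depth = max(1, int(rng.poisson(mean_depth)))
            true_vaf = rng.beta(5, 15)  # subclonal-to-clonal spread
            alt = min(depth, max(5, int(rng.binomial(depth, true_vaf))))
            row = {
                "sample": f"T{tumour:04d}",
                "mouse": f"M{tumour // 20:03d}",
                "chrom": "chr_synth",
                "pos": rec.cds_pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "gene": gene,
                "protein_change": f"p.{rec.aa_change}",
                "residue": rec.residue,
                "consequence": rec.mclass,
                "channel": rec.channel,
                "flank5": rec.channel[0] if rec.channel else "",
                "flank3": rec.channel[6] if rec.channel else "",
                "vaf": alt / depth,
                "alt_reads": alt,
                "depth": depth,
            }
            if dialect == "capture":
                row.update(
                    caller_pass=True,
                    snp_overlap=False,
                    germline_overlap=False,
                    alt_bq30_reads=alt,
                    normals_gapped=int(rng.integers(0, 3)),
                    mappability=1.0,
                    normals_somatic_calls=int(rng.integers(0, 2)),
                    matched_normal_vaf=0.0,
                )
            else:
                row.update(amplicons=int(rng.integers(2, 5)), caller_pass=True)
            rows.append(row)
            i_mut += 1
    df = pd.DataFrame(rows)
    return MutationTable(
        rows=df, dialect=dialect, provenance=f"synthetic seed={seed}"
    )


def gen_cohorts(
    cohorts: Sequence[Mapping],
    drift: DriftParams,
    seed: int,
) -> tuple[list[CohortSummary], pd.DataFrame]:
    """Simulate per-mouse tumour counts and per-tumour driver classes.

    Each cohort dict needs: label, protocol ('TE' or 'ETxx'), n_mice, mean,
    dispersion, mixture (driver class -> proportion) and, for rescue
    protocols, day and per-class replacement bias 'pr' (class -> pr).  TE
    counts are negative-binomial per mouse; rescue cohorts thin each TE-drawn
    tumour by the drift-model survival probability of its class at the rescue
    day, so a class with pr=0.5 decays exactly like the neutral null.
    """
    rng = np.random.default_rng(seed)
    summaries, tumour_rows = [], []
    for spec in cohorts:
        mixture = dict(spec["mixture"])
        classes = sorted(mixture)
        mix_p = np.array([mixture[c] for c in classes])
        if abs(mix_p.sum() - 1) > 1e-9:
            raise ValueError(f"mixture must sum to 1 in cohort {spec['label']}")
        day = float(spec.get("day", 0.0))
        surv = {}
        for c in classes:
            pr_c = dict(spec.get("pr", {})).get(c, 0.5)
            params_c = DriftParams(
                ns=drift.ns, lam=drift.lam, pr=pr_c, tau=drift.tau, kernel=drift.kernel
            )
            surv[c] = 1.0 if day == 0 else neutral_fraction_at(params_c, day)
        disp = float(spec.get("dispersion", 5.0))
        mean = float(spec["mean"])
        counts = []
        for mouse in range(int(spec["n_mice"])):
            n_init = rng.negative_binomial(disp, disp / (disp + mean))
            kept = 0
            for t in range(n_init):
                c = classes[rng.choice(len(classes), p=mix_p)]
                if rng.random() < surv[c]:
                    kept += 1
                    tumour_rows.append(
                        {
                            "cohort": spec["label"],
                            "protocol": spec["protocol"],
                            "mouse": f"{spec['label']}_M{mouse:02d}",
                            "driver_class": c,
                        }
                    )
            counts.append(kept)
        counts = np.array(counts, dtype=float)
        sub = [r for r in tumour_rows if r["cohort"] == spec["label"]]
        class_n = {c: sum(1 for r in sub if r["driver_class"] == c) for c in classes}
        total = max(1, sum(class_n.values()))
        summaries.append(
            CohortSummary(
                label=spec["label"],
                protocol=spec["protocol"],
                mean_count=float(counts.mean()),
                sd=float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
                proportions={c: class_n[c] / total for c in classes},
            )
        )
    return summaries, pd.DataFrame(tumour_rows)


def residue_for_score(score: int, repeats: RepeatAnnotation) -> int:
    """A truncation residue whose retention score is exactly ``score``."""
    ivs = repeats.intervals
    if not 0 <= score <= 7:
        raise ValueError("score must be in 0..7")
    if score == 0:
        return max(1, ivs[0].start - 5)
    if score == 7:
        return ivs[-1].end + 5
    return ivs[score - 1].end + 1


def gen_polyps(
    n_polyps: int,
    seed: int,
    repeats: RepeatAnnotation,
    chronology_mixture: Mapping[str, float] | None = None,
    mean_depth: int = 500,
    retention_probs: Mapping[str, Sequence[float]] | None = None,
    kras_mutant_fraction: float = 1.0,
) -> list[RegistrySample]:
    """Simulate polyps with APC/KRAS VAF read support and retention scores.

    The earlier mutation of an ordered pair occupies a larger cancer-cell
    fraction (CCF); VAF = CCF/2 for a heterozygous autosomal hit, and read
    counts are binomial at a Poisson-distributed depth.  ``retention_probs``
    maps stratum ('KRAS-mutant'/'KRAS-WT') to a length-8 score distribution.
    """
    rng = np.random.default_rng(seed)
    mixture = dict(
        chronology_mixture
        or {"APC-first": 0.35, "KRAS-first": 0.05, "synchronous": 0.60}
    )
    kinds = sorted(mixture)
    kind_p = np.array([mixture[k] for k in kinds])
    if abs(kind_p.sum() - 1) > 1e-9:
        raise ValueError("chronology mixture must sum to 1")
    default_ret = {
        "KRAS-mutant": [0.05, 0.15, 0.45, 0.15, 0.08, 0.05, 0.04, 0.03],
        "KRAS-WT": [0.10, 0.45, 0.20, 0.10, 0.05, 0.04, 0.03, 0.03],
    }
    retention_probs = {k: np.asarray(v, dtype=float) for k, v in (retention_probs or default_ret).items()}
    samples = []
    for i in range(n_polyps):
        kras_mutant = bool(rng.random() < kras_mutant_fraction)
        kind = kinds[rng.choice(len(kinds), p=kind_p)]
        if kind == "synchronous":
            ccf = rng.uniform(0.2, 0.9)
            ccf_apc = ccf_kras = ccf
        else:
            first = rng.uniform(0.5, 0.95)
            second = first * rng.uniform(0.15, 0.7)
            if kind == "APC-first":
                ccf_apc, ccf_kras = first, second
            else:
                ccf_apc, ccf_kras = second, first
        stratum = "KRAS-mutant" if kras_mutant else "KRAS-WT"
        score = int(rng.choice(8, p=retention_probs[stratum] / retention_probs[stratum].sum()))
        residue = residue_for_score(score, repeats)
        depth_a = max(1, int(rng.poisson(mean_depth)))
        depth_k = max(1, int(rng.poisson(mean_depth)))
        alt_a = int(rng.binomial(depth_a, ccf_apc / 2))
        alt_k = int(rng.binomial(depth_k, ccf_kras / 2))
        samples.append(
            RegistrySample(
                sample_id=f"P{i:04d}",
                apc_mutations=[
                    ApcMutation(
                        residue=residue,
                        mclass="nonsense",
                        vaf=alt_a / depth_a,
                        alt_reads=alt_a,
                        depth=depth_a,
                    )
                ],
                kras_mutant=kras_mutant,
                kras_vaf=alt_k / depth_k if kras_mutant else None,
                kras_alt_reads=alt_k if kras_mutant else None,
                kras_depth=depth_k if kras_mutant else None,
                other_driver_genes=[],
                side=str(rng.choice(["right", "left", "rectum"], p=[0.4, 0.45, 0.15])),
            )
        )
    return samples
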