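import math

import numpy as np
import pytest

from cryptselect import (
    ApcMutation,
    CdsFasta,
    RegistrySample,
    TrinucleotideSpectrum,
    chronology_call,
    expected_stop_profile,
    halve_loh_vaf,
    registry_filter,
    retention_by_kras,
    sample_chronology,
)
from cryptselect.synthetic_data import gen_polyps, gen_random_cds, residue_for_score


def _sample(sid="S", apc_residues=(1450,), other=(), kras=False, n_apc_vaf=None):
    return RegistrySample(
        sample_id=sid,
        apc_mutations=[ApcMutation(residue=r) for r in apc_residues],
        kras_mutant=kras,
        other_driver_genes=list(other),
    )


class TestRegistryFilter:
    def test_too_many_other_drivers_excluded(self):
        kept, counts = registry_filter([_sample(other=["ATM", "BRAF", "PTEN"])])
        assert kept == []
        assert counts["too_many_other_drivers"] == 1

    def test_too_many_apc_excluded(self):
        kept, counts = registry_filter([_sample(apc_residues=(100, 200, 300))])
        assert kept == []
        assert counts["too_many_apc"] == 1

    def test_within_limits_retained(self):
        s = _sample(apc_residues=(100, 1450), other=["SMAD4"], kras=True)
        kept, _ = registry_filter([s])
        assert kept == [s]

    def test_non_listed_genes_ignored(self):
        s = _sample(other=["TP53", "MYC", "EGFR", "SMAD4", "SOX9"])
        kept, _ = registry_filter([s])  # only 2 from the exclusion set
        assert kept == [s]

    def test_idempotent_and_order_independent(self):
        samples = [
            _sample("a"),
            _sample("b", other=["ATM", "BRAF", "PTEN"]),
            _sample("c", apc_residues=(1, 2, 3)),
        ]
        once, _ = registry_filter(samples)
        twice, counts = registry_filter(once)
        assert twice == once
        assert sum(counts.values()) == 0
        rev, _ = registry_filter(samples[::-1])
        assert {s.sample_id for s in rev} == {s.sample_id for s in once}


class TestRetentionByKras:
    def test_degenerate_strata(self, human_repeats):
        samples = [
            _sample(f"m{i}", apc_residues=(residue_for_score(2, human_repeats),), kras=True)
            for i in range(5)
        ] + [
            _sample(f"w{i}", apc_residues=(residue_for_score(1, human_repeats),))
            for i in range(5)
        ]
        df = retention_by_kras(samples, human_repeats)
        row2 = df[df["score"] == 2].iloc[0]
        row1 = df[df["score"] == 1].iloc[0]
        assert row2["pct_kras_mutant"] == 100.0 and row2["pct_kras_wt"] == 0.0
        assert row1["pct_kras_wt"] == 100.0 and row1["pct_kras_mutant"] == 0.0

    def test_percentages_sum_to_100_per_stratum(self, human_repeats):
        samples = gen_polyps(
            120, seed=5, repeats=human_repeats, kras_mutant_fraction=0.5
        )
        df = retention_by_kras(samples, human_repeats)
        assert df["pct_kras_mutant"].sum() == pytest.approx(100.0)
        assert df["pct_kras_wt"].sum() == pytest.approx(100.0)

    def test_identical_strata_fisher_p1(self, human_repeats):
        samples = [
            _sample(f"m{i}", apc_residues=(residue_for_score(3, human_repeats),), kras=(i % 2 == 0))
            for i in range(10)
        ]
        df = retention_by_kras(samples, human_repeats)
        assert df[df["score"] == 3].iloc[0]["fisher_p"] == pytest.approx(1.0)

    def test_detects_known_score_shift(self, human_repeats):
        """Strata built with a deliberate one-repeat shift give a strong
        Fisher signal at the shifted scores for a few hundred samples."""
        n = 300
        samples = [
            _sample(f"m{i}", apc_residues=(residue_for_score(2, human_repeats),), kras=True)
            for i in range(n)
        ] + [
            _sample(f"w{i}", apc_residues=(residue_for_score(1, human_repeats),))
            for i in range(n)
        ]
        df = retention_by_kras(samples, human_repeats)
        assert df[df["score"] == 2].iloc[0]["fisher_p"] < 1e-6


class TestHalveLohVaf:
    def test_top_ranked_above_half_halved(self):
        muts = [ApcMutation(100, vaf=0.8), ApcMutation(200, vaf=0.3)]
        out = halve_loh_vaf(muts)
        assert out[0].vaf == pytest.approx(0.4)
        assert out[1].vaf == pytest.approx(0.3)

    def test_exactly_half_untouched(self):
        out = halve_loh_vaf([ApcMutation(100, vaf=0.5)])
        assert out[0].vaf == 0.5

    def test_second_rank_never_halved(self):
        muts = [ApcMutation(100, vaf=0.9), ApcMutation(200, vaf=0.7)]
        out = halve_loh_vaf(muts)
        assert out[1].vaf == pytest.approx(0.7)

    def test_tie_broken_toward_n_terminal(self):
        muts = [ApcMutation(900, vaf=0.8), ApcMutation(100, vaf=0.8)]
        out = halve_loh_vaf(muts)
        assert out[0].residue == 100 and out[0].vaf == pytest.approx(0.4)
        assert out[1].vaf == pytest.approx(0.8)


class TestChronologyCall:
    def test_clear_separation_apc_first(self):
        call = chronology_call(0.40, 100, 0.05, 100)
        assert call.verdict == "APC-first"

    def test_identical_counts_unresolved(self):
        call = chronology_call(0.2, 100, 0.2, 100)
        assert call.verdict == "unresolved"

    def test_antisymmetry(self):
        fwd = chronology_call(0.40, 100, 0.05, 100)
        rev = chronology_call(0.05, 100, 0.40, 100)
        assert fwd.verdict == "APC-first" and rev.verdict == "KRAS-first"

    def test_missing_depth_unresolved(self):
        call = chronology_call(0.4, None, 0.05, 100)
        assert call.verdict == "unresolved" and "depth" in call.reason

    def test_null_calibration(self, rng):
        """Equal true VAFs: a verdict is called at most ~alpha of the time."""
        alpha, reps, depth, vaf = 0.05, 800, 200, 0.25
        called = 0
        for _ in range(reps):
            a = rng.binomial(depth, vaf) / depth
            k = rng.binomial(depth, vaf) / depth
            if chronology_call(a, depth, k, depth, alpha).verdict != "unresolved":
                called += 1
        rate = called / reps
        # two independent (1-alpha) intervals disjoint under the null less
        # often than alpha; allow 3 binomial SEs above alpha
        assert rate <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / reps)

    def test_sample_chronology_uses_loh_adjusted_top_hit(self):
        s = RegistrySample(
            sample_id="p",
            apc_mutations=[ApcMutation(1300, vaf=0.9, depth=400)],
            kras_mutant=True,
            kras_vaf=0.1,
            kras_depth=400,
        )
        call = sample_chronology(s)
        # 0.9 halves to 0.45, still clearly above 0.1
        assert call.verdict == "APC-first"


class TestExpectedStopProfile:
    def test_no_stop_codon_possible_gives_zero(self, uniform_sig):
        # codon 2 AAA: only A>T at position 1 (TAA)? A->T at cds 4 gives TAA;
        # use CCC which admits no single-base stop
        cds = CdsFasta(gene="g", seq="ATGCCCTGGTAA")
        prof = expected_stop_profile(cds, uniform_sig)
        assert prof.loc[prof["residue"] == 2, "expected"].iloc[0] == 0.0

    def test_uniform_signature_counts_stop_paths(self, uniform_sig):
        cds = CdsFasta(gene="g", seq="ATGCAATGGTAA")
        prof = expected_stop_profile(cds, uniform_sig)
        e2 = prof.loc[prof["residue"] == 2, "expected"].iloc[0]
        e3 = prof.loc[prof["residue"] == 3, "expected"].iloc[0]
        # TGG has 2 stop paths, CAA has 1; profile normalized to max = 1
        assert e3 == pytest.approx(1.0)
        assert e2 == pytest.approx(0.5)

    def test_cpg_weighted_signature_favours_cga_codons(self):
        # CGA -> TGA by C>T at a CpG; weight that channel heavily
        cds = CdsFasta(gene="g", seq="ATGCGAAAGCAATAA")
        sig = TrinucleotideSpectrum.from_frequencies(
            {ch: (50.0 if ch[2:5] == "C>T" and ch[6] == "G" else 0.1)
             for ch in __import__("cryptselect").CHANNELS_96}
        )
        prof = expected_stop_profile(cds, sig)
        best = prof.loc[prof["expected"].idxmax(), "residue"]
        assert best == 2  # the CGA codon dominates
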