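import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from cryptselect import (
    CdsFasta,
    DomainBinScheme,
    enumerate_snvs,
    expected_missense_probs,
    expected_stop_probs_by_bin,
)
from cryptselect.binning import BinInterval
from cryptselect.consequence import ConsequenceError, stop_mass_by_bin
from cryptselect.synthetic_data import gen_random_cds
import numpy as np


def brute_force_consequences(cds: CdsFasta):
    """Independent oracle: mutate the full CDS, re-translate everything."""
    out = {}
    ref_protein = str(Seq(cds.seq).translate())
    for i in range(len(cds.seq)):
        for alt in "ACGT":
            if alt == cds.seq[i]:
                continue
            mutant = cds.seq[:i] + alt + cds.seq[i + 1 :]
            prot = str(Seq(mutant).translate())
            residue = i // 3 + 1
            ref_aa, alt_aa = ref_protein[residue - 1], prot[residue - 1]
            if ref_aa == "*":
                mclass = "other"
            elif alt_aa == "*":
                mclass = "nonsense"
            elif ref_aa == alt_aa:
                mclass = "synonymous"
            elif residue == 1:
                mclass = "other"
            else:
                mclass = "missense"
            out[(i + 1, alt)] = (residue, ref_aa, alt_aa, mclass)
    return out


class TestEnumerateSnvs:
    def test_record_count_is_three_per_position(self):
        cds = CdsFasta(gene="g", seq="ATGCAATGGTAA")
        recs = enumerate_snvs(cds)
        assert len(recs) == 3 * len(cds.seq)
        per_pos = {}
        for r in recs:
            per_pos[r.cds_pos] = per_pos.get(r.cds_pos, 0) + 1
        assert set(per_pos.values()) == {3}

    def test_trp_codon_has_two_nonsense_outcomes(self):
        # TGG at residue 3 of ATG CAA TGG TAA -> TAG and TGA
        cds = CdsFasta(gene="g", seq="ATGCAATGGTAA")
        stops = [r for r in enumerate_snvs(cds) if r.mclass == "nonsense" and r.residue == 3]
        assert sorted(r.alt_aa for r in stops) == ["*", "*"]
        assert len(stops) == 2

    def test_caa_codon_single_nonsense_via_c_to_t(self):
        cds = CdsFasta(gene="g", seq="ATGCAATGGTAA")
        stops = [r for r in enumerate_snvs(cds) if r.mclass == "nonsense" and r.residue == 2]
        assert len(stops) == 1
        assert (stops[0].ref, stops[0].alt) == ("C", "T")

    def test_degron_codon_t41i_channel(self):
        # residue 41 carries ACC; the middle C>T is p.T41I in channel A[C>T]C
        seq = "ATG" + "GCT" * 39 + "ACC" + "GCT" * 5 + "TAA"
        cds = CdsFasta(gene="Ctnnb1", seq=seq)
        hits = [
            r
            for r in enumerate_snvs(cds)
            if r.residue == 41 and r.ref == "C" and r.alt == "T" and r.alt_aa == "I"
        ]
        assert len(hits) == 1
        assert hits[0].aa_change == "T41I"
        assert hits[0].channel == "A[C>T]C"

    def test_terminal_positions_lack_channel_unless_padded(self):
        cds = CdsFasta(gene="g", seq="ATGAAATAA")
        recs = enumerate_snvs(cds)
        assert all(r.channel is None for r in recs if r.cds_pos in (1, len(cds.seq)))
        padded = enumerate_snvs(cds, pad5="T", pad3="G")
        assert all(r.channel is not None for r in padded)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_retranslation(self, seed):
        cds = gen_random_cds(np.random.default_rng(seed), n_codons=int(3 + seed % 30))
        oracle = brute_force_consequences(cds)
        recs = enumerate_snvs(cds)
        assert len(recs) == len(oracle)
        for r in recs:
            assert oracle[(r.cds_pos, r.alt)] == (r.residue, r.ref_aa, r.alt_aa, r.mclass)


class TestExpectedMissense:
    def test_i35s_is_reachable(self, uniform_sig):
        # ATC (Ile) at residue 35; ATC->AGC gives I>S
        seq = "ATG" + "GCT" * 33 + "ATC" + "GCT" * 5 + "TAA"
        cds = CdsFasta(gene="Ctnnb1", seq=seq)
        probs = expected_missense_probs(cds, uniform_sig, codons=[35])
        assert "I35S" in probs
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_point_mass_signature_forces_single_outcome(self):
        from cryptselect import TrinucleotideSpectrum

        seq = "ATG" + "GCT" * 39 + "ACC" + "GCT" * 5 + "TAA"
        cds = CdsFasta(gene="g", seq=seq)
        sig = TrinucleotideSpectrum.from_frequencies({"A[C>T]C": 1.0})
        probs = expected_missense_probs(cds, sig, codons=[41])
        assert probs["T41I"] == 1.0
        assert all(v == 0.0 for k, v in probs.items() if k != "T41I")

    def test_two_codon_cds_matches_hand_enumeration(self, uniform_sig):
        # CDS: ATG AAA CCC TAA; codons 2-3 admit 18 SNVs total
        cds = CdsFasta(gene="g", seq="ATGAAACCCTAA")
        probs = expected_missense_probs(cds, uniform_sig, codons=[2, 3])
        recs = [
            r
            for r in enumerate_snvs(cds)
            if r.residue in (2, 3) and r.mclass == "missense" and r.channel
        ]
        by_change = {}
        for r in recs:
            by_change[r.aa_change] = by_change.get(r.aa_change, 0) + 1
        total = sum(by_change.values())
        assert probs == pytest.approx({k: v / total for k, v in by_change.items()})


class TestExpectedStopByBin:
    def _scheme(self):
        return DomainBinScheme(
            intervals=(
                BinInterval("A", 1, 1),
                BinInterval("B", 2, 2),
                BinInterval("C", 3, 3),
            )
        )

    def test_toy_cds_one_vs_two_stop_paths(self, uniform_sig):
        cds = CdsFasta(gene="g", seq="ATGCAATGGTAA")
        probs = expected_stop_probs_by_bin(
            cds, uniform_sig, self._scheme(), analyzed=["B", "C"]
        )
        assert probs == pytest.approx({"B": 1 / 3, "C": 2 / 3})

    def test_zero_mass_bin(self):
        from cryptselect import TrinucleotideSpectrum

        cds = CdsFasta(gene="g", seq="ATGCAATGGTAA")
        # all signature mass on the TGG->TGA generating channel (G>A center,
        # folded): codon 3 only
        recs = [
            r for r in enumerate_snvs(cds) if r.mclass == "nonsense" and r.residue == 3
        ]
        sig = TrinucleotideSpectrum.from_frequencies({recs[0].channel: 1.0})
        probs = expected_stop_probs_by_bin(cds, sig, self._scheme(), analyzed=["B", "C"])
        assert probs["B"] == 0.0 and probs["C"] == 1.0

    def test_bin_mass_additive_under_merging(self, uniform_sig, rng):
        cds = gen_random_cds(rng, n_codons=40)
        split = DomainBinScheme(
            intervals=(BinInterval("X", 1, 10), BinInterval("Y", 11, 25))
        )
        merged = DomainBinScheme(intervals=(BinInterval("XY", 1, 25),))
        m_split = stop_mass_by_bin(cds, uniform_sig, split)
        m_merged = stop_mass_by_bin(cds, uniform_sig, merged)
        assert m_split["X"] + m_split["Y"] == pytest.approx(m_merged["XY"])

    def test_bin_beyond_protein_errors(self, uniform_sig):
        cds = CdsFasta(gene="g", seq="ATGCAATGGTAA")
        too_long = DomainBinScheme(intervals=(BinInterval("A", 1, 10),))
        with pytest.raises(ConsequenceError):
            expected_stop_probs_by_bin(cds, uniform_sig, too_long)
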