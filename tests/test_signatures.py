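import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cryptselect import (
    CHANNELS_96,
    TrinucleotideSpectrum,
    count_opportunities,
    estimate_signature,
    fold_context,
    rescale_to_outcome_set,
)
from cryptselect.signatures import (
    PYRIMIDINE_TRINUCS,
    SignatureError,
    channel_parts,
    channel_trinuc,
    revcomp,
)

bases = st.sampled_from("ACGT")


class TestFoldContext:
    def test_pyrimidine_center_unchanged(self):
        assert fold_context("C", "T", "A", "C") == "A[C>T]C"

    def test_purine_center_reverse_complemented(self):
        assert fold_context("G", "A", "T", "A") == "T[C>T]A"

    @given(ref=bases, alt=bases, f5=bases, f3=bases)
    @settings(max_examples=200, derandomize=True)
    def test_folding_idempotent_and_pyrimidine(self, ref, alt, f5, f3):
        if ref == alt:
            return
        ch = fold_context(ref, alt, f5, f3)
        f5b, refb, altb, f3b = channel_parts(ch)
        assert refb in "CT"
        assert fold_context(refb, altb, f5b, f3b) == ch

    def test_non_acgt_rejected(self):
        with pytest.raises(SignatureError):
            fold_context("N", "T", "A", "C")
        with pytest.raises(SignatureError):
            fold_context("C", "C", "A", "C")


class TestOpportunities:
    def test_enumerated_windows(self):
        # ACT (kept), CTG (already pyrimidine-centred), TGA (folds to TCA)
        assert count_opportunities(["ACTGA"]) == {"ACT": 1, "CTG": 1, "TCA": 1}

    def test_purine_homopolymer_folds(self):
        assert count_opportunities(["AAA"]) == {"TTT": 1}

    def test_additive_over_sequences(self):
        one = count_opportunities(["ACGTACGT"])
        two = count_opportunities(["ACGTACGT", "ACGTACGT"])
        assert two == {k: 2 * v for k, v in one.items()}

    def test_empty_territory_errors(self):
        with pytest.raises(SignatureError):
            count_opportunities([])

    @given(st.text(alphabet="ACGT", min_size=3, max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_revcomp_invariance(self, seq):
        assert count_opportunities([seq]) == count_opportunities([revcomp(seq)])


class TestSpectrum:
    def test_opportunity_normalization_arithmetic(self):
        x, y = "A[C>T]A", "A[T>C]A"
        sig = TrinucleotideSpectrum(
            counts={x: 10, y: 10},
            opportunities={channel_trinuc(x): 100, channel_trinuc(y): 50},
        )
        f = sig.frequencies
        assert f[x] == pytest.approx(1 / 3) and f[y] == pytest.approx(2 / 3)

    def test_single_channel_mass(self):
        sig = TrinucleotideSpectrum(counts={"A[C>T]G": 5})
        assert sig.frequency("A[C>T]G") == 1.0

    def test_frequencies_sum_to_one(self):
        sig = TrinucleotideSpectrum(counts={ch: i + 1 for i, ch in enumerate(CHANNELS_96)})
        assert sum(sig.frequencies.values()) == pytest.approx(1.0)

    def test_inconsistent_territory_errors(self):
        with pytest.raises(SignatureError, match="inconsistent"):
            TrinucleotideSpectrum(counts={"A[C>T]G": 3}, opportunities={"TTT": 5})

    def test_tsv_round_trip(self, tmp_path):
        sig = TrinucleotideSpectrum(
            counts={"A[C>T]G": 3, "T[T>A]T": 7},
            opportunities={t: 10 for t in PYRIMIDINE_TRINUCS},
        )
        sig.to_tsv(tmp_path / "sig.tsv")
        back = TrinucleotideSpectrum.from_tsv(tmp_path / "sig.tsv")
        assert back.frequencies == pytest.approx(sig.frequencies)


class TestEstimateSignature:
    def _catalog(self, channels, gene="passenger", consequence="missense"):
        rows = []
        for ch in channels:
            f5, ref, alt, f3 = channel_parts(ch)
            rows.append(
                dict(ref=ref, alt=alt, flank5=f5, flank3=f3, gene=gene, consequence=consequence)
            )
        return pd.DataFrame(rows)

    def test_exclusion_rules_applied(self):
        df = pd.concat(
            [
                self._catalog(["A[C>T]G"] * 4, gene="Psg1"),
                self._catalog(["T[T>A]T"] * 4, gene="Ctnnb1"),
                self._catalog(["T[T>C]T"] * 4, gene="Apc", consequence="nonsense"),
                self._catalog(["T[T>C]T"] * 2, gene="Apc", consequence="missense"),
            ],
            ignore_index=True,
        )
        opps = {t: 100 for t in PYRIMIDINE_TRINUCS}
        sig, excluded = estimate_signature(df, opps)
        # all Ctnnb1 rows and high-impact Apc rows are held out
        assert len(excluded) == 8
        assert sig.counts == {"A[C>T]G": 4, "T[T>C]T": 2}

    def test_batch_and_order_invariance(self, rng):
        channels = list(rng.choice(CHANNELS_96, size=200))
        df = self._catalog(channels)
        opps = {t: 50 for t in PYRIMIDINE_TRINUCS}
        whole, _ = estimate_signature(df, opps, exclusions=())
        shuffled, _ = estimate_signature(
            df.sample(frac=1.0, random_state=1), opps, exclusions=()
        )
        assert whole.frequencies == pytest.approx(shuffled.frequencies)
        a, _ = estimate_signature(df.iloc[:90], opps, exclusions=())
        b, _ = estimate_signature(df.iloc[90:], opps, exclusions=())
        merged = TrinucleotideSpectrum(
            counts={
                ch: a.counts.get(ch, 0) + b.counts.get(ch, 0) for ch in CHANNELS_96
            },
            opportunities=opps,
        )
        assert merged.frequencies == pytest.approx(whole.frequencies)

    def test_simulation_recovery_within_three_ses(self, rng):
        """10,000 SNVs drawn from a known signature over a known territory are
        re-estimated within 3 binomial SEs per channel."""
        true_freq = rng.dirichlet(np.full(96, 2.0))
        opps = {t: int(o) for t, o in zip(PYRIMIDINE_TRINUCS, rng.integers(50, 500, 32))}
        # draw probability per channel folds opportunity back in
        draw_p = np.array(
            [f * opps[channel_trinuc(ch)] for f, ch in zip(true_freq, CHANNELS_96)]
        )
        draw_p /= draw_p.sum()
        n = 10_000
        counts = rng.multinomial(n, draw_p)
        df = self._catalog(
            [ch for ch, c in zip(CHANNELS_96, counts) for _ in range(c)]
        )
        est, _ = estimate_signature(df, opps, exclusions=())
        est_f = np.array([est.frequency(ch) for ch in CHANNELS_96])
        se = np.sqrt(draw_p * (1 - draw_p) / n)
        # propagate the count SE through the (linear) opportunity rescaling
        opp = np.array([opps[channel_trinuc(ch)] for ch in CHANNELS_96])
        norm = (counts / opp).sum()
        assert np.all(np.abs(est_f - true_freq / (true_freq.sum())) < 3 * se * n / (norm * opp) + 1e-12)


class TestRescale:
    def test_renormalization(self):
        sig = TrinucleotideSpectrum.from_frequencies(
            {"A[C>T]A": 0.02, "A[C>T]C": 0.02, "A[C>T]G": 0.01}
        )
        out = rescale_to_outcome_set(
            sig, {"x": "A[C>T]A", "y": "A[C>T]C", "z": "A[C>T]G"}
        )
        assert out == pytest.approx({"x": 0.4, "y": 0.4, "z": 0.2})

    def test_single_outcome_is_certain(self, uniform_sig):
        assert rescale_to_outcome_set(uniform_sig, {"only": "T[T>G]T"}) == {"only": 1.0}

    def test_projective_consistency(self, uniform_sig):
        outcomes = {"a": "A[C>A]A", "b": "A[C>G]A", "c": "A[C>T]A"}
        once = rescale_to_outcome_set(uniform_sig, {k: outcomes[k] for k in ("a", "b")})
        sub_sig = TrinucleotideSpectrum.from_frequencies(
            {outcomes[k]: rescale_to_outcome_set(uniform_sig, outcomes)[k] for k in outcomes}
        )
        twice = rescale_to_outcome_set(sub_sig, {k: outcomes[k] for k in ("a", "b")})
        assert once == pytest.approx(twice)

    def test_zero_mass_outcomes_error(self):
        sig = TrinucleotideSpectrum.from_frequencies({"A[C>T]A": 1.0})
        with pytest.raises(SignatureError):
            rescale_to_outcome_set(sig, {"x": "T[T>G]T"})
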