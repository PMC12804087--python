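import numpy as np
import pandas as pd
import pytest

from cryptselect import (
    CdsFasta,
    DomainBinScheme,
    MutationTable,
    RepeatAnnotation,
    TrinucleotideSpectrum,
    default_data_path,
)


@pytest.fixture
def uniform_sig() -> TrinucleotideSpectrum:
    return TrinucleotideSpectrum.uniform()


@pytest.fixture
def mouse_bins() -> DomainBinScheme:
    return DomainBinScheme.from_tsv(default_data_path("mouse_apc_bins.tsv"))


@pytest.fixture
def human_repeats() -> RepeatAnnotation:
    return RepeatAnnotation.from_tsv(default_data_path("human_apc_20aa_repeats.tsv"))


@pytest.fixture
def colon_sig() -> TrinucleotideSpectrum:
    return TrinucleotideSpectrum.from_tsv(
        default_data_path("colon_signature_synthetic.tsv")
    )


def _capture_row(**over):
    row = dict(
        sample="T1",
        mouse="M1",
        chrom="chr1",
        pos=100,
        ref="C",
        alt="T",
        gene="g",
        vaf=0.3,
        caller_pass=True,
        snp_overlap=False,
        germline_overlap=False,
        alt_reads=10,
        alt_bq30_reads=10,
        normals_gapped=0,
        mappability=1.0,
        normals_somatic_calls=0,
        matched_normal_vaf=0.0,
    )
    row.update(over)
    return row


@pytest.fixture
def capture_toy_table() -> MutationTable:
    """Six rows: one clean, one violating each of the support rules.

    Hand-derived survivors: only the clean row passes every predicate.
    """
    rows = [
        _capture_row(pos=1),  # clean
        _capture_row(pos=2, alt_reads=1, alt_bq30_reads=1),  # alt_support
        _capture_row(pos=3, normals_gapped=4),  # gapped_normals
        _capture_row(pos=4, mappability=0.8),  # mappability
        _capture_row(pos=5, normals_somatic_calls=2),  # somatic_normals
        # recurrent in two mice with max VAF <= 0.05
        _capture_row(pos=6, sample="T1", mouse="M1", vaf=0.03),
        _capture_row(pos=6, sample="T9", mouse="M2", vaf=0.04),
    ]
    return MutationTable(rows=pd.DataFrame(rows), dialect="capture")


@pytest.fixture
def amplicon_toy_table() -> MutationTable:
    """Four rows with AFs {0.005, 0.01, 0.5, 0.2}; all else passing."""
    rows = [
        dict(
            sample="T1",
            chrom="chr1",
            pos=p,
            ref="C",
            alt="T",
            vaf=af,
            alt_reads=20,
            amplicons=3,
            caller_pass=True,
        )
        for p, af in enumerate([0.005, 0.01, 0.5, 0.2], start=1)
    ]
    return MutationTable(rows=pd.DataFrame(rows), dialect="amplicon")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
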