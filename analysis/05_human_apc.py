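#!/usr/bin/env python
"""Human-arm analyses on the simulated polyp cohort.

Scores 20-amino-acid-repeat retention stratified by KRAS status, calls the
APC/KRAS mutation chronology from VAF confidence intervals, and writes the
expected stop-codon profile of the synthetic CDS under the packaged
(synthetic, SBS1-dominant) normal-colon signature.
"""

import argparse
from pathlib import Path

import pandas as pd

from cryptselect import (
    ApcMutation,
    RegistrySample,
    RepeatAnnotation,
    TrinucleotideSpectrum,
    default_data_path,
    expected_stop_profile,
    read_cds_fasta,
    retention_by_kras,
    sample_chronology,
)
from cryptselect.io_formats import write_tsv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    repeats = RepeatAnnotation.from_tsv(default_data_path("human_apc_20aa_repeats.tsv"))
    df = pd.read_csv(args.indir / "polyps.tsv", sep="\t")
    samples = [
        RegistrySample(
            sample_id=str(r["sample"]),
            apc_mutations=[ApcMutation(residue=int(r["apc_residue"]),
                                       vaf=r["apc_vaf"],
                                       depth=int(r["apc_depth"]))],
            kras_mutant=bool(r["kras_mutant"]),
            kras_vaf=r["kras_vaf"] if pd.notna(r["kras_vaf"]) else None,
            kras_depth=int(r["kras_depth"]) if pd.notna(r["kras_depth"]) else None,
            side=r["side"],
        )
        for _, r in df.iterrows()
    ]

    retention = retention_by_kras(samples, repeats)
    write_tsv(retention, args.indir / "retention_by_kras.tsv")
    mode_mut = retention.loc[retention["pct_kras_mutant"].idxmax(), "score"]
    mode_wt = retention.loc[retention["pct_kras_wt"].idxmax(), "score"]
    print(f"modal retention score: KRAS-mutant {mode_mut}, KRAS-WT {mode_wt} "
          "(the generator plants 2 vs 1, echoing the registry pattern)")

    calls = [(s.sample_id, sample_chronology(s, alpha=args.alpha)) for s in samples
             if s.kras_mutant]
    out = pd.DataFrame(
        dict(sample=sid, verdict=c.verdict, kras_apc_vaf_ratio=c.vaf_ratio)
        for sid, c in calls
    )
    write_tsv(out, args.indir / "chronology_calls.tsv")
    counts = out["verdict"].value_counts()
    resolved = int(counts.get("APC-first", 0) + counts.get("KRAS-first", 0))
    print(f"chronology at {100 * (1 - args.alpha):.0f}% confidence: "
          f"{resolved}/{len(out)} polyps resolved "
          f"({counts.get('APC-first', 0)} APC-first, "
          f"{counts.get('KRAS-first', 0)} KRAS-first)")

    cds = read_cds_fasta(args.indir / "cds.fa", "synthgene")
    colon = TrinucleotideSpectrum.from_tsv(
        default_data_path("colon_signature_synthetic.tsv")
    )
    profile = expected_stop_profile(cds, colon)
    write_tsv(profile, args.indir / "expected_stop_profile.tsv")
    peak = profile.loc[profile["expected"].idxmax(), "residue"]
    print(f"expected stop profile peaks at residue {peak} "
          "(CpG-to-TpG-susceptible codons dominate under the colon signature)")


if __name__ == "__main__":
    main()
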