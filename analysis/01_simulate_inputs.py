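#!/usr/bin/env python
"""Generate the synthetic study inputs every downstream stage consumes.

Emulates the study's data shapes: a coding sequence, a mutagen-like SBS96
signature, a capture-dialect SNV catalog with a fourfold selection
multiplier injected on one missense outcome, priming/rescue cohort tumour
tables, and a polyp cohort with APC/KRAS read support.  Everything is
deterministic under --seed and written as TSV/FASTA under results/synthetic/.
"""

import argparse
from pathlib import Path

import numpy as np

from cryptselect import DriftParams, RepeatAnnotation, default_data_path
from cryptselect.io_formats import write_cds_fasta, write_tsv
from cryptselect.consequence import enumerate_snvs
from cryptselect.signatures import channel_trinuc
from cryptselect.synthetic_data import (
    enu_like_signature,
    gen_cohorts,
    gen_mutation_catalog,
    gen_polyps,
    gen_random_cds,
)
import pandas as pd

COHORT_SPECS = [
    # priming (TE) vs 30-day rescue (ET30); Apc truncations carry a negative
    # bias (pr=0.3), Ctnnb1 exon-3 drivers decay neutrally here
    dict(label="TE", protocol="TE", n_mice=10, mean=388, dispersion=8,
         mixture={"Apc": 0.3, "Ctnnb1": 0.7}),
    dict(label="ET30", protocol="ET30", n_mice=10, mean=388, dispersion=8,
         mixture={"Apc": 0.3, "Ctnnb1": 0.7}, day=30,
         pr={"Apc": 0.3, "Ctnnb1": 0.45}),
]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    cds = gen_random_cds(rng, n_codons=150, gene="synthgene")
    write_cds_fasta(cds, args.outdir / "cds.fa")
    sig = enu_like_signature(rng)
    sig.to_tsv(args.outdir / "signature_true.tsv")

    # pick a rare missense outcome as the selected driver (multiplier 4)
    freqs = sig.frequencies
    by_change: dict[str, float] = {}
    for r in enumerate_snvs(cds):
        if r.mclass == "missense" and r.channel:
            by_change[r.aa_change] = by_change.get(r.aa_change, 0.0) + freqs[r.channel]
    total = sum(by_change.values())
    target = min(by_change, key=lambda k: abs(by_change[k] / total - 0.005))
    catalog = gen_mutation_catalog(
        cds, sig, 20_000, seed=int(rng.integers(2**31)),
        selection={target: 4.0},
        restrict_classes=["missense"],
    )
    catalog.write(args.outdir / "catalog_capture.tsv")
    (args.outdir / "selected_outcome.txt").write_text(target + "\n")
    print(f"catalog: 20,000 missense SNVs over {cds.protein_length} residues; "
          f"selection multiplier 4 injected on {target}")

    summaries, tumours = gen_cohorts(COHORT_SPECS, DriftParams(), seed=args.seed)
    write_tsv(tumours, args.outdir / "tumours.tsv")
    write_tsv(
        pd.DataFrame(
            [
                dict(cohort=s.label, protocol=s.protocol, mean=s.mean_count,
                     sd=s.sd, **{f"prop_{k}": v for k, v in s.proportions.items()})
                for s in summaries
            ]
        ),
        args.outdir / "cohorts.tsv",
    )
    for s in summaries:
        print(f"cohort {s.label}: mean {s.mean_count:.1f} (sd {s.sd:.1f}) "
              f"proportions {s.proportions}")

    repeats = RepeatAnnotation.from_tsv(default_data_path("human_apc_20aa_repeats.tsv"))
    polyps = gen_polyps(810, seed=args.seed + 1, repeats=repeats,
                        kras_mutant_fraction=0.6)
    write_tsv(
        pd.DataFrame(
            dict(
                sample=s.sample_id,
                apc_residue=s.apc_mutations[0].residue,
                apc_vaf=s.apc_mutations[0].vaf,
                apc_depth=s.apc_mutations[0].depth,
                kras_mutant=s.kras_mutant,
                kras_vaf=s.kras_vaf,
                kras_depth=s.kras_depth,
                side=s.side,
            )
            for s in polyps
        ),
        args.outdir / "polyps.tsv",
    )
    print(f"polyps: {len(polyps)} simulated "
          f"({sum(s.kras_mutant for s in polyps)} KRAS-mutant)")


if __name__ == "__main__":
    main()
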