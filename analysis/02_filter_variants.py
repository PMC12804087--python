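#!/usr/bin/env python
"""Apply the post-caller filters to the synthetic capture catalog.

The generated catalog is built to pass every support rule, so this stage
mostly documents the filter bookkeeping: it spikes in a handful of rows that
each violate one rule, runs the capture filter, and writes the filtered
table plus the per-rule removal report.
"""

import argparse
from pathlib import Path

import pandas as pd

from cryptselect import MutationTable, filter_capture, read_mutation_table
from cryptselect.io_formats import write_tsv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()

    table = read_mutation_table(args.indir / "catalog_capture.tsv", dialect="capture")
    spikes = []
    template = table.rows.iloc[0].to_dict()
    for over in (
        dict(sample="SPIKE1", alt_reads=1, alt_bq30_reads=1),
        dict(sample="SPIKE2", mappability=0.7),
        dict(sample="SPIKE3", normals_gapped=6),
        dict(sample="SPIKE4", normals_somatic_calls=3),
    ):
        spikes.append({**template, **over})
    spiked = MutationTable(
        rows=pd.concat([table.rows, pd.DataFrame(spikes)], ignore_index=True),
        dialect="capture",
    )
    filtered, report = filter_capture(spiked)
    filtered.write(args.indir / "catalog_filtered.tsv")
    write_tsv(report, args.indir / "filter_report.tsv")
    print(f"input {len(spiked)} rows (incl. 4 spiked artefacts) -> "
          f"{len(filtered)} retained")
    print(report.to_string(index=False))
    assert len(spiked) - len(filtered) == 4, "only the spiked artefacts should drop"


if __name__ == "__main__":
    main()
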