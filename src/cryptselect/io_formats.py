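"""Readers/writers for the pipeline's tabular and sequence formats.

The canonical mutation format is a MAF-like tab-separated table, one somatic
SNV per row, with a small required core (sample, chromosome, 1-based position,
single-base ref/alt) and dialect-specific support columns (capture, amplicon
or registry).  Coding sequences arrive as plain FASTA, one record per gene,
and are validated as complete ORFs.  Run-level settings live in a YAML/JSON
config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("cryptselect")

VALID_BASES = {"A", "C", "G", "T"}
DIALECTS = ("capture", "amplicon", "registry")

REQUIRED_COLUMNS = ("sample", "chrom", "pos", "ref", "alt")

#: Header synonyms accepted on read (MAF, GENIE and in-house tables differ
#: only in their headers).
COLUMN_ALIASES = {
    "tumor_sample_barcode": "sample",
    "sample_id": "sample",
    "chromosome": "chrom",
    "start_position": "pos",
    "position": "pos",
    "reference_allele": "ref",
    "tumor_seq_allele2": "alt",
    "hugo_symbol": "gene",
    "t_alt_count": "alt_reads",
    "t_depth": "depth",
    "af": "vaf",
    "allele_fraction": "vaf",
    "hgvsp_short": "protein_change",
}


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class MutationTable:
    """A validated catalog of somatic SNV calls.

    ``rows`` is a DataFrame with the required core columns plus any
    dialect-specific support columns; ``rejected`` records rows that failed
    validation together with their (1-based, data) row number and the violated
    rule.
    """

    rows: pd.DataFrame
    dialect: str = "capture"
    provenance: str = ""
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "rule"])
    )

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise FormatError(f"unknown dialect {self.dialect!r}")
        missing = [c for c in REQUIRED_COLUMNS if c not in self.rows.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")

    def __len__(self) -> int:
        return len(self.rows)

    def write(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split rows into (valid, rejected-with-reason)."""
    reasons = []
    keep = pd.Series(True, index=df.index)
    for i, idx in enumerate(df.index, start=1):
        row = df.loc[idx]
        rule = None
        ref = str(row["ref"]).upper()
        alt = str(row["alt"]).upper()
        if len(ref) != 1 or len(alt) != 1:
            rule = "non-SNV alleles (length != 1)"
        elif ref not in VALID_BASES or alt not in VALID_BASES:
            rule = "non-ACGT allele"
        elif ref == alt:
            rule = "ref equals alt"
        elif pd.isna(row["sample"]) or str(row["sample"]) == "":
            rule = "missing sample identifier"
        elif pd.isna(row["pos"]) or int(row["pos"]) < 1:
            rule = "position must be a positive 1-based integer"
        elif "vaf" in df.columns and pd.notna(row.get("vaf")) and not (
            0 <= float(row["vaf"]) <= 1
        ):
            rule = "VAF outside [0,1]"
        if rule is not None:
            keep.at[idx] = False
            reasons.append({"row": i, "rule": rule})
            logger.warning("rejected row %d: %s", i, rule)
    valid = df[keep].copy()
    if "pos" in valid.columns and len(valid):
        valid["pos"] = valid["pos"].astype(int)
    for col in ("ref", "alt"):
        if len(valid):
            valid[col] = valid[col].str.upper()
    return valid, pd.DataFrame(reasons, columns=["row", "rule"])


def read_mutation_table(path, dialect: str = "capture") -> MutationTable:
    """Read a MAF-like TSV into a validated :class:`MutationTable`.

    Header synonyms are mapped onto canonical names; malformed rows are
    rejected individually (with their row number) rather than failing the
    whole file, except for missing required columns which are a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    df.columns = [COLUMN_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    valid, rejected = _validate_rows(df)
    return MutationTable(
        rows=valid.reset_index(drop=True),
        dialect=dialect,
        provenance=str(path),
        rejected=rejected,
    )


def write_mutation_table(table: MutationTable, path) -> None:
    table.write(path)


@dataclass
class CdsFasta:
    """A complete coding sequence: ATG..stop on the coding strand."""

    gene: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if set(self.seq) - VALID_BASES:
            raise FormatError(f"{self.gene}: non-ACGT bases in CDS")
        if len(self.seq) % 3 != 0:
            raise FormatError(
                f"{self.gene}: CDS length {len(self.seq)} not divisible by 3"
            )
        if not self.seq.startswith("ATG"):
            raise FormatError(f"{self.gene}: CDS does not start with ATG")
        stops = {"TAA", "TAG", "TGA"}
        codons = [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]
        if codons[-1] not in stops:
            raise FormatError(f"{self.gene}: CDS does not end with a stop codon")
        for i, codon in enumerate(codons[:-1], start=1):
            if codon in stops:
                raise FormatError(f"{self.gene}: internal stop codon at residue {i}")

    @property
    def protein_length(self) -> int:
        """Length of the encoded protein, excluding the stop."""
        return len(self.seq) // 3 - 1

    def codon(self, residue: int) -> str:
        """The codon for a 1-based residue."""
        if not 1 <= residue <= self.protein_length + 1:
            raise FormatError(f"residue {residue} outside CDS")
        return self.seq[(residue - 1) * 3 : residue * 3]


def read_cds_fasta(path, gene: str) -> CdsFasta:
    """Read one gene's CDS from a FASTA file (one record per gene)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id == gene or record.id.split("|")[0] == gene:
            return CdsFasta(gene=gene, seq=str(record.seq).upper())
    raise FormatError(f"gene {gene!r} not found in {path}")


def write_cds_fasta(cds: CdsFasta, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{cds.gene}\n")
        for i in range(0, len(cds.seq), 60):
            fh.write(cds.seq[i : i + 60] + "\n")


@dataclass
class RunConfig:
    """Run-level settings shared by the CLI and the analysis drivers."""

    bin_scheme_path: str | None = None
    repeat_annotation_path: str | None = None
    drift: dict = field(
        default_factory=lambda: {"ns": 5, "lam": 0.1, "pr": 0.5, "tau": 1.0}
    )
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise FormatError("significance level must be in (0,1)")
        if int(self.seed) < 0:
            raise FormatError("seed must be a non-negative integer")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def default_data_path(name: str) -> Path:
    """Path to a data file shipped with the package."""
    return Path(__file__).parent / "data" / name
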