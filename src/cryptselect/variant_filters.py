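"""Post-caller somatic SNV filters for the capture and amplicon dialects.

Each filter is a pure conjunction of declarative, order-independent
predicates over the call's support fields; a row survives iff it passes every
rule it can be evaluated against.  Filtering a filtered table therefore
removes nothing (idempotence), and per-rule removal counts are reported so
the provenance of every dropped call is visible.

Capture rules (hybridization capture calls against panels of normals):
  caller_pass      caller-internal filters passed
  snp_overlap      not a known SNP/indel site with the same allele
  germline_overlap not overlapping a germline-mode normal call, same allele
  alt_support      >= 2 alt reads AND >= half of them with base alignment
                   quality >= 30
  gapped_normals   fewer than 4 normals with >= 4 gapped reads within 10 bp
  mappability      mappability score at the site equals 1
  somatic_normals  called in somatic mode in fewer than 2 normals
  recurrent_lowvaf recurrent variants (same chrom/pos/alt in tumours of >= 2
                   mice — suspected lymphoid expansions) are removed when the
                   maximum VAF across sharing tumours is <= 0.05 OR the
                   matched-normal VAF is >= 0.01 (either clause suffices)

Amplicon rules: SNV alleles only; allele fraction >= 0.01; called in >= 2
overlapping amplicons; >= 5 mutant reads; caller noise filters passed.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Callable

import pandas as pd

from .io_formats import MutationTable

logger = logging.getLogger("cryptselect")


class FilterConfigError(ValueError):
    """A rule cannot be evaluated because its support column is absent."""


def _require(df: pd.DataFrame, cols: list[str], rule: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FilterConfigError(
            f"rule '{rule}' cannot be evaluated: missing column(s) {missing}"
        )


def _truthy(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.astype(str).str.lower().isin(("true", "1", "yes", "t"))


def _apply_rules(
    table: MutationTable,
    rules: dict[str, Callable[[pd.DataFrame], pd.Series]],
) -> tuple[MutationTable, pd.DataFrame]:
    """Evaluate each rule (True = passes) and keep the conjunction.

    Rules returning NA for a row (optional field absent) are skipped for that
    row; the skip is logged.  Removal counts allow one row to hit several
    rules: they sum to at least the number of removed rows.
    """
    df = table.rows
    keep = pd.Series(True, index=df.index)
    removal_counts = {}
    for name, rule in rules.items():
        passed = rule(df)
        na = passed.isna()
        if na.any():
            logger.info(
                "rule %s: skipped for %d row(s) lacking the needed field",
                name,
                int(na.sum()),
            )
        failed = (~passed.fillna(True).astype(bool)) & keep.notna()
        removal_counts[name] = int(failed.sum())
        keep &= passed.fillna(True).astype(bool)
    report = pd.DataFrame(
        {"rule": list(removal_counts), "removed": list(removal_counts.values())}
    )
    filtered = replace(
        table, rows=df[keep].reset_index(drop=True), rejected=table.rejected
    )
    return filtered, report


def _recurrent_groups(df: pd.DataFrame) -> pd.Series:
    """True where the variant recurs in tumours of >= 2 mice."""
    if "mouse" not in df.columns:
        return pd.Series(False, index=df.index)
    key = list(zip(df["chrom"], df["pos"], df["alt"]))
    n_mice = (
        pd.DataFrame({"key": key, "mouse": df["mouse"].values})
        .groupby("key")["mouse"]
        .nunique()
    )
    return pd.Series([n_mice[k] >= 2 for k in key], index=df.index)


def filter_capture(
    table: MutationTable,
    recurrence_min_mice: int = 2,
    recurrent_clauses: str = "either",
) -> tuple[MutationTable, pd.DataFrame]:
    """Apply the capture-dialect post-caller filters.

    ``recurrent_clauses`` controls the low-VAF lymphoid rule: ``either``
    (default, matching the printed 'or') removes a recurrent variant when
    max VAF <= 0.05 or matched-normal VAF >= 0.01; ``both`` requires both.
    """
    if table.dialect != "capture":
        raise FilterConfigError(f"expected capture dialect, got {table.dialect!r}")
    df = table.rows
    _require(df, ["alt_reads", "alt_bq30_reads"], "alt_support")
    _require(df, ["mappability"], "mappability")
    _require(df, ["normals_gapped"], "gapped_normals")
    _require(df, ["normals_somatic_calls"], "somatic_normals")

    def opt_bool(col: str, good_when: bool) -> Callable[[pd.DataFrame], pd.Series]:
        def rule(d: pd.DataFrame) -> pd.Series:
            if col not in d.columns:
                return pd.Series(pd.NA, index=d.index, dtype="object")
            vals = _truthy(d[col])
            return vals if good_when else ~vals

        return rule

    def recurrent_lowvaf(d: pd.DataFrame) -> pd.Series:
        if "vaf" not in d.columns:
            return pd.Series(pd.NA, index=d.index, dtype="object")
        recurrent = _recurrent_groups(d)
        key = list(zip(d["chrom"], d["pos"], d["alt"]))
        max_vaf = (
            pd.DataFrame({"key": key, "vaf": d["vaf"].values}).groupby("key")["vaf"].max()
        )
        low_max = pd.Series([max_vaf[k] <= 0.05 for k in key], index=d.index)
        if "matched_normal_vaf" in d.columns:
            normal_high = d["matched_normal_vaf"].fillna(0.0) >= 0.01
        else:
            normal_high = pd.Series(False, index=d.index)
        if recurrent_clauses == "both":
            suspect = low_max & normal_high
        else:
            suspect = low_max | normal_high
        return ~(recurrent & suspect)

    rules: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
        "caller_pass": opt_bool("caller_pass", good_when=True),
        "snp_overlap": opt_bool("snp_overlap", good_when=False),
        "germline_overlap": opt_bool("germline_overlap", good_when=False),
        "alt_support": lambda d: (d["alt_reads"] >= 2)
        & (d["alt_bq30_reads"] >= d["alt_reads"] / 2),
        "gapped_normals": lambda d: d["normals_gapped"] < 4,
        "mappability": lambda d: d["mappability"] >= 1,
        "somatic_normals": lambda d: d["normals_somatic_calls"] < 2,
        "recurrent_lowvaf": recurrent_lowvaf,
    }
    # the recurrence definition is configurable but the grouping helper is
    # fixed at >=2 mice; other thresholds would need a different helper
    if recurrence_min_mice != 2:
        raise FilterConfigError("recurrence_min_mice other than 2 is not supported")
    return _apply_rules(table, rules)


def filter_amplicon(table: MutationTable) -> tuple[MutationTable, pd.DataFrame]:
    """Apply the amplicon-dialect post-caller filters."""
    if table.dialect != "amplicon":
        raise FilterConfigError(f"expected amplicon dialect, got {table.dialect!r}")
    df = table.rows
    _require(df, ["amplicons", "alt_reads", "vaf"], "amplicon_support")

    rules: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
        "snv_only": lambda d: (d["ref"].str.len() == 1) & (d["alt"].str.len() == 1),
        "allele_fraction": lambda d: d["vaf"] >= 0.01,
        "amplicon_count": lambda d: d["amplicons"] >= 2,
        "mutant_reads": lambda d: d["alt_reads"] >= 5,
        "caller_pass": lambda d: (
            _truthy(d["caller_pass"])
            if "caller_pass" in d.columns
            else pd.Series(pd.NA, index=d.index, dtype="object")
        ),
    }
    return _apply_rules(table, rules)
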