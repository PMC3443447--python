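"""Plain-text table I/O: UTF-8 TSV with a mandatory header, "NA" for missing."""

from __future__ import annotations

import pandas as pd

NA = "NA"


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


def read_intensities(path: str) -> pd.DataFrame:
    """Read a probe-level intensity table (probe_id, x, y, contig_id, samples...)."""
    table = read_table(path)
    required = {"probe_id", "x", "y", "contig_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"intensity table lacks columns {sorted(missing)}")
    return table


def read_design(path: str) -> pd.DataFrame:
    table = read_table(path)
    required = {"sample_id", "wing", "morph", "section", "stage"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"design table lacks columns {sorted(missing)}")
    return table


def read_expression(path: str) -> pd.DataFrame:
    table = read_table(path)
    if "contig_id" not in table.columns:
        raise ValueError("expression table lacks a contig_id column")
    return table.set_index("contig_id")
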