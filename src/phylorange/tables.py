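"""Bit-stable TSV reading and writing for pipeline artifacts.

All tabular outputs are UTF-8, tab-separated with a header row; floats are
written with 6 significant digits and missing values as empty fields, so
re-running a pipeline with the same configuration produces byte-identical
files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_table", "write_table"]


def read_table(path, index_col=None) -> pd.DataFrame:
    """Read a TSV table, rejecting ragged rows with the offending line number."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    width = len(header)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        fields = line.split("\t")
        if len(fields) != width:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(fields)} fields, expected {width})"
            )
        rows.append([f if f != "" else None for f in fields])
    df = pd.DataFrame(rows, columns=header)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.notna().all() or (converted.isna() == df[col].isna()).all():
            df[col] = converted
    if index_col is not None:
        df = df.set_index(index_col)
    return df


def _format_value(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    if isinstance(v, (float, np.floating)):
        return f"{v:.6g}"
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    return str(v)


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    """Write a table as TSV with 6-significant-digit floats and empty-field NA."""
    with open(path, "w", encoding="utf-8") as fh:
        cols = list(df.columns)
        if index_label is not None:
            fh.write("\t".join([index_label] + [str(c) for c in cols]) + "\n")
        else:
            fh.write("\t".join(str(c) for c in cols) + "\n")
        for idx, row in df.iterrows():
            fields = [_format_value(row[c]) for c in cols]
            if index_label is not None:
                fields = [str(idx)] + fields
            fh.write("\t".join(fields) + "\n")
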