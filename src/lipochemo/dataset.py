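"""Packaged study tables and delimited-text I/O.

The study data are two compound-by-measure tables for 27 anticancer
sulfonamide derivatives:

* ``table1`` — seven computational logP estimates per compound
  (iLogP, XLogP3, WLogP, MLogP, Silicos-IT LogP, Consensus LogP,
  KOWWIN LogP);
* ``table2`` — five chromatographic lipophilicity indices
  (logk_IAM, CHI_logD, logkw_C8, logkw_CN, logkw_Ph) together with the
  raw CHI_IAM and CHI_C18 retention indices, the computed pKa, and the
  anticancer potency pIC50 against the HCT-116 cell line.

Tables are represented as :class:`pandas.DataFrame` objects with the
compound labels ("1".."27", kept as strings) in the index and measure
names in the columns.  Descriptor matrices use the same layout with a
``provenance`` entry ("user" or "synthetic") stored in ``DataFrame.attrs``.
"""

from __future__ import annotations

import csv
import io
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_table1",
    "load_table2",
    "lipophilicity_panel",
    "PANEL_MEASURES",
    "read_table",
    "write_table",
    "drop_near_constant",
]

#: The twelve lipophilicity measures compared by the ranking analysis:
#: seven computational logP estimates plus five chromatographic indices.
#: The raw CHI retention indices are excluded (they are affine transforms
#: of logk_IAM / CHI_logD and therefore rank-identical), as are pKa and
#: pIC50, which are not lipophilicity measures.
PANEL_MEASURES = (
    "iLogP",
    "XLogP3",
    "WLogP",
    "MLogP",
    "Silicos-IT LogP",
    "Consensus LogP",
    "KOWWIN LogP",
    "logk_IAM",
    "CHI_logD",
    "logkw_C8",
    "logkw_CN",
    "logkw_Ph",
)


def _load_packaged(name: str) -> pd.DataFrame:
    text = resources.files("lipochemo.data").joinpath(name).read_text()
    df = pd.read_csv(io.StringIO(text), dtype={"compound": str})
    df = df.set_index("compound")
    df.index.name = "compound"
    return df.astype(float)


def load_table1() -> pd.DataFrame:
    """Return the 27x7 table of computational logP values."""
    return _load_packaged("table1.csv")


def load_table2() -> pd.DataFrame:
    """Return the 27x9 table of chromatographic indices, pKa and pIC50."""
    return _load_packaged("table2.csv")


def lipophilicity_panel(include_pic50: bool = False) -> pd.DataFrame:
    """Assemble the 27x12 panel of lipophilicity measures.

    Joins the computational logP estimates with the five chromatographic
    indices.  With ``include_pic50`` the potency column is appended as a
    thirteenth variable, as used for the clustered heat map.
    """
    t1 = load_table1()
    t2 = load_table2()
    panel = t1.join(t2[["logk_IAM", "CHI_logD", "logkw_C8", "logkw_CN", "logkw_Ph"]])
    panel = panel[list(PANEL_MEASURES)]
    if include_pic50:
        panel["pIC50"] = t2["pIC50"]
    return panel


def read_table(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a compound-by-measure table from delimited text.

    Expects one header row (identifier column followed by measure names)
    and one leading identifier column per row.  Non-numeric cells are
    coerced to NaN and reported in ``DataFrame.attrs["dropped_cells"]``
    as ``(row_id, column)`` pairs.

    Raises
    ------
    ValueError
        On duplicated compound identifiers, or on a ragged row (the
        message names the offending 1-based line number).
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    width = len(header)
    if width < 2:
        raise ValueError(f"{path}: need an identifier column and at least one measure")
    ids, body = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != width:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(row)} fields, expected {width})"
            )
        ids.append(row[0].strip())
        body.append(row[1:])
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicated compound identifiers: {dupes}")
    raw = pd.DataFrame(body, index=pd.Index(ids, name=header[0] or "compound"),
                       columns=[c.strip() for c in header[1:]])
    values = raw.apply(pd.to_numeric, errors="coerce")
    dropped = [
        (rid, col)
        for rid, col in zip(*np.nonzero(values.isna().to_numpy()))
    ]
    values.attrs["dropped_cells"] = [
        (values.index[r], values.columns[c]) for r, c in dropped
    ]
    return values


def write_table(table: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write a table in the layout :func:`read_table` expects."""
    table.to_csv(path, sep=delimiter, index_label=table.index.name or "compound")


def drop_near_constant(matrix: pd.DataFrame, variance_tol: float = 1e-8) -> pd.DataFrame:
    """Remove constant and near-constant descriptor columns.

    A column is kept when its sample variance (n-1 denominator) exceeds
    ``variance_tol``.  Removed column names are recorded in
    ``DataFrame.attrs["removed_columns"]``.
    """
    if variance_tol < 0:
        raise ValueError("variance_tol must be >= 0")
    variances = matrix.var(axis=0, ddof=1)
    keep = variances > variance_tol
    if not keep.any():
        raise ValueError("all descriptor columns are constant or near-constant")
    cleaned = matrix.loc[:, keep].copy()
    cleaned.attrs = dict(matrix.attrs)
    cleaned.attrs["removed_columns"] = list(matrix.columns[~keep])
    return cleaned
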