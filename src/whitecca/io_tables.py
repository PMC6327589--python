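"""Reading, aligning and writing the delimited sample-by-variable tables.

Input convention: delimited text (CSV or TSV), one header row of variable
names, first column holding unique sample identifiers, strictly numeric
cells (no missing values — imputation is out of scope and must happen
upstream).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("whitecca")

#: significant digits used for all numeric text output (enough to make
#: byte-level determinism checks meaningful)
FLOAT_FORMAT = "%.12g"


def _sniff_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_matrix(
    path: str | Path, delimiter: str | None = None
) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a samples-by-variables table.

    Returns ``(matrix, row_ids, col_names)``.  The delimiter is inferred
    from the file extension (``.tsv``/``.tab``/``.txt`` -> tab, else comma)
    unless given explicitly.

    Raises
    ------
    ValueError
        On duplicate sample identifiers (named in the message), missing or
        non-numeric cells, or ragged rows.
    """
    try:
        df = pd.read_csv(path, sep=_sniff_delimiter(path, delimiter), index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    ids = df.index.astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate sample ID {dup[0]!r}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ValueError(
            f"{path}: missing value in column {col!r}; imputation is not performed"
        )
    try:
        mat = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    return mat, list(ids), [str(c) for c in df.columns]


def align_samples(
    X_table: tuple[np.ndarray, list[str], list[str]],
    Y_table: tuple[np.ndarray, list[str], list[str]],
) -> tuple[tuple[np.ndarray, list[str], list[str]],
           tuple[np.ndarray, list[str], list[str]]]:
    """Inner-join two tables on sample IDs, preserving X's row order.

    Logs how many rows each side loses; fewer than 3 common samples is an
    error (CCA needs matched samples).
    """
    Xm, x_ids, x_cols = X_table
    Ym, y_ids, y_cols = Y_table
    y_pos = {sid: i for i, sid in enumerate(y_ids)}
    common = [sid for sid in x_ids if sid in y_pos]
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} samples are shared between the two tables; "
            "need at least 3"
        )
    dropped_x = len(x_ids) - len(common)
    dropped_y = len(y_ids) - len(common)
    if dropped_x or dropped_y:
        log.info(
            "aligned on %d common samples (dropped %d from X, %d from Y)",
            len(common), dropped_x, dropped_y,
        )
    xi = [x_ids.index(sid) for sid in common]
    yi = [y_pos[sid] for sid in common]
    return (Xm[xi], common, x_cols), (Ym[yi], common, y_cols)


def write_table(
    path: str | Path,
    matrix: np.ndarray,
    row_ids,
    col_names,
    index_label: str = "id",
) -> None:
    """Write a numeric table as TSV with 12-significant-digit formatting."""
    df = pd.DataFrame(np.atleast_2d(matrix), index=row_ids, columns=col_names)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)
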