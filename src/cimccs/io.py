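"""Schema-validated delimited-text readers and writers.

Comma-separated UTF-8 text with a header row is the canonical interchange
format; nested reports and simulation truth go to JSON.  Decimal parsing is
locale-independent ("1.5", never "1,5").
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = ["SchemaError", "read_table", "write_table"]


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


def read_table(
    path,
    required: Union[Sequence[str], Mapping[str, type]],
    optional: Optional[Mapping[str, type]] = None,
) -> pd.DataFrame:
    """Read a CSV and validate it against a declared schema.

    ``required`` is a list of column names or a name -> dtype mapping;
    missing columns and non-coercible values raise :class:`SchemaError`
    naming the offending column.
    """
    df = pd.read_csv(path)
    req_types: Mapping[str, Optional[type]] = (
        {c: None for c in required} if not isinstance(required, Mapping) else required
    )
    for col in req_types:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col, dtype in {**dict(req_types), **dict(optional or {})}.items():
        if dtype is None or col not in df.columns:
            continue
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: column {col!r} is not {dtype}: {exc}") from exc
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as comma-separated UTF-8 text (round-trip stable)."""
    df.to_csv(path, index=False)
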