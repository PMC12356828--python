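"""Table loading with dialect normalization.

All tabular inputs are TSV (tab-separated, UTF-8, header row); CSV is
accepted on read.  Unicode minus (U+2212), which appears in many
publisher-exported tables, is normalized to ASCII hyphen-minus before
parsing so that numeric columns parse identically regardless of dialect.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = ["TableFormatError", "load_table", "write_table", "sha256_file"]


class TableFormatError(ValueError):
    """Raised when a tabular input violates its declared schema."""


def _normalize(text: str) -> str:
    # Only U+2212 is normalized; hyphens inside identifiers are untouched.
    return text.replace("−", "-")


def load_table(
    path: str | Path,
    required: Iterable[str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a TSV/CSV table into a DataFrame, validating its shape.

    Parameters
    ----------
    path
        File to read.  ``.csv`` implies comma separation, anything else tab.
    required
        Column names that must be present; a missing one raises
        :class:`TableFormatError` naming the column and the file.
    sep
        Explicit separator override.

    Raises
    ------
    TableFormatError
        On missing columns or rows whose field count differs from the
        header (reported with the 1-based line number).
    """
    path = Path(path)
    text = _normalize(path.read_text(encoding="utf-8"))
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TableFormatError(f"{path}: empty table")
    n_fields = len(lines[0].split(sep))
    for lineno, ln in enumerate(lines[1:], start=2):
        got = len(ln.split(sep))
        if got != n_fields:
            raise TableFormatError(
                f"{path}: line {lineno}: expected {n_fields} fields, got {got}"
            )
    df = pd.read_csv(_io.StringIO(text), sep=sep)
    if required is not None:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise TableFormatError(
                f"{path}: missing column(s) {', '.join(missing)}"
            )
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    """Write ``df`` as canonical TSV (tab, UTF-8, header row)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def sha256_file(path: str | Path) -> str:
    """Hex SHA-256 of a file's bytes (used for provenance logging)."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
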