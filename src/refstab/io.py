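"""Reading and writing Cp tables, role/plate maps and sample annotations.

Cp tables are delimited text (CSV or TSV, sniffed from the extension or
overridable) with unique header ids.  The canonical layout is targets in
rows, matching typical qPCR panel exports; samples-in-rows files are
accepted via the ``orientation`` flag and transposed on read.  Cells that
are empty or spelled ``NA``, ``NaN``, ``Undetermined`` or ``Undet.`` are
treated as missing, since instrument exports vary.  A locale flag accepts
decimal commas.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .core import ANNOTATION_COLUMNS, CpMatrix, validate_annotation

#: Accepted spellings of a missing cell.
MISSING_TOKENS = {"", "NA", "NaN", "Undetermined", "Undet."}

#: Decimal places used when writing Cp values.
WRITE_DECIMALS = 4

_HEADER_COMMENT = (
    f"# Cp table; targets in rows; NA = missing/undetected; "
    f"values fixed to {WRITE_DECIMALS} decimal places"
)

MapLike = Union[str, Path, Mapping[str, str], None]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def _load_map(spec: MapLike, key_col: str, val_col: str) -> dict:
    """Load a two-column CSV mapping, or pass a dict through."""
    if spec is None:
        return {}
    if isinstance(spec, Mapping):
        return dict(spec)
    path = Path(spec)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if key_col not in df.columns or val_col not in df.columns:
        raise ValueError(
            f"map file {path} must have columns {key_col!r}, {val_col!r}"
        )
    if df[key_col].duplicated().any():
        dupes = df.loc[df[key_col].duplicated(), key_col].tolist()
        raise ValueError(f"duplicate ids in {path}: {dupes}")
    return dict(zip(df[key_col], df[val_col]))


def _parse_cell(raw, decimal_comma: bool) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    s = str(raw).strip()
    if s in MISSING_TOKENS:
        return np.nan
    if decimal_comma:
        s = s.replace(",", ".")
    try:
        return float(s)
    except ValueError as exc:
        raise ValueError(f"cell {raw!r} is neither numeric nor a missing token") from exc


def read_cp_table(
    path,
    orientation: str = "targets_in_rows",
    role_map: MapLike = None,
    plate_map: MapLike = None,
    decimal_comma: bool = False,
    sep: str | None = None,
) -> CpMatrix:
    """Read a delimited Cp table into a :class:`CpMatrix`.

    Parameters
    ----------
    path
        CSV/TSV file.  Lines starting with ``#`` are ignored.
    orientation
        ``"targets_in_rows"`` (canonical) or ``"samples_in_rows"``.
    role_map
        target id -> role, as a dict or a CSV with columns
        ``target_id,role``.  Targets absent from the map default to role
        ``mirna``.
    plate_map
        sample id -> plate label, as a dict or a CSV with columns
        ``sample_id,plate``.  Every sample in the table must be covered.
    decimal_comma
        Accept ``24,35`` as 24.35 (off by default).
    """
    if orientation not in {"targets_in_rows", "samples_in_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    use_sep = sep or _sep_for(path)
    # pandas silently mangles duplicate header ids; check them up front
    with path.open() as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                header = next(pd.read_csv(_io.StringIO(line), sep=use_sep, header=None,
                                          dtype=str, keep_default_na=False).itertuples(index=False))
                ids = list(header)[1:]
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                if dupes:
                    raise ValueError(f"duplicate header ids in {path}: {dupes}")
                break
    df = pd.read_csv(
        path,
        sep=use_sep,
        index_col=0,
        comment="#",
        dtype=str,
        keep_default_na=False,
    )
    if orientation == "samples_in_rows":
        df = df.T
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate target ids in {path}: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dupes}")

    values = df.map(lambda c: _parse_cell(c, decimal_comma)).astype(float)
    mask = values.isna()

    roles = _load_map(role_map, "target_id", "role")
    plates = _load_map(plate_map, "sample_id", "plate")
    absent = [s for s in values.columns if s not in plates]
    if plates and absent:
        raise ValueError(f"samples missing from plate map: {absent}")
    if not plates:  # single unnamed plate
        plates = {s: "plate1" for s in values.columns}
    return CpMatrix(values, mask, roles, plates)


def write_cp_table(m: CpMatrix, path) -> None:
    """Write a CpMatrix as CSV, targets in rows, masked cells as ``NA``.

    The numeric format (fixed 4 decimals) is documented in a ``#`` header
    comment so the file round-trips bit-identically through
    :func:`read_cp_table`.
    """
    path = Path(path)
    out = m.values.where(~m.mask)
    buf = _io.StringIO()
    buf.write(_HEADER_COMMENT + "\n")
    out.to_csv(buf, na_rep="NA", float_format=f"%.{WRITE_DECIMALS}f")
    path.write_text(buf.getvalue())


def write_role_map(m: CpMatrix, path) -> None:
    pd.DataFrame(
        {"target_id": list(m.targets), "role": [m.roles[t] for t in m.targets]}
    ).to_csv(path, index=False)


def write_plate_map(m: CpMatrix, path) -> None:
    pd.DataFrame(
        {"sample_id": list(m.samples), "plate": [m.plate[s] for s in m.samples]}
    ).to_csv(path, index=False)


def read_sample_annotation(path) -> pd.DataFrame:
    """Read and validate a sample-annotation CSV.

    Expects columns ``sample_id, os_months, event, age, histology,
    panel``; malformed survival rows are rejected with their row numbers.
    """
    path = Path(path)
    ann = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"{path} missing mandatory columns: {missing}")
    return validate_annotation(ann)


def write_sample_annotation(ann: pd.DataFrame, path) -> None:
    ann.reset_index(drop=True)[list(ANNOTATION_COLUMNS)].to_csv(path, index=False)
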