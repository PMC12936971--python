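"""Workspace I/O: delimited-text matrices, deterministic archives, JSON.

All outputs are reproducible byte for byte for a fixed pipeline seed:
archives carry fixed timestamps and JSON is written with sorted keys and
no incidental whitespace differences.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_matrix_archive",
    "read_matrix_archive",
    "write_json",
    "read_json",
    "write_tsv",
    "read_tsv",
    "sha256_file",
]

_FIXED_DATE = (1980, 1, 1, 0, 0, 0)  # deterministic zip member timestamps


def write_matrix_archive(path: str | Path, matrices: dict[str, np.ndarray], fmt: str = "%.8g") -> None:
    """Write named matrices as TSV members of one zip archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(matrices):
            buf = _io.StringIO()
            np.savetxt(buf, np.atleast_2d(matrices[name]), fmt=fmt, delimiter="\t")
            info = zipfile.ZipInfo(f"{name}.tsv", date_time=_FIXED_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, buf.getvalue())


def read_matrix_archive(path: str | Path) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    with zipfile.ZipFile(path) as zf:
        for member in zf.namelist():
            with zf.open(member) as fh:
                out[member.removesuffix(".tsv")] = np.loadtxt(fh, delimiter="\t")
    return out


def write_json(path: str | Path, obj) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
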