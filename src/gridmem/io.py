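"""Plain-text file formats for patterns, matrices and result tables.

Pattern file: one pattern per line, space-separated sorted 0-based active
indices; ``#`` lines are comments, and a header comment records N, S, D.

Matrix file: first line the integer N, then N lines of N space-separated
0/1 values (row = input unit).

Tables are CSV with run metadata embedded as leading ``#`` comment lines.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import NetworkParams, PatternSet, as_pattern

__all__ = [
    "write_patterns",
    "read_patterns",
    "write_matrix",
    "read_matrix",
    "write_table",
    "read_table",
]


def write_patterns(
    path, patterns: Iterable, params: NetworkParams | None = None,
    metadata: Mapping | None = None,
) -> None:
    path = Path(path)
    lines = []
    if params is not None:
        lines.append(f"# N={params.n} S={params.s} D={params.d}")
    for key, val in (metadata or {}).items():
        lines.append(f"# {key}={val}")
    for p in patterns:
        lines.append(" ".join(str(i) for i in sorted(p)))
    path.write_text("\n".join(lines) + "\n")


def read_patterns(path) -> tuple[list, dict]:
    """Parse a pattern file; returns (patterns, header key/value dict)."""
    header: dict = {}
    patterns = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            for token in line[1:].split():
                if "=" in token:
                    key, _, val = token.partition("=")
                    header[key.strip()] = val.strip()
            continue
        patterns.append(as_pattern(int(tok) for tok in line.split()))
    return patterns, header


def read_pattern_set(path) -> PatternSet:
    """Read a pattern file whose header records N, S, D."""
    patterns, header = read_patterns(path)
    try:
        params = NetworkParams(int(header["N"]), int(header["S"]), int(header.get("D", 1)))
    except KeyError as exc:
        raise ValueError(f"pattern file {path} lacks an N/S header comment") from exc
    return PatternSet(params, patterns)


def write_matrix(path, w: np.ndarray) -> None:
    w = np.asarray(w)
    n = w.shape[0]
    lines = [str(n)]
    for row in w:
        lines.append(" ".join(str(int(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix(path) -> np.ndarray:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    n = int(lines[0])
    rows = [[int(tok) for tok in ln.split()] for ln in lines[1 : n + 1]]
    w = np.array(rows, dtype=np.uint8)
    if w.shape != (n, n):
        raise ValueError(f"matrix file {path} is not {n}x{n}")
    if not np.isin(w, (0, 1)).all():
        raise ValueError(f"matrix file {path} has non-binary entries")
    return w


def write_table(path, df: pd.DataFrame, metadata: Mapping | None = None) -> None:
    """CSV with ``# key: value`` metadata header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
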