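"""Readers and writers for contact matrices and one-body scales.

Three plain-text matrix dialects are supported:

``square_tsv``
    A header row of residue labels, then one row per residue:
    label followed by n tab-separated values.  Square input must be
    symmetric to 1e-9; it is exactly symmetrized on load.
``lower_triangle``
    A label line, then the lower triangle including the diagonal in
    row-major order (``n (n + 1) / 2`` values, 210 for 20 residues);
    whitespace and line breaks are free-form.
``aaindex``
    A single AAindex-style matrix entry (read-only): an ``M`` line declaring
    the row/column alphabets followed by a lower-triangular or square
    numeric body terminated by ``//``.

One-body scales travel as two-column TSV (residue, value).
"""

from __future__ import annotations

import re
from os import PathLike
from pathlib import Path
from typing import TextIO

import numpy as np

from .matrices import ContactMatrix, OneBodyScale

DIALECTS = ("square_tsv", "lower_triangle", "aaindex")

_SYMMETRY_TOL = 1e-9


class ContactMatrixParseError(ValueError):
    """Malformed matrix input; the message names the offending cell."""


def _as_text(source: str | PathLike | TextIO) -> str:
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, str) and "\n" in source:
        return source  # literal text
    return Path(source).read_text()


def _default_name(source) -> str:
    if hasattr(source, "read"):
        return str(getattr(source, "name", "") or "")
    if isinstance(source, str) and "\n" in source:
        return ""
    return Path(source).stem


def _parse_float(token: str, where: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ContactMatrixParseError(
            f"non-numeric cell {token!r} at {where}"
        ) from None


def _check_square_symmetry(labels, values) -> np.ndarray:
    asym = np.abs(values - values.T)
    i, j = np.unravel_index(np.argmax(asym), asym.shape)
    if asym[i, j] > _SYMMETRY_TOL:
        raise ContactMatrixParseError(
            f"asymmetric input: ({labels[i]},{labels[j]}) = {values[i, j]} "
            f"but ({labels[j]},{labels[i]}) = {values[j, i]}"
        )
    return (values + values.T) / 2.0


def _read_square_tsv(text: str) -> tuple[tuple[str, ...], np.ndarray]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ContactMatrixParseError("empty input")
    header = lines[0].rstrip().split("\t")
    if header and header[0] in ("", "res", "residue"):
        header = header[1:]
    labels = tuple(h.strip() for h in header)
    n = len(labels)
    if len(lines) - 1 != n:
        raise ContactMatrixParseError(
            f"expected {n} data rows for {n} labels, found {len(lines) - 1}"
        )
    values = np.empty((n, n))
    seen = []
    for r, ln in enumerate(lines[1:]):
        cells = ln.rstrip("\n").split("\t")
        row_label = cells[0].strip()
        seen.append(row_label)
        if row_label != labels[r]:
            raise ContactMatrixParseError(
                f"row label {row_label!r} at row {r + 1} does not match "
                f"header label {labels[r]!r}"
            )
        if len(cells) - 1 != n:
            raise ContactMatrixParseError(
                f"row {row_label!r} has {len(cells) - 1} values, expected {n}"
            )
        for c, tok in enumerate(cells[1:]):
            values[r, c] = _parse_float(tok, f"({row_label},{labels[c]})")
    values = _check_square_symmetry(labels, values)
    return labels, values


def _read_lower_triangle(text: str) -> tuple[tuple[str, ...], np.ndarray]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ContactMatrixParseError("empty input")
    labels = tuple(lines[0].split())
    n = len(labels)
    tokens = " ".join(lines[1:]).split()
    expected = n * (n + 1) // 2
    if len(tokens) != expected:
        raise ContactMatrixParseError(
            f"lower triangle for {n} labels needs {expected} values, "
            f"found {len(tokens)}"
        )
    values = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1):
            v = _parse_float(tokens[k], f"({labels[i]},{labels[j]})")
            values[i, j] = values[j, i] = v
            k += 1
    return labels, values


_AAINDEX_M_RE = re.compile(
    r"^M\s+rows\s*=\s*([A-Za-z]+)\s*,\s*cols\s*=\s*([A-Za-z]+)"
)


def _read_aaindex(text: str) -> tuple[tuple[str, ...], np.ndarray]:
    lines = text.splitlines()
    m_idx = None
    rows = cols = None
    for i, ln in enumerate(lines):
        m = _AAINDEX_M_RE.match(ln.strip())
        if m:
            m_idx, rows, cols = i, m.group(1), m.group(2)
            break
    if m_idx is None:
        raise ContactMatrixParseError("no 'M rows = ..., cols = ...' line found")
    if rows != cols:
        raise ContactMatrixParseError(
            f"row alphabet {rows!r} differs from column alphabet {cols!r}"
        )
    labels = tuple(rows)
    n = len(labels)
    body: list[list[str]] = []
    for ln in lines[m_idx + 1 :]:
        stripped = ln.strip()
        if not stripped:
            continue
        if stripped.startswith("//"):
            break
        if re.match(r"^[A-Z*]\s", ln) and not re.match(r"^[-\d]", stripped):
            # a new key line (e.g. another entry) ends the body
            break
        body.append(stripped.split())
    if len(body) != n:
        raise ContactMatrixParseError(
            f"expected {n} matrix rows after the M line, found {len(body)}"
        )
    values = np.zeros((n, n))
    lower = all(len(row) == i + 1 for i, row in enumerate(body))
    square = all(len(row) == n for row in body)
    if lower:
        for i, row in enumerate(body):
            for j, tok in enumerate(row):
                v = _parse_float(tok, f"({labels[i]},{labels[j]})")
                values[i, j] = values[j, i] = v
    elif square:
        for i, row in enumerate(body):
            for j, tok in enumerate(row):
                values[i, j] = _parse_float(tok, f"({labels[i]},{labels[j]})")
        values = _check_square_symmetry(labels, values)
    else:
        raise ContactMatrixParseError(
            "matrix body is neither lower-triangular nor square"
        )
    return labels, values


def read_contact_matrix(
    source: str | PathLike | TextIO,
    dialect: str = "square_tsv",
    name: str | None = None,
) -> ContactMatrix:
    """Read a contact matrix from a path, stream or literal text."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    text = _as_text(source)
    reader = {
        "square_tsv": _read_square_tsv,
        "lower_triangle": _read_lower_triangle,
        "aaindex": _read_aaindex,
    }[dialect]
    labels, values = reader(text)
    if name is None:
        name = _default_name(source)
    return ContactMatrix(labels, values, name=name)


def write_contact_matrix(matrix: ContactMatrix, dialect: str = "square_tsv") -> str:
    """Serialize a contact matrix; round-trips through the reader exactly."""
    if dialect == "square_tsv":
        out = ["\t" + "\t".join(matrix.labels)]
        for a, row in zip(matrix.labels, matrix.values):
            out.append(a + "\t" + "\t".join(f"{v:.17g}" for v in row))
        return "\n".join(out) + "\n"
    if dialect == "lower_triangle":
        out = [" ".join(matrix.labels)]
        for i in range(matrix.n):
            out.append(" ".join(f"{matrix.values[i, j]:.17g}" for j in range(i + 1)))
        return "\n".join(out) + "\n"
    if dialect == "aaindex":
        raise ValueError("the aaindex dialect is read-only")
    raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")


def read_one_body_scale(
    source: str | PathLike | TextIO, name: str | None = None
) -> OneBodyScale:
    """Read a two-column (residue, value) TSV scale."""
    text = _as_text(source)
    labels, values = [], []
    for ln in text.splitlines():
        stripped = ln.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 2:
            raise ContactMatrixParseError(f"expected 'residue value', got {ln!r}")
        labels.append(parts[0])
        values.append(_parse_float(parts[1], f"residue {parts[0]}"))
    if name is None:
        name = _default_name(source)
    return OneBodyScale(tuple(labels), np.array(values), name=name)


def write_one_body_scale(scale: OneBodyScale) -> str:
    return (
        "\n".join(f"{a}\t{v:.17g}" for a, v in zip(scale.labels, scale.values)) + "\n"
    )
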