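"""Bundled and user-supplied reference data.

Two small fixtures ship with the package:

* ``mj_contact_energies.tsv`` -- the Miyazawa-Jernigan residue-residue
  contact energies e_ij (Miyazawa & Jernigan, J. Mol. Biol. 1996, Table 5;
  quasi-chemical approximation with solvent reference, RT units), transcribed
  to two decimals in the customary C M F I L V W Y A G T S N Q D E H R K P
  order.
* ``onebody_scales.tsv`` -- six per-residue free-energy scales used in the
  one-body analyses: the fitted one-body terms of the MJ, parallel and
  antiparallel beta-strand potentials in the HP-HB decomposition, the MJ
  q-values of Li, Tang & Wingreen, and parallel/antiparallel beta-sheet
  formation free energies derived from the Steward-Thornton propensities.

Strand-pairing (PASTA) and SJKG-style matrices are external publications'
data and are not bundled; :func:`load_external_matrix` reads a user-supplied
copy, optionally verifying a SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from os import PathLike
from pathlib import Path

import pandas as pd

from .io import read_contact_matrix, read_one_body_scale
from .matrices import ContactMatrix, OneBodyScale

SCALE_COLUMNS = (
    "mj_q",
    "parallel_q",
    "antiparallel_q",
    "q_values",
    "parallel_sheet_dg",
    "antiparallel_sheet_dg",
)


def _data_path(filename: str):
    return resources.files("potdecomp.data").joinpath(filename)


def mj_matrix() -> ContactMatrix:
    """The bundled Miyazawa-Jernigan contact-energy matrix."""
    with _data_path("mj_contact_energies.tsv").open() as fh:
        return read_contact_matrix(fh, dialect="square_tsv", name="MJ")


def table2_scales() -> dict[str, OneBodyScale]:
    """The six bundled one-body scales, keyed by column name."""
    with _data_path("onebody_scales.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    out = {}
    for col in SCALE_COLUMNS:
        out[col] = OneBodyScale(
            tuple(df["residue"]), df[col].to_numpy(dtype=float), name=col
        )
    return out


def load_external_matrix(
    path: str | PathLike,
    dialect: str = "square_tsv",
    sha256: str | None = None,
    name: str | None = None,
) -> ContactMatrix:
    """Read a user-supplied matrix file, optionally checking its SHA-256."""
    path = Path(path)
    if sha256 is not None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        if digest != sha256.lower():
            raise ValueError(
                f"checksum mismatch for {path}: expected {sha256}, got {digest}"
            )
    return read_contact_matrix(path, dialect=dialect, name=name)
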