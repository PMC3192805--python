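"""Binary pair-interaction bases: HP-model classes and backbone hydrogen bonding.

``HH``, ``HP`` and ``HB`` are symmetric 0/1 matrices over residue pairs.
``HH_ij = 1`` iff both residues are hydrophobic, ``HP_ij = 1`` iff exactly one
is, and the implicit polar-polar class is their complement.  ``HB_ij = 1`` iff
neither residue is proline -- proline's backbone nitrogen lacks the amide
hydrogen, so it is the one residue that cannot donate a backbone hydrogen
bond.  Under the default ten/ten hydropathy split the unique-pair counts are
|HH| = 55, |HP| = 100, |PP| = 55 and |HB| = 190.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .matrices import (
    PROLINE,
    STANDARD_RESIDUES,
    HydropathyClassification,
    _check_labels,
)


@dataclass
class BasisSet:
    """The HH/HP/HB indicator matrices aligned to a label order."""

    labels: tuple[str, ...]
    classification: HydropathyClassification
    hh: np.ndarray
    hp: np.ndarray
    hb: np.ndarray

    @property
    def pp(self) -> np.ndarray:
        """Implicit polar-polar indicator: complement of HH and HP."""
        return 1.0 - self.hh - self.hp

    def unique_pair_counts(self) -> dict[str, int]:
        """Number of unique (unordered, diagonal included) pairs per basis."""
        iu = np.triu_indices(len(self.labels))
        return {
            "HH": int(self.hh[iu].sum()),
            "HP": int(self.hp[iu].sum()),
            "PP": int(self.pp[iu].sum()),
            "HB": int(self.hb[iu].sum()),
        }

    def aligned(self, labels: Sequence[str]) -> "BasisSet":
        labels = tuple(labels)
        if set(labels) != set(self.labels):
            raise ValueError("basis and target labels differ")
        idx = {a: i for i, a in enumerate(self.labels)}
        perm = [idx[a] for a in labels]
        sel = np.ix_(perm, perm)
        return BasisSet(
            labels, self.classification, self.hh[sel], self.hp[sel], self.hb[sel]
        )


def build_basis(
    classification: HydropathyClassification,
    labels: Sequence[str] = STANDARD_RESIDUES,
) -> BasisSet:
    """Construct the HH/HP/HB indicator matrices for a label order."""
    labels = _check_labels(labels)
    h = np.array([classification.is_hydrophobic(a) for a in labels], dtype=bool)
    hh = np.outer(h, h).astype(float)
    hp = (np.outer(h, ~h) | np.outer(~h, h)).astype(float)
    can_hb = np.array([a != PROLINE for a in labels], dtype=bool)
    hb = np.outer(can_hb, can_hb).astype(float)
    return BasisSet(labels, classification, hh, hp, hb)


def pair_class(classification: HydropathyClassification, a: str, b: str) -> str:
    """Hydropathy class of an unordered residue pair: ``"HH"``, ``"HP"`` or ``"PP"``."""
    n_hydrophobic = classification.is_hydrophobic(a) + classification.is_hydrophobic(b)
    return ("PP", "HP", "HH")[n_hydrophobic]
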