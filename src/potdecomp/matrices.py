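"""Core containers: contact matrices, hydropathy classifications, one-body scales.

All energies are treated as a consistent dimensionless RT-like scale; no unit
conversion is attempted.  A :class:`ContactMatrix` is symmetric by
construction and exposes its ``n (n + 1) / 2`` unique elements (210 for the
full 20-residue alphabet), which are the fundamental observations every fit
and summary in this package operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

#: The 20 standard residues, alphabetical by one-letter code (canonical
#: internal order; I/O preserves and records source order).
STANDARD_RESIDUES: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

PROLINE = "P"


@dataclass(frozen=True)
class HydropathyClassification:
    """Partition of the residue alphabet into hydrophobic and hydrophilic sets."""

    name: str
    hydrophobic: frozenset[str]
    hydrophilic: frozenset[str]

    def __post_init__(self) -> None:
        both = self.hydrophobic & self.hydrophilic
        if both:
            raise ValueError(f"residues in both classes: {sorted(both)}")
        union = self.hydrophobic | self.hydrophilic
        if union != set(STANDARD_RESIDUES):
            missing = set(STANDARD_RESIDUES) - union
            extra = union - set(STANDARD_RESIDUES)
            raise ValueError(
                f"classification must cover the 20 standard residues exactly "
                f"(missing {sorted(missing)}, unknown {sorted(extra)})"
            )

    def is_hydrophobic(self, residue: str) -> bool:
        if residue in self.hydrophobic:
            return True
        if residue in self.hydrophilic:
            return False
        raise KeyError(residue)

    def moved(self, name: str, to_hydrophilic: Iterable[str] = ()) -> "HydropathyClassification":
        """A new classification with the given residues moved to the hydrophilic set."""
        moved = frozenset(to_hydrophilic)
        return HydropathyClassification(
            name, self.hydrophobic - moved, self.hydrophilic | moved
        )


#: Two-state hydropathy assignment of Dill and co-workers: ten hydrophobic
#: residues (including Ala and Pro) versus ten hydrophilic ones.
DILL = HydropathyClassification(
    "dill", frozenset("CFLWVIMYAP"), frozenset("HGNTSRQDKE")
)
#: Variant with proline regarded as hydrophilic.
PRO_POLAR = DILL.moved("pro_polar", "P")
#: Variant with both proline and alanine regarded as hydrophilic.
PRO_ALA_POLAR = DILL.moved("pro_ala_polar", "PA")

CLASSIFICATIONS: Mapping[str, HydropathyClassification] = {
    c.name: c for c in (DILL, PRO_POLAR, PRO_ALA_POLAR)
}


def _check_labels(labels: Sequence[str]) -> tuple[str, ...]:
    labels = tuple(labels)
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate residue labels: {labels}")
    unknown = set(labels) - set(STANDARD_RESIDUES)
    if unknown:
        raise ValueError(f"unknown residue codes: {sorted(unknown)}")
    return labels


@dataclass
class ContactMatrix:
    """A symmetric residue-residue contact free-energy matrix.

    Parameters
    ----------
    labels
        Residue one-letter codes, in the order rows/columns are stored.
        A full matrix carries all 20 standard residues; smaller alphabets
        are permitted for toy inputs.
    values
        Symmetric ``(n, n)`` array of contact free energies (RT-like units).
    name
        Free-text provenance tag.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.labels = _check_labels(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("contact matrix contains non-finite values")
        # store exactly symmetric values
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.labels)}

    def value(self, a: str, b: str) -> float:
        idx = self.index
        return float(self.values[idx[a], idx[b]])

    def unique_elements(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        """Pairs and values of the upper triangle including the diagonal.

        Returns ``n (n + 1) / 2`` entries (210 for 20 residues), each unique
        unordered pair counted exactly once.
        """
        iu = np.triu_indices(self.n)
        pairs = [(self.labels[i], self.labels[j]) for i, j in zip(*iu)]
        return pairs, self.values[iu].copy()

    def reordered(self, labels: Sequence[str]) -> "ContactMatrix":
        """The same matrix with rows/columns permuted to ``labels``."""
        labels = tuple(labels)
        if set(labels) != set(self.labels):
            raise ValueError("reordering labels must be a permutation")
        perm = [self.index[a] for a in labels]
        return ContactMatrix(labels, self.values[np.ix_(perm, perm)], self.name)

    def shifted(self, constant: float) -> "ContactMatrix":
        """The matrix with a constant added to every element."""
        return replace(self, values=self.values + constant)

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.labels, self.values.copy(), self.name)


@dataclass
class OneBodyScale:
    """A per-residue free-energy scale (q-values, beta-sheet free energies, fitted q)."""

    labels: tuple[str, ...]
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.labels = _check_labels(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels),):
            raise ValueError("one value per residue required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("one-body scale contains non-finite values")

    def as_dict(self) -> dict[str, float]:
        return {a: float(v) for a, v in zip(self.labels, self.values)}

    def value(self, residue: str) -> float:
        return self.as_dict()[residue]

    def subset(self, residues: Iterable[str]) -> "OneBodyScale":
        keep = [a for a in self.labels if a in set(residues)]
        d = self.as_dict()
        return OneBodyScale(tuple(keep), np.array([d[a] for a in keep]), self.name)

    def aligned_values(self, labels: Sequence[str]) -> np.ndarray:
        d = self.as_dict()
        return np.array([d[a] for a in labels])


@dataclass
class MatrixSummary:
    """Moment summary of a contact matrix's unique elements."""

    mean: float
    sd: float
    min: float
    max: float
    n_elements: int
    per_class: dict[str, tuple[float, float]] | None = field(default=None)


def summary_stats(matrix: ContactMatrix) -> MatrixSummary:
    """Mean, population standard deviation and range of the unique elements."""
    _, vals = matrix.unique_elements()
    return MatrixSummary(
        mean=float(np.mean(vals)),
        sd=float(np.std(vals)),  # population convention (divide by N)
        min=float(np.min(vals)),
        max=float(np.max(vals)),
        n_elements=vals.size,
    )


def boltzmann_invert(
    pair_probabilities: np.ndarray,
    reference: np.ndarray,
    labels: Sequence[str] = STANDARD_RESIDUES,
    name: str = "boltzmann",
) -> ContactMatrix:
    """Contact free energies from pair probabilities: ``e_ij = -ln(p_ij / ref_ij)``.

    Both inputs must be strictly positive matrices over the same alphabet;
    the result is in RT units.
    """
    p = np.asarray(pair_probabilities, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if p.shape != ref.shape:
        raise ValueError("probability and reference shapes differ")
    if np.any(p <= 0) or np.any(ref <= 0):
        raise ValueError("probabilities must be strictly positive")
    return ContactMatrix(tuple(labels), -np.log(p / ref), name)
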