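"""Solvation correction of one-body scales and scale comparisons.

A fitted one-body term is modelled as the sum of a residue-specific
secondary-structure formation free energy and a class-level (hydrophobic or
hydrophilic) solvation free energy.  Removing each class's mean from its
members isolates the secondary-structure component; the removed means are the
solvation shifts (for the reference MJ q-value scale: a hydrophobic penalty
of magnitude ~1.45 RT and a near-zero hydrophilic shift of ~0.07 RT).

Because published analyses are ambiguous about where proline sits in this
correction, the grouping of proline is an explicit policy: kept in the class
its classification assigns (``in_hydrophobic`` under the default split),
grouped with the hydrophilic residues (``in_hydrophilic``), or dropped from
the correction entirely (``excluded``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import PROLINE, HydropathyClassification, OneBodyScale

PROLINE_POLICIES = ("in_hydrophobic", "in_hydrophilic", "excluded")


@dataclass
class SolvationDecomposition:
    """A class-centered scale plus the removed class-mean solvation shifts."""

    corrected: OneBodyScale
    shift_hydrophobic: float
    shift_hydrophilic: float
    classification: HydropathyClassification
    proline_policy: str

    def groups(self) -> tuple[list[str], list[str]]:
        """Retained residues per effective class under the policy."""
        return _policy_groups(
            self.corrected.labels, self.classification, self.proline_policy
        )


def _policy_groups(labels, classification, proline_policy):
    if proline_policy not in PROLINE_POLICIES:
        raise ValueError(
            f"unknown proline policy {proline_policy!r}; choose from {PROLINE_POLICIES}"
        )
    hyd, pol = [], []
    for a in labels:
        if a == PROLINE:
            if proline_policy == "excluded":
                continue
            if proline_policy == "in_hydrophilic":
                pol.append(a)
                continue
        (hyd if classification.is_hydrophobic(a) else pol).append(a)
    return hyd, pol


def solvation_correct(
    scale: OneBodyScale,
    classification: HydropathyClassification,
    proline_policy: str = "in_hydrophobic",
) -> SolvationDecomposition:
    """Center a one-body scale within each hydropathy class.

    Subtracts the hydrophobic-class mean from the hydrophobic residues and
    the hydrophilic-class mean from the hydrophilic residues, recording the
    two means as the solvation shifts.  With ``proline_policy="excluded"``
    proline is dropped from both the means and the corrected scale.
    """
    hyd, pol = _policy_groups(scale.labels, classification, proline_policy)
    if not hyd or not pol:
        raise ValueError("both classes must retain at least one residue")
    d = scale.as_dict()
    shift_h = float(np.mean([d[a] for a in hyd]))
    shift_p = float(np.mean([d[a] for a in pol]))
    labels = tuple(a for a in scale.labels if a in set(hyd) | set(pol))
    values = np.array(
        [d[a] - (shift_h if a in set(hyd) else shift_p) for a in labels]
    )
    corrected = OneBodyScale(
        labels, values, name=f"{scale.name} class-centered".strip()
    )
    return SolvationDecomposition(
        corrected=corrected,
        shift_hydrophobic=shift_h,
        shift_hydrophilic=shift_p,
        classification=classification,
        proline_policy=proline_policy,
    )


def compare_scales(
    a: OneBodyScale, b: OneBodyScale, residues=None
) -> tuple[float, float]:
    """Pearson r and rmsd between two scales over the retained residues.

    ``residues`` defaults to the residues the two scales share; at least
    three are required.
    """
    shared = [x for x in a.labels if x in set(b.labels)]
    if residues is not None:
        keep = set(residues)
        shared = [x for x in shared if x in keep]
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared residues, have {len(shared)}")
    av = a.aligned_values(shared)
    bv = b.aligned_values(shared)
    if np.std(av) == 0 or np.std(bv) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance scale")
    r = float(np.corrcoef(av, bv)[0, 1])
    rmsd = float(np.sqrt(np.mean((av - bv) ** 2)))
    return r, rmsd


def secondary_structure_component(
    fitted_q: OneBodyScale, solvation: SolvationDecomposition
) -> OneBodyScale:
    """Secondary-structure free energy implied by a fitted one-body scale.

    Subtracts the class solvation shifts recorded in ``solvation`` from the
    fitted q, i.e. the per-residue estimate of the free energy of forming
    hydrogen-bonded secondary structure.
    """
    hyd, pol = _policy_groups(
        fitted_q.labels, solvation.classification, solvation.proline_policy
    )
    d = fitted_q.as_dict()
    labels = tuple(a for a in fitted_q.labels if a in set(hyd) | set(pol))
    values = np.array(
        [
            d[a]
            - (
                solvation.shift_hydrophobic
                if a in set(hyd)
                else solvation.shift_hydrophilic
            )
            for a in labels
        ]
    )
    return OneBodyScale(labels, values, name=f"{fitted_q.name} ss-component".strip())
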