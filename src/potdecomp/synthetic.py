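"""Seeded generators for matrices and scales with the model's statistical structure.

A synthetic contact matrix is built directly from the generative form the
decomposition assumes::

    e_ij = eta0 - (eta_HH * HH_ij + eta_HP * HP_ij + eta_HB * HB_ij)
           + q_i + q_j + eps_ij,    eps_ij ~ iid Normal(0, noise_sd^2)

with the noise drawn once per unique element and mirrored, matching the
210-independent-variables picture of a symmetric matrix.  The default ground
truth mimics a native-fold (MJ-like) potential: two-body weights
(3.64, 1.48, 1.76, 0.07) RT, the fitted MJ one-body scale as q, and
noise sd 0.23 RT (the residual scale of the full-model fit to MJ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import build_basis
from .matrices import (
    DILL,
    STANDARD_RESIDUES,
    ContactMatrix,
    HydropathyClassification,
    OneBodyScale,
)


@dataclass
class GroundTruth:
    """Generating parameters for a synthetic contact matrix."""

    eta_hh: float
    eta_hp: float
    eta_hb: float
    eta0: float
    q: OneBodyScale
    classification: HydropathyClassification = DILL
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        # The truth must satisfy the estimation gauge, otherwise "recovery"
        # is ill-defined.  Scales transcribed from rounded tables can be off
        # by ~1e-4, so project onto the gauge rather than reject.
        labels = self.q.labels
        d = self.q.as_dict()
        values = np.empty(len(labels))
        for group in (self.classification.hydrophobic, self.classification.hydrophilic):
            members = [a for a in group if a in d]
            if not members:
                continue
            mean = sum(d[a] for a in members) / len(members)
            for a in members:
                values[labels.index(a)] = d[a] - mean
        self.q = OneBodyScale(labels, values, name=self.q.name)


def zero_q(
    labels=STANDARD_RESIDUES, name: str = "zero one-body truth"
) -> OneBodyScale:
    return OneBodyScale(tuple(labels), np.zeros(len(labels)), name)


def mj_like_truth(noise_sd: float = 0.23, seed: int = 0) -> GroundTruth:
    """Ground truth mimicking the decomposition of a native-fold potential."""
    from .datasets import table2_scales

    q = table2_scales()["mj_q"]
    return GroundTruth(
        eta_hh=3.64,
        eta_hp=1.48,
        eta_hb=1.76,
        eta0=0.07,
        q=q,
        classification=DILL,
        noise_sd=noise_sd,
        seed=seed,
    )


def generate_matrix(truth: GroundTruth) -> tuple[ContactMatrix, GroundTruth]:
    """Draw a synthetic contact matrix from the generative model.

    Deterministic under ``truth.seed``; returns the matrix together with the
    truth so downstream code can score recovery.
    """
    labels = truth.q.labels
    basis = build_basis(truth.classification, labels)
    qv = truth.q.aligned_values(labels)
    mean = (
        truth.eta0
        - (truth.eta_hh * basis.hh + truth.eta_hp * basis.hp + truth.eta_hb * basis.hb)
        + qv[:, None]
        + qv[None, :]
    )
    n = len(labels)
    rng = np.random.default_rng(truth.seed)
    eps = np.zeros((n, n))
    iu = np.triu_indices(n)
    eps[iu] = rng.normal(0.0, truth.noise_sd, size=len(iu[0]))
    eps = eps + np.triu(eps, 1).T  # mirror the unique-element draws
    name = f"synthetic[noise={truth.noise_sd:g}, seed={truth.seed}]"
    return ContactMatrix(labels, mean + eps, name=name), truth


def generate_scale(
    class_means: tuple[float, float],
    within_sd: float,
    seed: int = 0,
    classification: HydropathyClassification = DILL,
    labels=STANDARD_RESIDUES,
) -> OneBodyScale:
    """A per-residue scale: class mean plus iid Gaussian within-class scatter."""
    if within_sd < 0:
        raise ValueError("within-class sd must be non-negative")
    s_h, s_p = class_means
    rng = np.random.default_rng(seed)
    values = np.array(
        [
            (s_h if classification.is_hydrophobic(a) else s_p)
            + rng.normal(0.0, within_sd)
            for a in labels
        ]
    )
    name = f"synthetic scale[means=({s_h:g},{s_p:g}), sd={within_sd:g}, seed={seed}]"
    return OneBodyScale(tuple(labels), values, name=name)
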