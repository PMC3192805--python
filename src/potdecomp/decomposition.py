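"""Least-squares decomposition of contact matrices into HP/HB and one-body terms.

Two nested linear models are fitted over the unique matrix elements
(210 for the full alphabet, each unordered pair counted once, unweighted):

two-body (the coarse-grained HP-HB model)::

    e_ij = eta0 - (eta_HH * HH_ij + eta_HP * HP_ij + eta_HB * HB_ij)

full (two-body plus residue-specific one-body terms)::

    e_ij = eta0 - (eta_HH * HH_ij + eta_HP * HP_ij + eta_HB * HB_ij) + q_i + q_j

Sign convention: the ``eta`` coefficients are positive stabilization
magnitudes entering with a minus sign, so ``eta_HB`` is the free energy
gained per backbone hydrogen bond and ``eta0`` (the solvent-solvent
constant) absorbs any overall shift of the matrix.

The one-body vector ``q`` is only defined up to per-class constants that can
be traded against ``eta0``, ``eta_HH`` and ``eta_HP``; the gauge is fixed by
requiring ``q`` to sum to zero separately over the hydrophobic and the
hydrophilic residues.  Two strategies are offered for the full model:

``joint``
    One constrained least-squares problem in all 24 parameters.  This is the
    statistically clean estimator and recovers noiseless synthetic matrices
    exactly, but note that ``eta_HB`` and ``q`` at proline are close to
    collinear (they are separated only by the single Pro-Pro element), so
    the two-body block can drift far from the two-body-only fit.
``sequential``
    Fit the two-body model first, then fit ``q`` to its residuals under the
    gauge constraints.  The two-body block is exactly the two-body fit; the
    one-body terms match published q-scale decompositions of the MJ matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .basis import BasisSet
from .matrices import ContactMatrix, HydropathyClassification, OneBodyScale

GAUGES = ("classwise_zero_sum",)
STRATEGIES = ("joint", "sequential")


@dataclass(frozen=True)
class FitOptions:
    """Options shared by the fitting routines.

    The element weighting is fixed to "unweighted over the unique elements"
    and the sign convention to stabilization magnitudes; both are part of the
    model definition rather than tunable knobs.  ``excluded_pairs`` drops
    individual unordered pairs (e.g. Cys-Cys) from the fitted element set.
    """

    excluded_pairs: tuple[tuple[str, str], ...] = ()
    ss_regressor: bool = False  # add a binary Cys-Cys (disulfide) column

    def excludes(self, a: str, b: str) -> bool:
        return (a, b) in self.excluded_pairs or (b, a) in self.excluded_pairs


@dataclass
class TwoBodyFit:
    """Result of the two-body (HP-HB) decomposition."""

    eta_hh: float
    eta_hp: float
    eta_hb: float
    eta0: float
    se_hh: float
    se_hp: float
    se_hb: float
    se_eta0: float
    pearson_r: float
    rmsd: float
    classification: HydropathyClassification
    labels: tuple[str, ...]
    n_elements: int
    eta_ss: float | None = None  # optional disulfide (Cys-Cys) term
    matrix_name: str = ""

    @property
    def etas(self) -> tuple[float, float, float, float]:
        return (self.eta_hh, self.eta_hp, self.eta_hb, self.eta0)


@dataclass
class FullFit(TwoBodyFit):
    """Two-body decomposition augmented with gauge-fixed one-body terms."""

    q: OneBodyScale = None  # type: ignore[assignment]
    gauge: str = "classwise_zero_sum"
    strategy: str = "joint"


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric simulated-annealing schedule.

    The temperature is multiplied by ``cooling`` after every sweep over the
    free parameters; proposals are Gaussian with standard deviation
    ``proposal_sd * sqrt(T)``, floored at ``proposal_floor`` so the late,
    effectively greedy phase can still refine the solution.
    """

    t0: float = 1.0
    cooling: float = 0.995
    steps: int = 200_000
    proposal_sd: float = 0.05
    proposal_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("initial temperature must be positive")
        if self.steps <= 0:
            raise ValueError("step count must be positive")
        if not 0 < self.cooling <= 1:
            raise ValueError("cooling factor must be in (0, 1]")


def _fit_rows(matrix: ContactMatrix, basis: BasisSet, opts: FitOptions):
    """Unique-element response vector and aligned basis lookups."""
    if set(matrix.labels) != set(basis.labels):
        raise ValueError("matrix and basis labels differ")
    basis = basis.aligned(matrix.labels)
    pairs, values = matrix.unique_elements()
    keep = [k for k, (a, b) in enumerate(pairs) if not opts.excludes(a, b)]
    pairs = [pairs[k] for k in keep]
    values = values[keep]
    iu = np.triu_indices(matrix.n)
    sel = (iu[0][keep], iu[1][keep])
    return basis, pairs, values, sel


def _two_body_design(basis: BasisSet, sel, pairs, opts: FitOptions) -> np.ndarray:
    cols = [np.ones(len(pairs)), -basis.hh[sel], -basis.hp[sel], -basis.hb[sel]]
    if opts.ss_regressor:
        cols.append(np.array([-float(a == "C" and b == "C") for a, b in pairs]))
    return np.column_stack(cols)


def _q_reduction(
    classification: HydropathyClassification, labels: Sequence[str]
) -> tuple[list[str], list[str], np.ndarray]:
    """Map from gauge-reduced q parameters to the 20 per-residue values.

    Within each hydropathy class the last residue's q is minus the sum of the
    others, which enforces the class-wise zero-sum gauge exactly.
    """
    hyd = [a for a in labels if classification.is_hydrophobic(a)]
    pol = [a for a in labels if not classification.is_hydrophobic(a)]
    n_free = (len(hyd) - 1) + (len(pol) - 1)
    rows = {}
    for group, offset in ((hyd, 0), (pol, len(hyd) - 1)):
        for k, a in enumerate(group):
            z = np.zeros(n_free)
            if k < len(group) - 1:
                z[offset + k] = 1.0
            else:
                z[offset : offset + len(group) - 1] = -1.0
            rows[a] = z
    expand = np.vstack([rows[a] for a in labels])  # (20, n_free)
    return hyd, pol, expand


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient design: the classification/basis combination does "
            "not identify all coefficients"
        )


def _ols(X: np.ndarray, y: np.ndarray):
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    return res.params, res.bse, X @ res.params


def _pearson_rmsd(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    r = float(np.corrcoef(y, yhat)[0, 1])
    rmsd = float(np.sqrt(np.mean((y - yhat) ** 2)))
    return r, rmsd


def fit_two_body(
    matrix: ContactMatrix,
    basis: BasisSet,
    opts: FitOptions = FitOptions(),
) -> TwoBodyFit:
    """Ordinary least squares of the two-body HP-HB model."""
    basis, pairs, y, sel = _fit_rows(matrix, basis, opts)
    X = _two_body_design(basis, sel, pairs, opts)
    params, bse, yhat = _ols(X, y)
    r, rmsd = _pearson_rmsd(y, yhat)
    return TwoBodyFit(
        eta_hh=float(params[1]),
        eta_hp=float(params[2]),
        eta_hb=float(params[3]),
        eta0=float(params[0]),
        se_hh=float(bse[1]),
        se_hp=float(bse[2]),
        se_hb=float(bse[3]),
        se_eta0=float(bse[0]),
        pearson_r=r,
        rmsd=rmsd,
        classification=basis.classification,
        labels=matrix.labels,
        n_elements=len(y),
        eta_ss=float(params[4]) if opts.ss_regressor else None,
        matrix_name=matrix.name,
    )


def fit_full(
    matrix: ContactMatrix,
    basis: BasisSet,
    gauge: str = "classwise_zero_sum",
    opts: FitOptions = FitOptions(),
    strategy: str = "joint",
) -> FullFit:
    """Fit the full two-body + one-body model under the class-wise zero-sum gauge."""
    if gauge not in GAUGES:
        raise ValueError(f"unknown gauge {gauge!r}; choose from {GAUGES}")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    basis, pairs, y, sel = _fit_rows(matrix, basis, opts)
    X2 = _two_body_design(basis, sel, pairs, opts)
    _, _, expand = _q_reduction(basis.classification, matrix.labels)
    # one-body design: q_i + q_j in the reduced parametrization
    Q = expand[sel[0]] + expand[sel[1]]

    if strategy == "joint":
        X = np.hstack([X2, Q])
        params, bse, yhat = _ols(X, y)
        eta = params[: X2.shape[1]]
        eta_se = bse[: X2.shape[1]]
        q_free = params[X2.shape[1] :]
    else:  # sequential: two-body first, then q on the residuals
        eta, eta_se, yhat2 = _ols(X2, y)
        q_free, _, resid_hat = _ols(Q, y - yhat2)
        yhat = yhat2 + resid_hat
    r, rmsd = _pearson_rmsd(y, yhat)
    q_values = expand @ q_free
    q = OneBodyScale(matrix.labels, q_values, name=f"{matrix.name} fitted q".strip())
    return FullFit(
        eta_hh=float(eta[1]),
        eta_hp=float(eta[2]),
        eta_hb=float(eta[3]),
        eta0=float(eta[0]),
        se_hh=float(eta_se[1]),
        se_hp=float(eta_se[2]),
        se_hb=float(eta_se[3]),
        se_eta0=float(eta_se[0]),
        pearson_r=r,
        rmsd=rmsd,
        classification=basis.classification,
        labels=matrix.labels,
        n_elements=len(y),
        eta_ss=float(eta[4]) if opts.ss_regressor else None,
        matrix_name=matrix.name,
        q=q,
        gauge=gauge,
        strategy=strategy,
    )


def reconstruct(fit: TwoBodyFit | FullFit, basis: BasisSet) -> ContactMatrix:
    """The model matrix implied by a fit; symmetric by construction."""
    if basis.classification != fit.classification:
        raise ValueError("fit and basis use different classifications")
    basis = basis.aligned(fit.labels)
    values = fit.eta0 - (
        fit.eta_hh * basis.hh + fit.eta_hp * basis.hp + fit.eta_hb * basis.hb
    )
    if fit.eta_ss is not None:
        idx = {a: i for i, a in enumerate(fit.labels)}
        if "C" in idx:
            values[idx["C"], idx["C"]] -= fit.eta_ss
    if isinstance(fit, FullFit) and fit.q is not None:
        qv = fit.q.aligned_values(fit.labels)
        values = values + qv[:, None] + qv[None, :]
    name = f"reconstructed {fit.matrix_name}".strip()
    return ContactMatrix(fit.labels, values, name=name)


def fit_metrics(
    original: ContactMatrix, reconstructed: ContactMatrix
) -> tuple[float, float]:
    """Pearson r and rmsd between two matrices over their unique elements."""
    if set(original.labels) != set(reconstructed.labels):
        raise ValueError("matrices have different labels")
    other = reconstructed.reordered(original.labels)
    _, a = original.unique_elements()
    _, b = other.unique_elements()
    return _pearson_rmsd(a, b)


def hb_hh_ratio(fit: TwoBodyFit) -> float:
    """The hydrogen-bonding to hydrophobic weighting ratio ``eta_HB / eta_HH``.

    Below one: hydrophobic-dominated stabilization (native folds).  Above
    one: hydrogen-bond-dominated stabilization (amyloid beta-sheets).
    """
    if fit.eta_hh == 0:
        raise ZeroDivisionError("eta_HH is zero; ratio undefined")
    return fit.eta_hb / fit.eta_hh


def effective_energy(
    sequence: str,
    contacts: Sequence[tuple[int, int]],
    fit: TwoBodyFit | FullFit,
    basis: BasisSet,
) -> float:
    """Contact-approximation energy of a conformation.

    ``contacts`` lists index pairs (0-based positions in ``sequence``) that
    are in spatial proximity; the adjacency itself is the caller's concern.
    The energy is the sum of the fitted pair free energies over the contacts.
    """
    recon = reconstruct(fit, basis)
    total = 0.0
    n = len(sequence)
    for i, j in contacts:
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"contact ({i},{j}) outside sequence of length {n}")
        if i == j:
            raise ValueError(f"self-contact ({i},{j}) is not allowed")
        total += recon.value(sequence[i], sequence[j])
    return total


def _objective(y: np.ndarray, X: np.ndarray, theta: np.ndarray) -> float:
    r = y - X @ theta
    return float(r @ r)


def anneal_refine(
    matrix: ContactMatrix,
    basis: BasisSet,
    init: FullFit | None = None,
    schedule: AnnealSchedule = AnnealSchedule(),
    seed: int = 0,
    opts: FitOptions = FitOptions(),
) -> FullFit:
    """Simulated-annealing minimisation of the full-model residual sum of squares.

    A stochastic cross-check of :func:`fit_full`: single-coordinate Gaussian
    proposals with Metropolis acceptance under a geometric cooling schedule,
    tracking the best parameters seen.  The search runs in the gauge-reduced
    parametrization, so the class-wise zero-sum constraints hold exactly on
    output.  Deterministic under ``seed``.
    """
    basis_a, pairs, y, sel = _fit_rows(matrix, basis, opts)
    X2 = _two_body_design(basis_a, sel, pairs, opts)
    _, _, expand = _q_reduction(basis_a.classification, matrix.labels)
    Q = expand[sel[0]] + expand[sel[1]]
    X = np.hstack([X2, Q])
    d = X.shape[1]

    theta = np.zeros(d)
    if init is not None:
        theta[0] = init.eta0
        theta[1] = init.eta_hh
        theta[2] = init.eta_hp
        theta[3] = init.eta_hb
        if opts.ss_regressor:
            theta[4] = init.eta_ss or 0.0
        qv = init.q.aligned_values(matrix.labels)
        # reduced coordinates: free entries are all class members but the last
        theta[X2.shape[1] :], *_ = np.linalg.lstsq(expand, qv, rcond=None)

    rng = np.random.default_rng(seed)
    cols = X.T.copy()
    resid = y - X @ theta
    f = float(resid @ resid)
    best_theta, best_f = theta.copy(), f
    T = schedule.t0
    for step in range(schedule.steps):
        k = step % d
        if k == 0 and step:
            T *= schedule.cooling
        sd = max(schedule.proposal_sd * math.sqrt(T), schedule.proposal_floor)
        dtheta = rng.normal(0.0, sd)
        new_resid = resid - dtheta * cols[k]
        f_new = float(new_resid @ new_resid)
        if f_new < f or rng.random() < math.exp(-(f_new - f) / max(T, 1e-300)):
            theta[k] += dtheta
            resid = new_resid
            f = f_new
            if f < best_f:
                best_f = f
                best_theta = theta.copy()

    eta = best_theta[: X2.shape[1]]
    q_values = expand @ best_theta[X2.shape[1] :]
    yhat = X @ best_theta
    r, rmsd = _pearson_rmsd(y, yhat)
    q = OneBodyScale(matrix.labels, q_values, name=f"{matrix.name} annealed q".strip())
    return FullFit(
        eta_hh=float(eta[1]),
        eta_hp=float(eta[2]),
        eta_hb=float(eta[3]),
        eta0=float(eta[0]),
        se_hh=math.nan,
        se_hp=math.nan,
        se_hb=math.nan,
        se_eta0=math.nan,
        pearson_r=r,
        rmsd=rmsd,
        classification=basis_a.classification,
        labels=matrix.labels,
        n_elements=len(y),
        eta_ss=float(eta[4]) if opts.ss_regressor else None,
        matrix_name=matrix.name,
        q=q,
        gauge="classwise_zero_sum",
        strategy="anneal",
    )
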