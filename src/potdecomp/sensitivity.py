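"""Robustness controls for the HP-HB decomposition.

Three controls probe the stability of the eta_HB/eta_HH ratio:

* **Proline scaling** -- divide the Pro-X contact free energies by a factor
  and refit, or bisect for the factor that brings a beta-strand matrix's
  ratio down to a target (e.g. a native-fold matrix's value).
* **Reclassification battery** -- refit the two-body model under alternative
  hydropathy partitions (proline hydrophilic; proline and alanine
  hydrophilic).
* **Disulfide handling** -- the Cys-Cys element mixes covalent disulfide
  chemistry into the statistics; either drop it from the fit or absorb it
  with a dedicated indicator regressor.

Everything here is deterministic given the matrix and variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .basis import BasisSet, build_basis
from .decomposition import FitOptions, TwoBodyFit, fit_two_body, hb_hh_ratio
from .matrices import PROLINE, ContactMatrix, HydropathyClassification

DISULFIDE_MODES = ("exclude_cys_cys", "ss_regressor")


@dataclass
class SensitivityReport:
    """Collected control results for one matrix."""

    matrix_name: str
    baseline_ratio: float
    classification_ratios: dict[str, float] = field(default_factory=dict)
    pro_factor: float | None = None
    pro_target_ratio: float | None = None
    disulfide: dict[str, float] = field(default_factory=dict)


def scale_pro_contacts(matrix: ContactMatrix, factor: float) -> ContactMatrix:
    """Reduce every Pro-X free energy ``factor``-fold (divide by ``factor``).

    All other elements are untouched and symmetry is preserved.
    """
    if factor <= 0:
        raise ValueError("scaling factor must be positive")
    values = matrix.values.copy()
    if PROLINE in matrix.index:
        p = matrix.index[PROLINE]
        values[p, :] /= factor
        values[:, p] /= factor
        values[p, p] = matrix.values[p, p] / factor  # divide the diagonal once
    return ContactMatrix(
        matrix.labels, values, name=f"{matrix.name} pro/{factor:g}".strip()
    )


def _ratio_at(matrix: ContactMatrix, basis: BasisSet, factor: float) -> float:
    return hb_hh_ratio(fit_two_body(scale_pro_contacts(matrix, factor), basis))


def find_pro_factor(
    matrix: ContactMatrix,
    basis: BasisSet,
    target_ratio: float,
    bounds: tuple[float, float] = (1.0, 20.0),
    tol: float = 1e-3,
    max_iter: int = 200,
) -> float:
    """Bisection for the Pro-X reduction factor that reaches a target ratio.

    Finds ``f`` with ``hb_hh_ratio(fit(scale_pro_contacts(m, f))) == target
    +/- tol``.  The endpoint ratios must bracket the target.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    lo, hi = bounds
    if not 0 < lo < hi:
        raise ValueError("bounds must satisfy 0 < lo < hi")
    r_lo = _ratio_at(matrix, basis, lo)
    r_hi = _ratio_at(matrix, basis, hi)
    if not (min(r_lo, r_hi) <= target_ratio <= max(r_lo, r_hi)):
        raise ValueError(
            f"target ratio {target_ratio} not bracketed: "
            f"ratio({lo}) = {r_lo:.4f}, ratio({hi}) = {r_hi:.4f}"
        )
    sign = 1.0 if r_hi >= r_lo else -1.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        r_mid = _ratio_at(matrix, basis, mid)
        if abs(r_mid - target_ratio) <= tol:
            return mid
        if sign * (r_mid - target_ratio) < 0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("bisection did not converge within max_iter")


def classification_battery(
    matrix: ContactMatrix,
    variants: Sequence[HydropathyClassification],
) -> dict[str, float]:
    """Refit the two-body model under each classification; report eta_HB/eta_HH."""
    out = {}
    for variant in variants:
        basis = build_basis(variant, matrix.labels)
        out[variant.name] = hb_hh_ratio(fit_two_body(matrix, basis))
    return out


def refit_with_disulfide(
    matrix: ContactMatrix, basis: BasisSet, mode: str = "exclude_cys_cys"
) -> TwoBodyFit:
    """Two-body refit with the Cys-Cys (disulfide) element handled specially.

    ``exclude_cys_cys`` drops the (C,C) element from the fitted set;
    ``ss_regressor`` keeps it but adds a dedicated binary indicator, so the
    remaining coefficients are no longer pulled by disulfide chemistry.
    Metrics are computed over the fitted element set.
    """
    if mode == "exclude_cys_cys":
        opts = FitOptions(excluded_pairs=(("C", "C"),))
    elif mode == "ss_regressor":
        opts = FitOptions(ss_regressor=True)
    else:
        raise ValueError(f"unknown mode {mode!r}; choose from {DISULFIDE_MODES}")
    return fit_two_body(matrix, basis, opts)


def sensitivity_report(
    matrix: ContactMatrix,
    baseline: HydropathyClassification,
    variants: Iterable[HydropathyClassification] = (),
    pro_target_ratio: float | None = None,
    pro_bounds: tuple[float, float] = (1.0, 20.0),
) -> SensitivityReport:
    """Run the named controls for one matrix and collect the results."""
    basis = build_basis(baseline, matrix.labels)
    report = SensitivityReport(
        matrix_name=matrix.name,
        baseline_ratio=hb_hh_ratio(fit_two_body(matrix, basis)),
    )
    variants = list(variants)
    if variants:
        report.classification_ratios = classification_battery(matrix, variants)
    if pro_target_ratio is not None:
        report.pro_target_ratio = pro_target_ratio
        report.pro_factor = find_pro_factor(
            matrix, basis, pro_target_ratio, bounds=pro_bounds
        )
    for mode in DISULFIDE_MODES:
        fit = refit_with_disulfide(matrix, basis, mode)
        report.disulfide[mode] = fit.pearson_r
    return report
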