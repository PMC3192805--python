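"""Two-body and full decomposition fits, annealing, reconstruction, metrics."""

import numpy as np
import pytest

from potdecomp import (
    DILL,
    AnnealSchedule,
    ContactMatrix,
    FitOptions,
    HydropathyClassification,
    STANDARD_RESIDUES,
    anneal_refine,
    build_basis,
    effective_energy,
    fit_full,
    fit_metrics,
    fit_two_body,
    generate_matrix,
    hb_hh_ratio,
    reconstruct,
)
from potdecomp.synthetic import zero_q

from conftest import make_truth


def normal_equations_fit(matrix, basis):
    """Independent oracle: two-body OLS via explicit normal equations."""
    basis = basis.aligned(matrix.labels)
    pairs, y = matrix.unique_elements()
    iu = np.triu_indices(matrix.n)
    X = np.column_stack(
        [np.ones(len(y)), -basis.hh[iu], -basis.hp[iu], -basis.hb[iu]]
    )
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    cov = np.linalg.inv(X.T @ X) * (resid @ resid / dof)
    return beta, np.sqrt(np.diag(cov))


class TestTwoBodyFit:
    def test_noiseless_identifiable_model_recovered_exactly(self, dill_basis):
        truth = make_truth(zero_q())
        matrix, _ = generate_matrix(truth)
        fit = fit_two_body(matrix, dill_basis)
        assert fit.etas == pytest.approx((2.0, 1.0, 1.5, 0.5), abs=1e-9)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_mj_matches_published_decomposition(self, mj, dill_basis):
        fit = fit_two_body(mj, dill_basis)
        # published: 3.64, 1.48, 1.76, 0.07 with SEs 0.10/0.09/0.12/0.14
        assert fit.eta_hh == pytest.approx(3.64, abs=0.10)
        assert fit.eta_hp == pytest.approx(1.48, abs=0.09)
        assert fit.eta_hb == pytest.approx(1.76, abs=0.12)
        assert fit.eta0 == pytest.approx(0.07, abs=0.14)
        assert fit.pearson_r == pytest.approx(0.87, abs=0.01)
        assert hb_hh_ratio(fit) == pytest.approx(0.48, abs=0.05)

    def test_agrees_with_normal_equations_oracle(self, mj, dill_basis):
        fit = fit_two_body(mj, dill_basis)
        beta, se = normal_equations_fit(mj, dill_basis)
        assert fit.etas == pytest.approx(
            (beta[1], beta[2], beta[3], beta[0]), abs=1e-9
        )
        assert (fit.se_hh, fit.se_hp, fit.se_hb, fit.se_eta0) == pytest.approx(
            (se[1], se[2], se[3], se[0]), abs=1e-9
        )

    def test_noisy_synthetic_recovery_within_three_se(self, mj_q_truth):
        truth = make_truth(mj_q_truth, noise_sd=0.3, seed=1)
        matrix, _ = generate_matrix(truth)
        basis = build_basis(truth.classification, matrix.labels)
        fit = fit_full(matrix, basis)  # the generating model includes q
        for est, se, true in [
            (fit.eta_hh, fit.se_hh, truth.eta_hh),
            (fit.eta_hp, fit.se_hp, truth.eta_hp),
            (fit.eta_hb, fit.se_hb, truth.eta_hb),
            (fit.eta0, fit.se_eta0, truth.eta0),
        ]:
            assert abs(est - true) < 3 * se

    def test_rank_deficient_classification_raises(self, mj):
        degenerate = HydropathyClassification(
            "all_h", frozenset(STANDARD_RESIDUES), frozenset()
        )
        basis = build_basis(degenerate, mj.labels)
        with pytest.raises(ValueError, match="rank"):
            fit_two_body(mj, basis)

    def test_label_mismatch_raises(self, toy3, dill_basis):
        with pytest.raises(ValueError, match="labels"):
            fit_two_body(toy3, dill_basis)


class TestFullFit:
    def test_noiseless_gauge_truth_recovered_exactly(self, noiseless_matrix, dill_basis):
        matrix, truth = noiseless_matrix
        fit = fit_full(matrix, dill_basis)
        assert fit.etas == pytest.approx(
            (truth.eta_hh, truth.eta_hp, truth.eta_hb, truth.eta0), abs=1e-9
        )
        assert fit.q.aligned_values(truth.q.labels) == pytest.approx(
            truth.q.values, abs=1e-9
        )

    @pytest.mark.parametrize("strategy", ["joint", "sequential"])
    def test_gauge_sums_vanish(self, mj, dill_basis, strategy):
        fit = fit_full(mj, dill_basis, strategy=strategy)
        q = fit.q.as_dict()
        for group in (DILL.hydrophobic, DILL.hydrophilic):
            assert abs(sum(q[a] for a in group)) < 1e-9

    def test_full_model_never_fits_worse_than_two_body(self, mj, dill_basis):
        assert (
            fit_full(mj, dill_basis).pearson_r
            >= fit_two_body(mj, dill_basis).pearson_r
        )

    def test_sequential_two_body_block_equals_two_body_fit(self, mj, dill_basis):
        seq = fit_full(mj, dill_basis, strategy="sequential")
        two = fit_two_body(mj, dill_basis)
        assert seq.etas == pytest.approx(two.etas, abs=1e-12)

    def test_sequential_q_matches_published_mj_onebody(self, mj, dill_basis, scales):
        from potdecomp import compare_scales

        fit = fit_full(mj, dill_basis, strategy="sequential")
        r, rmsd = compare_scales(fit.q, scales["mj_q"])
        assert r > 0.99
        assert rmsd < 0.05

    def test_constant_shift_moves_only_eta0(self, mj, dill_basis):
        base = fit_full(mj, dill_basis)
        shifted = fit_full(mj.shifted(0.7), dill_basis)
        assert shifted.eta0 == pytest.approx(base.eta0 + 0.7, abs=1e-9)
        assert shifted.eta_hh == pytest.approx(base.eta_hh, abs=1e-9)
        assert shifted.eta_hp == pytest.approx(base.eta_hp, abs=1e-9)
        assert shifted.eta_hb == pytest.approx(base.eta_hb, abs=1e-9)
        assert shifted.q.values == pytest.approx(base.q.values, abs=1e-9)
        assert hb_hh_ratio(shifted) == pytest.approx(hb_hh_ratio(base), abs=1e-12)

    def test_reconstruction_invariant_under_label_permutation(self, mj, dill_basis):
        fit = fit_full(mj, dill_basis)
        recon = reconstruct(fit, dill_basis)
        perm = mj.reordered(STANDARD_RESIDUES)
        basis_p = build_basis(DILL, perm.labels)
        recon_p = reconstruct(fit_full(perm, basis_p), basis_p)
        for a in mj.labels:
            for b in mj.labels:
                assert recon.value(a, b) == pytest.approx(
                    recon_p.value(a, b), abs=1e-9
                )

    def test_unknown_gauge_and_strategy_rejected(self, mj, dill_basis):
        with pytest.raises(ValueError, match="gauge"):
            fit_full(mj, dill_basis, gauge="overall_zero")
        with pytest.raises(ValueError, match="strategy"):
            fit_full(mj, dill_basis, strategy="magic")


class TestReconstructAndMetrics:
    def test_two_body_closed_forms(self, mj, dill_basis):
        fit = fit_two_body(mj, dill_basis)
        recon = reconstruct(fit, dill_basis)
        # proline-involving polar pair: HP class, no hydrogen bonding
        assert recon.value("P", "K") == pytest.approx(fit.eta0 - fit.eta_hp, abs=1e-12)
        # non-proline polar-polar pair: only the hydrogen-bond term
        assert recon.value("D", "K") == pytest.approx(fit.eta0 - fit.eta_hb, abs=1e-12)
        # matches the published polar-polar class mean of the native potential
        assert fit.eta0 - fit.eta_hb == pytest.approx(-1.69, abs=0.05)

    def test_refit_of_reconstruction_is_idempotent(self, mj, dill_basis):
        fit = fit_two_body(mj, dill_basis)
        refit = fit_two_body(reconstruct(fit, dill_basis), dill_basis)
        assert refit.etas == pytest.approx(fit.etas, abs=1e-12)
        assert refit.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_identical_matrices_give_perfect_metrics(self, mj):
        r, rmsd = fit_metrics(mj, mj.copy())
        assert r == pytest.approx(1.0, abs=1e-12)
        assert rmsd == 0.0

    def test_hand_computed_pearson_and_rmsd(self):
        a = ContactMatrix(("A", "R"), np.array([[1.0, 2.0], [2.0, 3.0]]))
        b = ContactMatrix(("A", "R"), np.array([[2.0, 1.0], [1.0, 4.0]]))
        r, rmsd = fit_metrics(a, b)
        # unique elements (1,2,3) vs (2,1,4): r = sqrt(3/7), rmsd = 1
        assert r == pytest.approx(np.sqrt(3.0 / 7.0), abs=1e-12)
        assert rmsd == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_raises(self, mj):
        flat = ContactMatrix(mj.labels, np.zeros((20, 20)))
        with pytest.raises(ValueError, match="variance"):
            fit_metrics(mj, flat)

    def test_equal_etas_give_unit_ratio(self, mj, dill_basis):
        fit = fit_two_body(mj, dill_basis)
        fit.eta_hb = fit.eta_hh
        assert hb_hh_ratio(fit) == 1.0
        fit.eta_hh = 0.0
        with pytest.raises(ZeroDivisionError):
            hb_hh_ratio(fit)


class TestEffectiveEnergy:
    def test_empty_contact_list_is_zero(self, mj, dill_basis):
        fit = fit_two_body(mj, dill_basis)
        assert effective_energy("ACDEF", [], fit, dill_basis) == 0.0

    def test_single_polar_polar_contact(self, mj, dill_basis):
        fit = fit_two_body(mj, dill_basis)
        e = effective_energy("DK", [(0, 1)], fit, dill_basis)
        assert e == pytest.approx(fit.eta0 - fit.eta_hb, abs=1e-12)

    def test_matches_brute_force_pair_sum(self, mj, dill_basis):
        fit = fit_full(mj, dill_basis)
        recon = reconstruct(fit, dill_basis)
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list(mj.labels), size=12))
        contacts = [tuple(sorted(rng.choice(12, 2, replace=False))) for _ in range(10)]
        expected = sum(recon.value(seq[i], seq[j]) for i, j in contacts)
        assert effective_energy(seq, contacts, fit, dill_basis) == pytest.approx(
            expected, abs=1e-12
        )

    def test_bad_contacts_rejected(self, mj, dill_basis):
        fit = fit_two_body(mj, dill_basis)
        with pytest.raises(IndexError):
            effective_energy("DK", [(0, 5)], fit, dill_basis)
        with pytest.raises(ValueError):
            effective_energy("DK", [(1, 1)], fit, dill_basis)


class TestAnnealRefine:
    short = AnnealSchedule(steps=30_000)

    def test_same_seed_reproduces_output(self, mj, dill_basis):
        a = anneal_refine(mj, dill_basis, schedule=self.short, seed=11)
        b = anneal_refine(mj, dill_basis, schedule=self.short, seed=11)
        assert a.etas == b.etas
        assert np.array_equal(a.q.values, b.q.values)

    def test_init_at_optimum_never_degrades(self, mj, dill_basis):
        opt = fit_full(mj, dill_basis)
        refined = anneal_refine(mj, dill_basis, init=opt, schedule=self.short, seed=2)
        assert refined.rmsd <= opt.rmsd + 1e-12

    def test_reaches_closed_form_objective(self, mj, dill_basis):
        opt = fit_full(mj, dill_basis)
        refined = anneal_refine(mj, dill_basis, seed=0)  # default schedule, zeros init
        n = refined.n_elements
        gap = n * (refined.rmsd**2 - opt.rmsd**2)
        assert 0 <= gap < 1e-3

    def test_refines_q_close_to_closed_form(self, mj, dill_basis):
        opt = fit_full(mj, dill_basis)
        refined = anneal_refine(mj, dill_basis, init=opt, schedule=self.short, seed=5)
        assert refined.q.values == pytest.approx(opt.q.values, abs=0.01)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            AnnealSchedule(t0=0.0)
        with pytest.raises(ValueError):
            AnnealSchedule(steps=0)
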