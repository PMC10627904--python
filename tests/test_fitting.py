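"""Maximum-likelihood estimation: gradient correctness, likelihood
equivalence, fit indices, BIC and invariances."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import random_stationary_params, small_config
from panelnet.datasets import PanelDataset
from panelnet.fitting import (
    GVARObjective,
    ParamSpec,
    SuffStats,
    fit_indices,
    fit_panel_gvar,
    information_bic,
    saturated_loglik,
    saturated_moments,
    wald_edge_tests,
)
from panelnet.model import ModelMask, implied_moments
from panelnet.simulate import simulate_panel


def _random_theta(rng, spec):
    theta = rng.normal(scale=0.2, size=spec.n_theta)
    mu, B, Lz, Lb = spec.unpack(theta)
    np.fill_diagonal(Lz, np.abs(np.diag(Lz)) + 0.8)
    np.fill_diagonal(Lb, np.abs(np.diag(Lb)) + 0.5)
    return spec.pack(mu, 0.5 * B, Lz, Lb)


@pytest.mark.parametrize(
    "means_by_wave,zeta_diag,free_frac",
    [(False, False, 1.0), (True, False, 0.5), (False, True, 0.3)],
)
def test_analytic_gradient_matches_finite_differences(
    means_by_wave, zeta_diag, free_frac
):
    rng = np.random.default_rng(0)
    P, T, n = 3, 3, 50
    X = rng.normal(size=(n, T, P)) + 0.3 * rng.normal(size=(n, 1, P))
    X[rng.random(X.shape) < 0.1] = np.nan  # exercise the FIML patterns
    ds = PanelDataset(X, [f"s{i}" for i in range(n)], list(range(T)),
                      [f"v{i}" for i in range(P)])
    free = rng.random((P, P)) < free_frac
    free[0, 0] = True
    mask = ModelMask(free, zeta_diagonal=zeta_diag)
    spec = ParamSpec(P, T, mask, means_by_wave=means_by_wave)
    obj = GVARObjective(SuffStats.from_dataset(ds), spec)
    theta = _random_theta(rng, spec)
    _, g = obj.value_and_grad(theta)
    eps = 1e-6
    for i in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += eps
        tm[i] -= eps
        fd = (obj.value(tp) - obj.value(tm)) / (2 * eps)
        assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)


def test_fiml_equals_closed_form_loglik_complete_data():
    # P = 2, T = 2, n = 20: objective loglik equals the direct sum of
    # multivariate-normal log-densities of the stacked observations
    rng = np.random.default_rng(1)
    n, T, P = 20, 2, 2
    X = rng.normal(size=(n, T, P))
    ds = PanelDataset(X, [f"s{i}" for i in range(n)], [0, 1], ["a", "b"])
    spec = ParamSpec(P, T, ModelMask.saturated(P))
    obj = GVARObjective(SuffStats.from_dataset(ds), spec)
    theta = _random_theta(rng, spec)
    mu, B, Lz, Lb = spec.unpack(theta)
    from panelnet.model import PanelGVARParams

    params = PanelGVARParams(mu, B, Lz @ Lz.T, Lb @ Lb.T)
    mean, cov = implied_moments(params, T)
    direct = sps.multivariate_normal(mean, cov).logpdf(ds.stacked()).sum()
    assert obj.loglik(theta) == pytest.approx(direct, rel=1e-10)


def test_moment_supplied_mode_zero_discrepancy():
    # feeding the model-implied moments back as data: fitted loglik
    # reaches the saturated loglik (discrepancy 0)
    rng = np.random.default_rng(2)
    p = random_stationary_params(rng, P=3)
    mean, cov = implied_moments(p, 3)
    fit = fit_panel_gvar(None, moments=(mean, cov, 500, 3, 3),
                         compute_se=False, init=p)
    assert fit.chisq == pytest.approx(0.0, abs=1e-5)
    assert fit.converged


def test_saturated_reference_model_has_zero_discrepancy():
    ds = simulate_panel(small_config(P=3, n=100, seed=3))
    st = SuffStats.from_dataset(ds)
    mu, sig = saturated_moments(st)
    assert st.loglik_at(mu, sig) == pytest.approx(saturated_loglik(st))
    # df = 0 convention of the fit indices
    assert fit_indices(0.0, 0, 100.0, 10, 50) == (1.0, 1.0, 0.0)


def test_em_saturated_matches_closed_form_when_complete():
    ds = simulate_panel(small_config(P=3, n=80, seed=4))
    st = SuffStats.from_dataset(ds)
    mu, sig = saturated_moments(st)
    X = ds.stacked()
    assert np.allclose(mu, X.mean(0))
    assert np.allclose(sig, np.cov(X, rowvar=False, ddof=0))


def test_fiml_handles_missing_cells():
    cfg = small_config(P=3, n=1500, seed=5, mcar=0.15)
    ds = simulate_panel(cfg)
    fit = fit_panel_gvar(ds, ModelMask(cfg.B_true != 0), compute_se=False)
    assert fit.converged
    assert np.abs(fit.params.B - cfg.B_true).max() < 0.12
    # complete-cases option drops subjects listwise
    fit_cc = fit_panel_gvar(ds, ModelMask(cfg.B_true != 0),
                            complete_cases=True, compute_se=False)
    assert fit_cc.n_subjects == ds.drop_incomplete().n_subjects
    assert fit_cc.n_subjects < fit.n_subjects


def test_fit_indices_printed_formula_example():
    cfi, tli, rmsea = fit_indices(50.0, 40, 500.0, 56, 101)
    assert cfi == pytest.approx(1.0 - 10.0 / 444.0, abs=1e-10)
    assert rmsea == pytest.approx(0.05, abs=1e-10)
    expected_tli = (500 / 56 - 50 / 40) / (500 / 56 - 1)
    assert tli == pytest.approx(expected_tli, abs=1e-10)
    # chisq equal to df: perfect fit
    cfi2, _, rmsea2 = fit_indices(40.0, 40, 500.0, 56, 101)
    assert cfi2 == 1.0 and rmsea2 == 0.0


def test_information_bic_definition_and_nesting_identity():
    class Dummy:
        loglik = -100.0
        n_free = 5
        n_subjects = int(np.exp(2))

    # ln(n) for n = floor(e^2) = 7 subjects
    assert information_bic(Dummy()) == pytest.approx(200 + 5 * np.log(7))
    Dummy.n_subjects = 1
    with pytest.raises(ValueError):
        information_bic(Dummy())

    ds = simulate_panel(small_config(P=3, n=300, seed=6))
    full = fit_panel_gvar(ds, ModelMask.saturated(3), compute_se=False)
    diag = fit_panel_gvar(ds, ModelMask(np.eye(3, dtype=bool)), compute_se=False)
    expected = (-2 * (diag.loglik - full.loglik)
                + (diag.n_free - full.n_free) * np.log(300))
    assert diag.bic - full.bic == pytest.approx(expected, abs=1e-8)


def test_bic_prefers_true_sparse_model():
    hits = 0
    for rep in range(5):
        cfg = small_config(P=4, n=2000, seed=50 + rep,
                           B=np.diag([0.3, 0.35, 0.3, 0.25]))
        ds = simulate_panel(cfg)
        sparse = fit_panel_gvar(ds, ModelMask(cfg.B_true != 0), compute_se=False)
        sat = fit_panel_gvar(ds, ModelMask.saturated(4), compute_se=False)
        hits += sparse.bic < sat.bic
    assert hits >= 4


def test_estimates_invariant_to_subject_order():
    ds = simulate_panel(small_config(P=3, n=200, seed=7))
    perm = np.random.default_rng(0).permutation(200)
    ds_perm = ds.subset(perm)
    f1 = fit_panel_gvar(ds, compute_se=False)
    f2 = fit_panel_gvar(ds_perm, compute_se=False)
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
    assert np.allclose(f1.params.B, f2.params.B, atol=1e-5)


def test_estimates_map_under_variable_reordering():
    cfg = small_config(P=3, n=400, seed=8,
                       B=np.array([[0.3, 0.15, 0.0],
                                   [0.0, 0.25, 0.0],
                                   [0.0, 0.0, 0.2]]))
    ds = simulate_panel(cfg)
    order = [2, 0, 1]
    ds_re = PanelDataset(
        ds.values[:, :, order], ds.subject_ids, ds.wave_labels,
        [ds.var_names[i] for i in order],
    )
    f1 = fit_panel_gvar(ds, compute_se=False)
    f2 = fit_panel_gvar(ds_re, compute_se=False)
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
    assert np.allclose(f1.params.B[np.ix_(order, order)], f2.params.B, atol=1e-5)


def test_wald_se_shrinks_with_sample_size():
    cfg1 = small_config(P=3, n=500, seed=9)
    cfg2 = small_config(P=3, n=2000, seed=9)
    f1 = fit_panel_gvar(simulate_panel(cfg1))
    f2 = fit_panel_gvar(simulate_panel(cfg2))
    se1, _ = wald_edge_tests(f1)
    se2, _ = wald_edge_tests(f2)
    ratio = np.nanmedian(se1) / np.nanmedian(se2)
    assert 1.6 < ratio < 2.4  # doubling n twice ~ factor 2


def test_nonconvergence_is_flagged_not_silent():
    # two subjects cannot identify a saturated 8-variable model
    ds = simulate_panel(small_config(P=3, n=12, seed=10))
    with pytest.warns(UserWarning, match="fewer subjects"):
        fit = fit_panel_gvar(ds, compute_se=False, max_restarts=0, maxiter=5)
    assert fit.converged in (True, False)  # returned, never raised
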