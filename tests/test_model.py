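"""Model-implied moment structure: Lyapunov solution, block-Toeplitz
covariance and standardization."""

import numpy as np
import pytest

from conftest import random_stationary_params
from panelnet.model import (
    ModelMask,
    PanelGVARParams,
    check_stationarity,
    implied_moments,
    standardize_temporal,
    stationary_within_covariance,
)
from panelnet.simulate import reference_network


def test_stationarity_check_boundaries():
    assert check_stationarity(np.zeros((3, 3))) == (True, 0.0)
    ok, radius = check_stationarity(np.eye(2))
    assert not ok and radius == pytest.approx(1.0)
    ok, _ = check_stationarity(reference_network())
    assert ok
    with pytest.raises(ValueError):
        check_stationarity(np.zeros((2, 3)))


def test_within_covariance_trivial_cases():
    sz = np.array([[2.0, 0.3], [0.3, 1.0]])
    assert np.allclose(stationary_within_covariance(np.zeros((2, 2)), sz), sz)
    # scalar closed form sigma^2 / (1 - b^2)
    out = stationary_within_covariance(0.5 * np.eye(2), 0.75 * np.eye(2))
    assert np.allclose(out, np.eye(2), atol=1e-12)


def test_within_covariance_against_two_oracles():
    rng = np.random.default_rng(3)
    for _ in range(5):
        p = random_stationary_params(rng, P=4)
        sig = stationary_within_covariance(p.B, p.sigma_zeta)
        # oracle 1: vec form (I - B kron B)^-1 vec(Sigma_zeta)
        P = 4
        vec = np.linalg.solve(
            np.eye(P * P) - np.kron(p.B, p.B), p.sigma_zeta.reshape(-1)
        ).reshape(P, P)
        assert np.allclose(sig, vec, atol=1e-10)
        # oracle 2: limit of iterating S <- B S B' + Sigma_zeta from 0
        it = np.zeros((P, P))
        for _ in range(2000):
            it = p.B @ it @ p.B.T + p.sigma_zeta
        assert np.allclose(sig, it, atol=1e-8)
        # satisfies the identity itself
        assert np.allclose(sig, p.B @ sig @ p.B.T + p.sigma_zeta, atol=1e-10)


def test_within_covariance_rejects_nonstationary():
    with pytest.raises(ValueError, match="spectral radius"):
        stationary_within_covariance(1.2 * np.eye(2), np.eye(2))


def test_implied_moments_single_wave_and_independence():
    rng = np.random.default_rng(4)
    p = random_stationary_params(rng, P=3)
    eta = stationary_within_covariance(p.B, p.sigma_zeta)
    _, cov1 = implied_moments(p, 1)
    assert np.allclose(cov1, eta + p.sigma_between, atol=1e-12)
    # B = 0: off-diagonal blocks are exactly the between-person covariance
    p0 = PanelGVARParams(p.mu, np.zeros((3, 3)), p.sigma_zeta, p.sigma_between)
    _, cov = implied_moments(p0, 3)
    assert np.allclose(cov[0:3, 3:6], p.sigma_between, atol=1e-14)
    assert np.allclose(cov[0:3, 6:9], p.sigma_between, atol=1e-14)


def test_implied_moments_block_structure_and_psd():
    rng = np.random.default_rng(5)
    for _ in range(5):
        p = random_stationary_params(rng, P=3)
        mean, cov = implied_moments(p, 4)
        P = 3
        assert np.allclose(cov, cov.T, atol=1e-12)
        assert np.min(np.linalg.eigvalsh(cov)) > -1e-10
        assert np.allclose(mean, np.tile(p.mu, 4))
        # within part is block-Toeplitz: block (s, t) depends only on s - t
        for k in range(1, 4):
            for s in range(k, 4):
                ref = cov[k * P:(k + 1) * P, 0:P]
                blk = cov[s * P:(s + 1) * P, (s - k) * P:(s - k + 1) * P]
                assert np.allclose(blk, ref, atol=1e-12)


def test_standardize_temporal():
    # equal stationary variances: unchanged
    B = np.array([[0.5, 0.0], [0.0, 0.5]])
    p = PanelGVARParams(np.zeros(2), B, 0.75 * np.eye(2), np.zeros((2, 2)))
    assert np.allclose(standardize_temporal(p), B)
    # hand computation: variances 1 and 4 -> sd ratio 2, b_std(1,2) = 0.2*2 = 0.4
    B2 = np.array([[0.0, 0.2], [0.0, 0.0]])
    eta_target = np.diag([1.0, 4.0])
    sigma_zeta = eta_target - B2 @ eta_target @ B2.T
    p2 = PanelGVARParams(np.zeros(2), B2, sigma_zeta, np.zeros((2, 2)))
    std = standardize_temporal(p2)
    assert std[0, 1] == pytest.approx(0.4, abs=1e-12)
    assert std[1, 0] == 0.0  # zero entries stay exactly zero


def test_standardize_idempotent_at_unit_variances():
    rng = np.random.default_rng(6)
    B = 0.3 * rng.normal(size=(3, 3))
    B *= 0.5 / np.max(np.abs(np.linalg.eigvals(B)))
    eta = np.eye(3)
    sigma_zeta = eta - B @ eta @ B.T  # forces unit stationary variances
    p = PanelGVARParams(np.zeros(3), B, sigma_zeta, np.zeros((3, 3)))
    assert np.allclose(standardize_temporal(p), B, atol=1e-10)


def test_params_json_roundtrip():
    rng = np.random.default_rng(8)
    p = random_stationary_params(rng, P=3)
    p.var_names = ["x", "y", "z"]
    q = PanelGVARParams.from_json(p.to_json())
    assert np.allclose(q.B, p.B)
    assert np.allclose(q.sigma_between, p.sigma_between)
    assert q.var_names == ["x", "y", "z"]


def test_model_mask_validation():
    m = ModelMask.saturated(3)
    assert m.free_B.all() and m.n_vars == 3
    with pytest.raises(ValueError):
        ModelMask(np.ones((2, 3), dtype=bool))
    e = ModelMask.empty(3)
    assert not e.free_B.any()
    assert e.key() != m.key()
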