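import numpy as np
import pytest

from panelnet.datasets import PanelDataset
from panelnet.simulate import GeneratorConfig, make_default_scenario, simulate_panel


def small_config(P=3, n=200, seed=0, B=None, between=0.4, n_waves=3, **kw):
    """Compact generator config for unit tests."""
    if B is None:
        B = 0.3 * np.eye(P)
    return GeneratorConfig(
        n_subjects=n,
        n_waves=n_waves,
        var_names=[f"v{i}" for i in range(P)],
        B_true=np.asarray(B, dtype=float),
        sigma_zeta=np.eye(P),
        sigma_between=between * np.eye(P),
        mu=np.zeros(P),
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def default_ds():
    """One mid-sized draw from the CBCL-like default scenario."""
    return simulate_panel(make_default_scenario(800, seed=42))


@pytest.fixture()
def tiny_ds():
    rng = np.random.default_rng(7)
    values = rng.normal(size=(12, 3, 2))
    return PanelDataset(
        values=values,
        subject_ids=[f"s{i}" for i in range(12)],
        wave_labels=[0, 1, 2],
        var_names=["a", "b"],
    )


def random_stationary_params(rng, P=4, radius=0.6):
    """Random stationary parameter set for moment-structure oracles."""
    from panelnet.model import PanelGVARParams

    B = rng.normal(size=(P, P))
    r = np.max(np.abs(np.linalg.eigvals(B)))
    B *= radius / r
    A = rng.normal(size=(P, P))
    sigma_zeta = A @ A.T / P + 0.5 * np.eye(P)
    C = rng.normal(size=(P, P))
    sigma_between = 0.5 * (C @ C.T / P)
    return PanelGVARParams(
        mu=rng.normal(size=P), B=B, sigma_zeta=sigma_zeta,
        sigma_between=sigma_between,
    )
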