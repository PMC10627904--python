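"""Panel GVAR parameterization and model-implied moments.

The model for subject *i*, wave *t* and variable vector ``y`` is

    y_it = mu + b_i + eta_it
    eta_it = B eta_{i,t-1} + zeta_it

with between-person random intercepts ``b_i ~ MVN(0, Sigma_between)``,
within-person innovations ``zeta_it ~ MVN(0, Sigma_zeta)`` and a
wave-constant (stationary) lag-1 coefficient matrix ``B``.  Rows of
``B`` index the outcome ("to") variable, columns the predictor
("from") variable: ``B[i, j]`` is the effect of variable *j* at wave
t-1 on variable *i* at wave t.

Under stationarity the within-person process covariance solves the
discrete Lyapunov equation ``Sigma_eta = B Sigma_eta B' + Sigma_zeta``
and the stacked T-wave observation vector has block-Toeplitz covariance
``Cov(y_s, y_t) = B^(s-t) Sigma_eta + Sigma_between`` for ``s >= t``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import linalg


@dataclass
class PanelGVARParams:
    """Parameter state of a panel GVAR model."""

    mu: np.ndarray           # (P,) means, constant over waves
    B: np.ndarray            # (P, P) temporal coefficients, rows = "to"
    sigma_zeta: np.ndarray   # (P, P) within-person innovation covariance (PD)
    sigma_between: np.ndarray  # (P, P) between-person covariance (PSD)
    var_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.sigma_zeta = np.asarray(self.sigma_zeta, dtype=float)
        self.sigma_between = np.asarray(self.sigma_between, dtype=float)
        P = len(self.mu)
        for name, m in (("B", self.B), ("sigma_zeta", self.sigma_zeta),
                        ("sigma_between", self.sigma_between)):
            if m.shape != (P, P):
                raise ValueError(f"{name} must be {P}x{P}, got {m.shape}")
        if self.var_names is not None and len(self.var_names) != P:
            raise ValueError("var_names length does not match mu")

    @property
    def n_vars(self) -> int:
        return len(self.mu)

    def to_json(self) -> str:
        names = list(self.var_names) if self.var_names is not None else [
            f"v{i}" for i in range(self.n_vars)
        ]
        payload = {
            "var_names": names,
            "mu": self.mu.tolist(),
            "B": self.B.tolist(),
            "sigma_zeta": self.sigma_zeta.tolist(),
            "sigma_between": self.sigma_between.tolist(),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PanelGVARParams":
        d = json.loads(text)
        return cls(
            mu=np.array(d["mu"]),
            B=np.array(d["B"]),
            sigma_zeta=np.array(d["sigma_zeta"]),
            sigma_between=np.array(d["sigma_between"]),
            var_names=d.get("var_names"),
        )


@dataclass
class ModelMask:
    """Free/fixed-zero structure over the temporal matrix.

    ``free_B[i, j]`` is True when the (to=i, from=j) temporal entry is
    freely estimated; False fixes it to zero.  The innovation and
    between-person covariances are estimated saturated by default;
    ``zeta_diagonal`` / ``between_diagonal`` restrict them to diagonal.
    """

    free_B: np.ndarray
    zeta_diagonal: bool = False
    between_diagonal: bool = False

    def __post_init__(self) -> None:
        self.free_B = np.asarray(self.free_B, dtype=bool)
        if self.free_B.ndim != 2 or self.free_B.shape[0] != self.free_B.shape[1]:
            raise ValueError("free_B must be a square boolean matrix")

    @property
    def n_vars(self) -> int:
        return self.free_B.shape[0]

    @classmethod
    def saturated(cls, P: int, **kw) -> "ModelMask":
        return cls(np.ones((P, P), dtype=bool), **kw)

    @classmethod
    def empty(cls, P: int, **kw) -> "ModelMask":
        """No temporal effects at all (intercept-only temporal structure)."""
        return cls(np.zeros((P, P), dtype=bool), **kw)

    def copy(self) -> "ModelMask":
        return ModelMask(self.free_B.copy(), self.zeta_diagonal, self.between_diagonal)

    def key(self) -> bytes:
        """Hashable identity of the temporal structure (cycle detection)."""
        return self.free_B.tobytes()


def check_stationarity(B: np.ndarray) -> tuple[bool, float]:
    """Whether the lag-1 process with coefficients ``B`` is stationary.

    Returns ``(stationary, spectral_radius)`` where stationarity requires
    the largest eigenvalue magnitude to be strictly below 1.
    """
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError("B must be square")
    radius = float(np.max(np.abs(np.linalg.eigvals(B)))) if B.size else 0.0
    return radius < 1.0, radius


def stationary_within_covariance(B: np.ndarray, sigma_zeta: np.ndarray) -> np.ndarray:
    """Stationary covariance of the within-person process.

    Solves ``Sigma_eta = B Sigma_eta B' + Sigma_zeta`` (discrete
    Lyapunov equation).
    """
    B = np.asarray(B, dtype=float)
    ok, radius = check_stationarity(B)
    if not ok:
        raise ValueError(f"non-stationary temporal matrix (spectral radius {radius:.4f})")
    sig = linalg.solve_discrete_lyapunov(B, np.asarray(sigma_zeta, dtype=float))
    return (sig + sig.T) / 2.0


def implied_moments(params: PanelGVARParams, n_waves: int) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean and covariance of the stacked wave vector.

    The stacked vector is wave-major: ``(y_1', ..., y_T')'`` with ``P``
    variables per wave.  Returns ``(mean (P*T,), cov (P*T, P*T))``.
    """
    if n_waves < 1:
        raise ValueError("n_waves must be >= 1")
    P = params.n_vars
    sigma_eta = stationary_within_covariance(params.B, params.sigma_zeta)
    powers = [np.eye(P)]
    for _ in range(n_waves - 1):
        powers.append(powers[-1] @ params.B)
    # powers[k] = B^k; note Cov(y_s, y_t) = B^(s-t) Sigma_eta + Sigma_b, s >= t
    cov = np.empty((P * n_waves, P * n_waves))
    for s in range(n_waves):
        for t in range(n_waves):
            if s >= t:
                block = powers[s - t] @ sigma_eta + params.sigma_between
            else:
                block = (powers[t - s] @ sigma_eta).T + params.sigma_between
            cov[s * P:(s + 1) * P, t * P:(t + 1) * P] = block
    mean = np.tile(params.mu, n_waves)
    return mean, (cov + cov.T) / 2.0


def standardize_temporal(params: PanelGVARParams) -> np.ndarray:
    """Standardized temporal coefficients.

    ``b_std[i, j] = B[i, j] * sd_j / sd_i`` with standard deviations from
    the diagonal of the stationary within-person covariance; fixed-zero
    entries stay exactly zero.
    """
    sigma_eta = stationary_within_covariance(params.B, params.sigma_zeta)
    sd = np.sqrt(np.diag(sigma_eta))
    if np.any(sd <= 0):
        raise ValueError("zero stationary variance; cannot standardize")
    return params.B * (sd[None, :] / sd[:, None])
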