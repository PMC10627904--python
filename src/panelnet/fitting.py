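"""Maximum-likelihood estimation of masked panel GVAR models.

Fitting maximizes the full-information multivariate-normal likelihood of
each subject's stacked wave vector under the model-implied moment
structure.  Subjects are grouped by missingness pattern; each pattern
contributes the likelihood of its observed sub-vector through pattern
sufficient statistics (mean and scatter), so complete data reduce to the
classical closed form in the sample mean and covariance.

The objective (average negative log-likelihood per subject) carries an
analytic gradient: derivatives flow through the block-Toeplitz implied
covariance, the discrete Lyapunov equation (via its adjoint) and the
Cholesky factors that keep the two covariance components positive
(semi)definite during unconstrained quasi-Newton optimization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .datasets import PanelDataset
from .model import ModelMask, PanelGVARParams

logger = logging.getLogger(__name__)

_RADIUS_MAX = 0.995
_PENALTY = 1e10


# ---------------------------------------------------------------------------
# sufficient statistics
# ---------------------------------------------------------------------------

@dataclass
class _Pattern:
    obs: np.ndarray      # boolean (d,) observed indicator
    n: int
    mean: np.ndarray     # (d_k,) mean of observed sub-vector
    scatter: np.ndarray  # (d_k, d_k) MLE covariance around the pattern mean


@dataclass
class SuffStats:
    """Pattern-wise sufficient statistics of the stacked panel."""

    patterns: list
    n_subjects: int
    d: int               # stacked dimension P*T
    P: int
    T: int

    @classmethod
    def from_dataset(cls, ds: PanelDataset) -> "SuffStats":
        X = ds.stacked()
        d = X.shape[1]
        obs = ~np.isnan(X)
        keep = obs.any(axis=1)
        X, obs = X[keep], obs[keep]
        pats: list = []
        uniq, inverse = np.unique(obs, axis=0, return_inverse=True)
        for k in range(uniq.shape[0]):
            rows = X[inverse == k][:, uniq[k]]
            m = rows.mean(axis=0)
            c = rows - m
            pats.append(_Pattern(uniq[k], rows.shape[0], m, c.T @ c / rows.shape[0]))
        return cls(pats, X.shape[0], d, ds.n_vars, ds.n_waves)

    @classmethod
    def from_moments(cls, mean: np.ndarray, cov: np.ndarray, n: int,
                     P: int, T: int) -> "SuffStats":
        """Moment-supplied mode: treat (mean, cov) as complete-data stats."""
        mean = np.asarray(mean, dtype=float)
        cov = np.asarray(cov, dtype=float)
        d = len(mean)
        if d != P * T:
            raise ValueError("moment dimension does not match P*T")
        pat = _Pattern(np.ones(d, dtype=bool), n, mean, cov)
        return cls([pat], n, d, P, T)

    @property
    def complete(self) -> bool:
        return len(self.patterns) == 1 and self.patterns[0].obs.all()

    def n_sat_params(self) -> int:
        return self.d + self.d * (self.d + 1) // 2

    def loglik_at(self, mean: np.ndarray, cov: np.ndarray) -> float:
        """FIML log-likelihood of arbitrary (mean, cov) on these stats."""
        ll = 0.0
        for p in self.patterns:
            idx = np.where(p.obs)[0]
            sig = cov[np.ix_(idx, idx)]
            c, low = linalg.cho_factor(sig, lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            inv = linalg.cho_solve((c, low), np.eye(len(idx)))
            delta = p.mean - mean[idx]
            quad = np.sum(inv * p.scatter) + delta @ inv @ delta
            ll -= 0.5 * p.n * (len(idx) * np.log(2 * np.pi) + logdet + quad)
        return float(ll)


def saturated_moments(stats_: SuffStats, tol: float = 1e-10,
                      max_iter: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Unstructured FIML (mean, covariance) estimate.

    Closed form for complete data; EM over missingness patterns
    otherwise.
    """
    d = stats_.d
    N = stats_.n_subjects
    if stats_.complete:
        p = stats_.patterns[0]
        return p.mean.copy(), p.scatter.copy()
    # initialize from available-case moments
    mu = np.zeros(d)
    cnt = np.zeros(d)
    for p in stats_.patterns:
        idx = np.where(p.obs)[0]
        mu[idx] += p.n * p.mean
        cnt[idx] += p.n
    mu = mu / np.maximum(cnt, 1)
    sig = np.eye(d)
    for p in stats_.patterns:
        idx = np.where(p.obs)[0]
        sig[np.ix_(idx, idx)] += p.n * p.scatter / N
    prev = -np.inf
    for _ in range(max_iter):
        T1 = np.zeros(d)
        T2 = np.zeros((d, d))
        for p in stats_.patterns:
            o = np.where(p.obs)[0]
            m = np.where(~p.obs)[0]
            Soo = sig[np.ix_(o, o)]
            inv = np.linalg.solve(Soo, np.eye(len(o)))
            yo_sum = p.n * p.mean
            T2_oo = p.n * (p.scatter + np.outer(p.mean, p.mean))
            T1[o] += yo_sum
            T2[np.ix_(o, o)] += T2_oo
            if len(m):
                A = sig[np.ix_(m, o)] @ inv
                c = mu[m] - A @ mu[o]
                ym_sum = p.n * c + A @ yo_sum
                T1[m] += ym_sum
                T2_om = np.outer(yo_sum, c) + T2_oo @ A.T
                T2[np.ix_(o, m)] += T2_om
                T2[np.ix_(m, o)] += T2_om.T
                V = sig[np.ix_(m, m)] - A @ sig[np.ix_(o, m)]
                T2[np.ix_(m, m)] += (
                    p.n * np.outer(c, c)
                    + np.outer(c, A @ yo_sum)
                    + np.outer(A @ yo_sum, c)
                    + A @ T2_oo @ A.T
                    + p.n * V
                )
        mu = T1 / N
        sig = T2 / N - np.outer(mu, mu)
        sig = (sig + sig.T) / 2.0
        ll = stats_.loglik_at(mu, sig)
        if abs(ll - prev) < tol * (1 + abs(ll)):
            break
        prev = ll
    return mu, sig


def saturated_loglik(stats_: SuffStats) -> float:
    mu, sig = saturated_moments(stats_)
    return stats_.loglik_at(mu, sig)


def independence_loglik(stats_: SuffStats) -> tuple[float, int]:
    """Baseline model: each stacked coordinate an independent normal with
    its own mean and variance.  Returns (loglik, n_params)."""
    d = stats_.d
    n = np.zeros(d)
    s1 = np.zeros(d)
    s2 = np.zeros(d)
    for p in stats_.patterns:
        idx = np.where(p.obs)[0]
        n[idx] += p.n
        s1[idx] += p.n * p.mean
        s2[idx] += p.n * (np.diag(p.scatter) + p.mean ** 2)
    mean = s1 / np.maximum(n, 1)
    var = s2 / np.maximum(n, 1) - mean ** 2
    var = np.maximum(var, 1e-12)
    ll = float(np.sum(-0.5 * n * (np.log(2 * np.pi) + np.log(var) + 1.0)))
    return ll, int(2 * (n > 0).sum())


# ---------------------------------------------------------------------------
# parameter vector layout
# ---------------------------------------------------------------------------

class ParamSpec:
    """Layout of the free parameter vector theta.

    Order: means, free temporal entries (row-major over the mask), the
    lower-triangular Cholesky factor of the innovation covariance, then
    of the between-person covariance.
    """

    def __init__(self, P: int, T: int, mask: ModelMask,
                 means_by_wave: bool = False) -> None:
        if mask.n_vars != P:
            raise ValueError("mask dimension does not match P")
        self.P, self.T = P, T
        self.mask = mask
        self.means_by_wave = means_by_wave
        self.n_mu = P * T if means_by_wave else P
        self.B_idx = np.argwhere(mask.free_B)  # (nB, 2) rows (to, from)
        self.nB = len(self.B_idx)
        if self.nB == 0 and mask.free_B.size:
            pass  # intercept-only temporal structure is allowed
        tri = np.tril_indices(P)
        diag = (np.arange(P), np.arange(P))
        self.z_idx = diag if mask.zeta_diagonal else tri
        self.b_idx = diag if mask.between_diagonal else tri
        self.nz = len(self.z_idx[0])
        self.nb = len(self.b_idx[0])
        self.n_theta = self.n_mu + self.nB + self.nz + self.nb

    @property
    def n_free(self) -> int:
        """Count of free statistical parameters (for df and BIC)."""
        return self.n_theta

    def slices(self):
        a = self.n_mu
        b = a + self.nB
        c = b + self.nz
        return slice(0, a), slice(a, b), slice(b, c), slice(c, self.n_theta)

    def b_positions(self) -> np.ndarray:
        """theta index of each free B entry, aligned with ``B_idx``."""
        return self.n_mu + np.arange(self.nB)

    def unpack(self, theta: np.ndarray):
        s_mu, s_B, s_z, s_b = self.slices()
        P = self.P
        mu = theta[s_mu]
        B = np.zeros((P, P))
        if self.nB:
            B[self.B_idx[:, 0], self.B_idx[:, 1]] = theta[s_B]
        Lz = np.zeros((P, P))
        Lz[self.z_idx] = theta[s_z]
        Lb = np.zeros((P, P))
        Lb[self.b_idx] = theta[s_b]
        return mu, B, Lz, Lb

    def pack(self, mu: np.ndarray, B: np.ndarray, Lz: np.ndarray,
             Lb: np.ndarray) -> np.ndarray:
        theta = np.empty(self.n_theta)
        s_mu, s_B, s_z, s_b = self.slices()
        theta[s_mu] = mu
        if self.nB:
            theta[s_B] = B[self.B_idx[:, 0], self.B_idx[:, 1]]
        theta[s_z] = Lz[self.z_idx]
        theta[s_b] = Lb[self.b_idx]
        return theta

    def pack_params(self, params: PanelGVARParams) -> np.ndarray:
        Lz = _safe_cholesky(params.sigma_zeta)
        Lb = _safe_cholesky(params.sigma_between)
        mu = np.tile(params.mu, self.T) if self.means_by_wave else params.mu
        return self.pack(mu, params.B * self.mask.free_B, Lz, Lb)

    def to_params(self, theta: np.ndarray,
                  var_names: Optional[Sequence[str]] = None) -> PanelGVARParams:
        mu, B, Lz, Lb = self.unpack(theta)
        if self.means_by_wave:
            mu = mu.reshape(self.T, self.P).mean(axis=0)
        return PanelGVARParams(
            mu=mu, B=B, sigma_zeta=Lz @ Lz.T, sigma_between=Lb @ Lb.T,
            var_names=list(var_names) if var_names is not None else None,
        )


def _safe_cholesky(sigma: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    sigma = (sigma + sigma.T) / 2.0
    scale = max(np.trace(sigma) / len(sigma), 1e-6)
    for boost in (0.0, ridge, 1e-4, 1e-2):
        try:
            return np.linalg.cholesky(sigma + boost * scale * np.eye(len(sigma)))
        except np.linalg.LinAlgError:
            continue
    w, v = np.linalg.eigh(sigma)
    w = np.maximum(w, 1e-6 * scale)
    return np.linalg.cholesky(v @ np.diag(w) @ v.T)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

class GVARObjective:
    """Average negative FIML log-likelihood and its analytic gradient."""

    def __init__(self, stats_: SuffStats, spec: ParamSpec) -> None:
        if stats_.P != spec.P or stats_.T != spec.T:
            raise ValueError("statistics and spec disagree on P or T")
        self.stats = stats_
        self.spec = spec

    # objective value only
    def value(self, theta: np.ndarray) -> float:
        return self.value_and_grad(theta)[0]

    def loglik(self, theta: np.ndarray) -> float:
        return -self.stats.n_subjects * self.value(theta)

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        spec, st = self.spec, self.stats
        P, T = spec.P, spec.T
        d = P * T
        N = st.n_subjects
        mu, B, Lz, Lb = spec.unpack(theta)

        radius = float(np.max(np.abs(np.linalg.eigvals(B)))) if P else 0.0
        if not np.isfinite(radius) or radius >= _RADIUS_MAX:
            return _PENALTY * (1.0 + radius), np.zeros_like(theta)

        sigma_zeta = Lz @ Lz.T
        sigma_b = Lb @ Lb.T
        try:
            sigma_eta = linalg.solve_discrete_lyapunov(B, sigma_zeta)
        except Exception:
            return _PENALTY, np.zeros_like(theta)
        sigma_eta = (sigma_eta + sigma_eta.T) / 2.0

        powers = [np.eye(P)]
        for _ in range(T - 1):
            powers.append(powers[-1] @ B)
        cov = np.empty((d, d))
        for s in range(T):
            for t in range(T):
                if s >= t:
                    block = powers[s - t] @ sigma_eta + sigma_b
                else:
                    block = (powers[t - s] @ sigma_eta).T + sigma_b
                cov[s * P:(s + 1) * P, t * P:(t + 1) * P] = block
        cov = (cov + cov.T) / 2.0
        mu_full = mu if spec.means_by_wave else np.tile(mu, T)

        f = 0.0
        G = np.zeros((d, d))
        h = np.zeros(d)
        for p in st.patterns:
            idx = np.where(p.obs)[0]
            sig = cov[np.ix_(idx, idx)]
            try:
                c, low = linalg.cho_factor(sig, lower=True)
            except linalg.LinAlgError:
                return _PENALTY, np.zeros_like(theta)
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            inv = linalg.cho_solve((c, low), np.eye(len(idx)))
            delta = p.mean - mu_full[idx]
            A = p.scatter + np.outer(delta, delta)
            f += 0.5 * p.n * (len(idx) * np.log(2 * np.pi) + logdet
                              + np.sum(inv * A))
            W = 0.5 * p.n * (inv - inv @ A @ inv)
            G[np.ix_(idx, idx)] += W
            h[idx] += -p.n * (inv @ delta)
        f /= N
        G /= N
        h /= N

        # block-reduce G by lag: C_k collects tr(G dSigma) coefficients
        C = [np.zeros((P, P)) for _ in range(T)]
        for s in range(T):
            C[0] += G[s * P:(s + 1) * P, s * P:(s + 1) * P]
            for t in range(s):
                C[s - t] += 2.0 * G[s * P:(s + 1) * P, t * P:(t + 1) * P]

        grad_Sb = np.zeros((P, P))
        Q = np.zeros((P, P))
        grad_B = np.zeros((P, P))
        for k in range(T):
            grad_Sb += C[k]
            Q += powers[k].T @ C[k]
            for j in range(k):  # d(B^k) route, k >= 1
                grad_B += (powers[j].T @ C[k] @ sigma_eta
                           @ powers[k - 1 - j].T)
        # adjoint of the Lyapunov map: R = B' R B + Q
        R = linalg.solve_discrete_lyapunov(B.T, Q)
        grad_B += (R + R.T) @ B @ sigma_eta
        grad_Lz = (R + R.T) @ Lz
        grad_Lb = (grad_Sb + grad_Sb.T) @ Lb

        if spec.means_by_wave:
            grad_mu = h
        else:
            grad_mu = h.reshape(T, P).sum(axis=0)

        g = np.empty_like(theta)
        s_mu, s_B, s_z, s_b = spec.slices()
        g[s_mu] = grad_mu
        if spec.nB:
            g[s_B] = grad_B[spec.B_idx[:, 0], spec.B_idx[:, 1]]
        g[s_z] = grad_Lz[spec.z_idx]
        g[s_b] = grad_Lb[spec.b_idx]
        return float(f), g

    def numerical_hessian(self, theta: np.ndarray, step: float = 1e-5) -> np.ndarray:
        """Hessian of the average objective by central differences of the
        analytic gradient."""
        k = len(theta)
        H = np.empty((k, k))
        for i in range(k):
            hstep = step * (1.0 + abs(theta[i]))
            tp = theta.copy(); tp[i] += hstep
            tm = theta.copy(); tm[i] -= hstep
            H[:, i] = (self.value_and_grad(tp)[1]
                       - self.value_and_grad(tm)[1]) / (2 * hstep)
        return (H + H.T) / 2.0


# ---------------------------------------------------------------------------
# warm start
# ---------------------------------------------------------------------------

def warm_start(stats_: SuffStats, spec: ParamSpec) -> np.ndarray:
    """Moment-based starting values.

    Temporal coefficients come from a pooled lag-1 regression of
    within-person deviations; the two covariance components from a
    within/between moment split.  Rough but close enough for the
    quasi-Newton optimizer to converge quickly and deterministically.
    """
    P, T = spec.P, spec.T
    mu_sat, sig_sat = saturated_moments(stats_)
    mean_pw = mu_sat.reshape(T, P)
    mu0 = mean_pw.mean(axis=0)

    # average same-lag covariance blocks of the saturated estimate
    def lag_block(k: int) -> np.ndarray:
        acc = np.zeros((P, P))
        cnt = 0
        for s in range(k, T):
            t = s - k
            acc += sig_sat[s * P:(s + 1) * P, t * P:(t + 1) * P]
            cnt += 1
        return acc / max(cnt, 1)

    S0, S1 = lag_block(0), lag_block(1)
    S_last = lag_block(T - 1)
    # between-person component: shared across all lags; the most-distant
    # lag is the least contaminated by the within process
    sigma_b0 = (S_last + S_last.T) / 2.0
    sigma_b0 = _project_psd(sigma_b0, floor=0.0)
    eta0 = _project_psd(S0 - sigma_b0, floor=1e-3)
    eta1 = S1 - sigma_b0
    try:
        B0 = np.linalg.solve(eta0.T, eta1.T).T  # eta1 = B0 @ eta0
    except np.linalg.LinAlgError:
        B0 = np.zeros((P, P))
    B0 = B0 * spec.mask.free_B
    rad = float(np.max(np.abs(np.linalg.eigvals(B0)))) if P else 0.0
    if rad >= 0.9:
        B0 *= 0.85 / rad
    sigma_z0 = _project_psd(eta0 - B0 @ eta0 @ B0.T, floor=1e-3)
    Lz = _safe_cholesky(sigma_z0)
    scale = np.trace(eta0) / P
    Lb = _safe_cholesky(sigma_b0 + 0.05 * scale * np.eye(P))
    mu_init = mean_pw.reshape(-1) if spec.means_by_wave else mu0
    return spec.pack(mu_init, B0, Lz, Lb)


def _project_psd(m: np.ndarray, floor: float = 0.0) -> np.ndarray:
    m = (m + m.T) / 2.0
    w, v = np.linalg.eigh(m)
    scale = max(abs(w).max(), 1e-6)
    w = np.maximum(w, floor * scale)
    return v @ np.diag(w) @ v.T


# ---------------------------------------------------------------------------
# fit result and main entry point
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, fit statistics and inferential quantities of one fit."""

    params: PanelGVARParams
    mask: ModelMask
    loglik: float
    n_free: int
    n_subjects: int
    chisq: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    bic: float
    converged: bool
    se_B: Optional[np.ndarray] = None
    p_B: Optional[np.ndarray] = None
    ll_saturated: Optional[float] = None
    ll_baseline: Optional[float] = None
    df_baseline: Optional[int] = None
    grad_norm: Optional[float] = None
    theta: Optional[np.ndarray] = field(default=None, repr=False)
    _objective: Optional[GVARObjective] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        names = (list(self.params.var_names)
                 if self.params.var_names is not None else None)
        return {
            "var_names": names,
            "mu": self.params.mu.tolist(),
            "B": self.params.B.tolist(),
            "sigma_zeta": self.params.sigma_zeta.tolist(),
            "sigma_between": self.params.sigma_between.tolist(),
            "free_B": self.mask.free_B.tolist(),
            "loglik": self.loglik,
            "n_free": self.n_free,
            "n_subjects": self.n_subjects,
            "chisq": self.chisq,
            "df": self.df,
            "cfi": self.cfi,
            "tli": self.tli,
            "rmsea": self.rmsea,
            "bic": self.bic,
            "converged": self.converged,
            "se_B": None if self.se_B is None else self.se_B.tolist(),
            "p_B": None if self.p_B is None else self.p_B.tolist(),
        }


def fit_indices(chisq_m: float, df_m: int, chisq_0: float, df_0: int,
                n_subjects: int) -> tuple[float, float, float]:
    """CFI, TLI and RMSEA from model and baseline chi-square statistics.

    When the model has zero degrees of freedom the conventions CFI = 1,
    TLI = 1 and RMSEA = 0 apply.
    """
    if df_m == 0:
        return 1.0, 1.0, 0.0
    num = max(chisq_m - df_m, 0.0)
    den = max(chisq_0 - df_0, chisq_m - df_m, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    if df_0 > 0 and chisq_0 / df_0 != 1.0:
        tli = (chisq_0 / df_0 - chisq_m / df_m) / (chisq_0 / df_0 - 1.0)
    else:
        tli = 1.0
    rmsea = float(np.sqrt(num / (df_m * (n_subjects - 1))))
    return float(cfi), float(tli), rmsea


def fit_indices_from_results(fit: FitResult, baseline: FitResult
                             ) -> tuple[float, float, float]:
    """Fit indices of ``fit`` against an explicit baseline fit."""
    return fit_indices(fit.chisq, fit.df, baseline.chisq, baseline.df,
                       fit.n_subjects)


def information_bic(fit: FitResult) -> float:
    """BIC = -2 loglik + k log(n), n the number of subjects."""
    if fit.n_subjects < 2:
        raise ValueError("BIC undefined for fewer than 2 subjects")
    return -2.0 * fit.loglik + fit.n_free * np.log(fit.n_subjects)


def wald_edge_tests(fit: FitResult) -> tuple[np.ndarray, np.ndarray]:
    """Standard errors and two-sided Wald p-values of free temporal entries.

    SEs come from the inverse observed information at the optimum;
    fixed-zero entries are NaN.  Results are cached on the fit.
    """
    if fit.se_B is not None and fit.p_B is not None:
        return fit.se_B, fit.p_B
    if fit._objective is None or fit.theta is None:
        raise ValueError("fit does not carry its objective; refit with compute_se")
    se_B, p_B = _compute_wald(fit._objective, fit.theta, fit.n_subjects)
    fit.se_B, fit.p_B = se_B, p_B
    return se_B, p_B


def _compute_wald(obj: GVARObjective, theta: np.ndarray, n: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    spec = obj.spec
    H = obj.numerical_hessian(theta)
    info = n * H  # observed information of the total loglik
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        deficient = int(np.argmin(np.diag(info)))
        raise np.linalg.LinAlgError(
            f"observed information is singular (parameter index {deficient})"
        )
    var = np.diag(cov)
    if np.any(var[spec.b_positions()] <= 0) if spec.nB else False:
        # indefinite information at a boundary: fall back to pseudo-inverse
        cov = np.linalg.pinv(info)
        var = np.abs(np.diag(cov))
    P = spec.P
    se_B = np.full((P, P), np.nan)
    p_B = np.full((P, P), np.nan)
    if spec.nB:
        pos = spec.b_positions()
        se = np.sqrt(np.maximum(var[pos], 0.0))
        b_hat = theta[pos]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, b_hat / se, np.inf * np.sign(b_hat))
        z = np.where(b_hat == 0.0, 0.0, z)
        pv = 2.0 * stats.norm.sf(np.abs(z))
        se_B[spec.B_idx[:, 0], spec.B_idx[:, 1]] = se
        p_B[spec.B_idx[:, 0], spec.B_idx[:, 1]] = pv
    return se_B, p_B


def fit_panel_gvar(
    ds: Optional[PanelDataset],
    mask: Optional[ModelMask] = None,
    *,
    moments: Optional[tuple] = None,
    complete_cases: bool = False,
    means_by_wave: bool = False,
    compute_se: bool = True,
    init: Optional[PanelGVARParams] = None,
    init_theta: Optional[np.ndarray] = None,
    max_restarts: int = 3,
    seed: int = 0,
    gtol: float = 1e-6,
    maxiter: int = 4000,
) -> FitResult:
    """Fit a masked panel GVAR by full-information maximum likelihood.

    Parameters
    ----------
    ds
        Panel dataset (ignored when ``moments`` is given).
    mask
        Free/fixed-zero temporal structure; defaults to saturated.
    moments
        Optional ``(mean, cov, n_subjects, P, T)`` tuple for
        moment-supplied mode.
    complete_cases
        Drop subjects with any missing cell before fitting (listwise).
    init, init_theta
        Optional warm start (parameter object or raw theta vector).
    max_restarts
        Jittered restarts attempted when the optimizer fails to reach
        the gradient tolerance.

    Notes
    -----
    Estimates are invariant to subject order (the likelihood depends on
    the data only through pattern sufficient statistics).  Non-converged
    fits are returned with ``converged=False`` and a logged warning,
    never silently.
    """
    var_names = None
    if moments is not None:
        mean, cov, n, P, T = moments
        stats_ = SuffStats.from_moments(mean, cov, n, P, T)
    else:
        if ds is None:
            raise ValueError("either ds or moments is required")
        if ds.n_waves < 2:
            raise ValueError("need at least two waves")
        if complete_cases:
            ds = ds.drop_incomplete()
        stats_ = SuffStats.from_dataset(ds)
        var_names = list(ds.var_names)
    return fit_from_suffstats(
        stats_, mask, var_names=var_names, means_by_wave=means_by_wave,
        compute_se=compute_se, init=init, init_theta=init_theta,
        max_restarts=max_restarts, seed=seed, gtol=gtol, maxiter=maxiter,
    )


def fit_from_suffstats(
    stats_: SuffStats,
    mask: Optional[ModelMask] = None,
    *,
    var_names: Optional[Sequence[str]] = None,
    means_by_wave: bool = False,
    compute_se: bool = True,
    init: Optional[PanelGVARParams] = None,
    init_theta: Optional[np.ndarray] = None,
    max_restarts: int = 3,
    seed: int = 0,
    gtol: float = 1e-6,
    maxiter: int = 4000,
) -> FitResult:
    """Fit directly from pattern sufficient statistics (advanced use)."""
    if mask is None:
        mask = ModelMask.saturated(stats_.P)
    spec = ParamSpec(stats_.P, stats_.T, mask, means_by_wave=means_by_wave)
    if stats_.n_subjects <= spec.n_free:
        warnings.warn(
            f"fewer subjects ({stats_.n_subjects}) than free parameters "
            f"({spec.n_free}); estimates will be unstable"
        )
    obj = GVARObjective(stats_, spec)

    if init_theta is not None:
        theta0 = np.asarray(init_theta, dtype=float).copy()
    elif init is not None:
        theta0 = spec.pack_params(init)
    else:
        theta0 = warm_start(stats_, spec)

    rng = np.random.default_rng(seed)
    best = None
    converged = False
    theta_start = theta0
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(
            obj.value_and_grad, theta_start, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-13, "gtol": gtol / 10.0},
        )
        gnorm = float(np.max(np.abs(res.jac)))
        if best is None or res.fun < best[0].fun:
            best = (res, gnorm)
        if gnorm < gtol or res.fun >= _PENALTY:
            converged = gnorm < gtol
            break
        theta_start = theta0 + rng.normal(scale=0.05, size=theta0.shape)
    res, gnorm = best
    converged = converged or gnorm < gtol
    if not converged:
        logger.warning("fit did not reach gradient tolerance (|g|=%.2e)", gnorm)
    theta = res.x

    params = spec.to_params(theta, var_names)
    N = stats_.n_subjects
    loglik = -N * float(res.fun)
    ll_sat = saturated_loglik(stats_)
    chisq = max(2.0 * (ll_sat - loglik), 0.0)
    df = stats_.n_sat_params() - spec.n_free
    ll_0, n_0 = independence_loglik(stats_)
    chisq_0 = max(2.0 * (ll_sat - ll_0), 0.0)
    df_0 = stats_.n_sat_params() - n_0
    cfi, tli, rmsea = fit_indices(chisq, df, chisq_0, df_0, N)
    bic = -2.0 * loglik + spec.n_free * np.log(N)

    fit = FitResult(
        params=params, mask=mask, loglik=loglik, n_free=spec.n_free,
        n_subjects=N, chisq=chisq, df=df, cfi=cfi, tli=tli, rmsea=rmsea,
        bic=bic, converged=converged, ll_saturated=ll_sat, ll_baseline=ll_0,
        df_baseline=df_0, grad_norm=gnorm, theta=theta, _objective=obj,
    )
    if compute_se:
        try:
            fit.se_B, fit.p_B = _compute_wald(obj, theta, N)
        except np.linalg.LinAlgError as err:
            logger.warning("Wald SEs unavailable: %s", err)
    return fit
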