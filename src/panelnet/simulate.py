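"""Synthetic multi-wave panel generation.

Generates panels from the same data-generating process the estimator
assumes: a stationary within-person lag-1 process on top of
between-person random intercepts, optionally pushed through a CBCL-like
T-score transform (floor 50, ceiling 100) that induces the positive
skew and excess kurtosis seen in bounded syndrome-scale scores.
Ground-truth parameters are retained on the result for recovery tests.

The default scenario reproduces the published total-sample temporal
network of eight CBCL syndrome scales: the signed standardized
coefficients of its 20 retained edges populate ``B_true`` (rows = "to",
columns = "from"), everything else is zero, innovations have unit
variance and between-person variances are 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .datasets import DEFAULT_COMMUNITIES, DEFAULT_VARS, PanelDataset
from .model import PanelGVARParams, check_stationarity, stationary_within_covariance

#: Published total-sample temporal edges as (from, to, standardized beta).
#: Autoregressive effects sit on the diagonal of the assembled matrix.
REFERENCE_EDGES: tuple[tuple[str, str, float], ...] = (
    ("AnxDep", "AnxDep", 0.091),
    ("AnxDep", "Somatic", 0.049),
    ("AnxDep", "Social", 0.089),
    ("AnxDep", "Thought", 0.066),
    ("WithDep", "WithDep", 0.104),
    ("WithDep", "RuleBreak", 0.067),
    ("Somatic", "Somatic", 0.116),
    ("Somatic", "Social", -0.042),
    ("Social", "AnxDep", 0.067),
    ("Social", "Social", 0.158),
    ("Social", "RuleBreak", 0.047),
    ("Thought", "AnxDep", 0.032),
    ("Thought", "Thought", 0.099),
    ("Attention", "Attention", 0.074),
    ("RuleBreak", "WithDep", 0.033),
    ("RuleBreak", "RuleBreak", 0.109),
    ("Aggressive", "WithDep", 0.035),
    ("Aggressive", "Thought", 0.049),
    ("Aggressive", "Attention", 0.042),
    ("Aggressive", "Aggressive", 0.166),
)

#: Gender-contrast overrides: the externalizing -> other-scale edges whose
#: published female and male estimates flip sign.  Keys are (from, to).
GROUP_CONTRAST_EDGES: Mapping[str, Mapping[tuple, float]] = {
    "female": {
        ("RuleBreak", "AnxDep"): -0.034,
        ("RuleBreak", "Thought"): -0.052,
        ("Aggressive", "Somatic"): -0.058,
    },
    "male": {
        ("RuleBreak", "AnxDep"): 0.095,
        ("RuleBreak", "Thought"): 0.069,
        ("Aggressive", "Somatic"): 0.067,
    },
}


@dataclass
class GeneratorConfig:
    """Full specification of the data-generating process."""

    n_subjects: int
    n_waves: int
    var_names: Sequence[str]
    B_true: np.ndarray
    sigma_zeta: np.ndarray
    sigma_between: np.ndarray
    mu: np.ndarray
    communities: Mapping[str, str] = field(default_factory=dict)
    censor: bool = False
    mcar: float = 0.0
    group_configs: Optional[Mapping[str, np.ndarray]] = None  # label -> B override
    group_sizes: Optional[Mapping[str, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.B_true = np.asarray(self.B_true, dtype=float)
        self.sigma_zeta = np.asarray(self.sigma_zeta, dtype=float)
        self.sigma_between = np.asarray(self.sigma_between, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        P = len(self.var_names)
        if self.B_true.shape != (P, P):
            raise ValueError("B_true shape does not match var_names")
        if self.n_subjects < 1 or self.n_waves < 2:
            raise ValueError("need n_subjects >= 1 and n_waves >= 2")
        if not 0.0 <= self.mcar < 1.0:
            raise ValueError("mcar must be in [0, 1)")
        for B in [self.B_true] + list((self.group_configs or {}).values()):
            ok, radius = check_stationarity(B)
            if not ok:
                raise ValueError(
                    f"non-stationary generating matrix (spectral radius {radius:.4f})"
                )
        np.linalg.cholesky(self.sigma_zeta)  # PD check

    def params(self, group: Optional[str] = None) -> PanelGVARParams:
        B = self.B_true
        if group is not None and self.group_configs:
            B = self.group_configs.get(group, self.B_true)
        return PanelGVARParams(
            mu=self.mu,
            B=np.asarray(B, dtype=float),
            sigma_zeta=self.sigma_zeta,
            sigma_between=self.sigma_between,
            var_names=list(self.var_names),
        )


def reference_network(var_names: Sequence[str] = DEFAULT_VARS) -> np.ndarray:
    """Assemble the published edge list into a (to, from) matrix."""
    pos = {v: i for i, v in enumerate(var_names)}
    B = np.zeros((len(var_names), len(var_names)))
    for frm, to, beta in REFERENCE_EDGES:
        B[pos[to], pos[frm]] = beta
    return B


def make_default_scenario(
    n_subjects: int,
    seed: int = 0,
    n_waves: int = 3,
    censor: bool = False,
    mcar: float = 0.0,
) -> GeneratorConfig:
    """Default CBCL-like scenario: published temporal network, unit
    innovation variances, between-person variance 0.5 per variable."""
    P = len(DEFAULT_VARS)
    return GeneratorConfig(
        n_subjects=n_subjects,
        n_waves=n_waves,
        var_names=list(DEFAULT_VARS),
        B_true=reference_network(),
        sigma_zeta=np.eye(P),
        sigma_between=0.5 * np.eye(P),
        mu=np.zeros(P),
        communities=dict(DEFAULT_COMMUNITIES),
        censor=censor,
        mcar=mcar,
        seed=seed,
    )


def make_group_scenario(
    n_per_group: int,
    seed: int = 0,
    n_waves: int = 3,
    censor: bool = False,
) -> GeneratorConfig:
    """Two-group scenario with the published gender sign contrast.

    Both groups share the default temporal network except for three
    externalizing -> other-scale edges whose signs flip between groups,
    giving invariance tests a true positive.
    """
    base = make_default_scenario(2 * n_per_group, seed=seed, n_waves=n_waves, censor=censor)
    pos = {v: i for i, v in enumerate(base.var_names)}
    groups = {}
    for label, overrides in GROUP_CONTRAST_EDGES.items():
        B = base.B_true.copy()
        for (frm, to), beta in overrides.items():
            B[pos[to], pos[frm]] = beta
        groups[label] = B
    base.group_configs = groups
    base.group_sizes = {"female": n_per_group, "male": n_per_group}
    return base


def _simulate_block(
    rng: np.random.Generator,
    n: int,
    n_waves: int,
    params: PanelGVARParams,
) -> np.ndarray:
    """Simulate n subjects from one parameter set; (n, T, P) array."""
    P = params.n_vars
    sigma_eta = stationary_within_covariance(params.B, params.sigma_zeta)
    # between-person covariance may be singular (PSD): use an eigen factor
    w, v = np.linalg.eigh((params.sigma_between + params.sigma_between.T) / 2.0)
    factor = v @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    b_i = rng.standard_normal(size=(n, P)) @ factor.T
    eta = rng.multivariate_normal(np.zeros(P), sigma_eta, size=n, method="cholesky")
    out = np.empty((n, n_waves, P))
    out[:, 0, :] = params.mu + b_i + eta
    for t in range(1, n_waves):
        zeta = rng.multivariate_normal(np.zeros(P), params.sigma_zeta, size=n,
                                       method="cholesky")
        eta = eta @ params.B.T + zeta
        out[:, t, :] = params.mu + b_i + eta
    return out


def simulate_panel(config: GeneratorConfig) -> PanelDataset:
    """Simulate a panel dataset from ``config``.

    The within-person process starts in its stationary distribution, so
    every wave is marginally stationary and three waves suffice for the
    stationary estimator.  The generating parameters are attached to the
    result as ``ds.ground_truth`` (label ``None`` for the single-group
    case, one entry per label otherwise).  Fixed seed implies
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    if config.group_configs:
        sizes = config.group_sizes
        if sizes is None:
            labels = sorted(config.group_configs)
            base, extra = divmod(config.n_subjects, len(labels))
            sizes = {g: base + (1 if i < extra else 0) for i, g in enumerate(labels)}
        blocks, group = [], []
        truth = {}
        for label in sorted(sizes):
            p = config.params(label)
            truth[label] = p
            blocks.append(_simulate_block(rng, sizes[label], config.n_waves, p))
            group.extend([label] * sizes[label])
        values = np.concatenate(blocks, axis=0)
    else:
        p = config.params()
        truth = {None: p}
        values = _simulate_block(rng, config.n_subjects, config.n_waves, p)
        group = None

    n = values.shape[0]
    if config.mcar > 0:
        drop = rng.random(values.shape) < config.mcar
        values = np.where(drop, np.nan, values)

    ds = PanelDataset(
        values=values,
        subject_ids=[f"s{i:06d}" for i in range(n)],
        wave_labels=list(range(config.n_waves)),
        var_names=list(config.var_names),
        group=group,
        communities=dict(config.communities),
    )
    if config.censor:
        ds = apply_tscore_censoring(ds)
    ds.ground_truth = truth
    return ds


def apply_tscore_censoring(ds: PanelDataset) -> PanelDataset:
    """Map scores onto the bounded T-score scale.

    Each variable is z-scored over all observed cells and transformed as
    ``clip(50 + 10 z, 50, 100)``: everything at or below the variable
    mean collapses onto the floor of 50, producing the mass point,
    positive skew and excess kurtosis characteristic of normed syndrome
    scores.
    """
    vals = ds.values.copy()
    for j in range(ds.n_vars):
        col = vals[:, :, j]
        obs = ~np.isnan(col)
        m = col[obs].mean()
        s = col[obs].std()
        z = (col - m) / (s if s > 0 else 1.0)
        vals[:, :, j] = np.clip(50.0 + 10.0 * z, 50.0, 100.0)
    out = PanelDataset(
        values=vals,
        subject_ids=list(ds.subject_ids),
        wave_labels=list(ds.wave_labels),
        var_names=list(ds.var_names),
        group=None if ds.group is None else list(ds.group),
        communities=dict(ds.communities),
    )
    if hasattr(ds, "ground_truth"):
        out.ground_truth = ds.ground_truth
    return out
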