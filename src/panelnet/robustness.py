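"""Bootstrap robustness of the searched network and centrality stability.

Two arms mirror how directed symptom networks are stress-tested:

* **edge-inclusion bootstrap** — resample subjects with replacement,
  rerun the full model search on each replicate, and record how often
  each temporal edge lands in the optimal model; inclusion above 50%
  counts as robust.
* **case-dropping subset bootstrap** — repeatedly drop a fixed fraction
  of subjects (without replacement), refit the *fixed* final structure,
  recompute centralities and take 2.5th/97.5th percentile bounds.

Replicates draw from independent substreams spawned off the master
seed, so results are bit-identical for a given seed whether replicates
run sequentially or in parallel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from joblib import Parallel, delayed

from .centrality import CentralityTable, centrality_table
from .datasets import PanelDataset
from .fitting import FitResult, fit_panel_gvar

from .search import search_model

logger = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    """Results of either bootstrap arm (unused fields stay None)."""

    var_names: list
    seed: int
    # edge-inclusion arm
    n_boot: Optional[int] = None
    n_success: Optional[int] = None
    inclusion_prob: Optional[np.ndarray] = None   # (P, P), rows = "to"
    sign_agreement: Optional[np.ndarray] = None   # (P, P), NaN if never included
    robust: Optional[np.ndarray] = None           # inclusion_prob > 0.5
    # case-drop arm
    n_iter: Optional[int] = None
    drop_fraction: Optional[float] = None
    point: Optional[CentralityTable] = None
    lower: Optional[np.ndarray] = None            # (4, P) per index x node
    upper: Optional[np.ndarray] = None
    index_names: tuple = ("instrength", "outstrength", "bridge_in", "bridge_out")
    warning: Optional[str] = None


def _spawn_seeds(seed: int, n: int) -> list:
    return np.random.SeedSequence(seed).spawn(n)


def _inclusion_replicate(ds: PanelDataset, child_seed, alpha: float,
                         search_kwargs: Mapping) -> Optional[tuple]:
    rng = np.random.default_rng(child_seed)
    idx = rng.integers(0, ds.n_subjects, ds.n_subjects)
    sub = ds.subset(idx)
    try:
        res = search_model(sub, alpha=alpha, **dict(search_kwargs))
    except Exception as err:  # noqa: BLE001 - replicate failures are counted
        logger.warning("bootstrap replicate failed: %s", err)
        return None
    if not res.fit.converged:
        return None
    return res.fit.mask.free_B.copy(), np.sign(res.fit.params.B)


def bootstrap_edge_inclusion(
    ds: PanelDataset,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
    n_jobs: int = 1,
    **search_kwargs,
) -> BootstrapResult:
    """Edge-inclusion probabilities over non-parametric bootstrap samples.

    Each replicate resamples ``n`` subjects with replacement, runs
    ``search_model`` and records the final structure and edge signs.
    Inclusion probabilities use successful replicates as denominator;
    when more than 5% of replicates fail a warning is attached.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    seeds = _spawn_seeds(seed, n_boot)
    if n_jobs == 1:
        results = [_inclusion_replicate(ds, s, alpha, search_kwargs) for s in seeds]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_inclusion_replicate)(ds, s, alpha, search_kwargs)
            for s in seeds
        )
    ok = [r for r in results if r is not None]
    n_success = len(ok)
    P = ds.n_vars
    if n_success == 0:
        raise RuntimeError("all bootstrap replicates failed")
    incl = np.zeros((P, P))
    pos = np.zeros((P, P))
    neg = np.zeros((P, P))
    for mask, sign in ok:
        incl += mask
        pos += mask & (sign > 0)
        neg += mask & (sign < 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        inclusion_prob = incl / n_success
        sign_agreement = np.where(incl > 0, np.maximum(pos, neg) / incl, np.nan)
    result = BootstrapResult(
        var_names=list(ds.var_names), seed=seed, n_boot=n_boot,
        n_success=n_success, inclusion_prob=inclusion_prob,
        sign_agreement=sign_agreement, robust=inclusion_prob > 0.5,
    )
    fail_frac = 1.0 - n_success / n_boot
    if fail_frac > 0.05:
        msg = f"{fail_frac:.1%} of bootstrap replicates failed"
        result.warning = msg
        warnings.warn(msg)
    return result


def _casedrop_replicate(ds: PanelDataset, child_seed, n_keep: int,
                        fit: FitResult, communities, signed: bool
                        ) -> Optional[np.ndarray]:
    rng = np.random.default_rng(child_seed)
    keep = rng.choice(ds.n_subjects, size=n_keep, replace=False)
    keep.sort()
    sub = ds.subset(keep)
    try:
        refit = fit_panel_gvar(sub, fit.mask, init_theta=fit.theta,
                               compute_se=False)
    except Exception as err:  # noqa: BLE001
        logger.warning("case-drop replicate failed: %s", err)
        return None
    if not refit.converged:
        return None
    return centrality_table(refit, communities, signed=signed).stacked()


def casedrop_centrality_ci(
    ds: PanelDataset,
    fit: FitResult,
    drop_fraction: float = 0.2,
    n_iter: int = 1000,
    seed: int = 0,
    n_jobs: int = 1,
    communities: Optional[Mapping[str, str]] = None,
    signed: bool = False,
) -> BootstrapResult:
    """95% case-dropping subset bootstrap intervals for centrality.

    Each iteration drops ``floor(drop_fraction * n)`` subjects without
    replacement and refits the fixed final structure (no re-search);
    bounds are the 2.5th and 97.5th percentiles per node and centrality
    index.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in [0, 1)")
    n = ds.n_subjects
    n_keep = n - int(np.floor(drop_fraction * n))
    if n_keep < 10:
        raise ValueError("fewer than 10 subjects would remain after dropping")
    if communities is None:
        communities = dict(ds.communities)
    point = centrality_table(fit, communities, signed=signed)
    seeds = _spawn_seeds(seed, n_iter)
    if n_jobs == 1:
        results = [
            _casedrop_replicate(ds, s, n_keep, fit, communities, signed)
            for s in seeds
        ]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_casedrop_replicate)(ds, s, n_keep, fit, communities, signed)
            for s in seeds
        )
    ok = [r for r in results if r is not None]
    if not ok:
        raise RuntimeError("all case-drop replicates failed")
    stack = np.stack(ok)  # (n_ok, 4, P)
    lower = np.percentile(stack, 2.5, axis=0)
    upper = np.percentile(stack, 97.5, axis=0)
    result = BootstrapResult(
        var_names=list(ds.var_names), seed=seed, n_iter=n_iter,
        drop_fraction=drop_fraction, point=point, lower=lower, upper=upper,
    )
    fail_frac = 1.0 - len(ok) / n_iter
    if fail_frac > 0.05:
        msg = f"{fail_frac:.1%} of case-drop replicates failed"
        result.warning = msg
        warnings.warn(msg)
    return result
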