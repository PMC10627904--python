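"""Multi-group panel GVAR estimation and invariance testing.

Groups are fitted jointly: the joint log-likelihood is the sum of the
group log-likelihoods, and equality constraints tie selected temporal
entries to a single shared value across groups.  Without constraints the
joint fit coincides with fitting each group separately (likelihood
additivity), which is how the unconstrained reference model is computed.

Equality of structure is tested by the chi-square difference
Δχ² = 2·(loglik_unconstrained − loglik_constrained) with degrees of
freedom equal to the number of independent constraints: constraining one
edge across G groups removes G − 1 parameters, so the omnibus test that
equates the full P×P temporal matrix across two groups has Δdf = P²
(64 for the eight-scale panel).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .datasets import PanelDataset
from .fitting import (
    FitResult,
    GVARObjective,
    ParamSpec,
    SuffStats,
    _PENALTY,
    fit_from_suffstats,
    independence_loglik,
    saturated_loglik,
    warm_start,
)
from .model import ModelMask

logger = logging.getLogger(__name__)


@dataclass
class MultigroupFit:
    """Joint fit over groups, possibly with cross-group constraints."""

    group_fits: "dict[object, FitResult]"
    loglik: float
    n_free: int
    n_subjects: int
    bic: float
    chisq: float
    df: int
    converged: bool
    constraints: list = field(default_factory=list)
    grad_norm: Optional[float] = None

    @property
    def labels(self) -> list:
        return list(self.group_fits)


@dataclass
class InvarianceResult:
    """Chi-square difference test of cross-group equality constraints."""

    delta_chisq: float
    delta_df: int
    p_value: float
    constrained_edges: list
    loglik_unconstrained: float
    loglik_constrained: float


def _resolve_masks(masks, labels, P) -> dict:
    if masks is None:
        return {g: ModelMask.saturated(P) for g in labels}
    if isinstance(masks, ModelMask):
        return {g: masks.copy() for g in labels}
    out = {}
    for g in labels:
        if g not in masks:
            raise ValueError(f"no mask supplied for group {g!r}")
        out[g] = masks[g]
    return out


def _edge_positions(spec: ParamSpec) -> dict:
    """(to, from) -> theta index of that free temporal entry."""
    pos = spec.b_positions()
    return {(int(i), int(j)): int(pos[k]) for k, (i, j) in enumerate(spec.B_idx)}


def fit_multigroup(
    ds: PanelDataset,
    masks: "Optional[Mapping | ModelMask]" = None,
    constraints: Sequence[tuple] = (),
    *,
    group_datasets: Optional[Mapping] = None,
    complete_cases: bool = False,
    compute_se: bool = True,
    init_fits: Optional[Mapping] = None,
    max_restarts: int = 3,
    seed: int = 0,
    gtol: float = 1e-6,
    maxiter: int = 8000,
) -> MultigroupFit:
    """Jointly fit a panel GVAR per group with optional equality constraints.

    Parameters
    ----------
    ds
        Dataset with group labels (subjects with missing labels are
        excluded from this analysis only).  Alternatively pass
        ``group_datasets`` directly.
    masks
        One mask for all groups, or a mapping label -> mask.
    constraints
        Edges (to_index, from_index) — or (to_name, from_name) — whose
        temporal coefficient is forced equal across all groups.  Each
        edge must be free in every group's mask.
    init_fits
        Optional label -> FitResult warm starts (e.g. the unconstrained
        per-group fits).
    """
    if group_datasets is None:
        group_datasets = ds.split_by_group()
        if complete_cases:
            group_datasets = {g: d.drop_incomplete() for g, d in group_datasets.items()}
    labels = sorted(group_datasets, key=str)
    if len(labels) < 2:
        raise ValueError("multigroup estimation needs at least 2 groups")
    for g in labels:
        if group_datasets[g].n_subjects < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    first = group_datasets[labels[0]]
    P, T = first.n_vars, first.n_waves
    var_names = list(first.var_names)
    masks_by_g = _resolve_masks(masks, labels, P)

    # resolve constraint edges to indices and validate
    name_pos = {v: i for i, v in enumerate(var_names)}
    edges = []
    for to, frm in constraints:
        if isinstance(to, str):
            to, frm = name_pos[to], name_pos[frm]
        to, frm = int(to), int(frm)
        for g in labels:
            if not masks_by_g[g].free_B[to, frm]:
                raise ValueError(
                    f"constraint on edge (to={var_names[to]}, from={var_names[frm]}) "
                    f"is undefined: fixed to zero in group {g!r}"
                )
        edges.append((to, frm))

    stats_by_g = {g: _stats_of(group_datasets[g]) for g in labels}
    specs = {g: ParamSpec(P, T, masks_by_g[g]) for g in labels}
    objs = {g: GVARObjective(stats_by_g[g], specs[g]) for g in labels}
    N = sum(st.n_subjects for st in stats_by_g.values())

    if not edges:
        # unconstrained: separate fits, joint quantities by additivity
        fits = {}
        for g in labels:
            init_theta = None
            if init_fits is not None and g in init_fits:
                init_theta = init_fits[g].theta
            fits[g] = fit_from_suffstats(
                stats_by_g[g], masks_by_g[g], var_names=var_names,
                compute_se=compute_se, init_theta=init_theta,
                max_restarts=max_restarts, seed=seed, gtol=gtol,
            )
        loglik = sum(f.loglik for f in fits.values())
        n_free = sum(f.n_free for f in fits.values())
        chisq = sum(f.chisq for f in fits.values())
        df = sum(f.df for f in fits.values())
        return MultigroupFit(
            group_fits=fits, loglik=loglik, n_free=n_free, n_subjects=N,
            bic=-2.0 * loglik + n_free * np.log(N), chisq=chisq, df=df,
            converged=all(f.converged for f in fits.values()),
            constraints=[], grad_norm=max(f.grad_norm for f in fits.values()),
        )

    # ---- constrained joint optimization --------------------------------
    # global theta: group-0 keeps all parameters; later groups drop their
    # constrained entries, which map onto group-0's slots
    offsets = {}
    index_maps = {}
    shared_slots = {e: None for e in edges}
    k_global = 0
    for g in labels:
        spec = specs[g]
        epos = _edge_positions(spec)
        idx_map = np.empty(spec.n_theta, dtype=int)
        local_shared = {epos[e]: e for e in edges}
        for i in range(spec.n_theta):
            e = local_shared.get(i)
            if e is not None and shared_slots[e] is not None:
                idx_map[i] = shared_slots[e]
            else:
                idx_map[i] = k_global
                if e is not None:
                    shared_slots[e] = k_global
                k_global += 1
        offsets[g] = None
        index_maps[g] = idx_map
    n_global = k_global
    weights = {g: stats_by_g[g].n_subjects / N for g in labels}

    def value_and_grad(theta_g: np.ndarray):
        f = 0.0
        grad = np.zeros(n_global)
        for g in labels:
            fg, gg = objs[g].value_and_grad(theta_g[index_maps[g]])
            if fg >= _PENALTY:
                return fg, np.zeros(n_global)
            f += weights[g] * fg
            np.add.at(grad, index_maps[g], weights[g] * gg)
        return f, grad

    # warm start: per-group warm starts (or supplied fits), constrained
    # entries set to their subject-weighted average
    theta0 = np.zeros(n_global)
    wsum = np.zeros(n_global)
    for g in labels:
        if init_fits is not None and g in init_fits:
            tg = np.asarray(init_fits[g].theta, dtype=float)
        else:
            tg = warm_start(stats_by_g[g], specs[g])
        np.add.at(theta0, index_maps[g], weights[g] * tg)
        np.add.at(wsum, index_maps[g], weights[g])
    theta0 = theta0 / np.maximum(wsum, 1e-12)

    rng = np.random.default_rng(seed)
    best = None
    converged = False
    theta_start = theta0
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(
            value_and_grad, theta_start, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-13, "gtol": gtol / 10.0},
        )
        gnorm = float(np.max(np.abs(res.jac)))
        if best is None or res.fun < best[0].fun:
            best = (res, gnorm)
        if gnorm < gtol:
            converged = True
            break
        theta_start = theta0 + rng.normal(scale=0.05, size=n_global)
    res, gnorm = best
    converged = converged or gnorm < gtol
    if not converged:
        logger.warning("multigroup fit did not reach gradient tolerance "
                       "(|g|=%.2e)", gnorm)
    theta_g = res.x

    n_constraints = (len(labels) - 1) * len(edges)
    n_free = sum(specs[g].n_free for g in labels) - n_constraints
    loglik = 0.0
    fits = {}
    for g in labels:
        tg = theta_g[index_maps[g]]
        obj = objs[g]
        ll_g = obj.loglik(tg)
        loglik += ll_g
        ll_sat = saturated_loglik(stats_by_g[g])
        ll0, n0 = independence_loglik(stats_by_g[g])
        params = specs[g].to_params(tg, var_names)
        fits[g] = FitResult(
            params=params, mask=masks_by_g[g], loglik=ll_g,
            n_free=specs[g].n_free, n_subjects=stats_by_g[g].n_subjects,
            chisq=max(2.0 * (ll_sat - ll_g), 0.0),
            df=stats_by_g[g].n_sat_params() - specs[g].n_free,
            cfi=np.nan, tli=np.nan, rmsea=np.nan,
            bic=np.nan, converged=converged, ll_saturated=ll_sat,
            ll_baseline=ll0, df_baseline=stats_by_g[g].n_sat_params() - n0,
            theta=tg, _objective=obj,
        )
    chisq = sum(f.chisq for f in fits.values())
    df = sum(stats_by_g[g].n_sat_params() for g in labels) - n_free
    return MultigroupFit(
        group_fits=fits, loglik=loglik, n_free=n_free, n_subjects=N,
        bic=-2.0 * loglik + n_free * np.log(N), chisq=chisq, df=df,
        converged=converged, constraints=list(edges), grad_norm=gnorm,
    )


def equality_constraint_test(
    ds: Optional[PanelDataset],
    base_fit: Optional[MultigroupFit] = None,
    edges_to_constrain: "Sequence[tuple] | str" = "all",
    *,
    masks: "Optional[Mapping | ModelMask]" = None,
    group_datasets: Optional[Mapping] = None,
    tol: float = 1e-4,
    **fit_kw,
) -> InvarianceResult:
    """Chi-square difference test for cross-group equality of edges.

    ``edges_to_constrain`` is a list of (to, from) edges or ``"all"``
    for the omnibus test constraining the full temporal matrix
    (Δdf = P² for two groups with saturated masks).  ``base_fit`` is the
    unconstrained multigroup fit; it is computed when absent.
    """
    if base_fit is None:
        base_fit = fit_multigroup(ds, masks=masks, group_datasets=group_datasets,
                                  compute_se=False, **fit_kw)
    labels = base_fit.labels
    first = base_fit.group_fits[labels[0]]
    P = first.params.n_vars
    if isinstance(edges_to_constrain, str):
        if edges_to_constrain != "all":
            raise ValueError("edges_to_constrain must be a list or 'all'")
        edges = [(i, j) for i in range(P) for j in range(P)]
    else:
        edges = list(edges_to_constrain)
    if not edges:
        return InvarianceResult(0.0, 0, 1.0, [], base_fit.loglik, base_fit.loglik)

    group_masks = {g: base_fit.group_fits[g].mask for g in labels}
    group_stats = {g: base_fit.group_fits[g]._objective.stats for g in labels}
    # rebuild datasets is unnecessary: reuse sufficient statistics
    constrained = _fit_constrained_from_stats(
        base_fit, group_masks, edges, **fit_kw
    )
    delta = 2.0 * (base_fit.loglik - constrained.loglik)
    if delta < -tol * max(1.0, abs(base_fit.loglik)):
        raise RuntimeError(
            "constrained log-likelihood exceeds the unconstrained one; "
            "optimization failure"
        )
    delta = max(delta, 0.0)
    delta_df = (len(labels) - 1) * len(edges)
    p = float(sps.chi2.sf(delta, delta_df)) if delta_df > 0 else 1.0
    return InvarianceResult(
        delta_chisq=float(delta), delta_df=int(delta_df), p_value=p,
        constrained_edges=edges, loglik_unconstrained=base_fit.loglik,
        loglik_constrained=constrained.loglik,
    )


def _fit_constrained_from_stats(base_fit: MultigroupFit, masks, edges,
                                **fit_kw) -> MultigroupFit:
    """Constrained refit reusing the base fit's sufficient statistics."""
    labels = base_fit.labels
    group_datasets = {}
    for g in labels:
        st = base_fit.group_fits[g]._objective.stats
        group_datasets[g] = _StatsDataset(st, base_fit.group_fits[g].params.var_names)
    return fit_multigroup(
        None, masks=masks, constraints=edges, group_datasets=group_datasets,
        init_fits=base_fit.group_fits, compute_se=False, **fit_kw,
    )


class _StatsDataset:
    """Minimal dataset stand-in backed by precomputed sufficient stats."""

    def __init__(self, stats_: SuffStats, var_names) -> None:
        self._stats = stats_
        self.n_vars = stats_.P
        self.n_waves = stats_.T
        self.n_subjects = stats_.n_subjects
        self.var_names = list(var_names) if var_names is not None else [
            f"v{i}" for i in range(stats_.P)
        ]


def _stats_of(ds) -> SuffStats:
    if isinstance(ds, _StatsDataset):
        return ds._stats
    if isinstance(ds, SuffStats):
        return ds
    return SuffStats.from_dataset(ds)
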