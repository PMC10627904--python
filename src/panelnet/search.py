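"""Stepwise structure search over temporal edges.

Starting from a fitted model (typically with all temporal entries free),
the search alternates two moves until the structure is stable:

* **prune** — fix to zero, in one batch, every free temporal entry whose
  Wald p-value is at or above ``alpha`` and refit; if the batch worsens
  the BIC, fall back to removing single edges (least significant first)
  until one removal improves the BIC.
* **expand** — score every fixed-zero entry with a modification index
  (score test from the gradient and observed information at the current
  optimum), confirm the most significant candidate with a one-edge-freed
  refit likelihood-ratio test, and add it only when it is significant at
  ``alpha`` and improves the BIC.

Accepted moves strictly lower the BIC, so the search is BIC-monotone and
terminates; revisiting a previously seen structure (possible only
through floating-point ties) stops the search at the best BIC
encountered.  Lower BIC indicates the preferred model throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps

from .fitting import (
    FitResult,
    GVARObjective,
    ParamSpec,
    fit_from_suffstats,
    wald_edge_tests,
)
from .model import ModelMask

logger = logging.getLogger(__name__)


@dataclass
class SearchResult:
    """Final fit plus a record of every attempted move."""

    fit: FitResult
    trace: list = field(default_factory=list)
    n_sweeps: int = 0
    cycled: bool = False

    @property
    def mask(self) -> ModelMask:
        return self.fit.mask

    def trace_text(self) -> str:
        lines = []
        for rec in self.trace:
            lines.append(
                "{sweep:>3} {move:<7} {edge:<28} bic={bic:.3f} {status}".format(
                    sweep=rec.get("sweep", "-"),
                    move=rec["move"],
                    edge=str(rec.get("edge") or "-"),
                    bic=rec["bic"],
                    status=rec["status"],
                )
            )
        return "\n".join(lines) + "\n"


def _refit(fit: FitResult, mask: ModelMask, **fit_kw) -> FitResult:
    """Refit with a new mask, warm-started from the current optimum."""
    obj = fit._objective
    spec = obj.spec
    new_spec = ParamSpec(spec.P, spec.T, mask, means_by_wave=spec.means_by_wave)
    mu, B, Lz, Lb = spec.unpack(fit.theta)
    theta0 = new_spec.pack(mu, B * mask.free_B, Lz, Lb)
    return fit_from_suffstats(
        obj.stats, mask,
        var_names=list(fit.params.var_names) if fit.params.var_names else None,
        means_by_wave=spec.means_by_wave, init_theta=theta0, **fit_kw,
    )


def prune_step(ds, fit: FitResult, alpha: float = 0.05, **fit_kw
               ) -> Optional[tuple[ModelMask, FitResult]]:
    """Remove non-significant free temporal entries; None when unchanged.

    ``ds`` is accepted for interface symmetry; the refit reuses the
    sufficient statistics cached on ``fit``.
    """
    del ds
    _, p_B = wald_edge_tests(fit)
    free = fit.mask.free_B
    with np.errstate(invalid="ignore"):
        weak = free & (np.isnan(p_B) | (p_B >= alpha))
    if not weak.any():
        return None
    bic0 = fit.bic
    batch = fit.mask.copy()
    batch.free_B = free & ~weak
    refit = _refit(fit, batch, **fit_kw)
    if refit.bic < bic0:
        return batch, refit
    # batch worsened BIC: drop single edges, least significant first
    weak_idx = np.argwhere(weak)
    weak_p = np.where(np.isnan(p_B), 2.0, p_B)[weak]
    for k in np.argsort(weak_p)[::-1]:
        i, j = weak_idx[k]
        single = fit.mask.copy()
        single.free_B = free.copy()
        single.free_B[i, j] = False
        refit = _refit(fit, single, **fit_kw)
        if refit.bic < bic0:
            return single, refit
    return None


def _score_tests(fit: FitResult) -> np.ndarray:
    """Modification indices for all fixed-zero temporal entries.

    Returns a (P, P) array of score (Lagrange-multiplier) statistics,
    NaN on free entries, computed from the gradient of the extended
    parameter vector and the observed information at the restricted
    optimum.
    """
    obj = fit._objective
    spec = obj.spec
    ext_mask = ModelMask(
        np.ones_like(fit.mask.free_B), fit.mask.zeta_diagonal,
        fit.mask.between_diagonal,
    )
    ext_spec = ParamSpec(spec.P, spec.T, ext_mask, means_by_wave=spec.means_by_wave)
    mu, B, Lz, Lb = spec.unpack(fit.theta)
    theta_ext = ext_spec.pack(mu, B, Lz, Lb)
    ext_obj = GVARObjective(obj.stats, ext_spec)
    _, g = ext_obj.value_and_grad(theta_ext)
    H = ext_obj.numerical_hessian(theta_ext)
    Hinv = np.linalg.pinv(H)
    N = obj.stats.n_subjects
    scores = np.full(fit.mask.free_B.shape, np.nan)
    pos = ext_spec.b_positions()
    for k, (i, j) in enumerate(ext_spec.B_idx):
        if fit.mask.free_B[i, j]:
            continue
        idx = pos[k]
        denom = Hinv[idx, idx]
        scores[i, j] = N * g[idx] ** 2 * denom if denom > 0 else 0.0
    return scores


def expand_step(ds, fit: FitResult, alpha: float = 0.05, **fit_kw
                ) -> Optional[tuple[ModelMask, FitResult]]:
    """Add the most promising omitted temporal entry; None when unchanged.

    Candidates are ranked by modification index (ties broken by row-major
    (to, from) position in declared variable order); the top candidate is
    confirmed by a likelihood-ratio refit and accepted only when
    significant at ``alpha`` with a lower BIC.
    """
    del ds
    fixed = ~fit.mask.free_B
    if not fixed.any():
        return None
    scores = _score_tests(fit)
    with np.errstate(invalid="ignore"):
        score_p = sps.chi2.sf(scores, 1)
    flat = np.where(np.isnan(scores), -np.inf, scores)
    i, j = np.unravel_index(int(np.argmax(flat)), scores.shape)
    if not np.isfinite(flat[i, j]) or score_p[i, j] >= alpha:
        return None
    new = fit.mask.copy()
    new.free_B = fit.mask.free_B.copy()
    new.free_B[i, j] = True
    refit = _refit(fit, new, **fit_kw)
    lr = max(2.0 * (refit.loglik - fit.loglik), 0.0)
    lr_p = float(sps.chi2.sf(lr, 1))
    if lr_p < alpha and refit.bic < fit.bic:
        return new, refit
    return None


def search_model(
    ds,
    start_mask: Optional[ModelMask] = None,
    alpha: float = 0.05,
    max_sweeps: int = 20,
    start_fit: Optional[FitResult] = None,
    **fit_kw,
) -> SearchResult:
    """Alternate pruning and expansion until the structure stabilizes.

    Returns the final fit with a search trace.  The result's BIC never
    exceeds the starting model's.  Deterministic given the data.
    """
    if start_fit is not None:
        fit = start_fit
    else:
        from .fitting import fit_panel_gvar

        fit = fit_panel_gvar(ds, start_mask, **fit_kw)
    trace: list = [{"move": "start", "edge": None, "bic": fit.bic,
                    "status": "initial", "sweep": 0}]
    visited = {fit.mask.key()}
    best = fit
    cycled = False
    sweep = 0
    var_names = list(fit.params.var_names) if fit.params.var_names else None

    def edge_name(i: int, j: int) -> str:
        if var_names:
            return f"{var_names[j]}->{var_names[i]}"
        return f"{j}->{i}"

    for sweep in range(1, max_sweeps + 1):
        changed = False
        for move, step in (("prune", prune_step), ("expand", expand_step)):
            out = step(ds, fit, alpha=alpha, **fit_kw)
            if out is None:
                trace.append({"move": move, "edge": None, "bic": fit.bic,
                              "status": "no-change", "sweep": sweep})
                continue
            mask, refit = out
            delta = np.argwhere(mask.free_B != fit.mask.free_B)
            label = ",".join(edge_name(i, j) for i, j in delta)
            key = mask.key()
            if key in visited:
                cycled = True
                logger.warning("model search revisited a structure; "
                               "stopping at the best BIC seen")
                trace.append({"move": move, "edge": label, "bic": refit.bic,
                              "status": "cycle", "sweep": sweep})
                break
            visited.add(key)
            fit = refit
            changed = True
            if fit.bic < best.bic:
                best = fit
            trace.append({"move": move, "edge": label, "bic": fit.bic,
                          "status": "accepted", "sweep": sweep})
        if cycled or not changed:
            break
    final = best if best.bic < fit.bic else fit
    return SearchResult(fit=final, trace=trace, n_sweeps=sweep, cycled=cycled)
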