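"""Node centrality of the directed standardized temporal network.

Centrality follows the directed-strength convention: absolute values of
standardized lag-1 coefficients, autoregressive self-loops excluded.

* instrength(i)  = sum over j != i of |b_std[i, j]|  (edges into i)
* outstrength(j) = sum over i != j of |b_std[i, j]|  (edges out of j)
* bridge in/out-degree restrict those sums to edges crossing between the
  internalizing and externalizing communities; nodes outside both
  communities score zero and their edges never count.

A ``signed=True`` variant sums raw coefficients instead of magnitudes
(values may then be negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import COMMUNITIES
from .model import standardize_temporal


@dataclass
class CentralityTable:
    """Per-node centrality values of one temporal network."""

    nodes: Sequence[str]
    communities: Sequence[str]
    instrength: np.ndarray
    outstrength: np.ndarray
    bridge_in: np.ndarray
    bridge_out: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": list(self.nodes),
                "community": list(self.communities),
                "instrength": self.instrength,
                "outstrength": self.outstrength,
                "bridge_in": self.bridge_in,
                "bridge_out": self.bridge_out,
            }
        )

    def stacked(self) -> np.ndarray:
        """(4, n_nodes) array in the order instrength, outstrength,
        bridge_in, bridge_out (used by the case-drop bootstrap)."""
        return np.vstack(
            [self.instrength, self.outstrength, self.bridge_in, self.bridge_out]
        )


def strength_centrality(B_std: np.ndarray, signed: bool = False
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Instrength and outstrength of every node.

    ``B_std[i, j]`` is the standardized effect of node j on node i;
    self-loops are excluded from both sums.  Returns ``(instrength,
    outstrength)`` arrays.
    """
    B_std = np.asarray(B_std, dtype=float)
    if B_std.ndim != 2 or B_std.shape[0] != B_std.shape[1]:
        raise ValueError("B_std must be square")
    W = B_std if signed else np.abs(B_std)
    off = W - np.diag(np.diag(W))
    return off.sum(axis=1), off.sum(axis=0)


def bridge_centrality(
    B_std: np.ndarray,
    communities: "Mapping[str, str] | Sequence[str]",
    var_names: Optional[Sequence[str]] = None,
    signed: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Bridge in-degree and out-degree between the two communities.

    ``communities`` maps each node to ``internalizing``,
    ``externalizing`` or ``none`` (either a dict keyed by ``var_names``
    or a sequence aligned with the matrix).  For a node in one labelled
    community, bridge in-degree sums incoming edges from the other
    community and bridge out-degree the outgoing ones; ``none`` nodes
    score zero and never contribute.
    """
    B_std = np.asarray(B_std, dtype=float)
    P = B_std.shape[0]
    if isinstance(communities, Mapping):
        if var_names is None:
            raise ValueError("var_names required with a community mapping")
        labels = [communities.get(v, "none") for v in var_names]
    else:
        labels = list(communities)
    if len(labels) != P:
        raise ValueError("community labels do not match matrix size")
    for lab in labels:
        if lab not in COMMUNITIES:
            raise ValueError(f"unknown community label {lab!r}")
    labels_arr = np.array(labels)
    W = B_std if signed else np.abs(B_std)
    bridge_in = np.zeros(P)
    bridge_out = np.zeros(P)
    opposite = {"internalizing": "externalizing", "externalizing": "internalizing"}
    for v in range(P):
        lab = labels_arr[v]
        if lab not in opposite:
            continue
        other = labels_arr == opposite[lab]
        bridge_in[v] = W[v, other].sum()   # edges u -> v, u in the other community
        bridge_out[v] = W[other, v].sum()  # edges v -> u
    return bridge_in, bridge_out


def centrality_table(
    fit_or_params,
    communities: Optional[Mapping[str, str]] = None,
    signed: bool = False,
) -> CentralityTable:
    """Assemble the full centrality table of a fitted model.

    Accepts a ``FitResult`` or a ``PanelGVARParams``; standardization
    uses the stationary within-person variances.  Nodes missing from
    ``communities`` count as ``none``.
    """
    params = getattr(fit_or_params, "params", fit_or_params)
    B_std = standardize_temporal(params)
    names = list(params.var_names) if params.var_names is not None else [
        f"v{i}" for i in range(params.n_vars)
    ]
    communities = dict(communities or {})
    labels = [communities.get(v, "none") for v in names]
    instr, outstr = strength_centrality(B_std, signed=signed)
    b_in, b_out = bridge_centrality(B_std, labels, signed=signed)
    return CentralityTable(
        nodes=names, communities=labels, instrength=instr,
        outstrength=outstr, bridge_in=b_in, bridge_out=b_out,
    )
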