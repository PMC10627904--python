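"""Strength and bridge centrality, anchored to the published edge table."""

import numpy as np
import pytest

from panelnet.centrality import (
    bridge_centrality,
    centrality_table,
    strength_centrality,
)
from panelnet.datasets import DEFAULT_COMMUNITIES, DEFAULT_VARS
from panelnet.simulate import reference_network

POS = {v: i for i, v in enumerate(DEFAULT_VARS)}
LABELS = [DEFAULT_COMMUNITIES[v] for v in DEFAULT_VARS]


def test_zero_matrix_gives_zero_centralities():
    instr, outstr = strength_centrality(np.zeros((4, 4)))
    assert not instr.any() and not outstr.any()
    b_in, b_out = bridge_centrality(
        np.zeros((4, 4)), ["internalizing", "internalizing",
                           "externalizing", "none"]
    )
    assert not b_in.any() and not b_out.any()


def test_published_network_strength_values():
    B = reference_network()
    instr, outstr = strength_centrality(B)
    # outgoing from AnxDep: 0.049 + 0.089 + 0.066
    assert outstr[POS["AnxDep"]] == pytest.approx(0.204, abs=1e-12)
    # incoming to Social: 0.089 + |-0.042|
    assert instr[POS["Social"]] == pytest.approx(0.131, abs=1e-12)
    assert instr[POS["AnxDep"]] == pytest.approx(0.099, abs=1e-12)
    # Social tops instrength on the printed edge set, ahead of AnxDep
    assert instr[POS["Social"]] == instr.max()
    assert instr[POS["Social"]] > instr[POS["AnxDep"]]


def test_published_network_bridge_values():
    B = reference_network()
    b_in, b_out = bridge_centrality(B, LABELS)
    # WithDep -> RuleBreak is the only internalizing -> externalizing edge
    assert b_out[POS["WithDep"]] == pytest.approx(0.067, abs=1e-12)
    # RuleBreak -> WithDep and Aggressive -> WithDep
    assert b_in[POS["WithDep"]] == pytest.approx(0.068, abs=1e-12)
    # WithDep tops the internalizing side, RuleBreak the bridge-in source side
    internal = [POS[v] for v in ("AnxDep", "WithDep", "Somatic")]
    assert b_in[POS["WithDep"]] == max(b_in[i] for i in internal)
    assert b_out[POS["WithDep"]] == max(b_out[i] for i in internal)
    external = [POS[v] for v in ("RuleBreak", "Aggressive")]
    assert b_in[POS["RuleBreak"]] == max(b_in[i] for i in external)
    # uncommunitied nodes are transparent
    for v in ("Social", "Thought", "Attention"):
        assert b_in[POS[v]] == 0.0 and b_out[POS[v]] == 0.0


def test_no_cross_community_edges_no_bridges():
    B = np.zeros((4, 4))
    B[0, 1] = 0.5  # within internalizing
    B[2, 3] = 0.4  # within externalizing
    labels = ["internalizing", "internalizing", "externalizing", "externalizing"]
    b_in, b_out = bridge_centrality(B, labels)
    assert not b_in.any() and not b_out.any()


def test_unknown_community_label_rejected():
    with pytest.raises(ValueError, match="unknown community"):
        bridge_centrality(np.zeros((2, 2)), ["internalizing", "purple"])


def test_strength_conservation_and_monotonicity():
    rng = np.random.default_rng(0)
    for _ in range(10):
        B = rng.normal(size=(5, 5))
        instr, outstr = strength_centrality(B)
        assert instr.sum() == pytest.approx(outstr.sum())
        off = np.abs(B - np.diag(np.diag(B))).sum()
        assert instr.sum() == pytest.approx(off)
        # adding an edge can only increase the affected strengths
        B2 = B.copy()
        B2[0, 1] += np.sign(B2[0, 1] or 1) * 0.3
        instr2, outstr2 = strength_centrality(B2)
        assert instr2[0] >= instr[0] and outstr2[1] >= outstr[1]


def test_bridge_bounded_by_strength():
    rng = np.random.default_rng(1)
    labels = ["internalizing", "internalizing", "none", "externalizing",
              "externalizing"]
    for _ in range(10):
        B = rng.normal(size=(5, 5))
        instr, outstr = strength_centrality(B)
        b_in, b_out = bridge_centrality(B, labels)
        assert np.all(b_in <= instr + 1e-12)
        assert np.all(b_out <= outstr + 1e-12)
        assert np.all(b_in >= 0) and np.all(b_out >= 0)


def test_centrality_table_from_params_and_permutation_invariance():
    from panelnet.model import PanelGVARParams

    B = reference_network()
    eta = np.eye(8)
    params = PanelGVARParams(
        mu=np.zeros(8), B=B, sigma_zeta=eta - B @ eta @ B.T,
        sigma_between=np.zeros((8, 8)), var_names=list(DEFAULT_VARS),
    )
    table = centrality_table(params, DEFAULT_COMMUNITIES)
    frame = table.to_frame().set_index("node")
    assert frame.loc["AnxDep", "outstrength"] == pytest.approx(0.204, abs=1e-10)
    assert frame.loc["WithDep", "bridge_in"] == pytest.approx(0.068, abs=1e-10)

    perm = [3, 0, 7, 1, 5, 2, 6, 4]
    params_p = PanelGVARParams(
        mu=np.zeros(8), B=B[np.ix_(perm, perm)],
        sigma_zeta=params.sigma_zeta[np.ix_(perm, perm)],
        sigma_between=np.zeros((8, 8)),
        var_names=[DEFAULT_VARS[i] for i in perm],
    )
    frame_p = centrality_table(params_p, DEFAULT_COMMUNITIES).to_frame()
    frame_p = frame_p.set_index("node")
    for v in DEFAULT_VARS:
        for col in ("instrength", "outstrength", "bridge_in", "bridge_out"):
            assert frame_p.loc[v, col] == pytest.approx(frame.loc[v, col])


def test_empty_network_all_zero_table():
    from panelnet.model import PanelGVARParams

    params = PanelGVARParams(np.zeros(3), np.zeros((3, 3)), np.eye(3),
                             np.zeros((3, 3)), var_names=["a", "b", "c"])
    table = centrality_table(params, {"a": "internalizing", "b": "externalizing"})
    assert not table.stacked().any()


def test_signed_variant_can_go_negative():
    B = np.array([[0.0, -0.3], [0.0, 0.0]])
    instr, outstr = strength_centrality(B, signed=True)
    assert instr[0] == -0.3
    assert outstr[1] == -0.3


# -- property-based invariants ----------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp


@settings(derandomize=True, max_examples=40, deadline=None)
@given(hnp.arrays(float, (4, 4), elements=st.floats(-1, 1, allow_nan=False)),
       st.lists(st.sampled_from(["internalizing", "externalizing", "none"]),
                min_size=4, max_size=4))
def test_centrality_invariants_property(B, labels):
    instr, outstr = strength_centrality(B)
    assert np.all(instr >= 0) and np.all(outstr >= 0)
    assert instr.sum() == pytest.approx(outstr.sum())
    b_in, b_out = bridge_centrality(B, labels)
    assert np.all(b_in <= instr + 1e-12) and np.all(b_out <= outstr + 1e-12)
    for k, lab in enumerate(labels):
        if lab == "none":
            assert b_in[k] == 0.0 and b_out[k] == 0.0
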