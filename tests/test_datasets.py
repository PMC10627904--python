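"""Panel table I/O, validation and description."""

import numpy as np
import pandas as pd
import pytest

from panelnet.datasets import (
    EdgeRecord,
    PanelDataError,
    PanelDataset,
    describe_dataset,
    read_edge_list,
    read_panel_table,
    write_edge_list,
    write_panel_table,
)
from panelnet.simulate import (
    apply_tscore_censoring,
    make_default_scenario,
    simulate_panel,
)

LONG_ROWS = [
    (s, w, v, float(10 * i + w))
    for i, s in enumerate(["s1", "s2"])
    for w in (0, 1, 2)
    for v in ("a", "b")
]


def _write_long(path, rows):
    pd.DataFrame(rows, columns=["subject", "wave", "variable", "value"]).to_csv(
        path, index=False
    )


def test_long_roundtrip_complete(tmp_path):
    path = tmp_path / "panel.csv"
    _write_long(path, LONG_ROWS)
    ds = read_panel_table(path, "long", {})
    assert ds.values.shape == (2, 3, 2)
    assert not np.isnan(ds.values).any()
    assert list(ds.var_names) == ["a", "b"]
    assert ds.values[1, 2, 0] == 12.0


def test_long_missing_cell(tmp_path):
    path = tmp_path / "panel.csv"
    _write_long(path, LONG_ROWS[:-1])  # drop one row
    ds = read_panel_table(path, "long", {})
    assert int(np.isnan(ds.values).sum()) == 1
    assert np.isnan(ds.values[1, 2, 1])


@pytest.mark.parametrize("layout", ["wide", "long"])
def test_write_read_roundtrip_matches_generator(tmp_path, layout):
    ds = simulate_panel(make_default_scenario(30, seed=9, mcar=0.05))
    path = tmp_path / f"panel_{layout}.csv"
    write_panel_table(ds, path, layout=layout)
    back = read_panel_table(
        path, layout,
        {"var_names": list(ds.var_names), "communities": dict(ds.communities),
         "wave_labels": list(ds.wave_labels)},
    )
    assert back == ds


def test_group_column_roundtrip(tmp_path):
    from panelnet.simulate import make_group_scenario

    ds = simulate_panel(make_group_scenario(15, seed=3))
    path = tmp_path / "panel.csv"
    write_panel_table(ds, path, layout="wide")
    back = read_panel_table(
        path, "wide",
        {"group_column": "group", "var_names": list(ds.var_names),
         "communities": dict(ds.communities), "wave_labels": list(ds.wave_labels)},
    )
    assert back == ds
    assert set(back.group) == {"female", "male"}


def test_reading_twice_is_identical(tmp_path):
    path = tmp_path / "panel.csv"
    _write_long(path, LONG_ROWS)
    assert read_panel_table(path, "long", {}) == read_panel_table(path, "long", {})


def test_duplicate_rows_rejected(tmp_path):
    path = tmp_path / "panel.csv"
    _write_long(path, LONG_ROWS + [LONG_ROWS[0]])
    with pytest.raises(PanelDataError, match="duplicate"):
        read_panel_table(path, "long", {})


def test_unknown_community_variable_rejected(tmp_path):
    path = tmp_path / "panel.csv"
    _write_long(path, LONG_ROWS)
    with pytest.raises(PanelDataError, match="unknown variable"):
        read_panel_table(path, "long", {"communities": {"zzz": "internalizing"}})


def test_non_numeric_value_names_row(tmp_path):
    rows = [list(r) for r in LONG_ROWS]
    rows[5][3] = "oops"
    path = tmp_path / "panel.csv"
    _write_long(path, rows)
    with pytest.raises(PanelDataError, match="row 5"):
        read_panel_table(path, "long", {})


def test_dataset_invariants():
    with pytest.raises(PanelDataError):
        PanelDataset(np.zeros((2, 1, 2)), ["a", "b"], [0], ["x", "y"])  # T < 2
    with pytest.raises(PanelDataError):
        PanelDataset(np.zeros((2, 2, 2)), ["a"], [0, 1], ["x", "y"])  # id mismatch
    with pytest.raises(PanelDataError, match="community"):
        PanelDataset(np.zeros((2, 2, 2)), ["a", "b"], [0, 1], ["x", "y"],
                     communities={"x": "purple"})
    # no subject with two consecutive observations of the same variable
    vals = np.full((2, 2, 2), np.nan)
    vals[:, 0, 0] = 1.0
    vals[:, 1, 1] = 1.0
    with pytest.raises(PanelDataError, match="consecutive"):
        PanelDataset(vals, ["a", "b"], [0, 1], ["x", "y"])


# -- describe ---------------------------------------------------------------

def test_describe_constant_column_flagged():
    vals = np.random.default_rng(0).normal(size=(20, 2, 2))
    vals[:, 0, 0] = 5.0
    ds = PanelDataset(vals, [f"s{i}" for i in range(20)], [0, 1], ["x", "y"])
    summ = describe_dataset(ds)
    row = summ[(summ.variable == "x") & (summ.wave == 0)].iloc[0]
    assert row.sd == 0.0
    assert bool(row.undefined)
    assert np.isnan(row.skewness)


def test_describe_censored_scores_positively_skewed():
    ds = simulate_panel(make_default_scenario(2000, seed=5, censor=True))
    summ = describe_dataset(ds)
    assert (summ.skewness > 0).all()
    assert (summ.excess_kurtosis > 0).all()


def test_describe_symmetric_gaussian_near_zero_skew():
    # skewness SE ~ sqrt(6/n); with n = 10,000 pooled per cell, |skew| < 0.1
    rng = np.random.default_rng(11)
    vals = rng.normal(size=(10000, 2, 2))
    ds = PanelDataset(vals, [f"s{i}" for i in range(10000)], [0, 1], ["x", "y"])
    summ = describe_dataset(ds)
    assert (summ.skewness.abs() < 0.1).all()


def test_describe_reports_missing_fraction():
    vals = np.random.default_rng(1).normal(size=(10, 2, 2))
    vals[:5, 0, 0] = np.nan
    ds = PanelDataset(vals, [f"s{i}" for i in range(10)], [0, 1], ["x", "y"])
    summ = describe_dataset(ds)
    row = summ[(summ.variable == "x") & (summ.wave == 0)].iloc[0]
    assert row.pct_missing == pytest.approx(50.0)
    assert row.n == 5


# -- edge lists -------------------------------------------------------------

def test_edge_list_empty_is_header_only(tmp_path):
    path = tmp_path / "edges.csv"
    write_edge_list([], path)
    lines = path.read_text().splitlines()
    assert lines == ["from,to,beta,p,included,inclusion_prob,sign"]


def test_edge_list_roundtrip_and_stable_order(tmp_path):
    records = [
        EdgeRecord("a", "a", 0.25, 0.001, True, 0.9),
        EdgeRecord("a", "b", -0.1, 0.03, True, 0.55),
        EdgeRecord("b", "a", None, None, False, 0.2),
    ]
    p1, p2 = tmp_path / "e1.csv", tmp_path / "e2.csv"
    write_edge_list(records, p1)
    write_edge_list(records, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert len(p1.read_text().splitlines()) == 4
    back = read_edge_list(p1)
    assert [(r.from_var, r.to_var, r.included) for r in back] == [
        ("a", "a", True), ("a", "b", True), ("b", "a", False)
    ]
    assert back[0].beta == pytest.approx(0.25)
    assert back[1].sign == "neg"
    assert back[2].beta is None


def test_edge_record_validation():
    with pytest.raises(ValueError, match="sign"):
        EdgeRecord("a", "b", 0.2, 0.01, True, sign="neg")
    with pytest.raises(ValueError, match="p_value"):
        EdgeRecord("a", "b", 0.2, 1.5, True)
    assert EdgeRecord("a", "b", -0.3, 0.2, True).sign == "neg"


# -- censoring --------------------------------------------------------------

def test_tscore_censoring_bounds_and_mass_point():
    rng = np.random.default_rng(2)
    vals = rng.normal(size=(10000, 2, 2))
    ds = PanelDataset(vals, [f"s{i}" for i in range(10000)], [0, 1], ["x", "y"])
    cen = apply_tscore_censoring(ds)
    assert cen.values.min() >= 50.0
    assert cen.values.max() <= 100.0
    # standard-normal input: half the mass collapses onto the floor of 50
    frac50 = float(np.mean(cen.values == 50.0))
    assert abs(frac50 - 0.5) < 3 * np.sqrt(0.25 / cen.values.size)
    # z = 6 would exceed the ceiling: values at +6 SD clip at 100
    vals2 = vals.copy()
    vals2[0, 0, 0] = 12.0  # far beyond 6 SD
    ds2 = PanelDataset(vals2, ds.subject_ids, ds.wave_labels, ds.var_names)
    assert apply_tscore_censoring(ds2).values[0, 0, 0] == 100.0


# -- property-based round trip ---------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@st.composite
def _edge_records(draw):
    names = ["a", "b", "c"]
    frm = draw(st.sampled_from(names))
    to = draw(st.sampled_from(names))
    included = draw(st.booleans())
    beta = draw(st.floats(-0.5, 0.5, allow_nan=False)) if included else None
    p = draw(st.floats(0, 1, allow_nan=False)) if included else None
    incl = draw(st.one_of(st.none(), st.floats(0, 1, allow_nan=False)))
    return EdgeRecord(frm, to, beta, p, included, incl)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.lists(_edge_records(), max_size=9))
def test_edge_list_roundtrip_property(tmp_path_factory, records):
    path = tmp_path_factory.mktemp("edges") / "e.csv"
    write_edge_list(records, path)
    back = read_edge_list(path)
    assert len(back) == len(records)
    for orig, rec in zip(records, back):
        assert (rec.from_var, rec.to_var, rec.included) == (
            orig.from_var, orig.to_var, orig.included
        )
        if orig.beta is None:
            assert rec.beta is None
        else:
            assert rec.beta == pytest.approx(orig.beta, abs=1e-6)
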