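"""Panel dataset container and delimited-text I/O.

The central in-memory object is :class:`PanelDataset`: a ``(subjects,
waves, variables)`` score array plus subject identifiers, ordered wave
labels, variable names, an optional per-subject group label and a
community map assigning each variable to the internalizing community,
the externalizing community, or to neither.

Two text layouts are supported:

* **long** — one row per observed (subject, wave, variable) cell with
  columns ``subject, wave, variable, value`` (and optionally a group
  column),
* **wide** — one row per subject with columns named ``<var>__w<k>`` for
  wave ``k`` (0-based) and optionally a group column.

Unobserved cells are NaN, never zero.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Valid community labels.
COMMUNITIES = ("internalizing", "externalizing", "none")

#: CBCL-style syndrome-scale variable set used by the default scenario.
DEFAULT_VARS = (
    "AnxDep",
    "WithDep",
    "Somatic",
    "Social",
    "Thought",
    "Attention",
    "RuleBreak",
    "Aggressive",
)

#: Default community assignment: anxious/depressed, withdrawn/depressed
#: and somatic complaints form the internalizing community; rule-breaking
#: and aggressive behavior the externalizing community; social, thought
#: and attention problems belong to neither.
DEFAULT_COMMUNITIES: Mapping[str, str] = {
    "AnxDep": "internalizing",
    "WithDep": "internalizing",
    "Somatic": "internalizing",
    "Social": "none",
    "Thought": "none",
    "Attention": "none",
    "RuleBreak": "externalizing",
    "Aggressive": "externalizing",
}


class PanelDataError(ValueError):
    """Raised when a panel table violates the dataset contract."""


@dataclass
class PanelDataset:
    """Multi-wave panel of numeric scores.

    Parameters
    ----------
    values
        Array of shape ``(n_subjects, n_waves, n_vars)``; NaN marks an
        unobserved cell.
    subject_ids
        One identifier per subject.
    wave_labels
        Ordered wave labels (length ``n_waves``, strictly increasing when
        numeric-comparable).
    var_names
        Ordered variable names (length ``n_vars``).
    group
        Optional categorical label per subject.
    communities
        Map ``var_name -> {internalizing, externalizing, none}``.
        Variables missing from the supplied map default to ``"none"``.
    """

    values: np.ndarray
    subject_ids: Sequence
    wave_labels: Sequence
    var_names: Sequence[str]
    group: Optional[Sequence] = None
    communities: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise PanelDataError("values must have shape (subjects, waves, variables)")
        n, T, P = self.values.shape
        if len(self.subject_ids) != n:
            raise PanelDataError("subject_ids length does not match values")
        if len(self.wave_labels) != T:
            raise PanelDataError("wave_labels length does not match values")
        if len(self.var_names) != P:
            raise PanelDataError("var_names length does not match values")
        if T < 2:
            raise PanelDataError("a panel needs at least two waves")
        if P < 2:
            raise PanelDataError("a panel needs at least two variables")
        if len(set(self.var_names)) != P:
            raise PanelDataError("variable names must be unique")
        if self.group is not None and len(self.group) != n:
            raise PanelDataError("group length does not match values")
        comm = dict(self.communities)
        for unknown in set(comm) - set(self.var_names):
            raise PanelDataError(f"community map names unknown variable {unknown!r}")
        for v in self.var_names:
            comm.setdefault(v, "none")
        for v, c in comm.items():
            if c not in COMMUNITIES:
                raise PanelDataError(f"unknown community label {c!r} for {v!r}")
        self.communities = comm
        # at least one subject must contribute a lag-1 transition
        obs = ~np.isnan(self.values)
        consec = obs[:, :-1, :] & obs[:, 1:, :]
        if not consec.any():
            raise PanelDataError(
                "no subject has the same variable observed at two consecutive waves"
            )
        finite = self.values[obs]
        if finite.size and ((finite < 50) | (finite > 100)).any():
            logger.warning(
                "values outside the T-score range [50, 100] present; "
                "the model is scale-agnostic, continuing"
            )

    # -- convenience ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_waves(self) -> int:
        return self.values.shape[1]

    @property
    def n_vars(self) -> int:
        return self.values.shape[2]

    def stacked(self) -> np.ndarray:
        """Subjects x (waves*vars) matrix, wave-major (wave 0 vars first)."""
        n, T, P = self.values.shape
        return self.values.reshape(n, T * P)

    def subset(self, idx) -> "PanelDataset":
        """Dataset restricted to the subject positions in ``idx``."""
        idx = np.asarray(idx)
        return PanelDataset(
            values=self.values[idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            wave_labels=list(self.wave_labels),
            var_names=list(self.var_names),
            group=None if self.group is None else [self.group[i] for i in idx],
            communities=dict(self.communities),
        )

    def split_by_group(self) -> dict:
        """Group label -> dataset of the subjects carrying that label.

        Subjects with a missing (None/NaN) group label are excluded.
        """
        if self.group is None:
            raise PanelDataError("dataset has no group labels")
        out = {}
        labels = pd.Series(list(self.group))
        for g in labels.dropna().unique():
            idx = np.where((labels == g).to_numpy())[0]
            out[g] = self.subset(idx)
        return out

    def drop_incomplete(self) -> "PanelDataset":
        """Listwise-complete subjects only (every cell observed)."""
        keep = ~np.isnan(self.values).any(axis=(1, 2))
        return self.subset(np.where(keep)[0])

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, PanelDataset):
            return NotImplemented
        same_grp = (self.group is None and other.group is None) or (
            self.group is not None
            and other.group is not None
            and list(self.group) == list(other.group)
        )
        return (
            np.array_equal(self.values, other.values, equal_nan=True)
            and list(self.subject_ids) == list(other.subject_ids)
            and list(self.wave_labels) == list(other.wave_labels)
            and list(self.var_names) == list(other.var_names)
            and same_grp
            and dict(self.communities) == dict(other.communities)
        )


@dataclass
class EdgeRecord:
    """One directed temporal edge of the network.

    ``beta`` is the standardized lag-1 coefficient of ``from_var`` at wave
    t-1 on ``to_var`` at wave t; ``included`` marks membership in the
    final searched model; ``inclusion_prob`` is the bootstrap edge
    inclusion probability when available.
    """

    from_var: str
    to_var: str
    beta: Optional[float]
    p_value: Optional[float]
    included: bool
    inclusion_prob: Optional[float] = None
    sign: Optional[str] = None

    def __post_init__(self) -> None:
        if self.beta is not None and self.sign is None:
            self.sign = "pos" if self.beta >= 0 else "neg"
        if self.beta is not None and self.sign is not None and self.beta != 0:
            expect = "pos" if self.beta > 0 else "neg"
            if self.sign != expect:
                raise ValueError(
                    f"sign {self.sign!r} inconsistent with beta {self.beta!r}"
                )
        if self.p_value is not None and not 0 <= self.p_value <= 1:
            raise ValueError("p_value outside [0, 1]")
        if self.inclusion_prob is not None and not 0 <= self.inclusion_prob <= 1:
            raise ValueError("inclusion_prob outside [0, 1]")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_LONG_DEFAULTS = {"subject": "subject", "wave": "wave", "variable": "variable", "value": "value"}


def _delimiter_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_panel_table(path, layout: str, config: Optional[Mapping] = None) -> PanelDataset:
    """Read a delimited panel table into a :class:`PanelDataset`.

    Parameters
    ----------
    path
        CSV or TSV file (delimiter chosen by extension).
    layout
        ``"long"`` (one row per cell) or ``"wide"`` (one row per subject,
        ``<var>__w<k>`` columns).
    config
        Optional mapping with keys ``columns`` (column-name overrides for
        the long layout), ``group_column``, ``communities`` (variable ->
        community), ``var_names`` (declared variable order) and
        ``wave_labels``.
    """
    config = dict(config or {})
    sep = _delimiter_for(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if layout == "long":
        return _read_long(df, config)
    if layout == "wide":
        return _read_wide(df, config)
    raise ValueError(f"unknown layout {layout!r}")


def _coerce_values(series: pd.Series) -> np.ndarray:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna() & (series.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.where(bad.to_numpy())[0][0])
        raise PanelDataError(f"non-numeric value at row {row}: {series.iloc[row]!r}")
    return out.to_numpy(dtype=float)


def _read_long(df: pd.DataFrame, config: Mapping) -> PanelDataset:
    cols = {**_LONG_DEFAULTS, **config.get("columns", {})}
    for key in ("subject", "wave", "variable", "value"):
        if cols[key] not in df.columns:
            raise PanelDataError(f"long table is missing column {cols[key]!r}")
    group_col = config.get("group_column")
    if group_col is not None and group_col not in df.columns:
        raise PanelDataError(f"group column {group_col!r} not in table")

    dup = df.duplicated(subset=[cols["subject"], cols["wave"], cols["variable"]])
    if dup.any():
        raise PanelDataError(
            f"duplicate (subject, wave, variable) rows, first at row {int(np.where(dup)[0][0])}"
        )
    values = _coerce_values(df[cols["value"]])

    subj = df[cols["subject"]]
    subject_ids = list(config.get("subject_ids", pd.unique(subj)))
    wave_labels = config.get("wave_labels")
    if wave_labels is None:
        wave_labels = sorted(pd.unique(df[cols["wave"]]))
    var_names = config.get("var_names")
    if var_names is None:
        var_names = list(pd.unique(df[cols["variable"]]))
    unknown = set(df[cols["variable"]]) - set(var_names)
    if unknown:
        raise PanelDataError(f"table contains undeclared variables {sorted(unknown)!r}")
    communities = dict(config.get("communities", {}))
    for v in communities:
        if v not in var_names:
            raise PanelDataError(f"community map names unknown variable {v!r}")

    s_idx = pd.Series(range(len(subject_ids)), index=subject_ids)
    w_idx = pd.Series(range(len(wave_labels)), index=wave_labels)
    v_idx = pd.Series(range(len(var_names)), index=var_names)
    arr = np.full((len(subject_ids), len(wave_labels), len(var_names)), np.nan)
    arr[
        s_idx[subj].to_numpy(),
        w_idx[df[cols["wave"]]].to_numpy(),
        v_idx[df[cols["variable"]]].to_numpy(),
    ] = values

    group = None
    if group_col is not None:
        per_subj = df.groupby(cols["subject"], sort=False)[group_col].first()
        group = [per_subj.get(s) for s in subject_ids]
    return PanelDataset(arr, subject_ids, list(wave_labels), list(var_names), group, communities)


def _read_wide(df: pd.DataFrame, config: Mapping) -> PanelDataset:
    subject_col = config.get("columns", {}).get("subject", "subject")
    group_col = config.get("group_column")
    if subject_col not in df.columns:
        raise PanelDataError(f"wide table is missing subject column {subject_col!r}")
    if df[subject_col].duplicated().any():
        raise PanelDataError("duplicate subject rows in wide table")

    cells = []  # (var, wave_index, column)
    for col in df.columns:
        if col in (subject_col, group_col):
            continue
        if "__w" not in col:
            raise PanelDataError(f"unexpected wide column {col!r} (expected <var>__w<k>)")
        var, _, k = col.rpartition("__w")
        cells.append((var, int(k), col))
    var_names = config.get("var_names") or list(dict.fromkeys(v for v, _, _ in cells))
    unknown = set(v for v, _, _ in cells) - set(var_names)
    if unknown:
        raise PanelDataError(f"table contains undeclared variables {sorted(unknown)!r}")
    n_waves = max(k for _, k, _ in cells) + 1
    wave_labels = config.get("wave_labels", list(range(n_waves)))
    communities = dict(config.get("communities", {}))
    for v in communities:
        if v not in var_names:
            raise PanelDataError(f"community map names unknown variable {v!r}")

    arr = np.full((len(df), n_waves, len(var_names)), np.nan)
    vpos = {v: i for i, v in enumerate(var_names)}
    for var, k, col in cells:
        arr[:, k, vpos[var]] = _coerce_values(df[col])
    group = list(df[group_col]) if group_col is not None else None
    return PanelDataset(
        arr, list(df[subject_col]), list(wave_labels), list(var_names), group, communities
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_panel_table(ds: PanelDataset, path, layout: str = "wide", group_column: str = "group") -> None:
    """Write a dataset back to delimited text (inverse of ``read_panel_table``)."""
    sep = _delimiter_for(path)
    if layout == "wide":
        data = {"subject": list(ds.subject_ids)}
        if ds.group is not None:
            data[group_column] = list(ds.group)
        for k in range(ds.n_waves):
            for j, v in enumerate(ds.var_names):
                data[f"{v}__w{k}"] = ds.values[:, k, j]
        pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.17g")
        return
    if layout == "long":
        rows = []
        for i, s in enumerate(ds.subject_ids):
            for k, w in enumerate(ds.wave_labels):
                for j, v in enumerate(ds.var_names):
                    val = ds.values[i, k, j]
                    if np.isnan(val):
                        continue
                    row = {"subject": s, "wave": w, "variable": v, "value": val}
                    if ds.group is not None:
                        row[group_column] = ds.group[i]
                    rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.17g")
        return
    raise ValueError(f"unknown layout {layout!r}")


def write_edge_list(records: Sequence[EdgeRecord], path) -> None:
    """Write edge records as delimited text.

    Column order is ``from,to,beta,p,included,inclusion_prob,sign``; rows
    are sorted by the order records were supplied for ``from``, then
    ``to`` (callers pass records in declared variable order, making the
    file deterministic).
    """
    sep = _delimiter_for(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["from", "to", "beta", "p", "included", "inclusion_prob", "sign"])
        for r in records:
            w.writerow(
                [
                    r.from_var,
                    r.to_var,
                    "" if r.beta is None else f"{r.beta:.6f}",
                    "" if r.p_value is None else f"{r.p_value:.6g}",
                    str(bool(r.included)),
                    "" if r.inclusion_prob is None else f"{r.inclusion_prob:.6f}",
                    "" if r.sign is None else r.sign,
                ]
            )


def read_edge_list(path) -> list:
    """Read an edge-list file written by :func:`write_edge_list`."""
    sep = _delimiter_for(path)
    df = pd.read_csv(path, sep=sep)
    out = []
    for _, row in df.iterrows():
        out.append(
            EdgeRecord(
                from_var=row["from"],
                to_var=row["to"],
                beta=None if pd.isna(row["beta"]) else float(row["beta"]),
                p_value=None if pd.isna(row["p"]) else float(row["p"]),
                included=bool(row["included"]),
                inclusion_prob=None
                if pd.isna(row["inclusion_prob"])
                else float(row["inclusion_prob"]),
                sign=None if pd.isna(row["sign"]) else str(row["sign"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# description
# ---------------------------------------------------------------------------

def describe_dataset(ds: PanelDataset) -> pd.DataFrame:
    """Per-variable, per-wave summary statistics.

    Returns one row per variable x wave with mean, SD, moment skewness,
    excess kurtosis and percent missing.  Cells observed for fewer than 3
    subjects, or with zero variance, get NaN skewness/kurtosis and are
    flagged ``undefined``.
    """
    rows = []
    for k, w in enumerate(ds.wave_labels):
        for j, v in enumerate(ds.var_names):
            col = ds.values[:, k, j]
            obs = col[~np.isnan(col)]
            pct_missing = 100.0 * (1 - len(obs) / len(col))
            rec = {
                "variable": v,
                "wave": w,
                "n": len(obs),
                "pct_missing": pct_missing,
            }
            if len(obs) == 0:
                rec.update(mean=np.nan, sd=np.nan, skewness=np.nan,
                           excess_kurtosis=np.nan, undefined=True)
            else:
                sd = float(np.std(obs, ddof=1)) if len(obs) > 1 else 0.0
                undef = len(obs) < 3 or sd == 0.0
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    skew = np.nan if undef else float(stats.skew(obs, bias=False))
                    kurt = np.nan if undef else float(stats.kurtosis(obs, bias=False))
                rec.update(
                    mean=float(np.mean(obs)),
                    sd=sd,
                    skewness=skew,
                    excess_kurtosis=kurt,
                    undefined=undef,
                )
            rows.append(rec)
    return pd.DataFrame(rows)
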