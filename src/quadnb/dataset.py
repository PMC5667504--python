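"""Paired IP/input count data for MeRIP-Seq differential methylation analysis.

A MeRIP-Seq experiment produces, for every biological replicate, two
sequencing libraries: an immunoprecipitated (IP) library whose reads are
proportional to the amount of methylated RNA fragments, and an input control
library measuring basal transcript abundance.  After peak calling and read
counting (both outside the scope of this package), the data reduce to two
integer matrices of identical shape — features x replicates — plus a
condition label per replicate.  :class:`MeripDataset` holds that triple and
enforces its invariants; everything downstream reads from it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["MeripDataset", "load_counts", "naive_methylation_rate"]


@dataclass(frozen=True)
class MeripDataset:
    """Validated paired IP/input count matrices with a replicate-to-condition map.

    Parameters
    ----------
    feature_ids
        One opaque identifier per feature (methylation site or gene).
        Must be unique.
    ip_counts, input_counts
        Non-negative integer matrices of shape (n_features, n_replicates)
        with identical replicate ordering.
    conditions
        Condition label for each replicate column.  Exactly two distinct
        labels must be present, each with at least one replicate.
    """

    feature_ids: tuple
    ip_counts: np.ndarray
    input_counts: np.ndarray
    conditions: tuple

    def __post_init__(self):
        ip = np.asarray(self.ip_counts)
        inp = np.asarray(self.input_counts)
        for name, mat in (("ip_counts", ip), ("input_counts", inp)):
            if mat.ndim != 2:
                raise ValueError(f"{name} must be a 2-D matrix, got ndim={mat.ndim}")
            if not np.issubdtype(mat.dtype, np.integer):
                if not np.all(np.isfinite(mat)) or np.any(mat != np.floor(mat)):
                    bad = np.argwhere(~np.isfinite(mat) | (mat != np.floor(mat)))[0]
                    raise ValueError(
                        f"{name} contains a non-integer value at row {bad[0]}, "
                        f"column {bad[1]}: {mat[bad[0], bad[1]]!r}"
                    )
                mat = mat.astype(np.int64)
            if np.any(mat < 0):
                bad = np.argwhere(mat < 0)[0]
                raise ValueError(
                    f"{name} contains a negative count at row {bad[0]}, column {bad[1]}"
                )
        ip = ip.astype(np.int64)
        inp = inp.astype(np.int64)
        if ip.shape != inp.shape:
            raise ValueError(
                f"ip_counts and input_counts dimensions differ: {ip.shape} vs {inp.shape}"
            )
        ids = tuple(str(f) for f in self.feature_ids)
        if len(ids) != ip.shape[0]:
            raise ValueError(
                f"{len(ids)} feature ids for {ip.shape[0]} matrix rows"
            )
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for f in ids:
                if f in seen:
                    dup = f
                    break
                seen.add(f)
            raise ValueError(f"duplicated feature ID: {dup!r}")
        conds = tuple(str(c) for c in self.conditions)
        if len(conds) != ip.shape[1]:
            raise ValueError(
                f"{len(conds)} condition labels for {ip.shape[1]} replicate columns"
            )
        distinct = list(dict.fromkeys(conds))
        if len(distinct) != 2:
            raise ValueError(
                f"exactly two condition labels required, got {distinct!r}"
            )
        object.__setattr__(self, "feature_ids", ids)
        object.__setattr__(self, "ip_counts", ip)
        object.__setattr__(self, "input_counts", inp)
        object.__setattr__(self, "conditions", conds)

    # -- shape / label helpers -------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.ip_counts.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.ip_counts.shape[1]

    @property
    def condition_names(self) -> tuple:
        """The two condition labels, in order of first appearance."""
        return tuple(dict.fromkeys(self.conditions))

    def replicates_of(self, condition: str) -> np.ndarray:
        """Column indices of the replicates in ``condition``."""
        idx = np.flatnonzero(np.asarray(self.conditions, dtype=object) == condition)
        if idx.size == 0:
            raise KeyError(f"unknown condition {condition!r}")
        return idx

    @property
    def total_counts(self) -> np.ndarray:
        """n[i,j] = t[i,j] + c[i,j]."""
        return self.ip_counts + self.input_counts

    def with_conditions(self, conditions: Sequence[str]) -> "MeripDataset":
        """Same count data under a different replicate-to-condition map."""
        return MeripDataset(self.feature_ids, self.ip_counts, self.input_counts,
                            tuple(conditions))

    def subset(self, rows) -> "MeripDataset":
        rows = np.asarray(rows)
        ids = tuple(np.asarray(self.feature_ids, dtype=object)[rows])
        return MeripDataset(ids, self.ip_counts[rows], self.input_counts[rows],
                            self.conditions)


def _read_table(source, label: str) -> pd.DataFrame:
    """Read a headered TSV/CSV with the feature-ID column first."""
    df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{label} table needs a feature-ID column plus replicates")
    df = df.set_index(df.columns[0])
    return df


def _to_int_matrix(df: pd.DataFrame, label: str) -> np.ndarray:
    out = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            row = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise ValueError(
                f"{label} table: non-integer count in column {col!r}, "
                f"row {row!r}: {df.loc[row, col]!r}"
            )
        if (vals < 0).any():
            row = df.index[np.flatnonzero((vals < 0).to_numpy())[0]]
            raise ValueError(
                f"{label} table: negative count in column {col!r}, row {row!r}"
            )
        out[:, j] = vals.to_numpy()
    return out


def load_counts(
    ip_table: Union[str, Path],
    input_table: Union[str, Path],
    condition_labels: Sequence[str],
) -> MeripDataset:
    """Load and validate an IP/input table pair into a :class:`MeripDataset`.

    Both tables are headered TSV/CSV files whose first column holds feature
    IDs and whose remaining columns are replicates; the two files must share
    the same feature IDs (same order) and the same replicate column names.
    ``condition_labels`` assigns one of two condition labels to each
    replicate column, in column order.
    """
    ip = _read_table(ip_table, "IP")
    inp = _read_table(input_table, "input")
    if list(ip.columns) != list(inp.columns):
        raise ValueError(
            "replicate columns differ between IP and input tables: "
            f"{list(ip.columns)} vs {list(inp.columns)}"
        )
    if list(ip.index) != list(inp.index):
        raise ValueError("feature IDs differ between IP and input tables")
    labels = list(condition_labels)
    if len(labels) != ip.shape[1]:
        raise ValueError(
            f"{len(labels)} condition labels for {ip.shape[1]} replicate columns"
        )
    return MeripDataset(
        feature_ids=tuple(ip.index),
        ip_counts=_to_int_matrix(ip, "IP"),
        input_counts=_to_int_matrix(inp, "input"),
        conditions=tuple(labels),
    )


def naive_methylation_rate(t, c):
    """Point estimate of the methylation level, ``t / (t + c)``.

    ``t`` is the IP read count of a site and ``c`` its input-control count;
    the ratio estimates the fraction of molecules carrying the mark.  When
    ``t + c == 0`` there is no information and NaN is returned (never 0).
    Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    n = t + c
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(n > 0, t / np.where(n > 0, n, 1.0), np.nan)
    if rate.ndim == 0:
        return float(rate)
    return rate
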