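"""Benchmarking utilities: ranking AUC and the sample-swop protocol.

Real differential-methylation datasets lack validated ground truth, so two
surrogate evaluations are provided.  Against simulated data, features are
ranked by p-value and scored by ROC AUC versus the known differential
labels.  Against real data, a "mock" dataset — one replicate exchanged
between the two conditions — acts as an empirical negative control: at any
fixed fraction of features called on the mock data, a better method calls
more features on the genuine data at the same significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .dataset import MeripDataset

__all__ = ["roc_auc", "SwopPair", "make_swop_pairs", "swop_curve"]


def roc_auc(p_values, truth_labels) -> float:
    """AUC of ranking features by ascending p-value against binary truth.

    Missing p-values rank last (least significant); ties contribute with
    mid-rank semantics.
    """
    p = np.asarray(p_values, dtype=float)
    y = np.asarray(truth_labels).astype(int)
    if p.shape != y.shape:
        raise ValueError("p_values and truth_labels must have equal length")
    if np.unique(y).size < 2:
        raise ValueError("truth labels contain a single class; AUC undefined")
    score = -np.where(np.isnan(p), 1.1, p)  # NaN ranks below any real p-value
    return float(roc_auc_score(y, score))


@dataclass(frozen=True)
class SwopPair:
    """A genuine dataset and its mock partner with one replicate pair exchanged.

    ``swapped`` records the exchanged replicate columns as global column
    indices ``(column_in_A, column_in_B)``; the replicate's IP and input
    columns move together.
    """

    genuine: MeripDataset
    mock: MeripDataset
    swapped: Tuple[int, int]


def make_swop_pairs(dataset: MeripDataset) -> List[SwopPair]:
    """Build the cyclic genuine/mock pairs used by the sample-swop test.

    With ``k`` replicates per condition, the ``k`` cyclic pairings
    (A-replicate ``i`` with B-replicate ``(i+1) mod k``) each produce one
    mock dataset in which that single replicate pair trades conditions —
    for 3+3 designs: pairs (1,2), (2,3), (3,1).  Requires a balanced
    design.
    """
    cond_a, cond_b = dataset.condition_names
    ia = dataset.replicates_of(cond_a)
    ib = dataset.replicates_of(cond_b)
    if ia.size != ib.size:
        raise ValueError(
            f"sample-swop needs equal replicate counts per condition, "
            f"got {ia.size} vs {ib.size}"
        )
    k = ia.size
    pairs = []
    for i in range(k):
        a_col = int(ia[i])
        b_col = int(ib[(i + 1) % k])
        labels = list(dataset.conditions)
        labels[a_col], labels[b_col] = labels[b_col], labels[a_col]
        pairs.append(SwopPair(
            genuine=dataset,
            mock=dataset.with_conditions(labels),
            swapped=(a_col, b_col),
        ))
    return pairs


def _curve_one(genuine_p: np.ndarray, mock_p: np.ndarray, fractions: np.ndarray):
    g = np.asarray(genuine_p, dtype=float)
    m = np.asarray(mock_p, dtype=float)
    if g.size == 0 or m.size == 0:
        raise ValueError("empty results")
    if g.size != m.size:
        raise ValueError("genuine and mock results must cover the same features")
    m_sorted = np.sort(m[~np.isnan(m)])
    n_m = m_sorted.size
    mock_real = np.empty(fractions.size)
    genuine_frac = np.empty(fractions.size)
    n_g = g.size
    for i, x in enumerate(fractions):
        k = int(np.ceil(x * n_m))
        if k <= 0:
            mock_real[i] = 0.0
            genuine_frac[i] = 0.0
            continue
        thr = m_sorted[min(k, n_m) - 1]
        # ties at the boundary p-value are all included
        mock_real[i] = np.sum(m <= thr) / m.size
        genuine_frac[i] = np.sum(g <= thr) / n_g
    return mock_real, genuine_frac


def swop_curve(
    genuine_results,
    mock_results,
    mock_fractions: Sequence[float] = (0.001, 0.005, 0.01, 0.02, 0.05, 0.1),
) -> pd.DataFrame:
    """Fraction of genuine calls at thresholds fixed by the mock call fraction.

    ``genuine_results``/``mock_results`` are p-value vectors (or result
    DataFrames with a ``p_value`` column), or equal-length lists of them —
    one per swop pair, averaged.  For each target mock fraction ``x`` the
    significance threshold is the mock p-value quantile realizing at least
    ``x`` calls; the curve reports the genuine call fraction at that same
    threshold and the implied empirical false discovery rate
    ``mock_fraction / genuine_fraction``.
    """
    def extract(obj):
        if isinstance(obj, pd.DataFrame):
            return obj["p_value"].to_numpy(dtype=float)
        return np.asarray(obj, dtype=float)

    if isinstance(genuine_results, (list, tuple)):
        gs = [extract(o) for o in genuine_results]
        ms = [extract(o) for o in mock_results]
    else:
        gs = [extract(genuine_results)]
        ms = [extract(mock_results)]
    if len(gs) != len(ms):
        raise ValueError("need one mock result per genuine result")
    fr = np.asarray(list(mock_fractions), dtype=float)
    mock_acc = np.zeros(fr.size)
    gen_acc = np.zeros(fr.size)
    for g, m in zip(gs, ms):
        mr, gf = _curve_one(g, m, fr)
        mock_acc += mr
        gen_acc += gf
    mock_acc /= len(gs)
    gen_acc /= len(gs)
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(gen_acc > 0, mock_acc / np.where(gen_acc > 0, gen_acc, 1.0),
                       np.nan)
    return pd.DataFrame({
        "mock_fraction": fr,
        "mock_fraction_realized": mock_acc,
        "genuine_fraction": gen_acc,
        "implied_fdr": fdr,
    })
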