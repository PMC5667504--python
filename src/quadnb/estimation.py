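"""Feature-level estimators of the quad-negative-binomial model.

The generative model for counts of feature ``i`` in replicate ``j`` is

    t[i,j] ~ NB(mu_t, sigma_t^2),   mu_t = q_i * p_{i,rho(j)} * e_{i,rho(j)} * s_t[j]
    c[i,j] ~ NB(mu_c, sigma_c^2),   mu_c = q_i * (1 - p_{i,rho(j)}) * e_{i,rho(j)} * s_c[j]

with ``q_i`` the expected abundance of the feature in a standard library,
``p`` the methylation rate on the common scale, ``e`` a condition-specific
expression factor and ``s`` the library size factors.  The variance is the
shot-noise mean plus an over-dispersion term ``(e*s)^2 * v`` driven by the
raw variance ``v``, itself modelled as a smooth function of ``(p, q)``.

This module computes the moment estimators of ``q``, ``p``, ``e``, the
common-scale replicate variances ``w`` and the bias term ``z`` whose
difference ``w - z`` is an unbiased estimate of the raw variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .dataset import MeripDataset
from .normalization import NormalizationFactors

__all__ = [
    "FeatureEstimates",
    "estimate_abundance",
    "estimate_methylation_rate",
    "estimate_expression_factor",
    "common_scale_variance",
    "bias_term_z",
    "compute_estimates",
    "POOLED",
    "BLIND",
]

POOLED = "pooled"   # union of both conditions in rate estimation
BLIND = "blind"     # all replicates treated as one condition in variance estimation


def _normalized(dataset: MeripDataset, factors: NormalizationFactors):
    """Depth-normalized IP and input matrices: t/s_t and c/s_c."""
    t_norm = dataset.ip_counts / factors.s_ip[None, :]
    c_norm = dataset.input_counts / factors.s_input[None, :]
    return t_norm, c_norm


def _group_indices(dataset: MeripDataset, group: str) -> np.ndarray:
    if group in (POOLED, BLIND):
        return np.arange(dataset.n_replicates)
    return dataset.replicates_of(group)


def estimate_abundance(
    dataset: MeripDataset, factors: NormalizationFactors
) -> np.ndarray:
    """Expected standard-library abundance ``q_hat``.

    Mean over *all* replicates of the depth-normalized total
    ``t/s_t + c/s_c``; both IP and input libraries contribute, which keeps
    the background estimate stable for lowly expressed features.
    """
    t_norm, c_norm = _normalized(dataset, factors)
    return (t_norm + c_norm).mean(axis=1)


def estimate_methylation_rate(
    dataset: MeripDataset, factors: NormalizationFactors, group: str
) -> np.ndarray:
    """Common-scale methylation rate ``p_hat`` within a replicate group.

    ``group`` is a condition label, or :data:`POOLED` for the null-pooled
    rate over both conditions.  The estimator is the ratio of summed
    depth-normalized IP counts to summed depth-normalized totals; NaN when
    the denominator is zero.
    """
    idx = _group_indices(dataset, group)
    t_norm, c_norm = _normalized(dataset, factors)
    num = t_norm[:, idx].sum(axis=1)
    den = num + c_norm[:, idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


def estimate_expression_factor(
    dataset: MeripDataset,
    factors: NormalizationFactors,
    q_hat: np.ndarray,
    condition: str,
) -> np.ndarray:
    """Condition-specific expression factor ``e_hat``.

    The mean depth-normalized total within the condition, divided by the
    overall abundance ``q_hat``; equals 1 when the condition behaves like
    the across-condition average.  NaN where ``q_hat == 0``.
    """
    idx = _group_indices(dataset, condition)
    t_norm, c_norm = _normalized(dataset, factors)
    mean_total = (t_norm[:, idx] + c_norm[:, idx]).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(q_hat > 0, mean_total / np.where(q_hat > 0, q_hat, 1.0), np.nan)


def _type_factors(factors: NormalizationFactors, sample_type: str) -> np.ndarray:
    if sample_type == "ip":
        return factors.s_ip
    if sample_type == "input":
        return factors.s_input
    raise ValueError(f'sample_type must be "ip" or "input", got {sample_type!r}')


def common_scale_variance(
    dataset: MeripDataset,
    factors: NormalizationFactors,
    e_hat: np.ndarray,
    group: str,
    sample_type: str,
) -> Tuple[np.ndarray, np.ndarray]:
    """Unbiased sample variance of the counts rescaled to the common scale.

    Each replicate count is divided by ``s[j] * e_hat[i]``; the function
    returns ``(w_hat, q_bar)`` — the ddof-1 variance and the mean of those
    rescaled counts within the group.  ``group`` may be a condition label or
    :data:`BLIND` (all replicates as one group, with ``e_hat`` of ones).
    """
    idx = _group_indices(dataset, group)
    if idx.size < 2:
        raise ValueError(
            f"group {group!r} has a single replicate; an unbiased variance needs "
            'at least two — use variance mode "blind" or "pooled"'
        )
    counts = dataset.ip_counts if sample_type == "ip" else dataset.input_counts
    s = _type_factors(factors, sample_type)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = counts[:, idx] / (s[idx][None, :] * e_hat[:, None])
        q_bar = x.mean(axis=1)
        w_hat = ((x - q_bar[:, None]) ** 2).sum(axis=1) / (idx.size - 1)
    return w_hat, q_bar


def bias_term_z(
    dataset: MeripDataset,
    factors: NormalizationFactors,
    q_hat: np.ndarray,
    rate: np.ndarray,
    e_hat: np.ndarray,
    group: str,
    sample_type: str,
) -> np.ndarray:
    """Shot-noise bias term ``z`` of the common-scale variance.

    ``w_hat`` overstates the raw variance by the expected Poisson
    contribution ``z = q_hat * rate / |g| * sum_j 1/(s[j] * e_hat)`` (IP);
    the input analogue uses ``1 - rate`` and the input size factors.
    ``rate`` is the methylation rate at which the term is evaluated.
    """
    idx = _group_indices(dataset, group)
    s = _type_factors(factors, sample_type)
    rate = np.asarray(rate, dtype=float)
    eff_rate = rate if sample_type == "ip" else 1.0 - rate
    inv_s_sum = float(np.sum(1.0 / s[idx]))
    with np.errstate(invalid="ignore", divide="ignore"):
        return q_hat * eff_rate / idx.size * (inv_s_sum / e_hat)


@dataclass
class FeatureEstimates:
    """All per-feature moment estimates needed by the variance model and test.

    ``w`` and ``q_bar`` are keyed by ``(sample_type, group)`` where
    ``sample_type`` is ``"ip"`` or ``"input"`` and ``group`` is a condition
    label or :data:`BLIND`.  ``group_rate[group]`` is the methylation rate
    used as the x-coordinate of that group's variance scatter (per-condition
    rate for condition groups, the pooled rate for the blind group).
    """

    dataset: MeripDataset
    factors: NormalizationFactors
    q_hat: np.ndarray
    p_hat: Dict[str, np.ndarray]
    e_hat: Dict[str, np.ndarray]
    w: Dict[Tuple[str, str], np.ndarray]
    q_bar: Dict[Tuple[str, str], np.ndarray]
    group_rate: Dict[str, np.ndarray]
    variance_groups: Tuple[str, ...]

    @property
    def n_features(self) -> int:
        return self.q_hat.size

    def bias_term(self, rate: np.ndarray, group: str, sample_type: str) -> np.ndarray:
        """Recompute ``z`` for a fitting group at an arbitrary rate."""
        return bias_term_z(
            self.dataset, self.factors, self.q_hat, rate,
            self.e_hat[group], group, sample_type,
        )

    def raw_variance_scatter(self, group: str, sample_type: str) -> np.ndarray:
        """Unsmoothed raw-variance estimate ``w - z`` (may be negative)."""
        return self.w[(sample_type, group)] - self.bias_term(
            self.group_rate[group], group, sample_type
        )

    def to_frame(self) -> pd.DataFrame:
        """Diagnostics table of per-feature estimates, one block per group."""
        frames = []
        for (stype, group), w in self.w.items():
            z = self.bias_term(self.group_rate[group], group, stype)
            frames.append(pd.DataFrame({
                "feature_id": list(self.dataset.feature_ids),
                "sample_type": stype,
                "group": group,
                "p_hat": self.group_rate[group],
                "q_hat": self.q_hat,
                "w_hat": w,
                "z": z,
                "v_hat": w - z,
            }))
        return pd.concat(frames, ignore_index=True)


def resolve_variance_groups(dataset: MeripDataset, mode: str) -> Tuple[str, ...]:
    """Replicate groups whose common-scale variances feed the smoother.

    ``per-condition`` needs at least two replicates in every condition;
    ``pooled`` uses every condition that has replicates; ``blind`` collapses
    all samples into one pseudo-condition; ``auto`` picks per-condition when
    every condition is replicated, otherwise blind.
    """
    names = dataset.condition_names
    sizes = {c: dataset.replicates_of(c).size for c in names}
    if mode == "auto":
        mode = "per-condition" if all(v >= 2 for v in sizes.values()) else "blind"
    if mode == "per-condition":
        lacking = [c for c, v in sizes.items() if v < 2]
        if lacking:
            raise ValueError(
                f"variance mode 'per-condition' needs >=2 replicates per condition; "
                f"condition(s) {lacking} lack replicates — use 'blind' or 'pooled'"
            )
        return names
    if mode == "pooled":
        replicated = tuple(c for c, v in sizes.items() if v >= 2)
        if not replicated:
            raise ValueError(
                "variance mode 'pooled' needs at least one condition with "
                ">=2 replicates — use 'blind'"
            )
        return replicated
    if mode == "blind":
        return (BLIND,)
    raise ValueError(f"unknown variance mode {mode!r}")


def compute_estimates(
    dataset: MeripDataset,
    factors: NormalizationFactors,
    mode: str = "auto",
) -> FeatureEstimates:
    """Run every moment estimator once and bundle the results."""
    q_hat = estimate_abundance(dataset, factors)
    names = dataset.condition_names
    p_hat = {c: estimate_methylation_rate(dataset, factors, c) for c in names}
    p_hat[POOLED] = estimate_methylation_rate(dataset, factors, POOLED)
    e_hat = {c: estimate_expression_factor(dataset, factors, q_hat, c) for c in names}
    # pooled over all replicates the expression factor is identically 1 by
    # construction of q_hat; keep it exact rather than recomputed
    e_hat[BLIND] = np.where(np.isnan(q_hat) | (q_hat <= 0), np.nan, 1.0)

    groups = resolve_variance_groups(dataset, mode)
    w: Dict[Tuple[str, str], np.ndarray] = {}
    q_bar: Dict[Tuple[str, str], np.ndarray] = {}
    group_rate: Dict[str, np.ndarray] = {}
    for g in groups:
        group_rate[g] = p_hat[POOLED] if g == BLIND else p_hat[g]
        for stype in ("ip", "input"):
            w[(stype, g)], q_bar[(stype, g)] = common_scale_variance(
                dataset, factors, e_hat[g], g, stype
            )
    return FeatureEstimates(
        dataset=dataset, factors=factors, q_hat=q_hat, p_hat=p_hat,
        e_hat=e_hat, w=w, q_bar=q_bar, group_rate=group_rate,
        variance_groups=groups,
    )
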