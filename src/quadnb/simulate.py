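"""Synthetic MeRIP-Seq count generator with ground truth.

Counts are drawn from the same generative model the test assumes: per
feature, a standard-library abundance ``q`` with log-uniform distribution,
a methylation rate ``p`` uniform on (0, 1) per condition (shared between
conditions for non-differential features), lognormal condition-specific
expression factors ``e`` and lognormal per-library size factors ``s``.
Each count is negative binomial with mean ``q*p*e*s`` (IP) or
``q*(1-p)*e*s`` (input) and variance ``mean + (e*s)^2 * v`` where the raw
variance is ``v = d / (e * s)`` for a dispersion constant ``d >= 0`` — so
over-dispersion shrinks with expression level and depth, and ``d = 0``
recovers pure Poisson shot noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .dataset import MeripDataset

__all__ = ["SimulationConfig", "SimulatedTruth", "simulate", "empirical_moments",
           "sample_nb"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic dataset.

    Defaults mirror a typical transcriptome-wide study: 20000 methylation
    sites, 3 replicates per condition, half the sites differential, site
    abundances log-uniform between 10 and 10000 reads, and mild lognormal
    variation (sd 0.25 on the log scale) of expression factors and library
    depths.
    """

    n_features: int = 20000
    reps_per_condition: int = 3
    d: float = 1.0
    frac_differential: float = 0.5
    log_abundance_range: Tuple[float, float] = (math.log(10.0), math.log(10000.0))
    sd_log_e: float = 0.25
    sd_log_s: float = 0.25
    seed: Optional[int] = None
    conditions: Tuple[str, str] = ("A", "B")

    def __post_init__(self):
        if self.n_features < 1 or self.reps_per_condition < 1:
            raise ValueError("n_features and reps_per_condition must be >= 1")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ValueError("frac_differential must be in [0, 1]")
        if self.d < 0 or self.sd_log_e < 0 or self.sd_log_s < 0:
            raise ValueError("d and log-sds must be non-negative")
        lo, hi = self.log_abundance_range
        if not lo < hi:
            raise ValueError("log_abundance_range must satisfy lo < hi")
        if len(set(self.conditions)) != 2:
            raise ValueError("two distinct condition labels required")


@dataclass(frozen=True)
class SimulatedTruth:
    """Ground-truth parameters behind one simulated dataset."""

    q: np.ndarray
    p_a: np.ndarray
    p_b: np.ndarray
    e_a: np.ndarray
    e_b: np.ndarray
    s_ip: np.ndarray
    s_input: np.ndarray
    is_differential: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature_id": [f"site_{i}" for i in range(self.q.size)],
            "q": self.q,
            "p_A": self.p_a,
            "p_B": self.p_b,
            "e_A": self.e_a,
            "e_B": self.e_b,
            "is_differential": self.is_differential.astype(int),
        })


def sample_nb(rng: np.random.Generator, mean: np.ndarray, variance: np.ndarray):
    """Draw counts from NB(mean, variance), Poisson when variance <= mean.

    Uses the same (mean, variance) -> (size, prob) conversion as the test's
    mass function, so simulated data follow exactly the assumed model.
    """
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    pois = pos & (variance <= mean)
    if np.any(pois):
        out[pois] = rng.poisson(mean[pois])
    nb = pos & (variance > mean)
    if np.any(nb):
        m, v = mean[nb], variance[nb]
        r = m * m / (v - m)
        p = m / v
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate(config: SimulationConfig) -> Tuple[MeripDataset, SimulatedTruth]:
    """Generate one dataset plus its ground truth, reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    reps = config.reps_per_condition
    lo, hi = config.log_abundance_range

    q = np.exp(rng.uniform(lo, hi, size=n))
    p_a = rng.uniform(0.0, 1.0, size=n)
    n_diff = int(round(config.frac_differential * n))
    is_diff = np.zeros(n, dtype=bool)
    is_diff[rng.choice(n, size=n_diff, replace=False)] = True
    p_b = p_a.copy()
    if n_diff:
        draw = rng.uniform(0.0, 1.0, size=n_diff)
        same = draw == p_a[is_diff]
        while np.any(same):  # essentially never at float precision
            draw[same] = rng.uniform(0.0, 1.0, size=int(same.sum()))
            same = draw == p_a[is_diff]
        p_b[is_diff] = draw

    e_a = np.exp(rng.normal(0.0, config.sd_log_e, size=n))
    e_b = np.exp(rng.normal(0.0, config.sd_log_e, size=n))
    n_cols = 2 * reps
    s_ip = np.exp(rng.normal(0.0, config.sd_log_s, size=n_cols))
    s_input = np.exp(rng.normal(0.0, config.sd_log_s, size=n_cols))

    conditions = (config.conditions[0],) * reps + (config.conditions[1],) * reps
    ip = np.empty((n, n_cols), dtype=np.int64)
    inp = np.empty((n, n_cols), dtype=np.int64)
    for j in range(n_cols):
        in_a = j < reps
        p = p_a if in_a else p_b
        e = e_a if in_a else e_b
        mu_t = q * p * e * s_ip[j]
        mu_c = q * (1.0 - p) * e * s_input[j]
        if config.d > 0:
            v_t = config.d / (e * s_ip[j])
            v_c = config.d / (e * s_input[j])
        else:
            v_t = v_c = np.zeros(n)
        ip[:, j] = sample_nb(rng, mu_t, mu_t + (e * s_ip[j]) ** 2 * v_t)
        inp[:, j] = sample_nb(rng, mu_c, mu_c + (e * s_input[j]) ** 2 * v_c)

    dataset = MeripDataset(
        feature_ids=tuple(f"site_{i}" for i in range(n)),
        ip_counts=ip,
        input_counts=inp,
        conditions=conditions,
    )
    truth = SimulatedTruth(q=q, p_a=p_a, p_b=p_b, e_a=e_a, e_b=e_b,
                           s_ip=s_ip, s_input=s_input, is_differential=is_diff)
    return dataset, truth


def _model_moments(truth: SimulatedTruth, config: SimulationConfig,
                   cols: np.ndarray, sample_type: str, in_a: bool):
    """Closed-form mean/variance of the count mixture across a column group."""
    p = truth.p_a if in_a else truth.p_b
    e = truth.e_a if in_a else truth.e_b
    s = (truth.s_ip if sample_type == "ip" else truth.s_input)[cols]
    rate = p if sample_type == "ip" else 1.0 - p
    mu_j = truth.q[:, None] * rate[:, None] * e[:, None] * s[None, :]
    if config.d > 0:
        var_j = mu_j + (e[:, None] * s[None, :]) ** 2 * (
            config.d / (e[:, None] * s[None, :]))
    else:
        var_j = mu_j
    mean = mu_j.mean(axis=1)
    # across a group whose libraries differ in depth, the marginal variance
    # adds the between-library spread of the means
    var = var_j.mean(axis=1) + mu_j.var(axis=1)
    return mean, var


def empirical_moments(
    dataset: MeripDataset,
    truth: SimulatedTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Per-feature empirical vs model moments, per sample type and condition.

    Validation aid: the empirical mean and (ddof-1) variance of the counts
    across a condition's replicate columns, next to the model's closed-form
    moments given the true parameters.
    """
    cond_a, cond_b = dict.fromkeys(dataset.conditions)
    rows = []
    for cond, in_a in ((cond_a, True), (cond_b, False)):
        cols = dataset.replicates_of(cond)
        for stype, mat in (("ip", dataset.ip_counts), ("input", dataset.input_counts)):
            sub = mat[:, cols].astype(float)
            model_mean, model_var = _model_moments(truth, config, cols, stype, in_a)
            rows.append(pd.DataFrame({
                "feature_id": list(dataset.feature_ids),
                "sample_type": stype,
                "condition": cond,
                "emp_mean": sub.mean(axis=1),
                "emp_var": sub.var(axis=1, ddof=1) if cols.size > 1 else np.nan,
                "model_mean": model_mean,
                "model_var": model_var,
            }))
    return pd.concat(rows, ignore_index=True)
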