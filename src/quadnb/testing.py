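"""The quad-negative-binomial exact conditional test.

For each feature the replicate counts are collapsed into four group sums —
IP and input under each of the two conditions — and each sum is modelled as
a negative binomial whose mean and variance derive from the null hypothesis
of a common methylation rate ``p_O`` across conditions:

    mu_tA     = p_O * q * e_A * sum_{j in A} s_t[j]
    sigma_tA^2 = mu_tA + v_A(p_O, q) * e_A^2 * sum_{j in A} s_t[j]^2

(input groups use ``1 - p_O``, the input size factors and the input-type
variance surface).  Conditioning on the total IP count ``t_i = t_A + t_B``
and the per-condition totals ``n_A``, ``n_B``, the probability of observing
the split ``t_A = t`` is the product of the four marginal masses, and the
two-sided p-value sums the probabilities of all splits no more likely than
the observed one, normalized by the total mass over the valid support
``t in [max(0, t_i - n_B), min(t_i, n_A)]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .dataset import MeripDataset
from .estimation import (
    BLIND,
    POOLED,
    FeatureEstimates,
    compute_estimates,
)
from .normalization import NormalizationFactors, estimate_size_factors
from .variance import VarianceModel, fit_variance_model, raw_variance

__all__ = [
    "GroupNBParams",
    "QNBConfig",
    "nb_logpmf",
    "nb_pmf",
    "group_nb_params",
    "joint_conditional_probability",
    "qnb_pvalue",
    "risk_ratio",
    "odds_ratio",
    "run_qnb",
]

# discreteness plus floating point makes a strict "P(t) <= P(t_obs)"
# comparison fragile; a tiny relative tolerance errs on the conservative side
_TIE_RTOL = 1e-8

STATUS_TESTED = "tested"
STATUS_SKIPPED_ZERO = "skipped-zero"
STATUS_SKIPPED_DEGENERATE = "skipped-degenerate"


def nb_logpmf(k, mean, variance):
    """Log-mass of a negative binomial in the (mean, variance) parameterization.

    ``size = mean^2 / (variance - mean)`` and success probability
    ``mean / variance``.  When ``variance <= mean`` the Poisson limit is
    used (the NB is undefined at or below the shot-noise floor), and a
    non-positive mean degenerates to a point mass at zero.  Negative or
    non-integer ``k`` get probability zero.
    """
    k = np.asarray(k, dtype=float)
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    k, mean, variance = np.broadcast_arrays(k, mean, variance)
    out = np.full(k.shape, -np.inf)
    valid_k = (k >= 0) & (k == np.floor(k))

    degenerate = (mean <= 0) & valid_k
    out[degenerate & (k == 0)] = 0.0

    poisson = (mean > 0) & (variance <= mean) & valid_k
    if np.any(poisson):
        kk, m = k[poisson], mean[poisson]
        out[poisson] = kk * np.log(m) - m - gammaln(kk + 1)

    nb = (mean > 0) & (variance > mean) & valid_k
    if np.any(nb):
        kk, m, v = k[nb], mean[nb], variance[nb]
        r = m * m / (v - m)
        out[nb] = (gammaln(kk + r) - gammaln(r) - gammaln(kk + 1)
                   + r * np.log(m / v) + kk * np.log1p(-m / v))
    if out.ndim == 0:
        return float(out)
    return out


def nb_pmf(k, mean, variance):
    """Negative binomial mass in the (mean, variance) parameterization."""
    return np.exp(nb_logpmf(k, mean, variance))


@dataclass(frozen=True)
class GroupNBParams:
    """Null NB parameters and observed raw sums of the four test groups.

    ``mu``/``var`` are keyed by ``("ip"|"input", "A"|"B")`` where A is the
    treated condition and B the control; observed sums are integer sums of
    raw (unnormalized) counts.
    """

    mu: Dict[Tuple[str, str], float]
    var: Dict[Tuple[str, str], float]
    t_a: int
    t_b: int
    c_a: int
    c_b: int

    @property
    def t_total(self) -> int:
        return self.t_a + self.t_b

    @property
    def n_a(self) -> int:
        return self.t_a + self.c_a

    @property
    def n_b(self) -> int:
        return self.t_b + self.c_b

    def support(self) -> Tuple[int, int]:
        """Inclusive range of valid IP-in-A splits given the fixed totals."""
        return (max(0, self.t_total - self.n_b), min(self.t_total, self.n_a))


def group_nb_params(
    dataset: MeripDataset,
    factors: NormalizationFactors,
    estimates: FeatureEstimates,
    model: VarianceModel,
    feature: int,
) -> GroupNBParams:
    """Null NB parameters of the four group sums for one feature row."""
    mu, var, obs = _all_group_params(dataset, factors, estimates, model)
    i = int(feature)
    return GroupNBParams(
        mu={key: float(m[i]) for key, m in mu.items()},
        var={key: float(v[i]) for key, v in var.items()},
        t_a=int(obs["t_a"][i]), t_b=int(obs["t_b"][i]),
        c_a=int(obs["c_a"][i]), c_b=int(obs["c_b"][i]),
    )


def _all_group_params(dataset, factors, estimates, model):
    """Vectorized null means/variances and observed sums for all features."""
    cond_a, cond_b = dataset.condition_names
    p_o = estimates.p_hat[POOLED]
    q = estimates.q_hat
    mu: Dict[Tuple[str, str], np.ndarray] = {}
    var: Dict[Tuple[str, str], np.ndarray] = {}
    for label, cond in (("A", cond_a), ("B", cond_b)):
        idx = dataset.replicates_of(cond)
        e = estimates.e_hat[cond]
        for stype, s_all in (("ip", factors.s_ip), ("input", factors.s_input)):
            s_sum = float(s_all[idx].sum())
            s_sq_sum = float((s_all[idx] ** 2).sum())
            rate = p_o if stype == "ip" else 1.0 - p_o
            v_null = raw_variance(model, estimates, cond, stype, p_o)
            m = rate * q * e * s_sum
            mu[(stype, label)] = m
            var[(stype, label)] = m + v_null * e ** 2 * s_sq_sum
    ia = dataset.replicates_of(cond_a)
    ib = dataset.replicates_of(cond_b)
    obs = {
        "t_a": dataset.ip_counts[:, ia].sum(axis=1),
        "t_b": dataset.ip_counts[:, ib].sum(axis=1),
        "c_a": dataset.input_counts[:, ia].sum(axis=1),
        "c_b": dataset.input_counts[:, ib].sum(axis=1),
    }
    return mu, var, obs


def _joint_logprob(t, params: GroupNBParams):
    """Log joint mass of the four groups at IP-in-A split ``t``."""
    t = np.asarray(t, dtype=float)
    ti, na, nb = params.t_total, params.n_a, params.n_b
    return (
        nb_logpmf(t, params.mu[("ip", "A")], params.var[("ip", "A")])
        + nb_logpmf(ti - t, params.mu[("ip", "B")], params.var[("ip", "B")])
        + nb_logpmf(na - t, params.mu[("input", "A")], params.var[("input", "A")])
        + nb_logpmf(nb - ti + t, params.mu[("input", "B")], params.var[("input", "B")])
    )


def joint_conditional_probability(params: GroupNBParams, t) -> float:
    """Joint probability of the split ``t_A = t`` given the fixed totals.

    Product of the four marginal NB masses; zero outside the valid support.
    """
    lo, hi = params.support()
    t_arr = np.atleast_1d(np.asarray(t))
    out = np.where(
        (t_arr >= lo) & (t_arr <= hi),
        np.exp(_joint_logprob(t_arr, params)),
        0.0,
    )
    if np.ndim(t) == 0:
        return float(out[0])
    return out


def qnb_pvalue(params: GroupNBParams) -> float:
    """Two-sided exact conditional p-value for one feature.

    Sums the joint probabilities of every valid split no more likely than
    the observed one and normalizes by the total mass over the support.
    Returns 1.0 when every split has (numerically) zero probability.
    """
    lo, hi = params.support()
    ts = np.arange(lo, hi + 1)
    logp = _joint_logprob(ts, params)
    if not np.any(np.isfinite(logp)):
        return 1.0
    shift = logp.max()
    prob = np.exp(logp - shift)
    p_obs = prob[params.t_a - lo]
    return float(prob[prob <= p_obs * (1.0 + _TIE_RTOL)].sum() / prob.sum())


def _batch_pvalues(mu, var, obs, chunk_flat=4_000_000):
    """Vectorized p-values over all features.

    Enumerates the full valid support of every feature in flat concatenated
    arrays.  Within a segment the log joint mass is built by a running
    recurrence — each unit step in ``t`` changes every marginal log-mass by
    the log of a rational expression — so only the segment starts need full
    log-pmf evaluations.  Chunked to bound memory.
    """
    t_a = obs["t_a"].astype(np.int64)
    t_b = obs["t_b"].astype(np.int64)
    c_a = obs["c_a"].astype(np.int64)
    c_b = obs["c_b"].astype(np.int64)
    t_i = t_a + t_b
    n_a = t_a + c_a
    n_b = t_b + c_b
    lo = np.maximum(0, t_i - n_b)
    hi = np.minimum(t_i, n_a)
    width = hi - lo + 1
    n = t_a.size
    pvals = np.full(n, np.nan)
    degenerate = np.zeros(n, dtype=bool)

    # features with a degenerate marginal (mean <= 0) take the generic
    # per-feature path; the recurrence assumes positive means throughout
    regular = np.ones(n, dtype=bool)
    for key in mu:
        regular &= mu[key] > 0
    for i in np.flatnonzero(~regular):
        params = GroupNBParams(
            mu={k: float(mu[k][i]) for k in mu},
            var={k: float(var[k][i]) for k in var},
            t_a=int(t_a[i]), t_b=int(t_b[i]), c_a=int(c_a[i]), c_b=int(c_b[i]),
        )
        pvals[i] = qnb_pvalue(params)

    # per feature-group step constants: for an NB group a unit increase of
    # its count k multiplies the mass by (k-1+r)/k * (1 - m/v); the Poisson
    # limit multiplies by m/k.  r_eff stores r (NB) or 0 with step_m = m.
    r_eff, step_a, is_nb = {}, {}, {}
    for key in mu:
        m, v = mu[key], var[key]
        nbm = (v > m) & (m > 0)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            r = np.where(nbm, m * m / np.maximum(v - m, 1e-300), 0.0)
            a = np.where(nbm, np.log1p(-np.where(nbm, m / np.maximum(v, 1e-300), 0.0)),
                         0.0)
        r_eff[key] = r
        step_a[key] = a
        is_nb[key] = nbm

    idx_all = np.flatnonzero(regular)
    start = 0
    while start < idx_all.size:
        stop = start
        flat = 0
        while stop < idx_all.size and (
            flat + width[idx_all[stop]] <= chunk_flat or stop == start
        ):
            flat += width[idx_all[stop]]
            stop += 1
        sel = idx_all[start:stop]
        start = stop
        w_sel = width[sel]
        offsets = np.concatenate([[0], np.cumsum(w_sel)])[:-1]
        total = int(w_sel.sum())
        rep = np.repeat(np.arange(sel.size), w_sel)
        intra = np.arange(total) - np.repeat(offsets, w_sel)
        t_vals = (lo[sel][rep] + intra).astype(float)

        ti_r = t_i[sel][rep].astype(float)
        na_r = n_a[sel][rep].astype(float)
        nb_r = n_b[sel][rep].astype(float)

        def fac(key, k_new, rising):
            """Numerator/denominator factor pair of one group's step ratio."""
            r = r_eff[key][sel][rep]
            m = mu[key][sel][rep]
            nbm = is_nb[key][sel][rep]
            if rising:
                top = np.where(nbm, k_new - 1.0 + r, m)
                return top, k_new
            top = k_new + 1.0
            bot = np.where(nbm, k_new + r, m)
            return top, bot

        # delta(t) = log L(t) - log L(t-1); position lo of each segment gets 0
        n1, d1 = fac(("ip", "A"), t_vals, True)
        n2, d2 = fac(("ip", "B"), ti_r - t_vals, False)
        n3, d3 = fac(("input", "A"), na_r - t_vals, False)
        n4, d4 = fac(("input", "B"), nb_r - ti_r + t_vals, True)
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.log((n1 * n2) * (n3 * n4) / ((d1 * d2) * (d3 * d4)))
        a_const = (step_a[("ip", "A")] - step_a[("ip", "B")]
                   - step_a[("input", "A")] + step_a[("input", "B")])[sel][rep]
        delta += a_const
        delta[offsets] = 0.0

        # base value: full log joint mass at t = lo, exact via log-pmfs
        base = np.zeros(sel.size)
        lo_s = lo[sel].astype(float)
        base += nb_logpmf(lo_s, mu[("ip", "A")][sel], var[("ip", "A")][sel])
        base += nb_logpmf(t_i[sel] - lo_s, mu[("ip", "B")][sel], var[("ip", "B")][sel])
        base += nb_logpmf(n_a[sel] - lo_s, mu[("input", "A")][sel],
                          var[("input", "A")][sel])
        base += nb_logpmf(n_b[sel] - t_i[sel] + lo_s, mu[("input", "B")][sel],
                          var[("input", "B")][sel])

        cs = np.cumsum(delta)
        logp = base[rep] + cs - cs[offsets][rep]

        seg_max = np.maximum.reduceat(logp, offsets)
        finite_max = np.where(np.isfinite(seg_max), seg_max, 0.0)
        prob = np.exp(logp - finite_max[rep])
        prob[~np.isfinite(prob)] = 0.0
        denom = np.add.reduceat(prob, offsets)
        p_obs = prob[offsets + (t_a[sel] - lo[sel])]
        incl = prob <= (p_obs[rep] * (1.0 + _TIE_RTOL))
        numer = np.add.reduceat(np.where(incl, prob, 0.0), offsets)
        bad = (denom <= 0) | ~np.isfinite(seg_max)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(bad, 1.0, numer / np.where(denom > 0, denom, 1.0))
        pvals[sel] = np.minimum(p, 1.0)
        degenerate[sel] = bad
    return pvals, degenerate


def risk_ratio(dataset, factors, feature=None):
    """Risk ratio of methylation, ``p_hat_A / p_hat_B`` (B is the control).

    NaN where the control rate is zero or undefined.  With ``feature=None``
    returns the full vector.
    """
    from .estimation import estimate_methylation_rate

    cond_a, cond_b = dataset.condition_names
    pa = estimate_methylation_rate(dataset, factors, cond_a)
    pb = estimate_methylation_rate(dataset, factors, cond_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        rr = np.where(pb > 0, pa / np.where(pb > 0, pb, 1.0), np.nan)
    if feature is None:
        return rr
    return float(rr[int(feature)])


def odds_ratio(dataset, factors, feature=None):
    """Odds ratio of methylation from depth-normalized group sums.

    ``[sum_A(t/s_t) / sum_A(c/s_c)] / [sum_B(t/s_t) / sum_B(c/s_c)]``;
    NaN when any of the four sums is zero.
    """
    cond_a, cond_b = dataset.condition_names
    t_norm = dataset.ip_counts / factors.s_ip[None, :]
    c_norm = dataset.input_counts / factors.s_input[None, :]
    ia = dataset.replicates_of(cond_a)
    ib = dataset.replicates_of(cond_b)
    ta, ca = t_norm[:, ia].sum(axis=1), c_norm[:, ia].sum(axis=1)
    tb, cb = t_norm[:, ib].sum(axis=1), c_norm[:, ib].sum(axis=1)
    ok = (ta > 0) & (ca > 0) & (tb > 0) & (cb > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        or_ = np.where(ok, (ta / np.where(ok, ca, 1.0)) / np.where(
            ok, tb / np.where(ok, cb, 1.0), 1.0), np.nan)
    if feature is None:
        return or_
    return float(or_[int(feature)])


@dataclass(frozen=True)
class QNBConfig:
    """Pipeline configuration for :func:`run_qnb`.

    The first condition label (order of first appearance, or ``control`` if
    given) plays the control role B of a case-control comparison; effect
    sizes are reported as treated over control.
    """

    size_factor_method: str = "geometric"
    mode: str = "auto"
    span: float = 0.7
    grid_size: int = 21
    adjust_method: str = "fdr_bh"
    control: Optional[str] = None
    drop_zero_features: bool = False


def run_qnb(dataset: MeripDataset, config: QNBConfig = QNBConfig()) -> pd.DataFrame:
    """Full differential-methylation pipeline on one dataset.

    Size factors -> moment estimates -> variance surfaces -> per-feature
    exact conditional test -> multiple-testing adjustment.  Returns one row
    per input feature (in input order) with columns ``feature_id, p_hat_A,
    p_hat_B, p_hat_O, q_hat, rr, log2_rr, or_, p_value, p_adjusted,
    status``.  Per-feature failures are reported through ``status``; they
    never abort the run.
    """
    names = dataset.condition_names
    if config.control is not None:
        if config.control not in names:
            raise ValueError(f"control condition {config.control!r} not in {names}")
        cond_b = config.control
        cond_a = names[0] if names[1] == cond_b else names[1]
    else:
        cond_a, cond_b = names

    factors = estimate_size_factors(dataset, config.size_factor_method)
    estimates = compute_estimates(dataset, factors, config.mode)
    model = fit_variance_model(estimates, config.mode, config.span, config.grid_size)

    mu, var, obs_raw = _all_group_params(dataset, factors, estimates, model)
    # _all_group_params labels groups by dataset order; remap to treated/control
    if (cond_a, cond_b) != names:
        swap = {"A": "B", "B": "A"}
        mu = {(st, swap[g]): v for (st, g), v in mu.items()}
        var = {(st, swap[g]): v for (st, g), v in var.items()}
        obs = {"t_a": obs_raw["t_b"], "t_b": obs_raw["t_a"],
               "c_a": obs_raw["c_b"], "c_b": obs_raw["c_a"]}
    else:
        obs = obs_raw

    t_i = obs["t_a"] + obs["t_b"]
    n_a = obs["t_a"] + obs["c_a"]
    n_b = obs["t_b"] + obs["c_b"]
    p_o = estimates.p_hat[POOLED]
    q = estimates.q_hat

    skipped_zero = (t_i == 0) | ((n_a == 0) & (n_b == 0)) | ~(q > 0) | ~np.isfinite(p_o)
    testable = ~skipped_zero

    pvals = np.full(dataset.n_features, np.nan)
    degenerate = np.zeros(dataset.n_features, dtype=bool)
    if np.any(testable):
        sub = {k: v[testable] for k, v in obs.items()}
        mu_sub = {k: v[testable] for k, v in mu.items()}
        var_sub = {k: v[testable] for k, v in var.items()}
        p_sub, deg_sub = _batch_pvalues(mu_sub, var_sub, sub)
        pvals[testable] = p_sub
        degenerate[testable] = deg_sub

    status = np.where(
        skipped_zero, STATUS_SKIPPED_ZERO,
        np.where(degenerate, STATUS_SKIPPED_DEGENERATE, STATUS_TESTED),
    )

    p_adj = np.full(dataset.n_features, np.nan)
    tested = status == STATUS_TESTED
    if np.any(tested):
        p_adj[tested] = multipletests(pvals[tested], method=config.adjust_method)[1]
    # degenerate features carry p=1 by convention but are excluded from BH
    pvals[degenerate] = 1.0

    pa = estimates.p_hat[cond_a]
    pb = estimates.p_hat[cond_b]
    with np.errstate(invalid="ignore", divide="ignore"):
        rr = np.where(pb > 0, pa / np.where(pb > 0, pb, 1.0), np.nan)
        log2_rr = np.where(rr > 0, np.log2(np.where(rr > 0, rr, 1.0)), np.nan)
    or_ = odds_ratio(dataset, factors)
    if (cond_a, cond_b) != names:
        with np.errstate(invalid="ignore", divide="ignore"):
            or_ = 1.0 / or_

    result = pd.DataFrame({
        "feature_id": list(dataset.feature_ids),
        "p_hat_A": pa,
        "p_hat_B": pb,
        "p_hat_O": p_o,
        "q_hat": q,
        "rr": rr,
        "log2_rr": log2_rr,
        "or_": or_,
        "p_value": pvals,
        "p_adjusted": p_adj,
        "status": status,
    })
    if config.drop_zero_features:
        result = result[result["status"] != STATUS_SKIPPED_ZERO].reset_index(drop=True)
    return result
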