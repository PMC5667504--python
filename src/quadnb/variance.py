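"""Smoothing of common-scale variances over the (methylation rate, abundance) plane.

With two or three replicates per condition the per-feature variance
estimate ``w_hat`` is far too noisy to use directly.  Following the
DESeq-style treatment, the raw variance is assumed to be a smooth function
of the methylation rate ``p`` and the abundance ``q``: the per-feature
scatter ``(p_hat_i, q_hat_i) -> w_hat_i`` is smoothed by a local
gamma-family regression (log link, tricube weights, nearest-neighbour
bandwidth), and the raw variance at any point is the smoothed ``w`` minus
the shot-noise bias term ``z`` recomputed there, clamped at zero.

Covariates are ``(p, log q)`` — abundance spans orders of magnitude and the
log stabilizes the smoother.  Fits are evaluated on a rectangular grid and
predictions bilinearly interpolated; query points outside the fitted range
are clamped to the boundary rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .estimation import BLIND, FeatureEstimates, resolve_variance_groups

__all__ = ["LocalGammaSurface", "VarianceModel", "fit_variance_model", "raw_variance"]

_W_FLOOR = 1e-8     # gamma response must be positive; zero-spread features get this
_MIN_FEATURES = 30  # below this a local fit is meaningless


def _gamma_local_fit(X: np.ndarray, y: np.ndarray, weights: np.ndarray) -> float:
    """Weighted gamma GLM with log link, local-linear design, at the origin.

    For the gamma family with log link the IRLS working weights are the
    prior weights themselves, so each iteration is a plain weighted least
    squares on the working response ``eta + (y - mu)/mu``.  Returns the
    fitted log-mean at the (centred) evaluation point, i.e. the intercept.
    """
    keep = weights > 0
    Xk, yk, wk = X[keep], y[keep], weights[keep]
    logy = np.log(yk)
    wbar = float(np.average(logy, weights=wk))
    if Xk.shape[0] <= Xk.shape[1]:
        return wbar
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(float(np.average(yk, weights=wk)))
    sw = np.sqrt(wk)
    Xw = Xk * sw[:, None]
    for _ in range(25):
        eta = np.clip(Xk @ beta, -40.0, 40.0)
        mu = np.exp(eta)
        z = eta + (yk - mu) / mu
        try:
            beta_new, *_ = np.linalg.lstsq(Xw, z * sw, rcond=None)
        except np.linalg.LinAlgError:
            return wbar
        if not np.all(np.isfinite(beta_new)):
            return wbar
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < 1e-8:
            break
    b0 = float(beta[0])
    if not np.isfinite(b0):
        return wbar
    return float(np.clip(b0, -46.0, 46.0))


def _axis_grid(lo: float, hi: float, size: int) -> np.ndarray:
    if hi - lo < 1e-12:
        return np.array([lo])
    return np.linspace(lo, hi, size)


@dataclass(frozen=True)
class LocalGammaSurface:
    """A fitted positive surface ``w(p, q)``, queried by bilinear interpolation."""

    p_grid: np.ndarray          # grid coordinates along the rate axis
    u_grid: np.ndarray          # grid coordinates along log-abundance
    log_w: np.ndarray           # fitted log-w, shape (len(p_grid), len(u_grid))
    n_points: int               # scatter size used for the fit
    span: float                 # nearest-neighbour fraction

    def predict(self, p, q) -> np.ndarray:
        """Evaluate the surface; covariates are clamped to the fitted range."""
        p = np.atleast_1d(np.asarray(p, dtype=float))
        q = np.atleast_1d(np.asarray(q, dtype=float))
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.log(np.maximum(q, 1e-300))
        out = np.exp(self._interp(np.clip(p, self.p_grid[0], self.p_grid[-1]),
                                  np.clip(u, self.u_grid[0], self.u_grid[-1])))
        out[~(np.isfinite(p) & np.isfinite(q))] = np.nan
        return out

    def _interp(self, p: np.ndarray, u: np.ndarray) -> np.ndarray:
        def locate(grid, x):
            if grid.size == 1:
                return np.zeros(x.size, dtype=int), np.zeros(x.size)
            i = np.clip(np.searchsorted(grid, x) - 1, 0, grid.size - 2)
            frac = (x - grid[i]) / (grid[i + 1] - grid[i])
            return i, np.clip(frac, 0.0, 1.0)

        ip_, fp = locate(self.p_grid, p)
        iu_, fu = locate(self.u_grid, u)
        g = self.log_w
        if self.p_grid.size == 1 and self.u_grid.size == 1:
            return np.full(p.size, g[0, 0])
        if self.p_grid.size == 1:
            return g[0, iu_] * (1 - fu) + g[0, iu_ + 1] * fu
        if self.u_grid.size == 1:
            return g[ip_, 0] * (1 - fp) + g[ip_ + 1, 0] * fp
        return (g[ip_, iu_] * (1 - fp) * (1 - fu)
                + g[ip_ + 1, iu_] * fp * (1 - fu)
                + g[ip_, iu_ + 1] * (1 - fp) * fu
                + g[ip_ + 1, iu_ + 1] * fp * fu)


def _fit_surface(
    p: np.ndarray, q: np.ndarray, w: np.ndarray,
    span: float, grid_size: int,
) -> LocalGammaSurface:
    ok = np.isfinite(p) & np.isfinite(q) & np.isfinite(w) & (q > 0)
    p, q, w = p[ok], q[ok], w[ok]
    if p.size < _MIN_FEATURES:
        raise ValueError(
            f"insufficient features for variance smoothing: {p.size} usable, "
            f"need at least {_MIN_FEATURES}"
        )
    y = np.maximum(w, _W_FLOOR)
    u = np.log(q)
    # standardize covariates so the euclidean neighbourhood is meaningful
    sp = max(float(np.std(p)), 1e-8)
    su = max(float(np.std(u)), 1e-8)
    xs = np.column_stack([p / sp, u / su])

    p_grid = _axis_grid(float(p.min()), float(p.max()), grid_size)
    u_grid = _axis_grid(float(u.min()), float(u.max()), grid_size)
    k = max(int(np.ceil(span * p.size)), min(p.size, 10))
    log_w = np.empty((p_grid.size, u_grid.size))
    for a, gp in enumerate(p_grid):
        # vectorized over the abundance axis: distances to every scatter point
        d_p = (xs[:, 0] - gp / sp) ** 2
        for b, gu in enumerate(u_grid):
            d = d_p + (xs[:, 1] - gu / su) ** 2
            if k < p.size:
                idx = np.argpartition(d, k - 1)[:k]
            else:
                idx = np.arange(p.size)
            h2 = max(float(d[idx].max()), 1e-16)
            tri = (1.0 - np.minimum(d[idx] / h2, 1.0) ** 1.5) ** 3
            X = np.column_stack([
                np.ones(idx.size),
                xs[idx, 0] - gp / sp,
                xs[idx, 1] - gu / su,
            ])
            log_w[a, b] = _gamma_local_fit(X, y[idx], tri)
    return LocalGammaSurface(p_grid=p_grid, u_grid=u_grid, log_w=log_w,
                             n_points=int(p.size), span=span)


@dataclass
class VarianceModel:
    """Fitted raw-variance surfaces per sample type and fitting group.

    ``surfaces`` is keyed by ``(sample_type, key)`` where ``key`` is a
    condition label (modes per-condition / auto), the literal ``"pooled"``,
    or the literal ``"blind"``.  ``z_group_of`` maps each condition to the
    replicate group whose bias term is subtracted when converting a smoothed
    ``w`` into a raw variance.
    """

    mode: str
    resolved_mode: str
    surfaces: Dict[Tuple[str, str], LocalGammaSurface]
    z_group_of: Dict[str, str]
    diagnostics: Dict[str, object] = field(default_factory=dict)

    def surface_for(self, sample_type: str, condition: str) -> LocalGammaSurface:
        if self.resolved_mode == "per-condition":
            return self.surfaces[(sample_type, condition)]
        if self.resolved_mode == "pooled":
            return self.surfaces[(sample_type, "pooled")]
        return self.surfaces[(sample_type, BLIND)]


def fit_variance_model(
    estimates: FeatureEstimates,
    mode: str = "auto",
    span: float = 0.7,
    grid_size: int = 21,
) -> VarianceModel:
    """Fit the smooth variance surfaces for one dataset.

    Modes: ``per-condition`` fits one surface per sample type and condition;
    ``pooled`` fits a single surface per sample type from the union of all
    replicated conditions' scatters; ``blind`` ignores condition labels and
    treats all samples of a type as replicates of one condition; ``auto``
    resolves to per-condition when every condition has >=2 replicates,
    otherwise to blind.
    """
    dataset = estimates.dataset
    groups = resolve_variance_groups(dataset, mode)
    if set(groups) != set(estimates.variance_groups):
        raise ValueError(
            f"estimates were computed for variance groups {estimates.variance_groups}, "
            f"mode {mode!r} needs {groups}"
        )
    resolved = mode
    if mode == "auto":
        resolved = "blind" if groups == (BLIND,) else "per-condition"
    surfaces: Dict[Tuple[str, str], LocalGammaSurface] = {}
    sizes: Dict[str, int] = {}
    for stype in ("ip", "input"):
        if resolved == "pooled":
            ps = np.concatenate([estimates.group_rate[g] for g in groups])
            qs = np.concatenate([estimates.q_hat for _ in groups])
            ws = np.concatenate([estimates.w[(stype, g)] for g in groups])
            surfaces[(stype, "pooled")] = _fit_surface(ps, qs, ws, span, grid_size)
            sizes[f"{stype}/pooled"] = surfaces[(stype, "pooled")].n_points
        else:
            for g in groups:
                surfaces[(stype, g)] = _fit_surface(
                    estimates.group_rate[g], estimates.q_hat,
                    estimates.w[(stype, g)], span, grid_size,
                )
                sizes[f"{stype}/{g}"] = surfaces[(stype, g)].n_points
    names = dataset.condition_names
    if resolved == "blind":
        z_group_of = {c: BLIND for c in names}
    else:
        z_group_of = {c: c for c in names}
    return VarianceModel(
        mode=mode, resolved_mode=resolved, surfaces=surfaces,
        z_group_of=z_group_of,
        diagnostics={"span": span, "grid_size": grid_size, "group_sizes": sizes,
                     "family": "gamma-log-link local linear"},
    )


def raw_variance(
    model: VarianceModel,
    estimates: FeatureEstimates,
    condition: str,
    sample_type: str,
    at_rate,
) -> np.ndarray:
    """Raw-variance estimate ``max(0, w_surface(at_rate, q) - z)`` per feature.

    ``at_rate`` is the methylation rate at which the surface and the bias
    term are evaluated: the per-condition rate for descriptive use, or the
    pooled null rate when parameterizing the null distributions of the test.
    """
    at_rate = np.asarray(at_rate, dtype=float)
    if at_rate.ndim == 0:
        at_rate = np.full(estimates.n_features, float(at_rate))
    surface = model.surface_for(sample_type, condition)
    w_pred = surface.predict(at_rate, estimates.q_hat)
    zg = model.z_group_of[condition]
    # the bias correction matches the scatter the surface was fitted on:
    # pooled surfaces still subtract the target condition's own z
    z_group = condition if (model.resolved_mode == "pooled" and zg != BLIND) else zg
    z = estimates.bias_term(at_rate, z_group, sample_type)
    with np.errstate(invalid="ignore"):
        return np.maximum(w_pred - z, 0.0)
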