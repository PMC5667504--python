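"""Library size factors for IP and input samples.

Size factors compensate for sequencing depth.  Because immunoprecipitated
libraries and input controls have intrinsically different read-count
distributions, factors are always computed separately within each sample
type — IP factors from the IP matrix only, input factors from the input
matrix only — and are relative quantities of order one, not absolute depths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import MeripDataset

__all__ = ["NormalizationFactors", "estimate_size_factors"]

# geometric factors get unreliable when the all-positive reference set is thin
_MIN_REFERENCE_FEATURES = 50


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-replicate positive size factors: ``s_ip[j]`` and ``s_input[j]``."""

    s_ip: np.ndarray
    s_input: np.ndarray

    def __post_init__(self):
        for name in ("s_ip", "s_input"):
            s = np.asarray(getattr(self, name), dtype=float)
            if s.ndim != 1:
                raise ValueError(f"{name} must be 1-D")
            if not np.all(np.isfinite(s)) or np.any(s <= 0):
                raise ValueError(f"{name} must be strictly positive and finite")
            object.__setattr__(self, name, s)
        if self.s_ip.shape != self.s_input.shape:
            raise ValueError("s_ip and s_input must have the same length")

    @property
    def n_replicates(self) -> int:
        return self.s_ip.size


def _geometric_factors(counts: np.ndarray, sample_type: str) -> np.ndarray:
    """DESeq median-of-ratios within one sample type.

    The reference profile is the per-feature geometric mean across columns,
    restricted to features positive in every column; each column's factor is
    the median ratio of its counts to the reference.
    """
    positive = np.all(counts > 0, axis=1)
    n_ref = int(positive.sum())
    if n_ref == 0:
        raise ValueError(
            f"geometric size factors need at least one feature with positive "
            f"counts in every {sample_type} column; none found — "
            f'use method="total" instead'
        )
    if n_ref < _MIN_REFERENCE_FEATURES:
        warnings.warn(
            f"only {n_ref} features are positive in all {sample_type} columns; "
            f'geometric size factors may be unstable, consider method="total"',
            UserWarning,
            stacklevel=3,
        )
    ref = counts[positive].astype(float)
    gm = np.exp(np.mean(np.log(ref), axis=1))
    return np.median(ref / gm[:, None], axis=0)


def _total_factors(counts: np.ndarray) -> np.ndarray:
    colsums = counts.sum(axis=0, dtype=float)
    if np.any(colsums <= 0):
        raise ValueError("total size factors need a positive column sum in every column")
    return colsums / colsums.mean()


def estimate_size_factors(
    dataset: MeripDataset, method: str = "geometric"
) -> NormalizationFactors:
    """Estimate per-replicate size factors, separately for IP and input.

    ``method="geometric"`` uses the DESeq median-of-ratios estimator;
    ``method="total"`` divides each column sum by the mean column sum of its
    sample type.  IP and input factors never share information.
    """
    if method == "geometric":
        s_ip = _geometric_factors(dataset.ip_counts, "IP")
        s_input = _geometric_factors(dataset.input_counts, "input")
    elif method == "total":
        s_ip = _total_factors(dataset.ip_counts)
        s_input = _total_factors(dataset.input_counts)
    else:
        raise ValueError(f'method must be "geometric" or "total", got {method!r}')
    return NormalizationFactors(s_ip=s_ip, s_input=s_input)
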