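"""MCMC convergence diagnostics and chain management.

Implements the classic (non-split, non-rank-normalized) Gelman-Rubin
potential scale reduction factor, matching the era of general-purpose MCMC
engines this package's samplers emulate, with an optional split-chain
variant.  Chains with R-hat below 1.1 are conventionally taken as adequately
mixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["gelman_rubin", "burn_thin", "RhatReport", "rhat_report", "DegenerateChainsWarning"]

RHAT_THRESHOLD = 1.1


class DegenerateChainsWarning(UserWarning):
    """Between-chain or total variance is degenerate; R-hat is not meaningful."""


def gelman_rubin(chains: Sequence[Sequence[float]] | np.ndarray, split: bool = False) -> float:
    """Potential scale reduction factor R-hat for a set of parallel chains.

    With within-chain variance ``W`` (mean of per-chain sample variances) and
    between-chain variance ``B`` (n times the variance of chain means),

        R-hat = sqrt( ((n-1)/n * W + B/n) / W ).

    Parameters
    ----------
    chains
        m >= 2 equal-length draw vectors.
    split
        If True, split each chain in half first (the split-chain variant,
        sensitive to within-chain trends).

    Returns NaN with a :class:`DegenerateChainsWarning` when every draw is
    identical (W = 0), and warns when the between-chain variance is exactly
    zero (identical chains), where the statistic degenerates to
    sqrt((n-1)/n) < 1.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a 2-D array (m chains x n draws)")
    if arr.shape[0] < 2:
        raise ValueError("at least two chains are required")
    if split:
        m, n = arr.shape
        half = n // 2
        arr = np.concatenate([arr[:, :half], arr[:, n - half:]], axis=0)
    m, n = arr.shape
    if n < 2:
        raise ValueError("chains must contain at least two draws")
    W = arr.var(axis=1, ddof=1).mean()
    B_over_n = arr.mean(axis=1).var(ddof=1)  # = B / n
    if W == 0.0:
        warnings.warn("zero within-chain variance everywhere; R-hat undefined", DegenerateChainsWarning)
        return float("nan")
    if B_over_n == 0.0:
        warnings.warn(
            "zero between-chain variance (identical chains); R-hat degenerates to sqrt((n-1)/n)",
            DegenerateChainsWarning,
        )
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def burn_thin(draws: Sequence[float] | np.ndarray, burn: int, thin: int = 1) -> np.ndarray:
    """Drop the first ``burn`` draws, then keep every ``thin``-th of the rest.

    The first retained draw is the first post-burn-in draw.
    """
    if burn < 0:
        raise ValueError("burn must be nonnegative")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    arr = np.asarray(draws)
    if burn >= arr.shape[-1]:
        raise ValueError(f"burn={burn} leaves no draws from a series of length {arr.shape[-1]}")
    return arr[..., burn::thin]


@dataclass
class RhatReport:
    """Per-parameter R-hat values with a pass flag at the 1.1 threshold."""

    rhats: dict[str, float]
    threshold: float = RHAT_THRESHOLD
    failed: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.failed = [k for k, v in self.rhats.items() if not (v < self.threshold)]

    @property
    def passed(self) -> bool:
        return not self.failed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.rhats),
                "rhat": list(self.rhats.values()),
                "pass": [k not in self.failed for k in self.rhats],
            }
        )


def rhat_report(draws: Mapping[str, np.ndarray], threshold: float = RHAT_THRESHOLD) -> RhatReport:
    """Compute R-hat for every parameter in a dict of (chains, draws) arrays."""
    return RhatReport({name: gelman_rubin(arr) for name, arr in draws.items()}, threshold=threshold)
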