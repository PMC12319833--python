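"""Simulation of channel concentration series from a design matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal


def _check_stationary(ar: np.ndarray) -> None:
    """Validate that the AR(p) polynomial 1 - sum phi_k B^k has roots outside
    the unit circle."""
    if len(ar) == 0:
        return
    # highest degree first for np.roots
    poly = np.concatenate([[-c for c in ar[::-1]], [1.0]])
    roots = np.roots(poly)
    if len(roots) and np.min(np.abs(roots)) <= 1.0 + 1e-9:
        raise ValueError(f"AR coefficients {list(ar)} are not stationary")


def ar_noise(
    n_samples: int,
    ar: np.ndarray | list[float],
    noise_sd: float,
    rng: np.random.Generator,
    burn_in: int = 200,
) -> np.ndarray:
    """Gaussian AR(p) noise with innovation SD ``noise_sd``."""
    ar = np.asarray(ar, dtype=float)
    _check_stationary(ar)
    white = rng.normal(0.0, noise_sd, size=n_samples + burn_in)
    if len(ar) == 0:
        return white[burn_in:]
    out = signal.lfilter([1.0], np.concatenate([[1.0], -ar]), white)
    return out[burn_in:]


def simulate_channels(
    design: pd.DataFrame | np.ndarray,
    betas: np.ndarray,
    ar: np.ndarray | list[float] = (),
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate ``y = X @ beta + AR(p) noise`` per channel, seeded.

    ``betas`` has shape (n_channels, n_columns) matching the design columns;
    returns an array of shape (n_channels, n_samples).
    """
    X = design.to_numpy() if isinstance(design, pd.DataFrame) else np.asarray(design)
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    if betas.shape[1] != X.shape[1]:
        raise ValueError(
            f"betas have {betas.shape[1]} columns, design has {X.shape[1]}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty((betas.shape[0], X.shape[0]))
    for ch in range(betas.shape[0]):
        noise = ar_noise(X.shape[0], ar, noise_sd, rng) if noise_sd > 0 else 0.0
        out[ch] = X @ betas[ch] + noise
    return out
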