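"""Canonical double-gamma hemodynamic response function."""

from __future__ import annotations

import numpy as np
from scipy import stats


def double_gamma_hrf(
    sampling_rate: float,
    peak_s: float = 4.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    duration_s: float = 32.0,
) -> np.ndarray:
    """Double-gamma HRF kernel sampled at ``sampling_rate``.

    Difference of two gamma densities with modes at ``peak_s`` and
    ``undershoot_s`` (unit scale, so shape = mode + 1) and undershoot
    amplitude ``undershoot_ratio``; normalized to unit peak amplitude.
    """
    if min(sampling_rate, peak_s, undershoot_s, duration_s) <= 0:
        raise ValueError("all HRF parameters must be positive")
    t = np.arange(0.0, duration_s, 1.0 / sampling_rate)
    main = stats.gamma.pdf(t, a=peak_s + 1.0)
    undershoot = stats.gamma.pdf(t, a=undershoot_s + 1.0)
    h = main - undershoot_ratio * undershoot
    return h / h.max()
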