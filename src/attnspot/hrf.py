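"""Canonical double-gamma hemodynamic response function."""
from __future__ import annotations

import numpy as np
from scipy import stats


def double_gamma_hrf(
    tr: float,
    duration_s: float = 32.0,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Sampled double-gamma HRF (response peak at ``peak_s``, undershoot at
    ``undershoot_s``, peak/undershoot amplitude ratio 6), normalized to unit
    peak."""
    t = np.arange(0.0, duration_s, tr)
    # gamma shape k, scale 1 peaks at (k-1); choose k = peak + 1 so the pdf
    # peaks at the requested latency
    peak = stats.gamma.pdf(t, peak_s + 1.0, scale=1.0)
    under = stats.gamma.pdf(t, undershoot_s + 1.0, scale=1.0)
    h = peak - under / ratio
    return h / h.max()
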