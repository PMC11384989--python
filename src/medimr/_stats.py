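"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr
from scipy.stats import t as t_dist

# conventional normal quantile used for the 95% CIs reported alongside ORs
Z95 = 1.96

# floor keeping p-values strictly positive after underflow of the normal tail
_P_FLOOR = 1e-300


def two_sided_normal_p(z):
    """Two-sided p-value 2·(1−Φ(|z|)) with an underflow floor."""
    z = np.asarray(z, dtype=float)
    p = 2.0 * ndtr(-np.abs(z))
    return np.maximum(p, _P_FLOOR)


def two_sided_t_p(z, df):
    """Two-sided p-value from a t reference distribution."""
    z = np.asarray(z, dtype=float)
    p = 2.0 * t_dist.sf(np.abs(z), df)
    return np.maximum(p, _P_FLOOR)
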