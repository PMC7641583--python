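"""Discrete-hopping simplification of the SDC model.

Diffusion is replaced by hopping between adjacent cells at rate h (each
direction).  For a cell with stationary mean m_j on an effectively infinite
chain, the count autocovariance and correlation time are

    C_j(t) = m_j I0(2 h t) e^{-(2h + nu) t},
    tau    = int_0^inf C_j(t) dt / C_j(0) = [nu (4h + nu)]^{-1/2},

with I0 the zeroth modified Bessel function of the first kind.  e^{-2ht} I0(2ht)
is exactly the return probability of an unbiased continuous-time random walk,
so C_j is the independent-molecule survival-and-return covariance.  In the
fast-hopping limit h >> nu, tau -> (4 nu h)^{-1/2}, matching the continuum SDC
correlation time with h = D/(2a)^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0e

__all__ = ["HoppingParams", "autocorrelation_hopping", "correlation_time_hopping"]


@dataclass(frozen=True)
class HoppingParams:
    h: float      # hop rate to each adjacent cell
    nu: float     # degradation rate
    m_j: float    # stationary mean count in the probed cell

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("hop rate must be non-negative")
        if self.nu <= 0 or self.m_j <= 0:
            raise ValueError("nu and m_j must be positive")


def autocorrelation_hopping(params: HoppingParams, t) -> np.ndarray | float:
    """C_j(t) = m_j I0(2ht) e^{-(2h+nu)t}; C_j(0) = m_j (Poisson variance).

    Uses the exponentially scaled Bessel function i0e(x) = e^{-x} I0(x), so
    large 2ht never overflows."""
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be non-negative")
    out = params.m_j * i0e(2.0 * params.h * tt) * np.exp(-params.nu * tt)
    return float(out) if np.isscalar(t) else out


def correlation_time_hopping(h: float, nu: float) -> float:
    """tau = [nu (4h + nu)]^{-1/2}; reduces to 1/nu at h = 0 and to
    (4 nu h)^{-1/2} for h >> nu."""
    if h < 0 or nu <= 0:
        raise ValueError("need h >= 0 and nu > 0")
    return float(1.0 / np.sqrt(nu * (4.0 * h + nu)))
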