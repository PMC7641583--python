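"""Synthesis-diffusion-clearance (SDC) morphogen model.

Molecules are produced at a localized source at rate beta, diffuse with
coefficient D and degrade uniformly at rate nu, giving the exponential steady
state c(x) = beta e^{-|x|/lambda} / (2 nu lambda) with lambda = sqrt(D/nu).
A target cell at x = 2ja counts the molecules in its volume, so its mean is

    m_j = (beta/nu) sinh(1/lambda_hat) e^{-2 j / lambda_hat},

and its time-averaged readout has variance 2 m_j tau / T with correlation time

    tau = (1/nu) [1 - ((2/lh) + sinh(2/lh)) / (4 sinh(1/lh) e^{1/lh})],

which is shorter than the birth-death value 1/nu because molecules also leave
the cell by diffusion (a higher refresh rate, hence more independent
measurements in the window T).  The bracketed factor B satisfies 0 < B < 1,
decreases with lambda_hat, tends to 3/4 as lambda_hat -> 0 and to 1/lambda_hat
as lambda_hat -> infinity.

The 2D/3D extension (line of sources feeding a sheet, sheet feeding a volume)
keeps the same perpendicular mean profile; its correlation time is computed by
the exact independent-molecule route: because the Langevin system is linear
with Poissonian noise, the count autocovariance is C(t) = m e^{-nu t} K(t)
where K(t) is the probability that a diffusing molecule initially inside the
cell (distributed per the steady profile) is inside it again at time t.  K
factorises over dimensions, and tau = int_0^infty C(t)/C(0) dt equals the
zero-frequency power-spectrum prescription sigma^2 = S_m(0)/T = 2 m tau / T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import erf, roots_legendre

from .types import PrecisionResult, Profile

__all__ = [
    "SDCParams",
    "LangevinNoiseSpec",
    "mean_concentration",
    "mean_profile_sdc",
    "bracket_factor",
    "correlation_time_sdc",
    "precision_sdc",
    "correlation_time_sdc_nd",
    "precision_sdc_nd",
    "interval_survival_kernel",
    "profile_weighted_survival_kernel",
]


@dataclass(frozen=True)
class SDCParams:
    """Physical SDC parameters; lambda_hat = sqrt(D/nu)/a is derived.

    ``one_sided`` doubles the mean profile for systems (like Bicoid) whose
    target cells extend on one side of the source only.  The accompanying
    variance correction (a factor slightly greater than 2) is not implemented;
    the flag affects the mean only.
    """

    beta: float
    D: float
    nu: float
    a: float
    dim: int = 1
    one_sided: bool = False

    def __post_init__(self) -> None:
        if min(self.beta, self.D, self.nu, self.a) <= 0:
            raise ValueError("beta, D, nu and a must all be positive")
        if self.dim not in (1, 2, 3):
            raise ValueError("dim must be 1, 2 or 3")

    @property
    def lam(self) -> float:
        """Profile lengthscale lambda = sqrt(D/nu)."""
        return float(np.sqrt(self.D / self.nu))

    @property
    def lambda_hat(self) -> float:
        return self.lam / self.a

    @classmethod
    def from_lambda_hat(cls, beta: float, nu: float, a: float,
                        lambda_hat: float, dim: int = 1,
                        one_sided: bool = False) -> "SDCParams":
        if lambda_hat <= 0:
            raise ValueError("lambda_hat must be positive")
        return cls(beta=beta, D=nu * (lambda_hat * a) ** 2, nu=nu, a=a,
                   dim=dim, one_sided=one_sided)


@dataclass(frozen=True)
class LangevinNoiseSpec:
    """The three white-noise correlators of the SDC Langevin equation.

    diffusion:   <eta_D eta_D'> = 2 D grad.grad' c(x) delta(x-x') delta(t-t')
    degradation: <eta_nu eta_nu'> = nu c(x) delta(x-x') delta(t-t')
    production:  <eta_b eta_b'>  = beta delta(t-t')  (at the source)

    Cross-correlations vanish.  The record exists to document what the spectral
    / propagator computation integrates; the three local strengths at position
    x are returned by :meth:`strengths`.
    """

    params: SDCParams

    def strengths(self, x: float) -> dict[str, float]:
        c = mean_concentration(self.params, x)
        return {
            "diffusion": 2.0 * self.params.D * c,
            "degradation": self.params.nu * c,
            "production": self.params.beta,
        }


def mean_concentration(params: SDCParams, x: float) -> float:
    """Steady-state concentration c(x) = beta e^{-|x|/lambda} / (2 nu lambda).

    Integrates to beta/nu over the whole line.  ``one_sided`` doubles it."""
    lam = params.lam
    c = params.beta * np.exp(-abs(x) / lam) / (2.0 * params.nu * lam)
    return float(2.0 * c if params.one_sided else c)


def _log_sinh(u: float) -> float:
    """log(sinh u) without overflow for large u."""
    return u + np.log1p(-np.exp(-2.0 * u)) - np.log(2.0)


def mean_profile_sdc(params: SDCParams, N: int) -> Profile:
    """Cell means m_j = (beta/nu) sinh(1/lh) e^{-2j/lh} for j = 1..N.

    Exact integral of c(x) over cell j's extent [2ja - a, 2ja + a]; consecutive
    ratios are exactly e^{-2/lambda_hat}.  Evaluated in the log domain so very
    short profiles (lambda_hat << 1) do not overflow sinh."""
    if N < 2:
        raise ValueError("need at least two target cells per side")
    lh = params.lambda_hat
    j = np.arange(1, N + 1, dtype=float)
    logm = np.log(params.beta / params.nu) + _log_sinh(1.0 / lh) - 2.0 * j / lh
    m = np.exp(logm)
    if params.one_sided:
        m = 2.0 * m
    return Profile(values=m, side_count=N)


def bracket_factor(lambda_hat: float) -> float:
    """The dimensionless factor B(lambda_hat) in tau_SDC = B / nu.

    B = 1 - [(2/lh) + sinh(2/lh)] / [4 sinh(1/lh) e^{1/lh}], evaluated through
    e^{-2u} (u = 1/lh) so neither limit overflows.  0 < B < 1, strictly
    decreasing; B -> 3/4 as lh -> 0 and lh*B -> 1 as lh -> infinity."""
    if lambda_hat <= 0:
        raise ValueError("lambda_hat must be positive")
    u = 1.0 / lambda_hat
    e2 = np.exp(-2.0 * u)
    # [(2u) + sinh(2u)] / [2 (e^{2u} - 1)], multiplied through by e^{-2u}
    num = 2.0 * u * e2 + 0.5 * (1.0 - e2 * e2)
    den = 2.0 * (1.0 - e2)
    return float(1.0 - num / den)


def correlation_time_sdc(lambda_hat: float, nu: float) -> float:
    """Correlation time tau_SDC = B(lambda_hat) / nu of a cell's molecule count."""
    if nu <= 0:
        raise ValueError("nu must be positive")
    return bracket_factor(lambda_hat) / nu


def precision_sdc(params: SDCParams, N: int, T: float) -> PrecisionResult:
    """Squared readout precision of the 1D SDC model for cells j = 1..N-1.

    P_j^2 = (m_j T / 2 tau_SDC)(Delta m_j/m_j)^2 with the constant steepness
    Delta m_j/m_j = 1 - e^{-2/lambda_hat}.  Depends on (beta*T, lambda_hat, j)
    only; nu cancels between the mean and the refresh rate."""
    if T <= 0:
        raise ValueError("T must be positive")
    if T * params.nu < 10:
        warnings.warn("T*nu < 10: the time-averaging variance formula assumes "
                      "T >> tau", stacklevel=2)
    prof = mean_profile_sdc(params, N)
    tau = correlation_time_sdc(params.lambda_hat, params.nu)
    m = prof.values
    dm = prof.delta
    p2 = (m[:-1] * T / (2.0 * tau)) * (dm / m[:-1]) ** 2
    return PrecisionResult(p_squared=p2, tau=tau, delta_m=dm)


# ---------------------------------------------------------------------------
# survival kernels for the propagator (zero-frequency spectrum) route
# ---------------------------------------------------------------------------

def interval_survival_kernel(t: float, half_width: float, D: float) -> float:
    """Probability a molecule uniformly distributed on [-w, w] is inside the
    interval again after free diffusion for time t (w = half_width).

    (1/2w) int int G(x - x', t) dx dx' = erf(u) - (1 - e^{-u^2})/(u sqrt(pi)),
    u = 2w / sqrt(4Dt).  Tends to 1 as w -> infinity (no transverse escape)."""
    if t <= 0:
        return 1.0
    u = 2.0 * half_width / np.sqrt(4.0 * D * t)
    return float(erf(u) - (1.0 - np.exp(-u * u)) / (u * np.sqrt(np.pi)))


_GL_NODES, _GL_WEIGHTS = roots_legendre(48)


def profile_weighted_survival_kernel(t: float, a: float, lam: float,
                                     D: float) -> float:
    """Probability a molecule drawn from the steady exponential profile inside
    a cell [-a, a] (local weight e^{-x/lam}) is inside the cell after time t."""
    if t <= 0:
        return 1.0
    s = np.sqrt(4.0 * D * t)
    x = a * _GL_NODES
    w = a * _GL_WEIGHTS
    inner = 0.5 * (erf((a - x) / s) + erf((a + x) / s))
    num = np.sum(w * np.exp(-x / lam) * inner)
    den = lam * (np.exp(a / lam) - np.exp(-a / lam))
    return float(num / den)


def correlation_time_sdc_nd(lambda_hat: float, nu: float, dim: int,
                            transverse_half_width: float | None = None,
                            a: float = 1.0) -> float:
    """Correlation time of a cubic cell's count in a dim-dimensional SDC system.

    The source is a (dim-1)-dimensional sheet at x = 0; the cell is a cube of
    side 2a at perpendicular position 2ja (j-independent by translation of the
    local exponential weight).  tau = int_0^inf e^{-nu t} K_perp(t)
    K_tr(t)^{dim-1} dt, where K_perp weights by the steady profile and K_tr is
    the uniform-interval kernel of half-width ``transverse_half_width``
    (default a).  As the transverse half-width grows, K_tr -> 1 and the 1D
    closed form is recovered; dim = 1 returns it directly."""
    if dim == 1:
        return correlation_time_sdc(lambda_hat, nu)
    if dim not in (2, 3):
        raise ValueError("dim must be 1, 2 or 3")
    w_tr = a if transverse_half_width is None else transverse_half_width
    lam = lambda_hat * a
    D = nu * lam * lam

    def integrand(t: float) -> float:
        k = profile_weighted_survival_kernel(t, a, lam, D)
        ktr = interval_survival_kernel(t, w_tr, D)
        return np.exp(-nu * t) * k * ktr ** (dim - 1)

    # log-time substitution: at large D the kernels decay on timescales many
    # orders below 1/nu and a linear-time quadrature misses the spike
    t_min = min(1e-9 / nu, 1e-3 * (2.0 * a) ** 2 / D)
    upper = 60.0 / nu
    val, err = quad(lambda s: integrand(np.exp(s)) * np.exp(s),
                    np.log(t_min), np.log(upper), limit=400, epsrel=1e-9,
                    epsabs=1e-14)
    val += t_min * integrand(0.5 * t_min)   # kernels ~ 1 below t_min
    if not np.isfinite(val) or (val > 0 and err > 1e-4 * val):
        raise RuntimeError(f"correlation-time quadrature did not converge: "
                           f"value={val}, abserr={err}")
    return float(val)


def precision_sdc_nd(params: SDCParams, N: int, T: float,
                     transverse_half_width: float | None = None
                     ) -> PrecisionResult:
    """Squared readout precision in 2D/3D geometry.

    The mean profile in the perpendicular coordinate is identical to the 1D
    case (each source cell of the sheet supplies beta to its own column); only
    the correlation time changes, because molecules also refresh by transverse
    diffusion.  Reduces to :func:`precision_sdc` when dim = 1 or when the
    transverse cell extent is made large."""
    if T <= 0:
        raise ValueError("T must be positive")
    prof = mean_profile_sdc(params, N)
    tau = correlation_time_sdc_nd(params.lambda_hat, params.nu, params.dim,
                                  transverse_half_width, a=params.a)
    m = prof.values
    dm = prof.delta
    p2 = (m[:-1] * T / (2.0 * tau)) * (dm / m[:-1]) ** 2
    return PrecisionResult(p_squared=p2, tau=tau, delta_m=dm)
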