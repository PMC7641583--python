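"""Direct-transport (cytoneme) morphogen model: steady state and readout precision.

A single source cell feeds 2N target cells through cytonemes of length 2ja.
Inside a cytoneme molecules run forward (velocity v+) or backward (v-) and switch
direction at rates zeta+/zeta-.  Only two dimensionless combinations of these
microscopic parameters survive in the steady state: the shape parameter
phi = log(d-/d+) and kappa = 1/d+ - 1/d- (with d+- = v+-/zeta+- the mean run
lengths), entering through the per-cytoneme transport factor

    Gamma_j = e^{-2 j kappa a} (1 - e^{-phi}) / (1 - e^{-phi - 2 j kappa a}).

The mean count in cell j is m_j = beta Gamma_j / (2 nu sum_k Gamma_k), and the
time-averaged readout has birth-death statistics (variance 2 m_j / (T / tau),
tau = 1/nu) regardless of the transport delay distribution, so the squared
precision is P_j^2 = (m_j T / 2 tau) (Delta m_j / m_j)^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .types import PrecisionResult, Profile

__all__ = [
    "PHI_POWERLAW_THRESHOLD",
    "DTShape",
    "DTRates",
    "gamma_profile",
    "lengthscale_dt",
    "lengthscale_dt_discrete",
    "lengthscale_dt_quadrature",
    "solve_kappa",
    "solve_dplus_powerlaw",
    "mean_profile_dt",
    "precision_dt",
    "optimize_phi",
]

#: below this |phi| the closed forms degenerate and the power-law branch is used
PHI_POWERLAW_THRESHOLD = 1e-3

#: default search window and grid for the phi optimisation
PHI_WINDOW = (1e-3, 30.0)
PHI_GRID_POINTS = 400


def _neg_log1mexp(p: float) -> float:
    """-log(1 - e^{-p}) for p > 0, stable for both tiny and huge p."""
    if p > 36.0:  # e^{-p} below double resolution of log1p
        return np.exp(-p)
    return -np.log(-np.expm1(-p))


def solve_kappa(phi: float, lambda_hat: float) -> float:
    """Invert the profile-lengthscale relation for kappa*a.

    kappa a = sign(phi) (e^{|phi|} - 1)(|phi| - log(e^{|phi|} - 1)) / lambda_hat.
    Returns 0 for phi = 0, in which case the profile must be parametrised through
    the power-law branch (see :func:`solve_dplus_powerlaw`).
    """
    if lambda_hat <= 0:
        raise ValueError("lambda_hat must be positive")
    if phi == 0.0:
        return 0.0
    p = abs(phi)
    if p > 36.0:
        # (e^p - 1) * e^{-p} -> 1 - e^{-p}; avoids expm1 overflow
        return float(np.sign(phi) * -np.expm1(-p) / lambda_hat)
    # |phi| - log(e^|phi| - 1) == -log(1 - e^{-|phi|}), cancellation-free
    return float(np.sign(phi) * np.expm1(p) * _neg_log1mexp(p) / lambda_hat)


def lengthscale_dt(phi: float, kappa_a: float) -> float:
    """Closed-form profile lengthscale lambda_hat = lambda/a of the DT model.

    lambda_hat = (e^{|phi|} - 1)(|phi| - log(e^{|phi|} - 1)) / |kappa a|, the
    product form obtained by integrating Gamma(j) over continuous j.  It equals
    2 * int_0^N Gamma dj / (Gamma(0) - Gamma(N)) for N >> 1 to machine precision
    (see :func:`lengthscale_dt_quadrature`).
    """
    if phi == 0.0 and kappa_a == 0.0:
        raise ValueError("phi = 0 profile has no exponential lengthscale; "
                         "use the power-law parametrisation")
    if kappa_a == 0.0:
        raise ValueError("kappa_a = 0 with phi != 0 is inconsistent")
    if np.sign(kappa_a) != np.sign(phi):
        raise ValueError("sign(kappa_a) must equal sign(phi)")
    p = abs(phi)
    if p > 36.0:
        return float(-np.expm1(-p) / abs(kappa_a))
    return float(np.expm1(p) * _neg_log1mexp(p) / abs(kappa_a))


def _log_gamma(phi: float, kappa_a: float, j: np.ndarray) -> np.ndarray:
    """log Gamma_j, evaluated in the log domain so large |phi| or large
    j*kappa_a never overflow.  Uses Gamma_j = (1 - e^{-phi})/(e^{2j kappa a} - e^{-phi})."""
    j = np.asarray(j, dtype=float)
    t = phi + 2.0 * j * kappa_a
    if phi > 0:
        return np.log1p(-np.exp(-phi)) - 2.0 * j * kappa_a - np.log1p(-np.exp(-t))
    # phi < 0 (then kappa_a < 0 and t < 0): numerator and denominator of the
    # defining ratio are both negative; this is their stable positive form.
    return np.log1p(-np.exp(phi)) - np.log1p(-np.exp(t))


@dataclass(frozen=True)
class DTShape:
    """Dimensionless description of a DT profile.

    Built from (phi, lambda_hat, N); kappa_a is derived by inverting the
    closed-form lengthscale.  For |phi| below ``PHI_POWERLAW_THRESHOLD`` the
    exponential parametrisation degenerates and the profile is represented as
    the power law Gamma_j = (1 + 2 j a/d+)^{-1} with d+/a solved from the
    requested lengthscale at the given N.
    """

    phi: float
    lambda_hat: float
    N: int
    kappa_a: float
    d_plus_over_a: Optional[float] = None

    @classmethod
    def from_lengthscale(cls, phi: float, lambda_hat: float, N: int) -> "DTShape":
        if lambda_hat <= 0:
            raise ValueError("lambda_hat must be positive")
        if N < 2:
            raise ValueError("need at least two target cells per side")
        if abs(phi) < PHI_POWERLAW_THRESHOLD:
            dplus = solve_dplus_powerlaw(lambda_hat, N)
            return cls(phi=phi, lambda_hat=lambda_hat, N=N, kappa_a=0.0,
                       d_plus_over_a=dplus)
        return cls(phi=phi, lambda_hat=lambda_hat, N=N,
                   kappa_a=solve_kappa(phi, lambda_hat))

    @property
    def powerlaw(self) -> bool:
        return self.d_plus_over_a is not None

    def __post_init__(self) -> None:
        if self.lambda_hat <= 0 or self.N < 2:
            raise ValueError("invalid DTShape")
        if not self.powerlaw:
            if np.sign(self.kappa_a) != np.sign(self.phi):
                raise ValueError("sign(kappa_a) must equal sign(phi)")


@dataclass(frozen=True)
class DTRates:
    """Production rate beta, degradation rate nu and integration time T."""

    beta: float
    nu: float
    T: float

    def __post_init__(self) -> None:
        if min(self.beta, self.nu, self.T) <= 0:
            raise ValueError("beta, nu and T must all be positive")
        if self.T * self.nu < 10:
            warnings.warn("T*nu < 10: the time-averaging variance formula "
                          "assumes T >> 1/nu", stacklevel=3)


def solve_dplus_powerlaw(lambda_hat: float, N: int, tol: float = 1e-8) -> float:
    """Solve d+/a so the power-law profile Gamma_j = (1 + 2j a/d+)^{-1} has the
    requested lengthscale under the quadrature definition
    2 int_0^N Gamma dj / (Gamma(0) - Gamma(N)) = lambda_hat (bisection to tol)."""

    def lam_of(delta: float) -> float:
        gN = 1.0 / (1.0 + 2.0 * N / delta)
        integral = 0.5 * delta * np.log1p(2.0 * N / delta)
        return 2.0 * integral / (1.0 - gN)

    lo, hi = 1e-12, 1.0
    while lam_of(hi) < lambda_hat:
        hi *= 2.0
        if hi > 1e14:
            raise ValueError("cannot bracket d+/a for requested lengthscale")
    return float(brentq(lambda d: lam_of(d) - lambda_hat, lo, hi,
                        xtol=tol, rtol=tol))


def gamma_profile(shape: DTShape, j) -> np.ndarray | float:
    """Transport factor Gamma_j in (0, 1], non-increasing in j.

    Scalar j gives a scalar; an array of j gives an array.  j = 0 formally
    returns 1 for any parameters (numerator equals denominator in Eq form).
    """
    scalar = np.isscalar(j)
    jj = np.atleast_1d(np.asarray(j, dtype=float))
    if np.any(jj < 0) or np.any(jj > shape.N):
        raise ValueError("cell index out of range 0..N")
    if shape.powerlaw:
        out = 1.0 / (1.0 + 2.0 * jj / shape.d_plus_over_a)
    else:
        out = np.exp(_log_gamma(shape.phi, shape.kappa_a, jj))
        out[jj == 0] = 1.0
    return float(out[0]) if scalar else out


def lengthscale_dt_discrete(shape: DTShape) -> float:
    """Literal integer-sum lengthscale 2 (sum_{j=1..N} Gamma_j - Gamma_N) / (Gamma_1 - Gamma_N).

    This is the sum-based definition before the continuum approximation.  It is
    biased upward relative to the closed form by O(1/lambda_hat) because the sum
    over integer j misses the steep decay inside the first cell; the two agree
    as lambda_hat grows.  Exposed for validation, not used internally.
    """
    G = gamma_profile(shape, np.arange(1, shape.N + 1))
    return float(2.0 * (G.sum() - G[-1]) / (G[0] - G[-1]))


def lengthscale_dt_quadrature(shape: DTShape, lower: float = 0.0) -> float:
    """Quadrature lengthscale 2 int_lower^N Gamma(j) dj / (Gamma(lower) - Gamma(N)).

    With lower = 0 this reproduces the closed form of :func:`lengthscale_dt`
    essentially exactly; it is the independent oracle for the Eq-form product.
    """
    g = lambda x: float(gamma_profile(shape, x))
    integral, _ = quad(g, lower, shape.N, limit=400)
    return float(2.0 * integral / (g(lower) - g(shape.N)))


def mean_profile_dt(shape: DTShape, rates: DTRates) -> Profile:
    """Steady-state means m_j = beta Gamma_j / (2 nu sum_k Gamma_k).

    Summing over all 2N target cells gives exactly beta/nu (production balances
    degradation)."""
    G = gamma_profile(shape, np.arange(1, shape.N + 1))
    m = rates.beta * G / (2.0 * rates.nu * G.sum())
    return Profile(values=m, side_count=shape.N)


def precision_dt(shape: DTShape, rates: DTRates) -> PrecisionResult:
    """Squared readout precision of the DT model for cells j = 1..N-1.

    P_j^2 = (m_j T / 2 tau) (Delta m_j / m_j)^2 with tau = 1/nu.  At fixed
    beta*T, lambda_hat, phi and N the result is independent of nu: the mean
    scales as 1/nu while the number of independent measurements T/tau scales
    as nu.
    """
    prof = mean_profile_dt(shape, rates)
    tau = 1.0 / rates.nu
    m = prof.values
    dm = prof.delta
    with np.errstate(divide="ignore", invalid="ignore"):
        p2 = np.where(m[:-1] > 0,
                      (m[:-1] * rates.T / (2.0 * tau)) * (dm / m[:-1]) ** 2,
                      0.0)
    if np.any(m[:-1] == 0):
        warnings.warn("zero mean count encountered; P^2 defined as 0 there",
                      stacklevel=2)
    return PrecisionResult(p_squared=p2, tau=tau, delta_m=dm)


def _p2_at(phi: float, lambda_hat: float, N: int, j: int) -> float:
    """P_j^2 at beta = T = nu = 1 for a single cell (helper for optimisation)."""
    shape = DTShape.from_lengthscale(phi, lambda_hat, N)
    G = gamma_profile(shape, np.arange(1, N + 1))
    m = G / (2.0 * G.sum())
    dm = m[j - 1] - m[j]
    if m[j - 1] == 0:
        return 0.0
    return float((m[j - 1] / 2.0) * (dm / m[j - 1]) ** 2)


def _golden_max(f, lo: float, hi: float, tol: float) -> float:
    """Golden-section maximisation on [lo, hi]; ties break toward smaller x."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:  # >= keeps the left interval on ties
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def optimize_phi(N: int, j: int, lambda_hat: float,
                 window: tuple[float, float] = PHI_WINDOW,
                 n_grid: int = PHI_GRID_POINTS,
                 tol: float = 1e-6) -> tuple[float, float]:
    """Shape parameter phi* > 0 maximising P_j^2 at fixed lengthscale.

    Log-spaced grid scan over ``window`` followed by golden-section refinement
    (tolerance ``tol`` in phi).  For large lengthscales P^2(phi) saturates
    monotonically toward the pure-exponential-profile limit; in that case no
    interior maximum exists and the window-boundary argmax is returned with a
    warning.  Returns (phi_star, p_squared_star) at beta = T = nu = 1.
    """
    if not 1 <= j <= N - 1:
        raise ValueError("need 1 <= j <= N-1")
    grid = np.logspace(np.log10(window[0]), np.log10(window[1]), n_grid)
    vals = np.array([_p2_at(p, lambda_hat, N, j) for p in grid])
    k = int(vals.argmax())
    if k == 0 or k == n_grid - 1:
        warnings.warn("P^2(phi) has no interior maximum in the search window; "
                      "returning the boundary argmax", stacklevel=2)
        return float(grid[k]), float(vals[k])
    f = lambda logp: _p2_at(np.exp(logp), lambda_hat, N, j)
    lo, hi = np.log(grid[k - 1]), np.log(grid[k + 1])
    log_star = _golden_max(f, lo, hi, tol=tol / max(grid[k], tol))
    phi_star = float(np.exp(log_star))
    p2_star = _p2_at(phi_star, lambda_hat, N, j)
    if p2_star < vals[k]:
        phi_star, p2_star = float(grid[k]), float(vals[k])
    return phi_star, float(p2_star)
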