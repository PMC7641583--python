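"""Synthetic-data generators and brute-force oracles.

Every closed form in the package is validated against one of these seeded
simulators:

* :func:`simulate_birth_death` -- exact Gillespie birth-death traces; the
  stationary distribution is Poisson and the window-averaged count has
  variance 2 m tau / T.
* :func:`simulate_generalized_dt` -- independent molecules produced at rate
  beta, delayed by an arbitrary transport law p(tau), degraded at nu inside
  the target.  Demonstrates that the arrival process is Poisson(beta)
  regardless of p(tau), so target-cell statistics are birth-death.
* :func:`integrate_cytoneme_ode` -- deterministic finite-volume integration of
  the cytoneme transport equations to steady state, reproducing the
  closed-form DT profile.
* :func:`simulate_sdc_lattice` / :func:`simulate_sdc_lattice_2d` -- exact
  Gillespie birth-hop-death dynamics on a subcell lattice, the oracle for the
  SDC means, correlation time, and the 2D extension.
* :func:`arrival_vs_concentration_cv` -- compares a time-averaged
  concentration readout against counting arrivals; the squared-CV ratio
  approaches 2 (degradation noise eliminated, arrival noise remains).

All simulators are reproducible bit-for-bit given the configured seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from ._gillespie import lattice_1d, lattice_2d
from .dt_model import DTShape, DTRates
from .types import Profile, SimConfig, TraceStats

__all__ = [
    "SimConfig",
    "TraceStats",
    "CytonemeMicroParams",
    "DeterministicDelay",
    "ExponentialDelay",
    "TelegraphFirstPassageDelay",
    "simulate_birth_death",
    "simulate_generalized_dt",
    "integrate_cytoneme_ode",
    "simulate_sdc_lattice",
    "simulate_sdc_lattice_2d",
    "simulate_hopping_chain",
    "SDCLatticeResult",
    "arrival_vs_concentration_cv",
    "CVRatioResult",
]


def _kernel_seed(seed: int) -> int:
    return int(seed) % (2 ** 31 - 1)


def _stats_from_windows(avg: np.ndarray, occ2_avg: np.ndarray,
                        births: Optional[np.ndarray],
                        samples: Optional[np.ndarray],
                        window: float, sample_interval: float,
                        max_lag: int = 10) -> TraceStats:
    """Assemble TraceStats from per-replicate window integrals and samples."""
    reps = avg.size
    sem = avg.std(ddof=1) / np.sqrt(reps) if reps > 1 else np.nan
    var_r = occ2_avg - avg ** 2          # per-replicate time-weighted variance
    svar = var_r.mean()
    svar_se = var_r.std(ddof=1) / np.sqrt(reps) if reps > 1 else np.nan
    tav = avg.var(ddof=1) if reps > 1 else np.nan
    tav_se = tav * np.sqrt(2.0 / (reps - 1)) if reps > 2 else np.nan
    lags = np.empty(0)
    acov = np.empty(0)
    acov_se = np.empty(0)
    if samples is not None and samples.shape[1] > 2 * max_lag:
        nlag = max_lag + 1
        per_rep = np.empty((reps, nlag))
        for r in range(reps):
            x = samples[r].astype(float)
            xc = x - x.mean()
            nobs = x.size
            for l in range(nlag):
                per_rep[r, l] = np.mean(xc[: nobs - l] * xc[l:]) if l else np.mean(xc * xc)
        lags = np.arange(nlag) * sample_interval
        acov = per_rep.mean(axis=0)
        acov_se = per_rep.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else np.full(nlag, np.nan)
    av = np.nan
    av_se = np.nan
    if births is not None and reps > 1:
        av = births.var(ddof=1)
        av_se = av * np.sqrt(2.0 / (reps - 1)) if reps > 2 else np.nan
    return TraceStats(
        stationary_mean=float(avg.mean()), stationary_mean_se=float(sem),
        stationary_variance=float(svar), stationary_variance_se=float(svar_se),
        time_avg_variance=float(tav), time_avg_variance_se=float(tav_se),
        autocov_lags=lags, autocov=acov, autocov_se=acov_se,
        arrival_count_variance=float(av), arrival_count_variance_se=float(av_se),
        n_replicates=reps, window=window)


def simulate_birth_death(birth: float, death: float,
                         config: SimConfig, max_lag: int = 10) -> TraceStats:
    """Exact Gillespie simulation of a birth-death process.

    Stationary distribution Poisson(birth/death); the variance of the window
    average obeys time_avg_variance * T / (mean * tau) -> 2 with tau = 1/death.
    """
    if min(birth, death) <= 0:
        raise ValueError("birth and death rates must be positive")
    W = config.window
    if W < 10.0 / death:
        warnings.warn("window shorter than 10/death: T >> tau assumption "
                      "violated", stacklevel=2)
    mean = birth / death
    max_mol = int(mean + 12.0 * np.sqrt(mean + 1.0) + 100)
    n_samples = max(0, int(W / config.sample_interval))
    probe_id = np.zeros(1, dtype=np.int64)
    occ1, occ2, births, samples, _, err = lattice_1d(
        _kernel_seed(config.seed), 1, 0, 0, float(birth), 0.0, float(death),
        float(config.burn_in), float(W), int(config.n_replicates),
        probe_id, 1, float(config.sample_interval), n_samples, max_mol)
    if err:
        raise RuntimeError("molecule capacity exceeded (rate excursion)")
    return _stats_from_windows(occ1[:, 0] / W, occ2[:, 0] / W, births,
                               samples[:, :, 0] if n_samples else None,
                               W, config.sample_interval, max_lag)


# ---------------------------------------------------------------------------
# generalized DT: independent molecules with arbitrary transport delay
# ---------------------------------------------------------------------------

class DeterministicDelay:
    """Every molecule takes exactly tau0 to reach the target."""

    def __init__(self, tau0: float):
        if tau0 < 0:
            raise ValueError("delay must be non-negative")
        self.tau0 = tau0

    def __call__(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, self.tau0)


class ExponentialDelay:
    """Exponentially distributed transport delay with the given mean."""

    def __init__(self, mean: float):
        if mean < 0:
            raise ValueError("mean delay must be non-negative")
        self.mean = mean

    def __call__(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.exponential(self.mean, size=n)


class TelegraphFirstPassageDelay:
    """First-passage delay of the two-state run process inside a cytoneme.

    A molecule waits Exp(entry_rate) in the source, enters the cytoneme moving
    forward, and alternates forward runs (speed v+, mean length d+ = v+/zeta+)
    and backward runs (speed v-, mean length d- = v-/zeta-).  Reaching x = L
    delivers it; returning to x = 0 sends it back to the source to try again.
    The delay is the total time from production to delivery.
    """

    def __init__(self, v_plus: float, v_minus: float, zeta_plus: float,
                 zeta_minus: float, length: float, entry_rate: float = 1.0):
        if min(v_plus, v_minus, zeta_plus, zeta_minus, length, entry_rate) <= 0:
            raise ValueError("all telegraph parameters must be positive")
        self.v_plus, self.v_minus = v_plus, v_minus
        self.zeta_plus, self.zeta_minus = zeta_plus, zeta_minus
        self.length, self.entry_rate = length, entry_rate

    def __call__(self, rng: np.random.Generator, n: int) -> np.ndarray:
        d_plus = self.v_plus / self.zeta_plus
        d_minus = self.v_minus / self.zeta_minus
        t = rng.exponential(1.0 / self.entry_rate, size=n)
        x = np.zeros(n)
        forward = np.ones(n, dtype=bool)
        active = np.ones(n, dtype=bool)
        while active.any():
            idx = np.flatnonzero(active)
            fwd = forward[idx]
            run = np.where(fwd, rng.exponential(d_plus, idx.size),
                           rng.exponential(d_minus, idx.size))
            newx = np.where(fwd, x[idx] + run, x[idx] - run)
            speed = np.where(fwd, self.v_plus, self.v_minus)
            hit_target = fwd & (newx >= self.length)
            hit_source = ~fwd & (newx <= 0.0)
            dist = np.where(hit_target, self.length - x[idx],
                            np.where(hit_source, x[idx], run))
            t[idx] += dist / speed
            x[idx] = np.clip(newx, 0.0, self.length)
            # delivered molecules stop; returned molecules wait and re-enter
            back = idx[hit_source]
            t[back] += rng.exponential(1.0 / self.entry_rate, back.size)
            forward[back] = True
            forward[idx[~hit_target & ~hit_source]] = ~fwd[~hit_target & ~hit_source]
            active[idx[hit_target]] = False
        return t


def simulate_generalized_dt(beta: float,
                            delay_sampler: Callable[[np.random.Generator, int], np.ndarray],
                            nu: float, config: SimConfig,
                            routing: Optional[np.ndarray] = None,
                            return_arrivals: bool = False):
    """Independent-molecule simulation of the generalized DT model.

    Molecules are produced at Poisson rate beta starting ``burn_in`` before the
    observation window, delayed by ``delay_sampler``, and live Exp(nu) inside
    the target.  Whatever the delay law, the arrival process into the target is
    Poisson(beta), so the stationary count statistics equal those of a
    birth-death process with birth rate beta (molecule independence is the key
    assumption).

    With ``routing`` (a probability vector pi over cells, summing to 1) each
    molecule is routed to one cell and the per-cell window-averaged means are
    returned alongside; with ``return_arrivals`` the arrival times of the first
    replicate are returned for inter-event statistics.

    Returns ``stats`` or ``(stats, extra)`` where ``extra`` holds the requested
    per-cell means and/or arrivals.
    """
    if min(beta, nu) <= 0:
        raise ValueError("beta and nu must be positive")
    W = config.window
    burn = config.burn_in
    if burn < 10.0 / nu:
        warnings.warn("burn_in < 10/nu: pre-window production may not have "
                      "reached stationarity", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    reps = config.n_replicates
    n_samples = max(1, int(W / config.sample_interval))
    sample_t = np.arange(n_samples) * config.sample_interval
    avgs = np.empty(reps)
    occ2 = np.empty(reps)
    arrivals_in_window = np.empty(reps)
    first_arrivals = None
    cell_avgs = None
    if routing is not None:
        routing = np.asarray(routing, dtype=float)
        if abs(routing.sum() - 1.0) > 1e-9 or np.any(routing < 0):
            raise ValueError("routing must be a probability vector")
        cell_avgs = np.zeros((reps, routing.size))
    for r in range(reps):
        n = rng.poisson(beta * (burn + W))
        t_prod = rng.uniform(-burn, W, size=n)
        delay = np.asarray(delay_sampler(rng, n), dtype=float)
        if np.any(delay < 0):
            raise ValueError("delay sampler returned negative delays")
        arr = t_prod + delay
        dep = arr + rng.exponential(1.0 / nu, size=n)
        overlap = np.clip(np.minimum(dep, W) - np.maximum(arr, 0.0), 0.0, None)
        avgs[r] = overlap.sum() / W
        arr_sorted = np.sort(arr)
        dep_sorted = np.sort(dep)
        counts = (np.searchsorted(arr_sorted, sample_t, side="right")
                  - np.searchsorted(dep_sorted, sample_t, side="right"))
        occ2[r] = np.mean(counts.astype(float) ** 2)
        in_win = (arr >= 0) & (arr <= W)
        arrivals_in_window[r] = in_win.sum()
        if r == 0 and return_arrivals:
            first_arrivals = np.sort(arr[in_win])
        if routing is not None:
            cells = rng.choice(routing.size, size=n, p=routing)
            np.add.at(cell_avgs[r], cells, overlap / W)
    # occ2 here is a sampled (not time-weighted) second moment; adequate for
    # stationary-variance estimates at sample_interval >> tau
    stats = _stats_from_windows(avgs, occ2, arrivals_in_window.astype(np.int64),
                                None, W, config.sample_interval)
    extras = {}
    if routing is not None:
        extras["cell_means"] = cell_avgs.mean(axis=0)
        extras["cell_means_se"] = cell_avgs.std(axis=0, ddof=1) / np.sqrt(reps)
    if return_arrivals:
        extras["arrivals"] = first_arrivals
    return (stats, extras) if extras else stats


# ---------------------------------------------------------------------------
# deterministic cytoneme transport integrator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CytonemeMicroParams:
    """Microscopic cytoneme parameters (velocities, switch rates, entry rate).

    Only d+- = v+-/zeta+- enter the steady state (through phi and kappa); v and
    zeta separately set how fast it is reached, and gamma cancels entirely.
    """

    v_plus: float
    v_minus: float
    zeta_plus: float
    zeta_minus: float
    gamma: float
    beta: float
    nu: float
    N: int
    a: float = 1.0

    def __post_init__(self) -> None:
        if min(self.v_plus, self.v_minus, self.zeta_plus, self.zeta_minus,
               self.gamma, self.beta, self.nu, self.a) <= 0 or self.N < 1:
            raise ValueError("invalid cytoneme parameters")

    @property
    def d_plus(self) -> float:
        return self.v_plus / self.zeta_plus

    @property
    def d_minus(self) -> float:
        return self.v_minus / self.zeta_minus

    @property
    def phi(self) -> float:
        return float(np.log(self.d_minus / self.d_plus))

    @property
    def kappa_a(self) -> float:
        return float(self.a * (1.0 / self.d_plus - 1.0 / self.d_minus))

    @classmethod
    def from_shape(cls, shape: DTShape, rates: DTRates, gamma: float = 1.0,
                   v: float = 1.0, a: float = 1.0) -> "CytonemeMicroParams":
        """Concrete microscopic parameters realising a given (phi, kappa_a)."""
        if shape.powerlaw:
            d_plus = shape.d_plus_over_a * a
            d_minus = d_plus * np.exp(shape.phi)
        else:
            kappa = shape.kappa_a / a
            d_plus = -np.expm1(-shape.phi) / kappa   # (1 - e^{-phi}) / kappa
            d_minus = d_plus * np.exp(shape.phi)
        return cls(v_plus=v, v_minus=v, zeta_plus=v / d_plus,
                   zeta_minus=v / d_minus, gamma=gamma, beta=rates.beta,
                   nu=rates.nu, N=shape.N, a=a)


def _minmod(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.where(a * b > 0.0, np.sign(a) * np.minimum(np.abs(a), np.abs(b)),
                    0.0)


def integrate_cytoneme_ode(params: CytonemeMicroParams,
                           grid_points: int = 400,
                           flux_order: int = 2,
                           cfl: float = 0.4,
                           tol: float = 1e-10,
                           t_max: float = 2000.0) -> Profile:
    """Integrate the mean-field cytoneme transport system to steady state.

    Finite-volume discretisation of the forward/backward densities u+-_j(x, t)
    on each cytoneme (length 2ja, ``grid_points`` cells), with inflow boundary
    v+ u+(0) = gamma m0 and v- u-(L) = 0.  ``flux_order`` 2 uses
    minmod-limited (MUSCL) upwind fluxes with Heun (RK2) stepping, TVD-stable
    at the given CFL number; ``flux_order`` 1 is plain donor-cell upwinding.
    Marches until the relative change of the target-cell means per unit time
    drops below ``tol``.  The steady state matches the closed-form DT profile,
    and total degradation flux balances production.
    """
    N, G, a = params.N, grid_points, params.a
    vp, vm = params.v_plus, params.v_minus
    zp, zm = params.zeta_plus, params.zeta_minus
    gamma, beta, nu = params.gamma, params.beta, params.nu
    L = 2.0 * a * np.arange(1, N + 1)
    dx = (L / G)[:, None]                       # (N, 1)
    dt = cfl * float(dx.min()) / max(vp, vm)

    def slopes(u: np.ndarray) -> np.ndarray:
        if flux_order < 2 or G < 3:
            return np.zeros_like(u)
        d = u[:, 1:] - u[:, :-1]
        s = np.zeros_like(u)
        s[:, 1:-1] = _minmod(d[:, :-1], d[:, 1:])
        return s

    def rhs(up, um, m, m0):
        s = slopes(up)
        Fp = np.empty((N, G + 1))
        Fp[:, 0] = gamma * m0
        Fp[:, 1:] = vp * (up + 0.5 * s)          # upwind from the left cell
        s = slopes(um)
        Fm = np.zeros((N, G + 1))
        Fm[:, :G] = vm * (um - 0.5 * s)          # upwind from the right cell
        dup = (Fp[:, :-1] - Fp[:, 1:]) / dx + zm * um - zp * up
        dum = (Fm[:, 1:] - Fm[:, :-1]) / dx + zp * up - zm * um
        dm = Fp[:, -1] - nu * m
        dm0 = beta - 2.0 * np.sum(gamma * m0 - Fm[:, 0])
        return dup, dum, dm, dm0

    up = np.zeros((N, G))
    um = np.zeros((N, G))
    m = np.zeros(N)
    m0 = 0.0
    check_every = max(1, int(round(1.0 / dt)))  # compare m once per unit time
    m_prev = m.copy()
    t = 0.0
    step = 0
    while t < t_max:
        k1 = rhs(up, um, m, m0)
        y1 = (up + dt * k1[0], um + dt * k1[1], m + dt * k1[2], m0 + dt * k1[3])
        k2 = rhs(*y1)
        up += 0.5 * dt * (k1[0] + k2[0])
        um += 0.5 * dt * (k1[1] + k2[1])
        m += 0.5 * dt * (k1[2] + k2[2])
        m0 += 0.5 * dt * (k1[3] + k2[3])
        t += dt
        step += 1
        if not np.isfinite(m).all() or np.any(m < -1e-6 * beta / nu):
            raise FloatingPointError("integration unstable; reduce cfl")
        if step % check_every == 0:
            scale = max(m.max(), beta / (2 * nu * N))
            change = np.abs(m - m_prev).max() / scale / (check_every * dt)
            if change < tol and t > 10.0 / nu:
                break
            m_prev = m.copy()
    else:
        warnings.warn("steady state not reached within t_max", stacklevel=2)
    return Profile(values=np.clip(m, 0.0, None), side_count=N)


# ---------------------------------------------------------------------------
# SDC lattice oracles
# ---------------------------------------------------------------------------

@dataclass
class SDCLatticeResult:
    per_cell: dict[int, TraceStats]
    total_mean: float
    total_mean_se: float


def simulate_sdc_lattice(beta: float, D: float, nu: float, a: float,
                         n_cells: int, subcells_per_cell: int,
                         config: SimConfig,
                         probe_cells: tuple[int, ...] = (1, 2),
                         max_lag: int = 10) -> SDCLatticeResult:
    """Exact Gillespie simulation of the 1D SDC system on a subcell lattice.

    ``n_cells`` target cells on each side of a central source cell, each split
    into ``subcells_per_cell`` compartments of width 2a/subcells; hop rate
    between adjacent compartments D/width^2; production at the centre of the
    source cell; per-molecule degradation nu.  Reflecting outer boundaries must
    be at least 5 lambda beyond the outermost probed cell.  Returns per probed
    cell the TraceStats of the aggregated (cell-level) count.
    """
    if min(beta, D, nu, a) <= 0:
        raise ValueError("beta, D, nu, a must be positive")
    lam = np.sqrt(D / nu)
    if (n_cells - max(probe_cells)) * 2.0 * a < 5.0 * lam:
        raise ValueError("reflecting boundary closer than 5 lambda to a "
                         "probed cell; increase n_cells")
    S = subcells_per_cell
    n_sites = (2 * n_cells + 1) * S
    source_cell = n_cells
    source_site = source_cell * S + S // 2
    source_site2 = source_cell * S + (S - 1) // 2
    width = 2.0 * a / S
    hop = D / width ** 2
    probe_id = np.full(n_sites, -1, dtype=np.int64)
    for p, j in enumerate(probe_cells):
        cell = source_cell + j
        probe_id[cell * S:(cell + 1) * S] = p
    W = config.window
    n_samples = max(0, int(W / config.sample_interval))
    mean_total = beta / nu
    max_mol = int(mean_total + 12.0 * np.sqrt(mean_total + 1.0) + 200)
    occ1, occ2, _, samples, total_occ, err = lattice_1d(
        _kernel_seed(config.seed), n_sites, source_site, source_site2,
        float(beta), float(hop), float(nu), float(config.burn_in), float(W),
        int(config.n_replicates), probe_id, len(probe_cells),
        float(config.sample_interval), n_samples, max_mol)
    if err:
        raise RuntimeError("molecule capacity exceeded")
    per_cell = {}
    for p, j in enumerate(probe_cells):
        per_cell[j] = _stats_from_windows(
            occ1[:, p] / W, occ2[:, p] / W, None,
            samples[:, :, p] if n_samples else None,
            W, config.sample_interval, max_lag)
    totals = total_occ / W
    return SDCLatticeResult(per_cell=per_cell,
                            total_mean=float(totals.mean()),
                            total_mean_se=float(totals.std(ddof=1)
                                                / np.sqrt(totals.size)))


def simulate_sdc_lattice_2d(beta_per_cell: float, D: float, nu: float,
                            a: float, n_cells_x: int, n_cells_y: int,
                            subcells_per_cell: int, config: SimConfig,
                            probe_cell_x: int = 2) -> TraceStats:
    """2D SDC oracle: a transverse line of source cells feeding a sheet.

    The lattice has (2 n_cells_x + 1) x n_cells_y cells (periodic in the
    transverse direction y), each of side 2a split into subcells.  Each source
    cell (the x = 0 column) produces at ``beta_per_cell``, injected at the
    column's subcell centre with uniformly random y.  The probe is the single
    cell at perpendicular index ``probe_cell_x``, transverse index 0; its mean
    matches the 1D profile and its window-averaged variance matches
    2 m tau_2d / T with tau_2d from the 2D correlation-time quadrature.
    """
    lam = np.sqrt(D / nu)
    if (n_cells_x - probe_cell_x) * 2.0 * a < 5.0 * lam:
        raise ValueError("boundary closer than 5 lambda to the probed cell")
    S = subcells_per_cell
    nx = (2 * n_cells_x + 1) * S
    ny = n_cells_y * S
    width = 2.0 * a / S
    hop = D / width ** 2
    source_x = n_cells_x * S + S // 2
    source_x2 = n_cells_x * S + (S - 1) // 2
    beta_total = beta_per_cell * n_cells_y
    cell_x = n_cells_x + probe_cell_x
    px0, px1 = cell_x * S, (cell_x + 1) * S
    py0, py1 = 0, S
    W = config.window
    n_samples = max(0, int(W / config.sample_interval))
    mean_total = beta_total / nu
    max_mol = int(mean_total + 12.0 * np.sqrt(mean_total + 1.0) + 200)
    occ1, occ2, samples, _, err = lattice_2d(
        _kernel_seed(config.seed), nx, ny, source_x, source_x2,
        float(beta_total),
        float(hop), float(nu), float(config.burn_in), float(W),
        int(config.n_replicates), px0, px1, py0, py1,
        float(config.sample_interval), n_samples, max_mol)
    if err:
        raise RuntimeError("molecule capacity exceeded")
    return _stats_from_windows(occ1 / W, occ2 / W, None,
                               samples if n_samples else None,
                               W, config.sample_interval)


def simulate_hopping_chain(beta: float, h: float, nu: float, n_sites: int,
                           config: SimConfig, max_lag: int = 10) -> TraceStats:
    """Gillespie simulation of the discrete hopping chain, probing the centre
    cell (where production at rate beta is injected).

    The chain should be long enough that the reflecting ends never matter for
    the probed cell (>= 25 * max(1, sqrt(h/nu)) cells per side); a ValueError
    enforces this.  The sampled-trace autocovariance is the oracle for the
    Bessel-form closed autocorrelation.
    """
    if n_sites % 2 == 0:
        raise ValueError("use an odd number of sites so the centre is a cell")
    half = n_sites // 2
    if half < 25 * max(1.0, np.sqrt(h / nu)):
        raise ValueError("chain too short: boundary effects on the probed "
                         "cell would exceed the infinite-chain assumption")
    center = half
    probe_id = np.full(n_sites, -1, dtype=np.int64)
    probe_id[center] = 0
    W = config.window
    n_samples = max(0, int(W / config.sample_interval))
    mean_total = beta / nu
    max_mol = int(mean_total + 12.0 * np.sqrt(mean_total + 1.0) + 200)
    occ1, occ2, _, samples, _, err = lattice_1d(
        _kernel_seed(config.seed), n_sites, center, center, float(beta),
        float(h), float(nu), float(config.burn_in), float(W),
        int(config.n_replicates), probe_id, 1,
        float(config.sample_interval), n_samples, max_mol)
    if err:
        raise RuntimeError("molecule capacity exceeded")
    return _stats_from_windows(occ1[:, 0] / W, occ2[:, 0] / W, None,
                               samples[:, :, 0] if n_samples else None,
                               W, config.sample_interval, max_lag)


# ---------------------------------------------------------------------------
# concentration readout vs arrival counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVRatioResult:
    """Squared-CV ratio of the two readouts, with a jackknife standard error."""

    ratio: float
    ratio_se: float
    cv2_concentration: float
    cv2_arrival: float

    def __float__(self) -> float:
        return self.ratio


def arrival_vs_concentration_cv(birth: float, death: float,
                                config: SimConfig) -> CVRatioResult:
    """Ratio of squared CVs: time-averaged count vs arrival-event count.

    Counting arrivals eliminates degradation noise but keeps arrival noise, so
    the variance can at best be halved: the ratio converges to 2 as
    T*death -> infinity.  The arrival-count squared CV itself is 1/(birth*T)
    (Poisson).  Standard error by leave-one-replicate-out jackknife.
    """
    if config.n_replicates < 3:
        raise ValueError("need at least 3 replicates for a jackknife SE")
    W = config.window
    mean = birth / death
    max_mol = int(mean + 12.0 * np.sqrt(mean + 1.0) + 100)
    probe_id = np.zeros(1, dtype=np.int64)
    occ1, _, births, _, _, err = lattice_1d(
        _kernel_seed(config.seed), 1, 0, 0, float(birth), 0.0, float(death),
        float(config.burn_in), float(W), int(config.n_replicates),
        probe_id, 1, 1.0, 0, max_mol)
    if err:
        raise RuntimeError("molecule capacity exceeded")
    A = occ1[:, 0] / W
    Bc = births.astype(float)

    def cv_ratio(a: np.ndarray, b: np.ndarray) -> float:
        return (a.var(ddof=1) / a.mean() ** 2) / (b.var(ddof=1) / b.mean() ** 2)

    n = A.size
    full = cv_ratio(A, Bc)
    loo = np.array([cv_ratio(np.delete(A, i), np.delete(Bc, i))
                    for i in range(n)])
    se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    return CVRatioResult(ratio=float(full), ratio_se=se,
                         cv2_concentration=float(A.var(ddof=1) / A.mean() ** 2),
                         cv2_arrival=float(Bc.var(ddof=1) / Bc.mean() ** 2))
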