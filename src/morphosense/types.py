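"""Shared result containers used across the DT and SDC models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Profile:
    """Mean molecule counts m_j for target cells j = 1..N on one side of the source.

    The source sits at x = 0 and cell j occupies [2ja - a, 2ja + a] where a is the
    cell radius.  By symmetry the mirror cells at -j carry the same means, so total
    production balance reads 2 * sum(values) = beta / nu for both transport models.
    """

    values: np.ndarray
    side_count: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size != self.side_count:
            raise ValueError("values must be a 1-D array of length side_count")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("mean molecule counts must be finite and non-negative")

    def __len__(self) -> int:
        return self.side_count

    @property
    def delta(self) -> np.ndarray:
        """Adjacent-cell differences Delta m_j = m_j - m_{j+1}, j = 1..N-1."""
        return self.values[:-1] - self.values[1:]

    @property
    def steepness(self) -> np.ndarray:
        """Relative steepness Delta m_j / m_j, j = 1..N-1."""
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(self.values[:-1] > 0, self.delta / self.values[:-1], 0.0)
        return s


@dataclass(frozen=True)
class PrecisionResult:
    """Squared readout precision P_j^2 = (m_j T / 2 tau) (Delta m_j / m_j)^2.

    ``p_squared`` is indexed by j = 1..N-1 (the edge cell has no neighbour below
    it), ``tau`` is the correlation time of the molecule count in a single cell,
    and ``delta_m`` holds the adjacent-cell differences that set the signal.
    """

    p_squared: np.ndarray
    tau: float
    delta_m: np.ndarray

    def __post_init__(self) -> None:
        p2 = np.asarray(self.p_squared, dtype=float)
        dm = np.asarray(self.delta_m, dtype=float)
        object.__setattr__(self, "p_squared", p2)
        object.__setattr__(self, "delta_m", dm)
        if self.tau <= 0:
            raise ValueError("correlation time must be positive")
        if np.any(p2 < 0):
            raise ValueError("squared precision cannot be negative")


@dataclass
class SimConfig:
    """Plumbing for the stochastic oracles: seed, window lengths, replicates."""

    seed: int = 0
    total_time: float = 100.0
    burn_in: float = 10.0
    n_replicates: int = 10
    sample_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.burn_in >= self.total_time:
            raise ValueError("burn_in must be shorter than total_time")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")

    @property
    def window(self) -> float:
        return self.total_time - self.burn_in


@dataclass
class TraceStats:
    """Summary statistics of a simulated molecule-count trace.

    Every estimate is accompanied by a standard error so that closed-form
    predictions can be compared at a stated number of standard errors.
    ``time_avg_variance`` is the variance across replicate windows of the
    window-averaged count -- the quantity bounded by 2 m tau / T.
    """

    stationary_mean: float
    stationary_mean_se: float
    stationary_variance: float
    stationary_variance_se: float
    time_avg_variance: float
    time_avg_variance_se: float
    autocov_lags: np.ndarray = field(default_factory=lambda: np.empty(0))
    autocov: np.ndarray = field(default_factory=lambda: np.empty(0))
    autocov_se: np.ndarray = field(default_factory=lambda: np.empty(0))
    arrival_count_variance: float = float("nan")
    arrival_count_variance_se: float = float("nan")
    n_replicates: int = 0
    window: float = float("nan")

    @property
    def fano(self) -> float:
        return self.stationary_variance / self.stationary_mean
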