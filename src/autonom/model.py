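"""Piecewise sinusoidal model: data containers, likelihood and priors.

The observed series ``y_1..y_n`` is modelled as a piecewise harmonic
regression.  Between consecutive change-points ``s_{j-1} <= t < s_j`` the mean
is

    f(t) = alpha_j + mu_j * t
           + sum_l [ beta_{j,l}^(1) cos(2 pi omega_{j,l} t)
                   + beta_{j,l}^(2) sin(2 pi omega_{j,l} t) ]

with iid Gaussian errors of segment-specific variance ``sigma_j^2``.  The
number of change-points ``k``, their locations, the number of sinusoids per
segment ``m_j``, and all segment parameters are unknown; priors are
truncated Poisson on the dimensions, the even-order-statistics density on the
locations, Uniform(0, 0.5) on frequencies (cycles per sample), a diffuse
isotropic Gaussian on the linear coefficients and Inverse-Gamma on the
variances.

Everything downstream (the reversible-jump samplers, the engine, the
summaries) evaluates log-posteriors through this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp

TWO_PI = 2.0 * math.pi

__all__ = [
    "TimeSeriesData",
    "SegmentParams",
    "ModelState",
    "Hyperparams",
    "basis_row",
    "design_matrix",
    "segment_loglik",
    "total_loglik",
    "log_prior_changepoint_locations",
    "log_prior_dimension",
    "log_prior_theta",
    "segment_log_prior",
    "log_posterior",
    "move_probabilities",
    "segment_ranges",
    "min_frequency_separation",
    "invgamma_logpdf",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class TimeSeriesData:
    """An evenly sampled univariate series with implicit time index 1..n.

    ``dt`` (time units per sample) is metadata only; the model works on the
    integer sample index.
    """

    values: np.ndarray
    dt: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise ValueError("time series must contain at least 2 points")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(1, self.n + 1, dtype=float)


@dataclass
class SegmentParams:
    """Parameters of one segment: frequencies, linear coefficients, variance.

    ``omega`` is kept sorted ascending (canonical representative of the
    exchangeable iid-uniform prior).  ``beta`` is ordered
    (alpha, [mu,] b_1^(1), b_1^(2), ..., b_m^(1), b_m^(2)); the slope column
    ``mu`` is present only when the trend is enabled.
    """

    omega: np.ndarray
    beta: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        self.beta = np.asarray(self.beta, dtype=float).ravel()

    @property
    def m(self) -> int:
        return self.omega.size

    def validate(self, m_max: int, include_trend: bool) -> None:
        if not (1 <= self.m <= m_max):
            raise ValueError(f"m={self.m} outside [1, {m_max}]")
        if np.any(self.omega <= 0.0) or np.any(self.omega >= 0.5):
            raise ValueError("frequencies must lie strictly inside (0, 0.5)")
        if np.any(np.diff(self.omega) < 0):
            raise ValueError("frequencies must be sorted ascending")
        if self.beta.size != n_coef(self.m, include_trend):
            raise ValueError("coefficient vector has wrong length")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")

    def copy(self) -> "SegmentParams":
        return SegmentParams(self.omega.copy(), self.beta.copy(), self.sigma2)


@dataclass
class ModelState:
    """Full model state: change-points and per-segment parameters.

    ``s`` holds the k interior change-points (continuous, sorted); the
    boundaries s_0 = 1 and s_{k+1} = n are implicit.  ``loglik`` caches the
    per-segment log-likelihoods.
    """

    s: np.ndarray
    segments: list[SegmentParams]
    n: int
    loglik: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s = np.atleast_1d(np.asarray(self.s, dtype=float)) if np.size(self.s) else np.empty(0)

    @property
    def k(self) -> int:
        return self.s.size

    def copy(self) -> "ModelState":
        return ModelState(
            self.s.copy(),
            [seg.copy() for seg in self.segments],
            self.n,
            None if self.loglik is None else self.loglik.copy(),
        )

    def validate(self, hp: "Hyperparams") -> None:
        if not (0 <= self.k <= hp.k_max):
            raise ValueError(f"k={self.k} outside [0, {hp.k_max}]")
        if len(self.segments) != self.k + 1:
            raise ValueError("need exactly k+1 segments")
        bounds = np.concatenate(([1.0], self.s, [float(self.n)]))
        if np.any(np.diff(bounds) < hp.psi_s):
            raise ValueError("change-points violate the minimum separation psi_s")
        for seg in self.segments:
            seg.validate(hp.m_max, hp.include_trend)


@dataclass
class Hyperparams:
    """Prior and proposal hyperparameters.

    Defaults follow the illustrative simulation settings: prior means
    lambda_s = lambda_omega = 2, k_max = 15, m_max = 10, diffuse coefficient
    prior sigma_beta2 = 1e6, vague Inverse-Gamma(nu0/2, gamma0/2) with
    nu0 = gamma0 = 0.01, move constant c = 0.4, minimum change-point
    separation psi_s = 20 samples and frequency-birth upper bound
    phi_omega = 0.25.

    Proposal scales (``freq_rw_sd``, ``pgram_kde_sd``) default to half a
    Fourier bin of the segment, 1/(2 n_seg), when left as None.
    ``lik_weight`` = 0 switches the likelihood off (prior sampling), used by
    the prior-recovery diagnostics.
    """

    lambda_s: float = 2.0
    lambda_omega: float = 2.0
    k_max: int = 15
    m_max: int = 10
    sigma_beta2: float = 1.0e6
    nu0: float = 0.01
    gamma0: float = 0.01
    c: float = 0.4
    psi_s: float = 20.0
    phi_omega: float = 0.25
    include_trend: bool = True
    # frequency within-model proposal
    freq_mix_rw: float = 0.8
    freq_rw_sd: float | None = None
    pgram_kde_sd: float | None = None
    # frequency birth proposal: weight of the periodogram component
    # (default 0: pure Uniform(0, phi_omega))
    birth_pgram_weight: float = 0.0
    # change-point relocation proposal
    cp_rw_sd: float = 15.0
    cp_mix_rw: float = 0.75
    # sd of the jitter component of the fresh-segment frequency proposal in
    # change-point births; None -> 1/n
    cp_freq_jitter_sd: float | None = None
    # Beta(a, a) concentration of the variance-split mixing variable u
    # (1 = uniform; larger keeps child variances closer to the parent's)
    cp_u_conc: float = 2.0
    # variance handling in change-point births/deaths: "gibbs" re-proposes
    # each affected variance from its Inverse-Gamma full conditional;
    # "split" uses the multiplicative u/(1-u) pairing with its Jacobian
    cp_var_mode: str = "gibbs"
    lik_weight: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.c <= 0.5):
            raise ValueError("c must lie in [0, 0.5]")
        if not (0.0 < self.phi_omega <= 0.5):
            raise ValueError("phi_omega must lie in (0, 0.5]")
        if self.psi_s < 1:
            raise ValueError("psi_s must be >= 1")
        if self.sigma_beta2 <= 0:
            raise ValueError("sigma_beta2 must be positive")
        if self.k_max < 0 or self.m_max < 1:
            raise ValueError("k_max >= 0 and m_max >= 1 required")
        if not (0.0 <= self.freq_mix_rw <= 1.0 and 0.0 <= self.cp_mix_rw <= 1.0):
            raise ValueError("mixture weights must lie in [0, 1]")
        if not (0.0 <= self.birth_pgram_weight <= 1.0):
            raise ValueError("birth_pgram_weight must lie in [0, 1]")
        if self.cp_var_mode not in ("gibbs", "split"):
            raise ValueError("cp_var_mode must be 'gibbs' or 'split'")

    @property
    def f_max(self) -> float:
        """Upper bound of the explored frequency band."""
        return min(0.5, self.phi_omega)

    def replace(self, **kw) -> "Hyperparams":
        return replace(self, **kw)


def n_coef(m: int, include_trend: bool) -> int:
    """Length of the coefficient vector: 2m+2 with trend, 2m+1 without."""
    return 2 * m + 2 if include_trend else 2 * m + 1


def min_frequency_separation(n_seg: int) -> float:
    """Hard-core separation between frequencies within a segment, 1/(2 n_seg).

    Closer pairs give near-collinear design columns; states violating this are
    assigned zero posterior mass and proposals into them are rejected.
    """
    return 0.5 / max(n_seg, 2)


# ---------------------------------------------------------------------------
# basis and likelihood


def basis_row(t: float, omega: np.ndarray, include_trend: bool = True) -> np.ndarray:
    """The regression row x_t(omega) = (1, t, cos 2*pi*w_1 t, sin 2*pi*w_1 t, ...).

    Without the trend the slope entry ``t`` is omitted.
    """
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    if np.any(omega <= 0.0) or np.any(omega >= 0.5):
        raise ValueError("frequencies must lie strictly inside (0, 0.5)")
    ang = TWO_PI * omega * t
    head = [1.0, float(t)] if include_trend else [1.0]
    row = np.empty(len(head) + 2 * omega.size)
    row[: len(head)] = head
    row[len(head)::2] = np.cos(ang)
    row[len(head) + 1::2] = np.sin(ang)
    return row


def design_matrix(times: np.ndarray, omega: np.ndarray, include_trend: bool = True) -> np.ndarray:
    """Stacked basis rows for a vector of (integer) times."""
    times = np.asarray(times, dtype=float)
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    off = 2 if include_trend else 1
    X = np.empty((times.size, off + 2 * omega.size))
    X[:, 0] = 1.0
    if include_trend:
        X[:, 1] = times
    ang = TWO_PI * np.outer(times, omega)
    X[:, off::2] = np.cos(ang)
    X[:, off + 1::2] = np.sin(ang)
    return X


def gaussian_loglik(n_obs: int, rss: float, sigma2: float) -> float:
    return -0.5 * n_obs * math.log(TWO_PI * sigma2) - 0.5 * rss / sigma2


def segment_loglik(
    y_seg: np.ndarray,
    theta: SegmentParams,
    times: np.ndarray,
    include_trend: bool = True,
    lik_weight: float = 1.0,
) -> float:
    """Gaussian log-likelihood of one segment."""
    y_seg = np.asarray(y_seg, dtype=float)
    if y_seg.size == 0:
        raise ValueError("empty segment")
    if y_seg.size != np.size(times):
        raise ValueError("y_seg and times must have equal length")
    if lik_weight == 0.0:
        return 0.0
    X = design_matrix(times, theta.omega, include_trend)
    resid = y_seg - X @ theta.beta
    return lik_weight * gaussian_loglik(y_seg.size, float(resid @ resid), theta.sigma2)


def segment_ranges(s: np.ndarray, n: int) -> list[tuple[int, int]]:
    """Integer index range (lo, hi), inclusive, of each segment.

    Segment j covers the half-open interval [s_{j-1}, s_j); the final segment
    is closed at n.
    """
    bounds = np.concatenate(([1.0], np.atleast_1d(s) if np.size(s) else [], [float(n)]))
    ranges = []
    for j in range(len(bounds) - 1):
        lo = math.ceil(bounds[j])
        hi = n if j == len(bounds) - 2 else math.ceil(bounds[j + 1]) - 1
        ranges.append((lo, hi))
    return ranges


def total_loglik(data: TimeSeriesData, state: ModelState, hp: Hyperparams) -> float:
    """Sum of segment log-likelihoods over the k+1 segments."""
    out = 0.0
    for (lo, hi), seg in zip(segment_ranges(state.s, data.n), state.segments):
        times = np.arange(lo, hi + 1, dtype=float)
        out += segment_loglik(data.values[lo - 1: hi], seg, times, hp.include_trend, hp.lik_weight)
    return out


# ---------------------------------------------------------------------------
# priors


def log_prior_changepoint_locations(s: np.ndarray, n: int) -> float:
    """Log even-order-statistics prior (Green-style) for the k locations.

    pi(s | k) = (2k+1)! / (n-1)^(2k+1) * prod_j (s_{j+1} - s_j) on the ordered
    simplex 1 < s_1 < ... < s_k < n; integrates to 1 there.  Ordering
    violations return -inf rather than raising.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float)) if np.size(s) else np.empty(0)
    k = s.size
    bounds = np.concatenate(([1.0], s, [float(n)]))
    diffs = np.diff(bounds)
    if np.any(diffs <= 0):
        return -np.inf
    return float(gammaln(2 * k + 2) - (2 * k + 1) * math.log(n - 1) + np.log(diffs).sum())


@lru_cache(maxsize=64)
def _trunc_poisson_table(lam: float, z_min: int, z_max: int) -> np.ndarray:
    z = np.arange(z_min, z_max + 1)
    logw = z * math.log(lam) - gammaln(z + 1) if lam > 0 else np.where(z == 0, 0.0, -np.inf)
    return logw - logsumexp(logw)


def log_prior_dimension(z: int, lam: float, z_min: int, z_max: int) -> float:
    """Truncated-Poisson log-mass on z_min..z_max; -inf outside."""
    if not (z_min <= z <= z_max):
        return -np.inf
    return float(_trunc_poisson_table(float(lam), int(z_min), int(z_max))[z - z_min])


def invgamma_logpdf(x: float, a: float, b: float) -> float:
    """Inverse-Gamma(a, b) log-density (shape a, scale b)."""
    if x <= 0:
        return -np.inf
    return a * math.log(b) - gammaln(a) - (a + 1.0) * math.log(x) - b / x


def log_prior_theta(theta: SegmentParams, hp: Hyperparams) -> float:
    """Log-prior of one segment's (omega, beta, sigma2).

    Uniform(0, 0.5) per frequency (density 2), N(0, sigma_beta2 I) on the
    coefficients, Inverse-Gamma(nu0/2, gamma0/2) on the variance.
    """
    if np.any(theta.omega <= 0.0) or np.any(theta.omega >= 0.5):
        return -np.inf
    freq_term = theta.m * math.log(2.0)
    p = theta.beta.size
    beta_term = -0.5 * p * math.log(TWO_PI * hp.sigma_beta2) - 0.5 * float(
        theta.beta @ theta.beta
    ) / hp.sigma_beta2
    var_term = invgamma_logpdf(theta.sigma2, 0.5 * hp.nu0, 0.5 * hp.gamma0)
    return freq_term + beta_term + var_term


def segment_log_prior(theta: SegmentParams, hp: Hyperparams) -> float:
    """m-prior plus theta-prior of one segment."""
    return log_prior_dimension(theta.m, hp.lambda_omega, 1, hp.m_max) + log_prior_theta(theta, hp)


def log_posterior(data: TimeSeriesData, state: ModelState, hp: Hyperparams) -> float:
    """Unnormalized log-posterior of the full state.

    Includes the psi_s-separation constraint as part of the support (states
    violating it get -inf), matching the sampler's target.
    """
    bounds = np.concatenate(([1.0], state.s, [float(data.n)]))
    if np.any(np.diff(bounds) < hp.psi_s):
        return -np.inf
    out = log_prior_dimension(state.k, hp.lambda_s, 0, hp.k_max)
    out += log_prior_changepoint_locations(state.s, data.n)
    for seg in state.segments:
        out += segment_log_prior(seg, hp)
    if not np.isfinite(out):
        return -np.inf
    return out + total_loglik(data, state, hp)


# ---------------------------------------------------------------------------
# move schedule


def move_probabilities(
    z: int, lam: float, z_min: int, z_max: int, c: float
) -> tuple[float, float]:
    """Birth/death probabilities (b_z, d_z) of the dimension-changing moves.

    b_z = c * min{1, pi(z+1)/pi(z)},  d_z = c * min{1, pi(z-1)/pi(z)} with the
    truncated-Poisson prior pi; b vanishes at z_max and d at z_min, and the
    pairing b_z * pi(z) = d_{z+1} * pi(z+1) holds exactly.
    """
    lp = _trunc_poisson_table(float(lam), int(z_min), int(z_max))
    i = z - z_min
    b = c * min(1.0, math.exp(lp[i + 1] - lp[i])) if z < z_max else 0.0
    d = c * min(1.0, math.exp(lp[i - 1] - lp[i])) if z > z_min else 0.0
    return b, d
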