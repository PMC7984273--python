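"""Reversible-jump updates on the number and positions of change-points.

Three moves: relocation of an existing change-point (within-model), a segment
split (birth) and a segment merge (death).  Births draw the new location
uniformly on the admissible support left by the minimum-separation constraint
psi_s.  At a split or merge, every newly created segment receives a fresh
frequency set drawn from a data-driven mixture (the segment's own
periodogram, a jitter around the adjacent segments' current frequencies, and
a uniform floor) whose density enters the acceptance ratio, so the pair of
moves is exactly reversible.  Variances at a split/merge are, by default,
re-proposed from their Inverse-Gamma full conditionals; the Green-style
multiplicative u/(1-u) map with its analytic Jacobian is available as
cp_var_mode="split".  The affected coefficient vectors are re-proposed from
their Gaussian full conditionals in either mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import betaln

from .model import (
    Hyperparams,
    ModelState,
    SegmentParams,
    TimeSeriesData,
    _trunc_poisson_table,
    log_prior_changepoint_locations,
    log_prior_dimension,
    min_frequency_separation,
    move_probabilities,
    segment_log_prior,
)
from .segment_sampler import (
    _seg_loglik_from_beta,
    _sigma2_logq,
    beta_full_conditional,
    beta_logpdf,
    draw_beta,
    reflect,
    reflected_normal_logpdf,
    sample_sigma2,
)

__all__ = [
    "AdmissibleSupport",
    "admissible_support",
    "split_variance",
    "merge_variance",
    "relocate_changepoint",
    "birth_changepoint",
    "death_changepoint",
    "changepoint_move",
]


# ---------------------------------------------------------------------------
# admissible support for a new change-point


@dataclass
class AdmissibleSupport:
    """Union of intervals where a new change-point may be born:
    [s_j + psi_s, s_{j+1} - psi_s] for j = 0..k with s_0 = 1, s_{k+1} = n."""

    intervals: np.ndarray  # shape (q, 2)
    total_length: float

    @property
    def empty(self) -> bool:
        return self.total_length <= 0.0

    def sample(self, rng: np.random.Generator) -> float:
        lengths = self.intervals[:, 1] - self.intervals[:, 0]
        i = rng.choice(len(lengths), p=lengths / lengths.sum())
        lo, hi = self.intervals[i]
        return lo + (hi - lo) * rng.random()


def admissible_support(s: np.ndarray, n: int, psi_s: float) -> AdmissibleSupport:
    bounds = np.concatenate(([1.0], np.atleast_1d(s) if np.size(s) else [], [float(n)]))
    ivals = []
    for j in range(len(bounds) - 1):
        lo, hi = bounds[j] + psi_s, bounds[j + 1] - psi_s
        if hi > lo:
            ivals.append((lo, hi))
    if not ivals:
        return AdmissibleSupport(np.empty((0, 2)), 0.0)
    arr = np.asarray(ivals, dtype=float)
    return AdmissibleSupport(arr, float((arr[:, 1] - arr[:, 0]).sum()))


# ---------------------------------------------------------------------------
# variance split / merge


def split_variance(sigma2: float, u: float) -> tuple[float, float, float]:
    """Split sigma2 into (sigma2 u/(1-u), sigma2 (1-u)/u); returns both
    children and log|J| = log(2 sigma2) - log(u(1-u)) of the map
    (sigma2, u) -> (sigma2_l, sigma2_r)."""
    if not (0.0 < u < 1.0):
        raise ValueError("u must lie strictly inside (0, 1)")
    left = sigma2 * u / (1.0 - u)
    right = sigma2 * (1.0 - u) / u
    log_jac = math.log(2.0 * sigma2) - math.log(u * (1.0 - u))
    return left, right, log_jac


def merge_variance(sigma2_left: float, sigma2_right: float) -> tuple[float, float]:
    """Inverse of :func:`split_variance`: geometric mean and the mixing u."""
    sigma2 = math.sqrt(sigma2_left * sigma2_right)
    sl, sr = math.sqrt(sigma2_left), math.sqrt(sigma2_right)
    return sigma2, sl / (sl + sr)


def _u_logpdf(u: float, a: float) -> float:
    """Log-density of the symmetric Beta(a, a) proposal for the mixing u."""
    if not (0.0 < u < 1.0):
        return -np.inf
    return (a - 1.0) * (math.log(u) + math.log1p(-u)) - float(betaln(a, a))


# ---------------------------------------------------------------------------
# fresh-segment frequency proposal (splits and merges) and its density
#
# A newly created segment draws m from the truncated-Poisson prior and each
# frequency iid from a mixture of (i) a sharp draw at the segment's own
# periodogram argmax, (ii) a periodogram-weighted draw, (iii) a jittered copy
# of a random frequency of the adjacent current set(s) and (iv) a uniform
# floor.  All components are deterministic functions of the segment's data
# slice, and the matched reverse move evaluates the same density, so split
# and merge are exactly reversible.


def _jitter_sd(hp: Hyperparams, n: int) -> float:
    return hp.cp_freq_jitter_sd if hp.cp_freq_jitter_sd is not None else 1.0 / n


def _fresh_freq_components(y_child: np.ndarray, hp: Hyperparams):
    """(pgram proposal or None, weights (peak, pgram, jitter, uniform))."""
    from .segment_sampler import make_proposal_dist

    if np.size(y_child) >= 4:
        return make_proposal_dist(np.asarray(y_child, dtype=float), hp), (0.35, 0.2, 0.3, 0.15)
    return None, (0.0, 0.0, 0.5, 0.5)


def _fresh_m_logpmf(m_b: int, m_ref: int, hp: Hyperparams) -> float:
    """Log-pmf of the fresh set's sinusoid count: a point mass at the
    reference count (the adjacent segment's current m) mixed with the
    truncated-Poisson prior, so splits can preserve the local structure even
    under a sparse prior."""
    table = _trunc_poisson_table(float(hp.lambda_omega), 1, int(hp.m_max))
    base = 0.6 * math.exp(table[m_b - 1])
    if m_b == min(m_ref, hp.m_max):
        base += 0.4
    return math.log(base)


def _sample_fresh_m(m_ref: int, hp: Hyperparams, rng: np.random.Generator) -> int:
    if rng.random() < 0.4:
        return min(m_ref, hp.m_max)
    table = _trunc_poisson_table(float(hp.lambda_omega), 1, int(hp.m_max))
    return 1 + int(rng.choice(table.size, p=np.exp(table)))


def _fresh_freq_logpdf_one(
    w: float, parent_omega: np.ndarray, pdist, weights, hp: Hyperparams, n: int
) -> float:
    w_peak, w_pg, w_jit, w_unif = weights
    sd = _jitter_sd(hp, n)
    dens = reflected_normal_logpdf(w, parent_omega, sd, hp.f_max)
    mx = float(np.max(dens))
    jitter = mx + math.log(float(np.mean(np.exp(dens - mx))))
    terms = [math.log(w_jit) + jitter, math.log(w_unif) - math.log(hp.f_max)]
    if pdist is not None:
        if w_pg > 0.0:
            terms.append(math.log(w_pg) + pdist.pgram_logpdf(w))
        if w_peak > 0.0:
            f_peak = float(pdist.fourier_grid[int(np.argmax(pdist.weights))])
            terms.append(
                math.log(w_peak)
                + float(reflected_normal_logpdf(w, f_peak, pdist.kde_sd, hp.f_max))
            )
    m = max(terms)
    return m + math.log(sum(math.exp(t - m) for t in terms))


def fresh_freqs_logq(
    omega_b: np.ndarray,
    parent_omega: np.ndarray,
    y_child: np.ndarray,
    hp: Hyperparams,
    n: int,
) -> float:
    """Log proposal mass/density of a fresh frequency set (count + values).

    The reference count for the size pmf is the adjacent set's cardinality.
    """
    pdist, weights = _fresh_freq_components(y_child, hp)
    out = _fresh_m_logpmf(omega_b.size, parent_omega.size, hp)
    for w in omega_b:
        out += _fresh_freq_logpdf_one(float(w), parent_omega, pdist, weights, hp, n)
    return out


# probability that a split/merge replicates the source frequency set
# (sorted-paired jitter) rather than drawing a fresh data-driven set
_REPLICATE_WEIGHT = 0.6


def _replicate_sd(omega_src: np.ndarray, n: int) -> float:
    """Jitter sd of the replicate mode: well below both the Fourier scale and
    the source set's smallest gap, so the sorted pairing identifies the
    density (non-identity pairings are numerically zero)."""
    tau = 1.0 / n
    if omega_src.size > 1:
        tau = min(tau, float(np.min(np.diff(omega_src))) / 5.0)
    return max(tau, 1e-8)


def _replicate_logq(omega_new: np.ndarray, omega_src: np.ndarray,
                    hp: Hyperparams, n: int) -> float:
    """Density of a sorted-paired jittered copy of the source set."""
    if omega_new.size != omega_src.size:
        return -np.inf
    tau = _replicate_sd(omega_src, n)
    return float(sum(
        reflected_normal_logpdf(float(w), float(src), tau, hp.f_max)
        for w, src in zip(omega_new, omega_src)
    ))


def _sample_replicate(omega_src: np.ndarray, hp: Hyperparams, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    tau = _replicate_sd(omega_src, n)
    out = np.array([reflect(float(w) + tau * rng.standard_normal(), hp.f_max)
                    for w in omega_src])
    return np.sort(out)


def pair_freqs_logq(
    omega_L: np.ndarray,
    omega_R: np.ndarray,
    parent_omega: np.ndarray,
    yL: np.ndarray,
    yR: np.ndarray,
    hp: Hyperparams,
    n: int,
) -> float:
    """Log-density of the two children's frequency sets at a split: a shared
    mode flag chooses 'replicate the parent into both children' or 'fresh
    data-driven sets for both'."""
    rep = (_replicate_logq(omega_L, parent_omega, hp, n)
           + _replicate_logq(omega_R, parent_omega, hp, n))
    fresh = (fresh_freqs_logq(omega_L, parent_omega, yL, hp, n)
             + fresh_freqs_logq(omega_R, parent_omega, yR, hp, n))
    terms = [math.log(1.0 - _REPLICATE_WEIGHT) + fresh]
    if np.isfinite(rep):
        terms.append(math.log(_REPLICATE_WEIGHT) + rep)
    m = max(terms)
    return m + math.log(sum(math.exp(t - m) for t in terms))


def sample_pair_freqs(
    parent_omega: np.ndarray,
    yL: np.ndarray,
    yR: np.ndarray,
    hp: Hyperparams,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    if rng.random() < _REPLICATE_WEIGHT:
        return (_sample_replicate(parent_omega, hp, n, rng),
                _sample_replicate(parent_omega, hp, n, rng))
    return (sample_fresh_freqs(parent_omega, yL, hp, n, rng),
            sample_fresh_freqs(parent_omega, yR, hp, n, rng))


def merged_freqs_logq(
    omega_m: np.ndarray,
    omega_L: np.ndarray,
    omega_R: np.ndarray,
    y_m: np.ndarray,
    hp: Hyperparams,
    n: int,
) -> float:
    """Log-density of the merged segment's frequency set at a merge: a
    jittered copy of one side's current set (the side chosen with equal
    probability) or a fresh data-driven set referencing the union.  The copy
    modes make the merge the proper reverse of a replicate split."""
    union = np.sort(np.concatenate([omega_L, omega_R]))
    half = 0.5 * _REPLICATE_WEIGHT
    terms = [math.log(1.0 - _REPLICATE_WEIGHT)
             + fresh_freqs_logq(omega_m, union, y_m, hp, n)]
    for side in (omega_L, omega_R):
        rep = _replicate_logq(omega_m, side, hp, n)
        if np.isfinite(rep):
            terms.append(math.log(half) + rep)
    m = max(terms)
    return m + math.log(sum(math.exp(t - m) for t in terms))


def sample_merged_freqs(
    omega_L: np.ndarray,
    omega_R: np.ndarray,
    y_m: np.ndarray,
    hp: Hyperparams,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    u = rng.random()
    if u < _REPLICATE_WEIGHT:
        side = omega_L if u < 0.5 * _REPLICATE_WEIGHT else omega_R
        return _sample_replicate(side, hp, n, rng)
    union = np.sort(np.concatenate([omega_L, omega_R]))
    return sample_fresh_freqs(union, y_m, hp, n, rng)


def sample_fresh_freqs(
    parent_omega: np.ndarray,
    y_child: np.ndarray,
    hp: Hyperparams,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    pdist, (w_peak, w_pg, w_jit, _) = _fresh_freq_components(y_child, hp)
    m_b = _sample_fresh_m(parent_omega.size, hp, rng)
    sd = _jitter_sd(hp, n)
    out = np.empty(m_b)
    for i in range(m_b):
        u = rng.random()
        if u < w_peak:
            f_peak = float(pdist.fourier_grid[int(np.argmax(pdist.weights))])
            out[i] = reflect(f_peak + pdist.kde_sd * rng.standard_normal(), hp.f_max)
        elif u < w_peak + w_pg:
            l = rng.choice(pdist.fourier_grid.size, p=pdist.weights)
            out[i] = reflect(float(pdist.fourier_grid[l]) + pdist.kde_sd * rng.standard_normal(),
                             hp.f_max)
        elif u < w_peak + w_pg + w_jit:
            src = parent_omega[rng.integers(parent_omega.size)]
            out[i] = reflect(float(src) + sd * rng.standard_normal(), hp.f_max)
        else:
            out[i] = hp.f_max * rng.random()
    return np.sort(out)


# ---------------------------------------------------------------------------
# helpers


def _plugin_var(omega: np.ndarray, y: np.ndarray, t: np.ndarray, hp: Hyperparams) -> float:
    """Deterministic data-adapted variance used to condition coefficient
    re-proposals in splits/merges: an iterated ridge plug-in of the residual
    variance under the given frequencies.  Both directions of a move compute
    it from the segment's own data, so the proposal densities stay matched
    no matter how different the carried variances are."""
    sigma2 = float(np.var(y)) or 1.0
    if hp.lik_weight == 0.0:
        return sigma2
    for _ in range(2):
        mean, _, X = beta_full_conditional(omega, sigma2, y, t, hp)
        resid = y - X @ mean
        sigma2 = (float(resid @ resid) + hp.gamma0) / (y.size + hp.nu0 + 2.0)
    return max(sigma2, 1e-12)


def _slice(data: TimeSeriesData, lo_bound: float, hi_bound: float, closed_right: bool):
    lo = math.ceil(lo_bound)
    hi = data.n if closed_right else math.ceil(hi_bound) - 1
    return data.values[lo - 1: hi], np.arange(lo, hi + 1, dtype=float)


def _state_bounds(state: ModelState, n: int) -> np.ndarray:
    return np.concatenate(([1.0], state.s, [float(n)]))


def _refresh_sigma2(state: ModelState, data: TimeSeriesData, hp: Hyperparams,
                    rng: np.random.Generator, seg_idx: list[int]) -> None:
    """Gibbs-update sigma2 (and cached loglik) of the given segments."""
    bounds = _state_bounds(state, data.n)
    for j in seg_idx:
        seg = state.segments[j]
        y, t = _slice(data, bounds[j], bounds[j + 1], j == len(state.segments) - 1)
        sigma2, _, _ = sample_sigma2(seg.omega, seg.beta, y, t, hp, rng)
        seg.sigma2 = sigma2
        if state.loglik is not None:
            state.loglik[j] = _seg_loglik_from_beta(seg.omega, seg.beta, sigma2, y, t, hp)


# ---------------------------------------------------------------------------
# within-model move: relocation


def relocate_changepoint(
    state: ModelState, data: TimeSeriesData, hp: Hyperparams, rng: np.random.Generator
) -> tuple[ModelState, bool]:
    """Move one change-point; the adjacent coefficient vectors are re-proposed
    and the whole block accepted jointly, then the two variances are
    Gibbs-refreshed."""
    k = state.k
    if k < 1:
        return state, False
    j = int(rng.integers(k))
    bounds = _state_bounds(state, data.n)
    lo_b = bounds[j] + hp.psi_s
    hi_b = bounds[j + 2] - hp.psi_s
    s_cur = float(state.s[j])
    if rng.random() < hp.cp_mix_rw:
        s_prop = s_cur + hp.cp_rw_sd * rng.standard_normal()
    else:
        s_prop = lo_b + (hi_b - lo_b) * rng.random()
    if not (lo_b <= s_prop <= hi_b):
        return state, False
    last = j + 1 == len(state.segments) - 1
    segL, segR = state.segments[j], state.segments[j + 1]
    yL_c, tL_c = _slice(data, bounds[j], s_cur, False)
    yR_c, tR_c = _slice(data, s_cur, bounds[j + 2], last)
    yL_p, tL_p = _slice(data, bounds[j], s_prop, False)
    yR_p, tR_p = _slice(data, s_prop, bounds[j + 2], last)

    # forward beta proposals on the shifted segments (current sigma2)
    meanL, LL, _ = beta_full_conditional(segL.omega, segL.sigma2, yL_p, tL_p, hp)
    betaL, logq_L = draw_beta(meanL, LL, rng)
    meanR, LR, _ = beta_full_conditional(segR.omega, segR.sigma2, yR_p, tR_p, hp)
    betaR, logq_R = draw_beta(meanR, LR, rng)
    # reverse densities at the current coefficients on the current segments
    meanLc, LLc, _ = beta_full_conditional(segL.omega, segL.sigma2, yL_c, tL_c, hp)
    meanRc, LRc, _ = beta_full_conditional(segR.omega, segR.sigma2, yR_c, tR_c, hp)
    logq_Lc = beta_logpdf(segL.beta, meanLc, LLc)
    logq_Rc = beta_logpdf(segR.beta, meanRc, LRc)

    s_new = state.s.copy()
    s_new[j] = s_prop
    delta = (
        _seg_loglik_from_beta(segL.omega, betaL, segL.sigma2, yL_p, tL_p, hp)
        + _seg_loglik_from_beta(segR.omega, betaR, segR.sigma2, yR_p, tR_p, hp)
        - (state.loglik[j] + state.loglik[j + 1] if state.loglik is not None else
           _seg_loglik_from_beta(segL.omega, segL.beta, segL.sigma2, yL_c, tL_c, hp)
           + _seg_loglik_from_beta(segR.omega, segR.beta, segR.sigma2, yR_c, tR_c, hp))
        + log_prior_changepoint_locations(s_new, data.n)
        - log_prior_changepoint_locations(state.s, data.n)
        - 0.5 * (betaL @ betaL + betaR @ betaR
                 - segL.beta @ segL.beta - segR.beta @ segR.beta) / hp.sigma_beta2
    )
    # the location-proposal mixture is symmetric (same interval, plain RW)
    log_a = delta + logq_Lc + logq_Rc - logq_L - logq_R
    if not (log_a >= 0.0 or math.log(rng.random()) < log_a):
        return state, False
    new_state = state.copy()
    new_state.s[j] = s_prop
    new_state.segments[j].beta = betaL
    new_state.segments[j + 1].beta = betaR
    if new_state.loglik is not None:
        new_state.loglik[j] = _seg_loglik_from_beta(segL.omega, betaL, segL.sigma2, yL_p, tL_p, hp)
        new_state.loglik[j + 1] = _seg_loglik_from_beta(segR.omega, betaR, segR.sigma2, yR_p, tR_p, hp)
    _refresh_sigma2(new_state, data, hp, rng, [j, j + 1])
    return new_state, True


# ---------------------------------------------------------------------------
# split/merge acceptance ratio (shared by birth and death)


def split_log_acceptance(
    s_lo: np.ndarray,
    s_star: float,
    parent: SegmentParams,
    segL: SegmentParams,
    segR: SegmentParams,
    data: TimeSeriesData,
    hp: Hyperparams,
) -> float:
    """Log M-H acceptance ratio of the split (birth) move.

    ``s_lo`` is the change-point vector WITHOUT ``s_star``; ``parent`` is the
    segment covering ``s_star`` in the low-dimensional state and
    ``segL``/``segR`` the children in the high-dimensional one.  All proposal
    densities (fresh frequency sets, coefficient and variance re-proposals,
    and the variance split construction) are evaluated symmetrically from
    the two configurations, so the matched merge (death) ratio is exactly
    the negative of this value.
    """
    n = data.n
    k = int(np.size(s_lo))
    j = int(np.searchsorted(s_lo, s_star))
    bounds = np.concatenate(([1.0], np.atleast_1d(s_lo) if k else [], [float(n)]))
    last = j == k
    y_par, t_par = _slice(data, bounds[j], bounds[j + 1], last)
    yL, tL = _slice(data, bounds[j], s_star, False)
    yR, tR = _slice(data, s_star, bounds[j + 1], last)
    s_hi = np.sort(np.append(s_lo, s_star))

    supp = admissible_support(s_lo, n, hp.psi_s)
    if supp.empty:
        return -np.inf
    b_lo, _ = move_probabilities(k, hp.lambda_s, 0, hp.k_max, hp.c)
    _, d_hi = move_probabilities(k + 1, hp.lambda_s, 0, hp.k_max, hp.c)
    if b_lo == 0.0 or d_hi == 0.0:
        return -np.inf

    geo, u = merge_variance(segL.sigma2, segR.sigma2)
    if hp.cp_var_mode == "split":
        # children's variances arise from the u/(1-u) map applied to the
        # parent's (geo == parent.sigma2 on the move's trajectory); beta
        # re-proposals condition on each side's own variance
        log_jac = math.log(2.0 * geo) - math.log(u * (1.0 - u))
        var_term = log_jac - _u_logpdf(u, hp.cp_u_conc)
        meanL, LL = beta_full_conditional(segL.omega, segL.sigma2, yL, tL, hp)[:2]
        meanR, LR = beta_full_conditional(segR.omega, segR.sigma2, yR, tR, hp)[:2]
        mean_p, L_p = beta_full_conditional(parent.omega, parent.sigma2, y_par, t_par, hp)[:2]
    else:
        # every affected coefficient vector is re-proposed at a deterministic
        # plug-in variance of its own segment, then each residual variance
        # from its Inverse-Gamma full conditional
        var_term = (
            _sigma2_logq(parent.omega, parent.beta, y_par, t_par, hp, parent.sigma2)
            - _sigma2_logq(segL.omega, segL.beta, yL, tL, hp, segL.sigma2)
            - _sigma2_logq(segR.omega, segR.beta, yR, tR, hp, segR.sigma2)
        )
        meanL, LL = beta_full_conditional(
            segL.omega, _plugin_var(segL.omega, yL, tL, hp), yL, tL, hp)[:2]
        meanR, LR = beta_full_conditional(
            segR.omega, _plugin_var(segR.omega, yR, tR, hp), yR, tR, hp)[:2]
        mean_p, L_p = beta_full_conditional(
            parent.omega, _plugin_var(parent.omega, y_par, t_par, hp), y_par, t_par, hp)[:2]
    logq_L = beta_logpdf(segL.beta, meanL, LL)
    logq_R = beta_logpdf(segR.beta, meanR, LR)
    logq_par = beta_logpdf(parent.beta, mean_p, L_p)

    delta_post = (
        _seg_loglik_from_beta(segL.omega, segL.beta, segL.sigma2, yL, tL, hp)
        + _seg_loglik_from_beta(segR.omega, segR.beta, segR.sigma2, yR, tR, hp)
        - _seg_loglik_from_beta(parent.omega, parent.beta, parent.sigma2, y_par, t_par, hp)
        + segment_log_prior(segL, hp) + segment_log_prior(segR, hp)
        - segment_log_prior(parent, hp)
        + log_prior_changepoint_locations(s_hi, n)
        - log_prior_changepoint_locations(s_lo, n)
        + log_prior_dimension(k + 1, hp.lambda_s, 0, hp.k_max)
        - log_prior_dimension(k, hp.lambda_s, 0, hp.k_max)
    )
    return (
        delta_post
        + math.log(d_hi) - math.log(k + 1) - math.log(b_lo)
        + math.log(supp.total_length)
        + merged_freqs_logq(parent.omega, segL.omega, segR.omega, y_par, hp, n)
        - pair_freqs_logq(segL.omega, segR.omega, parent.omega, yL, yR, hp, n)
        + logq_par - logq_L - logq_R
        + var_term
    )


# ---------------------------------------------------------------------------
# birth: split a segment


def birth_changepoint(
    state: ModelState, data: TimeSeriesData, hp: Hyperparams, rng: np.random.Generator
) -> tuple[ModelState, bool]:
    k = state.k
    if k >= hp.k_max:
        return state, False
    supp = admissible_support(state.s, data.n, hp.psi_s)
    if supp.empty:
        return state, False
    s_star = supp.sample(rng)
    j = int(np.searchsorted(state.s, s_star))  # parent segment index
    bounds = _state_bounds(state, data.n)
    parent = state.segments[j]
    last = j == len(state.segments) - 1
    yL, tL = _slice(data, bounds[j], s_star, False)
    yR, tR = _slice(data, s_star, bounds[j + 1], last)

    sep = min_frequency_separation(data.n)
    omega_L, omega_R = sample_pair_freqs(parent.omega, yL, yR, hp, data.n, rng)
    if any(om.size > 1 and np.min(np.diff(om)) < sep for om in (omega_L, omega_R)):
        return state, False  # hard-core constraint on a fresh set

    if hp.cp_var_mode == "split":
        u = float(rng.beta(hp.cp_u_conc, hp.cp_u_conc))
        if not (0.0 < u < 1.0):
            return state, False
        s2L, s2R, _ = split_variance(parent.sigma2, u)
        betaL, _ = (lambda m, L: draw_beta(m, L, rng))(
            *beta_full_conditional(omega_L, s2L, yL, tL, hp)[:2])
        betaR, _ = (lambda m, L: draw_beta(m, L, rng))(
            *beta_full_conditional(omega_R, s2R, yR, tR, hp)[:2])
    else:
        betaL, _ = (lambda m, L: draw_beta(m, L, rng))(
            *beta_full_conditional(omega_L, _plugin_var(omega_L, yL, tL, hp), yL, tL, hp)[:2])
        betaR, _ = (lambda m, L: draw_beta(m, L, rng))(
            *beta_full_conditional(omega_R, _plugin_var(omega_R, yR, tR, hp), yR, tR, hp)[:2])
        s2L, _, _ = sample_sigma2(omega_L, betaL, yL, tL, hp, rng)
        s2R, _, _ = sample_sigma2(omega_R, betaR, yR, tR, hp, rng)
    segL = SegmentParams(omega_L, betaL, s2L)
    segR = SegmentParams(omega_R, betaR, s2R)

    log_a = split_log_acceptance(state.s, s_star, parent, segL, segR, data, hp)
    if not (log_a >= 0.0 or math.log(rng.random()) < log_a):
        return state, False
    s_new = np.sort(np.append(state.s, s_star))
    llL = _seg_loglik_from_beta(omega_L, betaL, s2L, yL, tL, hp)
    llR = _seg_loglik_from_beta(omega_R, betaR, s2R, yR, tR, hp)
    segments = state.segments[:j] + [segL, segR] + state.segments[j + 1:]
    loglik = None
    if state.loglik is not None:
        loglik = np.concatenate([state.loglik[:j], [llL, llR], state.loglik[j + 1:]])
    return ModelState(s_new, [sg.copy() for sg in segments], data.n, loglik), True


# ---------------------------------------------------------------------------
# death: merge two segments


def death_changepoint(
    state: ModelState, data: TimeSeriesData, hp: Hyperparams, rng: np.random.Generator
) -> tuple[ModelState, bool]:
    k = state.k
    if k < 1:
        return state, False
    j = int(rng.integers(k))  # remove s_j, merging segments j and j+1
    bounds = _state_bounds(state, data.n)
    segL, segR = state.segments[j], state.segments[j + 1]
    last = j + 1 == len(state.segments) - 1
    y_m, t_m = _slice(data, bounds[j], bounds[j + 2], last)

    omega_m = sample_merged_freqs(segL.omega, segR.omega, y_m, hp, data.n, rng)
    if omega_m.size > 1 and np.min(np.diff(omega_m)) < min_frequency_separation(data.n):
        return state, False
    geo, _ = merge_variance(segL.sigma2, segR.sigma2)
    if hp.cp_var_mode == "split":
        sigma2_m = geo
        beta_m, _ = (lambda m, L: draw_beta(m, L, rng))(
            *beta_full_conditional(omega_m, sigma2_m, y_m, t_m, hp)[:2])
    else:
        beta_m, _ = (lambda m, L: draw_beta(m, L, rng))(
            *beta_full_conditional(omega_m, _plugin_var(omega_m, y_m, t_m, hp), y_m, t_m, hp)[:2])
        sigma2_m, _, _ = sample_sigma2(omega_m, beta_m, y_m, t_m, hp, rng)
    merged = SegmentParams(omega_m, beta_m, sigma2_m)

    s_new = np.delete(state.s, j)
    log_a = -split_log_acceptance(
        s_new, float(state.s[j]), merged, segL, segR, data, hp
    )
    if not (log_a >= 0.0 or math.log(rng.random()) < log_a):
        return state, False
    ll_m = _seg_loglik_from_beta(omega_m, beta_m, sigma2_m, y_m, t_m, hp)
    segments = state.segments[:j] + [merged] + state.segments[j + 2:]
    loglik = None
    if state.loglik is not None:
        loglik = np.concatenate([state.loglik[:j], [ll_m], state.loglik[j + 2:]])
    return ModelState(s_new, [sg.copy() for sg in segments], data.n, loglik), True


# ---------------------------------------------------------------------------
# dispatch


def changepoint_move(
    state: ModelState, data: TimeSeriesData, hp: Hyperparams, rng: np.random.Generator
) -> tuple[ModelState, str, bool]:
    """One change-point model move: birth, death or relocation, chosen with
    the dimension-dependent probabilities (b_k, d_k)."""
    b_k, d_k = move_probabilities(state.k, hp.lambda_s, 0, hp.k_max, hp.c)
    u = rng.random()
    if u <= b_k:
        state, acc = birth_changepoint(state, data, hp, rng)
        return state, "cp_birth", acc
    if u <= b_k + d_k:
        state, acc = death_changepoint(state, data, hp, rng)
        return state, "cp_death", acc
    state, acc = relocate_changepoint(state, data, hp, rng)
    return state, "cp_within", acc
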