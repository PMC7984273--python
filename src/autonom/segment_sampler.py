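"""Per-segment reversible-jump updates.

One segment at a time, this module updates the frequencies by
Metropolis-Hastings with a mixture proposal (reflected random walk +
periodogram-informed independence draw), the linear coefficients by an exact
Gibbs draw from their Gaussian full conditional, the residual variance by a
Gibbs draw from its Inverse-Gamma full conditional, and the number of
sinusoids by birth/death moves whose acceptance ratios carry the proposal
densities of the re-drawn coefficients and variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram as _scipy_periodogram

from .model import (
    Hyperparams,
    SegmentParams,
    design_matrix,
    gaussian_loglik,
    invgamma_logpdf,
    min_frequency_separation,
    move_probabilities,
    segment_log_prior,
    TWO_PI,
)

__all__ = [
    "FrequencyProposalDist",
    "periodogram_proposal",
    "reflected_normal_logpdf",
    "reflect",
    "beta_full_conditional",
    "draw_beta",
    "beta_logpdf",
    "sample_beta",
    "sample_sigma2",
    "sigma2_posterior_params",
    "update_frequencies_within",
    "update_frequency_beta_joint",
    "birth_frequency",
    "death_frequency",
    "segment_move",
]

_LOG_SQRT_2PI = 0.5 * math.log(TWO_PI)


# ---------------------------------------------------------------------------
# reflected normal helpers (proposals on the open band (0, hi))


def reflect(x: float, hi: float) -> float:
    """Fold x into (0, hi) by reflection at both boundaries."""
    period = 2.0 * hi
    x = math.fmod(x, period)
    if x < 0.0:
        x += period
    return x if x <= hi else period - x

def _normal_logpdf(d: np.ndarray, sd: float) -> np.ndarray:
    return -0.5 * (d / sd) ** 2 - math.log(sd) - _LOG_SQRT_2PI


_REFLECT_OFFSETS = np.array([-2.0, 0.0, 2.0])


def reflected_normal_logpdf(x: float, mu, sd: float, hi: float):
    """Log-density at x of a N(mu, sd^2) reflected into (0, hi).

    Method of images: sum the source density over the mirror images
    +-x + 2 r hi (|r| <= 1 suffices for sd well below hi).  ``mu`` may be an
    array (vectorized over sources).
    """
    mu = np.asarray(mu, dtype=float)
    off = _REFLECT_OFFSETS * hi  # (3,)
    d = np.concatenate([
        (x - mu[..., None]) + off,
        (-x - mu[..., None]) + off,
    ], axis=-1)
    z = -0.5 * (d / sd) ** 2
    mx = z.max(axis=-1)
    out = mx + np.log(np.exp(z - mx[..., None]).sum(axis=-1)) - math.log(sd) - _LOG_SQRT_2PI
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# periodogram-informed frequency proposal


@dataclass
class FrequencyProposalDist:
    """Mixture proposal for a single frequency on (0, f_max).

    With probability ``mix_weight_rw`` a reflected normal random walk of sd
    ``rw_sd`` centred at the current value; otherwise a Fourier frequency is
    drawn with probability proportional to the segment periodogram and
    smoothed by a reflected normal kernel of sd ``kde_sd`` (so the proposal
    has a proper density on the band).
    """

    fourier_grid: np.ndarray
    weights: np.ndarray
    rw_sd: float
    mix_weight_rw: float
    kde_sd: float
    f_max: float

    def pgram_logpdf(self, x: float) -> float:
        dens = reflected_normal_logpdf(x, self.fourier_grid, self.kde_sd, self.f_max)
        mx = dens.max()
        return float(mx + math.log(float(np.exp(dens - mx) @ self.weights)))

    def logpdf(self, x_from: float, x_to: float) -> float:
        """Mixture log-density q(x_to | x_from)."""
        lw = []
        if self.mix_weight_rw > 0.0:
            lw.append(
                math.log(self.mix_weight_rw)
                + float(reflected_normal_logpdf(x_to, x_from, self.rw_sd, self.f_max))
            )
        if self.mix_weight_rw < 1.0:
            lw.append(math.log(1.0 - self.mix_weight_rw) + self.pgram_logpdf(x_to))
        m = max(lw)
        return m + math.log(sum(math.exp(v - m) for v in lw))

    def sample(self, x_from: float, rng: np.random.Generator) -> float:
        if rng.random() < self.mix_weight_rw:
            return reflect(x_from + self.rw_sd * rng.standard_normal(), self.f_max)
        l = rng.choice(self.fourier_grid.size, p=self.weights)
        return reflect(self.fourier_grid[l] + self.kde_sd * rng.standard_normal(), self.f_max)


def periodogram_proposal(
    y_seg: np.ndarray,
    phi_omega: float,
    rw_sd: float | None = None,
    mix_weight_rw: float = 0.8,
    kde_sd: float | None = None,
) -> FrequencyProposalDist:
    """Build the frequency proposal from the segment's periodogram.

    Ordinates are computed on the mean-detrended segment at the Fourier
    frequencies l/n_seg restricted to (0, min(0.5, phi_omega)); an all-zero
    (or constant) segment falls back to uniform weights.
    """
    y_seg = np.asarray(y_seg, dtype=float)
    n_seg = y_seg.size
    if n_seg < 4:
        raise ValueError("segment too short for a periodogram proposal")
    f_max = min(0.5, phi_omega)
    freqs, pxx = _scipy_periodogram(y_seg, window="boxcar", detrend="constant")
    mask = (freqs > 0.0) & (freqs < f_max)
    grid, power = freqs[mask], pxx[mask]
    if grid.size == 0:
        # band narrower than a Fourier bin: fall back to a uniform coarse grid
        grid = f_max * (np.arange(1, 17) / 17.0)
        power = np.ones_like(grid)
    total = power.sum()
    weights = power / total if total > 0 else np.full(grid.size, 1.0 / grid.size)
    default_sd = 0.5 / n_seg
    return FrequencyProposalDist(
        fourier_grid=grid,
        weights=weights,
        rw_sd=default_sd if rw_sd is None else rw_sd,
        mix_weight_rw=mix_weight_rw,
        kde_sd=default_sd if kde_sd is None else kde_sd,
        f_max=f_max,
    )


_PDIST_CACHE: dict = {}


def make_proposal_dist(y_seg: np.ndarray, hp: Hyperparams) -> FrequencyProposalDist:
    """Build (or fetch from a content-keyed cache) the frequency proposal of
    a data segment; the sampler evaluates proposal densities for the same
    slices many times per move."""
    y_arr = np.ascontiguousarray(np.asarray(y_seg, dtype=float))
    key = (hash(y_arr.tobytes()), hp.phi_omega, hp.freq_rw_sd, hp.freq_mix_rw, hp.pgram_kde_sd)
    hit = _PDIST_CACHE.get(key)
    if hit is not None:
        return hit
    dist = _build_proposal_dist(y_arr, hp)
    if len(_PDIST_CACHE) > 512:
        _PDIST_CACHE.clear()
    _PDIST_CACHE[key] = dist
    return dist


def _build_proposal_dist(y_seg: np.ndarray, hp: Hyperparams) -> FrequencyProposalDist:
    if np.size(y_seg) < 4:
        # segment too short for a periodogram: uninformative coarse grid
        f_max = hp.f_max
        grid = f_max * (np.arange(1, 17) / 17.0)
        sd = f_max / 16.0
        return FrequencyProposalDist(
            fourier_grid=grid, weights=np.full(16, 1.0 / 16.0),
            rw_sd=hp.freq_rw_sd or sd, mix_weight_rw=hp.freq_mix_rw,
            kde_sd=hp.pgram_kde_sd or sd, f_max=f_max,
        )
    return periodogram_proposal(
        y_seg, hp.phi_omega, rw_sd=hp.freq_rw_sd, mix_weight_rw=hp.freq_mix_rw,
        kde_sd=hp.pgram_kde_sd,
    )


# ---------------------------------------------------------------------------
# conjugate full conditionals


def beta_full_conditional(
    omega: np.ndarray,
    sigma2: float,
    y_seg: np.ndarray,
    times: np.ndarray,
    hp: Hyperparams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean and Cholesky precision of the Gaussian full conditional of beta.

    Precision P = w X'X / sigma2 + I / sigma_beta2, mean solves
    P b = w X'y / sigma2 (w = lik_weight; w = 0 gives the prior).  The model
    being linear-Gaussian, this conditional is exact, so the within-model
    coefficient update is a Gibbs step.
    """
    w = hp.lik_weight
    if w == 0.0:  # prior: mean 0, isotropic precision; the design is unused
        from .model import n_coef

        p = n_coef(np.atleast_1d(omega).size, hp.include_trend)
        L = np.eye(p) / math.sqrt(hp.sigma_beta2)
        return np.zeros(p), L, None
    X = design_matrix(times, omega, hp.include_trend)
    p = X.shape[1]
    P = (w / sigma2) * (X.T @ X) + np.eye(p) / hp.sigma_beta2
    rhs = (w / sigma2) * (X.T @ np.asarray(y_seg, dtype=float))
    try:
        L = np.linalg.cholesky(P)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by freq separation
        raise np.linalg.LinAlgError(
            f"ill-conditioned design (p={p}, cond(P)~{np.linalg.cond(P):.2e})"
        ) from exc
    mean = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
    return mean, L, X


def draw_beta(mean: np.ndarray, L: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Draw from N(mean, P^{-1}) given the Cholesky factor L of P; return
    the draw and its log-density."""
    z = rng.standard_normal(mean.size)
    beta = mean + np.linalg.solve(L.T, z)
    logq = float(np.log(np.diag(L)).sum() - mean.size * _LOG_SQRT_2PI - 0.5 * z @ z)
    return beta, logq


def beta_logpdf(beta: np.ndarray, mean: np.ndarray, L: np.ndarray) -> float:
    """Log-density of N(mean, P^{-1}) at beta, with L = chol(P)."""
    u = (beta - mean) @ L  # == L.T (beta - mean)
    return float(np.log(np.diag(L)).sum() - mean.size * _LOG_SQRT_2PI - 0.5 * u @ u)


def sample_beta(
    omega: np.ndarray,
    sigma2: float,
    y_seg: np.ndarray,
    times: np.ndarray,
    hp: Hyperparams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Gibbs draw of the coefficients plus its log proposal density."""
    mean, L, _ = beta_full_conditional(omega, sigma2, y_seg, times, hp)
    return draw_beta(mean, L, rng)


def sigma2_posterior_params(n_seg: int, rss: float, hp: Hyperparams) -> tuple[float, float]:
    """Shape/scale of the Inverse-Gamma full conditional of sigma2."""
    w = hp.lik_weight
    return 0.5 * (w * n_seg + hp.nu0), 0.5 * (hp.gamma0 + w * rss)


def sample_sigma2(
    omega: np.ndarray,
    beta: np.ndarray,
    y_seg: np.ndarray,
    times: np.ndarray,
    hp: Hyperparams,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Gibbs draw of sigma2 from IG((w n + nu0)/2, (gamma0 + w RSS)/2).

    Returns (draw, log proposal density, rss).
    """
    if hp.lik_weight == 0.0:
        a, b = 0.5 * hp.nu0, 0.5 * hp.gamma0
        sigma2 = b / _gamma_draw(a, rng)
        return sigma2, invgamma_logpdf(sigma2, a, b), 0.0
    X = design_matrix(times, omega, hp.include_trend)
    resid = np.asarray(y_seg, dtype=float) - X @ beta
    rss = float(resid @ resid)
    a, b = sigma2_posterior_params(np.size(times), rss, hp)
    sigma2 = b / _gamma_draw(a, rng)
    return sigma2, invgamma_logpdf(sigma2, a, b), rss


def _gamma_draw(a: float, rng: np.random.Generator) -> float:
    """Gamma(a, 1) draw, stable for tiny shapes (vague-prior regime).

    For a < 0.1 the direct draw underflows to zero; use the boosting identity
    Gamma(a) = Gamma(a+1) * U^(1/a) in log space and clip to the float range.
    """
    if a >= 0.1:
        return float(rng.gamma(a))
    log_x = math.log(rng.gamma(a + 1.0)) + math.log(rng.random()) / a
    return math.exp(min(max(log_x, -700.0), 700.0))


def _sigma2_logq(omega, beta, y_seg, times, hp, sigma2_value) -> float:
    """Log-density of the sigma2 full-conditional proposal at a given value."""
    if hp.lik_weight == 0.0:
        return invgamma_logpdf(sigma2_value, 0.5 * hp.nu0, 0.5 * hp.gamma0)
    X = design_matrix(times, omega, hp.include_trend)
    resid = np.asarray(y_seg, dtype=float) - X @ beta
    a, b = sigma2_posterior_params(np.size(times), float(resid @ resid), hp)
    return invgamma_logpdf(sigma2_value, a, b)


# ---------------------------------------------------------------------------
# within-model frequency update


def update_frequencies_within(
    theta: SegmentParams,
    y_seg: np.ndarray,
    times: np.ndarray,
    hp: Hyperparams,
    rng: np.random.Generator,
    pdist: FrequencyProposalDist | None = None,
    min_sep: float | None = None,
) -> tuple[SegmentParams, int]:
    """One-at-a-time M-H sweep over the frequencies, beta and sigma2 fixed.

    Each frequency is proposed from the random-walk/periodogram mixture and
    accepted against the conditional target exp(-RSS/(2 sigma2)) restricted to
    the band, with the mixture density ratio.  Frequencies are re-sorted
    (with their coefficient pairs) at the end.  Returns the updated segment
    and the number of accepted flips.
    """
    y_seg = np.asarray(y_seg, dtype=float)
    if pdist is None:
        pdist = make_proposal_dist(y_seg, hp)
    omega = theta.omega.copy()
    beta = theta.beta.copy()
    off = 2 if hp.include_trend else 1
    sep = min_frequency_separation(y_seg.size) if min_sep is None else min_sep
    if hp.lik_weight == 0.0:
        # target is uniform on the band: M-H on the proposal ratio alone
        n_acc = 0
        for l in range(omega.size):
            w_cur = float(omega[l])
            w_prop = pdist.sample(w_cur, rng)
            if not (0.0 < w_prop < pdist.f_max):
                continue
            others = np.delete(omega, l)
            if others.size and np.min(np.abs(others - w_prop)) < sep:
                continue
            delta = pdist.logpdf(w_prop, w_cur) - pdist.logpdf(w_cur, w_prop)
            if delta >= 0.0 or math.log(rng.random()) < delta:
                omega[l] = w_prop
                n_acc += 1
        order = np.argsort(omega)
        if np.any(order != np.arange(omega.size)):
            omega = omega[order]
            pair_idx = off + 2 * np.repeat(order, 2) + np.tile([0, 1], omega.size)
            beta = np.concatenate([beta[:off], beta[pair_idx]])
        return SegmentParams(omega, beta, theta.sigma2), n_acc
    X = design_matrix(times, omega, hp.include_trend)
    resid = y_seg - X @ beta
    n_acc = 0
    tt = np.asarray(times, dtype=float)
    for l in range(omega.size):
        b1, b2 = beta[off + 2 * l], beta[off + 2 * l + 1]
        col_c, col_s = X[:, off + 2 * l], X[:, off + 2 * l + 1]
        r_base = resid + b1 * col_c + b2 * col_s
        w_cur = float(omega[l])
        w_prop = pdist.sample(w_cur, rng)
        if not (0.0 < w_prop < pdist.f_max):
            continue
        others = np.delete(omega, l)
        if others.size and np.min(np.abs(others - w_prop)) < sep:
            continue  # hard-core rejection
        ang = TWO_PI * w_prop * tt
        c_new, s_new = np.cos(ang), np.sin(ang)
        r_prop = r_base - b1 * c_new - b2 * s_new
        r_cur = resid
        delta = -0.5 * hp.lik_weight * (float(r_prop @ r_prop) - float(r_cur @ r_cur)) / theta.sigma2
        delta += pdist.logpdf(w_prop, w_cur) - pdist.logpdf(w_cur, w_prop)
        if delta >= 0.0 or math.log(rng.random()) < delta:
            omega[l] = w_prop
            X[:, off + 2 * l] = c_new
            X[:, off + 2 * l + 1] = s_new
            resid = r_prop
            n_acc += 1
    order = np.argsort(omega)
    if np.any(order != np.arange(omega.size)):
        omega = omega[order]
        pair_idx = off + 2 * np.repeat(order, 2) + np.tile([0, 1], omega.size)
        beta = np.concatenate([beta[:off], beta[pair_idx]])
    return SegmentParams(omega, beta, theta.sigma2), n_acc


def update_frequency_beta_joint(
    theta: SegmentParams,
    y_seg: np.ndarray,
    times: np.ndarray,
    hp: Hyperparams,
    rng: np.random.Generator,
    pdist: FrequencyProposalDist | None = None,
    min_sep: float | None = None,
) -> tuple[SegmentParams, bool]:
    """Joint M-H update of one frequency together with all coefficients.

    The one-at-a-time conditional frequency move holds beta fixed, which
    phase-locks the chain: a frequency jump of size df rotates the sinusoid
    phase by 2 pi df t across the segment, so independence jumps between
    spectral modes are almost always rejected.  Here a proposed frequency is
    paired with a coefficient vector freshly drawn from its Gaussian full
    conditional, whose densities enter the ratio; the kernel leaves the
    posterior invariant and restores mode-hopping.
    """
    y_seg = np.asarray(y_seg, dtype=float)
    if pdist is None:
        pdist = make_proposal_dist(y_seg, hp)
    sep = min_frequency_separation(y_seg.size) if min_sep is None else min_sep
    l = int(rng.integers(theta.m))
    w_cur = float(theta.omega[l])
    w_prop = pdist.sample(w_cur, rng)
    if not (0.0 < w_prop < pdist.f_max):
        return theta, False
    others = np.delete(theta.omega, l)
    if others.size and np.min(np.abs(others - w_prop)) < sep:
        return theta, False
    omega_p = np.sort(np.append(others, w_prop))
    mean_p, L_p, _ = beta_full_conditional(omega_p, theta.sigma2, y_seg, times, hp)
    beta_p, logq_beta_p = draw_beta(mean_p, L_p, rng)
    mean_c, L_c, _ = beta_full_conditional(theta.omega, theta.sigma2, y_seg, times, hp)
    logq_beta_c = beta_logpdf(theta.beta, mean_c, L_c)
    dbeta_prior = -0.5 * (float(beta_p @ beta_p) - float(theta.beta @ theta.beta)) / hp.sigma_beta2
    log_a = (
        _seg_loglik_from_beta(omega_p, beta_p, theta.sigma2, y_seg, times, hp)
        - _seg_loglik_from_beta(theta.omega, theta.beta, theta.sigma2, y_seg, times, hp)
        + dbeta_prior
        + pdist.logpdf(w_prop, w_cur) - pdist.logpdf(w_cur, w_prop)
        + logq_beta_c - logq_beta_p
    )
    if log_a >= 0.0 or math.log(rng.random()) < log_a:
        return SegmentParams(omega_p, beta_p, theta.sigma2), True
    return theta, False


# ---------------------------------------------------------------------------
# trans-dimensional moves on the number of frequencies


def _seg_loglik_from_beta(omega, beta, sigma2, y_seg, times, hp) -> float:
    if hp.lik_weight == 0.0:
        return 0.0
    X = design_matrix(times, omega, hp.include_trend)
    resid = np.asarray(y_seg, dtype=float) - X @ beta
    return hp.lik_weight * gaussian_loglik(np.size(times), float(resid @ resid), sigma2)


def _birth_freq_logq(omega_new: float, hp: Hyperparams, pdist: FrequencyProposalDist) -> float:
    """Density of the newborn-frequency proposal: Uniform(0, f_max) optionally
    mixed with the periodogram draw."""
    wb = hp.birth_pgram_weight
    log_unif = -math.log(hp.f_max)
    if wb == 0.0:
        return log_unif
    lp = pdist.pgram_logpdf(omega_new)
    m = max(log_unif + math.log1p(-wb), lp + math.log(wb))
    return m + math.log(
        math.exp(log_unif + math.log1p(-wb) - m) + math.exp(lp + math.log(wb) - m)
    )


def _sample_birth_freq(hp: Hyperparams, pdist: FrequencyProposalDist, rng) -> float:
    if hp.birth_pgram_weight > 0.0 and rng.random() < hp.birth_pgram_weight:
        l = rng.choice(pdist.fourier_grid.size, p=pdist.weights)
        return reflect(pdist.fourier_grid[l] + pdist.kde_sd * rng.standard_normal(), pdist.f_max)
    return hp.f_max * rng.random()


def freq_birth_log_acceptance(
    theta_lo: SegmentParams,
    theta_hi: SegmentParams,
    w_new: float,
    y_seg: np.ndarray,
    times: np.ndarray,
    hp: Hyperparams,
    pdist: FrequencyProposalDist,
) -> float:
    """Log M-H acceptance ratio of the frequency birth theta_lo -> theta_hi.

    ``theta_hi`` holds one more sinusoid (the one at ``w_new``); its
    coefficients and variance are treated as re-proposed from their full
    conditionals (beta at the other state's variance, then sigma2 given
    beta), and the reverse-path densities are evaluated the same way, so the
    matched death ratio is exactly the negative of this value.  The
    removal-selection and sorted-insertion position factors cancel under the
    iid-uniform frequency prior and are omitted.
    """
    y_seg = np.asarray(y_seg, dtype=float)
    m_lo = theta_lo.m
    b_lo, _ = move_probabilities(m_lo, hp.lambda_omega, 1, hp.m_max, hp.c)
    _, d_hi = move_probabilities(m_lo + 1, hp.lambda_omega, 1, hp.m_max, hp.c)

    # forward-path densities: beta_hi | sigma2_lo, then sigma2_hi | beta_hi
    mean_hi, L_hi, _ = beta_full_conditional(theta_hi.omega, theta_lo.sigma2, y_seg, times, hp)
    logq_beta_hi = beta_logpdf(theta_hi.beta, mean_hi, L_hi)
    logq_sig_hi = _sigma2_logq(theta_hi.omega, theta_hi.beta, y_seg, times, hp, theta_hi.sigma2)
    # reverse-path densities: beta_lo | sigma2_hi, then sigma2_lo | beta_lo
    mean_lo, L_lo, _ = beta_full_conditional(theta_lo.omega, theta_hi.sigma2, y_seg, times, hp)
    logq_beta_lo = beta_logpdf(theta_lo.beta, mean_lo, L_lo)
    logq_sig_lo = _sigma2_logq(theta_lo.omega, theta_lo.beta, y_seg, times, hp, theta_lo.sigma2)

    delta_post = (
        _seg_loglik_from_beta(theta_hi.omega, theta_hi.beta, theta_hi.sigma2, y_seg, times, hp)
        + segment_log_prior(theta_hi, hp)
        - _seg_loglik_from_beta(theta_lo.omega, theta_lo.beta, theta_lo.sigma2, y_seg, times, hp)
        - segment_log_prior(theta_lo, hp)
    )
    return (
        delta_post
        + math.log(d_hi) - math.log(b_lo)
        - _birth_freq_logq(w_new, hp, pdist)
        + logq_beta_lo + logq_sig_lo - logq_beta_hi - logq_sig_hi
    )


def birth_frequency(
    theta: SegmentParams,
    y_seg: np.ndarray,
    times: np.ndarray,
    hp: Hyperparams,
    rng: np.random.Generator,
    pdist: FrequencyProposalDist | None = None,
    min_sep: float | None = None,
) -> tuple[SegmentParams, bool]:
    """Propose adding one sinusoid; returns (new-or-current params, accepted).

    The coefficients and variance are re-proposed from their full
    conditionals, whose densities enter the ratio together with the move
    probabilities.
    """
    m = theta.m
    if m >= hp.m_max:
        return theta, False
    y_seg = np.asarray(y_seg, dtype=float)
    if pdist is None:
        pdist = make_proposal_dist(y_seg, hp)
    sep = min_frequency_separation(y_seg.size) if min_sep is None else min_sep
    w_new = _sample_birth_freq(hp, pdist, rng)
    if not (0.0 < w_new < pdist.f_max) or np.min(np.abs(theta.omega - w_new)) < sep:
        return theta, False  # auto-reject (hard-core constraint)
    omega_p = np.sort(np.append(theta.omega, w_new))
    beta_p, _ = sample_beta(omega_p, theta.sigma2, y_seg, times, hp, rng)
    sigma2_p, _, _ = sample_sigma2(omega_p, beta_p, y_seg, times, hp, rng)
    prop = SegmentParams(omega_p, beta_p, sigma2_p)
    log_a = freq_birth_log_acceptance(theta, prop, w_new, y_seg, times, hp, pdist)
    if log_a >= 0.0 or math.log(rng.random()) < log_a:
        return prop, True
    return theta, False


def death_frequency(
    theta: SegmentParams,
    y_seg: np.ndarray,
    times: np.ndarray,
    hp: Hyperparams,
    rng: np.random.Generator,
    pdist: FrequencyProposalDist | None = None,
    min_sep: float | None = None,
) -> tuple[SegmentParams, bool]:
    """Propose removing one uniformly chosen sinusoid; the acceptance ratio
    is the exact reciprocal of the matched birth construction."""
    m = theta.m
    if m <= 1:
        return theta, False
    y_seg = np.asarray(y_seg, dtype=float)
    if pdist is None:
        pdist = make_proposal_dist(y_seg, hp)
    idx = int(rng.integers(m))
    w_rm = float(theta.omega[idx])
    omega_p = np.delete(theta.omega, idx)
    beta_p, _ = sample_beta(omega_p, theta.sigma2, y_seg, times, hp, rng)
    sigma2_p, _, _ = sample_sigma2(omega_p, beta_p, y_seg, times, hp, rng)
    prop = SegmentParams(omega_p, beta_p, sigma2_p)
    log_a = -freq_birth_log_acceptance(prop, theta, w_rm, y_seg, times, hp, pdist)
    if log_a >= 0.0 or math.log(rng.random()) < log_a:
        return prop, True
    return theta, False


# ---------------------------------------------------------------------------
# dispatch


def segment_move(
    theta: SegmentParams,
    y_seg: np.ndarray,
    times: np.ndarray,
    hp: Hyperparams,
    rng: np.random.Generator,
    pdist: FrequencyProposalDist | None = None,
    min_sep: float | None = None,
) -> tuple[SegmentParams, str, bool]:
    """One segment-model move: birth, death or within, chosen with the
    dimension-dependent probabilities (b_m, d_m)."""
    b_m, d_m = move_probabilities(theta.m, hp.lambda_omega, 1, hp.m_max, hp.c)
    u = rng.random()
    if u <= b_m:
        theta, acc = birth_frequency(theta, y_seg, times, hp, rng, pdist, min_sep)
        return theta, "seg_birth", acc
    if u <= b_m + d_m:
        theta, acc = death_frequency(theta, y_seg, times, hp, rng, pdist, min_sep)
        return theta, "seg_death", acc
    theta, n_acc = update_frequencies_within(theta, y_seg, times, hp, rng, pdist, min_sep)
    theta, joint_acc = update_frequency_beta_joint(theta, y_seg, times, hp, rng, pdist, min_sep)
    beta, _ = sample_beta(theta.omega, theta.sigma2, y_seg, times, hp, rng)
    sigma2, _, _ = sample_sigma2(theta.omega, beta, y_seg, times, hp, rng)
    return SegmentParams(theta.omega, beta, sigma2), "seg_within", (n_acc > 0 or joint_acc)
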