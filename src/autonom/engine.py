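"""Sampler driver and posterior summaries.

One iteration performs a segment-model move on each of the k+1 segments
(frequency M-H sweep + conjugate Gibbs updates, or a frequency birth/death)
followed by one change-point model move (relocation, split or merge).  The
retained post-burn-in states form the trace from which every reported summary
is computed: model probabilities, conditional change-point and frequency
posteriors, per-sinusoid power and phase, the fitted signal with its credible
band, and the time-varying spectral peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    Hyperparams,
    ModelState,
    SegmentParams,
    TimeSeriesData,
    design_matrix,
    min_frequency_separation,
    segment_ranges,
)
from .segment_sampler import (
    _seg_loglik_from_beta,
    beta_full_conditional,
    draw_beta,
    make_proposal_dist,
    segment_move,
)
from .changepoint_sampler import changepoint_move

__all__ = [
    "PosteriorTrace",
    "PosteriorSummary",
    "initialize_state",
    "run_sampler",
    "model_probabilities",
    "changepoint_posterior",
    "frequency_posterior",
    "power",
    "phase",
    "fitted_signal",
    "time_varying_peak",
    "peak_rss",
    "summarize",
]


# ---------------------------------------------------------------------------
# trace containers


@dataclass
class PosteriorTrace:
    """Retained MCMC output.

    ``snapshots`` holds one entry per retained iteration:
    ``(k, s, [(omega, beta, sigma2), ...], total_loglik)``.
    ``loglik_path`` is the total log-likelihood at every iteration including
    burn-in (the convergence diagnostic).  ``acceptance`` maps move labels to
    ``[attempts, accepts]``.
    """

    n: int
    hp: Hyperparams
    n_iter: int
    burn_in: int
    thin: int
    snapshots: list = field(default_factory=list)
    loglik_path: np.ndarray | None = None
    acceptance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snapshots)

    @property
    def k_samples(self) -> np.ndarray:
        return np.array([snap[0] for snap in self.snapshots], dtype=int)

    def acceptance_rates(self) -> dict:
        return {
            lab: (a[1] / a[0] if a[0] else float("nan"))
            for lab, a in sorted(self.acceptance.items())
        }


# ---------------------------------------------------------------------------
# initialization and the main loop


def _init_segment(y: np.ndarray, times: np.ndarray, hp: Hyperparams,
                  rng: np.random.Generator | None) -> tuple[SegmentParams, float]:
    """One-sinusoid segment at the local periodogram argmax; coefficients and
    variance from their conditionals (posterior-mean plug-ins when rng is
    None, Gibbs draws otherwise)."""
    pdist = make_proposal_dist(y, hp)
    omega = np.array([float(pdist.fourier_grid[int(np.argmax(pdist.weights))])])
    sigma2_0 = float(np.var(y)) or 1.0
    mean, L, X = beta_full_conditional(omega, sigma2_0, y, times, hp)
    beta = mean if rng is None else draw_beta(mean, L, rng)[0]
    if X is None:  # prior-sampling mode: vague Inverse-Gamma draw
        a, b = 0.5 * hp.nu0, 0.5 * hp.gamma0
    else:
        resid = y - X @ beta
        a, b = 0.5 * (y.size + hp.nu0), 0.5 * (hp.gamma0 + float(resid @ resid))
    from .segment_sampler import _gamma_draw

    sigma2 = b / max(a - 1.0, 0.5) if rng is None else b / _gamma_draw(a, rng)
    seg = SegmentParams(omega, beta, sigma2)
    return seg, _seg_loglik_from_beta(omega, beta, sigma2, y, times, hp)


def _segment_evidence(y: np.ndarray, times: np.ndarray, hp: Hyperparams) -> float:
    """Coefficient-marginalized log-evidence of a one-sinusoid fit.

    The periodogram-argmax frequency and an iterated residual-variance
    plug-in are used; the Gaussian coefficient integral is exact, so the
    score carries the same dimensionality penalty the sampler's acceptance
    ratios do.  Used only to rank initial partitions.
    """
    pdist = make_proposal_dist(y, hp)
    omega = np.array([float(pdist.fourier_grid[int(np.argmax(pdist.weights))])])
    n = y.size
    sigma2 = float(np.var(y)) or 1.0
    for _ in range(2):  # plug-in iteration for the residual variance
        mean, _, X = beta_full_conditional(omega, sigma2, y, times, hp)
        resid = y - X @ mean
        sigma2 = (float(resid @ resid) + hp.gamma0) / (n + hp.nu0 + 2.0)
    mean, L, X = beta_full_conditional(omega, sigma2, y, times, hp)
    p = mean.size
    # log |I + (sb2/s2) X'X| via chol(P), P = X'X/s2 + I/sb2
    logdet = 2.0 * float(np.log(np.diag(L)).sum()) + p * math.log(hp.sigma_beta2)
    quad = float(y @ y) / sigma2 - float(mean @ ((X.T @ X) @ mean)) / sigma2 \
        - float(mean @ mean) / hp.sigma_beta2
    out = -0.5 * n * math.log(2.0 * math.pi * sigma2) - 0.5 * logdet - 0.5 * quad
    from .model import invgamma_logpdf, log_prior_dimension

    out += invgamma_logpdf(sigma2, 0.5 * hp.nu0, 0.5 * hp.gamma0)
    out += math.log(2.0) + log_prior_dimension(1, hp.lambda_omega, 1, hp.m_max)
    return out


def initialize_state(
    data: TimeSeriesData, hp: Hyperparams, rng: np.random.Generator,
    k_init: int | str = 0,
) -> ModelState:
    """Data-driven start.

    The default ``k_init=0`` starts from a single segment with one sinusoid
    at the global periodogram argmax, coefficients from their full
    conditional and a Gibbs-drawn variance — the standard cold start from
    which the sampler grows structure.  An integer forces that many equally
    spaced change-points (one local-argmax sinusoid each).  With
    ``k_init="auto"`` equal-split candidate partitions are scored by a
    coefficient-marginalized plug-in evidence and the best (plus a small
    over-partitioning margin that merge moves can trim) is taken; on
    strongly misspecified data this explores basins the rare birth moves
    reach only slowly, and correspondingly may find more change-points than
    a cold start would within the same run length.
    """
    from .model import log_prior_changepoint_locations, log_prior_dimension

    n = data.n
    cap = int(min(hp.k_max, n // max(2.0 * hp.psi_s, 2.0)))
    candidates = [int(k_init)] if k_init != "auto" else list(range(cap + 1))
    best: tuple[float, int] | None = None
    for k in candidates:
        s = np.linspace(1.0, float(n), k + 2)[1:-1]
        ranges = segment_ranges(s, n)
        if any(hi - lo + 1 < 4 for lo, hi in ranges):
            continue
        score = (
            log_prior_dimension(k, hp.lambda_s, 0, hp.k_max)
            + log_prior_changepoint_locations(s, n)
        )
        if hp.lik_weight != 0.0:
            for lo, hi in ranges:
                t = np.arange(lo, hi + 1, dtype=float)
                score += hp.lik_weight * _segment_evidence(data.values[lo - 1: hi], t, hp)
        if best is None or score > best[0]:
            best = (score, k)
    assert best is not None
    k_start = best[1]
    if k_init == "auto" and hp.lik_weight != 0.0:
        # over-partition slightly: merges of superfluous segments are easy
        # for the sampler, while one-shot splits of an adapted segment are
        # rare, so the posterior mode is best approached from above
        k_start = min(cap, k_start + 3)
    s = np.linspace(1.0, float(n), k_start + 2)[1:-1]
    segs, lls = [], []
    for lo, hi in segment_ranges(s, n):
        t = np.arange(lo, hi + 1, dtype=float)
        seg, ll = _init_segment(data.values[lo - 1: hi], t, hp, rng=rng)
        segs.append(seg)
        lls.append(ll)
    return ModelState(s, segs, n, np.array(lls))


def _segment_views(data: TimeSeriesData, state: ModelState, hp: Hyperparams):
    """(y, times, proposal dist) per segment for the current partition."""
    views = []
    for lo, hi in segment_ranges(state.s, data.n):
        y = data.values[lo - 1: hi]
        t = np.arange(lo, hi + 1, dtype=float)
        views.append((y, t, make_proposal_dist(y, hp)))
    return views


def run_sampler(
    data: TimeSeriesData,
    hp: Hyperparams,
    n_iter: int,
    burn_in: int = 0,
    rng: np.random.Generator | int | None = None,
    thin: int = 1,
    init_state: ModelState | None = None,
    k_init: int | str = 0,
    check_every: int = 0,
    log_every: int = 0,
    log_fn=print,
) -> PosteriorTrace:
    """Run the trans-dimensional sampler and return the retained trace.

    Fully reproducible given an integer seed or a Generator.  ``check_every``
    > 0 re-validates the state invariants and the cached per-segment
    log-likelihoods against a fresh recomputation every that many iterations
    (debug mode).
    """
    if not (n_iter > burn_in >= 0):
        raise ValueError("need n_iter > burn_in >= 0")
    if data.n < 2 * hp.psi_s:
        # change-point birth is impossible; allowed, but flag absurd configs
        if hp.k_max > 0 and data.n < hp.psi_s:
            raise ValueError("series shorter than the minimum segment length psi_s")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(hp.seed if rng is None else int(rng))

    state = init_state.copy() if init_state is not None else initialize_state(data, hp, rng, k_init)
    state.validate(hp)
    if state.loglik is None:
        views0 = _segment_views(data, state, hp)
        state.loglik = np.array([
            _seg_loglik_from_beta(sg.omega, sg.beta, sg.sigma2, y, t, hp)
            for (y, t, _), sg in zip(views0, state.segments)
        ])
    min_sep = min_frequency_separation(data.n)
    views = _segment_views(data, state, hp)

    trace = PosteriorTrace(n=data.n, hp=hp, n_iter=n_iter, burn_in=burn_in, thin=thin)
    acc: dict[str, list[int]] = {}
    loglik_path = np.empty(n_iter)

    for it in range(n_iter):
        for j, seg in enumerate(state.segments):
            y, t, pdist = views[j]
            theta, label, accepted = segment_move(seg, y, t, hp, rng, pdist, min_sep)
            state.segments[j] = theta
            state.loglik[j] = _seg_loglik_from_beta(
                theta.omega, theta.beta, theta.sigma2, y, t, hp
            )
            a = acc.setdefault(label, [0, 0])
            a[0] += 1
            a[1] += int(accepted)
        state, label, accepted = changepoint_move(state, data, hp, rng)
        a = acc.setdefault(label, [0, 0])
        a[0] += 1
        a[1] += int(accepted)
        if accepted:
            views = _segment_views(data, state, hp)
        total_ll = float(state.loglik.sum())
        loglik_path[it] = total_ll
        if it >= burn_in and (it - burn_in) % thin == 0:
            trace.snapshots.append((
                state.k,
                state.s.copy(),
                [(sg.omega.copy(), sg.beta.copy(), sg.sigma2) for sg in state.segments],
                total_ll,
            ))
        if check_every and (it + 1) % check_every == 0:
            state.validate(hp)
            for j, ((y, t, _), sg) in enumerate(zip(views, state.segments)):
                fresh = _seg_loglik_from_beta(sg.omega, sg.beta, sg.sigma2, y, t, hp)
                if not math.isclose(fresh, float(state.loglik[j]), rel_tol=1e-9, abs_tol=1e-7):
                    raise AssertionError(
                        f"cached log-likelihood drifted in segment {j}: "
                        f"{state.loglik[j]} vs fresh {fresh}"
                    )
        if log_every and (it + 1) % log_every == 0:
            rates = ", ".join(f"{k_}={v[1] / v[0]:.2f}" for k_, v in sorted(acc.items()) if v[0])
            log_fn(f"iter {it + 1}/{n_iter}  k={state.k}  loglik={total_ll:.2f}  acc[{rates}]")

    trace.loglik_path = loglik_path
    trace.acceptance = acc
    return trace


# ---------------------------------------------------------------------------
# summaries


def model_probabilities(trace: PosteriorTrace) -> dict:
    """Posterior table of k and, conditional on the modal k, of each m_j."""
    if not len(trace):
        raise ValueError("empty trace")
    ks = trace.k_samples
    vals, counts = np.unique(ks, return_counts=True)
    k_probs = {int(v): float(c) / ks.size for v, c in zip(vals, counts)}
    k_mode = int(vals[np.argmax(counts)])
    sel = [snap for snap in trace.snapshots if snap[0] == k_mode]
    m_tables = []
    for j in range(k_mode + 1):
        ms = np.array([len(snap[2][j][0]) for snap in sel])
        mv, mc = np.unique(ms, return_counts=True)
        m_tables.append({int(v): float(c) / ms.size for v, c in zip(mv, mc)})
    return {"k": k_probs, "k_mode": k_mode, "m_given_k_mode": m_tables}


def changepoint_posterior(trace: PosteriorTrace, k_cond: int) -> dict:
    """Componentwise mean/sd (and raw samples) of the ordered locations,
    over snapshots with exactly ``k_cond`` change-points."""
    samples = np.array([snap[1] for snap in trace.snapshots if snap[0] == k_cond])
    if samples.size == 0:
        return {"k": k_cond, "n_samples": 0, "mean": [], "sd": [], "samples": samples}
    return {
        "k": k_cond,
        "n_samples": samples.shape[0],
        "mean": samples.mean(axis=0).tolist(),
        "sd": samples.std(axis=0, ddof=0).tolist(),
        "samples": samples,
    }


def _select(trace: PosteriorTrace, k_cond: int, m_cond: Sequence[int] | None):
    for snap in trace.snapshots:
        if snap[0] != k_cond:
            continue
        if m_cond is not None and any(
            len(snap[2][j][0]) != m_cond[j] for j in range(k_cond + 1)
        ):
            continue
        yield snap


def frequency_posterior(
    trace: PosteriorTrace, k_cond: int, m_cond: Sequence[int]
) -> list[dict]:
    """Per-segment, per-sinusoid summaries conditional on (k, m_1..m_{k+1}).

    Within qualifying snapshots each segment's sorted frequency vector is
    matched componentwise by rank; summaries per rank are the mean, sd and
    2.5/97.5 percentiles, plus the posterior mean power and (circular mean)
    phase of the corresponding coefficient pair.
    """
    sel = list(_select(trace, k_cond, m_cond))
    if not sel:
        raise ValueError("no snapshots satisfy the conditioning")
    out = []
    for j in range(k_cond + 1):
        om = np.array([snap[2][j][0] for snap in sel])  # (q, m_j)
        betas = [snap[2][j][1] for snap in sel]
        off = betas[0].size - 2 * m_cond[j]
        pw = np.array([[power((b[off + 2 * l], b[off + 2 * l + 1])) for l in range(m_cond[j])]
                       for b in betas])
        ph = np.array([[phase((b[off + 2 * l], b[off + 2 * l + 1])) for l in range(m_cond[j])]
                       for b in betas])
        out.append({
            "m": m_cond[j],
            "n_samples": om.shape[0],
            "mean": om.mean(axis=0).tolist(),
            "sd": om.std(axis=0, ddof=0).tolist(),
            "q2.5": np.percentile(om, 2.5, axis=0).tolist(),
            "q97.5": np.percentile(om, 97.5, axis=0).tolist(),
            "power_mean": pw.mean(axis=0).tolist(),
            "phase_mean": np.arctan2(np.sin(ph).mean(axis=0), np.cos(ph).mean(axis=0)).tolist(),
        })
    return out


def power(beta_pair) -> float:
    """Power of one sinusoid: squared amplitude b1^2 + b2^2."""
    b1, b2 = beta_pair
    return float(b1 * b1 + b2 * b2)


def phase(beta_pair) -> float:
    """Phase phi in (-pi, pi] such that b1 cos + b2 sin = A cos(2 pi w t - phi).

    Undefined at zero power (raises)."""
    b1, b2 = beta_pair
    if b1 == 0.0 and b2 == 0.0:
        raise ValueError("phase undefined at zero power")
    return float(math.atan2(b2, b1))


def _signal_of_snapshot(snap, n: int, include_trend: bool) -> np.ndarray:
    out = np.empty(n)
    for (lo, hi), (omega, beta, _) in zip(segment_ranges(snap[1], n), snap[2]):
        t = np.arange(lo, hi + 1, dtype=float)
        out[lo - 1: hi] = design_matrix(t, omega, include_trend) @ beta
    return out


def fitted_signal(
    trace: PosteriorTrace,
    data: TimeSeriesData,
    k_cond: int | None = None,
    max_snapshots: int = 2000,
) -> dict:
    """Pointwise posterior mean and 2.5/97.5 percentile band of the piecewise
    mean function, across (optionally k-conditioned, evenly thinned)
    snapshots."""
    snaps = trace.snapshots if k_cond is None else [
        s for s in trace.snapshots if s[0] == k_cond
    ]
    if not snaps:
        raise ValueError("no qualifying snapshots")
    if len(snaps) > max_snapshots:
        idx = np.linspace(0, len(snaps) - 1, max_snapshots).astype(int)
        snaps = [snaps[i] for i in idx]
    sig = np.stack([
        _signal_of_snapshot(s, data.n, trace.hp.include_trend) for s in snaps
    ])
    return {
        "mean": sig.mean(axis=0),
        "lower": np.percentile(sig, 2.5, axis=0),
        "upper": np.percentile(sig, 97.5, axis=0),
    }


def time_varying_peak(trace: PosteriorTrace, n: int) -> np.ndarray:
    """Across-snapshot average of the per-time maximal-power frequency.

    Per snapshot and time point the peak is the frequency with the largest
    power in the segment containing t; averaging over the trace yields a
    smooth estimate that need not be piecewise constant.
    """
    if not len(trace):
        raise ValueError("empty trace")
    total = np.zeros(n)
    for snap in trace.snapshots:
        for (lo, hi), (omega, beta, _) in zip(segment_ranges(snap[1], n), snap[2]):
            off = beta.size - 2 * omega.size
            pw = beta[off::2] ** 2 + beta[off + 1::2] ** 2
            total[lo - 1: hi] += omega[int(np.argmax(pw))]
    return total / len(trace)


def peak_rss(true_track: np.ndarray, est_track: np.ndarray) -> float:
    """Residual sum of squares sum_t (w_t - w_hat_t)^2 between peak tracks."""
    d = np.asarray(true_track, dtype=float) - np.asarray(est_track, dtype=float)
    return float(d @ d)


@dataclass
class PosteriorSummary:
    """All standard posterior summaries, conditioned on the modal model."""

    k_probs: dict
    k_mode: int
    m_tables: list
    m_mode: tuple
    changepoints: dict
    frequencies: list
    fitted: dict | None
    acceptance: dict

    def to_dict(self) -> dict:
        cp = {kk: vv for kk, vv in self.changepoints.items() if kk != "samples"}
        out = {
            "k_probs": {str(kk): vv for kk, vv in self.k_probs.items()},
            "k_mode": self.k_mode,
            "m_given_k_mode": [{str(kk): vv for kk, vv in t.items()} for t in self.m_tables],
            "m_mode": list(self.m_mode),
            "changepoints": cp,
            "frequencies": self.frequencies,
            "acceptance": self.acceptance,
        }
        if self.fitted is not None:
            out["fitted_signal"] = {kk: np.asarray(vv).tolist() for kk, vv in self.fitted.items()}
        return out


def summarize(
    trace: PosteriorTrace, data: TimeSeriesData | None = None, with_signal: bool = True
) -> PosteriorSummary:
    """Condition on the modal k, then the modal m per segment, as in the
    standard reporting convention, and collect every summary table."""
    mp = model_probabilities(trace)
    k_mode = mp["k_mode"]
    m_mode = tuple(max(t, key=t.get) for t in mp["m_given_k_mode"])
    cp = changepoint_posterior(trace, k_mode)
    freqs = frequency_posterior(trace, k_mode, m_mode)
    fitted = None
    if with_signal and data is not None:
        fitted = fitted_signal(trace, data, k_cond=k_mode)
    return PosteriorSummary(
        k_probs=mp["k"],
        k_mode=k_mode,
        m_tables=mp["m_given_k_mode"],
        m_mode=m_mode,
        changepoints=cp,
        frequencies=freqs,
        fitted=fitted,
        acceptance=trace.acceptance_rates(),
    )
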