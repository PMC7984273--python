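"""Scikit-learn style estimator facade over the sampling engine."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import engine
from .model import Hyperparams, TimeSeriesData

__all__ = ["AutoNOM"]


class AutoNOM(BaseEstimator):
    """Automatic nonstationary oscillatory modelling of a univariate series.

    Fits a piecewise sinusoidal regression with an unknown number of
    change-points and an unknown number of sinusoids per segment by
    trans-dimensional MCMC.  ``fit`` runs the sampler; the posterior is then
    available through trailing-underscore attributes and ``predict`` returns
    the posterior-mean signal conditional on the modal model.

    Parameters mirror the sampler hyperparameters: truncated-Poisson prior
    means ``lambda_s`` (change-points) and ``lambda_omega`` (sinusoids per
    segment), caps ``k_max``/``m_max``, diffuse coefficient prior variance
    ``sigma_beta2``, Inverse-Gamma(nu0/2, gamma0/2) variance prior, move
    constant ``c``, minimum change-point separation ``psi_s`` (samples),
    frequency-birth upper bound ``phi_omega`` (cycles/sample), and the
    proposal-scale knobs.  ``n_iter``/``burn_in``/``thin`` set the protocol.

    Examples
    --------
    >>> from autonom import AutoNOM, simulate_piecewise_ar
    >>> data, truth = simulate_piecewise_ar(rng=1)
    >>> model = AutoNOM(n_iter=2000, burn_in=500, lambda_s=0.01,
    ...                 lambda_omega=0.05, psi_s=40, phi_omega=0.5,
    ...                 random_state=0).fit(data.values)
    >>> model.k_mode_  # doctest: +SKIP
    2
    """

    def __init__(
        self,
        n_iter: int = 20000,
        burn_in: int = 5000,
        thin: int = 1,
        lambda_s: float = 2.0,
        lambda_omega: float = 2.0,
        k_max: int = 15,
        m_max: int = 10,
        sigma_beta2: float = 1.0e6,
        nu0: float = 0.01,
        gamma0: float = 0.01,
        c: float = 0.4,
        psi_s: float = 20.0,
        phi_omega: float = 0.25,
        include_trend: bool = True,
        freq_mix_rw: float = 0.8,
        freq_rw_sd: float | None = None,
        pgram_kde_sd: float | None = None,
        birth_pgram_weight: float = 0.0,
        cp_rw_sd: float = 15.0,
        cp_mix_rw: float = 0.75,
        cp_freq_jitter_sd: float | None = None,
        random_state: int | None = None,
    ) -> None:
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.lambda_s = lambda_s
        self.lambda_omega = lambda_omega
        self.k_max = k_max
        self.m_max = m_max
        self.sigma_beta2 = sigma_beta2
        self.nu0 = nu0
        self.gamma0 = gamma0
        self.c = c
        self.psi_s = psi_s
        self.phi_omega = phi_omega
        self.include_trend = include_trend
        self.freq_mix_rw = freq_mix_rw
        self.freq_rw_sd = freq_rw_sd
        self.pgram_kde_sd = pgram_kde_sd
        self.birth_pgram_weight = birth_pgram_weight
        self.cp_rw_sd = cp_rw_sd
        self.cp_mix_rw = cp_mix_rw
        self.cp_freq_jitter_sd = cp_freq_jitter_sd
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _hyperparams(self) -> Hyperparams:
        return Hyperparams(
            lambda_s=self.lambda_s,
            lambda_omega=self.lambda_omega,
            k_max=self.k_max,
            m_max=self.m_max,
            sigma_beta2=self.sigma_beta2,
            nu0=self.nu0,
            gamma0=self.gamma0,
            c=self.c,
            psi_s=self.psi_s,
            phi_omega=self.phi_omega,
            include_trend=self.include_trend,
            freq_mix_rw=self.freq_mix_rw,
            freq_rw_sd=self.freq_rw_sd,
            pgram_kde_sd=self.pgram_kde_sd,
            birth_pgram_weight=self.birth_pgram_weight,
            cp_rw_sd=self.cp_rw_sd,
            cp_mix_rw=self.cp_mix_rw,
            cp_freq_jitter_sd=self.cp_freq_jitter_sd,
            seed=self.random_state,
        )

    @staticmethod
    def _as_series(X) -> TimeSeriesData:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 1:
            arr = arr[:, 0]
        if arr.ndim != 1:
            raise ValueError("expected a 1-D series or a single-column array")
        return TimeSeriesData(arr)

    def fit(self, X, y=None) -> "AutoNOM":
        """Run the sampler on the series ``X`` (1-D or single column)."""
        data = self._as_series(X)
        hp = self._hyperparams()
        self.trace_ = engine.run_sampler(
            data, hp, self.n_iter, self.burn_in, rng=self.random_state, thin=self.thin
        )
        self._data_ = data
        summary = engine.summarize(self.trace_, data, with_signal=False)
        self.summary_ = summary
        self.k_probs_ = summary.k_probs
        self.k_mode_ = summary.k_mode
        self.m_mode_ = summary.m_mode
        self.changepoints_ = np.asarray(summary.changepoints["mean"], dtype=float)
        self.changepoint_sds_ = np.asarray(summary.changepoints["sd"], dtype=float)
        self.frequencies_ = [np.asarray(f["mean"]) for f in summary.frequencies]
        self.loglik_path_ = self.trace_.loglik_path
        self.n_features_in_ = 1
        return self

    def predict(self, X=None) -> np.ndarray:
        """Posterior-mean fitted signal at the observed times, conditional on
        the modal number of change-points (``X`` is ignored; present for API
        compatibility)."""
        if not hasattr(self, "trace_"):
            raise AttributeError("call fit first")
        fitted = engine.fitted_signal(self.trace_, self._data_, k_cond=self.k_mode_)
        return fitted["mean"]

    def credible_band(self) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise 95% credible band of the fitted signal."""
        if not hasattr(self, "trace_"):
            raise AttributeError("call fit first")
        fitted = engine.fitted_signal(self.trace_, self._data_, k_cond=self.k_mode_)
        return fitted["lower"], fitted["upper"]
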