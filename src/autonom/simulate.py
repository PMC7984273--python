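"""Synthetic processes for testing and benchmarking.

Three generators: the piecewise sinusoid-plus-noise process the model assumes
(with Gaussian or Student-t errors), a three-regime piecewise autoregressive
process with sharply peaked local spectra, and a slowly varying AR(2) process
whose spectral peak drifts continuously — the latter two deliberately violate
the model's assumptions.  Every generator is seed-deterministic and returns
its ground truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import TimeSeriesData, design_matrix

__all__ = [
    "SimulationSpec",
    "illustrative_spec",
    "simulate_piecewise_sinusoid",
    "simulate_piecewise_ar",
    "simulate_slowly_varying_ar",
    "ar2_peak_frequency",
    "ar_peak_frequency",
    "PIECEWISE_AR_LENGTH",
    "SLOWLY_VARYING_AR_LENGTH",
]

PIECEWISE_AR_LENGTH = 550
SLOWLY_VARYING_AR_LENGTH = 1031


# ---------------------------------------------------------------------------
# piecewise sinusoid


@dataclass
class SimulationSpec:
    """Configuration of a piecewise-sinusoid simulation.

    ``segments`` is a list of dicts with keys ``omega`` (frequencies),
    ``beta`` (coefficients, ordered intercept[, slope], cos/sin pairs),
    ``sigma`` (noise sd) and optionally ``df`` (Student-t degrees of freedom;
    omit for Gaussian errors).
    """

    n: int
    changepoints: list = field(default_factory=list)
    segments: list = field(default_factory=list)
    include_trend: bool = False
    kind: str = "piecewise-sinusoid"

    def __post_init__(self) -> None:
        cps = np.asarray(self.changepoints, dtype=float)
        if cps.size and not (np.all(np.diff(cps) > 0) and cps[0] > 1 and cps[-1] < self.n):
            raise ValueError("change-points must be sorted strictly inside (1, n)")
        if len(self.segments) != cps.size + 1:
            raise ValueError("need one segment spec per regime")


def illustrative_spec(unit_variance: bool = True, t_errors: bool = False) -> SimulationSpec:
    """The standard three-regime fixture: n = 900, change-points (300, 650),
    m = (3, 1, 2) sinusoids with frequencies (0.042, 0.067, 0.143), (0.083)
    and (0.046, 0.067), unit cos/sin coefficients, zero intercept, no trend.

    ``unit_variance`` keeps all noise sds at 1; ``t_errors`` switches to
    Student-t errors with (2, 3, 2) degrees of freedom.
    """
    freqs = [(0.042, 0.067, 0.143), (0.083,), (0.046, 0.067)]
    dfs = (2, 3, 2)
    segments = []
    for j, om in enumerate(freqs):
        seg = {
            "omega": list(om),
            "beta": [0.0] + [1.0] * (2 * len(om)),
            "sigma": 1.0 if unit_variance else 2.0,
        }
        if t_errors:
            seg["df"] = dfs[j]
        segments.append(seg)
    return SimulationSpec(n=900, changepoints=[300, 650], segments=segments)


def simulate_piecewise_sinusoid(
    spec: SimulationSpec, rng: np.random.Generator | int | None = None
) -> tuple[TimeSeriesData, dict]:
    """Piecewise harmonic mean plus independent noise; returns the series and
    a ground-truth dict (noiseless signal, change-points, per-segment
    frequencies)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = spec.n
    bounds = np.concatenate(([1.0], np.asarray(spec.changepoints, dtype=float), [float(n)]))
    signal = np.empty(n)
    noise = np.empty(n)
    for j, seg in enumerate(spec.segments):
        lo = math.ceil(bounds[j])
        hi = n if j == len(spec.segments) - 1 else math.ceil(bounds[j + 1]) - 1
        t = np.arange(lo, hi + 1, dtype=float)
        X = design_matrix(t, np.asarray(seg["omega"], dtype=float), spec.include_trend)
        signal[lo - 1: hi] = X @ np.asarray(seg["beta"], dtype=float)
        if "df" in seg and seg["df"] is not None:
            eps = seg["sigma"] * rng.standard_t(seg["df"], size=t.size)
        else:
            eps = seg["sigma"] * rng.standard_normal(t.size)
        noise[lo - 1: hi] = eps
    truth = {
        "kind": spec.kind,
        "changepoints": list(map(float, spec.changepoints)),
        "frequencies": [list(map(float, seg["omega"])) for seg in spec.segments],
        "signal": signal,
    }
    return TimeSeriesData(signal + noise), truth


# ---------------------------------------------------------------------------
# autoregressive processes


_PW_AR_REGIMES = (
    # (coefficients, noise sd, last time index)
    ((1.9, -0.975), 0.5, 250),
    ((1.9, -0.991), 1.0, 400),
    ((-1.35, -0.37, 0.36), 1.0, 550),
)


def simulate_piecewise_ar(
    rng: np.random.Generator | int | None = None,
    presample: int = 1000,
    per_regime_presample: bool = False,
) -> tuple[TimeSeriesData, dict]:
    """The three-regime piecewise AR benchmark, n = 550.

    AR(2) (1.9, -0.975) with noise sd 0.5 for t = 1..250, AR(2) (1.9, -0.991)
    with unit noise for 251..400, AR(3) (-1.35, -0.37, 0.36) with unit noise
    for 401..550.  By default the presample burn-in runs once, before t = 1,
    and the single recursion then crosses the regime boundaries carrying its
    last values — the literal reading of the defining equations.  With
    ``per_regime_presample=True`` each regime start instead runs
    ``presample`` discarded steps of that regime's own recursion (seeded
    from the carried values), so every regime is observed at its stationary
    law; because the second regime's AR(2) has characteristic roots of
    modulus 0.9955 (relaxation time longer than the regime itself), that
    variant produces a much more violent middle regime whose internal
    amplitude bursts the piecewise model legitimately segments further.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    max_order = max(len(c) for c, _, _ in _PW_AR_REGIMES)
    buf = [0.0] * max_order  # most recent last
    y = np.empty(PIECEWISE_AR_LENGTH)
    t0 = 0
    for r, (coefs, sd, t_end) in enumerate(_PW_AR_REGIMES):
        if per_regime_presample or r == 0:
            for _ in range(presample):
                val = sum(c * buf[-1 - i] for i, c in enumerate(coefs)) \
                    + sd * rng.standard_normal()
                buf = buf[1:] + [val]
        for t in range(t0, t_end):
            val = sum(c * buf[-1 - i] for i, c in enumerate(coefs)) + sd * rng.standard_normal()
            buf = buf[1:] + [val]
            y[t] = val
        t0 = t_end
    truth = {
        "kind": "piecewise-ar",
        "changepoints": [251.0, 401.0],
        "peak_frequencies": [ar_peak_frequency(c) for c, _, _ in _PW_AR_REGIMES],
    }
    return TimeSeriesData(y), truth


def simulate_slowly_varying_ar(
    rng: np.random.Generator | int | None = None,
) -> tuple[TimeSeriesData, dict]:
    """Slowly varying AR(2): y_t = a_t y_{t-1} - 0.81 y_{t-2} + N(0, 1) with
    a_t = 0.8 [1 - 0.5 cos(pi t / 1031)], t = 1..1031.

    The returned truth includes the analytic time-varying spectral peak
    track derived from the AR(2) closed form.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = SLOWLY_VARYING_AR_LENGTH
    t = np.arange(1, n + 1)
    a = 0.8 * (1.0 - 0.5 * np.cos(math.pi * t / n))
    y = np.empty(n)
    prev1 = prev2 = 0.0
    eps = rng.standard_normal(n)
    for i in range(n):
        y[i] = a[i] * prev1 - 0.81 * prev2 + eps[i]
        prev2, prev1 = prev1, y[i]
    track = np.array([ar2_peak_frequency(ai, -0.81) for ai in a])
    truth = {"kind": "slowly-varying-ar", "a": a, "peak_track": track}
    return TimeSeriesData(y), truth


# ---------------------------------------------------------------------------
# AR spectral peaks


def ar2_peak_frequency(phi1: float, phi2: float) -> float:
    """Frequency (cycles/sample) maximizing the AR(2) spectral density.

    Closed form: cos(2 pi f*) = phi1 (1 - phi2) / (-4 phi2) when that value
    lies in [-1, 1]; otherwise the spectrum peaks at a band edge and the
    boundary argmax is returned.
    """
    if phi2 == 0.0:
        return 0.0 if phi1 > 0 else 0.5
    c = phi1 * (1.0 - phi2) / (-4.0 * phi2)
    if -1.0 <= c <= 1.0:
        return math.acos(c) / (2.0 * math.pi)
    return ar_peak_frequency((phi1, phi2))


def ar_peak_frequency(coefs, grid_size: int = 100_000) -> float:
    """Dense-grid argmax of an AR(p) spectral density on (0, 0.5)."""
    coefs = np.asarray(coefs, dtype=float)
    f = np.linspace(0.0, 0.5, grid_size)
    z = np.exp(-2j * np.pi * f)
    poly = np.ones_like(z)
    for i, c in enumerate(coefs, start=1):
        poly = poly - c * z**i
    dens = 1.0 / np.abs(poly) ** 2
    return float(f[int(np.argmax(dens))])
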