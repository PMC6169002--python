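"""Synthetic processes for estimator validation and study emulation.

Two families of generators live here:

* canonical stochastic processes with analytically (or semi-analytically)
  known mutual information / transfer entropy — bivariate Gaussians and
  coupled linear autoregressions — used as oracles for the nearest-neighbor
  estimators; and
* :func:`gen_cmc_recording`, a stimulus-locked LFP/EMG simulator that
  emulates the structure of in-vivo cortico-muscular recordings under pulsed
  ultrasound stimulation: a band-limited cortical oscillation plus 1/f
  background driving a delayed muscular response, weak ascending feedback,
  50 Hz mains contamination, slow baseline drift, and a tone-burst-count
  (NTB) dependent post-stimulation coupling gain.

All generators are deterministic given their seed: one
``numpy.random.default_rng`` stream is drawn from in a fixed order.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .protocols import StimProtocol, SynthConfig
from .recording import TimeSeriesRecording

__all__ = [
    "gen_bivariate_gaussian",
    "analytic_gaussian_mi",
    "gen_coupled_ar",
    "analytic_linear_te",
    "gen_cmc_recording",
]


def gen_bivariate_gaussian(
    n: int, rho: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` i.i.d. samples from a standard bivariate Gaussian with
    correlation ``rho``.

    Built from two independent standard normal streams via the Cholesky
    factor, so the marginals are exactly standard normal.
    """
    if abs(rho) >= 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got {n}")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x = z1
    y = rho * z1 + np.sqrt(1.0 - rho * rho) * z2
    return x, y


def analytic_gaussian_mi(rho: float) -> float:
    """Closed-form MI of a bivariate Gaussian: ``-0.5 * ln(1 - rho^2)`` nats."""
    if abs(rho) >= 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    return -0.5 * np.log1p(-rho * rho)


def gen_coupled_ar(
    n: int,
    a_x: float = 0.5,
    a_y: float = 0.5,
    c_xy: float = 0.0,
    c_yx: float = 0.0,
    lag: int = 1,
    noise_sd: float = 1.0,
    seed: int = 0,
    burn_in: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a pair of coupled AR(1) processes with lagged cross terms.

    .. math::

        x_t = a_x x_{t-1} + c_{yx} y_{t-\\mathrm{lag}} + \\epsilon_{x,t}

        y_t = a_y y_{t-1} + c_{xy} x_{t-\\mathrm{lag}} + \\epsilon_{y,t}

    with independent Gaussian innovations of standard deviation ``noise_sd``.
    A burn-in of ``burn_in + 10 * lag`` samples is discarded so the returned
    series are (approximately) stationary.
    """
    if abs(a_x) >= 1 or abs(a_y) >= 1:
        raise ValueError(
            f"AR coefficients must satisfy |a| < 1 for stationarity, "
            f"got a_x={a_x}, a_y={a_y}"
        )
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    if n <= 10 * lag:
        raise ValueError(f"n={n} too short for lag={lag}")
    rng = np.random.default_rng(seed)
    total = n + burn_in + 10 * lag
    ex = rng.normal(0.0, noise_sd, total)
    ey = rng.normal(0.0, noise_sd, total)
    x = np.zeros(total)
    y = np.zeros(total)
    for t in range(lag, total):
        x[t] = a_x * x[t - 1] + c_yx * y[t - lag] + ex[t]
        y[t] = a_y * y[t - 1] + c_xy * x[t - lag] + ey[t]
    return x[-n:], y[-n:]


def analytic_linear_te(
    a_x: float = 0.5,
    a_y: float = 0.5,
    c_xy: float = 0.0,
    c_yx: float = 0.0,
    lag: int = 1,
    noise_sd: float = 1.0,
    direction: str = "xy",
    d_source: int = 1,
    d_target: int = 1,
    n: int = 200_000,
    seed: int = 12345,
) -> float:
    """Transfer entropy of the linear-Gaussian coupled-AR system, in nats.

    For jointly Gaussian processes, transfer entropy equals half the log
    ratio of the target's prediction-error variance without versus with the
    source's past (the Granger-causality equivalence). This oracle computes
    that ratio by ordinary least squares on a long simulated realization of
    the model, using exactly ``d_target`` own-past lags and ``d_source``
    source lags (aligned at the model's coupling lag) as regressors — the
    same conditioning set a nearest-neighbor TE estimator with matching
    embedding uses, so the two are directly comparable.

    ``direction`` is ``"xy"`` (x drives y) or ``"yx"``.
    """
    if abs(a_x) >= 1 or abs(a_y) >= 1:
        raise ValueError("nonstationary model: |a| must be < 1")
    if direction not in ("xy", "yx"):
        raise ValueError(f"direction must be 'xy' or 'yx', got {direction!r}")
    x, y = gen_coupled_ar(
        n, a_x=a_x, a_y=a_y, c_xy=c_xy, c_yx=c_yx, lag=lag,
        noise_sd=noise_sd, seed=seed,
    )
    src, tgt = (x, y) if direction == "xy" else (y, x)

    # Regress tgt_{t} on its own past (reduced) and additionally on the
    # source's past at the coupling lag (full).
    max_back = max(d_target, lag + d_source - 1)
    t_idx = np.arange(max_back, n)
    resp = tgt[t_idx]
    own = np.column_stack([tgt[t_idx - j] for j in range(1, d_target + 1)])
    cross = np.column_stack(
        [src[t_idx - (lag + j)] for j in range(d_source)]
    )
    ones = np.ones((len(t_idx), 1))

    def _rss(design: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(design, resp, rcond=None)
        resid = resp - design @ coef
        return float(resid @ resid)

    rss_reduced = _rss(np.hstack([ones, own]))
    rss_full = _rss(np.hstack([ones, own, cross]))
    return 0.5 * np.log(rss_reduced / rss_full)


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi] Hz (zero-phase)."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, white)
    sd = out.std()
    return out / sd if sd > 0 else out


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance noise with ~1/f amplitude spectrum (pink background)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC
    out = np.fft.irfft(spec * scale, n)
    return out / out.std()


def gen_cmc_recording(
    protocol: StimProtocol,
    cfg: SynthConfig,
    phase: str = "pre",
) -> TimeSeriesRecording:
    """Generate one stimulus-locked synthetic LFP/EMG recording.

    Signal model
    ------------
    A cortical source ``s`` (beta-band oscillation plus broadband component)
    appears in the LFP immediately and, after the conduction delay, drives
    the muscle through a half-wave (threshold-linear) motor-unit recruitment
    nonlinearity: the EMG is a broadband interference-pattern carrier whose
    nonnegative envelope is ``tone + coupling_desc * relu(s(t - delay))``
    plus an independent muscle-intrinsic component ``m``. Full-wave
    rectification of the EMG therefore demodulates the envelope and recovers
    the delayed cortical drive, as it does for real interference-pattern
    EMG. The muscle-intrinsic activity feeds back into the LFP after the
    same delay with gain ``coupling_asc`` (proprioceptive afference). The
    LFP additionally carries 1/f background, slow baseline drift and a 50 Hz
    mains component; both channels carry white measurement noise.

    In ``phase="post"`` the two coupling gains are multiplied by
    ``1 + ntb_gain_slope * protocol.ntb``; all stochastic draws are shared
    between phases, so with a zero slope the pre and post recordings are
    bit-identical under the same seed.

    Stimulation triggers are placed every ``protocol.iti`` seconds starting
    1 s into the record.
    """
    if phase not in ("pre", "post"):
        raise ValueError(f"phase must be 'pre' or 'post', got {phase!r}")
    fs = cfg.fs
    pad = 2.0  # seconds of headroom after the last trial window
    duration = 1.0 + cfg.n_trials * protocol.iti + pad
    n = int(round(duration * fs))
    delay = int(round(cfg.conduction_delay * fs / 1000.0))
    if delay < 1:
        raise ValueError("conduction_delay shorter than one sample")

    rng = np.random.default_rng(cfg.seed)
    # Draw order is fixed; nothing below may depend on `phase`.
    n_ext = n + delay
    beta = _bandlimited_noise(rng, n_ext, fs, 18.0, 22.0)
    broad = _bandlimited_noise(rng, n_ext, fs, 10.0, 160.0)
    s = (0.85 * beta + 0.53 * broad) / np.sqrt(0.85**2 + 0.53**2)
    m = _bandlimited_noise(rng, n_ext, fs, 5.0, 60.0)
    carrier = _bandlimited_noise(rng, n, fs, 20.0, 160.0)
    pink = _one_over_f_noise(rng, n, fs)
    line_phase = rng.uniform(0.0, 2.0 * np.pi)
    drift_phase = rng.uniform(0.0, 2.0 * np.pi)
    noise_lfp = rng.standard_normal(n)
    noise_emg = rng.standard_normal(n)

    gain = 1.0
    if phase == "post":
        gain = 1.0 + cfg.ntb_gain_slope * protocol.ntb

    t = np.arange(n) / fs
    line = cfg.line_noise_amp * np.sin(2.0 * np.pi * 50.0 * t + line_phase)
    drift = cfg.drift_amp * np.sin(2.0 * np.pi * 0.2 * t + drift_phase)

    relu = lambda v: np.maximum(v, 0.0)  # motor-unit recruitment threshold
    # s[delay:] leads s[:n] by `delay` samples: the cortical source enters
    # the LFP now and the EMG `delay` samples later (and vice versa for m).
    lfp = (
        s[delay:]
        + gain * cfg.coupling_asc * relu(m[:n])
        + 0.4 * pink
        + line
        + drift
        + cfg.noise_sd * noise_lfp
    )
    envelope = (
        0.5  # baseline muscle tone
        + gain * cfg.coupling_desc * relu(s[:n])
        + 0.3 * relu(m[delay:])
    )
    emg = envelope * carrier + cfg.noise_sd * noise_emg

    triggers = 1.0 + np.arange(cfg.n_trials) * protocol.iti
    if triggers[-1] >= duration:
        raise ValueError(
            f"record of {duration:.1f} s too short for "
            f"{cfg.n_trials} trials at ITI {protocol.iti} s"
        )
    return TimeSeriesRecording(
        lfp=lfp,
        emg=emg,
        fs=fs,
        trigger_times=triggers,
        metadata={
            "phase": phase,
            "ntb": protocol.ntb,
            "seed": cfg.seed,
            "coupling_gain": gain,
        },
    )
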