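"""Parameter containers for the stimulation protocol, synthesis and estimation.

These dataclasses carry the knobs shared across the pipeline: the pulsed
ultrasound stimulation protocol, the synthetic-recording generator
configuration, the preprocessing filter bank, and the state-space embedding
used by the nearest-neighbor estimators. All validation happens in
``__post_init__`` so invalid parameter sets fail at construction, not deep
inside an estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class StimProtocol:
    """Pulsed transcranial ultrasound stimulation parameters.

    Parameters
    ----------
    acoustic_intensity : float
        Spatial-peak intensity in W/cm^2. Informational only; no acoustic
        physics is modeled.
    n_cycles_per_pulse : int
        Acoustic cycles per tone burst (NC).
    prf : float
        Pulse repetition frequency in Hz.
    ntb : int
        Number of tone bursts per stimulation train. With ``prf`` = 1 kHz the
        sonication duration in milliseconds equals ``ntb``.
    iti : float
        Inter-trial interval in seconds (onset-to-onset spacing of trains).
    fundamental_freq : float
        Transducer center frequency in Hz (informational).
    """

    acoustic_intensity: float = 1.10
    n_cycles_per_pulse: int = 250
    prf: float = 1000.0
    ntb: int = 250
    iti: float = 3.6
    fundamental_freq: float = 500e3

    def __post_init__(self) -> None:
        if self.ntb < 1:
            raise ValueError(f"ntb must be >= 1, got {self.ntb}")
        if self.prf <= 0:
            raise ValueError(f"prf must be positive, got {self.prf}")
        if self.iti <= self.sonication_duration:
            raise ValueError(
                f"iti ({self.iti} s) must exceed the sonication duration "
                f"({self.sonication_duration} s)"
            )

    @property
    def sonication_duration(self) -> float:
        """Duration of one stimulation train in seconds (= ntb / prf)."""
        return self.ntb / self.prf


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic LFP/EMG recording generator.

    The generator emulates a cortical drive that reaches the muscle after a
    conduction delay (descending pathway) and a weaker proprioceptive
    feedback from muscle to cortex (ascending pathway). After stimulation the
    coupling gains are scaled multiplicatively by ``1 + ntb_gain_slope * ntb``.

    Attributes
    ----------
    fs : float
        Sampling rate in Hz.
    n_trials : int
        Number of stimulation trains in the recording.
    coupling_desc, coupling_asc : float
        Unitless gains of the cortex->muscle and muscle->cortex pathways.
    conduction_delay : float
        Corticomuscular conduction delay in milliseconds. Kept inside the
        10-49 ms window scanned by the prediction-time optimization so the
        delay is recoverable.
    ntb_gain_slope : float
        Post-stimulation multiplicative gain increase per tone burst.
    line_noise_amp : float
        50 Hz mains amplitude, as a fraction of the cortical signal RMS.
    drift_amp : float
        Slow baseline-drift amplitude, as a fraction of signal RMS.
    noise_sd : float
        Standard deviation of additive white measurement noise on each
        channel, relative to unit-RMS signal components.
    seed : int
        Seed of the single PRNG stream controlling all draws.
    """

    fs: float = 2000.0
    n_trials: int = 30
    coupling_desc: float = 0.8
    coupling_asc: float = 0.25
    conduction_delay: float = 25.0
    ntb_gain_slope: float = 0.002
    line_noise_amp: float = 0.1
    drift_amp: float = 0.1
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (10.0 <= self.conduction_delay <= 49.0):
            raise ValueError(
                "conduction_delay must lie in [10, 49] ms (the scanned "
                f"prediction-time range), got {self.conduction_delay}"
            )
        if self.coupling_desc < 0 or self.coupling_asc < 0:
            raise ValueError("coupling gains must be nonnegative")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class FilterSpec:
    """Preprocessing filter parameters.

    ``lfp_band`` and ``emg_band`` are the pass bands applied to the cortical
    and muscular channel respectively; ``baseline_window`` is the length of
    the moving-average window subtracted to remove slow drift.
    """

    notch_freq: float = 50.0
    notch_bandwidth: float = 1.4
    lfp_band: tuple[float, float] = (0.5, 200.0)
    emg_band: tuple[float, float] = (10.0, 200.0)
    baseline_window: float = 0.5

    def __post_init__(self) -> None:
        for lo, hi in (self.lfp_band, self.emg_band):
            if not (0 < lo < hi):
                raise ValueError(f"invalid band ({lo}, {hi})")
        if self.notch_freq <= 0:
            raise ValueError("notch_freq must be positive")
        if self.notch_bandwidth <= 0:
            raise ValueError("notch_bandwidth must be positive")
        if self.baseline_window <= 0:
            raise ValueError("baseline_window must be positive")


@dataclass(frozen=True)
class EmbeddingSpec:
    """State-space reconstruction parameters for MI/TE estimation.

    Attributes
    ----------
    d : int
        Embedding dimension (number of delayed coordinates).
    tau : int
        Embedding delay in samples.
    u : float
        Prediction time in milliseconds; converted to samples via the
        sampling rate at estimation time.
    k : int
        Number of nearest neighbors of the KSG estimator.
    theiler : int
        Dynamical (Theiler) exclusion window in samples: neighbor candidates
        closer than this in time are ignored, preventing serial correlation
        from inflating neighbor counts.
    """

    d: int = 1
    tau: int = 1
    u: float = 25.0
    k: int = 4
    theiler: int = 0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("embedding dimension d must be >= 1")
        if self.tau < 1:
            raise ValueError("embedding delay tau must be >= 1")
        if self.k < 1:
            raise ValueError("neighbor count k must be >= 1")
        if self.theiler < 0:
            raise ValueError("theiler window must be >= 0")
        if self.u <= 0:
            raise ValueError("prediction time u must be positive")
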