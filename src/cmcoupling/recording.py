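"""Time-series containers and delimited-text I/O.

A :class:`TimeSeriesRecording` holds one paired LFP/EMG recording with its
sampling rate and stimulation trigger times; a :class:`TrialSet` holds the
equal-length pre- or post-stimulation windows cut from such a recording.

The on-disk format is plain CSV with two comment headers::

    # fs=2000.0
    # triggers=1.0,4.6,8.2
    time,lfp,emg
    0.0000000,...,...

which round-trips losslessly (values written with ``repr``-level precision).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class TimeSeriesRecording:
    """Paired single-channel LFP and EMG recording.

    ``lfp`` and ``emg`` must have equal length; ``trigger_times`` (seconds)
    must be strictly increasing and lie inside the record.
    """

    lfp: np.ndarray
    emg: np.ndarray
    fs: float
    trigger_times: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        self.trigger_times = np.asarray(self.trigger_times, dtype=float)
        if self.lfp.ndim != 1 or self.emg.ndim != 1:
            raise ValueError("lfp and emg must be 1-D arrays")
        if len(self.lfp) != len(self.emg):
            raise ValueError(
                f"lfp ({len(self.lfp)}) and emg ({len(self.emg)}) must have "
                "equal length"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.trigger_times.size:
            if np.any(np.diff(self.trigger_times) <= 0):
                raise ValueError("trigger_times must be strictly increasing")
            if self.trigger_times[0] < 0 or self.trigger_times[-1] >= self.duration:
                raise ValueError("all trigger_times must lie inside the record")

    @property
    def n_samples(self) -> int:
        return len(self.lfp)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.lfp) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class TrialSet:
    """Equal-length paired (lfp, emg) trial windows for one condition.

    ``window`` is the (start, stop) of the trial window in seconds relative
    to the stimulation trigger (negative start for pre-stimulation windows).
    """

    lfp: np.ndarray  # (n_trials, n_samples)
    emg: np.ndarray  # (n_trials, n_samples)
    fs: float
    window: tuple[float, float]
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lfp = np.atleast_2d(np.asarray(self.lfp, dtype=float))
        self.emg = np.atleast_2d(np.asarray(self.emg, dtype=float))
        if self.lfp.shape != self.emg.shape:
            raise ValueError("lfp and emg trial arrays must have equal shape")

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_samples(self) -> int:
        return self.lfp.shape[1]

    def __iter__(self):
        for i in range(self.n_trials):
            yield self.lfp[i], self.emg[i]


def write_recording(rec: TimeSeriesRecording, path: str | Path) -> None:
    """Write a recording to delimited text (CSV with ``# fs=``/``# triggers=``
    header lines). Full float precision, so a read-back is exact."""
    path = Path(path)
    trig = ",".join(repr(float(t)) for t in rec.trigger_times)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write(f"# triggers={trig}\n")
        fh.write("time,lfp,emg\n")
        t = rec.times
        for i in range(rec.n_samples):
            fh.write(
                f"{float(t[i])!r},{float(rec.lfp[i])!r},{float(rec.emg[i])!r}\n"
            )


def read_recording(path: str | Path) -> TimeSeriesRecording:
    """Read a recording written by :func:`write_recording`.

    Raises
    ------
    ValueError
        If the ``# fs=`` header is missing or a data line is malformed; the
        message names the offending line number.
    """
    path = Path(path)
    fs = None
    triggers: np.ndarray = np.empty(0)
    data_lines: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("fs="):
                fs = float(body[3:])
            elif body.startswith("triggers="):
                payload = body[len("triggers="):].strip()
                if payload:
                    triggers = np.array([float(v) for v in payload.split(",")])
        elif line.startswith("time"):
            continue
        else:
            data_lines.append(line)
            if line.count(",") != 2:
                raise ValueError(
                    f"{path}: malformed data line {lineno}: {line!r}"
                )
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=' header line")
    arr = np.loadtxt(io.StringIO("\n".join(data_lines)), delimiter=",")
    arr = np.atleast_2d(arr)
    return TimeSeriesRecording(
        lfp=arr[:, 1], emg=arr[:, 2], fs=fs, trigger_times=triggers
    )
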