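"""EMG calibration, envelope estimation and normalization.

The interface estimates the instantaneous activation level ``y`` of each
muscle by rectifying the raw EMG and averaging it over the preceding 750 ms
with a rectangular window, evaluated on the 75 Hz display frame grid.  A
per-channel calibration records the signal offset, the rest level ``y_r``
and the comfortable-contraction level ``y_c``; during operation the
normalized activation is

    y_n = max(0, (y - y_r) / (y_c - y_r)) ,

so that rest maps to 0 and comfortable contraction to 1.  Values above 1
are allowed (contraction beyond the comfortable level); values below rest
are clamped to 0.

Band-pass filtering of real recordings (30 Hz - 1 kHz) is assumed to have
been applied upstream by the acquisition hardware; the synthesizer in this
module generates in-band signal directly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

DEFAULT_SAMPLE_RATE = 2500.0
DEFAULT_WINDOW_S = 0.750
DEFAULT_BAND = (30.0, 1000.0)

__all__ = [
    "CalibrationError",
    "EmgStream",
    "ChannelCalibration",
    "envelope",
    "calibrate",
    "normalize",
    "synthesize_raw",
    "read_delimited",
    "write_delimited",
    "read_hdf5",
    "write_hdf5",
]


class CalibrationError(ValueError):
    """Raised when calibration segments cannot produce a valid contrast."""


@dataclass
class EmgStream:
    """Multichannel raw EMG.

    ``samples`` has shape (n_samples, n_channels) in millivolts; sample ``j``
    of every channel is taken at time ``t0 + j / sample_rate`` seconds.
    """

    sample_rate: float
    channel_names: tuple[str, ...]
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2D (n_samples, n_channels) array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.samples.shape[1]:
            raise ValueError("one channel name per sample column required")
        if self.samples.shape[1] < 1:
            raise ValueError("at least one channel required")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class ChannelCalibration:
    """Offset and activation anchor levels of one EMG channel."""

    offset: float
    rest_level: float
    comfortable_level: float

    def __post_init__(self) -> None:
        if self.rest_level < 0:
            raise CalibrationError("rest level must be non-negative")
        if self.comfortable_level <= self.rest_level:
            raise CalibrationError(
                "comfortable contraction level must exceed the rest level"
            )


def envelope(
    stream: EmgStream,
    frame_times,
    window_s: float = DEFAULT_WINDOW_S,
) -> np.ndarray:
    """Causal rectified moving-average envelope, evaluated at frame times.

    ``y(t)`` is the mean of the rectified signal over the half-open window
    ``(t - window_s, t]``.  At the start of the stream the window is
    truncated to the available samples.  Returns an array of shape
    (n_frames, n_channels).
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if stream.n_samples == 0:
        raise ValueError("cannot compute envelope of an empty stream")
    frame_times = np.asarray(frame_times, dtype=float)
    times = stream.times
    hi = np.searchsorted(times, frame_times, side="right")
    if np.any(hi == 0):
        raise ValueError("frame time precedes the first EMG sample")
    lo = np.searchsorted(times, frame_times - window_s, side="right")
    if np.any(lo >= hi):
        raise ValueError("envelope window contains no samples at some frame")
    rect = np.abs(stream.samples)
    csum = np.concatenate([np.zeros((1, rect.shape[1])), np.cumsum(rect, axis=0)])
    return (csum[hi] - csum[lo]) / (hi - lo)[:, None]


def calibrate(
    rest_segment: EmgStream,
    contraction_segment: EmgStream,
    window_s: float = DEFAULT_WINDOW_S,
) -> list[ChannelCalibration]:
    """Derive per-channel calibration from a rest and a contraction recording.

    The offset is the mean of the raw rest segment; the rest and
    comfortable-contraction levels are the time-averaged envelopes of the
    offset-corrected segments.  Raises :class:`CalibrationError` when the
    contraction level does not exceed the rest level (muscle not activated).
    """
    if rest_segment.channel_names != contraction_segment.channel_names:
        raise CalibrationError("rest and contraction segments must share channels")
    for seg, name in ((rest_segment, "rest"), (contraction_segment, "contraction")):
        if seg.duration < window_s:
            raise CalibrationError(
                f"{name} segment shorter than one smoothing window ({window_s} s)"
            )
    offsets = rest_segment.samples.mean(axis=0)

    def _mean_env(seg: EmgStream) -> np.ndarray:
        corrected = EmgStream(
            seg.sample_rate, seg.channel_names, seg.samples - offsets, seg.t0
        )
        # evaluate on full windows only, at the segment's own frame grid
        t_first = seg.t0 + window_s
        frames = np.arange(t_first, seg.t0 + seg.duration, 1.0 / 75.0)
        return envelope(corrected, frames, window_s).mean(axis=0)

    y_r = _mean_env(rest_segment)
    y_c = _mean_env(contraction_segment)
    cals = []
    for name, off, r, c in zip(rest_segment.channel_names, offsets, y_r, y_c):
        if c <= r:
            raise CalibrationError(
                f"channel {name!r}: contraction level {c:.4g} does not exceed "
                f"rest level {r:.4g}"
            )
        cals.append(ChannelCalibration(float(off), float(r), float(c)))
    return cals


def normalize(y, cal: ChannelCalibration) -> np.ndarray:
    """Normalized activation level, clamped at zero from below."""
    y = np.asarray(y, dtype=float)
    y_n = (y - cal.rest_level) / (cal.comfortable_level - cal.rest_level)
    return np.maximum(y_n, 0.0)


def synthesize_raw(
    target_envelope,
    frame_times,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    band: tuple[float, float] = DEFAULT_BAND,
    seed: int | np.random.Generator = 0,
    window_s: float = DEFAULT_WINDOW_S,
    channel_name: str = "SYN",
) -> EmgStream:
    """Amplitude-modulated band-limited Gaussian noise with a target envelope.

    Generates a single-channel stream whose rectified ``window_s`` moving
    average tracks ``target_envelope`` (given on the ``frame_times`` grid).
    The carrier is unit-variance band-passed Gaussian noise; because the
    rectified mean of a zero-mean Gaussian is sigma * sqrt(2/pi), the
    instantaneous standard deviation is set to target * sqrt(pi/2).

    The stream starts ``window_s`` before the first frame so the first
    frame's window is fully populated.  Reproducible for a fixed seed.
    """
    lo, hi_ = band
    if not (0.0 < lo < hi_ < sample_rate / 2.0):
        raise ValueError("band must satisfy 0 < low < high < sample_rate / 2")
    frame_times = np.asarray(frame_times, dtype=float)
    target = np.asarray(target_envelope, dtype=float)
    if target.shape != frame_times.shape:
        raise ValueError("target_envelope and frame_times must have equal shape")
    if np.any(target < 0):
        raise ValueError("target envelope must be non-negative")
    rng = np.random.default_rng(seed)
    t0 = frame_times[0] - window_s
    n = int(np.ceil((frame_times[-1] - t0) * sample_rate)) + 1
    noise = rng.standard_normal(n)
    sos = _signal.butter(4, band, btype="bandpass", fs=sample_rate, output="sos")
    carrier = _signal.sosfilt(sos, noise)
    std = carrier.std()
    if std > 0:
        carrier = carrier / std
    times = t0 + np.arange(n) / sample_rate
    sigma = np.interp(times, frame_times, target) * np.sqrt(np.pi / 2.0)
    return EmgStream(sample_rate, (channel_name,), (sigma * carrier)[:, None], t0)


# ---------------------------------------------------------------------------
# file formats: delimited text and HDF5 array container
# ---------------------------------------------------------------------------

def write_delimited(stream: EmgStream, path, delimiter: str = "\t") -> None:
    """Write a stream as delimited text: a metadata header line, a column
    header (time + channel names), then one row per sample."""
    header = f"# sample_rate_hz={stream.sample_rate!r}"
    cols = delimiter.join(["time_s", *stream.channel_names])
    data = np.column_stack([stream.times, stream.samples])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n" + cols + "\n")
        np.savetxt(fh, data, delimiter=delimiter, fmt="%.9g")


def read_delimited(path, delimiter: str = "\t") -> EmgStream:
    with open(path, "r", encoding="utf-8") as fh:
        meta = fh.readline().strip()
        cols = fh.readline().strip().split(delimiter)
        body = fh.read()
    if not meta.startswith("# sample_rate_hz="):
        raise ValueError("missing sample_rate header line")
    sample_rate = float(meta.split("=", 1)[1])
    names = tuple(cols[1:])
    data = np.loadtxt(io.StringIO(body), delimiter=delimiter, ndmin=2)
    return EmgStream(sample_rate, names, data[:, 1:], t0=float(data[0, 0]))


def write_hdf5(stream: EmgStream, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("samples", data=stream.samples)
        ds.attrs["sample_rate_hz"] = stream.sample_rate
        ds.attrs["t0_s"] = stream.t0
        ds.attrs["channel_names"] = list(stream.channel_names)


def read_hdf5(path) -> EmgStream:
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh["samples"]
        names = tuple(
            n.decode() if isinstance(n, bytes) else str(n)
            for n in ds.attrs["channel_names"]
        )
        return EmgStream(
            float(ds.attrs["sample_rate_hz"]), names, ds[...], float(ds.attrs["t0_s"])
        )
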