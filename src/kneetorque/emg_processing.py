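"""Surface-EMG conditioning chain.

Raw sEMG is band-pass filtered (20–450 Hz) to remove motion artefact and
high-frequency noise, full-wave rectified, low-pass filtered at 6 Hz to
obtain the linear envelope, normalized to the processed MVIC reference peak
so that 1.0 corresponds to maximal voluntary effort, and finally resampled
by linear interpolation onto the kinematic clock (100 Hz by default).

Filters are 4th-order Butterworth applied forward-backward (zero phase,
reflect padding) so the envelope carries no group delay relative to the
torque targets.  The first and last 0.1 s of every aligned envelope are
flagged as filter transients; windowing excludes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io_formats import MUSCLES, TimeSeriesTrial

#: Default band edges of the noise-rejection band-pass stage (Hz).
DEFAULT_BP_LOW_HZ = 20.0
DEFAULT_BP_HIGH_HZ = 450.0
#: Default envelope low-pass cutoff (Hz).
DEFAULT_ENVELOPE_CUTOFF_HZ = 6.0
DEFAULT_FILTER_ORDER = 4
#: Default kinematic (motion-capture) rate the envelope is aligned to (Hz).
DEFAULT_KINEMATIC_RATE_HZ = 100.0
#: Edge span flagged as zero-phase filter transient (s).
TRANSIENT_EDGE_S = 0.1


class FilterParameterError(ValueError):
    """Raised for infeasible filter specifications (e.g. cutoff >= Nyquist)."""


class DegenerateMvicError(ValueError):
    """Raised when an MVIC reference has a nonpositive peak."""


class ChannelMappingError(KeyError):
    """Raised when a required muscle channel is missing from a trial."""


@dataclass
class FilterSpec:
    """Butterworth filter specification (band-pass or low-pass)."""

    kind: str = "bandpass"
    low_cut_hz: float = DEFAULT_BP_LOW_HZ
    high_cut_hz: float = DEFAULT_BP_HIGH_HZ
    cutoff_hz: float = DEFAULT_ENVELOPE_CUTOFF_HZ
    order: int = DEFAULT_FILTER_ORDER
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if self.order < 1:
            raise FilterParameterError("filter order must be >= 1")
        if self.kind == "bandpass":
            if not (0 < self.low_cut_hz < self.high_cut_hz < nyq):
                raise FilterParameterError(
                    f"bandpass requires 0 < low ({self.low_cut_hz}) < high "
                    f"({self.high_cut_hz}) < Nyquist ({nyq})"
                )
        elif self.kind == "lowpass":
            if not (0 < self.cutoff_hz < nyq):
                raise FilterParameterError(
                    f"lowpass cutoff ({self.cutoff_hz}) must lie below Nyquist ({nyq})"
                )
        else:
            raise FilterParameterError(f"unknown filter kind {self.kind!r}")


def _sos(spec: FilterSpec, fs: float) -> np.ndarray:
    spec.validate(fs)
    if spec.kind == "bandpass":
        return sps.butter(
            spec.order, [spec.low_cut_hz, spec.high_cut_hz], btype="bandpass", fs=fs, output="sos"
        )
    return sps.butter(spec.order, spec.cutoff_hz, btype="lowpass", fs=fs, output="sos")


def _apply(spec: FilterSpec, x: np.ndarray, fs: float) -> np.ndarray:
    sos = _sos(spec, fs)
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x, padtype="even")
    return sps.sosfilt(sos, x)


def bandpass_filter(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase band-pass filter; same length out, DC strongly rejected."""
    x = np.asarray(x, dtype=float)
    spec = spec or FilterSpec(kind="bandpass")
    return _apply(spec, x, fs)


def full_wave_rectify(x: np.ndarray) -> np.ndarray:
    """Elementwise absolute value."""
    return np.abs(np.asarray(x, dtype=float))


def lowpass_envelope(
    rectified: np.ndarray,
    fs: float,
    cutoff_hz: float = DEFAULT_ENVELOPE_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Smooth the rectified signal into a nonnegative linear envelope."""
    spec = FilterSpec(kind="lowpass", cutoff_hz=cutoff_hz, order=order)
    out = _apply(spec, np.asarray(rectified, dtype=float), fs)
    return np.clip(out, 0.0, None)


def mvic_normalize(envelope: np.ndarray, mvic_reference: np.ndarray) -> np.ndarray:
    """Divide an envelope by the peak of the processed MVIC reference.

    Both arguments must be the same muscle's *processed* (filtered,
    rectified, smoothed) signals so the division is dimensionally consistent.
    """
    peak = float(np.max(mvic_reference))
    if not np.isfinite(peak) or peak <= 0:
        raise DegenerateMvicError(f"MVIC reference peak must be positive, got {peak}")
    return np.asarray(envelope, dtype=float) / peak


@dataclass
class EmgEnvelope:
    """MVIC-normalized envelopes of the seven muscles on the kinematic clock."""

    channel_names: list[str]
    data: np.ndarray  # time x 7, dimensionless
    sampling_rate_hz: float
    time_s: np.ndarray
    transient_mask: np.ndarray = field(default=None)  # True where edge transient

    def __post_init__(self) -> None:
        if self.transient_mask is None:
            self.transient_mask = np.zeros(self.data.shape[0], dtype=bool)


def _process_channel(x: np.ndarray, fs: float, bandpass: FilterSpec, envelope_cutoff: float) -> np.ndarray:
    filtered = bandpass_filter(x, fs, bandpass)
    return lowpass_envelope(full_wave_rectify(filtered), fs, envelope_cutoff)


def mvic_reference_peaks(
    mvic_trials: list[TimeSeriesTrial],
    bandpass: FilterSpec | None = None,
    envelope_cutoff: float = DEFAULT_ENVELOPE_CUTOFF_HZ,
) -> dict[str, float]:
    """Per-muscle peak of the processed MVIC envelope(s).

    With multiple reference trials the per-channel maximum across trials is
    used.
    """
    bandpass = bandpass or FilterSpec(kind="bandpass")
    peaks: dict[str, float] = {}
    for trial in mvic_trials:
        fs = trial.sampling_rate_hz
        for name in MUSCLES:
            if name not in trial.channel_names:
                continue
            env = _process_channel(trial.channel(name), fs, bandpass, envelope_cutoff)
            peak = float(np.max(env))
            peaks[name] = max(peaks.get(name, 0.0), peak)
    missing = [m for m in MUSCLES if m not in peaks]
    if missing:
        raise ChannelMappingError(f"MVIC references missing muscles: {missing}")
    bad = [m for m in MUSCLES if peaks[m] <= 0]
    if bad:
        raise DegenerateMvicError(f"nonpositive MVIC peaks for muscles: {bad}")
    return peaks


def process_emg(
    trial: TimeSeriesTrial,
    mvic_trials: list[TimeSeriesTrial],
    target_rate_hz: float = DEFAULT_KINEMATIC_RATE_HZ,
    target_time: np.ndarray | None = None,
    bandpass: FilterSpec | None = None,
    envelope_cutoff: float = DEFAULT_ENVELOPE_CUTOFF_HZ,
) -> EmgEnvelope:
    """Full conditioning chain for one trial.

    Per channel: band-pass -> rectify -> 6 Hz low-pass -> MVIC-normalize ->
    linear-interpolation resample onto the kinematic clock (``target_time``
    if given, else a uniform grid at ``target_rate_hz`` spanning the trial).
    """
    bandpass = bandpass or FilterSpec(kind="bandpass")
    missing = [m for m in MUSCLES if m not in trial.channel_names]
    if missing:
        raise ChannelMappingError(
            f"trial {trial.name!r} is missing EMG channels: {missing}"
        )
    peaks = mvic_reference_peaks(mvic_trials, bandpass, envelope_cutoff)

    fs = trial.sampling_rate_hz
    if target_time is None:
        n = int(np.floor(trial.duration_s * target_rate_hz)) + 1
        target_time = trial.time_s[0] + np.arange(n) / target_rate_hz
    else:
        target_time = np.asarray(target_time, dtype=float)
        if len(target_time) > 1:
            target_rate_hz = 1.0 / float(np.median(np.diff(target_time)))

    out = np.empty((target_time.shape[0], len(MUSCLES)), dtype=float)
    for j, name in enumerate(MUSCLES):
        env = _process_channel(trial.channel(name), fs, bandpass, envelope_cutoff)
        env = mvic_normalize(env, np.array([peaks[name]]))
        out[:, j] = np.interp(target_time, trial.time_s, env)

    t0, t1 = trial.time_s[0], trial.time_s[-1]
    transient = (target_time < t0 + TRANSIENT_EDGE_S) | (target_time > t1 - TRANSIENT_EDGE_S)
    return EmgEnvelope(
        channel_names=list(MUSCLES),
        data=out,
        sampling_rate_hz=target_rate_hz,
        time_s=target_time,
        transient_mask=transient,
    )
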