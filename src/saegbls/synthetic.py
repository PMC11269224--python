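"""Synthetic EEG-like recordings and separable feature tables.

Two generators make the whole pipeline testable without any data download:

* :func:`synth_recording` - multichannel background activity (1/f-shaped
  noise plus a low-amplitude 10 Hz rhythm) with high-amplitude ~3 Hz
  spike-and-wave-like bursts superimposed inside annotated seizure
  intervals. The morphology is a deliberate caricature (sawtooth slow wave
  plus a sharp transient each cycle): it produces the strong time-domain
  feature contrast between ictal and background segments that drives the
  classifier, without claiming physiological realism.
* :func:`synth_feature_clusters` - two unit-variance Gaussian clusters with
  per-dimension means at +/- separation/2, balanced labels; the standard
  well-separated two-class benchmark for the classifier stack.

Both are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import sawtooth

from .eeg import FeatureTable, Recording
from .errors import ParameterError, ValidationError


@dataclass
class SynthSpec:
    """Conditions of a simulated recording.

    Amplitudes are in microvolts; ``background_sigma`` scales the 1/f noise
    floor and ``seizure_sigma`` (> background) the ictal burst. Intervals
    must lie within the recording and not overlap.
    """

    fs: float = 256.0
    duration_s: float = 60.0
    n_channels: int = 3
    seizure_intervals: list[tuple[float, float]] = field(
        default_factory=lambda: [(20.0, 30.0), (40.0, 48.0)]
    )
    background_sigma: float = 10.0
    rhythm_hz: float = 10.0
    rhythm_amplitude: float = 5.0
    seizure_sigma: float = 60.0
    spike_rate_hz: float = 3.0
    rng_seed: int | None = 0

    def validate(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0 or self.n_channels < 1:
            raise ParameterError("fs, duration_s and n_channels must be positive")
        if self.seizure_sigma <= self.background_sigma:
            raise ValidationError(
                "seizure amplitude must exceed background amplitude"
            )
        prev_end = None
        for start, end in sorted(self.seizure_intervals):
            if not (0.0 <= start < end <= self.duration_s):
                raise ValidationError(
                    f"interval ({start}, {end}) outside [0, {self.duration_s}]"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError("seizure intervals overlap")
            prev_end = end


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-shaped noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synth_recording(spec: SynthSpec) -> Recording:
    """Simulate a recording per ``spec``; annotations equal its intervals."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    n = int(round(spec.fs * spec.duration_s))
    t = np.arange(n) / spec.fs
    channels = []
    for _ in range(spec.n_channels):
        bg = spec.background_sigma * _pink_noise(n, rng)
        phase = rng.uniform(0, 2 * np.pi)
        bg = bg + spec.rhythm_amplitude * np.sin(2 * np.pi * spec.rhythm_hz * t + phase)
        x = bg
        for start, end in spec.seizure_intervals:
            mask = (t >= start) & (t < end)
            tm = t[mask]
            slow = sawtooth(2 * np.pi * spec.spike_rate_hz * tm, width=0.9)
            # sharp transient riding each cycle, mimicking the spike
            cycle_phase = (spec.spike_rate_hz * tm) % 1.0
            spike = np.exp(-((cycle_phase - 0.05) ** 2) / (2 * 0.015**2))
            burst = spec.seizure_sigma * (slow + 1.5 * spike)
            x = x.copy()
            x[mask] += burst
        channels.append(x)
    names = [f"ch{i}" for i in range(spec.n_channels)]
    return Recording(
        samples=np.vstack(channels),
        fs=spec.fs,
        channel_names=names,
        annotations=list(spec.seizure_intervals),
    )


def synth_feature_clusters(
    n_per_class: int = 200,
    dim: int = 10,
    separation: float = 6.0,
    rng_seed: int | None = 0,
) -> FeatureTable:
    """Two balanced Gaussian clusters with means +/- separation/2 per dimension."""
    if separation < 0:
        raise ParameterError(f"separation must be >= 0, got {separation}")
    rng = np.random.default_rng(rng_seed)
    half = separation / 2.0
    X0 = rng.standard_normal((n_per_class, dim)) - half
    X1 = rng.standard_normal((n_per_class, dim)) + half
    X = np.vstack([X0, X1])
    labels = np.concatenate([np.zeros(n_per_class), np.ones(n_per_class)]).astype(int)
    order = rng.permutation(2 * n_per_class)
    names = [f"f{i}" for i in range(dim)]
    return FeatureTable(X[order], names, labels[order])
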