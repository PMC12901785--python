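"""Cleaning and filtering of raw HD-MEA recordings.

High-density MEA chips periodically recalibrate their amplifiers, which
injects artificial spike-like transients into every channel; whole-array
"flash" events additionally drive the majority of channels into saturation.
Both are excised by building a recording-wide boolean validity mask, and all
downstream statistics (thresholds, firing rates) are computed over valid
samples only.  Spike-band energy is isolated with a linear-phase FIR
bandpass (150-3000 Hz) designed by the Remez exchange algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as _sig


@dataclass
class Recording:
    """A multichannel extracellular voltage recording.

    Attributes
    ----------
    samples:
        Voltage matrix, shape ``(n_channels, n_samples)``, in microvolts.
    fs:
        Sampling frequency in Hz.
    recalib_timestamps:
        Sample indices at which the acquisition chip recalibrated.
    channel_ids:
        Integer identifier per channel (row order of ``samples``).
    metadata:
        Free-form provenance (organoid id, treatment group, stage, rail
        amplitude of the ADC in microvolts under key ``"rail_uv"``).
    """

    samples: np.ndarray
    fs: float
    recalib_timestamps: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    channel_ids: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.recalib_timestamps = np.asarray(self.recalib_timestamps, dtype=np.int64)
        if self.recalib_timestamps.size:
            ts = self.recalib_timestamps
            if np.any(np.diff(ts) < 0):
                raise ValueError("recalib_timestamps must be sorted")
            if ts[0] < 0 or ts[-1] >= self.n_samples:
                raise ValueError("recalib_timestamps out of range")
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.samples.shape[0])
        else:
            self.channel_ids = np.asarray(self.channel_ids)
            if self.channel_ids.shape[0] != self.samples.shape[0]:
                raise ValueError("channel_ids length must match number of channels")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass
class SampleMask:
    """Recording-wide per-sample validity.

    ``True`` marks a valid sample.  Masks combine with logical AND, so
    successive cleaning stages can only invalidate, never re-validate.
    """

    valid: np.ndarray
    fs: float

    def __post_init__(self):
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.ndim != 1:
            raise ValueError("mask must be 1-D")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.valid.size

    @property
    def effective_duration(self) -> float:
        """Seconds of usable recording (valid samples / fs)."""
        return float(np.count_nonzero(self.valid)) / self.fs

    def intersect(self, other: "SampleMask") -> "SampleMask":
        if other.n_samples != self.n_samples:
            raise ValueError("mask lengths differ")
        return SampleMask(self.valid & other.valid, self.fs)


def excise_recalibration(rec: Recording, border: int = 100) -> SampleMask:
    """Invalidate a symmetric border around every recalibration timestamp.

    Each timestamp ``t`` removes samples ``[t - border, t + border]``
    (inclusive on both sides: 2*border + 1 samples per isolated event;
    at 19,754 Hz and the default border of 100 this is ~10 ms).
    Overlapping borders merge.  An empty timestamp list yields an all-valid
    mask.
    """
    if border < 0:
        raise ValueError(f"border must be >= 0, got {border}")
    valid = np.ones(rec.n_samples, dtype=bool)
    for t in rec.recalib_timestamps:
        lo = max(0, int(t) - border)
        hi = min(rec.n_samples, int(t) + border + 1)
        valid[lo:hi] = False
    return SampleMask(valid, rec.fs)


def detect_flashes(
    rec: Recording,
    mask: SampleMask | None = None,
    saturation_frac: float = 0.9,
    channel_frac: float = 0.5,
    pad: int = 0,
    rail_uv: float | None = None,
) -> SampleMask:
    """Invalidate samples where a majority of channels are saturated.

    A sample is part of a flash when at least ``channel_frac`` of all
    channels exceed ``saturation_frac`` times the ADC rail amplitude in
    absolute value.  Flagged samples are invalidated together with ``pad``
    samples on either side.  Returns the intersection with ``mask`` when one
    is given, so flash removal composes monotonically with recalibration
    excision.
    """
    for name, v in (("saturation_frac", saturation_frac), ("channel_frac", channel_frac)):
        if not 0 < v <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {v}")
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if rail_uv is None:
        rail_uv = rec.metadata.get("rail_uv")
    if rail_uv is None:
        raise ValueError(
            "rail amplitude unknown: pass rail_uv= or set metadata['rail_uv'] "
            "to the ADC full-scale voltage in microvolts"
        )
    saturated = np.abs(rec.samples) >= saturation_frac * float(rail_uv)
    frac = saturated.sum(axis=0) / rec.n_channels
    flagged = frac >= channel_frac
    if pad and flagged.any():
        # dilate by pad samples on each side
        kernel = np.ones(2 * pad + 1, dtype=bool)
        flagged = np.convolve(flagged, kernel, mode="same") > 0
    valid = ~flagged
    out = SampleMask(valid, rec.fs)
    if mask is not None:
        out = out.intersect(mask)
    return out


def design_bandpass(
    fs: float,
    low: float = 150.0,
    high: float = 3000.0,
    numtaps: int = 513,
    transition: float | None = None,
    stop_weight: float = 5.0,
) -> np.ndarray:
    """Design the linear-phase FIR bandpass via the Remez exchange algorithm.

    Transition bands default to [low - 50, low] and [high, high + 100] Hz.
    The upper transition is kept narrow on purpose: wide, strongly
    asymmetric don't-care bands let the exchange algorithm park huge
    unconstrained peaks inside them.  ``stop_weight`` trades passband ripple
    for stopband rejection; the default keeps the passband within +-1 dB
    while attenuating 50 Hz mains by more than 40 dB at 513 taps.
    """
    if not (0 < low < high < fs / 2):
        raise ValueError(f"require 0 < low < high < fs/2, got low={low}, high={high}, fs={fs}")
    if numtaps < 3 or numtaps % 2 == 0:
        raise ValueError("numtaps must be an odd integer >= 3 (symmetric linear phase)")
    if transition is None:
        lo_edge, hi_edge = low - 50.0, high + 100.0
    else:
        lo_edge, hi_edge = low - transition, high + transition
    if lo_edge <= 0 or hi_edge >= fs / 2:
        raise ValueError("transition bands fall outside (0, fs/2)")
    bands = [0, lo_edge, low, high, hi_edge, fs / 2]
    return _sig.remez(numtaps, bands, [0, 1, 0], weight=[stop_weight, 1, stop_weight], fs=fs)


def bandpass_filter(
    trace: np.ndarray,
    fs: float,
    low: float = 150.0,
    high: float = 3000.0,
    numtaps: int = 513,
    taps: np.ndarray | None = None,
) -> np.ndarray:
    """Bandpass a single-channel trace, compensating the FIR group delay.

    The filter is symmetric (linear phase); convolving in ``same`` mode
    centres the kernel on each sample, which is exactly the
    (numtaps-1)/2-sample group-delay compensation.  Output length equals
    input length.
    """
    trace = np.asarray(trace, dtype=float)
    if taps is None:
        taps = design_bandpass(fs, low=low, high=high, numtaps=numtaps)
    if trace.size == 0:
        return trace.copy()
    return _sig.fftconvolve(trace, taps, mode="same")


def bandpass_filter_masked(
    trace: np.ndarray,
    mask: SampleMask,
    fs: float,
    low: float = 150.0,
    high: float = 3000.0,
    numtaps: int = 513,
    taps: np.ndarray | None = None,
) -> np.ndarray:
    """Filter each contiguous valid segment independently.

    Invalid samples (recalibration borders, flashes) are excluded rather than
    zero-filled: zero-filling would create step edges whose filter response
    mimics spikes.  Invalid output samples are set to 0 and must stay masked
    downstream.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size != mask.n_samples:
        raise ValueError("trace and mask lengths differ")
    if taps is None:
        taps = design_bandpass(fs, low=low, high=high, numtaps=numtaps)
    out = np.zeros_like(trace)
    for lo, hi in valid_segments(mask.valid):
        out[lo:hi] = _sig.fftconvolve(trace[lo:hi], taps, mode="same")
    return out


def valid_segments(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean array."""
    valid = np.asarray(valid, dtype=bool)
    if valid.size == 0:
        return []
    edges = np.flatnonzero(np.diff(valid.astype(np.int8)))
    bounds = np.concatenate(([0], edges + 1, [valid.size]))
    return [
        (int(bounds[i]), int(bounds[i + 1]))
        for i in range(len(bounds) - 1)
        if valid[bounds[i]]
    ]
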