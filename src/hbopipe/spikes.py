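"""Moving-threshold spike detection and firing-rate summaries.

Detection follows the multi-unit-activity convention for extracellular
recordings: within a short moving window (default 5 ms) the local mean and
standard deviation of the bandpassed trace set an event threshold at
mean +- k*SD (default k = 5); an excursion beyond either threshold is a
spike, timed at its sample of maximum absolute deviation.  Channel firing
rates are counts over the *effective* (mask-valid) duration.  Organoid-level
summaries keep the top-30 most active channels after excluding channels
with abnormally high rates (> 5 Hz), and an organoid enters group statistics
only when the mean rate of its selected channels is at least 0.5 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hbopipe.mea_signal import SampleMask, valid_segments


@dataclass
class SpikeTrain:
    """Detected spikes on one channel: sorted sample indices + peak amplitudes (µV)."""

    channel_id: int
    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.int64)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.size != self.amplitudes.size:
            raise ValueError("times and amplitudes lengths differ")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class ChannelActivity:
    channel_id: int
    n_spikes: int
    frequency_hz: float


@dataclass
class OrganoidActivity:
    """Activity summary of one organoid over its selected channels."""

    organoid_id: str
    channel_ids: list[int]
    frequencies_hz: list[float]
    mean_frequency_hz: float
    included: bool


def moving_threshold(
    trace: np.ndarray,
    fs: float,
    window_ms: float = 5.0,
    k: float = 5.0,
    valid: np.ndarray | None = None,
    mode: str = "centered",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample event thresholds ``(upper, lower, mean)``.

    At each sample the local mean and population SD are computed over a
    moving window of ``floor(window_ms * fs / 1000)`` samples (98 at
    19,754 Hz and 5 ms), truncated at the trace edges, over valid samples
    only.  Thresholds are ``mean +- k * SD``.

    ``mode="centered"`` uses the window centred on the sample (the sample
    itself included); ``mode="trailing"`` uses the ``window`` samples
    strictly before it.  The trailing window is the one the detector uses:
    a bandpass-limited spike spread over ~20 samples carries so much energy
    relative to its peak that including it in its own 98-sample SD estimate
    raises the 5xSD threshold above the peak for *any* spike amplitude
    (feasibility requires sum((w/peak)^2) < window/k^2 ~ 3.9, while
    bandlimiting to 150-3000 Hz at 19,754 Hz forces >~ 4).  Samples whose
    window contains fewer than 2 valid neighbours get NaN thresholds.
    """
    trace = np.asarray(trace, dtype=float)
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    if k <= 0:
        raise ValueError("k must be positive")
    w = int(np.floor(window_ms * fs / 1000.0))
    if w < 2:
        raise ValueError(f"window of {w} samples is too short (need >= 2)")
    n = trace.size
    if valid is None:
        valid = np.ones(n, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
        if valid.size != n:
            raise ValueError("valid mask length differs from trace")

    vm = valid.astype(float)
    # centre on the global valid mean before the cumulative sums: the
    # E[x^2]-E[x]^2 shortcut otherwise loses ~sqrt(eps)*|x| of precision
    offset = float(trace[valid].mean()) if valid.any() else 0.0
    x = np.where(valid, trace - offset, 0.0)
    cs_n = np.concatenate(([0.0], np.cumsum(vm)))
    cs_x = np.concatenate(([0.0], np.cumsum(x)))
    cs_x2 = np.concatenate(([0.0], np.cumsum(x * x)))
    idx = np.arange(n)
    if mode == "centered":
        # window [i - (w-1)//2, i + w//2], inclusive, truncated at edges
        lo = np.clip(idx - (w - 1) // 2, 0, n)
        hi = np.clip(idx + w // 2 + 1, 0, n)
    elif mode == "trailing":
        # the w samples strictly before i
        lo = np.clip(idx - w, 0, n)
        hi = np.clip(idx, 0, n)
    else:
        raise ValueError(f"mode must be 'centered' or 'trailing', got {mode!r}")
    cnt = cs_n[hi] - cs_n[lo]
    # a trailing SD from a handful of samples is garbage and fires spuriously
    # right after every masked gap; demand half a window of history there
    min_cnt = 2 if mode == "centered" else max(2, w // 2)
    ok = cnt >= min_cnt
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(ok, (cs_x[hi] - cs_x[lo]) / cnt, np.nan)
        var = np.where(ok, (cs_x2[hi] - cs_x2[lo]) / cnt - mean**2, np.nan)
    sd = np.sqrt(np.clip(var, 0.0, None))
    mean = mean + offset
    upper = mean + k * sd
    lower = mean - k * sd
    return upper, lower, mean


def detect_spikes(
    trace: np.ndarray,
    mask: SampleMask | None,
    fs: float,
    channel_id: int = 0,
    window_ms: float = 5.0,
    k: float = 5.0,
    refractory_ms: float = 1.0,
    threshold_mode: str = "trailing",
    min_width: int = 2,
) -> SpikeTrain:
    """Detect threshold-crossing spikes on a (filtered) single-channel trace.

    An excursion is a maximal run of consecutive valid samples strictly
    beyond the upper or lower moving threshold; its spike time is the sample
    of maximum |deviation from the local mean| in the run.  Excursions whose
    gap is shorter than ``refractory_ms`` merge into one event
    (double-counting guard for multiphasic waveforms).  Events on invalid
    samples never appear: thresholds, runs and peaks are all restricted to
    mask-valid samples.

    ``threshold_mode`` defaults to the trailing window so a spike does not
    inflate its own threshold estimate (see :func:`moving_threshold`).
    ``min_width`` is the minimum excursion length in samples: a bandlimited
    spike stays suprathreshold for several consecutive samples at ~20 kHz,
    whereas single-sample crossings are noise riding on a fluctuating local
    SD estimate.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    valid = np.ones(n, dtype=bool) if mask is None else mask.valid
    if valid.size != n:
        raise ValueError("mask length differs from trace")
    refractory = int(round(refractory_ms * fs / 1000.0))

    times: list[int] = []
    amps: list[float] = []
    # windows never straddle an invalid gap: treat each valid segment alone
    for seg_lo, seg_hi in valid_segments(valid):
        seg = trace[seg_lo:seg_hi]
        w = int(np.floor(window_ms * fs / 1000.0))
        if seg.size < max(2, w // 2):
            continue
        upper, lower, mean = moving_threshold(
            seg, fs, window_ms=window_ms, k=k, mode=threshold_mode
        )
        with np.errstate(invalid="ignore"):
            exceed = (seg > upper) | (seg < lower)  # NaN thresholds never fire
        if not exceed.any():
            continue
        dev = np.nan_to_num(np.abs(seg - mean))
        runs = [(lo, hi) for lo, hi in _runs(exceed) if hi - lo >= min_width]
        merged = _merge_runs(runs, refractory)
        for lo, hi in merged:
            peak = lo + int(np.argmax(dev[lo:hi]))
            times.append(seg_lo + peak)
            amps.append(float(trace[seg_lo + peak]))
    order = np.argsort(times, kind="stable")
    return SpikeTrain(
        channel_id=channel_id,
        times=np.asarray(times, dtype=np.int64)[order],
        amplitudes=np.asarray(amps, dtype=float)[order],
    )


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True."""
    if not flags.any():
        return []
    d = np.diff(flags.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if flags[0]:
        starts.insert(0, 0)
    if flags[-1]:
        stops.append(flags.size)
    return list(zip(starts, stops))


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    """Merge runs separated by fewer than ``gap`` samples."""
    if not runs:
        return []
    merged = [runs[0]]
    for lo, hi in runs[1:]:
        plo, phi = merged[-1]
        if lo - phi < gap:
            merged[-1] = (plo, hi)
        else:
            merged.append((lo, hi))
    return merged


def channel_frequency(train: SpikeTrain, mask: SampleMask) -> ChannelActivity:
    """Firing rate = spike count / effective (valid) duration in seconds."""
    eff = mask.effective_duration
    if eff <= 0:
        raise ValueError("effective duration is zero; cannot compute a rate")
    return ChannelActivity(
        channel_id=train.channel_id,
        n_spikes=train.n_spikes,
        frequency_hz=train.n_spikes / eff,
    )


def select_channels(
    activities: list[ChannelActivity],
    top_n: int = 30,
    max_hz: float = 5.0,
) -> list[ChannelActivity]:
    """Keep the ``top_n`` most active channels after the high-rate exclusion.

    Channels with frequency > ``max_hz`` (abnormally high multi-unit rates,
    typically electrode artifacts) are removed before ranking.  Remaining
    channels are ranked by frequency descending, ties broken by ascending
    channel id, and the first ``top_n`` kept.
    """
    if not activities:
        raise ValueError("no channels to select from")
    eligible = [a for a in activities if a.frequency_hz <= max_hz]
    ranked = sorted(eligible, key=lambda a: (-a.frequency_hz, a.channel_id))
    return ranked[:top_n]


def organoid_summary(
    selection: list[ChannelActivity],
    organoid_id: str = "",
    min_mean_hz: float = 0.5,
) -> OrganoidActivity:
    """Mean rate over selected channels; organoids below ``min_mean_hz`` are
    flagged for exclusion (``included=False``).  The boundary is inclusive:
    a mean of exactly 0.5 Hz is retained."""
    if not selection:
        raise ValueError("empty channel selection")
    freqs = [a.frequency_hz for a in selection]
    mean = float(np.mean(freqs))
    return OrganoidActivity(
        organoid_id=organoid_id,
        channel_ids=[a.channel_id for a in selection],
        frequencies_hz=freqs,
        mean_frequency_hz=mean,
        included=mean >= min_mean_hz,
    )
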