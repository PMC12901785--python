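"""Ground-truthed synthetic data matching the study's statistical structure.

Two generators:

* :func:`generate_mea_recording` — multichannel extracellular voltage with
  Poisson spike trains (biphasic ~1 ms waveforms) on an active subset of
  channels in Gaussian noise, periodic amplifier-recalibration pulses
  (every 400 ms by default) and rare multi-channel saturation "flashes".
* :func:`generate_expression_matrix` — a TPM matrix over four groups
  (mock/propofol at 60 and 90 days in vitro, n = 5 each) with log-normal
  baselines, a maturation signature separating 90 from 60 div, and a
  treatment signature whose overlap with the maturation set is
  configurable — the structure the representation-factor analysis probes.

Both return the full ground truth (spike times, artifact intervals, DE
flags, realized effect sizes) so detection sensitivity and DEG recovery can
be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hbopipe.deg import ExpressionMatrix
from hbopipe.mea_signal import Recording

GROUPS_DEFAULT = ("mock_60", "prop_60", "mock_90", "prop_90")


def _check(cond: bool, fieldname: str, msg: str):
    if not cond:
        raise ValueError(f"{fieldname}: {msg}")


@dataclass
class MeaSimConfig:
    """Parameters of the synthetic HD-MEA recording.

    Defaults reflect the recording protocol being emulated: 19,754 Hz
    sampling, 5-minute recordings, chip recalibration every 400 ms.
    """

    n_channels: int = 16
    fs: float = 19754.0
    duration: float = 300.0
    active_fraction: float = 0.5
    rate_hz: float = 1.0
    spike_amp: float = 80.0        # µV, negative-lobe depth before jitter
    noise_sd: float = 10.0         # µV
    recalib_period: float = 0.4    # s
    recalib_amp: float = 1500.0    # µV
    flash_rate: float = 0.02       # events/s
    flash_channel_frac: float = 0.9
    rail_uv: float = 2048.0        # ADC full-scale
    seed: int = 0

    def validate(self):
        _check(self.n_channels >= 1, "n_channels", "must be >= 1")
        _check(self.fs > 0, "fs", "must be positive")
        _check(self.duration > 0, "duration", "must be positive")
        for f in ("active_fraction", "flash_channel_frac"):
            v = getattr(self, f)
            _check(0 <= v <= 1, f, "must be in [0, 1]")
        _check(self.rate_hz >= 0, "rate_hz", "must be >= 0")
        _check(self.spike_amp >= 0, "spike_amp", "must be >= 0")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _check(self.recalib_period > 0, "recalib_period", "must be positive")
        _check(self.flash_rate >= 0, "flash_rate", "must be >= 0")
        _check(self.rail_uv > 0, "rail_uv", "must be positive")


@dataclass
class MeaGroundTruth:
    """Everything the generator injected, for exact scoring."""

    spike_times: dict[int, np.ndarray]          # channel -> sorted sample indices
    artifact_intervals: list[tuple[int, int]]   # half-open [lo, hi)
    flash_intervals: list[tuple[int, int]]

    @property
    def n_spikes(self) -> int:
        return sum(v.size for v in self.spike_times.values())


def biphasic_waveform(fs: float, amp: float, dur_ms: float = 1.0) -> np.ndarray:
    """Stereotyped extracellular action potential: a sharp negative lobe
    followed by a smaller, slower positive rebound, ~1 ms total."""
    n = max(4, int(round(dur_ms * fs / 1000.0)))
    t = np.linspace(0, 1, n)
    neg = -np.exp(-((t - 0.25) ** 2) / (2 * 0.07**2))
    pos = 0.45 * np.exp(-((t - 0.62) ** 2) / (2 * 0.14**2))
    w = neg + pos
    return amp * (w / -w.min())  # scaled so the negative lobe reaches -amp


def generate_mea_recording(cfg: MeaSimConfig) -> tuple[Recording, MeaGroundTruth]:
    """Simulate one recording plus its ground truth.

    Spikes are homogeneous-Poisson per active channel; waveform amplitudes
    jitter uniformly by +-20%.  Recalibration pulses are 1-ms square pulses
    of ``recalib_amp`` on every channel at exact multiples of
    ``recalib_period``.  Flashes saturate ``flash_channel_frac`` of channels
    at the rail for 5 ms at Poisson-random times.  Identical configs
    (including seed) give identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(np.floor(cfg.duration * cfg.fs))
    n_ch = cfg.n_channels
    x = rng.normal(0.0, cfg.noise_sd, size=(n_ch, n_samples))

    n_active = int(round(cfg.active_fraction * n_ch))
    active = rng.choice(n_ch, size=n_active, replace=False)
    wf = biphasic_waveform(cfg.fs, cfg.spike_amp)
    wlen = wf.size
    spike_times: dict[int, np.ndarray] = {ch: np.empty(0, dtype=np.int64) for ch in range(n_ch)}
    for ch in sorted(active):
        n_spk = rng.poisson(cfg.rate_hz * cfg.duration)
        if n_spk == 0:
            continue
        starts = np.sort(rng.integers(0, max(1, n_samples - wlen), size=n_spk))
        peak_off = int(np.argmin(wf))
        kept = []
        for s in starts:
            jitter = rng.uniform(0.8, 1.2)
            x[ch, s : s + wlen] += wf * jitter
            kept.append(s + peak_off)
        spike_times[ch] = np.asarray(sorted(set(kept)), dtype=np.int64)

    # recalibration pulses: 1 ms square on all channels, every recalib_period
    pulse_len = max(1, int(round(1e-3 * cfg.fs)))
    period = int(round(cfg.recalib_period * cfg.fs))
    recalib_ts = np.arange(period, n_samples, period, dtype=np.int64)
    artifact_intervals = []
    for t in recalib_ts:
        hi = min(n_samples, int(t) + pulse_len)
        x[:, t:hi] += cfg.recalib_amp
        artifact_intervals.append((int(t), hi))

    # flashes: rail saturation on a random channel subset, 5 ms
    flash_len = max(1, int(round(5e-3 * cfg.fs)))
    n_flash = rng.poisson(cfg.flash_rate * cfg.duration)
    flash_intervals = []
    n_flash_ch = int(round(cfg.flash_channel_frac * n_ch))
    for _ in range(n_flash):
        t = int(rng.integers(0, max(1, n_samples - flash_len)))
        chs = rng.choice(n_ch, size=n_flash_ch, replace=False)
        x[chs, t : t + flash_len] = cfg.rail_uv
        flash_intervals.append((t, t + flash_len))
    flash_intervals.sort()

    np.clip(x, -cfg.rail_uv, cfg.rail_uv, out=x)
    rec = Recording(
        samples=x,
        fs=cfg.fs,
        recalib_timestamps=recalib_ts,
        metadata={"rail_uv": cfg.rail_uv, "synthetic": True, "seed": cfg.seed},
    )
    return rec, MeaGroundTruth(spike_times, artifact_intervals, flash_intervals)


@dataclass
class ExprSimConfig:
    """Parameters of the synthetic four-group TPM matrix.

    The design mirrors the study layout: four groups (mock/propofol at each
    of two developmental stages), five samples each.  Effects are additive
    on log2 TPM: a "maturation" signature separates the 90-div groups
    from the 60-div groups, and treatment signatures act on the propofol
    group at each stage.  ``treatment_60_overlap`` is the fraction of
    60-div treatment-DE genes drawn from the maturation set with matching
    sign — the knob that makes representation-factor behaviour testable.
    """

    n_genes: int = 5000
    n_per_group: int = 5
    groups: tuple[str, str, str, str] = GROUPS_DEFAULT
    baseline_loc: float = 4.0      # log2-TPM location of baselines
    baseline_scale: float = 2.0    # log2 spread of baselines
    noise_sd: float = 0.25         # log2 residual noise
    maturation_n: int = 400
    maturation_effect: float = 2.0          # log2 units; sign randomized 88% up
    maturation_up_frac: float = 0.88        # matches a maturation signature dominated by up-regulation
    treatment_60_n: int = 40
    treatment_60_overlap: float = 0.8
    treatment_60_effect: float = 2.0
    treatment_90_n: int = 60
    treatment_90_effect: float = -2.0       # sign convention: negative = down-regulation
    seed: int = 0

    def validate(self):
        _check(self.n_genes >= 1, "n_genes", "must be >= 1")
        _check(self.n_per_group >= 2, "n_per_group", "must be >= 2")
        _check(len(self.groups) == 4, "groups", "exactly 4 group labels required")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        for f in ("maturation_n", "treatment_60_n", "treatment_90_n"):
            v = getattr(self, f)
            _check(0 <= v <= self.n_genes, f, "must be in [0, n_genes]")
        _check(0 <= self.treatment_60_overlap <= 1, "treatment_60_overlap", "must be in [0, 1]")
        _check(0 <= self.maturation_up_frac <= 1, "maturation_up_frac", "must be in [0, 1]")
        n_shared = int(round(self.treatment_60_overlap * self.treatment_60_n))
        n_mat_up = int(round(self.maturation_up_frac * self.maturation_n))
        _check(
            n_shared <= n_mat_up,
            "treatment_60_overlap",
            f"requires {n_shared} genes shared with the maturation-up set "
            f"but only {n_mat_up} are available",
        )


@dataclass
class ExprTruth:
    """Per-gene DE flags (+1 up, -1 down, 0 none) and realized log2 effects."""

    maturation: pd.Series
    treatment_60: pd.Series
    treatment_90: pd.Series
    effects: pd.DataFrame  # columns: maturation, treatment_60, treatment_90 (log2)


def generate_expression_matrix(cfg: ExprSimConfig) -> tuple[ExpressionMatrix, ExprTruth]:
    """Simulate the TPM matrix and its ground truth.

    log2-TPM values are baseline + maturation effect (90-div groups) +
    treatment effect (propofol group at the matching stage) + Gaussian
    noise; TPM = 2^x, so the matrix is strictly positive (log-normal) and
    configured effects are exact fold changes.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)])
    g60m, g60p, g90m, g90p = cfg.groups
    samples = []
    group_map = {}
    for g in cfg.groups:
        for r in range(cfg.n_per_group):
            s = f"{g}_r{r+1}"
            samples.append(s)
            group_map[s] = g

    baseline = rng.normal(cfg.baseline_loc, cfg.baseline_scale, size=cfg.n_genes)

    mat_flag = np.zeros(cfg.n_genes, dtype=int)
    t60_flag = np.zeros(cfg.n_genes, dtype=int)
    t90_flag = np.zeros(cfg.n_genes, dtype=int)

    mat_idx = rng.choice(cfg.n_genes, size=cfg.maturation_n, replace=False)
    n_mat_up = int(round(cfg.maturation_up_frac * cfg.maturation_n))
    mat_up = mat_idx[:n_mat_up]
    mat_down = mat_idx[n_mat_up:]
    mat_flag[mat_up] = 1
    mat_flag[mat_down] = -1

    n_shared = int(round(cfg.treatment_60_overlap * cfg.treatment_60_n))
    shared = rng.choice(mat_up, size=n_shared, replace=False) if n_shared else np.empty(0, int)
    pool = np.setdiff1d(np.arange(cfg.n_genes), mat_idx)
    fresh = rng.choice(pool, size=cfg.treatment_60_n - n_shared, replace=False)
    t60_idx = np.concatenate([shared, fresh]).astype(int)
    t60_flag[t60_idx] = 1 if cfg.treatment_60_effect >= 0 else -1

    pool90 = np.setdiff1d(np.arange(cfg.n_genes), t60_idx)
    t90_idx = rng.choice(pool90, size=cfg.treatment_90_n, replace=False)
    t90_flag[t90_idx] = 1 if cfg.treatment_90_effect >= 0 else -1

    eff_mat = mat_flag * np.abs(cfg.maturation_effect)
    eff_t60 = np.where(t60_flag != 0, cfg.treatment_60_effect, 0.0)
    eff_t90 = np.where(t90_flag != 0, cfg.treatment_90_effect, 0.0)

    log2 = np.empty((cfg.n_genes, len(samples)))
    for j, s in enumerate(samples):
        g = group_map[s]
        mu = baseline.copy()
        if g in (g90m, g90p):
            mu = mu + eff_mat
        if g == g60p:
            mu = mu + eff_t60
        if g == g90p:
            mu = mu + eff_t90
        log2[:, j] = mu + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
    tpm = 2.0**log2

    values = pd.DataFrame(tpm, index=genes, columns=samples)
    matrix = ExpressionMatrix(values=values, groups=pd.Series(group_map))
    truth = ExprTruth(
        maturation=pd.Series(mat_flag, index=genes),
        treatment_60=pd.Series(t60_flag, index=genes),
        treatment_90=pd.Series(t90_flag, index=genes),
        effects=pd.DataFrame(
            {"maturation": eff_mat, "treatment_60": eff_t60, "treatment_90": eff_t90},
            index=genes,
        ),
    )
    return matrix, truth
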