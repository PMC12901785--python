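"""HDF5 recording container and tabular readers/writers.

A recording file holds datasets ``samples`` (channels x time, µV), ``fs``
(scalar Hz), ``recalib_timestamps`` (sample indices) and ``channel_ids``,
plus free-form string/scalar attributes for metadata.  Expression matrices
travel as TSV (genes x samples, header row of sample ids); spike trains and
activity summaries as CSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from hbopipe.deg import ExpressionMatrix
from hbopipe.mea_signal import Recording
from hbopipe.spikes import OrganoidActivity, SpikeTrain


def write_recording(rec: Recording, path: str | Path):
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rec.samples)
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset("recalib_timestamps", data=rec.recalib_timestamps)
        f.create_dataset("channel_ids", data=rec.channel_ids)
        for k, v in rec.metadata.items():
            f.attrs[k] = v


def read_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        for name in ("samples", "fs", "recalib_timestamps", "channel_ids"):
            if name not in f:
                raise KeyError(f"recording file {path} is missing dataset {name!r}")
        fs = float(f["fs"][()])
        if fs <= 0:
            raise ValueError(f"recording file {path}: fs must be positive, got {fs}")
        meta = {}
        for k, v in f.attrs.items():
            meta[k] = v.item() if isinstance(v, np.generic) else v
        return Recording(
            samples=f["samples"][()],
            fs=fs,
            recalib_timestamps=f["recalib_timestamps"][()],
            channel_ids=f["channel_ids"][()],
            metadata=meta,
        )


def read_expression_tsv(path: str | Path, groups: dict[str, str] | pd.Series) -> ExpressionMatrix:
    """TSV with gene ids in the first column and sample ids as header."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, groups=pd.Series(dict(groups)))


def write_expression_tsv(m: ExpressionMatrix, path: str | Path):
    m.values.to_csv(path, sep="\t")


def spike_trains_to_frame(trains: list[SpikeTrain], fs: float, organoid_id: str = "") -> pd.DataFrame:
    rows = []
    for tr in trains:
        for t, a in zip(tr.times, tr.amplitudes):
            rows.append((organoid_id, tr.channel_id, t / fs, a))
    return pd.DataFrame(rows, columns=["organoid", "channel", "time_s", "amplitude_uV"])


def activity_to_frame(summaries: list[OrganoidActivity]) -> pd.DataFrame:
    rows = [
        (s.organoid_id, len(s.channel_ids), s.mean_frequency_hz, s.included)
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=["organoid", "n_channels", "mean_freq_hz", "included"])
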