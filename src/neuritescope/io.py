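"""Recording and table I/O.

MEA recordings travel as HDF5 (``traces`` dataset, channels x samples, with
``sampling_rate`` and ``units`` attributes) plus an optional electrode ->
chamber map CSV.  Result tables are CSV with floats rounded to six
significant digits at write time so repeated runs diff cleanly.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .ephys import RawRecording, SpikeTrain


def write_recording(path, rec: RawRecording) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("traces", data=rec.traces.astype(np.float32),
                               compression="gzip", compression_opts=4)
        ds.attrs["sampling_rate"] = rec.sampling_rate
        ds.attrs["units"] = "uV"
    if rec.channel_map is not None:
        rec.channel_map.to_csv(str(path) + ".channels.csv", index=False)


def read_recording(path) -> RawRecording:
    with h5py.File(path, "r") as fh:
        ds = fh["traces"]
        traces = ds[...]
        rate = float(ds.attrs["sampling_rate"])
    try:
        channel_map = pd.read_csv(str(path) + ".channels.csv")
    except FileNotFoundError:
        channel_map = None
    return RawRecording(traces, rate, channel_map)


def spikes_table(trains: list[SpikeTrain]) -> pd.DataFrame:
    rows = [dict(electrode=t.electrode, t_s=ts) for t in trains for ts in t.times]
    return pd.DataFrame(rows, columns=["electrode", "t_s"])


def write_table(path, table: pd.DataFrame) -> None:
    """CSV with 6-significant-digit floats for reproducible diffs."""
    table.to_csv(path, index=False, float_format="%.6g")
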