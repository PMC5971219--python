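"""Channel time-series I/O: a minimal SNIRF-layout HDF5 writer/reader and
long-format CSV.

The SNIRF subset written here covers continuous-wave amplitude or processed
(OD/concentration) blocks: /nirs/data1/dataTimeSeries + time, one
measurementList entry per row, and the probe's source/detector positions.
It is intentionally small -- enough for round-tripping this package's own
recordings and for inspection with generic HDF5 tools.
"""

from __future__ import annotations

import numpy as np

from .mesh import OptodeArray
from .preprocess import ChannelTimeSeries

__all__ = ["write_snirf", "read_snirf", "write_csv", "read_csv"]

_KIND_TO_SNIRF = {"intensity": 1, "optical_density": 99991, "concentration": 99992}
_SNIRF_TO_KIND = {v: k for k, v in _KIND_TO_SNIRF.items()}


def write_snirf(path, series: ChannelTimeSeries, array: OptodeArray = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=series.values.T)
        data.create_dataset("time", data=series.times)
        for i, meta in enumerate(series.channel_meta, start=1):
            ml = data.create_group(f"measurementList{i}")
            ml.create_dataset("dataType", data=_KIND_TO_SNIRF[series.kind])
            ml.create_dataset("dataTypeLabel", data=np.bytes_(str(meta)))
            ml.create_dataset("sourceIndex", data=1)
            ml.create_dataset("detectorIndex", data=1)
        if array is not None:
            probe = nirs.create_group("probe")
            src = np.array([array.sources[k] for k in sorted(array.sources)])
            det = np.array([array.detectors[k] for k in sorted(array.detectors)])
            probe.create_dataset("sourcePos3D", data=src)
            probe.create_dataset("detectorPos3D", data=det)
            probe.create_dataset(
                "sourceLabels", data=np.array(sorted(array.sources), dtype="S")
            )
            probe.create_dataset(
                "detectorLabels", data=np.array(sorted(array.detectors), dtype="S")
            )


def read_snirf(path) -> ChannelTimeSeries:
    import h5py

    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        values = data["dataTimeSeries"][()].T
        time = data["time"][()]
        fs = round(1.0 / float(np.median(np.diff(time))), 9)
        meta, kind = [], "intensity"
        for i in range(1, values.shape[0] + 1):
            ml = data[f"measurementList{i}"]
            kind = _SNIRF_TO_KIND.get(int(ml["dataType"][()]), "intensity")
            meta.append(ml["dataTypeLabel"][()].decode())
    return ChannelTimeSeries(values, fs, kind, meta)


def write_csv(path, series: ChannelTimeSeries) -> None:
    series.save_csv(path)


def read_csv(path, sampling_rate=None, kind="optical_density") -> ChannelTimeSeries:
    import pandas as pd

    frame = pd.read_csv(path)
    channels = list(dict.fromkeys(frame["channel"]))
    wide = frame.pivot_table(index="channel", columns="time", values="value", sort=False)
    wide = wide.loc[channels]
    times = np.asarray(wide.columns, dtype=float)
    fs = sampling_rate or 1.0 / float(np.median(np.diff(times)))
    return ChannelTimeSeries(wide.to_numpy(), fs, kind, channels)
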