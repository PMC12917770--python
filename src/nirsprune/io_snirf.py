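"""Minimal SNIRF (HDF5) reader/writer for raw two-wavelength intensity data.

Implements the subset of the SNIRF v1.1 layout needed for round-tripping
:class:`~nirsprune.recording.RawIntensityRecording`: one ``/nirs/data1``
block with a (time x measurement) ``dataTimeSeries``, one
``measurementListN`` group per channel-wavelength pair (dataType 1, raw
amplitude), the probe wavelength table, and metaDataTags. Channel ``i``
is written as source ``i+1`` paired with detector ``i+1``; optode
geometry is out of scope.
"""

from __future__ import annotations

import numpy as np

from .recording import RawIntensityRecording

__all__ = ["write_snirf", "read_snirf", "SnirfParseError"]


class SnirfParseError(ValueError):
    """Raised when a SNIRF file lacks a required field."""


def _str_dataset(group, name: str, value: str) -> None:
    group.create_dataset(name, data=np.bytes_(value))


def write_snirf(recording: RawIntensityRecording, path) -> None:
    """Write a recording to ``path`` in SNIRF v1.1 layout."""
    import h5py

    n_ch, _, n_samp = recording.intensity.shape
    with h5py.File(path, "w") as f:
        _str_dataset(f, "formatVersion", "1.1")
        nirs = f.create_group("/nirs")
        meta = nirs.create_group("metaDataTags")
        p = recording.participant
        _str_dataset(meta, "SubjectID", str(p.get("id", "unknown")))
        _str_dataset(meta, "MeasurementDate", "unknown")
        _str_dataset(meta, "MeasurementTime", "unknown")
        _str_dataset(meta, "LengthUnit", "mm")
        _str_dataset(meta, "TimeUnit", "s")
        _str_dataset(meta, "FrequencyUnit", "Hz")
        for key in ("age_months", "cohort", "task"):
            if key in p:
                _str_dataset(meta, key, str(p[key]))

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(recording.wavelengths, dtype=float))
        # geometry is not modelled; nominal co-located positions keep the layout valid
        pos = np.zeros((n_ch, 3))
        pos[:, 0] = np.arange(n_ch)
        probe.create_dataset("sourcePos3D", data=pos)
        probe.create_dataset("detectorPos3D", data=pos)

        data = nirs.create_group("data1")
        # measurement columns ordered channel-major: (ch0, wl0), (ch0, wl1), (ch1, wl0), ...
        series = recording.intensity.reshape(n_ch * 2, n_samp).T
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=np.arange(n_samp) / recording.sampling_rate)
        for c in range(n_ch):
            for w in range(2):
                ml = data.create_group(f"measurementList{c * 2 + w + 1}")
                ml.create_dataset("sourceIndex", data=np.int32(c + 1))
                ml.create_dataset("detectorIndex", data=np.int32(c + 1))
                ml.create_dataset("wavelengthIndex", data=np.int32(w + 1))
                ml.create_dataset("dataType", data=np.int32(1))  # raw amplitude
                ml.create_dataset("dataTypeIndex", data=np.int32(1))


def _require(group, name: str, path_desc: str):
    if name not in group:
        raise SnirfParseError(f"SNIRF file is missing required field '{path_desc}/{name}'")
    return group[name]


def read_snirf(path) -> RawIntensityRecording:
    """Read a SNIRF file written by :func:`write_snirf` (or compatible layout)."""
    import h5py

    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f.get("nirs1")
        if nirs is None:
            raise SnirfParseError("SNIRF file is missing required group '/nirs'")
        probe = _require(nirs, "probe", "/nirs")
        wavelengths = np.asarray(_require(probe, "wavelengths", "/nirs/probe")[()], dtype=float)
        if wavelengths.size != 2:
            raise SnirfParseError("exactly two wavelengths are supported")
        data = _require(nirs, "data1", "/nirs")
        series = np.asarray(_require(data, "dataTimeSeries", "/nirs/data1")[()], dtype=float)
        time = np.asarray(_require(data, "time", "/nirs/data1")[()], dtype=float)
        if time.size < 2:
            raise SnirfParseError("time vector must contain at least two samples")
        sampling_rate = 1.0 / float(time[1] - time[0])

        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        if not ml_names:
            raise SnirfParseError("SNIRF file has no measurementList entries")
        columns = {}
        for j, name in enumerate(ml_names):
            ml = data[name]
            src = int(_require(ml, "sourceIndex", f"/nirs/data1/{name}")[()])
            wli = int(_require(ml, "wavelengthIndex", f"/nirs/data1/{name}")[()])
            columns[(src - 1, wli - 1)] = series[:, j]
        n_ch = max(c for c, _ in columns) + 1
        n_samp = series.shape[0]
        intensity = np.empty((n_ch, 2, n_samp))
        for c in range(n_ch):
            for w in range(2):
                if (c, w) not in columns:
                    raise SnirfParseError(f"missing measurement for channel {c}, wavelength {w}")
                intensity[c, w] = columns[(c, w)]

        meta = nirs.get("metaDataTags")
        participant = {}
        if meta is not None:
            def _get(name):
                if name in meta:
                    v = meta[name][()]
                    return v.decode() if isinstance(v, bytes) else str(v)
                return None

            if _get("SubjectID") not in (None, "unknown"):
                participant["id"] = _get("SubjectID")
            for key, cast in (("age_months", int), ("cohort", str), ("task", str)):
                v = _get(key)
                if v is not None:
                    try:
                        participant[key] = cast(v)
                    except ValueError:
                        participant[key] = v

    return RawIntensityRecording(
        intensity=intensity,
        sampling_rate=sampling_rate,
        wavelengths=(float(wavelengths[0]), float(wavelengths[1])),
        participant=participant,
    )
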