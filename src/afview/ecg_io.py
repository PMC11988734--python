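"""ECG record containers, file I/O, and band-limiting pre-filtering.

Records hold single- or two-lead ECG in microvolts together with the beat
(QRS) annotations and atrial-fibrillation episode intervals that every
downstream stage consumes.  Two on-disk dialects are supported:

* native HDF5 — per-lead datasets ``ecg/<lead>``, root attribute ``fs``,
  datasets ``qrs`` (sample indices) and ``af_episodes`` (n x 2, half-open
  ``[onset, offset)`` sample intervals);
* CSV — header ``t_s,<lead1>[,<lead2>]`` plus a sidecar JSON
  (``<path>.json``) carrying ``fs``, ``qrs_idx`` and ``af_episodes``.

Sample indices are 0-based throughout; episode intervals are half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from scipy import signal as sps

__all__ = [
    "ECGRecord",
    "FilterSpec",
    "read_record",
    "write_record",
    "bandpass_filter",
]


@dataclass
class ECGRecord:
    """Multi-lead ECG with beat and AF-episode annotations.

    Parameters
    ----------
    record_id : str
        Identifier, unique within a cohort.
    leads : list of str
        Lead names in signal row order (e.g. ``["I", "II"]``).
    signal : ndarray, shape (n_leads, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz (Holter convention here is 200 Hz).
    qrs_idx : ndarray of int
        Strictly increasing QRS sample indices, shared across leads.
    af_episodes : list of (int, int)
        Half-open ``[onset, offset)`` sample intervals annotated as AF.
    meta : dict
        Free-form provenance (generator config, source file, ...).
    """

    record_id: str
    leads: list[str]
    signal: np.ndarray
    fs: float = 200.0
    qrs_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    af_episodes: list[tuple[int, int]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim == 1:
            self.signal = self.signal[None, :]
        if self.signal.ndim != 2:
            raise ValueError("signal must be (n_leads, n_samples)")
        if len(self.leads) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.leads)} lead names for {self.signal.shape[0]} signal rows"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.qrs_idx = np.asarray(self.qrs_idx, dtype=np.int64)
        if self.qrs_idx.size and np.any(np.diff(self.qrs_idx) <= 0):
            raise ValueError("qrs_idx must be strictly increasing")
        if self.qrs_idx.size and (
            self.qrs_idx[0] < 0 or self.qrs_idx[-1] >= self.n_samples
        ):
            raise ValueError("qrs_idx outside the record")
        eps = []
        for onset, offset in self.af_episodes:
            onset, offset = int(onset), int(offset)
            if not (0 <= onset < offset <= self.n_samples):
                raise ValueError(f"bad AF episode ({onset}, {offset})")
            eps.append((onset, offset))
        self.af_episodes = eps

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead_signal(self, lead: str) -> np.ndarray:
        try:
            return self.signal[self.leads.index(lead)]
        except ValueError:
            raise KeyError(f"record {self.record_id} has no lead {lead!r}") from None

    def af_mask(self) -> np.ndarray:
        """Boolean per-sample mask of annotated AF."""
        mask = np.zeros(self.n_samples, dtype=bool)
        for onset, offset in self.af_episodes:
            mask[onset:offset] = True
        return mask


@dataclass(frozen=True)
class FilterSpec:
    """Band-limiting pre-filter: cascade of first-order Butterworth sections.

    A true single-section first-order band-pass does not exist, so the
    stated order applies per edge: one first-order high-pass at
    ``highpass_hz`` and one first-order low-pass at ``lowpass_hz``.
    ``zero_phase`` applies each section forward-backward (filtfilt), which
    squares the magnitude response but leaves annotations phase-aligned.
    """

    highpass_hz: float = 0.5
    lowpass_hz: float = 40.0
    order: int = 1
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not (0 < self.highpass_hz < self.lowpass_hz):
            raise ValueError("need 0 < highpass_hz < lowpass_hz")
        if self.lowpass_hz >= fs / 2:
            raise ValueError(
                f"lowpass_hz={self.lowpass_hz} at or above Nyquist ({fs / 2} Hz)"
            )
        if self.order < 1:
            raise ValueError("order must be >= 1")


def bandpass_filter(record: ECGRecord, spec: FilterSpec | None = None) -> ECGRecord:
    """Apply the band-limiting pre-filter to every lead of a record.

    Returns a new record of identical length; QRS and episode annotations
    are carried over untouched.
    """
    spec = spec or FilterSpec()
    spec.validate(record.fs)
    sos_hp = sps.butter(spec.order, spec.highpass_hz, "highpass", fs=record.fs, output="sos")
    sos_lp = sps.butter(spec.order, spec.lowpass_hz, "lowpass", fs=record.fs, output="sos")
    out = np.empty_like(record.signal)
    for i in range(record.signal.shape[0]):
        x = record.signal[i]
        if spec.zero_phase:
            x = sps.sosfiltfilt(sos_hp, x)
            x = sps.sosfiltfilt(sos_lp, x)
        else:
            x = sps.sosfilt(sos_hp, x)
            x = sps.sosfilt(sos_lp, x)
        out[i] = x
    return replace(record, signal=out, meta={**record.meta, "filtered": spec.__dict__.copy()})


# ---------------------------------------------------------------------------
# file I/O


def write_record(record: ECGRecord, path: str | Path, format: str | None = None) -> Path:
    """Write a record in the native HDF5 layout or the CSV + JSON dialect."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "hdf5")
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["fs"] = float(record.fs)
            f.attrs["record_id"] = record.record_id
            f.attrs["leads"] = json.dumps(record.leads)
            grp = f.create_group("ecg")
            for name, row in zip(record.leads, record.signal):
                grp.create_dataset(name, data=row)
            f.create_dataset("qrs", data=record.qrs_idx)
            f.create_dataset(
                "af_episodes",
                data=np.asarray(record.af_episodes, dtype=np.int64).reshape(-1, 2),
            )
    elif fmt == "csv":
        t = np.arange(record.n_samples) / record.fs
        header = "t_s," + ",".join(record.leads)
        np.savetxt(
            path,
            np.column_stack([t, record.signal.T]),
            delimiter=",",
            header=header,
            comments="",
            fmt="%.17g",  # lossless float round-trip
        )
        sidecar = {
            "record_id": record.record_id,
            "fs": record.fs,
            "qrs_idx": record.qrs_idx.tolist(),
            "af_episodes": [list(e) for e in record.af_episodes],
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_record(path: str | Path, format: str | None = None) -> ECGRecord:
    """Read a record written by :func:`write_record`.

    Raises if annotations are missing or violate the record invariants
    (non-monotonic QRS indices, out-of-range episodes).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "hdf5")
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "qrs" not in f or "af_episodes" not in f:
                raise ValueError(f"{path}: missing qrs/af_episodes annotations")
            leads = json.loads(f.attrs["leads"])
            signal = np.stack([f["ecg"][name][()] for name in leads])
            return ECGRecord(
                record_id=str(f.attrs.get("record_id", path.stem)),
                leads=leads,
                signal=signal,
                fs=float(f.attrs["fs"]),
                qrs_idx=f["qrs"][()],
                af_episodes=[tuple(map(int, e)) for e in f["af_episodes"][()]],
            )
    if fmt == "csv":
        sidecar_path = Path(str(path) + ".json")
        if not sidecar_path.exists():
            raise ValueError(f"{path}: sidecar JSON with annotations not found")
        sidecar = json.loads(sidecar_path.read_text())
        with open(path) as fh:
            leads = fh.readline().strip().split(",")[1:]
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return ECGRecord(
            record_id=str(sidecar.get("record_id", path.stem)),
            leads=leads,
            signal=data[:, 1:].T,
            fs=float(sidecar["fs"]),
            qrs_idx=np.asarray(sidecar["qrs_idx"], dtype=np.int64),
            af_episodes=[tuple(map(int, e)) for e in sidecar["af_episodes"]],
        )
    raise ValueError(f"unknown format {fmt!r}")


def episode_coverage(
    episodes: Sequence[tuple[int, int]], start: int, stop: int
) -> float:
    """Fraction of samples in ``[start, stop)`` covered by the episodes."""
    if stop <= start:
        raise ValueError("empty interval")
    covered = 0
    for onset, offset in episodes:
        covered += max(0, min(offset, stop) - max(onset, start))
    return covered / (stop - start)
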