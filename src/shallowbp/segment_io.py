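"""Waveform segment containers and container-format I/O.

The pipeline works on short, synchronized multi-channel snippets of
physiological waveforms: photoplethysmogram (PPG), electrocardiogram (ECG)
and arterial blood pressure (ABP), all sampled at the same rate (125 Hz for
the reference corpora) and 1024 samples long after conditioning.  This
module defines the canonical in-memory containers (:class:`WaveformSegment`,
:class:`SegmentRecord`, :class:`SegmentStore`) plus readers/writers for the
container formats the pipeline touches:

* MAT-style files (both classic ``scipy.io`` level-5 files and HDF5-backed
  v7.3 layouts), read-only;
* a generic HDF5 layout (one 2-D dataset per channel, aligned id tables),
  the canonical on-disk form;
* bare CSV matrices (rows = segments, columns = samples) with a declared
  channel kind — never guessed from the data.

It also hosts rate conversion (polyphase, zero-phase anti-aliasing) and the
volt-to-mmHg denormalization needed for external corpora whose continuous
pressure channel is stored at a fixed mmHg-per-volt scale.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterator, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import io as sio
from scipy.signal import resample_poly

#: Channel kinds understood by the pipeline, in canonical stacking order.
CHANNEL_KINDS = ("PPG", "VPG", "APG", "ECG", "ABP")

#: Default channel row convention for bare 3-row matrices (the common
#: cuffless-BP ".mat" layout): pulse waveform first, pressure second, ECG third.
DEFAULT_MAT_CHANNEL_ORDER = ("PPG", "ABP", "ECG")


class SegmentIOError(IOError):
    """Raised when a store file cannot be read or written."""


class MalformedRecordError(ValueError):
    """Raised when a record violates the container invariants."""


@dataclass(frozen=True)
class WaveformSegment:
    """A single-channel waveform snippet.

    Parameters
    ----------
    samples : ndarray
        Real amplitudes, finite, length >= 2.
    fs : float
        Sampling rate in Hz, > 0.
    kind : str
        One of ``PPG, ECG, ABP, VPG, APG``.
    units : str
        Free-text unit tag, e.g. ``"mmHg"`` or ``"norm"``.
    """

    samples: np.ndarray
    fs: float
    kind: str
    units: str = "arb"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise MalformedRecordError(
                f"segment must be a 1-D sequence of length >= 2, got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise MalformedRecordError("segment contains non-finite samples")
        if not self.fs > 0:
            raise MalformedRecordError(f"sampling rate must be positive, got {self.fs}")
        if self.kind not in CHANNEL_KINDS:
            raise MalformedRecordError(f"unknown channel kind {self.kind!r}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Segment duration in seconds (n_samples / fs)."""
        return len(self) / self.fs


@dataclass(frozen=True)
class SegmentRecord:
    """One synchronized multi-channel segment with provenance ids."""

    segment_id: str
    subject_id: str
    channels: Mapping[str, WaveformSegment]

    def __post_init__(self) -> None:
        channels = dict(self.channels)
        object.__setattr__(self, "channels", channels)
        if not channels:
            raise MalformedRecordError(f"record {self.segment_id}: no channels")
        lengths = {len(seg) for seg in channels.values()}
        rates = {seg.fs for seg in channels.values()}
        if len(lengths) != 1 or len(rates) != 1:
            raise MalformedRecordError(
                f"record {self.segment_id}: channels disagree in length {sorted(lengths)} "
                f"or rate {sorted(rates)}"
            )
        for kind, seg in channels.items():
            if seg.kind != kind:
                raise MalformedRecordError(
                    f"record {self.segment_id}: channel key {kind!r} holds kind {seg.kind!r}"
                )

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def channel(self, kind: str) -> WaveformSegment:
        try:
            return self.channels[kind]
        except KeyError:
            raise KeyError(f"record {self.segment_id} has no {kind} channel") from None

    def with_channels(self, **updates: WaveformSegment) -> "SegmentRecord":
        merged = dict(self.channels)
        merged.update(updates)
        return replace(self, channels=merged)


@dataclass
class SegmentStore:
    """An ordered collection of records with source metadata.

    The ``history`` metadata list is append-only: each pipeline stage adds
    exactly one flag (e.g. ``"baseline_corrected"``).
    """

    records: list[SegmentRecord] = field(default_factory=list)
    source: str = "unknown"
    history: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SegmentRecord]:
        return iter(self.records)

    def __post_init__(self) -> None:
        ids = [r.segment_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise MalformedRecordError("duplicate segment_id in store")

    @property
    def fs(self) -> float:
        if not self.records:
            raise ValueError("empty store has no sampling rate")
        return self.records[0].fs

    def channel_kinds(self) -> tuple[str, ...]:
        present = set.intersection(*(set(r.channels) for r in self.records)) if self.records else set()
        return tuple(k for k in CHANNEL_KINDS if k in present)

    def channel_matrix(self, kind: str) -> np.ndarray:
        """Stack one channel across records into an (n_records, n_samples) array."""
        return np.stack([r.channel(kind).samples for r in self.records])

    def segment_ids(self) -> list[str]:
        return [r.segment_id for r in self.records]

    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def with_history(self, flag: str) -> "SegmentStore":
        return SegmentStore(list(self.records), self.source, self.history + [flag])

    def subset(self, indices: Sequence[int]) -> "SegmentStore":
        return SegmentStore([self.records[i] for i in indices], self.source, list(self.history))


# ---------------------------------------------------------------------------
# readers / writers


def _records_from_matrices(
    matrices: Mapping[str, np.ndarray],
    fs: float,
    source: str,
    units: Mapping[str, str] | None = None,
    segment_ids: Sequence[str] | None = None,
    subject_ids: Sequence[str] | None = None,
) -> SegmentStore:
    units = units or {}
    counts = {k: m.shape[0] for k, m in matrices.items()}
    if len(set(counts.values())) != 1:
        raise MalformedRecordError(f"channel matrices disagree in record count: {counts}")
    n = next(iter(counts.values()))
    if segment_ids is None:
        segment_ids = [f"seg{i:06d}" for i in range(n)]
    if subject_ids is None:
        subject_ids = ["unknown"] * n
    records = []
    for i in range(n):
        chans = {}
        for kind, mat in matrices.items():
            chans[kind] = WaveformSegment(
                mat[i], fs=fs, kind=kind, units=units.get(kind, "mmHg" if kind == "ABP" else "arb")
            )
        records.append(SegmentRecord(str(segment_ids[i]), str(subject_ids[i]), chans))
    return SegmentStore(records, source=source)


def read_store(
    path: str | os.PathLike,
    format: str = "hdf5",
    fs: float = 125.0,
    channel_order: Sequence[str] = DEFAULT_MAT_CHANNEL_ORDER,
    csv_channel: str = "PPG",
) -> SegmentStore:
    """Read a segment store from disk.

    Parameters
    ----------
    path : path
        File to read.
    format : {"hdf5", "mat", "csv"}
        Container layout.  ``"mat"`` accepts both classic and HDF5-backed
        v7.3 MAT files whose variables are (n_channels x n_samples) matrices
        per segment or one (n_channels x n_samples x n_segments) array; the
        channel row convention is declared via ``channel_order``.
    fs : float
        Sampling rate to stamp on formats that do not carry one.
    channel_order : sequence of str
        Declared row-to-kind mapping for bare matrices.
    csv_channel : str
        Channel kind declared for a bare CSV matrix.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise SegmentIOError(f"no such file: {path}")
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "csv":
        try:
            mat = np.loadtxt(path, delimiter=",", ndmin=2)
        except Exception as exc:  # pragma: no cover - numpy error text varies
            raise SegmentIOError(f"unreadable CSV matrix: {path}: {exc}") from exc
        return _records_from_matrices({csv_channel: mat}, fs=fs, source=path)
    if format == "mat":
        return _read_mat(path, fs=fs, channel_order=channel_order)
    raise ValueError(f"unsupported format {format!r}")


def _read_hdf5(path: str) -> SegmentStore:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise SegmentIOError(f"unreadable HDF5 file: {path}: {exc}") from exc
    with f:
        fs = float(f.attrs["fs"])
        source = str(f.attrs.get("source", path))
        history = [str(h) for h in f.attrs.get("history", [])]
        seg_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["segment_ids"][()]]
        sub_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["subject_ids"][()]]
        matrices = {}
        units = {}
        for kind in f["channels"]:
            ds = f["channels"][kind]
            matrices[kind] = ds[()]
            units[kind] = str(ds.attrs.get("units", "arb"))
    store = _records_from_matrices(
        matrices, fs=fs, source=source, units=units, segment_ids=seg_ids, subject_ids=sub_ids
    )
    store.history = history
    return store


def _read_mat(path: str, fs: float, channel_order: Sequence[str]) -> SegmentStore:
    """Read MAT-style files: classic level-5 via scipy, v7.3 via h5py."""
    try:
        data = sio.loadmat(path)
        arrays = {k: np.asarray(v) for k, v in data.items() if not k.startswith("__")}
    except NotImplementedError:
        arrays = {}
        with h5py.File(path, "r") as f:
            for k in f:
                if isinstance(f[k], h5py.Dataset):
                    arrays[k] = f[k][()].T  # MATLAB stores column-major
    if not arrays:
        raise SegmentIOError(f"no data variables in MAT file: {path}")
    name, arr = max(arrays.items(), key=lambda kv: kv[1].size)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None, ...] if arr.shape[0] == len(channel_order) else arr[:, None, :]
    if arr.ndim != 3:
        raise SegmentIOError(f"MAT variable {name!r} has unsupported shape {arr.shape}")
    # arr: (n_segments, n_channels, n_samples)
    if arr.shape[1] != len(channel_order):
        raise MalformedRecordError(
            f"MAT variable {name!r}: {arr.shape[1]} channel rows but "
            f"{len(channel_order)} declared kinds {tuple(channel_order)}"
        )
    matrices = {kind: arr[:, i, :] for i, kind in enumerate(channel_order)}
    return _records_from_matrices(matrices, fs=fs, source=path)


def write_store(store: SegmentStore, path: str | os.PathLike, format: str = "hdf5") -> None:
    """Write a store to disk in HDF5 (exact) or CSV (one file per channel)."""
    if len(store) == 0:
        raise ValueError("refusing to write an empty store")
    path = os.fspath(path)
    if format == "hdf5":
        try:
            f = h5py.File(path, "w")
        except OSError as exc:
            raise SegmentIOError(f"unwritable path: {path}: {exc}") from exc
        with f:
            f.attrs["fs"] = store.fs
            f.attrs["source"] = store.source
            f.attrs["history"] = store.history
            sdt = h5py.string_dtype()
            f.create_dataset("segment_ids", data=store.segment_ids(), dtype=sdt)
            f.create_dataset("subject_ids", data=store.subject_ids(), dtype=sdt)
            g = f.create_group("channels")
            for kind in store.channel_kinds():
                ds = g.create_dataset(kind, data=store.channel_matrix(kind))
                ds.attrs["units"] = store.records[0].channel(kind).units
        return
    if format == "csv":
        base, ext = os.path.splitext(path)
        for kind in store.channel_kinds():
            np.savetxt(f"{base}.{kind}{ext or '.csv'}", store.channel_matrix(kind), delimiter=",")
        return
    raise ValueError(f"unsupported format {format!r}")


def read_labels(path: str | os.PathLike) -> pd.DataFrame:
    """Read a label table CSV with header ``segment_id,subject_id,sbp,dbp,map``."""
    df = pd.read_csv(path, dtype={"segment_id": str, "subject_id": str})
    required = {"segment_id", "subject_id", "sbp", "dbp", "map"}
    missing = required - set(df.columns)
    if missing:
        raise SegmentIOError(f"label table missing columns: {sorted(missing)}")
    return df


def write_labels(labels: pd.DataFrame, path: str | os.PathLike) -> None:
    labels.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# rate conversion / external-data denormalization


def resample_segment(seg: WaveformSegment, target_fs: float) -> WaveformSegment:
    """Resample a segment to ``target_fs`` with polyphase anti-aliased filtering.

    Output length is ``round(n * target_fs / fs)``; a zero-phase FIR
    anti-aliasing low-pass is applied internally when down-sampling so the
    channels of a record stay synchronized.  ``target_fs == fs`` is the
    identity.
    """
    if not target_fs > 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if target_fs == seg.fs:
        return seg
    ratio = Fraction(target_fs / seg.fs).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    out = resample_poly(seg.samples, up, down)
    expected = int(round(len(seg) * target_fs / seg.fs))
    if len(out) > expected:
        out = out[:expected]
    elif len(out) < expected:
        out = np.pad(out, (0, expected - len(out)), mode="edge")
    return WaveformSegment(out, fs=target_fs, kind=seg.kind, units=seg.units)


def resample_store(store: SegmentStore, target_fs: float) -> SegmentStore:
    records = [
        r.with_channels(**{k: resample_segment(s, target_fs) for k, s in r.channels.items()})
        for r in store
    ]
    return SegmentStore(records, store.source, store.history + [f"resampled_{target_fs:g}Hz"])


def denormalize_external_abp(seg: WaveformSegment, scale: float = 100.0) -> WaveformSegment:
    """Convert a volt-scaled continuous pressure channel to mmHg.

    External corpora that store reconstructed brachial pressure at a fixed
    mmHg-per-volt scale (100 mmHg/volt for the reference external set) are
    brought back to absolute mmHg by multiplying through by ``scale``.
    """
    if seg.kind != "ABP":
        raise ValueError(f"denormalization applies to ABP channels only, got {seg.kind}")
    if not scale > 0:
        raise ValueError(f"scale must be positive, got {scale}")
    return WaveformSegment(seg.samples * scale, fs=seg.fs, kind="ABP", units="mmHg")
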