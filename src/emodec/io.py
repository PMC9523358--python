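"""Reading and writing continuous EEG, event annotations, and segment tensors.

Continuous signals travel as :class:`Recording` (samples x channels,
microvolts).  On disk they are supported in three forms:

* **BDF** -- the 24-bit BioSemi dialect of the European Data Format, the
  native format of high-density ActiveTwo amplifiers.
* **EDF** -- the 16-bit original.
* **container** -- a lossless HDF5 file with embedded events, used for
  intermediates.

Event annotations use the BIDS ``events.tsv`` dialect: UTF-8,
tab-separated, columns ``onset`` (seconds) and ``trial_type`` (label).
A sidecar events table always wins over events embedded in a signal file.

Epoched data travels as :class:`SegmentSet` (N segments x P samples x C
channels) and round-trips losslessly through one HDF5 container per
(subject, band) -- see :func:`save_segments`.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "Event",
    "Recording",
    "SegmentSet",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "save_segments",
    "load_segments",
]


@dataclass(frozen=True)
class Event:
    """A point annotation: seconds from recording start plus a free-form label.

    In the study design an event is the moment the subject pressed the
    "feeling it" button, labelled with one of 15 emotion names.
    """

    onset_s: float
    label: str

    def __post_init__(self):
        if self.onset_s < 0:
            raise ValidationError(f"event onset must be >= 0, got {self.onset_s}")


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data
        Signal matrix, shape ``(n_samples, n_channels)``, microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        One unique label per channel.
    subject_id
        Free-form subject identifier.
    events
        Point annotations; onsets must fall inside the recording.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = ""
    events: list[Event] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2-D (samples x channels) array")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.n_samples < 1 or self.n_channels < 1:
            raise ValidationError("recording must have >= 1 sample and >= 1 channel")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.n_channels:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )
        if len(set(self.channel_labels)) != self.n_channels:
            raise ValidationError("channel labels must be unique")
        for ev in self.events:
            if not 0 <= ev.onset_s < self.duration_s:
                raise ValidationError(
                    f"event at {ev.onset_s} s outside [0, {self.duration_s}) s"
                )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def subset_channels(self, indices: Sequence[int]) -> "Recording":
        """Return a copy restricted to ``indices``, in the given order."""
        idx = list(indices)
        return replace(
            self,
            data=self.data[:, idx].copy(),
            channel_labels=[self.channel_labels[i] for i in idx],
            events=list(self.events),
        )


@dataclass
class SegmentSet:
    """Fixed-length epochs with binary labels.

    ``tensor`` has shape ``(N, P, C)``: N segments of P samples over C
    channels.  ``band`` records which frequency band the data were filtered
    into (a :class:`~emodec.preprocess.BandSpec` or the string
    ``"broadband"``).
    """

    tensor: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    fs: float
    channel_labels: list[str]
    band: object = "broadband"

    def __post_init__(self):
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.tensor.ndim != 3:
            raise ValidationError("tensor must be (N, P, C)")
        n = self.tensor.shape[0]
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValidationError("labels/subject_ids length must equal N")
        if n and not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be binary (0/1)")
        if len(self.channel_labels) != self.n_channels:
            raise ValidationError("channel_labels length must equal C")

    @property
    def n_segments(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.tensor.shape[1]

    @property
    def n_channels(self) -> int:
        return self.tensor.shape[2]

    def subset(self, indices) -> "SegmentSet":
        """Row subset (segments), preserving metadata."""
        return SegmentSet(
            tensor=self.tensor[indices],
            labels=self.labels[indices],
            subject_ids=self.subject_ids[indices],
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            band=self.band,
        )


# ---------------------------------------------------------------------------
# EDF / BDF
#
# Both formats share a fixed-width ASCII header (256 bytes + 256 per signal)
# followed by data records of integer samples: 16-bit little-endian for EDF,
# 24-bit little-endian two's complement for BDF.  Only the subset needed for
# plain continuous EEG is implemented (no EDF+ annotation channels).
# ---------------------------------------------------------------------------

_EDF_DIG = (-32768, 32767)
_BDF_DIG = (-8388608, 8388607)


def _fmt8(v: float) -> str:
    """Shortest %g rendering of v that fits an 8-char header field."""
    for prec in range(6, 0, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{v:.0e}"


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_recording(recording: Recording, path, format: str | None = None) -> None:
    """Write a recording as BDF, EDF, or an HDF5 container.

    ``format`` defaults from the file suffix (.bdf / .edf / anything else ->
    container).  EDF/BDF store integer-second data records; a trailing
    partial second is zero-padded, and events are NOT embedded (write a
    sidecar table with :func:`write_events`).  The container is lossless and
    embeds events.
    """
    path = Path(path)
    fmt = (format or _format_from_suffix(path)).lower()
    if fmt == "container":
        _write_container(recording, path)
        return
    if fmt not in ("edf", "bdf"):
        raise ValidationError(f"unknown format {fmt!r}")
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValidationError("EDF/BDF writing requires an integer sampling rate")
    fs = int(round(fs))
    dig_min, dig_max = _EDF_DIG if fmt == "edf" else _BDF_DIG
    nchan = recording.n_channels
    n_records = -(-recording.n_samples // fs)  # ceil
    data = np.zeros((n_records * fs, nchan))
    data[: recording.n_samples] = recording.data

    # per-channel physical range with headroom; flat channels get +-1 uV.
    # The range is round-tripped through its 8-char ASCII header encoding so
    # digitisation uses exactly the values a reader will parse.
    pmax = np.abs(data).max(axis=0)
    pmax = np.where(pmax > 0, pmax * 1.01, 1.0)
    pmax = np.array([float(_fmt8(v)) for v in pmax])
    pmin = -pmax
    gain = (pmax - pmin) / (dig_max - dig_min)
    digital = np.rint((data - pmin) / gain).astype(np.int64) + dig_min
    np.clip(digital, dig_min, dig_max, out=digital)

    with open(path, "wb") as fh:
        if fmt == "bdf":
            fh.write(b"\xffBIOSEMI")
            reserved = "24BIT"
        else:
            fh.write(_ascii("0", 8))
            reserved = ""
        fh.write(_ascii(recording.subject_id or "X", 80))
        fh.write(_ascii("emodec", 80))
        fh.write(_ascii("01.01.00", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(256 * (1 + nchan), 8))
        fh.write(_ascii(reserved, 44))
        fh.write(_ascii(n_records, 8))
        fh.write(_ascii(1, 8))
        fh.write(_ascii(nchan, 4))
        for lab in recording.channel_labels:
            fh.write(_ascii(lab, 16))
        fh.write(_ascii("", 80) * nchan)  # transducer
        fh.write(_ascii("uV", 8) * nchan)
        for v in pmin:
            fh.write(_ascii(_fmt8(v), 8))
        for v in pmax:
            fh.write(_ascii(_fmt8(v), 8))
        fh.write(_ascii(dig_min, 8) * nchan)
        fh.write(_ascii(dig_max, 8) * nchan)
        fh.write(_ascii("", 80) * nchan)  # prefiltering
        fh.write(_ascii(fs, 8) * nchan)
        fh.write(_ascii("", 32) * nchan)

        for rec in range(n_records):
            block = digital[rec * fs : (rec + 1) * fs]  # (fs, nchan)
            for ch in range(nchan):
                col = block[:, ch]
                if fmt == "edf":
                    fh.write(col.astype("<i2").tobytes())
                else:
                    b4 = col.astype("<i4").tobytes()
                    # drop the high byte of each int32 -> 24-bit little endian
                    fh.write(np.frombuffer(b4, dtype=np.uint8).reshape(-1, 4)[:, :3].tobytes())


def _read_header_field(fh, width: int) -> str:
    raw = fh.read(width)
    if len(raw) != width:
        raise FormatError("truncated EDF/BDF header")
    return raw.decode("ascii", errors="replace").strip()


def _read_edf_bdf(path: Path, fmt: str) -> Recording:
    try:
        with open(path, "rb") as fh:
            magic = fh.read(8)
            if len(magic) != 8:
                raise FormatError("truncated EDF/BDF header")
            if fmt == "bdf" and magic != b"\xffBIOSEMI":
                raise FormatError(f"{path} is not a BDF file")
            if fmt == "edf" and not magic.startswith(b"0"):
                raise FormatError(f"{path} is not an EDF file")
            subject = _read_header_field(fh, 80)
            _read_header_field(fh, 80)
            _read_header_field(fh, 8)
            _read_header_field(fh, 8)
            _read_header_field(fh, 8)
            _read_header_field(fh, 44)
            n_records = int(_read_header_field(fh, 8))
            rec_dur = float(_read_header_field(fh, 8))
            nchan = int(_read_header_field(fh, 4))
            if nchan < 1:
                raise ValidationError("file declares zero channels")
            labels = [_read_header_field(fh, 16) for _ in range(nchan)]
            for _ in range(nchan):
                _read_header_field(fh, 80)
            for _ in range(nchan):
                _read_header_field(fh, 8)
            pmin = np.array([float(_read_header_field(fh, 8)) for _ in range(nchan)])
            pmax = np.array([float(_read_header_field(fh, 8)) for _ in range(nchan)])
            dmin = np.array([int(_read_header_field(fh, 8)) for _ in range(nchan)])
            dmax = np.array([int(_read_header_field(fh, 8)) for _ in range(nchan)])
            for _ in range(nchan):
                _read_header_field(fh, 80)
            spr = [int(_read_header_field(fh, 8)) for _ in range(nchan)]
            for _ in range(nchan):
                _read_header_field(fh, 32)
            if len(set(spr)) != 1:
                raise FormatError("mixed per-channel sampling rates are unsupported")
            fs = spr[0] / rec_dur
            bps = 2 if fmt == "edf" else 3
            payload = fh.read()
        expected = n_records * nchan * spr[0] * bps
        if len(payload) < expected:
            raise FormatError(
                f"truncated data: expected {expected} bytes, found {len(payload)}"
            )
        raw = np.frombuffer(payload[:expected], dtype=np.uint8)
        raw = raw.reshape(n_records, nchan, spr[0], bps)
        if fmt == "edf":
            digital = raw.view("<i2").reshape(n_records, nchan, spr[0]).astype(np.int64)
        else:
            b = raw.astype(np.int64)
            digital = b[..., 0] | (b[..., 1] << 8) | (b[..., 2] << 16)
            digital = np.where(digital >= 1 << 23, digital - (1 << 24), digital)
            digital = digital.reshape(n_records, nchan, spr[0])
        gain = (pmax - pmin) / (dmax - dmin)
        data = digital.transpose(0, 2, 1).reshape(-1, nchan).astype(np.float64)
        data = (data - dmin) * gain + pmin
        return Recording(data=data, fs=fs, channel_labels=labels, subject_id=subject)
    except (struct.error, ValueError) as exc:
        if isinstance(exc, ValidationError):
            raise
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def _format_from_suffix(path: Path) -> str:
    suf = path.suffix.lower()
    if suf == ".edf":
        return "edf"
    if suf == ".bdf":
        return "bdf"
    return "container"


def read_recording(path, format: str | None = None, events_path=None) -> Recording:
    """Read continuous EEG from BDF, EDF, or the HDF5 container.

    Signal values are returned in microvolts (EDF/BDF headers written by
    this package declare ``uV``; foreign files are trusted to do the same).
    If ``events_path`` points to a BIDS-style events table, those events
    replace any embedded in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = (format or _format_from_suffix(path)).lower()
    if fmt == "container":
        rec = _read_container(path)
    elif fmt in ("edf", "bdf"):
        rec = _read_edf_bdf(path, fmt)
    else:
        raise ValidationError(f"unknown format {fmt!r}")
    if events_path is not None:
        rec = replace(rec, events=read_events(events_path))
    return rec


def _write_container(recording: Recording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.attrs["fs"] = recording.fs
        f.attrs["subject_id"] = recording.subject_id
        f.create_dataset(
            "channel_labels",
            data=np.array(recording.channel_labels, dtype=h5py.string_dtype()),
        )
        f.create_dataset("event_onsets", data=[e.onset_s for e in recording.events])
        f.create_dataset(
            "event_labels",
            data=np.array([e.label for e in recording.events], dtype=h5py.string_dtype()),
        )


def _read_container(path: Path) -> Recording:
    try:
        with h5py.File(path, "r") as f:
            events = [
                Event(float(o), lab.decode() if isinstance(lab, bytes) else str(lab))
                for o, lab in zip(f["event_onsets"][()], f["event_labels"][()])
            ]
            return Recording(
                data=f["data"][()],
                fs=float(f.attrs["fs"]),
                channel_labels=[
                    c.decode() if isinstance(c, bytes) else str(c)
                    for c in f["channel_labels"][()]
                ],
                subject_id=str(f.attrs["subject_id"]),
                events=events,
            )
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read container {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# BIDS-style events tables
# ---------------------------------------------------------------------------


def read_events(path) -> list[Event]:
    """Read a tab-separated events table with ``onset`` and ``trial_type``.

    Returns events sorted by onset (stable, so same-onset rows keep file
    order); labels are preserved verbatim.
    """
    try:
        table = pd.read_csv(path, sep="\t", dtype={"trial_type": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse events table {path}: {exc}") from exc
    for col in ("onset", "trial_type"):
        if col not in table.columns:
            raise FormatError(f"events table {path} lacks required column {col!r}")
    if len(table) and (table["onset"] < 0).any():
        raise ValidationError("events table contains a negative onset")
    table = table.sort_values("onset", kind="stable")
    return [Event(float(r.onset), str(r.trial_type)) for r in table.itertuples()]


def write_events(events: Sequence[Event], path) -> None:
    """Write events as a BIDS-style ``events.tsv`` (onset, trial_type)."""
    pd.DataFrame(
        {"onset": [e.onset_s for e in events], "trial_type": [e.label for e in events]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Segment containers
# ---------------------------------------------------------------------------


def save_segments(segments: SegmentSet, path) -> None:
    """Persist a SegmentSet losslessly to one HDF5 file.

    Datasets: ``tensor`` (N x P x C float64), ``labels`` (N int64),
    ``subject_ids`` (N utf-8 strings), ``channel_labels`` (C utf-8 strings);
    attrs: ``fs``, ``band_name``, ``band_low_hz``, ``band_high_hz``.
    """
    from .preprocess import BandSpec

    with h5py.File(path, "w") as f:
        f.create_dataset("tensor", data=segments.tensor)
        f.create_dataset("labels", data=segments.labels)
        f.create_dataset(
            "subject_ids",
            data=np.array([str(s) for s in segments.subject_ids], dtype=h5py.string_dtype()),
        )
        f.create_dataset(
            "channel_labels",
            data=np.array(segments.channel_labels, dtype=h5py.string_dtype()),
        )
        f.attrs["fs"] = segments.fs
        if isinstance(segments.band, BandSpec):
            f.attrs["band_name"] = segments.band.name
            f.attrs["band_low_hz"] = segments.band.low_hz
            f.attrs["band_high_hz"] = segments.band.high_hz
        else:
            f.attrs["band_name"] = str(segments.band)


def load_segments(path) -> SegmentSet:
    """Inverse of :func:`save_segments`; bitwise-exact for the tensor."""
    from .preprocess import BandSpec

    try:
        with h5py.File(path, "r") as f:
            name = str(f.attrs["band_name"])
            if "band_low_hz" in f.attrs:
                band = BandSpec(name, float(f.attrs["band_low_hz"]), float(f.attrs["band_high_hz"]))
            else:
                band = name
            return SegmentSet(
                tensor=f["tensor"][()],
                labels=f["labels"][()],
                subject_ids=np.array([s.decode() for s in f["subject_ids"][()]], dtype=object),
                fs=float(f.attrs["fs"]),
                channel_labels=[c.decode() for c in f["channel_labels"][()]],
                band=band,
            )
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read segment container {path}: {exc}") from exc


def concatenate_segments(parts: Sequence[SegmentSet]) -> SegmentSet:
    """Stack SegmentSets (same P, C, fs, band) along the segment axis."""
    if not parts:
        raise ValidationError("nothing to concatenate")
    first = parts[0]
    for p in parts[1:]:
        if p.n_timepoints != first.n_timepoints or p.n_channels != first.n_channels:
            raise ValidationError("segment sets have mismatched shapes")
        if p.fs != first.fs:
            raise ValidationError("segment sets have mismatched sampling rates")
    return SegmentSet(
        tensor=np.concatenate([p.tensor for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        subject_ids=np.concatenate([p.subject_ids for p in parts]),
        fs=first.fs,
        channel_labels=list(first.channel_labels),
        band=first.band,
    )
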