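"""Band-pass filtering, event-centred segmentation, and emotion-label binarisation.

The pipeline decomposes continuous EEG into the five classical rhythms
before any channel selection or classification:

==========  ============
band        pass-band
==========  ============
delta       1 - 4 Hz
theta       4 - 8 Hz
alpha       8 - 14 Hz
beta        14 - 30 Hz
gamma       30 - 50 Hz
all         1 - 50 Hz
==========  ============

Filtering uses a zero-phase Butterworth band-pass (forward-backward, so a
4th-order design acts as an effective 8th-order magnitude response with no
phase distortion).  Analysis segments are 2-s windows centred on the
"feeling it" button press, and each segment receives a binary label on the
valence (negative/positive) or arousal (calm/active) axis of Russell's
circumplex model.

The 15 study emotions are binarised by circumplex quadrant.  Only example
emotions per class are fixed by the study description; the remaining
assignments are a documented interpretation and can be overridden from a
YAML mapping file (see :func:`load_label_scheme`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import yaml
from scipy import signal as sps

from .errors import ValidationError
from .io import Recording, SegmentSet

__all__ = [
    "BandSpec",
    "BANDS",
    "EMOTIONS",
    "LabelScheme",
    "default_label_scheme",
    "load_label_scheme",
    "save_label_scheme",
    "bandpass",
    "segment",
    "map_label",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with pass-band edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz:
            raise ValidationError(
                f"band edges must satisfy 0 < low < high, got ({self.low_hz}, {self.high_hz})"
            )


#: Canonical EEG rhythm table.
BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 1.0, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 14.0),
    "beta": BandSpec("beta", 14.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 50.0),
    "all": BandSpec("all", 1.0, 50.0),
}

#: The 15 self-induced emotions of the imagery protocol.
EMOTIONS = (
    "anger",
    "awe",
    "compassion",
    "contentedness",
    "disgust",
    "excitement",
    "fear",
    "frustration",
    "grief",
    "happiness",
    "jealousy",
    "joy",
    "love",
    "relief",
    "sadness",
)

_VALENCE_POSITIVE = {
    "awe", "compassion", "contentedness", "excitement",
    "happiness", "joy", "love", "relief",
}
_AROUSAL_HIGH = {
    "anger", "awe", "disgust", "excitement", "fear",
    "frustration", "jealousy", "joy", "happiness", "love",
}


@dataclass(frozen=True)
class LabelScheme:
    """Binary emotion labelling on one circumplex axis.

    ``scale`` is ``"valence"`` (0 = negative, 1 = positive) or ``"arousal"``
    (0 = calm, 1 = active); ``mapping`` must cover all 15 study emotions.
    """

    scale: str
    mapping: Mapping[str, int]

    def __post_init__(self):
        if self.scale not in ("valence", "arousal"):
            raise ValidationError(f"scale must be valence/arousal, got {self.scale!r}")
        missing = set(EMOTIONS) - set(self.mapping)
        if missing:
            raise ValidationError(f"label mapping lacks emotions: {sorted(missing)}")
        bad = {e: v for e, v in self.mapping.items() if v not in (0, 1)}
        if bad:
            raise ValidationError(f"label mapping values must be 0/1: {bad}")

    def classes(self, value: int) -> set[str]:
        return {e for e, v in self.mapping.items() if v == value}


def default_label_scheme(scale: str) -> LabelScheme:
    """Circumplex-quadrant binarisation of the 15 study emotions.

    The study fixes the class of only a few example emotions per axis; the
    rest follow their usual Russell-circumplex quadrant.  Treat this as an
    editable default, not ground truth.
    """
    if scale == "valence":
        mapping = {e: int(e in _VALENCE_POSITIVE) for e in EMOTIONS}
    elif scale == "arousal":
        mapping = {e: int(e in _AROUSAL_HIGH) for e in EMOTIONS}
    else:
        raise ValidationError(f"scale must be valence/arousal, got {scale!r}")
    return LabelScheme(scale=scale, mapping=mapping)


def load_label_scheme(path) -> LabelScheme:
    """Load a scheme from YAML: ``{scale: valence, mapping: {anger: 0, ...}}``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return LabelScheme(scale=doc["scale"], mapping={str(k): int(v) for k, v in doc["mapping"].items()})


def save_label_scheme(scheme: LabelScheme, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"scale": scheme.scale, "mapping": dict(scheme.mapping)}, fh)


def map_label(emotion: str, scheme: LabelScheme) -> int:
    """Binary class of an emotion under a scheme; unknown emotions error."""
    try:
        return int(scheme.mapping[emotion])
    except KeyError:
        raise ValidationError(
            f"unknown emotion {emotion!r}; known: {sorted(scheme.mapping)}"
        ) from None


def design_bandpass(band: BandSpec, fs: float, order: int = 4) -> np.ndarray:
    """Butterworth band-pass design in second-order sections."""
    if order < 1:
        raise ValidationError(f"filter order must be >= 1, got {order}")
    if band.high_hz >= fs / 2:
        raise ValidationError(
            f"band high edge {band.high_hz} Hz >= Nyquist {fs / 2} Hz"
        )
    return sps.butter(order, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass(recording: Recording, band: BandSpec | str, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass of every channel.

    The filter is applied forward and backward (``sosfiltfilt``), doubling
    the effective order and cancelling phase delay so that segment windows
    stay aligned to their events.  Returns a new Recording; events carry
    over unchanged.
    """
    if isinstance(band, str):
        try:
            band = BANDS[band]
        except KeyError:
            raise ValidationError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None
    sos = design_bandpass(band, recording.fs, order)
    filtered = sps.sosfiltfilt(sos, recording.data, axis=0)
    return replace(recording, data=np.ascontiguousarray(filtered), events=list(recording.events))


def bandpass_response(band: BandSpec, fs: float, freqs, order: int = 4) -> np.ndarray:
    """Magnitude response of the effective (forward-backward) filter.

    Serves as the analytic oracle for pass/stop-band behaviour: the
    two-pass magnitude is the squared single-pass magnitude.
    """
    sos = design_bandpass(band, fs, order)
    _, h = sps.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs, dtype=float) / fs)
    return np.abs(h) ** 2


def segment(
    recording: Recording,
    duration_s: float = 2.0,
    scheme: LabelScheme | None = None,
    band: BandSpec | str = "broadband",
) -> SegmentSet:
    """Cut event-centred windows and binarise their emotion labels.

    Each event whose label appears in the scheme yields one window of
    ``P = round(fs * duration_s)`` samples, ``floor(P/2)`` before the event
    sample and ``P - floor(P/2)`` after (half-open).  Windows that would
    cross a recording edge are dropped, not padded.  Events are processed
    in onset order (file order on ties).

    Returns an empty SegmentSet (with a warning) when no event is usable.
    """
    if duration_s <= 0:
        raise ValidationError(f"duration must be positive, got {duration_s}")
    if scheme is None:
        scheme = default_label_scheme("valence")
    P = int(round(recording.fs * duration_s))
    if P < 1:
        raise ValidationError("segment duration shorter than one sample")
    half = P // 2
    windows, labels = [], []
    n_dropped_bounds = 0
    events = sorted(recording.events, key=lambda e: e.onset_s)
    for ev in events:
        if ev.label not in scheme.mapping:
            continue
        center = int(round(ev.onset_s * recording.fs))
        start = center - half
        stop = start + P
        if start < 0 or stop > recording.n_samples:
            n_dropped_bounds += 1
            continue
        windows.append(recording.data[start:stop])
        labels.append(scheme.mapping[ev.label])
    if not windows:
        warnings.warn(
            f"recording {recording.subject_id!r}: no usable events "
            f"({n_dropped_bounds} dropped at recording edges)",
            stacklevel=2,
        )
        tensor = np.empty((0, P, recording.n_channels))
    else:
        tensor = np.stack(windows)
    n = tensor.shape[0]
    return SegmentSet(
        tensor=tensor,
        labels=np.asarray(labels, dtype=np.int64),
        subject_ids=np.array([recording.subject_id] * n, dtype=object),
        fs=recording.fs,
        channel_labels=list(recording.channel_labels),
        band=band,
    )
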