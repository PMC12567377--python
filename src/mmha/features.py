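"""EEG and facial-expression feature extraction.

EEG windows are band-decomposed with zero-phase band-pass filters into the
five classical rhythms (delta 1-4, theta 4-8, alpha 8-12, beta 12-30,
gamma 30-50 Hz), cut into 1 s non-overlapping windows, and summarised per
window, channel and band by differential entropy.  A band-filtered EEG
window is well modelled as Gaussian, for which the differential entropy
``-∫ f ln f`` has the closed form

    h = 1/2 * ln(2*pi*e*sigma^2)        (nats)

with ``sigma^2`` the maximum-likelihood (1/n) sample variance.  Facial
frames are center-cropped/resized and min-max normalized per feature within
each subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "BandSpec", "EEGRecording", "DEFeatureTensor", "FaceFrame",
    "DEFAULT_BANDS", "DE_FLOOR", "decompose_bands", "window_signal",
    "differential_entropy", "extract_de_features", "normalize_faces",
    "center_crop_resize",
]

#: clamp floor (nats) applied to degenerate zero-variance windows downstream
DE_FLOOR = -10.0

EMOTIONS = ("happy", "sad", "fear", "calm")


@dataclass(frozen=True)
class BandSpec:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band edges {self.lo}-{self.hi} Hz")


DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 12.0, 30.0),
    BandSpec("gamma", 30.0, 50.0),
)


@dataclass
class EEGRecording:
    """Multichannel EEG waveform with trial metadata (microvolts)."""

    data: np.ndarray                  # channels x samples
    sample_rate: float
    channel_names: list[str]
    subject_id: str
    clip_id: str
    emotion: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be channels x samples")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_names)} channel names")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sample_rate


@dataclass
class DEFeatureTensor:
    """Differential-entropy features: windows x channels x bands, in nats."""

    values: np.ndarray
    band_names: list[str]
    subject_id: str
    clip_id: str
    emotion: str | None = None
    window_length: float = 1.0
    degenerate: np.ndarray | None = field(default=None)  # True where clamped

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("DE tensor must be windows x channels x bands")
        if not np.isfinite(self.values).all():
            raise ValueError("DE tensor contains non-finite entries")


@dataclass
class FaceFrame:
    """One RGB face image tied to a 1 s EEG window; pixels are C x H x W."""

    pixels: np.ndarray
    subject_id: str
    clip_id: str
    window: int
    emotion: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != 3:
            raise ValueError("pixels must be 3 x H x W")


# ----------------------------------------------------------------------- EEG


def _bandpass_sos(band: BandSpec, fs: float, order: int = 4):
    nyq = fs / 2.0
    if band.hi >= nyq:
        raise ValueError(f"band {band.name} upper edge {band.hi} Hz >= Nyquist {nyq} Hz")
    return butter(order, [band.lo / nyq, band.hi / nyq], btype="band", output="sos")


def decompose_bands(rec: EEGRecording,
                    bands: tuple[BandSpec, ...] = DEFAULT_BANDS) -> list[EEGRecording]:
    """Zero-phase band-pass filtered copies of a recording, one per band.

    Forward-backward filtering doubles the effective order but leaves the
    phase untouched, so window boundaries stay aligned across bands.
    """
    out = []
    for band in bands:
        sos = _bandpass_sos(band, rec.sample_rate)
        filt = sosfiltfilt(sos, rec.data, axis=1)
        out.append(EEGRecording(filt, rec.sample_rate, list(rec.channel_names),
                                rec.subject_id, rec.clip_id, rec.emotion))
    return out


def window_signal(rec: EEGRecording, length: float = 1.0,
                  overlap: float = 0.0) -> list[np.ndarray]:
    """Cut a recording into fixed-length windows (channels x samples each).

    Trailing samples that do not fill a window are dropped.  ``overlap`` is
    in seconds; the protocol here uses non-overlapping 1 s windows.
    """
    if length <= 0:
        raise ValueError("window length must be positive")
    if not 0 <= overlap < length:
        raise ValueError("overlap must be in [0, length)")
    win = int(round(length * rec.sample_rate))
    step = int(round((length - overlap) * rec.sample_rate))
    n = rec.data.shape[1]
    return [rec.data[:, s:s + win] for s in range(0, n - win + 1, step)]


def differential_entropy(window: np.ndarray) -> np.ndarray:
    """Gaussian differential entropy of a signal window, in nats.

    Computes ``1/2 ln(2 pi e sigma^2)`` with the biased (1/n) sample
    variance over the last axis.  A zero-variance window yields ``-inf``
    as an explicit sentinel; callers clamp it (see :data:`DE_FLOOR`).
    """
    window = np.asarray(window, dtype=np.float64)
    if window.shape[-1] < 2:
        raise ValueError("need at least 2 samples per window")
    if not np.isfinite(window).all():
        raise ValueError("window contains non-finite samples")
    var = window.var(axis=-1)  # ddof=0: maximum-likelihood estimator
    with np.errstate(divide="ignore"):
        return 0.5 * np.log(2.0 * np.pi * np.e * var)


def extract_de_features(rec: EEGRecording,
                        bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
                        window_length: float = 1.0,
                        floor: float = DE_FLOOR) -> DEFeatureTensor:
    """Band decomposition -> 1 s windows -> DE; windows x channels x bands.

    Degenerate (zero-variance) entries are clamped to ``floor`` and flagged
    in the ``degenerate`` mask of the returned tensor.
    """
    per_band = decompose_bands(rec, bands)
    per_band_windows = [window_signal(b, window_length) for b in per_band]
    n_windows = len(per_band_windows[0])
    n_ch = rec.n_channels
    values = np.empty((n_windows, n_ch, len(bands)))
    for bi, wins in enumerate(per_band_windows):
        for wi, w in enumerate(wins):
            values[wi, :, bi] = differential_entropy(w)
    degenerate = ~np.isfinite(values)
    values = np.where(degenerate, floor, values)
    values = np.maximum(values, floor)
    return DEFeatureTensor(values, [b.name for b in bands], rec.subject_id,
                           rec.clip_id, rec.emotion, window_length,
                           degenerate=degenerate)


# ---------------------------------------------------------------------- faces


def center_crop_resize(image, size: int = 256) -> np.ndarray:
    """Center square crop then bilinear resize; returns 3 x size x size in [0, 1].

    Accepts a PIL image or an H x W x 3 array (uint8 or float in [0, 1]).
    """
    if isinstance(image, np.ndarray):
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError("expected an H x W x 3 RGB array")
        arr = image
        if arr.dtype != np.uint8:
            arr = (np.clip(arr, 0, 1) * 255).astype(np.uint8)
        img = Image.fromarray(arr, mode="RGB")
    elif isinstance(image, Image.Image):
        if image.mode != "RGB":
            raise ValueError(f"expected an RGB image, got mode {image.mode!r}")
        img = image
    else:
        raise TypeError("image must be a PIL image or numpy array")
    w, h = img.size
    side = min(w, h)
    left = (w - side) // 2
    top = (h - side) // 2
    img = img.crop((left, top, left + side, top + side))
    img = img.resize((size, size), Image.BILINEAR)
    out = np.asarray(img, dtype=np.float32) / 255.0
    return out.transpose(2, 0, 1)


def normalize_faces(frames: list[FaceFrame], signed: bool = False) -> list[FaceFrame]:
    """Per-subject, per-feature min-max normalization of face frames.

    Every pixel/channel position is one feature; for each subject the
    feature is mapped to ``(F - min) / (max - min)`` over that subject's
    frames, giving values in [0, 1] (constant features map to 0).  With
    ``signed=True`` the result is rescaled to ``2 x - 1``.
    """
    if not frames:
        raise ValueError("no frames to normalize")
    out: list[FaceFrame] = [None] * len(frames)
    by_subject: dict[str, list[int]] = {}
    for i, f in enumerate(frames):
        by_subject.setdefault(f.subject_id, []).append(i)
    for subject, idx in by_subject.items():
        stack = np.stack([frames[i].pixels for i in idx])  # n x 3 x H x W
        lo = stack.min(axis=0)
        hi = stack.max(axis=0)
        span = hi - lo
        safe = np.where(span > 0, span, 1.0)
        for i in idx:
            norm = np.where(span > 0, (frames[i].pixels - lo) / safe, 0.0)
            if signed:
                norm = 2.0 * norm - 1.0
            f = frames[i]
            out[i] = FaceFrame(norm.astype(np.float32), f.subject_id, f.clip_id,
                               f.window, f.emotion)
    return out
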