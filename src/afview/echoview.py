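"""Beat-stack colormap images (electrocardiomatrix transform).

A fixed-width amplitude window (±0.75 s) is cut around every annotated QRS
in an analysis interval; the windows are stacked as columns so consecutive
beats align horizontally, and amplitudes are rendered through a
black-blue-white-orange-red lookup table.  High positive R peaks come out
red, positive T waves orange, low-amplitude P waves near-white, and
negative deflections shade through blue to black.  The rendered image is
then rescaled by nearest-neighbor sampling to the fixed square input size
of a classifier backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .ecg_io import ECGRecord
from .registry import get_backbone_info

__all__ = [
    "ColorMap",
    "EchoViewImage",
    "extract_beat_window",
    "build_matrix",
    "amplitude_to_rgb",
    "rescale_image",
    "preprocess_for_model",
    "echoview_image",
]

HALF_WINDOW_S = 0.75  # beat window is ±0.75 s around the QRS annotation

DEFAULT_ANCHORS: tuple[tuple[float, tuple[float, float, float]], ...] = (
    (-1.0, (0.0, 0.0, 0.0)),  # black
    (-0.5, (0.0, 0.0, 1.0)),  # blue
    (0.0, (1.0, 1.0, 1.0)),  # white
    (0.5, (1.0, 0.65, 0.0)),  # orange
    (1.0, (1.0, 0.0, 0.0)),  # red
)


@dataclass(frozen=True)
class ColorMap:
    """Piecewise-linear amplitude -> RGB lookup table.

    ``amp_range_uv`` is the symmetric clipping range R: amplitudes are
    clipped to [-R, +R] and normalized to [-1, 1] before the LUT.  A fixed
    range (rather than per-image scaling) is the default so that
    low-amplitude leads render with low contrast and high-amplitude leads
    saturate, as on real Holter data.
    """

    anchors: tuple = DEFAULT_ANCHORS
    amp_range_uv: float = 2000.0

    def __post_init__(self):
        pos = [a for a, _ in self.anchors]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("colormap anchors must be strictly increasing")
        if self.amp_range_uv <= 0:
            raise ValueError("amp_range_uv must be positive")

    def __call__(self, norm: np.ndarray) -> np.ndarray:
        """Map normalized amplitudes in [-1, 1] to RGB in [0, 1]."""
        norm = np.clip(norm, -1.0, 1.0)
        xs = np.array([a for a, _ in self.anchors])
        rgb = np.empty(norm.shape + (3,))
        for c in range(3):
            ys = np.array([col[c] for _, col in self.anchors])
            rgb[..., c] = np.interp(norm, xs, ys)
        return rgb


@dataclass
class EchoViewImage:
    """A beat-stack image and the metadata needed to invert its pixels.

    ``matrix`` is (window_len x N): rows are intra-beat time offsets from
    -0.75 s (top) to +0.75 s (bottom), columns are beats in temporal order
    (window_len = round(1.5 * fs) = 300 at 200 Hz).  ``rgb`` and
    ``rescaled`` are filled by the rendering stages.  ``meta`` keeps the
    record id, lead, interval, absolute QRS indices of the columns, the
    half-window in samples, and the resize geometry, so any rescaled pixel
    maps deterministically back to (beat index, intra-beat sample offset).
    """

    matrix: np.ndarray
    meta: dict
    rgb: np.ndarray | None = None
    rescaled: np.ndarray | None = None

    @property
    def n_beats(self) -> int:
        return self.matrix.shape[1]

    def save_png(self, path, which: str = "rescaled") -> None:
        arr = getattr(self, which)
        if arr is None:
            raise ValueError(f"{which} stage not rendered yet")
        Image.fromarray((np.clip(arr, 0, 1) * 255).astype(np.uint8)).save(path)


def extract_beat_window(signal: np.ndarray, qrs_idx: int, fs: float) -> np.ndarray:
    """Amplitude window of length round(1.5*fs) centered on one QRS.

    Samples ``[qrs_idx - half, qrs_idx + half + parity)`` are taken from the
    signal; positions outside the record are zero-filled.
    """
    signal = np.asarray(signal)
    if not (0 <= qrs_idx < signal.size):
        raise IndexError(f"qrs_idx {qrs_idx} outside signal of length {signal.size}")
    length = int(round(2 * HALF_WINDOW_S * fs))
    half = length // 2
    out = np.zeros(length, dtype=np.float64)
    lo = qrs_idx - half
    hi = lo + length
    src_lo, src_hi = max(lo, 0), min(hi, signal.size)
    out[src_lo - lo : src_hi - lo] = signal[src_lo:src_hi]
    return out


def build_matrix(
    record: ECGRecord,
    lead: str,
    interval_start_sample: int,
    duration_s: float,
) -> EchoViewImage:
    """Stack the beat windows of one analysis interval into a matrix.

    One column per QRS annotation inside ``[start, start + duration*fs)``,
    in temporal order.  An interval containing no QRS raises ``ValueError``
    (callers scanning full recordings may catch it and flag the segment).
    """
    start = int(interval_start_sample)
    stop = start + int(round(duration_s * record.fs))
    if start < 0 or stop > record.n_samples:
        raise ValueError("interval outside record")
    sig = record.lead_signal(lead)
    qrs = record.qrs_idx[(record.qrs_idx >= start) & (record.qrs_idx < stop)]
    if qrs.size == 0:
        raise ValueError(
            f"empty interval: no QRS in [{start}, {stop}) of record {record.record_id}"
        )
    cols = [extract_beat_window(sig, int(q), record.fs) for q in qrs]
    matrix = np.stack(cols, axis=1)
    meta = {
        "record_id": record.record_id,
        "lead": lead,
        "start_sample": start,
        "duration_s": float(duration_s),
        "fs": record.fs,
        "qrs_indices": qrs.copy(),
        "half_width_samples": matrix.shape[0] // 2,
    }
    return EchoViewImage(matrix=matrix, meta=meta)


def amplitude_to_rgb(matrix: np.ndarray, colormap: ColorMap | None = None) -> np.ndarray:
    """Render an amplitude matrix to RGB in [0, 1] through the LUT."""
    cmap = colormap or ColorMap()
    norm = np.clip(matrix / cmap.amp_range_uv, -1.0, 1.0)
    return cmap(norm)


def rescale_image(rgb: np.ndarray, D: int) -> np.ndarray:
    """Nearest-neighbor resize of an H x W x 3 image to D x D x 3.

    Half-pixel center convention: output pixel ``i`` samples source row
    ``floor((i + 0.5) * H / D)``.  No interpolation, so no new colors.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    rgb = np.asarray(rgb)
    H, W = rgb.shape[:2]
    rows = np.minimum((np.floor((np.arange(D) + 0.5) * H / D)).astype(int), H - 1)
    cols = np.minimum((np.floor((np.arange(D) + 0.5) * W / D)).astype(int), W - 1)
    return rgb[np.ix_(rows, cols)]


def resize_index_map(n_src: int, n_dst: int) -> np.ndarray:
    """Source index sampled by each destination index (shared with inversion)."""
    return np.minimum((np.floor((np.arange(n_dst) + 0.5) * n_src / n_dst)).astype(int), n_src - 1)


# ImageNet channel statistics for the "torch" convention.
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])
# Caffe convention: BGR, 0-255 scale, per-channel mean subtraction.
CAFFE_MEAN_BGR = np.array([103.939, 116.779, 123.68])


def preprocess_for_model(rescaled: np.ndarray, backbone_id: str) -> np.ndarray:
    """Apply a backbone's published input normalization to a [0, 1] image."""
    x = np.asarray(rescaled, dtype=np.float64)
    if x.min() < 0 or x.max() > 1:
        raise ValueError("preprocess_for_model expects values in [0, 1]")
    mode = get_backbone_info(backbone_id).preprocess
    if mode == "identity":
        return x.copy()
    if mode == "tf":
        return 2.0 * x - 1.0
    if mode == "torch":
        return (x - IMAGENET_MEAN) / IMAGENET_STD
    if mode == "caffe":
        return 255.0 * x[..., ::-1] - CAFFE_MEAN_BGR
    raise ValueError(f"unknown preprocess mode {mode!r}")  # pragma: no cover


def echoview_image(
    record: ECGRecord,
    lead: str,
    interval_start_sample: int,
    duration_s: float,
    D: int = 224,
    colormap: ColorMap | None = None,
) -> EchoViewImage:
    """Full transform: matrix -> RGB -> nearest-neighbor rescale to D x D."""
    cmap = colormap or ColorMap()
    img = build_matrix(record, lead, interval_start_sample, duration_s)
    img.rgb = amplitude_to_rgb(img.matrix, cmap)
    img.rescaled = rescale_image(img.rgb, D)
    img.meta.update(
        D=D,
        colormap_anchors=cmap.anchors,
        amp_range_uv=cmap.amp_range_uv,
    )
    return img
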