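"""Class-conditional saliency via gradient-weighted class activation maps.

For a class score ``y_c`` and the feature maps ``A^k`` of the final
convolutional layer, each channel's importance is the spatial mean of the
gradient, ``alpha_k = (1/Z) sum_ij d y_c / d A^k_ij`` with ``Z`` the number
of feature-map pixels; the localization map is ``ReLU(sum_k alpha_k A^k)``,
upsampled to the input size by bilinear interpolation and normalized to
[0, 1] by its maximum (an identically zero map stays zero and is flagged).

The classifier head is a single sigmoid unit, so the AF class score is the
logit and the non-AF score its negation.  Because the beat-stack image
geometry is invertible, a heatmap can additionally be projected onto raw
ECG sample times: each heatmap pixel maps back through the
nearest-neighbor resize to (beat, intra-beat offset) and lands on sample
``qrs[beat] + offset``; where neighboring ±0.75 s beat windows overlap,
intensities combine by maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from PIL import Image
from scipy import ndimage

from . import nn
from .echoview import EchoViewImage, resize_index_map
from .ecg_io import ECGRecord
from .models import TrainedClassifier

__all__ = ["GradCAMResult", "compute_gradcam", "project_to_ecg", "render_overlay"]


@dataclass
class GradCAMResult:
    heatmap: np.ndarray  # (D, D) in [0, 1]
    target_class: str  # "AF" | "non-AF"
    layer_index: int
    fmap_shape: tuple
    p_af: float
    alphas: np.ndarray  # channel importances alpha_k
    all_zero: bool = False
    ecg_intensity: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def _last_conv_index(network: nn.Network) -> int:
    idx = [i for i, l in enumerate(network.layers) if isinstance(l, nn.Conv2D)]
    if not idx:
        raise ValueError("model has no convolutional layer")
    return idx[-1]


def compute_gradcam(
    model: TrainedClassifier,
    image: np.ndarray,
    target_class: str = "AF",
    layer_index: int | None = None,
) -> GradCAMResult:
    """Heatmap of the evidence for ``target_class`` in one input image.

    ``layer_index`` overrides the automatically resolved final
    convolutional layer (useful for backbones ending in non-conv blocks).
    """
    if target_class not in ("AF", "non-AF"):
        raise ValueError("target_class must be 'AF' or 'non-AF'")
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    net = model.network
    li = _last_conv_index(net) if layer_index is None else layer_index
    sign = 1.0 if target_class == "AF" else -1.0
    A, dA = net.grad_wrt_layer_output(x, li, sign=sign)
    A, dA = A[0], dA[0]  # (h, w, C)
    alphas = dA.mean(axis=(0, 1))  # spatial average over Z pixels
    cam = np.maximum((A * alphas).sum(axis=-1), 0.0)  # ReLU(sum_k alpha_k A^k)
    D = x.shape[1]
    h, w = cam.shape
    heat = ndimage.zoom(cam, (D / h, D / w), order=1, grid_mode=True, mode="nearest")
    heat = np.maximum(heat, 0.0)
    peak = heat.max()
    all_zero = peak <= 0.0
    if not all_zero:
        heat = heat / peak
    p_af = float(model.predict(x)[0])
    return GradCAMResult(
        heatmap=heat,
        target_class=target_class,
        layer_index=li,
        fmap_shape=A.shape,
        p_af=p_af,
        alphas=alphas,
        all_zero=all_zero,
    )


def project_to_ecg(
    result: GradCAMResult,
    image: EchoViewImage,
    n_samples: int | None = None,
    combine: str = "max",
) -> np.ndarray:
    """Per-sample saliency over the ECG, by inverting the image geometry.

    Returns an intensity array indexed by absolute sample; samples covered
    by no beat window are 0.  Stores the trace on ``result.ecg_intensity``.
    """
    meta = image.meta
    for key in ("qrs_indices", "half_width_samples"):
        if key not in meta:
            raise ValueError(f"image metadata missing {key!r}")
    if combine not in ("max", "mean"):
        raise ValueError("combine must be 'max' or 'mean'")
    heat = result.heatmap
    Dr, Dc = heat.shape
    n_rows, n_beats = image.matrix.shape
    half = meta["half_width_samples"]
    qrs = np.asarray(meta["qrs_indices"])

    # invert the nearest-neighbor resize: matrix cell <- max of its heatmap pixels
    rmap = resize_index_map(n_rows, Dr)
    cmap = resize_index_map(n_beats, Dc)
    cell = np.zeros((n_rows, n_beats))
    R, C = np.meshgrid(rmap, cmap, indexing="ij")
    np.maximum.at(cell, (R.ravel(), C.ravel()), heat.ravel())

    if n_samples is None:
        n_samples = int(qrs.max()) + (n_rows - half)
    out = np.zeros(n_samples)
    counts = np.zeros(n_samples)
    offsets = np.arange(n_rows) - half
    for b in range(n_beats):
        samples = qrs[b] + offsets
        ok = (samples >= 0) & (samples < n_samples)
        if combine == "max":
            np.maximum.at(out, samples[ok], cell[ok, b])
        else:
            np.add.at(out, samples[ok], cell[ok, b])
            np.add.at(counts, samples[ok], 1.0)
    if combine == "mean":
        out = np.divide(out, counts, out=out, where=counts > 0)
    result.ecg_intensity = out
    return out


def overlay_rgb(base: np.ndarray, heatmap: np.ndarray, alpha: float = 0.4) -> np.ndarray:
    """Alpha-blend a [0,1] heatmap over a base RGB image.

    Per-pixel opacity is ``alpha * heatmap``, so zero-saliency pixels show
    the base image unchanged.
    """
    cmap = plt.get_cmap("jet")
    heat_rgb = cmap(np.clip(heatmap, 0, 1))[..., :3]
    a = (alpha * np.clip(heatmap, 0, 1))[..., None]
    return (1 - a) * base + a * heat_rgb


def render_overlay(
    record: ECGRecord,
    lead: str,
    image: EchoViewImage,
    result: GradCAMResult,
    out_prefix: str | Path,
    alpha: float = 0.4,
) -> dict:
    """Write the heatmap-on-image and saliency-on-ECG figures as PNG.

    Produces ``<prefix>_echoview.png`` (heatmap alpha-blended over the
    rescaled beat-stack image) and ``<prefix>_ecg.png`` (the analysis
    interval's ECG trace banded by projected saliency, with QRS markers
    and the pAF caption).
    """
    if image.rescaled is None:
        raise ValueError("image has no rescaled rendering")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    caption = f"pAF = {result.p_af:.3f} ({result.target_class} evidence)"

    blended = overlay_rgb(image.rescaled, result.heatmap, alpha=alpha)
    echo_path = out_prefix.with_name(out_prefix.name + "_echoview.png")
    Image.fromarray((np.clip(blended, 0, 1) * 255).astype(np.uint8)).save(echo_path)

    intensity = result.ecg_intensity
    if intensity is None:
        intensity = project_to_ecg(result, image, n_samples=record.n_samples)
    start = image.meta["start_sample"]
    stop = start + int(round(image.meta["duration_s"] * record.fs))
    t = np.arange(start, stop) / record.fs
    sig = record.lead_signal(lead)[start:stop]
    seg_int = intensity[start:stop]

    fig, ax = plt.subplots(figsize=(12, 3))
    ax.pcolormesh(
        t, [sig.min(), sig.max()], np.vstack([seg_int, seg_int]),
        cmap="jet", vmin=0, vmax=1, alpha=0.35, shading="nearest",
    )
    ax.plot(t, sig, color="black", lw=0.7)
    qrs = image.meta["qrs_indices"]
    ax.plot(qrs / record.fs, sig[qrs - start], "r.", ms=5, label="QRS")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("amplitude (uV)")
    ax.set_title(f"{record.record_id} lead {lead}: {caption}")
    ax.legend(loc="upper right")
    fig.tight_layout()
    ecg_path = out_prefix.with_name(out_prefix.name + "_ecg.png")
    fig.savefig(ecg_path, dpi=110)
    plt.close(fig)
    return {"echoview": echo_path, "ecg": ecg_path, "p_af_caption": caption}
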