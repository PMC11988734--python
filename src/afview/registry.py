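"""Registry of classifier backbones.

Each entry records the published facts about an ImageNet architecture that
the pipeline needs without instantiating weights: the expected input size
``D`` (images are ``D x D x 3``), the feature dimension that the
global-average-pooled head sees, the input normalization convention, and —
where the architecture is defined shape-by-shape in
:mod:`afview.architectures` — a key to its layer table for exact parameter
counting.  ``tinycnn`` is the in-repo, fully trainable backbone used for
desk-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BackboneInfo", "BACKBONES", "get_backbone_info"]


@dataclass(frozen=True)
class BackboneInfo:
    backbone_id: str
    input_size: int  # D: expects D x D x 3 input
    feature_dim: int  # width of the global-average-pooled feature vector
    preprocess: str  # one of: identity, tf, torch, caffe
    layer_table: str | None = None  # key into afview.architectures, if defined


# The 18 ImageNet architectures compared in the study, plus tinycnn.
BACKBONES: dict[str, BackboneInfo] = {
    info.backbone_id: info
    for info in [
        BackboneInfo("tinycnn", 64, 64, "identity", "tinycnn"),
        BackboneInfo("mobilenetv2_035", 224, 1280, "tf", "mobilenetv2_035"),
        BackboneInfo("mobilenetv2_100", 224, 1280, "tf", "mobilenetv2_100"),
        BackboneInfo("mobilenetv2_140", 224, 1792, "tf", "mobilenetv2_140"),
        BackboneInfo("vgg16", 224, 512, "caffe", "vgg16"),
        BackboneInfo("nasnetmobile", 224, 1056, "tf", None),
        BackboneInfo("efficientnetb0", 224, 1280, "identity", None),
        BackboneInfo("efficientnetv2b0", 224, 1280, "identity", None),
        BackboneInfo("efficientnetb1", 240, 1280, "identity", None),
        BackboneInfo("efficientnetv2b1", 240, 1280, "identity", None),
        BackboneInfo("efficientnetb2", 260, 1408, "identity", None),
        BackboneInfo("efficientnetv2b2", 260, 1408, "identity", None),
        BackboneInfo("inceptionv3", 224, 2048, "tf", None),
        BackboneInfo("xception", 224, 2048, "tf", None),
        BackboneInfo("densenet121", 224, 1024, "torch", "densenet121"),
        BackboneInfo("densenet169", 224, 1664, "torch", "densenet169"),
        BackboneInfo("densenet201", 224, 1920, "torch", "densenet201"),
        BackboneInfo("resnet50", 224, 2048, "caffe", "resnet50"),
        BackboneInfo("resnet50v2", 224, 2048, "tf", "resnet50v2"),
    ]
}


def get_backbone_info(backbone_id: str) -> BackboneInfo:
    try:
        return BACKBONES[backbone_id]
    except KeyError:
        raise KeyError(
            f"unknown backbone {backbone_id!r}; registered: {sorted(BACKBONES)}"
        ) from None
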