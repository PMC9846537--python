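"""Dataset-diversification transforms: horizontal flip, scaling, HSV jitter.

These are the pre-processing augmentations applied when assembling a
detection training set. Geometric ops transform boxes consistently with
pixels (flip mirrors x about the image center; scaling multiplies all
coordinates); photometric HSV jitter leaves boxes untouched. Output boxes
are clipped to the image and dropped if degenerate; class labels never
change.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
from skimage import color, transform

from .annotations import AnnotatedInstance, BBox

__all__ = ["horizontal_flip", "scale", "hsv_jitter", "augment"]


def _clip_boxes(
    instances: Sequence[AnnotatedInstance], width: float, height: float
) -> tuple[AnnotatedInstance, ...]:
    out = []
    for inst in instances:
        b = inst.box
        x0, y0 = max(b.xmin, 0.0), max(b.ymin, 0.0)
        x1, y1 = min(b.xmax, width), min(b.ymax, height)
        if x1 <= x0 or y1 <= y0:
            continue  # fully clipped out
        out.append(replace(inst, box=BBox(x0, y0, x1, y1)))
    return tuple(out)


def horizontal_flip(
    image: np.ndarray, instances: Sequence[AnnotatedInstance]
) -> tuple[np.ndarray, tuple[AnnotatedInstance, ...]]:
    """Mirror pixels and boxes about the vertical image center line."""
    width = image.shape[1]
    flipped = [
        replace(i, box=BBox(width - i.box.xmax, i.box.ymin, width - i.box.xmin, i.box.ymax))
        for i in instances
    ]
    return image[:, ::-1].copy(), tuple(flipped)


def scale(
    image: np.ndarray, instances: Sequence[AnnotatedInstance], factor: float
) -> tuple[np.ndarray, tuple[AnnotatedInstance, ...]]:
    """Rescale image and multiply every box coordinate by ``factor``."""
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    scaled = transform.rescale(
        image,
        factor,
        channel_axis=2 if image.ndim == 3 else None,
        preserve_range=True,
        anti_aliasing=factor < 1,
    )
    scaled = scaled.astype(image.dtype)
    out = [
        replace(
            i,
            box=BBox(
                i.box.xmin * factor, i.box.ymin * factor, i.box.xmax * factor, i.box.ymax * factor
            ),
        )
        for i in instances
    ]
    return scaled, _clip_boxes(out, scaled.shape[1], scaled.shape[0])


def hsv_jitter(
    image: np.ndarray,
    instances: Sequence[AnnotatedInstance],
    saturation: float = 0.0,
    brightness: float = 0.0,
    contrast: float = 0.0,
) -> tuple[np.ndarray, tuple[AnnotatedInstance, ...]]:
    """Photometric jitter in HSV space; boxes are unchanged.

    Parameters are fractional deltas: saturation and brightness scale S
    and V by ``1 + delta``; contrast stretches V about its midpoint. All
    zeros is a pixel-identical no-op. Single-channel (infrared) images get
    only the brightness/contrast part.
    """
    if saturation == brightness == contrast == 0.0:
        return image.copy(), tuple(instances)
    img = image.astype(float) / 255.0
    if image.ndim == 2:
        v = img
        v = np.clip(v * (1.0 + brightness), 0, 1)
        v = np.clip((v - 0.5) * (1.0 + contrast) + 0.5, 0, 1)
        out = v
    else:
        hsv = color.rgb2hsv(img)
        hsv[..., 1] = np.clip(hsv[..., 1] * (1.0 + saturation), 0, 1)
        hsv[..., 2] = np.clip(hsv[..., 2] * (1.0 + brightness), 0, 1)
        hsv[..., 2] = np.clip((hsv[..., 2] - 0.5) * (1.0 + contrast) + 0.5, 0, 1)
        out = color.hsv2rgb(hsv)
    return (out * 255.0).round().astype(image.dtype), tuple(instances)


def augment(
    image: np.ndarray,
    instances: Sequence[AnnotatedInstance],
    ops: Sequence[tuple],
    seed: int | None = None,
) -> tuple[np.ndarray, tuple[AnnotatedInstance, ...]]:
    """Apply a sequence of augmentation ops.

    Each op is a tuple: ``("horizontal_flip",)``, ``("scale", factor)`` or
    ``("hsv_jitter", {"saturation": ..., "brightness": ..., "contrast": ...})``.
    A scale factor or jitter value given as a ``(lo, hi)`` range is drawn
    uniformly using ``seed``.
    """
    rng = np.random.default_rng(seed)

    def _draw(v):
        return float(rng.uniform(*v)) if isinstance(v, (tuple, list)) else v

    instances = tuple(instances)
    for op in ops:
        name = op[0]
        if name == "horizontal_flip":
            image, instances = horizontal_flip(image, instances)
        elif name == "scale":
            image, instances = scale(image, instances, _draw(op[1]))
        elif name == "hsv_jitter":
            params = {k: _draw(v) for k, v in op[1].items()}
            image, instances = hsv_jitter(image, instances, **params)
        else:
            raise ValueError(f"unknown augmentation op {name!r}")
    return image, instances
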