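"""Image conditioning: binning, background subtraction, blurring, projection.

These are the deterministic conditioning steps applied to every acquisition
before registration and spot calling: 2x2 binning with averaging,
subtraction of the mean intensity of a signal-free background ROI, per-slice
2D Gaussian blurring, per-slice rolling-ball background subtraction, and sum
projection along z.  All subtraction steps clamp at zero, and every step
appends itself to the stack's provenance log.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.restoration import rolling_ball

from .stack import ImageStack, Roi, register_op

__all__ = [
    "bin_half",
    "roi_background_subtract",
    "gaussian_blur",
    "rolling_ball_subtract",
    "sum_project",
]


@register_op("bin_half")
def bin_half(stack: ImageStack) -> ImageStack:
    """Scale y and x by 0.5 with averaging (2x2 binning).

    Each output pixel is the arithmetic mean of its 2x2 block; a trailing
    odd row/column is dropped.  z and channels are unchanged; the recorded
    pixel size doubles.
    """
    c, z, h, w = stack.shape
    if h < 2 or w < 2:
        raise ValueError(f"cannot bin a {h}x{w} frame; need >= 2 px per axis")
    h2, w2 = h // 2, w // 2
    d = stack.data[:, :, : 2 * h2, : 2 * w2]
    out = d.reshape(c, z, h2, 2, w2, 2).mean(axis=(3, 5))
    binned = stack.with_data(out, {"op": "bin_half"})
    binned.pixel_size_xy = stack.pixel_size_xy * 2
    return binned


@register_op("roi_background_subtract")
def roi_background_subtract(
    stack: ImageStack, roi: Roi | list, channel: str | None = None
) -> ImageStack:
    """Subtract the mean intensity of a background ROI from a channel.

    The background is a single scalar: the mean of the channel over *all*
    z-slices inside the 2D ROI.  The result is clamped at zero.  With
    ``channel=None`` every channel is corrected with its own ROI mean.
    """
    if not isinstance(roi, Roi):
        roi = Roi.from_config(roi)
    mask = roi.mask(stack.shape[2:])
    out = stack.data.copy()
    indices = (
        range(stack.shape[0]) if channel is None else [stack.channel_index(channel)]
    )
    for ci in indices:
        b = float(out[ci][:, mask].mean())
        out[ci] = np.maximum(out[ci] - b, 0.0)
    entry = {
        "op": "roi_background_subtract",
        "roi": roi.vertices.tolist(),
        "channel": channel,
    }
    return stack.with_data(out, entry)


@register_op("gaussian_blur")
def gaussian_blur(
    stack: ImageStack, sigma_xy: float, channels: list[str] | None = None
) -> ImageStack:
    """2D Gaussian blur applied per z-slice per channel (reflective border).

    Blurring is strictly lateral — nothing is mixed across z — and the
    reflective boundary preserves total intensity to float tolerance.
    """
    if sigma_xy < 0:
        raise ValueError("sigma_xy must be >= 0")
    out = stack.data.copy()
    indices = (
        range(stack.shape[0])
        if channels is None
        else [stack.channel_index(c) for c in channels]
    )
    if sigma_xy > 0:
        for ci in indices:
            out[ci] = ndi.gaussian_filter(
                stack.data[ci], sigma=(0, sigma_xy, sigma_xy), mode="reflect"
            )
    entry = {"op": "gaussian_blur", "sigma_xy": sigma_xy, "channels": channels}
    return stack.with_data(out, entry)


@register_op("rolling_ball_subtract")
def rolling_ball_subtract(
    stack: ImageStack, radius_px: float = 10, channels: list[str] | None = None
) -> ImageStack:
    """Per-slice rolling-ball background subtraction, clamped at zero.

    The background under each z-slice is estimated by rolling a ball of the
    given radius under the intensity surface (a grayscale opening with a
    ball element) and subtracted pixelwise.  Output <= input everywhere.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    out = stack.data.copy()
    indices = (
        range(stack.shape[0])
        if channels is None
        else [stack.channel_index(c) for c in channels]
    )
    for ci in indices:
        for zi in range(stack.shape[1]):
            bg = rolling_ball(stack.data[ci, zi], radius=radius_px)
            out[ci, zi] = np.maximum(stack.data[ci, zi] - bg, 0.0)
    entry = {"op": "rolling_ball_subtract", "radius_px": radius_px, "channels": channels}
    return stack.with_data(out, entry)


@register_op("sum_project")
def sum_project(stack: ImageStack) -> ImageStack:
    """Pixelwise sum over z; returns a stack with a single z-slice."""
    out = stack.data.sum(axis=1, keepdims=True)
    return stack.with_data(out, {"op": "sum_project"})
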