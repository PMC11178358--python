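"""Two-round rigid-body registration from DAPI.

The two hybridization rounds of a SABER-FISH experiment are imaged after
remounting the slide, so round 2 is related to round 1 by an in-plane
rigid-body motion (rotation about the image centre plus translation).  The
transform is estimated from the DAPI channel of one representative z-slice
and applied uniformly to every slice and channel of the moving round.

Estimation is coarse-to-fine: phase correlation gives the translation for
each candidate rotation on a bounded angle grid, the best angle is refined
by maximizing normalized cross-correlation (NCC), and the final translation
is re-estimated at sub-pixel precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import minimize_scalar
from skimage.registration import phase_cross_correlation

from .stack import ImageStack, register_op

__all__ = ["RigidTransform", "register_rigid", "apply_transform", "register_rounds",
           "merge_rounds"]


@dataclass(frozen=True)
class RigidTransform:
    """In-plane rigid motion: rotate by ``angle_deg`` about the image centre
    (or an explicit ``center``), then translate by ``(dy, dx)`` pixels.

    Points are ``(y, x)``; the forward map is ``p' = R (p - c) + c + t``.
    """

    angle_deg: float = 0.0
    dy: float = 0.0
    dx: float = 0.0
    center: tuple[float, float] | None = None  # (cy, cx); None = image centre

    # -- linear algebra ----------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        a = np.deg2rad(self.angle_deg)
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s], [s, c]])

    def _center_for(self, shape: tuple[int, int]) -> np.ndarray:
        if self.center is not None:
            return np.asarray(self.center, dtype=float)
        return (np.asarray(shape, dtype=float) - 1) / 2.0

    def apply_to_points(self, pts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        """Forward-map (n, 2) points given the frame shape (for the centre)."""
        c = self._center_for(shape)
        t = np.array([self.dy, self.dx])
        return (np.asarray(pts, dtype=float) - c) @ self.rotation.T + c + t

    def inverse(self) -> "RigidTransform":
        rinv = RigidTransform(-self.angle_deg, center=self.center).rotation
        t = rinv @ np.array([self.dy, self.dx])
        return RigidTransform(-self.angle_deg, -t[0], -t[1], self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``self`` then ``other``."""
        if self.center != other.center:
            raise ValueError("cannot compose transforms with different centres")
        t = other.rotation @ np.array([self.dy, self.dx]) + [other.dy, other.dx]
        return RigidTransform(self.angle_deg + other.angle_deg, t[0], t[1], self.center)

    def is_identity(self, tol: float = 1e-6) -> bool:
        return abs(self.angle_deg) < tol and abs(self.dy) < tol and abs(self.dx) < tol

    # -- serialization -----------------------------------------------------
    def as_dict(self) -> dict:
        return {
            "angle_deg": float(self.angle_deg),
            "dy": float(self.dy),
            "dx": float(self.dx),
            "center": None if self.center is None else [float(v) for v in self.center],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        center = d.get("center")
        return cls(
            float(d["angle_deg"]), float(d["dy"]), float(d["dx"]),
            None if center is None else (float(center[0]), float(center[1])),
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.as_dict(), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _warp2d(img: np.ndarray, t: RigidTransform) -> np.ndarray:
    """Forward-warp a 2D image by ``t`` (bilinear, zero fill)."""
    c = t._center_for(img.shape)
    rinv = RigidTransform(-t.angle_deg).rotation
    offset = c - rinv @ (c + [t.dy, t.dx])
    return ndi.affine_transform(img, rinv, offset=offset, order=1, mode="constant", cval=0.0)


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    av, bv = a[mask], b[mask]
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av ** 2).sum() * (bv ** 2).sum())
    return float((av * bv).sum() / denom) if denom > 0 else 0.0


def register_rigid(
    ref_slice: np.ndarray,
    mov_slice: np.ndarray,
    angle_window: float = 10.0,
    coarse_step: float = 1.0,
    ncc_floor: float = 0.2,
) -> RigidTransform:
    """Estimate the rigid transform mapping ``mov_slice`` onto ``ref_slice``.

    Searches rotations in ``[-angle_window, +angle_window]`` degrees
    (coarse grid, then bounded NCC refinement), with the translation at each
    angle obtained by phase correlation and finally re-estimated at 1/100 px.

    Raises ``ValueError`` on flat (zero-variance) input; warns if the final
    NCC falls below ``ncc_floor`` but still returns the transform.
    """
    ref = np.asarray(ref_slice, dtype=np.float64)
    mov = np.asarray(mov_slice, dtype=np.float64)
    if ref.shape != mov.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {mov.shape}")
    if ref.std() == 0 or mov.std() == 0:
        raise ValueError("cannot register a flat image (no signal)")

    valid_src = np.ones_like(mov)

    def solve_at(angle: float, upsample: int) -> tuple[RigidTransform, float]:
        rot = _warp2d(mov, RigidTransform(angle))
        shift, _, _ = phase_cross_correlation(
            ref, rot, upsample_factor=upsample, normalization=None
        )
        t = RigidTransform(angle, float(shift[0]), float(shift[1]))
        warped = _warp2d(mov, t)
        mask = _warp2d(valid_src, t) > 0.999
        if mask.sum() < 16:
            return t, -1.0
        return t, _ncc(ref, warped, mask)

    if angle_window > 0:
        angles = np.arange(-angle_window, angle_window + coarse_step / 2, coarse_step)
        scores = [solve_at(a, upsample=4)[1] for a in angles]
        best = angles[int(np.argmax(scores))]
        lo = max(best - 1.5 * coarse_step, -angle_window)
        hi = min(best + 1.5 * coarse_step, angle_window)
        res = minimize_scalar(
            lambda a: -solve_at(float(a), upsample=20)[1],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 0.01},
        )
        angle = float(res.x)
    else:
        angle = 0.0

    t, score = solve_at(angle, upsample=100)
    if score < ncc_floor:
        warnings.warn(
            f"registration similarity NCC={score:.3f} below floor {ncc_floor}",
            stacklevel=2,
        )
    return t


@register_op("apply_rigid")
def apply_transform(
    stack: ImageStack,
    t: RigidTransform | None = None,
    *,
    angle_deg: float = 0.0,
    dy: float = 0.0,
    dx: float = 0.0,
    center=None,
) -> ImageStack:
    """Apply one rigid transform to every slice and channel of a stack.

    Bilinear interpolation, out-of-frame pixels filled with 0.  The identity
    transform returns a bit-identical copy.
    """
    if t is None:
        t = RigidTransform(angle_deg, dy, dx, None if center is None else tuple(center))
    if not all(np.isfinite([t.angle_deg, t.dy, t.dx])):
        raise ValueError("transform parameters must be finite")
    entry = {"op": "apply_rigid", **t.as_dict()}
    if t.is_identity(tol=0.0):
        return stack.with_data(stack.data.copy(), entry)
    c = t._center_for(stack.shape[2:])
    rinv = RigidTransform(-t.angle_deg).rotation
    offset2 = c - rinv @ (c + [t.dy, t.dx])
    matrix = np.eye(3)
    matrix[1:, 1:] = rinv
    offset = np.array([0.0, offset2[0], offset2[1]])
    # warp channel by channel to bound peak memory on large stacks
    out = np.empty_like(stack.data)
    for ci in range(stack.shape[0]):
        out[ci] = ndi.affine_transform(
            stack.data[ci].astype(np.float64), matrix, offset=offset, order=1,
            mode="constant", cval=0.0,
        ).astype(np.float32)
    return stack.with_data(out, entry)


def register_rounds(
    round1: ImageStack,
    round2: ImageStack,
    ref_z: int | None = None,
    dapi: str = "DAPI",
    angle_window: float = 10.0,
) -> tuple[ImageStack, RigidTransform]:
    """Align round 2 onto round 1 using DAPI at one representative z-slice.

    Returns the fully warped round-2 stack (all channels, all slices) and
    the recovered transform.  ``ref_z`` defaults to the middle slice.
    """
    for stk in (round1, round2):
        if dapi not in stk.channel_names:
            raise KeyError(f"stack lacks a {dapi!r} channel: {stk.channel_names}")
    if ref_z is None:
        ref_z = round1.shape[1] // 2
    if not 0 <= ref_z < min(round1.shape[1], round2.shape[1]):
        raise IndexError(f"ref_z={ref_z} out of range")
    t = register_rigid(
        round1.plane(dapi, ref_z), round2.plane(dapi, ref_z), angle_window=angle_window
    )
    aligned = apply_transform(round2, t)
    return aligned, t


def merge_rounds(round1: ImageStack, aligned2: ImageStack, dapi: str = "DAPI") -> ImageStack:
    """Concatenate channels of the two aligned rounds into one stack.

    Round 1 contributes all channels; round 2 contributes its non-DAPI
    channels (its DAPI is redundant after alignment).
    """
    keep = [i for i, n in enumerate(aligned2.channel_names) if n != dapi]
    data = np.concatenate([round1.data, aligned2.data[keep]], axis=0)
    names = round1.channel_names + [aligned2.channel_names[i] for i in keep]
    log = list(round1.log) + [{"op": "merge_rounds", "round2_log": list(aligned2.log)}]
    return ImageStack(data, names, round1.pixel_size_xy, round1.z_step, log)
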