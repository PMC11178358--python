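"""Multi-channel 3D image stacks and regions of interest.

The :class:`ImageStack` is the carrier between every pipeline stage: a
``(channel, z, y, x)`` float array with per-axis pixel sizes, channel names
and an append-only provenance log.  Every conditioning operation records
itself in the log with its parameters, so the processed stack can be
reproduced bit-for-bit from the raw stack with :func:`replay`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import tifffile
from skimage.draw import polygon as draw_polygon

__all__ = ["ImageStack", "Roi", "replay", "register_op"]

# registry used by replay(); preprocess/registration ops register themselves
_OP_REGISTRY: dict[str, Callable] = {}


def register_op(name: str):
    """Decorator: make an ImageStack -> ImageStack op replayable by name."""

    def deco(fn):
        _OP_REGISTRY[name] = fn
        return fn

    return deco


@dataclass
class ImageStack:
    """A ``(c, z, y, x)`` intensity stack with metadata.

    Parameters
    ----------
    data : ndarray
        Intensities, shape ``(n_channels, n_z, n_y, n_x)``.  Stored as
        float32 internally regardless of input dtype.
    channel_names : list of str
        One name per channel, e.g. ``["DAPI", "Sox10", "Wnt1", "Sp5"]``.
    pixel_size_xy : float
        Lateral pixel size in micrometres (post-binning frame).
    z_step : float
        Axial step in micrometres per slice.
    log : list of dict
        Ordered provenance entries ``{"op": name, **params}``; append-only.
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size_xy: float = 1.0
    z_step: float = 1.0
    log: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim == 3:  # single channel convenience
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError(f"expected (c, z, y, x) data, got shape {self.data.shape}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}") from None

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) array for a named channel (a view)."""
        return self.data[self.channel_index(name)]

    def plane(self, name: str, z: int = 0) -> np.ndarray:
        """Return one 2D (y, x) slice of a named channel."""
        return self.data[self.channel_index(name), z]

    def with_data(self, data: np.ndarray, log_entry: dict | None = None) -> "ImageStack":
        """New stack sharing metadata, with ``log_entry`` appended if given."""
        log = list(self.log) + ([log_entry] if log_entry else [])
        return ImageStack(
            data, list(self.channel_names), self.pixel_size_xy, self.z_step, log
        )

    def copy(self) -> "ImageStack":
        return self.with_data(self.data.copy())

    # -- I/O ---------------------------------------------------------------
    def write_tiff(self, path: str | Path, dtype: str = "float32") -> Path:
        """Write as a CZYX multi-page TIFF with a JSON metadata description.

        ``dtype="uint16"`` clips to [0, 65535] and rounds (the on-disk
        convention for rendered synthetic acquisitions).
        """
        path = Path(path)
        if dtype == "uint16":
            arr = np.clip(np.rint(self.data), 0, 65535).astype(np.uint16)
        else:
            arr = self.data.astype(np.float32)
        meta = {
            "axes": "CZYX",
            "channel_names": self.channel_names,
            "pixel_size_xy_um": self.pixel_size_xy,
            "z_step_um": self.z_step,
        }
        tifffile.imwrite(path, arr, description=json.dumps(meta), photometric="minisblack")
        return path

    @classmethod
    def read_tiff(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            desc = tif.pages[0].description
        meta = {}
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        if arr.ndim == 3:
            arr = arr[None]
        names = meta.get("channel_names") or [f"ch{i}" for i in range(arr.shape[0])]
        return cls(
            arr,
            list(names),
            float(meta.get("pixel_size_xy_um", 1.0)),
            float(meta.get("z_step_um", 1.0)),
        )


@dataclass
class Roi:
    """A named closed 2D region (polygon) in post-binning pixel coordinates."""

    vertices: np.ndarray  # (n, 2) as (y, x)
    name: str = "roi"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("Roi needs >= 3 (y, x) vertices")
        y, x = self.vertices.T
        area = 0.5 * abs(np.dot(y, np.roll(x, 1)) - np.dot(x, np.roll(y, 1)))
        if area <= 0:
            raise ValueError("Roi polygon has zero area")

    @classmethod
    def rectangle(cls, y0: float, x0: float, y1: float, x1: float, name: str = "roi") -> "Roi":
        return cls(np.array([[y0, x0], [y0, x1], [y1, x1], [y1, x0]]), name=name)

    @classmethod
    def from_config(cls, spec: dict | Sequence) -> "Roi":
        """Build from a config entry: a rect dict or a vertex list.

        Accepted forms::

            {"rect": [y0, x0, y1, x1], "name": "bg"}
            {"polygon": [[y, x], ...]}
            [[y, x], [y, x], ...]
        """
        if isinstance(spec, dict):
            name = spec.get("name", "roi")
            if "rect" in spec:
                return cls.rectangle(*spec["rect"], name=name)
            return cls(np.asarray(spec["polygon"], dtype=float), name=name)
        return cls(np.asarray(spec, dtype=float))

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize to a boolean (y, x) mask; raises if empty."""
        y, x = self.vertices.T
        if y.min() < 0 or x.min() < 0 or y.max() > shape[0] or x.max() > shape[1]:
            raise ValueError("Roi vertices outside image bounds")
        rr, cc = draw_polygon(y, x, shape=shape)
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        if not m.any():
            raise ValueError("Roi rasterizes to an empty mask")
        return m


def replay(raw: ImageStack, log: Sequence[dict]) -> ImageStack:
    """Re-apply a provenance log to a raw stack, reproducing the output.

    Each log entry names a registered operation and carries its parameters;
    the result is bit-identical to the original processing chain.
    """
    out = raw
    for entry in log:
        entry = dict(entry)
        op = entry.pop("op")
        if op not in _OP_REGISTRY:
            raise KeyError(f"unknown operation in provenance log: {op!r}")
        out = _OP_REGISTRY[op](out, **entry)
    return out
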