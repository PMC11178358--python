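"""Transcripts per cell, transcript maps, and polyline kymographs.

Detected 3D transcript maxima are projected to 2D (z discarded) and each is
assigned to the nearest nuclear maximum, giving per-nucleus per-gene counts.
A 2D "transcripts per cell" map renders each nucleus as a disk whose pixel
value is its count.  Spatial expression along a drawn track is summarized
by a polyline kymograph: at each arc-length sample the intensity is
averaged across a fixed width perpendicular to the local track direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist
from skimage.draw import disk as draw_disk

from .spots import NucleusSet, SpotSet

__all__ = [
    "CellCounts",
    "Polyline",
    "Kymograph",
    "assign_spots",
    "make_nuclear_image",
    "polyline_kymograph",
    "kymograph_all",
]


@dataclass
class CellCounts:
    """Per-nucleus transcript counts for every gene.

    ``table`` is indexed by nucleus id with columns ``y``, ``x`` and one
    integer column per gene; ``unassigned`` counts spots farther than the
    (optional) maximum assignment radius per gene.
    """

    table: pd.DataFrame
    unassigned: dict[str, int] = field(default_factory=dict)
    max_radius: float | None = None

    @property
    def genes(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("y", "x")]

    def total(self, gene: str) -> int:
        return int(self.table[gene].sum())

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.rename_axis("nucleus_id").to_csv(path, sep="\t")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CellCounts":
        df = pd.read_csv(path, sep="\t", index_col="nucleus_id")
        return cls(df)


def assign_spots(
    spots: SpotSet, nuclei: NucleusSet, max_radius: float | None = None
) -> CellCounts:
    """Assign each spot to the nearest nuclear maximum in 2D.

    The spot's z is discarded; distance is Euclidean in (y, x); ties go to
    the lowest nucleus id.  With ``max_radius=None`` (unlimited, the
    default) every spot is assigned, so per-gene totals are conserved
    exactly.  Spots beyond a finite ``max_radius`` are tallied per gene in
    ``unassigned``.
    """
    n = len(nuclei)
    genes = spots.genes
    counts = {g: np.zeros(n, dtype=int) for g in genes}
    unassigned = {g: 0 for g in genes}
    for g in genes:
        pts = spots.positions[g]
        if len(pts) == 0 or n == 0:
            unassigned[g] = len(pts)
            continue
        d = cdist(pts[:, 1:].astype(float), nuclei.positions.astype(float))
        nearest = d.argmin(axis=1)  # argmin returns the lowest index on ties
        dmin = d[np.arange(len(pts)), nearest]
        ok = np.ones(len(pts), dtype=bool) if max_radius is None else dmin <= max_radius
        counts[g] = np.bincount(nearest[ok], minlength=n)
        unassigned[g] = int((~ok).sum())
    table = pd.DataFrame(
        {
            "y": nuclei.positions[:, 0] if n else [],
            "x": nuclei.positions[:, 1] if n else [],
            **{g: counts[g] for g in genes},
        }
    )
    return CellCounts(table, unassigned, max_radius)


def make_nuclear_image(
    counts: CellCounts, shape: tuple[int, int], gene: str, disk_radius: float = 10.0
) -> np.ndarray:
    """Render the transcripts-per-cell map for one gene.

    Each nucleus becomes a disk of ``disk_radius`` whose pixel value equals
    its count; overlapping disks resolve to the maximum.
    """
    img = np.zeros(shape, dtype=float)
    for _, row in counts.table.iterrows():
        if not (0 <= row["y"] < shape[0] and 0 <= row["x"] < shape[1]):
            raise ValueError("nucleus position outside the requested shape")
        rr, cc = draw_disk((row["y"], row["x"]), disk_radius, shape=shape)
        img[rr, cc] = np.maximum(img[rr, cc], row[gene])
    return img


@dataclass
class Polyline:
    """An ordered 2D track with an averaging width, in post-binning px."""

    vertices: np.ndarray          # (n, 2) as (y, x)
    width: float = 100.0
    step: float = 1.0

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 2:
            raise ValueError("Polyline needs >= 2 (y, x) vertices")
        if self.width < 1:
            raise ValueError("width must be >= 1 px")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.arc_length() <= 0:
            raise ValueError("polyline has zero length")

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)

    def arc_length(self) -> float:
        return float(self.segment_lengths().sum())

    def sample(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sample points, tangents and arc positions along the track.

        Points are spaced ``step`` px along the continuous arc-length
        parameterization; the tangent within a segment is the segment
        direction, and exactly at an interior vertex it is the normalized
        angle bisector of the adjacent segments.
        """
        v = self.vertices
        keep = np.concatenate(
            [[True], np.linalg.norm(np.diff(v, axis=0), axis=1) > 0]
        )
        v = v[keep]  # drop repeated consecutive vertices
        seg = np.diff(v, axis=0)
        lens = np.linalg.norm(seg, axis=1)
        dirs = seg / lens[:, None]
        cum = np.concatenate([[0.0], np.cumsum(lens)])
        s = np.arange(0, np.floor(cum[-1] / self.step) + 1) * self.step
        pts = np.empty((len(s), 2))
        tans = np.empty((len(s), 2))
        for j, sj in enumerate(s):
            i = min(int(np.searchsorted(cum, sj, side="right")) - 1, len(lens) - 1)
            local = sj - cum[i]
            pts[j] = v[i] + dirs[i] * local
            if 0 < i and abs(local) < 1e-9:  # exactly at an interior vertex
                t = dirs[i - 1] + dirs[i]
                norm = np.linalg.norm(t)
                tans[j] = t / norm if norm > 1e-12 else dirs[i]
            else:
                tans[j] = dirs[i]
        return pts, tans, s

    @classmethod
    def from_config(cls, spec: dict) -> "Polyline":
        return cls(
            np.asarray(spec["vertices"], dtype=float),
            width=float(spec.get("width", 100.0)),
            step=float(spec.get("step", 1.0)),
        )


@dataclass
class Kymograph:
    """Genes x arc-length matrix of width-averaged intensity."""

    values: np.ndarray            # (n_genes, n_samples)
    genes: list[str]
    arc_positions: np.ndarray     # (n_samples,) in px
    polyline: Polyline

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.values.T, columns=self.genes)
        df.insert(0, "arc_px", self.arc_positions)
        df.to_csv(path, sep="\t", index=False)
        return path

    def plot(self, path: str | Path):
        """Write a per-gene profile plot alongside the TSV export."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 3.5))
        for g, row in zip(self.genes, self.values):
            ax.plot(self.arc_positions, row, label=g)
        ax.set_xlabel("arc length (px)")
        ax.set_ylabel("width-averaged intensity")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return Path(path)


def polyline_kymograph(image: np.ndarray, line: Polyline) -> np.ndarray:
    """One kymograph row: width-averaged intensity along the track.

    At each arc-length sample, ``width`` points spaced 1 px are placed
    symmetrically along the unit normal to the local track direction,
    sampled by bilinear interpolation, and averaged; samples falling
    outside the image contribute only their in-bounds pixels.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    pts, tans, _ = line.sample()
    normals = np.column_stack([-tans[:, 1], tans[:, 0]])
    w = int(round(line.width))
    offsets = np.arange(w) - (w - 1) / 2.0
    # coords: (2, n_samples, width)
    coords = pts.T[:, :, None] + normals.T[:, :, None] * offsets[None, None, :]
    inside = (
        (coords[0] >= 0)
        & (coords[0] <= img.shape[0] - 1)
        & (coords[1] >= 0)
        & (coords[1] <= img.shape[1] - 1)
    )
    vals = ndi.map_coordinates(img, coords.reshape(2, -1), order=1, mode="constant",
                               cval=0.0).reshape(inside.shape)
    vals[~inside] = 0.0
    n_in = inside.sum(axis=1)
    if (n_in == 0).any():
        raise ValueError("a kymograph sample lies entirely outside the image")
    return vals.sum(axis=1) / n_in


def kymograph_all(
    images: dict[str, np.ndarray], line: Polyline, order: list[str] | None = None
) -> Kymograph:
    """Stack one kymograph row per gene into a genes x arc-length matrix."""
    genes = order or list(images)
    shapes = {images[g].shape for g in genes}
    if len(shapes) != 1:
        raise ValueError(f"mismatched image shapes: {shapes}")
    rows = [polyline_kymograph(images[g], line) for g in genes]
    _, _, s = line.sample()
    return Kymograph(np.vstack(rows), genes, s, line)
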