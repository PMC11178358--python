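"""Per-cell marker positivity and population-fraction statistics.

Given a DAPI-segmented label image (from the built-in threshold + watershed
segmenter or supplied externally), cells are classified positive or
negative per marker channel from their mean intensity, and the cell-cycle
style population fractions are computed over a selected region: the
percentage of A-positive, B-positive, double-positive and double-negative
cells (e.g. EdU / pHH3 within a neural plate border ROI), plus the ratio of
marker-positive cells in one region over all cells in a reference region
(e.g. Sox10-positive migratory cells over DAPI-positive neuroepithelium).

Marginal convention: A+% and B+% are *inclusive* of double positives, so
``n_A+ + n_B+ - n_double+ + n_double- = n_total`` holds identically.  An
exclusive mode (A+ only / B+ only) is available via ``exclusive=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

__all__ = [
    "LabeledCells",
    "PopulationFractions",
    "segment_nuclei_simple",
    "classify_positive",
    "population_fractions",
    "ratio_over_reference",
]


@dataclass
class LabeledCells:
    """A 2D label image plus per-cell measurements.

    ``labels`` uses 0 for background and 1..n for cells; ``means`` holds
    one row per cell (indexed by label) with a column per measured channel;
    ``centroids`` is (n, 2) as (y, x) in label order.
    """

    labels: np.ndarray
    means: pd.DataFrame = field(default_factory=pd.DataFrame)
    centroids: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        ids = self.cell_ids
        if len(ids) and not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("labels must be contiguous 1..n")
        if len(self.centroids) == 0 and len(ids):
            self.centroids = np.array(ndi.center_of_mass(self.labels > 0, self.labels, ids))

    @property
    def cell_ids(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def measure(self, channels: dict[str, np.ndarray]) -> "LabeledCells":
        """Populate per-cell mean intensities for the given channel images."""
        ids = self.cell_ids
        data = {
            name: ndi.mean(np.asarray(img, dtype=float), self.labels, ids)
            for name, img in channels.items()
        }
        self.means = pd.DataFrame(data, index=pd.Index(ids, name="label"))
        return self

    def in_mask(self, mask: np.ndarray | None) -> np.ndarray:
        """Boolean per cell: centroid lies inside the (y, x) mask."""
        if mask is None:
            return np.ones(self.n_cells, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        idx = np.clip(np.rint(self.centroids).astype(int), 0,
                      np.array(mask.shape) - 1)
        return mask[idx[:, 0], idx[:, 1]]


def segment_nuclei_simple(
    dapi: np.ndarray,
    min_distance: int = 10,
    min_area: int = 30,
) -> LabeledCells:
    """Classical DAPI segmentation: Otsu -> fill -> watershed split.

    A global Otsu threshold selects foreground, holes are filled, touching
    nuclei are split by a distance-transform watershed seeded at local
    maxima at least ``min_distance`` apart, and components smaller than
    ``min_area`` pixels are dropped.  A blank image yields zero cells.
    """
    img = np.asarray(dapi, dtype=float)
    if img.max() == img.min():
        return LabeledCells(np.zeros(img.shape, dtype=np.int32))
    fg = img > threshold_otsu(img)
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        return LabeledCells(np.zeros(img.shape, dtype=np.int32))
    dist = ndi.distance_transform_edt(fg)
    seeds = peak_local_max(dist, min_distance=min_distance, labels=fg)
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(seeds.T)] = np.arange(1, len(seeds) + 1)
    if len(seeds) == 0:
        labels = cc_label(fg)
    else:
        labels = watershed(-dist, markers, mask=fg)
    labels = remove_small_objects(labels, max_size=min_area - 1)
    # relabel contiguously, preserving spatial order of first occurrence
    _, labels = np.unique(labels, return_inverse=True)
    return LabeledCells(labels.reshape(img.shape).astype(np.int32))


def classify_positive(
    cells: LabeledCells, channel: str, threshold_spec: float | str = "otsu"
) -> np.ndarray:
    """Boolean per cell: mean intensity >= threshold.

    ``threshold_spec`` is either a fixed intensity or ``"otsu"``, in which
    case the threshold is computed by Otsu's method over the per-cell
    means (appropriate for well-separated positive/negative populations).
    """
    if cells.means.empty or channel not in cells.means:
        raise ValueError(f"no per-cell means for channel {channel!r}; call measure()")
    means = cells.means[channel].to_numpy(dtype=float)
    if isinstance(threshold_spec, str):
        if threshold_spec.lower() != "otsu":
            raise ValueError(f"unknown threshold spec {threshold_spec!r}")
        if np.ptp(means) == 0:
            return np.zeros(len(means), dtype=bool)
        thr = threshold_otsu(means)
    else:
        thr = float(threshold_spec)
    return means >= thr


@dataclass
class PopulationFractions:
    """Counts and percentages for a two-marker population.

    With the inclusive-marginal convention, ``n_a + n_b - n_double_pos +
    n_double_neg == n_total`` always holds; percentages are 100 * count /
    n_total.
    """

    n_total: int
    n_a: int
    n_b: int
    n_double_pos: int
    n_double_neg: int
    marker_a: str = "A"
    marker_b: str = "B"
    exclusive: bool = False

    def __post_init__(self):
        if self.n_total <= 0:
            raise ValueError("population is empty")
        if not self.exclusive:
            identity = self.n_a + self.n_b - self.n_double_pos + self.n_double_neg
            assert identity == self.n_total, "marginal identity violated"

    @property
    def pct_a(self) -> float:
        return 100.0 * self.n_a / self.n_total

    @property
    def pct_b(self) -> float:
        return 100.0 * self.n_b / self.n_total

    @property
    def pct_double_pos(self) -> float:
        return 100.0 * self.n_double_pos / self.n_total

    @property
    def pct_double_neg(self) -> float:
        return 100.0 * self.n_double_neg / self.n_total

    def as_series(self) -> pd.Series:
        a, b = self.marker_a, self.marker_b
        suffix = "_only" if self.exclusive else ""
        return pd.Series(
            {
                "n_total": self.n_total,
                f"{a}+%{suffix}": self.pct_a,
                f"{b}+%{suffix}": self.pct_b,
                f"{a}+{b}+%": self.pct_double_pos,
                f"{a}-{b}-%": self.pct_double_neg,
            }
        )


def population_fractions(
    cells: LabeledCells,
    marker_a: str,
    marker_b: str,
    population_mask: np.ndarray | None = None,
    threshold_spec: float | str = "otsu",
    exclusive: bool = False,
) -> PopulationFractions:
    """Two-marker positivity fractions over cells inside a region.

    Membership is by centroid-in-mask.  By default A+% and B+% include
    double positives (inclusive marginals); ``exclusive=True`` reports
    A+B- and A-B+ instead.
    """
    sel = cells.in_mask(population_mask)
    if not sel.any():
        raise ValueError("population mask selects no cells")
    pos_a = classify_positive(cells, marker_a, threshold_spec)[sel]
    pos_b = classify_positive(cells, marker_b, threshold_spec)[sel]
    both = pos_a & pos_b
    neither = ~pos_a & ~pos_b
    if exclusive:
        n_a, n_b = int((pos_a & ~pos_b).sum()), int((pos_b & ~pos_a).sum())
    else:
        n_a, n_b = int(pos_a.sum()), int(pos_b.sum())
    return PopulationFractions(
        int(sel.sum()), n_a, n_b, int(both.sum()), int(neither.sum()),
        marker_a, marker_b, exclusive,
    )


def ratio_over_reference(
    cells: LabeledCells,
    marker: str,
    reference_mask: np.ndarray | None,
    numerator_mask: np.ndarray | None = None,
    threshold_spec: float | str = "otsu",
) -> float:
    """Marker-positive cells in one region over all cells in a reference.

    The numerator region defaults to the whole field; the two regions may
    differ (e.g. migratory mesenchyme vs neuroepithelium).  Raises on an
    empty reference.
    """
    ref = cells.in_mask(reference_mask)
    n_ref = int(ref.sum())
    if n_ref == 0:
        raise ValueError("reference region selects no cells")
    pos = classify_positive(cells, marker, threshold_spec)
    num = pos & cells.in_mask(numerator_mask)
    return float(num.sum()) / n_ref
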