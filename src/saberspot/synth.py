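"""Synthetic two-round SABER-FISH acquisitions with complete ground truth.

Every downstream stage (registration, nuclei and 3D transcript detection,
transcripts-per-cell assignment, kymographs) is tested against scenes
generated here: DAPI nuclei as bright 3D Gaussian blobs, diffraction-limited
transcript puncta whose per-cell counts are Poisson with a per-gene rate,
rare very bright autofluorescent debris visible in every gene channel,
additive background plus Gaussian read noise, and a known rigid-body offset
between the two imaging rounds.

The default parameters are the package's frozen study conditions: a
32-slice stack (1 µm per slice) over a 1088x1088 post-binning field holding
20 well-separated cells expressing 5 genes at 30 transcripts per cell, with
20 debris at 10x the puncta amplitude.  Geometry is self-consistent with
the detection parameters used downstream (nuclear maxima >= 70 px apart,
transcript maxima separated by >= 12 px laterally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .register import RigidTransform
from .stack import ImageStack

__all__ = [
    "SceneParams",
    "GroundTruth",
    "SceneTooCrowdedError",
    "generate_scene",
    "render_round",
    "write_truth_tables",
    "read_truth_tables",
    "simulate_marker_cells",
]

DEFAULT_GENES = ("Sox10", "Wnt1", "Sp5", "Pak3", "Dlc1")
DEFAULT_ROUNDS = {"Sox10": 1, "Wnt1": 1, "Sp5": 1, "Pak3": 2, "Dlc1": 2}


class SceneTooCrowdedError(RuntimeError):
    """Nucleus placement failed: too many nuclei for the requested spacing."""


@dataclass
class SceneParams:
    """Generator configuration; defaults are the frozen study conditions."""

    image_shape: tuple[int, int, int] = (32, 1088, 1088)  # (z, y, x)
    n_nuclei: int = 20
    nucleus_radius_px: float = 24.0          # lateral blob radius (sigma = r/2)
    nucleus_z_extent: float = 10.0           # axial extent in slices (sigma = e/4)
    genes: tuple[str, ...] = DEFAULT_GENES
    round_assignment: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ROUNDS))
    expression_rate: dict[str, float] = field(
        default_factory=lambda: {g: 30.0 for g in DEFAULT_GENES}
    )
    puncta_scatter_radius: float = 90.0      # cytoplasmic spread around the nucleus
    min_center_distance: float = 160.0       # nucleus spacing (>= 2 * radius required)
    edge_margin: float = 80.0                # nucleus centres keep this xy margin
    puncta_edge_margin: float = 24.0         # puncta keep this xy margin
    spot_sigma_px: tuple[float, float] = (1.5, 1.0)    # (xy, z)
    spot_amplitude: float = 200.0
    amplitude_lognorm_sigma: float = 0.2     # per-punctum brightness spread
    nucleus_amplitude: float = 600.0
    n_debris: int = 20
    debris_amplitude: float = 2000.0
    debris_sigma_px: tuple[float, float] = (1.8, 0.8)
    background_level: float = 50.0
    noise_sd: float = 8.0
    inter_round_transform: RigidTransform = field(
        default_factory=lambda: RigidTransform(1.0, 3.0, -4.0)
    )
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_nuclei < 0 or self.n_debris < 0:
            raise ValueError("counts must be >= 0")
        if min(self.spot_amplitude, self.nucleus_amplitude, self.debris_amplitude) <= 0:
            raise ValueError("amplitudes must be > 0")
        if self.debris_amplitude <= self.spot_amplitude:
            raise ValueError("debris_amplitude must exceed spot_amplitude")
        if self.min_center_distance < 2 * self.nucleus_radius_px:
            raise ValueError("min_center_distance must be >= 2 * nucleus_radius_px")
        for g in self.genes:
            if self.round_assignment.get(g) not in (1, 2):
                raise ValueError(f"gene {g!r} must map to round 1 or 2")
            if self.expression_rate.get(g, 0.0) < 0:
                raise ValueError(f"expression_rate[{g!r}] must be >= 0")
        extra = set(self.round_assignment) - set(self.genes)
        if extra:
            raise ValueError(f"round_assignment covers unknown genes: {sorted(extra)}")

    def genes_in_round(self, round_id: int) -> list[str]:
        return [g for g in self.genes if self.round_assignment[g] == round_id]

    # -- config I/O --------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "image_shape": list(self.image_shape),
            "n_nuclei": self.n_nuclei,
            "nucleus_radius_px": self.nucleus_radius_px,
            "nucleus_z_extent": self.nucleus_z_extent,
            "genes": list(self.genes),
            "round_assignment": dict(self.round_assignment),
            "expression_rate": dict(self.expression_rate),
            "puncta_scatter_radius": self.puncta_scatter_radius,
            "min_center_distance": self.min_center_distance,
            "edge_margin": self.edge_margin,
            "puncta_edge_margin": self.puncta_edge_margin,
            "spot_sigma_px": list(self.spot_sigma_px),
            "spot_amplitude": self.spot_amplitude,
            "amplitude_lognorm_sigma": self.amplitude_lognorm_sigma,
            "nucleus_amplitude": self.nucleus_amplitude,
            "n_debris": self.n_debris,
            "debris_amplitude": self.debris_amplitude,
            "debris_sigma_px": list(self.debris_sigma_px),
            "background_level": self.background_level,
            "noise_sd": self.noise_sd,
            "inter_round_transform": self.inter_round_transform.as_dict(),
            "rng_seed": self.rng_seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneParams":
        d = dict(d)
        if "inter_round_transform" in d:
            d["inter_round_transform"] = RigidTransform.from_dict(d["inter_round_transform"])
        for key in ("image_shape", "spot_sigma_px", "debris_sigma_px", "genes"):
            if key in d:
                d[key] = tuple(d[key])
        p = cls(**d)
        p.validate()
        return p

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


@dataclass
class GroundTruth:
    """Everything the generator decided, in the round-1 coordinate frame."""

    nucleus_centers: np.ndarray                 # (n, 2) as (y, x)
    nucleus_z: np.ndarray                       # (n,)
    counts: dict[str, np.ndarray]               # gene -> (n,) int
    puncta: dict[str, np.ndarray]               # gene -> (m, 3) as (z, y, x)
    puncta_owner: dict[str, np.ndarray]         # gene -> (m,) nucleus index
    puncta_amplitude: dict[str, np.ndarray]     # gene -> (m,)
    debris: np.ndarray                          # (d, 3) as (z, y, x)
    debris_amplitude: np.ndarray                # (d,)
    transform: RigidTransform                   # applied to round-2 coordinates

    def check(self, params: SceneParams) -> None:
        """Assert the generator invariants (count conservation, bounds)."""
        nz, ny, nx = params.image_shape
        for g in params.genes:
            assert int(self.counts[g].sum()) == len(self.puncta[g])
            assert np.array_equal(
                np.bincount(self.puncta_owner[g], minlength=params.n_nuclei),
                self.counts[g],
            )
            if len(self.puncta[g]):
                p = self.puncta[g]
                assert (p[:, 0] >= 0).all() and (p[:, 0] <= nz - 1).all()
                assert (p[:, 1] >= 0).all() and (p[:, 1] <= ny - 1).all()
                assert (p[:, 2] >= 0).all() and (p[:, 2] <= nx - 1).all()


def _place_nuclei(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample nucleus centres with bounded retries."""
    _, ny, nx = params.image_shape
    m = params.edge_margin
    lo = np.array([m, m])
    hi = np.array([ny - 1 - m, nx - 1 - m])
    if params.n_nuclei == 0:
        return np.empty((0, 2))
    if (hi <= lo).any():
        raise SceneTooCrowdedError("edge margin leaves no room for nuclei")
    buf = np.empty((params.n_nuclei, 2))
    for _restart in range(10):
        k = 0
        for _dart in range(20000):
            p = rng.uniform(lo, hi)
            if k == 0 or np.hypot(*(buf[:k] - p).T).min() >= params.min_center_distance:
                buf[k] = p
                k += 1
                if k == params.n_nuclei:
                    return buf.copy()
    raise SceneTooCrowdedError(
        f"could not place {params.n_nuclei} nuclei at spacing "
        f">= {params.min_center_distance} px in {ny}x{nx}"
    )


def generate_scene(params: SceneParams) -> GroundTruth:
    """Draw the full scene: nuclei, per-cell puncta, debris.

    Deterministic for a fixed ``params.rng_seed``.  Per-cell transcript
    counts are Poisson with mean ``expression_rate[gene]``; puncta scatter
    uniformly in a disk of ``puncta_scatter_radius`` around the owning
    nucleus centre (resampled to respect the puncta edge margin) with z
    uniform over the usable slice range.
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    nz, ny, nx = params.image_shape
    centers = _place_nuclei(params, rng)
    n = len(centers)
    nucleus_z = np.clip(
        rng.normal((nz - 1) / 2, 2.0, size=n), 2.0, nz - 3.0
    ) if n else np.empty(0)

    pm = params.puncta_edge_margin
    zlo, zhi = 2.0, nz - 3.0
    counts: dict[str, np.ndarray] = {}
    puncta: dict[str, np.ndarray] = {}
    owner: dict[str, np.ndarray] = {}
    amp: dict[str, np.ndarray] = {}
    for g in params.genes:
        k = rng.poisson(params.expression_rate.get(g, 0.0), size=n).astype(int)
        counts[g] = k
        pts, own = [], []
        for i in range(n):
            for _ in range(k[i]):
                for _try in range(200):
                    r = params.puncta_scatter_radius * np.sqrt(rng.uniform())
                    th = rng.uniform(0, 2 * np.pi)
                    yx = centers[i] + [r * np.sin(th), r * np.cos(th)]
                    if pm <= yx[0] <= ny - 1 - pm and pm <= yx[1] <= nx - 1 - pm:
                        break
                else:  # pragma: no cover - margin always reachable by design
                    yx = np.clip(yx, pm, [ny - 1 - pm, nx - 1 - pm])
                z = rng.uniform(zlo, zhi)
                pts.append([z, yx[0], yx[1]])
                own.append(i)
        puncta[g] = np.array(pts, dtype=float).reshape(-1, 3)
        owner[g] = np.array(own, dtype=int)
        amp[g] = params.spot_amplitude * np.exp(
            rng.normal(0.0, params.amplitude_lognorm_sigma, size=len(own))
        )

    d = params.n_debris
    debris = np.column_stack(
        [
            rng.uniform(zlo, zhi, d),
            rng.uniform(8, ny - 9, d),
            rng.uniform(8, nx - 9, d),
        ]
    ) if d else np.empty((0, 3))
    debris_amp = params.debris_amplitude * rng.uniform(0.8, 1.5, d)

    truth = GroundTruth(
        centers, nucleus_z, counts, puncta, owner, amp, debris, debris_amp,
        params.inter_round_transform,
    )
    truth.check(params)
    return truth


def _add_gaussian(
    vol: np.ndarray, zyx: np.ndarray, amplitude: float, sigma_xy: float, sigma_z: float
) -> None:
    """Accumulate one 3D Gaussian source into ``vol`` (local patch only)."""
    nz, ny, nx = vol.shape
    z0, y0, x0 = zyx
    rz = max(int(np.ceil(4 * sigma_z)), 1)
    rxy = max(int(np.ceil(4 * sigma_xy)), 1)
    zs = slice(max(int(z0) - rz, 0), min(int(z0) + rz + 2, nz))
    ys = slice(max(int(y0) - rxy, 0), min(int(y0) + rxy + 2, ny))
    xs = slice(max(int(x0) - rxy, 0), min(int(x0) + rxy + 2, nx))
    if zs.start >= zs.stop or ys.start >= ys.stop or xs.start >= xs.stop:
        return
    zz = np.arange(zs.start, zs.stop, dtype=float)[:, None, None]
    yy = np.arange(ys.start, ys.stop, dtype=float)[None, :, None]
    xx = np.arange(xs.start, xs.stop, dtype=float)[None, None, :]
    vol[zs, ys, xs] += amplitude * np.exp(
        -((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * sigma_xy**2)
        - (zz - z0) ** 2 / (2 * sigma_z**2)
    )


def render_round(truth: GroundTruth, params: SceneParams, round_id: int) -> ImageStack:
    """Render one imaging round as a DAPI + assigned-genes stack.

    Round 2 is rendered after applying the inter-round transform to every
    ground-truth coordinate, so registration has to undo it.  Debris are
    broadband: they appear in every gene channel of both rounds at shared
    (transformed) locations.  Background and Gaussian read noise are added
    per channel; the noise realization differs between rounds but is
    deterministic for a fixed seed.
    """
    if round_id not in (1, 2):
        raise ValueError(f"round_id must be 1 or 2, got {round_id}")
    nz, ny, nx = params.image_shape
    genes = params.genes_in_round(round_id)
    names = ["DAPI"] + genes
    data = np.zeros((len(names), nz, ny, nx), dtype=np.float32)

    def map_pts(zyx: np.ndarray) -> np.ndarray:
        if round_id == 1 or len(zyx) == 0 or truth.transform.is_identity(tol=0.0):
            return zyx
        yx = truth.transform.apply_to_points(zyx[:, 1:], (ny, nx))
        return np.column_stack([zyx[:, 0], yx])

    # DAPI nuclei
    nuc = np.column_stack([truth.nucleus_z, truth.nucleus_centers]) if len(
        truth.nucleus_centers
    ) else np.empty((0, 3))
    for zyx in map_pts(nuc):
        _add_gaussian(
            data[0], zyx, params.nucleus_amplitude,
            params.nucleus_radius_px / 2, params.nucleus_z_extent / 4,
        )

    sxy, sz = params.spot_sigma_px
    dxy, dz = params.debris_sigma_px
    debris_pts = map_pts(truth.debris)
    for ci, g in enumerate(genes, start=1):
        for zyx, a in zip(map_pts(truth.puncta[g]), truth.puncta_amplitude[g]):
            _add_gaussian(data[ci], zyx, a, sxy, sz)
        for zyx, a in zip(debris_pts, truth.debris_amplitude):
            _add_gaussian(data[ci], zyx, a, dxy, dz)

    data += params.background_level
    if params.noise_sd > 0:
        noise_rng = np.random.default_rng([params.rng_seed, round_id, 0x5ABE])
        for ci in range(len(names)):
            data[ci] += noise_rng.normal(0, params.noise_sd, size=(nz, ny, nx)).astype(
                np.float32
            )
    return ImageStack(
        data, names, log=[{"op": "render_round", "round_id": round_id}]
    )


# ---------------------------------------------------------------------------
# truth-table serialization
# ---------------------------------------------------------------------------

def write_truth_tables(truth: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Emit plain-text truth tables; a round-trip read reproduces the truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = list(truth.counts)

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(len(truth.nucleus_centers)),
            "y": truth.nucleus_centers[:, 0] if len(truth.nucleus_centers) else [],
            "x": truth.nucleus_centers[:, 1] if len(truth.nucleus_centers) else [],
            "z": truth.nucleus_z,
        }
    )
    for g in genes:
        cells[f"count_{g}"] = truth.counts[g]

    rows = []
    for g in genes:
        for (z, y, x), own, a in zip(
            truth.puncta[g], truth.puncta_owner[g], truth.puncta_amplitude[g]
        ):
            rows.append((g, int(own), z, y, x, a))
    puncta = pd.DataFrame(
        rows, columns=["gene", "cell_id", "z", "y", "x", "amplitude"]
    )

    debris = pd.DataFrame(
        {
            "z": truth.debris[:, 0] if len(truth.debris) else [],
            "y": truth.debris[:, 1] if len(truth.debris) else [],
            "x": truth.debris[:, 2] if len(truth.debris) else [],
            "amplitude": truth.debris_amplitude,
        }
    )

    paths = {
        "cells": outdir / "truth_cells.tsv",
        "puncta": outdir / "truth_puncta.tsv",
        "debris": outdir / "truth_debris.tsv",
        "transform": outdir / "truth_transform.json",
    }
    cells.to_csv(paths["cells"], sep="\t", index=False, float_format="%.17g")
    puncta.to_csv(paths["puncta"], sep="\t", index=False, float_format="%.17g")
    debris.to_csv(paths["debris"], sep="\t", index=False, float_format="%.17g")
    truth.transform.to_json(paths["transform"])
    return paths


def read_truth_tables(outdir: str | Path) -> GroundTruth:
    """Inverse of :func:`write_truth_tables`."""
    outdir = Path(outdir)
    cells = pd.read_csv(outdir / "truth_cells.tsv", sep="\t", float_precision="round_trip")
    puncta = pd.read_csv(outdir / "truth_puncta.tsv", sep="\t", float_precision="round_trip")
    debris = pd.read_csv(outdir / "truth_debris.tsv", sep="\t", float_precision="round_trip")
    transform = RigidTransform.from_json(outdir / "truth_transform.json")

    genes = [c[len("count_"):] for c in cells.columns if c.startswith("count_")]
    counts = {g: cells[f"count_{g}"].to_numpy(dtype=int) for g in genes}
    pts, owner, amp = {}, {}, {}
    for g in genes:
        sub = puncta[puncta["gene"] == g]
        pts[g] = sub[["z", "y", "x"]].to_numpy(dtype=float).reshape(-1, 3)
        owner[g] = sub["cell_id"].to_numpy(dtype=int)
        amp[g] = sub["amplitude"].to_numpy(dtype=float)
    return GroundTruth(
        cells[["y", "x"]].to_numpy(dtype=float).reshape(-1, 2),
        cells["z"].to_numpy(dtype=float),
        counts, pts, owner, amp,
        debris[["z", "y", "x"]].to_numpy(dtype=float).reshape(-1, 3),
        debris["amplitude"].to_numpy(dtype=float),
        transform,
    )


# ---------------------------------------------------------------------------
# labelled-cell scenes for marker scoring
# ---------------------------------------------------------------------------

def simulate_marker_cells(
    n_cells: int,
    positive_rate_a: float,
    positive_rate_b: float | None = None,
    shape: tuple[int, int] = (256, 256),
    cell_radius: float = 7.0,
    spacing: float = 22.0,
    high_mean: float = 300.0,
    high_sd: float = 30.0,
    low_mean: float = 50.0,
    low_sd: float = 10.0,
    dapi_amplitude: float = 400.0,
    noise_sd: float = 5.0,
    seed: int = 0,
):
    """Render a 2D DAPI field plus one or two marker channels.

    Cells sit on a jittered grid; each cell is independently marker-positive
    with the given rate and gets a bright (high) or dim (low) mean intensity
    accordingly.  Returns ``(dapi, markers, centers, truth)`` where
    ``markers``/``truth`` map channel name ("A", "B") to the image and the
    true boolean positivity vector.
    """
    rng = np.random.default_rng(seed)
    ys = np.arange(spacing, shape[0] - spacing / 2, spacing)
    xs = np.arange(spacing, shape[1] - spacing / 2, spacing)
    grid = np.array([(y, x) for y in ys for x in xs])
    if n_cells > len(grid):
        raise ValueError(f"grid holds at most {len(grid)} cells")
    centers = grid[rng.choice(len(grid), size=n_cells, replace=False)]
    centers = centers + rng.uniform(-3, 3, size=centers.shape)

    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dapi = np.zeros(shape)
    disks = []
    for cy, cx in centers:
        d = (yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius**2
        disks.append(d)
        dapi[d] = dapi_amplitude
    dapi += rng.normal(0, noise_sd, shape)

    rates = {"A": positive_rate_a}
    if positive_rate_b is not None:
        rates["B"] = positive_rate_b
    markers, truth = {}, {}
    for name, rate in rates.items():
        pos = rng.uniform(size=n_cells) < rate
        img = np.full(shape, low_mean / 2.0)
        for d, p in zip(disks, pos):
            level = rng.normal(high_mean, high_sd) if p else rng.normal(low_mean, low_sd)
            img[d] = level
        img += rng.normal(0, noise_sd, shape)
        markers[name] = img
        truth[name] = pos
    return dapi, markers, centers, truth
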