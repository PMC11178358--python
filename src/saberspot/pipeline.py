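"""End-to-end synthetic experiment: simulate, register, detect, quantify.

This is the glue that runs the whole quantification chain on a generated
two-round scene and writes every tabular output.  Identical parameters and
seed produce byte-identical TSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import roi_background_subtract
from .quantify import CellCounts, Kymograph, Polyline, assign_spots, kymograph_all, \
    make_nuclear_image
from .register import RigidTransform, merge_rounds, register_rounds
from .spots import NucleusSet, SpotSet, detect_nuclei, detect_transcripts
from .stack import ImageStack, Roi
from .synth import GroundTruth, SceneParams, generate_scene, render_round, \
    write_truth_tables

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    params: SceneParams
    truth: GroundTruth
    transform: RigidTransform
    combined: ImageStack
    nuclei: NucleusSet
    spots: SpotSet
    counts: CellCounts
    count_maps: dict[str, np.ndarray]
    kymograph: Kymograph
    outputs: dict[str, Path]


def _quantize(stack: ImageStack) -> ImageStack:
    """Apply the on-disk uint16 quantization (clip + round) in memory."""
    q = np.clip(np.rint(stack.data), 0, 65535).astype(np.float32)
    return stack.with_data(q, {"op": "quantize_uint16"})


def run_pipeline(
    params: SceneParams,
    outdir: str | Path | None = None,
    *,
    bg_roi: Roi | None = None,
    kymo_line: Polyline | None = None,
    write_images: bool = False,
) -> PipelineResult:
    """Run the full chain on one synthetic scene.

    simulate both rounds -> uint16 quantization -> per-channel background
    subtraction from a signal-free ROI -> DAPI rigid registration of round
    2 -> channel merge -> nuclei detection -> 3D transcript detection ->
    nearest-nucleus assignment -> transcripts-per-cell maps -> polyline
    kymograph.  If ``outdir`` is given, truth tables and all TSV outputs
    (and optionally the rendered TIFF stacks) are written there.
    """
    truth = generate_scene(params)
    if bg_roi is None:
        bg_roi = Roi.rectangle(4, 4, 44, 44, name="background")

    written: dict[str, Path] = {}
    rounds = []
    for rid in (1, 2):
        stk = _quantize(render_round(truth, params, rid))
        if outdir is not None and write_images:
            Path(outdir).mkdir(parents=True, exist_ok=True)
            written[f"round{rid}"] = stk.write_tiff(
                Path(outdir) / f"round{rid}.tif", dtype="float32"
            )
        rounds.append(roi_background_subtract(stk, bg_roi))

    aligned2, transform = register_rounds(rounds[0], rounds[1])
    rounds[1] = None  # release the unaligned copy; memory matters at full scale
    combined = merge_rounds(rounds[0], aligned2)
    del aligned2
    rounds = None

    nuclei = detect_nuclei(combined)
    spots = detect_transcripts(combined, gene_channels=list(params.genes))
    counts = assign_spots(spots, nuclei)

    shape = combined.shape[2:]
    count_maps = {g: make_nuclear_image(counts, shape, g) for g in params.genes}

    if kymo_line is None:
        ny, nx = shape
        kymo_line = Polyline([[ny / 2, 40], [ny / 2, nx - 40]], width=100.0)
    kymo = kymograph_all(count_maps, kymo_line, order=list(params.genes))

    outputs: dict[str, Path] = dict(written)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        outputs.update(write_truth_tables(truth, outdir))
        params.to_yaml(outdir / "scene_params.yaml")
        outputs["params"] = outdir / "scene_params.yaml"
        outputs["nuclei"] = nuclei.to_tsv(outdir / "nuclei.tsv")
        outputs["spots"] = spots.to_tsv(outdir / "spots.tsv")
        outputs["counts"] = counts.to_tsv(outdir / "counts.tsv")
        outputs["kymograph"] = kymo.to_tsv(outdir / "kymograph.tsv")
        outputs["transform_est"] = transform.to_json(outdir / "transform_estimated.json")

    return PipelineResult(
        params, truth, transform, combined, nuclei, spots, counts, count_maps,
        kymo, outputs,
    )
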