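# saberspot

Quantification of multiplexed SABER-FISH imaging experiments: two-round
rigid registration, nuclei and 3D transcript spot detection, per-cell
transcript counting, polyline kymographs of spatial expression, and
per-cell marker-positivity statistics — together with a synthetic-scene
generator that provides complete ground truth for every stage.

## The problem

SABER-FISH reads out several RNA species on one tissue section over
multiple fluorophore-hybridization rounds. Quantifying such data means:
(i) conditioning each acquired z-stack (binning, background subtraction);
(ii) aligning the rounds, which are related by an in-plane rigid-body
motion from remounting the slide; (iii) finding nuclei as cell proxies in
a blurred DAPI sum projection; (iv) calling diffraction-limited transcript
puncta in 3D while rejecting rare very bright autofluorescent debris; (v)
attributing each transcript to the nearest nucleus; and (vi) summarizing
spatial expression along a drawn track as a width-averaged kymograph. The
package also implements the companion per-cell scoring used for cell-cycle
and lineage quantification: positive/negative classification per marker
channel on a segmented label image, the four population percentages (A+%,
B+%, double-positive %, double-negative %), and the ratio of
marker-positive cells over a reference population.

The detection core is greedy maximum finding: candidates strictly greater
than all neighbours are ranked by intensity and accepted unless they fall
inside the exclusion zone of an already accepted maximum — isotropic
(min distance 70 px, threshold 10% of maximum) for nuclei in 2D;
anisotropic (xy distance < 12 px AND |Δz| < 4 slices, threshold 7% of the
per-channel maximum) for transcripts in 3D, after a σ=1 blur, a radius-10
rolling-ball background subtraction, and removal of the 20 brightest spots
under a 15 × 15 × 5 spheroid. See `docs/methods.md` for the full
specification, the exact tie rules, and the synthetic-scene model.

## Worked example

Simulate a small two-round scene and run the whole chain:

```bash
cat > scene.yaml <<'YAML'
image_shape: [12, 320, 320]
n_nuclei: 6
nucleus_radius_px: 14.0
nucleus_z_extent: 6.0
min_center_distance: 90.0
edge_margin: 48.0
puncta_scatter_radius: 35.0
puncta_edge_margin: 12.0
expression_rate: {Sox10: 6.0, Wnt1: 6.0, Sp5: 6.0, Pak3: 6.0, Dlc1: 6.0}
n_debris: 4
YAML
saberspot pipeline --config scene.yaml --outdir out --seed 7
```

prints

```
nuclei=6 spots=144 conserved=True outputs=['cells', 'counts', 'debris',
'kymograph', 'nuclei', 'params', 'puncta', 'spots', 'transform', 'transform_est']
```

i.e. all 6 simulated nuclei were detected, 144 transcript maxima were
called across the 5 gene channels, and every spot was attributed to a cell
(`conserved=True`: per-gene column sums in `counts.tsv` equal the number
of detected spots). The per-cell count table starts

```
nucleus_id  y    x    Sox10  Wnt1  Sp5  Pak3  Dlc1
0           187  248  4      5     8    5     2
1           48   48   6      5     10   1     3
```

and `transform_estimated.json` holds the recovered round-2 alignment

```json
{"angle_deg": -0.9918, "dy": -2.92, "dx": 4.05, "center": null}
```

which undoes the simulated inter-round motion of +1.0°, (dy, dx) =
(3, −4) px to within 0.01° and 0.1 px. The same stages are available as
library functions (`saberspot.detect_transcripts`, `assign_spots`,
`polyline_kymograph`, `population_fractions`, …) operating on `ImageStack`
objects with an append-only provenance log.

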