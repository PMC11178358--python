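# Methods

## Scope and model of the data

`saberspot` quantifies multiplexed SABER-FISH acquisitions: two imaging
rounds of the same tissue section, each a multi-channel 3D stack (DAPI plus
a subset of gene probes; the canonical panel is round 1 = Sox10/Wnt1/Sp5,
round 2 = Pak3/Dlc1, 32 z-slices at 1 µm). Because the slide is remounted
between rounds, round 2 is displaced from round 1 by an in-plane rigid-body
motion. Signal is punctate: each diffraction-limited spot is treated as one
transcript. Nuclei are not segmented; the nuclear maxima of a blurred DAPI
sum projection act as cell proxies, and each transcript is attributed to
its nearest nucleus.

## Processing chain

All pixel-unit parameters below are interpreted in post-binning pixels,
because 2x binning is the first step of the chain.

1. **Conditioning.** 2x2 binning with averaging (trailing odd row/column
   dropped); subtraction of a single scalar background per channel — the
   mean intensity over all z inside a user-drawn signal-free ROI — clamped
   at zero. The scalar (rather than per-slice) background matches the
   one-number behaviour of the classical ROI-average plugin family.
2. **Registration.** The rigid transform (rotation about the image centre
   + translation) is estimated from the DAPI channel of one representative
   z-slice (default: the middle slice) and applied to every slice and
   channel of round 2 with bilinear interpolation and zero fill. The
   estimator is phase correlation for translation inside a coarse-to-fine
   search over rotation (default window ±10°, reflecting plausible
   remounting drift), refined by maximizing normalized cross-correlation
   on the overlap region, with a final 1/100-px phase-correlation
   translation. Flat inputs raise; a final NCC below a configurable floor
   warns but still returns the transform. No z-registration is attempted.
3. **Nuclei.** z sum projection of DAPI → 2D Gaussian blur σ = 4 → greedy
   maximum finding with minimum spot distance 70 px and a threshold at 10%
   of the (post-blur) image maximum.
4. **Transcripts.** Per gene channel: 2D-per-slice Gaussian blur σ = 1 →
   per-slice rolling-ball background subtraction, radius 10 px (ball
   rolled under the intensity surface; output clamped at zero) → removal
   of the 20 brightest 3D spots under an axis-aligned spheroid of xy
   diameter 15 and z diameter 5 (autofluorescent debris) → greedy 3D
   maximum finding with an anisotropic exclusion zone (xy distance < 12 px
   AND |Δz| < 4 slices), thresholded at 7% of the post-removal channel
   maximum.
5. **Transcripts per cell.** Spot z is discarded; each spot goes to the
   nearest nuclear maximum in 2D (unlimited radius by default, so per-gene
   totals are conserved exactly; a finite radius reports unassigned spots
   instead). Ties go to the lowest nucleus id.
6. **Maps and kymographs.** The transcripts-per-cell map renders each
   nucleus as a disk (default radius 10 px, a purely visual device) whose
   value is its count, overlaps resolved by maximum. The polyline
   kymograph samples the track at 1-px arc-length steps; at each sample,
   `width` points spaced 1 px are placed symmetrically along the unit
   normal to the local segment (angle bisector exactly at interior
   vertices), read by bilinear interpolation, and averaged; out-of-bounds
   points contribute nothing. Default width 100 px.

### Maximum finding: exact rules

The greedy finder is the package's core primitive, so its tie rules are
fixed precisely: a candidate is a pixel/voxel **strictly** greater than all
its 8 (2D) or 26 (3D) neighbours; candidates below the threshold fraction
of the global maximum are dropped; remaining candidates are ranked by
intensity descending, ties broken by lexicographically smallest coordinate;
each candidate is accepted unless it falls strictly inside the exclusion
zone of an already accepted maximum (a distance exactly equal to the limit
is allowed). Strict inequality means a perfectly flat plateau yields no
candidate; on continuous-valued data plateaus have measure zero, and the
rules make every output a deterministic function of the input. The greedy
pass is pinned to an exhaustive brute-force enumeration over random 2D/3D
arrays in the test suite.

Two ambiguities in the classical macro order are resolved as follows: the
10% nuclei threshold is computed on the blurred projection (thresholding
follows the blur), and debris-removal intensities are taken after the
rolling ball (removal follows it in the chain). Both choices are recorded
in the output parameter metadata.

## Marker scoring

For the cell-cycle and ratio quantifications, cells come from a label
image: either supplied externally or from the built-in classical segmenter
(global Otsu threshold on DAPI → hole filling → distance-transform
watershed seeded at local maxima ≥ `min_distance` apart → components below
`min_area` = 30 px dropped). The original analyses used learned
segmentation models that are not reproducible from a description, so the
package deliberately ships a transparent classical substitute with the same
interface. Positivity per channel is by per-cell mean intensity against
either a fixed threshold or Otsu's method over the per-cell means.

Population fractions over a region (membership = centroid inside the mask)
use the **inclusive-marginal** convention: A+% and B+% include double
positives, which makes the four reported quantities satisfy the identity
`n_A+ + n_B+ − n_double+ + n_double− = n_total` — this is the convention
under which the four headline percentages are mutually consistent, and an
exclusive mode (`exclusive=True`, reporting A+B−/A−B+) is provided because
the alternative reading cannot be ruled out. The ratio estimator counts
marker-positive cells in a numerator region over all cells in a reference
region; the two regions may differ.

The kymograph may be computed either from raw (processed) fluorescence or
from the transcripts-per-cell map; both are supported because the source
material describes the map as "number of transcripts per cell" but the
kymograph as "average intensity". The pipeline default uses the count map.

## Synthetic scenes and what they do (not) show

The generator renders both rounds with complete ground truth: nuclei as 3D
Gaussian blobs in DAPI (lateral σ = radius/2, axial σ = extent/4),
transcripts as 3D Gaussian puncta (σxy = 1.5 px, σz = 1 slice) with
per-cell counts drawn Poisson(rate), per-punctum brightness lognormal
(σ = 0.2) around the spot amplitude, debris as very bright compact
Gaussians rendered in **every** gene channel (autofluorescence is
spectrally broad; this also makes the fixed 20-spot removal well-posed),
constant background plus Gaussian read noise, and the configured rigid
transform applied to all round-2 coordinates before rendering. Writing to
disk quantizes to uint16; the pipeline applies the same quantization
in-memory so results are independent of the I/O path. Scenes are generated
directly in the post-binning frame; the binning operator is exercised on
small fixtures instead of doubling every synthetic render.

Default study conditions (frozen; every figure of merit in
`scripts/acceptance.py` is computed under them):

| parameter | value | rationale |
| --- | --- | --- |
| image shape | 32 × 1088 × 1088 | 32 slices at 1 µm as acquired; field sized so 20 cells fit at the spacing below |
| nuclei | 20, min centre distance 160 px, edge margin 80 px | spacing must exceed the 70-px nuclear exclusion and, with the scatter below, keep nearest-nucleus assignment faithful |
| transcripts | 5 genes × Poisson(30)/cell, scattered uniformly in a 90-px disk, z uniform over slices 2–29 | at rate 30 the cytoplasm must be large enough that the 12-px/4-slice exclusion only rarely merges true pairs |
| spot amplitude / noise | 200 vs σ = 8 (background 50) | amplified SABER puncta are bright; at σ ≳ 12 rolling-ball residual noise starts crossing the 7% threshold |
| debris | 20 at 10× spot amplitude, σ = (1.8, 0.8) px | compact so the 15 × 5 removal spheroid fully covers them without leaving above-threshold crater rims |
| inter-round transform | 1.0°, (dy, dx) = (3, −4) px | typical remounting drift; the registration sweep separately covers ±8° and ±15 px |

Geometry was fixed analytically from the detection parameters before the
pipeline was assembled: pair-collision rates under the anisotropic
exclusion predict the achievable recall, and the spacing-to-scatter ratio
bounds misassignment. The defaults sit where both recovery targets hold
with margin, and they were not revisited afterwards.

What the scenes do **not** emulate: optical PSF structure (spots are
Gaussians, not Airy/defocus patterns), spectral bleed-through, chromatic
aberration, intensity falloff with depth, tissue autofluorescence texture,
cell-shape heterogeneity, or correlated expression between neighbours.
Passing recovery tests therefore demonstrates the correctness and internal
consistency of the chain under its stated model, not performance on real
tissue; on real data the thresholds and the background ROI remain the
user's responsibility.

## Numerical choices

- Intensities are float32 internally; all subtraction steps clamp at zero.
- Gaussian blurs use reflective boundaries (total intensity preserved to
  float tolerance) and are strictly 2D per slice.
- The rolling-ball background is the classical ball-rolled-under-surface
  estimate (scikit-image implementation); the exact legacy variant differs
  between tools, so the choice is pinned by golden tests and recorded in
  the provenance log.
- Warping is bilinear with zero fill; rotation centre is the geometric
  image centre `((n−1)/2)`.
- Every stack operation appends `{op, params}` to an append-only
  provenance log; replaying the log on the raw stack reproduces the output
  bit for bit, and TSV outputs are byte-identical across runs for a fixed
  seed.
- Per-cell count recovery is summarized by the Spearman correlation pooled
  over all (cell, gene) pairs: with 20 cells per scene the per-gene rank
  correlation is too noisy to be a stable figure of merit, and the pooled
  statistic answers the question actually asked of the map (are high- and
  low-expressing cells ordered correctly across the panel).
- Nucleus placement is rejection sampling with bounded retries (10 restarts
  × 20 000 darts); an infeasible spacing raises `SceneTooCrowdedError`
  rather than looping forever.

## Known limitations

- Registration is 2D and single-slice by design; axial drift between
  rounds is not corrected.
- No sub-voxel spot localization: positions are voxel-grid maxima.
- Nearest-nucleus assignment has no notion of cell boundaries; in dense
  tissue counts blur between adjacent cells (quantified by the recovery
  tests at the default geometry).
- The fixed removal of the 20 brightest spots erases real signal when a
  channel contains fewer than 20 debris; with ≥ 500 spots per channel the
  effect on per-cell counts is below the 5% level (tested), but sparse
  channels would be biased.
- ImageJ `.roi` files are not parsed; ROIs and polylines are given as
  coordinate lists (rectangles or polygons) in config files.
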