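# Methods

## Scope and data model

The package quantifies duodenal mucosal architecture from 3-D voxel volumes
of the kind produced by contrast-enhanced micro-CT of endoscopic biopsies
(~2 µm voxels). Two quantities are computed: the **effective surface area
coefficient** (mucosal interface area within an orientated rectangle,
divided by the rectangle area; 1.0 = perfectly flat mucosa) and the
**VH:CrD ratio** (mean villous height over mean crypt depth on a digital
section, with the strict `< 2.0` lesion cutoff).

All volumes are `(z, y, x)` arrays with `z` the axial, lumen-pointing
direction; the world coordinate of a voxel is `index × spacing` (µm). Voxel
spacing is never defaulted: files without spacing metadata are rejected
(`MetadataError`), because every area in mm² scales with its square.

## Synthetic phantoms

No public scan volumes of this kind exist, so validation rests on phantom
families whose surface areas and morphometry are known in closed form:

- **flat_slab** — slab of thickness *t*; coefficient exactly 1.0.
- **sinusoid** — egg-crate relief
  `H(x, y) = t + (h/2)(1 + sin(2πx/λ) sin(2πy/λ))`, peak-to-trough
  amplitude *h*. Area over a rectangle is the graph integral
  `∬ √(1 + H_x² + H_y²) dx dy`, evaluated by midpoint quadrature (default
  400 points per wavelength per axis; halving the step changes the value by
  < 0.1 %, and it increases strictly with *h*).
- **finger_villi** — cylinders of radius *r* capped by hemispheres (total
  height *h*, cylindrical part *h − r*) on a square grid of pitch *p*,
  plus optional cylindrical crypt wells (radius *r_c*, depth *d_c*) sunk
  into the slab midway between neighbouring villi along each villus row.
  Closed-form area under a rectangle covering *N* villi and *N_c* wells:
  `s² − Nπr² + 2Nπr(h−r) + 2Nπr² + 2N_c π r_c d_c`
  (the crypt mouth removed from the base plane cancels the added floor
  disk). Ground-truth VH = *h*, CrD = *d_c*.

Occupancy is decided at voxel centres (centre-in-solid). Villi sit on a
regular grid without jitter so the closed forms stay exact; only circles
falling fully inside the lateral extent (or, for ground truth, fully under
the rectangle) are counted. Default study geometry for the
finger phantom (2 µm voxels, 250 µm slab, h = 300 µm, r = 25 µm,
p = 125 µm, d_c = 150 µm, r_c = 15 µm) uses a 0.70 mm lateral extent so the
centred 0.5 mm rectangle's edges run through the plateau between villi and
wells — partial structures straddling the boundary would otherwise be
measured fractionally while the closed form counts them all-or-nothing.

`render_grayscale` emulates a contrast-stained scan: tissue/background at
two intensity levels (defaults 200/50), Gaussian blur of stated physical
width, additive Gaussian noise from a seeded generator (fixed seed ⇒
byte-identical output). It does not model X-ray physics: no beam hardening,
ring artefacts, anisotropic PSF, intensity inhomogeneity from uneven stain
penetration, or correlated noise. Passing tests on these phantoms therefore
demonstrate correctness of the measurement chain, not robustness to every
artefact of real scans; on real data the manual threshold and manual
landmarks are the governing interfaces.

## Crofton surface-area estimator

The Cauchy–Crofton identity recovers a surface's area from intersection
counts with lines. On the lattice, for direction *d* with step vector
`v_d` (13 directions: 3 axes, 6 face diagonals, 4 body diagonals):

    S = Σ_d  W_d · a_d · I_d

where `I_d` counts occupancy transitions between neighbouring voxels along
*d*, `a_d = voxel volume / step length` is the cross-section per lattice
line, and `W_d` is a direction weight. For a unit-area plane with normal
*n* the estimator responds with `f(n) = Σ_d W_d |⟨v_d, n⟩|`; an unbiased
estimator needs `f ≡ 1`.

**Weight calibration.** Classical direction-density (spherical-Voronoi)
weights give `f ≈ 0.93–0.96` everywhere — they under-measure an
axis-aligned flat interface by ~7 %, which is unacceptable when the flat
mucosa baseline of exactly 1.0 is the reference point of the coefficient.
The default weights therefore solve a small linear program per spacing:
minimise `max_n |f(n) − 1|` over a 4000-point Fibonacci sampling of the
sphere, subject to non-negative weights, `f = 1` exactly for the three
axis-normal planes, and sphere-average of `f` equal to 1. For isotropic
spacing the LP is reduced to the three lattice-symmetry classes, keeping
the weights symmetric (≈ 0.065 per axis, 0.169 per face diagonal, 0.198
per body diagonal). Resulting behaviour, verified in the test suite:
axis-aligned plates exact to < 1 %; a digital ball of radius 30 voxels to
< 0.1 % with error decreasing under grid refinement (the sphere-mean
constraint makes the residual purely discretisation); worst-case plane
orientations ±7 %, azimuth-averaged bias within ±4 %, so smooth mixed-
orientation surfaces (sinusoids, villi) land within a few per cent. The
Voronoi scheme remains available (`weight_scheme="voronoi"`) for
comparison, and the 3-axis variant (`direction_count=3`, weights 2/3,
isotropically unbiased but strongly orientation-dependent) serves as a
bookkeeping cross-check: on axis-aligned boxes it must report exactly 2/3
of the true face area.

**Lookup table.** Contributions are tabulated over the 256 possible 2×2×2
occupancy patterns; an edge shared by several overlapping cells is divided
by its multiplicity (axis 4, face diagonal 2, body diagonal 1), so the
cell-sum reproduces the direction counts exactly. The table is zero for the
empty and full patterns, non-negative, and complement-symmetric.

**Measurement prism.** The rectangle is fitted in `auto` mode: a
least-squares plane through the per-column top-of-tissue height field gives
the mucosal normal (for flat, tilted, or periodically corrugated mucosa the
relief averages out of the fit); the plane is then dropped to the deepest
interface (mucosal base) and the prism spans from just above the tallest
tissue down to a pad below the base (`extra_depth_um` extends it when crypt
walls below the base must be counted). A 2×2×2 cell belongs to the prism
iff its centre lies in the half-open box — a centre rule rather than full
8-corner containment, because the corner rule biases the footprint by one
cell row (~1 % at 0.1 mm sides) while the centre rule is unbiased. No cut
faces are ever created: only tissue/background transitions of the stored
volume are counted, so deepening the prism into solid tissue changes the
area by < 0.5 % (tested).

**Replicates.** For each square side, *n* placements (default 20) at
uniformly random in-plane offsets share one fitted orientation, and the
mean with a Student-t 95 % CI (n − 1 df) is reported; `n = 1` yields an
undefined CI with a warning. When the fitted frame is lattice-aligned the
per-cell contribution field is reduced once to a 2-D integral image, making
each replicate a four-term box sum; the general oblique path evaluates each
prism directly, and both paths agree to 0.1 % (tested). The ROI-size study
runs on a 1.28 mm sinusoid phantom at 4 µm voxels — the coarser grid keeps
the volume at ~11 M voxels while leaving > 60 voxels per wavelength.

## Preprocessing

Non-local means (scikit-image, 3-D patches; defaults patch radius 2,
search radius 5, strength *h* ≈ 0.8 σ_noise) is the default denoiser;
a cubic median filter is retained as the tested alternative. No filter
parameters are claimed to match any commercial implementation — defaults
were chosen so the render → denoise → segment chain recovers phantom
occupancy with Dice ≥ 0.99 at intensity levels 200/50 and noise σ ≤ 20.
Segmentation thresholds the bright (stained-tissue) class at an explicit
number, or by Otsu's criterion for unattended runs; a constant volume
raises a degenerate-histogram error rather than guessing. Optional cleanup
keeps the largest 26-connected component. Thresholding is monotone:
raising the threshold never adds tissue.

## Digital sections and VH:CrD

`extract_section` resamples the volume on an orientated plane
(`scipy.ndimage.map_coordinates`; nearest-neighbour for binary, trilinear
for grayscale). Lattice-aligned planes reproduce stored slices exactly in
both modes (tested).

`compute_vhcd` enforces the morphometric rules: at least three
crypt-villous pairs, ratio = mean(VH)/mean(CrD) (robust to a single short
crypt; `method="mean_of_ratios"` exposes the alternative), and the strict
cutoff — ratio exactly 2.0 is *not* a lesion. Pairs whose crypt is absent
block the ratio with an explicit error.

`auto_landmarks` automates landmarking on binary phantom sections only; on
real scans expert landmarks (delimited text: sample, section_id, pair_id,
role ∈ {tip, junction, base}, x_um, y_um) govern. From the per-column
tissue height profile: prominent local maxima are villus tips; within each
inter-peak segment the heights are sorted and split at jumps larger than
`wall_jump_um` (25 µm — taller than any step a smooth relief can produce at
these slopes, far smaller than a crypt wall). A lowest cluster separated by
such a jump and lying below the saddle is a crypt floor; the saddle cluster
median is the junction level. Where the only jump is the villus wall
itself, the lowest cluster *is* the saddle and the crypt is flagged absent
(sinusoidal folds therefore yield `crd = None` and an undefined ratio, as
they should). Each pair's three landmarks are emitted collinear along the
villus axis so that VH and CrD are exactly the vertical tip–junction and
junction–base distances; how a villus–crypt junction should be located on
real digital sections is left to the expert reader. The heuristic is not
validated against wet-histology practice.

## Pipeline and reproducibility

`run_sample` composes the stages from a single YAML config (CLI flags can
override dotted keys); the resolved config, its SHA-256 and a stage log are
archived with `report.tsv`/`replicates.tsv`. All randomness (rendering
noise, replicate offsets) derives from the config seed, and report files
contain no timestamps, so a fixed config is byte-reproducible (tested).
Stage failures propagate annotated with sample id and stage name.

## Numerical choices and degenerate inputs

- LP weight calibration is deterministic (HiGHS on fixed Fibonacci
  samples); weights are recomputed per spacing, anisotropic spacing uses
  the full 13-weight problem.
- Half-open prism membership breaks ties deterministically.
- Empty measurement regions return area 0 with a warning instead of
  raising; a prism with no interface yields coefficient 0 with a warning.
- Sinusoid with h = 0 is bit-identical to the flat slab; finger villi need
  `h > r` so the cap fits; crypts must fit inside the slab and between
  villi (validated up front with actionable messages).
- Quadrature for the sinusoid truth uses midpoint sums (no endpoint
  singularities); the Richardson check (×2 resolution) guards it.

## Known limitations

- The estimator's worst-case plane response is ±7 % at isolated oblique
  orientations; numeric parity with any proprietary Crofton variant is not
  claimed.
- Phantoms do not model merged or branched villi — real atrophic mucosa can
  form complex fused structures whose surface area drops while VH:CrD stays
  normal; such geometry has no ground truth here and is out of scope.
- Inflammation (intraepithelial lymphocytes), enterocyte height and grouped
  histopathological classification are outside the package's scope.
- `auto_landmarks` assumes villi resolved as distinct height-profile peaks
  in the section; heavily tilted or overlapping villi defeat it (use manual
  landmarks).
- Rectangle auto-placement assumes the biopsy's mucosal surface is a
  single-valued height field over the fitted base plane; strongly folded or
  inverted geometries require a manual frame.
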