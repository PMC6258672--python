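# Methods

## Model and assumptions

The pipeline treats an epithelial monolayer's apical surface as a planar
graph of cells, junctions and vertices at quasi-static mechanical
equilibrium. Three assumptions carry all of the inference:

1. **Force balance at vertices.** Junctional tensions are much larger than
   the residual forces that drive morphogenetic movement, so the vector
   sum of tensions at every vertex is taken as zero. Tensions act along
   the junction chords; curvature is neglected.
2. **Uniform pressure.** With negligible junctional curvature, pressure
   differences between cells vanish from the balance, so only tensions are
   inferred.
3. **Three-fold vertices.** The dual tension network is a triangulation
   only if every vertex joins exactly three cells; cells touching
   higher-order vertices are excluded (`restrict_threefold`), which keeps
   most cells in practice.

Under these assumptions the balanced tension assignment is, up to scale,
the edge-length set of a dual triangulation perpendicular to the cell
network. The inference recovers it variationally: assembling the quadratic
forms `A` (perpendicularity violation, weighted by the squared chord) and
`B` (total squared dual-edge length) over the stacked 2·N_cells node
coordinates and solving `A q = Λ B q` for the smallest eigenvalue after
deflating the two global translations. On an exactly balanced tissue Λ = 0
and the eigenvector is the true dual; on noisy tissues the smallest mode
deforms continuously from it. Inferred tensions are relative; they are
rescaled so their mean over reported junctions is exactly 1.

**Fit set versus report set.** The eigenproblem is assembled over *all*
cells and every junction with two adjacent cells, including boundary ones.
Restricting the fit to interior cells leaves peripheral dual nodes with
one or two constraints; such nodes host near-null modes of `A` that
displace the physical eigenvector on noisy networks (recovery against
ground truth collapses). Tensions are nevertheless *reported* only for
interior junctions — both flanking cells inside the field of view — and
the normalisation runs over that set. Shear stress, correlations and
ablation logic consume reported tensions only.

## Shear stress

Cortical tensions on the two sides of a junction sum to the junctional
tension and are continuous at the end vertices. Eliminating the cortical
tensions in favour of the four neighbour junctions gives the average shear
stress `τ = |(T1 + T3) − (T2 + T4)| / (2L)`, with T1/T3 the diagonal pair
(opposite cells at opposite ends). Only the junction-averaged scalar is
computed — the pointwise profile τ(x) is not determined by the neighbour
tensions. The signed value and the dominant side are retained as metadata;
junctions without a complete quadruple (boundary, non-three-fold end, or a
neighbour without a tension) carry an explicit exclusion reason, never a
silent zero.

## Quantification conventions

* Junctional ROIs: the junction path dilated to 5 px width, minus 3-px
  disks around each vertex (the vertex-exclusion radius is not fixed by
  the published workflow; 3 px is this package's configurable default).
* Medial ROIs: the cell interior kept ≥ 2 px from any junctional ROI or
  vertex disk.
* Focus selection: per-64-px-tile Sobel gradient energy, plane with the
  maximal median tile score; the signal image max-projects that plane plus
  two basal planes, the background image max-projects the three basal-most
  planes followed by a 50-px-radius median filter, and the processed image
  is their clipped difference.
* Pixel SNR for the Vinc/E-cad profile: background = 50-px median filter
  of the E-cadherin channel; noise scale = 1.4826 × MAD of the residual
  over non-junctional pixels; pixels with SNR > 1 enter 25-unit-wide
  intensity bins. The exact estimator of the original macros is not
  published; this stand-in is configurable.
* Junction Vinc/E-cad is ratio-of-means (mean Vinculin density over mean
  E-cadherin density), matching the per-junction ratio of line densities.
* Polarity: six 15° bins of the angle to the AP axis (folded to [0, 90]);
  PCP = ratio of the extreme-bin ALDs in the requested orientation;
  relative intensity normalises by the smaller extreme bin. Orientation
  classes default to vertical = [60, 90], transverse = [0, 30] and are
  configurable — the published analysis names the classes without printing
  cutoffs.

## Correlation machinery

Line densities and inferred tensions both scale like 1/length, so their
raw correlation is confounded. Two guards are implemented:

* **Conditional correlation**: junctions sorted by length within each
  snapshot, chunked into bins of exactly 10 (remainder dropped, ties
  broken by input order), one coefficient per bin; the by-length curve
  groups bins whose mean length rounds to the same pixel.
* **Local correlation**: Pearson across the junctions of each cell with
  ≥ 4 junctions (Pearson needs 3; one more for stability — this package's
  choice). The null permutes the y-variable across all junctions of the
  snapshot and recomputes every per-cell coefficient; this preserves
  per-cell topology and both marginals. The null construction is not
  specified in the source workflow and is flagged as this package's
  design.

Method choice follows the small-sample rule: Spearman below 100 points,
Pearson otherwise, overridable. Bootstrap means are seeded resamples with
replacement.

## Synthetic data: what it emulates and what it does not

`generate_equilibrium_network` samples points in a square pixel domain
(default 200 cells in 400 px; 0.1 µm/px), applies two Lloyd relaxation
steps, and takes the Voronoi diagram as the cell network with Delaunay
edge lengths as tensions — exact force balance by construction. Lloyd
regularisation removes the sub-pixel junctions of a raw Poisson process
that no real segmentation would resolve. Boundary rays are clipped at
twice the median edge length and flagged; junctions flanked by boundary
cells are treated as boundary throughout.

Channel densities (line densities, a.u.):

* Myosin-II: `m₀ · T · (1 + p_myo sin²θ)` with multiplicative 10% noise;
  the modulation depth p is derived from a target extreme-bin PCP
  amplitude (default 2.0 DV/AP, a typical germband value).
* E-cadherin: `e₀ (1 + p_ecad cos²θ) + c·⟨L⟩/max(L, 5 px)` plus additive
  10% noise; polarity target 1.5 AP/DV, confound weight c = 0.5. The 5-px
  floor reflects that line densities are ROI means and cannot grow without
  bound on vanishing junctions. The confound dilutes the *measured*
  E-cadherin PCP below the polarized component's target — intentional, as
  in real images.
* Vinculin: `α·ecad + β·T` with α = 0.3, β = 0.5 and 5% noise. β = 0 is
  the constitutive-only regime (the Rok-inhibited analogue); the default
  β > 0 encodes load-dependent recruitment.

The renderer paints junction bands (7 px wide) at their line density,
applies a 1-px Gaussian PSF, builds an 8-plane stack with defocus blur
(+2 px σ per plane) and decay (0.45 per plane) around focus plane 2, adds
a flat background, Poisson shot noise (200 photons per unit) and Gaussian
read noise. With these defaults the ROI pipeline recovers painted
densities with a median ratio ≈ 0.99.

The ablation simulator zeroes one tension and moves vertices overdamped
(`v = F/γ`, γ = 1 tension·s/px, Euler dt = 0.02 s, frames every 0.25 s),
so the initial endpoint separation speed is `2T/γ` in closed form. The
optional E-cadherin turnover model `dE/dt = k_on − k_off0 (1 + s·τ) E`
(k_on = k_off0 = 0.05 s⁻¹, s = 20 per unit shear) is integrated exactly
per frame — the linear-ODE update is unconditionally stable even when a
collapsing junction sends τ to infinity. When densities were assigned, the
per-junction source term is chosen so each junction is stationary at its
pre-ablation shear, isolating ablation-driven changes. This turnover model
is synthetic: it encodes the *hypothesis* that shear accelerates
dissociation so the selection and relative-change logic can be validated
against a known direction of effect, not a claim about mechanism.

What the generator does **not** emulate: myosin pulsing, active junction
remodelling (T1 transitions), photobleaching, drift, curved junctions,
segmentation errors beyond vertex jitter. Passing tests therefore
demonstrate correctness of the analysis chain on data satisfying the
model's assumptions, not robustness to every artefact of live imaging.

## Numerical choices

* Eigensolver: dense symmetric generalised `eigh` on the
  translation-deflated subspace; chords are normalised by their mean
  (pure conditioning); the smallest eigenvector is polished by two shifted
  inverse-iteration steps. Eigen-gap warnings below 1e-6 relative;
  disconnected dual graphs are solved and normalised per component with a
  warning.
* Reproducibility floor: identical inputs give bit-identical tensions;
  under rigid motion of a ~100-cell network tensions agree to ~1e-10.
  For much larger networks the eigenproblem conditioning (~1e5) times
  coordinate rounding sets an irreducible ~1e-9 floor in double
  precision.
* Image-graph extraction: vertices are centroids of skeleton-pixel
  clusters adjacent to ≥ 3 labels; junction paths are ordered chains of
  two-label pixels; arc lengths are measured on a 1-px-simplified
  polyline, since raw 8-connected chains overestimate oblique lengths by
  up to ~40% (junction curvature is negligible, so simplification is
  faithful). Junctions shorter than the sub-pixel scale of the rendering
  cannot round-trip through a label image; the adjacency round-trip is
  exact for junctions ≥ 2 px.
* Degenerate inputs: constant probability maps raise a no-cells error;
  label images without triple points raise; empty ROIs yield NaN plus a
  flag; zero initial values make relative change an error, not infinity.

## Problem sizes

The test-suite and acceptance runs use 150–700-cell tissues, 256-px
renders, 1000-permutation nulls and 50 ablation events — sizes at which
every statistical check has comfortable power while a full run of suite
plus acceptance script completes in a few minutes on one CPU.

## Known limitations

* Tensions are relative within a connected component; absolute forces and
  cross-snapshot scales require external calibration.
* No pressure inference and no curved-edge (Young–Laplace) variant.
* The pointwise shear profile along a junction is not reconstructable
  from inferred tensions; only the junction average is reported.
* The image-graph extraction assumes a 1-px-wide skeleton between labels;
  heavily fragmented segmentations should be cleaned upstream.
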