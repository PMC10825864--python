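# Methods

This note records the generative model, the analysis chain, the parameter
defaults and the reasoning behind every choice that the model itself does
not force. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Receptor organisation

A cell footprint is a star-shaped polygon: 48 vertices at equally spaced
angles with radii `mean_radius · (1 + irregularity · U(−1, 1))`. With
irregularity < 1 every radius is positive, so the polygon is simple by
construction. Default mean radius 5 µm, irregularity 0.25 — a typical
adherent epithelial cell footprint. Coordinates are continuous nanometres
with the bounding-box lower-left at the origin.

Two organisations are generated:

- **Clustered** ("high-expression-like"): a Thomas process. Cluster centres
  are a homogeneous Poisson process of intensity κ inside the footprint;
  each centre draws Poisson(µ) receptors scattered with an isotropic
  Gaussian of sd σ_c; offspring landing outside the footprint are
  discarded. Defaults κ = 0.4 /µm², µ = 25, σ_c = 30 nm. These defaults
  are *illustrative*: measured cluster sizes/densities for HER2 on SKBR3
  are not available to calibrate against, so no quantitative claim rests
  on them.
- **Dispersed** ("low-expression-like"): complete spatial randomness at
  intensity λ (default 15 /µm²).

Both are thinned by sequential hard-core rejection with h = 2 nm: a point
is kept iff no earlier kept point lies strictly closer than h. Two
antibody-bound receptors cannot physically coincide, and h just below the
AIE window's lower edge keeps that bound non-vacuous.

**Disruption.** Each clustered receptor independently relocates to a
uniform position in the footprint (its cluster label reset) with
probability

    p(D, t) = p_max · (1 − exp(−t/τ)) · D^n / (D^n + EC50^n)

— a Hill curve in dose D (µg/mL) and a saturating exponential in time t (h).
Defaults p_max = 0.8, EC50 = 1 µg/mL, n = 1, τ = 8 h. The separable form is
the simplest shape consistent with a dose- and time-dependent disruption
process; no kinetic model is implied. Receptor count is conserved exactly —
disruption destroys *proximity*, not receptors. Relocated points are not
re-checked against the hard-core distance (the chance of landing within
2 nm of another receptor at these densities is ~10⁻⁵ per point).

## 2. Emission

Each receptor carries a dye with probability `labeling_efficiency`
(default 0.9, a high-affinity primary-antibody stain). Optionally the
per-receptor dye count can be drawn Poisson(1.35), the measured average
dye-to-antibody ratio, with all dyes co-located; the default is one dye per
labelled receptor, since co-located dyes are closer than d_min and do not
gate each other.

- **AIE rule**: a labelled fluorophore is emissive iff at least one other
  labelled fluorophore lies at Euclidean distance d with
  d_min ≤ d ≤ d_max, a closed interval evaluated with 10⁻⁹ relative
  tolerance against coordinate roundoff. Defaults d_min = 2.13 nm,
  d_max = 6.62 nm — the sensor's reported detection window (21.3–66.2 Å,
  the geometric reach of two antibody-tethered dyes on adjacent
  receptors). Emission is binary on/off at `unit_brightness` expected
  photons (default 500); graded partial restriction and higher-order
  (>2-body) enhancement are deliberately excluded for testability. The
  pair relation is symmetric by construction.
- **Conventional rule**: every labelled fluorophore is emissive,
  independent of geometry — the proximity-insensitive control channel.

With the defaults, a clustered fluorophore has on average ~0.23 labelled
partners inside the window ((µ·le − 1) · A_window / (4πσ_c²)), giving an
emissive fraction around 20–25%; a dispersed field at matched intensity is
three orders of magnitude lower. This is the contrast the sensor exploits.

## 3. Image formation

Emitter (x, y) nm maps to pixel (row, col) = (⌊y/s⌋, ⌊x/s⌋) with half-open
bins of pixel size s; brightness accumulates per pixel, is convolved with a
normalised isotropic Gaussian PSF (sd `psf_sigma`/s px, truncated at 4 sd),
and a constant background is added. With noise on, the expected photon
image is Poisson-sampled and zero-mean Gaussian read noise added, clipped
at 0. Defaults: s = 325 nm (20× objective with a 6.5 µm camera pixel),
psf_sigma = 170 nm (widefield at ~518 nm emission, NA ≈ 0.8), background
10 photons/px, read noise 3 photons. None of these are measured values —
they are documented, configurable assumptions of a realistic low-background
widefield setup.

## 4. Quantification

**Segmentation** (edge-detection ROI): Gaussian smoothing → Sobel gradient
magnitude (standard 3×3 kernels ±[[1,0,−1],[2,0,−2],[1,0,−1]]/4, Euclidean
magnitude) → threshold (Otsu on the gradient map, or a fixed value) →
morphological closing (disk) → hole filling → removal of components below
`min_object_area`. A constant image yields an empty mask with a warning;
quantification on an empty mask is an error (failures stay explicit per
well).

Two default parameter sets are provided, and the distinction matters:

- *Library default* (smooth 0.8 px, Otsu): resolves sharp isolated objects;
  segments a noise-free bright disk at IoU ≥ 0.9.
- *Plate default* (smooth 8 px, fixed threshold 10): used by
  `run_experiment`. The ROI must measure the **cell area**, not the
  receptor texture. With content-adaptive Otsu at small smoothing, the
  mask hugs bright cluster-rich regions; when disruption disperses the
  clusters the mask area grows ~40% and the count-conserving conventional
  channel spuriously drops to ~0.72 of control. Smoothing above the
  cluster spacing (8 px ≈ 2.6 µm vs ~1.6 µm mean spacing) with a
  threshold calibrated once to the imaging settings makes the mask
  organisation-invariant (area ratio 1.005 ± 0.024 between intact and
  fully disrupted states). This mirrors real plate analysis, where
  segmentation parameters are fixed per experiment, not re-estimated per
  image.

**Mean intensity** is the sum of masked pixel values over the masked area
(photons/px) — no background subtraction, matching the plain
sum-over-area definition.

**SNR** is defined here as (mean_fg − mean_bg)/sd_bg with the background
taken as the complement of the ROI dilated by 5 px (keeping the PSF halo
out) and a population sd (ddof 0). The original formula behind the
published SNR values is not available, so this definition is the package's
own; all SNR comparisons in the tests are internal-consistency and
ordering checks, never reproductions of published values.

**Colocalization**: Pearson correlation over masked pixel pairs (the ROI by
default, whole-frame by passing no mask), undefined (error) for a constant
channel; joint 2D histogram over equal-width bins spanning each channel's
masked min–max (64 bins default, half-open bins with the last closed).

**Dose–response**: within each (dye, time) stratum every well's mean
intensity is divided by the mean of that stratum's dose-0 wells (so control
rows are exactly 1), then conditions are summarised as mean ± sd over
replicates with a two-sided Welch t-test against the normalised controls;
stars are ** for p < 0.01 and * for p < 0.05, with no multiple-testing
correction (each condition is annotated independently, as in the figure
convention it mirrors; this is flagged here rather than in the output).
Normalising an already-normalised table is a no-op.

**Onset detection**: the model y = a + s·max(0, log₁₀c − log₁₀c_k) is
fitted by least squares for every candidate breakpoint c_k among the tested
concentrations (all but the last); the breakpoint minimising the residual
sum of squares wins, ties going to the smallest concentration, and a rise
is *detected* only when s > 2·SE(s) (SE from the residuals, or from a
user-supplied known noise sd). A series rising from the first point
therefore reports onset at the lowest tested concentration, and a flat
series reports no detection.

## 5. The simulated plate experiment

`run_experiment` simulates each well of a dose × time × replicate grid as
`cells_per_well` independently imaged cells: footprint → receptors →
disruption → one shared labelling realisation → AIE and conventional
emission → two rendered images with independent noise → segmentation **on
the conventional channel** (it marks the cell area regardless of
clustering state) → quantification of both channels under that mask. Well
mean intensity pools photons over cells (Σ sums / Σ areas); well SNR is the
mean per-cell SNR. Every random stream derives from
`SeedSequence(master_seed, spawn_key=(dose_idx, time_idx, replicate, cell,
stage))`, so any single cell can be re-simulated in isolation and the whole
run is byte-reproducible.

Defaults: dose grid {0, 0.01, 0.1, 1, 10, 100} µg/mL (serial dilution),
times {2, 8, 24} h, triplicate wells, 25 cells per well.

**Measurement effort and power.** The per-well receptor count has
CV ≈ 1/√(#cluster centres) (≈ 9% for a single cell), which is the dominant
noise on normalised intensities. The end-to-end checks in the acceptance
tests that resolve the ~1.5% intensity change at the smallest nonzero dose
(0.01 µg/mL with EC50 = 1) therefore use 150 cells/well and 10 replicate
wells — chosen by this power calculation, not tuned to outcomes. With
triplicate wells and 25 cells (the package default, matching a typical
manual imaging session), only effects of a few percent and larger are
resolvable.

## 6. What a green test does and does not establish

The generator emulates: clustered vs dispersed receptor geometry,
count-conserving dose/time disruption, proximity-gated vs unconditional
emission, and shot-/read-noise-limited widefield imaging of single cells.
It does **not** emulate: 3D membrane geometry, receptor diffusion or
internalisation, dimerisation kinetics, spectral bleed-through,
photobleaching, autofluorescent cell bodies, cell–cell contact, or
non-specific binding. Green tests therefore establish that the analysis
chain is correct and that the *qualitative* signatures (two-channel
contrast, clustering-dependent SNR ordering, dose/time ordering) follow
from the stated model — they do not reproduce any published image-derived
number, which would require the original images.

## 7. Known limitations

- **Apparent vs generative EC50.** The intensity readout is not linear in
  the relocated fraction p: with ~0.23 in-window partners per fluorophore,
  losing a single partner silences a fluorophore, so emission falls
  roughly quadratically in p. A Hill fit to the normalised AIE intensity
  therefore finds its half-effect near 0.59 µg/mL when the generative
  relocation EC50 is 1 µg/mL — a ~40% compression that is a property of
  the readout, not an estimator defect. Recovering the generative EC50
  from intensity data would require inverting the emission model (or a
  world with many partners per fluorophore, where the readout becomes
  linear in p). The corresponding acceptance test asserts the naive
  25% recovery bound and fails honestly; the measured median error is
  printed in its assertion message.
- The Thomas-process defaults are illustrative (see §1).
- The disruption functional form is a stand-in; only its monotone
  dose/time structure is load-bearing.
- Segmentation accuracy is scale-dependent (§4); masks are
  organisation-stable but systematically dilated by the smoothing band,
  which cancels in normalised quantities.
- The SNR definition is package-specific (§4).
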