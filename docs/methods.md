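# Methods

## Problem and approach

Cells encapsulated in a hydrogel scaffold are counted directly by staining
their nuclei in situ and imaging each field of view as a wide-field
fluorescence z-stack through the scaffold depth. Because only a thin slice
is in focus at each plane, the stack is first fused into a single fully
focused image; nuclei are then detected as bright connected cores and
converted to a density per mm³ of scaffold. Two-channel staining (a
pan-nuclear dye plus a dead-only dye) extends the same pipeline to
viability; repeating the measurement over culture days yields proliferation
statistics.

## Focus fusion

For each plane a per-pixel sharpness score is computed: the variance of the
discrete 5-point Laplacian over a local window (default 9 × 9 px; plain
local intensity variance is available as an alternative). The fused image
takes, at each pixel, the value from the plane with the highest score —
hard selection, ties broken toward the lower z index, reflective
(edge-inclusive) boundary padding.

Selection rather than weighted blending is a deliberate choice: the
downstream detection threshold acts on absolute peak intensities, and any
blending would dilute in-focus peaks with defocused copies. The window size
trades locality against noise robustness; 9 px (≈ 15 µm at the default 4x
pixel size) comfortably covers a nuclear core. A single-plane stack is
returned unchanged, making fusion idempotent.

## Nucleus detection

Pixels strictly greater than the intensity threshold (default 7000 a.u. on
a 16-bit scale) form the candidate set; its connected components (default
8-connectivity, configurable to 4) are the candidate nuclei. Because nuclei
are brightest at their centers, thresholding at a value above the halo
intensity isolates the cores and splits closely spaced nuclei whose haloes
touch. Components are then filtered by physical core area:

- area ≥ `max_area_um2` (default 30 µm²) → rejected `too_large` (dye
  debris, unsplit clusters). Both filters are strict, mirroring the
  "more than" / "less than" convention of the source protocol.
- area < `min_area_um2` (default 2 µm²) → rejected `too_small`. This floor
  is an addition to the original protocol (which states none) to reject
  single hot pixels; set it to 0 for the literal behaviour.

The stated size limit is ambiguous between an area in µm² and an
equivalent-circle diameter in µm; the default reads it as area, and
`area_unit` switches to the diameter interpretation.

8-bit inputs are rescaled ×257 to the 16-bit range before thresholding
(logged), since the threshold convention presumes a 16-bit intensity scale.
Centroids are intensity-weighted within the accepted core, reported in µm
with origin at the top-left pixel center. Every run can emit a "mask"
overlay (accepted outlines, rejected outlines with reason codes, label
rasters as sidecar files) so the operator can visually confirm that every
visible nucleus was counted — the protocol's prescribed way of validating
filter settings on new sample types.

## Density and summary statistics

K = N / (B · C · D · 10⁻⁹) cells/mm³, with N the mean per-field count and
B, C, D the field extents in µm. B and C derive from the pixel grid
(width × pixel size), D from the z-range actually analyzed (≤ 530 µm
recommended; deeper stacks trigger a warning, not an error). Fields with
differing geometry are rejected rather than volume-weighted. Dispersion
across per-field densities is the sample standard deviation σ (n − 1
denominator) with SEM = σ/√n; the n − 1 convention is pinned by the bundled
validation table, whose printed σ of 40.89 is only consistent with n − 1
(the population SD would be 38.79). The printed SEMs in that table (12.94,
15.98) are 0.01–0.02 above σ/√10 computed from its own per-field values
(12.93, 15.96); the package reports the computed values and tests document
the discrepancy. Report tables print at 2 decimal places.

Averaging fewer than 10 fields (or fewer than 5) logs a warning, following
the protocol's "10 images or more" guidance.

## Viability

The pan-nuclear channel gives the total density, the dead-only channel the
dead density, and percent dead = 100 · K_dead / K_total. The two channels
are counted independently by default, as in the source protocol. Optional
centroid matching (greedy nearest-neighbour within a radius, default 10 µm
≈ one nucleus diameter) enforces that each dead nucleus corresponds to a
total-channel nucleus, reporting unmatched dead objects separately and
guaranteeing percent dead ≤ 100.

## Proliferation statistics

Day-vs-day comparisons use the two-sample Wilcoxon rank-sum test, because
fields at different days come from different scaffold fragments (unpaired);
a signed-rank variant is provided for paired designs. For combined n ≤ 12
the null distribution of the rank sum is enumerated exactly over all
C(n₁+n₂, n₁) rank assignments using midranks, so ties need no correction;
two-sided p is twice the smaller tail, capped at 1. Larger samples use the
tie-corrected normal approximation with continuity correction. The two
paths agree within 0.02 at the crossover size (property-tested). Raw
pairwise p-values at α = 0.05 are reported by default, matching the source
analysis; Holm step-down adjustment is available. Fold change is the mean
density at a day divided by the seeding concentration or by an earlier
measured day.

## Synthetic data generator

The generator emulates what the pipeline actually exploits in real stacks,
with exact ground truth:

- **Geometry**: 1000 × 1000 µm field, 530 µm depth, six planes at 106 µm
  steps, 1.625 µm/px (a 4x objective on a ~6.5 µm-pixel camera). Nuclei are
  placed uniformly at random by dart throwing with a 30 µm minimum pairwise
  separation and a 5 µm lateral margin; an infeasible packing fails loudly,
  naming the achievable count.
- **Blob model**: each nucleus is an isotropic 2D Gaussian core (σ = 1.4 µm,
  in-focus peak 20 000 a.u.) whose defocus in a plane |dz| µm away adds
  blur σ_b = 0.03·|dz| in quadrature, with amplitude scaled by
  σ²/(σ² + σ_b²) to conserve integrated signal. With these defaults an
  in-focus supra-threshold core is ≈ 14–20 µm² (safely inside the 2–30 µm²
  acceptance band), a nucleus midway between planes still peaks ≈ 8700
  a.u. in its nearest plane, and a nucleus 530 µm out of focus contributes
  ≈ 150 a.u. — invisible, as in real deep-scaffold stacks.
- **Noise**: constant background 500 a.u. plus Gaussian read noise
  (sd 100); optional Poisson shot noise. The noise ceiling is far below the
  7000 threshold, as for a properly exposed nuclear stain.
- **Dead channel**: renders only dead-flagged nuclei (exactly
  round(fraction × n) of them) over the same background/noise model.
- **Determinism**: all randomness derives from the single scene seed;
  identical (parameters, seed) give byte-identical stacks.

What the generator does **not** model: a physically derived PSF, light
scattering and depth-dependent attenuation in the gel, photobleaching,
intensity heterogeneity between nuclei, mitotic figures, or nuclei overlapping
in projection along z. Passing the synthetic recovery tests therefore shows
the pipeline's logic is correct under the stated imaging model, not that
the default thresholds are optimal for any particular instrument or dye —
on real data the mask overlay remains the prescribed validation step.

## Problem sizes in the test suite

End-to-end recovery is measured on 50 generated scenes of 50 nuclei each
(six 615 × 615 px planes, both channels), chosen to give a stable exact-
recovery percentage while keeping the whole suite around half a minute.
The segmentation oracle runs 200 random 64 × 64 rasters; the rank-test
cross-check enumerates C(12, 6) = 924 assignments per sample.

## Known limitations

- Counts are not corrected for nuclei truncated at field borders or at the
  z-limits (the source protocol applies none); densities are slightly
  biased for small fields.
- The fusion operator is a design choice: the behaviour of the original
  instrument software ("detects only those areas that are in focus") is
  reproduced as hard selection, but its actual operator is undisclosed.
- The intensity threshold is assumed to map linearly onto exported TIFF
  counts; instruments that export tone-mapped images need recalibration.
- Proliferation tests support both per-field and per-sample entry points,
  but whether published analyses pooled fields or sample means is not
  stated; defaults (per-field, unpaired) are documented, not inferred.
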