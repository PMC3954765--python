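# Methods

## Scope and model

`synaptoquant` quantifies synapse development in 4-channel fluorescence
images of dissociated neuronal cultures. The operational definitions are:

- **Excitatory synapse** — a segmented Psd95 punctum sharing ≥1 pixel with
  a segmented Synapsin-1 punctum after registration.
- **Inhibitory synapse** — the same with Gephyrin in place of Psd95.
- **Synaptic density** — synapse (or punctum) count divided by the summed
  MAP2 dendrite length of the same image, in counts/μm.

Colocalization is strictly object-based (pixel overlap of label maps),
never intensity correlation: the readout is the *number* of apposed
pre/postsynaptic clusters, which is robust to staining intensity drift in
either channel. The pair-count statistic counts distinct postsynaptic
objects with any overlap, so one postsynaptic cluster straddling two
presynaptic clusters contributes one synapse (a config switch allows
keying on Syn1 instead).

## Pipeline stages and tunable parameters

**Illumination correction.** Per plate and channel: mean of all images,
median-smoothed with a square window (`illum_filter_size_px`, default
100 px — large enough that cellular structure averages out, leaving only
the optics' shading pattern), clamped positive, divided out. Window
semantics: floor-centered for even sizes; reflective padding; the median
of an even pixel count is the upper-middle order statistic. The production
filter quantizes the mean image to 8 bits to use a sliding-histogram rank
filter; the quantization error (≤0.4% of the dynamic range) is far below
the flat-field estimation error itself. Correction is per plate, never
across plates. Because the correction divides by an unnormalized mean
image, corrected intensities are on a relative (fold-over-typical) scale;
every downstream statistic is either scale-free or normalized to
negative controls.

**Registration.** Psd95 and Gephyrin are aligned to Synapsin-1 (MAP2 is
left untouched) by exhaustive integer-shift search within
±`registration_radius_px` (default 10), maximizing mutual information with
`registration_bins` (default 64) equal-width intensity bins per marginal
over each image's min–max range. MI is evaluated on the overlapping
region; for the search, pixels are binned once over the full image so the
objective depends only on alignment, not on the crop. Ties break toward
the smallest shift magnitude, then row-major order. An optimum on the
search boundary is flagged. No sub-pixel refinement: pairing is object
overlap and tolerates ≤1 px residual. The correction is estimated and
applied per site. After shifting, exposed borders are filled with the
image median rather than zero inside the pipeline — a zero strip next to
non-zero background is an artificial edge the top-hat would enhance and
which measurably biases automatic thresholds.

**Puncta segmentation.** White top-hat with a disk structuring element of
`se_diameter_px` (default 7, the middle of the 6–8 px range matching the
spot scale; per-channel override, warning outside that range), followed by
thresholding, 8-connected labeling, and removal of objects with median
enhanced intensity below `low_intensity_cutoff` (default 0) or area below
`min_area_px` (default 4). Three threshold modes:

- `"batch"` (pipeline default): plate-level robust background threshold,
  median + k·1.4826·MAD (k = `batch_threshold_k_mad`, default 4) of
  top-hat pixels pooled from up to 16 sites sampled across the plate in
  canonical site order. This mirrors how such screens calibrate their
  object filters once per experimental batch, and — unlike a per-image
  Otsu — does not collapse into the noise floor when foreground is sparse
  (strong-knockdown wells). k = 4 sits well above the top-hat noise tail
  (no spurious objects on puncta-free fields) while keeping full recovery
  of spots at 10:1 peak-to-noise. If the pooled MAD is zero (noise-free
  input), the mode falls back to per-site Otsu.
- `"auto"`: per-site Otsu (between-class variance maximizer on the 256-bin
  histogram).
- a number: fixed threshold in enhanced-image units.

Per object: area (px and μm²), best-fit-ellipse eccentricity from the
second central moments, median and integrated intensity measured on the
corrected (not enhanced) image, and expression = integrated intensity /
area. Median per-pixel intensity is also reported since "expression level"
admits both readings. No watershed splitting of touching puncta; the
generator's minimum spot separation and the small spot scale make merges
rare, and the screen statistics are robust to the residual few.

**Dendrites.** Single-scale tubeness: max(0, −λ_min) of the
Gaussian-derivative Hessian at `tubeness_sigma_px` (default 2, matching
the simulated ridge cross-section; one auditable scale rather than a
multi-scale maximum). Threshold (Otsu by default), thinning to a 1-px
8-connected skeleton, then despurring: terminal branches strictly shorter
than `spur_length_px` (default 5 — above typical thinning artifacts of
1–3 px, below genuine branchlets) are pruned iteratively, from endpoint to
the first junction, the junction itself kept. Isolated short segments
(no junction) are never pruned. Length = Σ steps (1 axial, √2 diagonal)
× `pixel_size_um`. Degrees and steps are computed on the *reduced*
skeleton graph: a diagonal adjacency whose two pixels share an axial
neighbor is redundant (it retraces a measured right-angle path) and is
ignored, which removes the double-counted edges thinning produces at
junctions. Sites with total length below `min_dendrite_length_um`
(default 50 μm) are flagged for low dendritic outgrowth and excluded from
density parameters (only) during aggregation; with zero length, densities
are undefined (NaN), never zero.

**The 21-parameter site vector.** 3 channels × {count, density, median
area, median eccentricity, median expression} (15) + 2 pair classes ×
{count, density} (4) + dendrite length (1) + total pair overlap area (1).
The first 20 slots follow directly from the tracked feature families; the
final slot (total overlap area) is this package's choice of the remaining
quantitative overlap readout.

**Screen statistics.** Median over sites within a well (density
parameters excluding flagged sites), then median, unscaled MAD and
%CV = 100·SD/mean over replicate wells per hairpin. Normalization is
per-plate: each hairpin's median divided by the median of the same
plate's negative-control well-medians; significance per hairpin by
two-tailed Welch t-test of its replicate wells against the control wells
(Welch because replicate counts vary). Hit rule: a gene is nominated when
≥`hit_min_hairpins` (2) of its hairpins have normalized
`hit_parameter` ≤ 1 − `hit_threshold_fraction` (0.40, boundary
inclusive; 0.60 available as the stricter follow-up rule). The headline
parameter defaults to excitatory pair density and is config-selectable.
Raw p-values are reported without screen-wide correction — the hit path
is threshold-based, not p-value based. Cross-readout consistency is
summarized by OLS of one normalized readout on another (slope, intercept,
r²), and populations (e.g. library vs controls) are compared by
two-tailed Welch t-test on per-hairpin normalized medians with empirical
CDFs exported.

## The synthetic-data generator

Defaults describe one 256×256 px site at 0.5 μm/px: 3 dendrite trees
totalling 400 μm of centerline, 60 puncta per synapse channel with peak
intensity 100 on background 10, 90% of puncta seeded on dendrites, 70%
of postsynaptic puncta colocalized with Syn1, a ±7.5% multiplicative
illumination gradient, channel misalignments of up to 2 px, and additive
Gaussian noise with SD 5 (5% of spot peak). These values were chosen once
for internal consistency — plausible puncta density per μm dendrite,
spot scale matching the 6–8 px top-hat range — not for fidelity to any
specific instrument, whose pixel size and PSF are not pinned down here.

Dendrites are low-curvature random walks (heading noise 0.12 rad per
4 px step) that steer smoothly away from the frame edge, rasterized and
blurred to a Gaussian ridge of σ 2 px; the recorded ground-truth length
is the analytic polyline length. Low curvature matters: a walk that
wiggles at the scale of the ridge cross-section would be shortened by the
very smoothing that gives the ridge its profile, making "true length"
ill-defined. Puncta are isotropic 2-D Gaussians (σ = radius/2) truncated
at 3σ, with a minimum center separation of 8 px enforced by rejection
sampling (relaxed gradually so dense configurations terminate).
Colocalized puncta share exact centers across channels before the
per-channel shift. Per-well effect multipliers scale the planted puncta
count in every synapse channel. One seed per plate fans out into
deterministic per-(well, site) substreams, so plates are reproducible
regardless of generation order.

What the generator does *not* emulate: cell bodies and nuclei, puncta
intensity heterogeneity, spatially correlated (structured) noise,
z-stack effects, well-edge artifacts, or biological covariation between
dendrite length and synapse counts. Passing tests therefore demonstrate
the algorithm's correctness on images whose difficulty is controlled by
noise, shading, misalignment and crowding — not robustness to every
pathology of real micrographs.

## Numerical choices and degenerate inputs

- Constant images: MI is 0 by convention (warned); Otsu on a degenerate
  histogram yields zero objects (warned); an empty dendrite foreground
  yields length 0 (warned).
- Division safety: illumination functions are clamped at 10⁻⁶ × their
  maximum.
- Otsu ties: on histograms with an empty gap between modes the
  between-class variance has a plateau and the chosen bin within it is
  implementation-defined; thresholds differ only within the plateau, where
  no pixel changes class.
- %CV is undefined (NaN, flagged) for a zero mean or a single replicate.
- Eccentricity of a single-pixel or otherwise degenerate object is 0.
- All coordinates are 0-based (row, col) from the top-left.

## Known limitations

- Dendrite length recovery is within ±5% on typical noise-free fields,
  but geometries where trees cross or run parallel within the ridge width
  merge under segmentation and can lose up to ~10% of length; the planted
  hit recovery is insensitive to this since densities normalize per plate.
- Measured pair counts include chance overlaps of non-colocalized puncta
  (a few percent at default densities), so raw pair counts sit slightly
  above the planted colocalized count; the screen normalization removes
  this bias from effect estimates.
- The per-batch threshold assumes the batch's background statistics are
  homogeneous across wells; gross well-to-well background drift would call
  for per-well calibration, which is not implemented.

## Problem sizes in the test suite

The suite validates operators against brute-force oracles on ≤64×64
instances, field-level recovery on 256×256 fields (tens of fields),
end-to-end screen recovery on twenty seeded 24-well plates (9 sites/well,
256×256), and null calibration on a 48-well all-null plate at 96×96 with
200 random-half t-tests. These sizes were chosen to exercise every stage
at full fidelity while keeping the default test run fast on a single CPU.
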