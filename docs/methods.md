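# Methods

`nociquant` implements the quantification and statistics used in larval
*Drosophila* nociception work: nuclear pMad immunofluorescence as a readout
of BMP-pathway activity in nociceptors, axon-terminal morphometry of sparse
single-cell clones, GCaMP ΔF/F0 responses to a slow thermal ramp, and the
nonparametric behavioral statistics that go with nocifensive-escape assays.
This note records the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic-data tests do and do not show.

## Nuclear pMad quantification

**Model.** BMP signaling drives phosphorylated Mad into the nucleus, so the
mean anti-pMad immunofluorescence over a nuclear ROI, measured on the
maximum-intensity projection of a confocal Z-stack, is the activity readout.
The nucleus is identified as the GFP-negative hole inside the GFP-filled
cell body (nociceptors carry a membrane GFP marker that excludes the
nucleus). Local background is the mean of four ROIs of identical size and
shape translated into the image corners; the corrected signal is
`raw nuclear mean − corner background`. Because absolute immunofluorescence
depends on the staining solution, effects are reported as percent change of
the group mean relative to control specimens processed in the same batch:

```
percent_change = 100 · (mean_exp − mean_ctrl) / mean_ctrl
```

**Conventions and defaults.**

- Corner ROIs sit `corner_margin_px = 2` pixels from each corner (the exact
  placement of "corners" is underdetermined; abutting the corner at a small
  margin is reproducible and keeps the ROI off edge artifacts).
- `corrected` may be negative and is recorded as-is; normalization requires
  a strictly positive control mean and raises otherwise.
- Manual nuclear masks are first-class inputs; the automatic hole
  segmentation (Otsu on GFP, largest below-threshold connected component
  not touching the border, or the component under a seed point) is a
  convenience. Recovery tests use truth masks so that segmentation error
  and quantification error stay decoupled.
- Three neurons are typically imaged per animal; `aggregate_by_animal`
  averages them before group statistics to avoid pseudo-replication, and is
  skipped when the caller wants neurons as units (both n's are reported).
- Normalization is strictly per staining batch; mixing batches raises.

**Invariances.** `corrected` is exactly invariant under a global additive
offset (the same offset enters nucleus and corners); `percent_change` is
exactly invariant under a global multiplicative gain applied to both groups.
Both are property-tested.

## Axon-terminal morphometry

**Model.** Single-cell flip-out clones label one nociceptor's terminal
arbor (GFP) inside the CD2-labelled neuropil. After maximum projection and
optional cropping, each channel is binarized independently with Otsu's
method; the terminal area is the GFP-positive pixel count normalized to the
average neuromere size:

```
normalized_area = gfp_pixels / (cd2_pixels / n_neuromeres)
```

`n_neuromeres` is a required per-image annotation — there is no automatic
neuromere segmentation. Clones too dim to binarize are marked excluded
(with the reason) rather than dropped silently; by default heat-map
percentages are computed over non-excluded clones.

**Otsu convention.** The threshold maximizes between-class variance over a
256-bin histogram of the channel's intensity range; integer images whose
range spans fewer than 256 levels are histogrammed at exact integer levels
(so 8-bit data uses the classic formulation, and sparse 16-bit histograms
are rescaled by the binning). Ties resolve to the smallest threshold and
foreground is strictly greater than the threshold. The implementation is
tested against an exhaustive search over all candidate thresholds and
cross-checked against `skimage.filters.threshold_otsu`.

**Linear enhancement.** Dim clones (e.g. after short induction windows) are
matched to control images by a pure gain (offset 0) chosen so the source's
upper-decile mean equals the reference's. The matching statistic is this
package's documented choice — "linearly enhanced to match" admits several
readings; the upper-decile mean is robust to the large dark background and
the map is monotone, so no pixel ordering changes.

**Projection heat maps.** Branch presence per (neuromere, longitudinal
tract) is a manual annotation. Clones entering at different segments are
aligned by re-indexing each profile by `offset = neuromere − entry
neuromere`; the heat map is the percent of clones present at each aligned
position. Offsets an annotation does not cover count as absent.

## Calcium imaging

**Model.** Recordings are ~4 Hz time series of small Z-stacks of the
nociceptor terminal region, with probe temperature logged at 4 Hz by a
thermocouple on its own clock. Per frame: max-project, then average the
pixels of a 6-pixel-diameter disc ROI centered on the A6 neuromere centroid
(an input annotation). `F0` is the mean of the first 30 frames and
`ΔF/F0 = 100·(F − F0)/F0`. The probe temperature at each frame time is
linearly interpolated from the log, holding the end temperatures outside
its span (the ramp is slow — 0.1 °C/s — so edge extrapolation error is
negligible). Curves are compared after averaging ΔF/F0 in 1 °C bins
`[k, k+1)` anchored at integer °C; empty bins are missing, never zero.

**Conventions.**

- ROI membership: pixel centers strictly within `diameter/2` of the ROI
  center, so pixel counts are reproducible.
- Per-animal binned curves are the unit of statistics; per-bin group
  comparisons use the two-sided Mann-Whitney U on per-animal means, and
  bins with fewer than two animals in either group are flagged untestable.
  In simulation studies that scan all bins, the per-bin tests are
  Bonferroni-corrected across tested bins so that a handful of pure-noise
  bins does not produce expected false positives.
- Max-projecting noisy Z-stacks adds a positive, roughly constant offset to
  F (the expected maximum of the per-slice noise). It inflates `F0` and
  scales ΔF/F0 down by `F/(F + offset)`; it cancels nowhere but is shared
  by baseline and response, so peak locations and group contrasts are
  unaffected. Noiseless recovery tests are exact because the offset is then
  zero.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of `(truth, seed)`, and the truth object
suffices to compute the expected output of each downstream stage in closed
form when noise is zero.

- **Soma images** (default 128×128, 16-bit): elliptical cytoplasm with an
  interior elliptical nucleus, both centered; GFP ≈ 150 on cytoplasm only;
  pMad = 100 (nucleus) / 40 (cytoplasm) over a background of 20 plus a
  symmetric linear gradient (±0.05 intensity/px), with i.i.d. Gaussian
  noise (SD 5), floor-clipped at 0 and rounded to integers. Centering the
  nucleus makes the four-corner estimator exactly unbiased under a linear
  gradient, so recovery tests isolate noise as the only error source. The
  corners are left as pure background by construction.
- **Clone images**: a rectangular neuropil "ladder" of equal neuromeres
  with an elliptical arbor inside; foreground/background ≈ 180/10 with
  noise SD 6 gives the bimodal histogram Otsu needs; a contrast below 4
  noise SDs sets a `low_contrast` flag (the exclusion rule's feeding case).
- **GCaMP recordings**: fluorescence is `f0·(1 + r(T))` on a bright disc,
  background elsewhere; `r` is a programmable temperature-response curve.
  The default control profile is a Gaussian bump (amplitude 0.5, width
  2 °C) whose peak sits at 43.5 °C — the midpoint of the 43 °C bin, since a
  response reported as "peaking at 43 °C" under `[k, k+1)` binning has its
  true peak somewhere in `[43, 44)`, and a peak exactly on a bin edge would
  make the two adjacent bins tie in expectation. A raised-cosine bump with
  strictly compact support is provided for two-cohort studies that need
  programmed responses to be *identical* outside a known range. Camera
  frame times carry small jitter, and the thermocouple log lives on a clock
  shifted by 0.25 s, because the real acquisition clocks were not
  synchronized; the resulting systematic interpolation error is
  `offset × ramp rate ≈ 0.025 °C`, which the tests measure explicitly.
- **Behavior tables**: latencies are lognormal (positive, right-skewed, the
  natural first choice for reaction latencies), censored at the 11 s
  stimulation cap with the censored flag set; binary responses are
  Bernoulli.

Not emulated: realistic dendrite/axon morphology, optical PSFs and
depth-dependent blur, photobleaching, motion, GCaMP kinetics
(rise/decay times), and animal-to-animal biological variance beyond what
the noise model induces. Passing recovery tests therefore show that the
*computational* pipeline is unbiased and correctly specified under its own
noise model — not that segmentation or annotation would be equally reliable
on real micrographs.

## Behavioral statistics

- **Summaries**: mean ± SE per genotype; censored latencies (exactly 11 s)
  enter at face value and are counted; proportions use the binomial SE
  `√(p̂(1−p̂)/n)`.
- **Mann-Whitney U**: two-sided; exact enumeration when the pooled sample
  has at most 20 observations and no ties, otherwise the normal
  approximation with mid-ranks, tie correction and continuity correction.
  Censored 11 s values form an ordinary tie block at the cap — rank tests
  tolerate ties, and this matches the assay protocol; fitting a survival
  model is out of scope and listed as a limitation.
- **Steel's many-to-one test** (rank analogue of Dunnett's): the package's
  reference definition is a joint permutation test. Per contrast *i*, the
  tie-corrected standardized rank sum `z_i` of the treatment group within
  the control+group subsample is computed; all observations are then
  jointly relabelled (default 100 000 resamples, seeded) and the adjusted
  p-value of group *i* is the permutation probability that
  `max_j |Z*_j| ≥ |z_i|`, with the add-one estimator. This controls the
  familywise error across the k contrasts by construction and reduces to
  the exact Mann-Whitney null at k = 1 (tested). The classic asymptotic
  variant — multivariate normal with correlation
  `ρ_ij = √(λ_i λ_j)`, `λ_i = n_i/(n_0+n_i)` — is provided for
  cross-checking; the two agree on moderate samples and the permutation
  version is exact at small n (tested against exhaustive enumeration).
- **Fisher's exact test**: two-sided, the sum of hypergeometric
  probabilities of tables no more probable than observed at fixed margins;
  Bonferroni (`min(1, p·m)`, m defaulting to the number of comparisons
  made) corrects families of proportion comparisons.
- Type-I calibration: with a control and two groups drawn from the same
  lognormal (n = 20 each), the familywise rejection rate of the permutation
  Steel test at α = 0.05 over 2000 simulations falls in the binomial 99%
  interval around 0.05. The calibration runs with 500 resamples per
  simulation; the permutation p-value's discreteness at that depth
  (`⌊α(R+1)⌋/(R+1) ≈ 0.0499`) keeps the check sharp.

## Problem sizes in the test and acceptance runs

Recovery studies run at sizes chosen to make Monte-Carlo error small
relative to the effects probed while keeping the suite quick on one CPU:
pMad cohorts use 3 batches × (20 control + 20 experimental) full-size
images (plus a 200-batch study at reduced image size for the unbiasedness
property); calcium cohorts use 17–19 animals × ~1060 frames of 10×24×32
stacks, with 20 replicate cohorts for the peak-bin consistency check.

## Known limitations

- Automatic nucleus segmentation assumes a single clean GFP-negative hole;
  crowded fields need manual masks (by design — the original measurements
  were manual ROIs).
- The upper-decile matching statistic for linear enhancement is a
  documented choice, not uniquely determined by the procedure it mirrors.
- Censored latencies at face value bias group means toward the cap; with
  heavy censoring the mean±SE summary understates true latencies. The
  censored count is always reported alongside.
- The asymptotic Steel variant is approximate at small n or heavy ties;
  the permutation variant is the definition.
- Mann-Whitney's asymptotic branch (used when n > 20 or ties exist) is
  accurate to ~0.01 in p around conventional thresholds; exact enumeration
  is used wherever its preconditions hold.
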