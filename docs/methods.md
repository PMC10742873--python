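# Methods

## The assay model

The toolkit analyses a nucleus-restricted dual-label senolysis assay.
Quiescent cells carry H2B-GFP and senescent cells H2B-RFP, co-cultured at a
1:1 ratio; after compound exposure the per-well counts of GFP⁺ and RFP⁺
nuclei are the readout. Confining the label to the nucleus matters because
senescent cells accumulate lipofuscin, whose broad cytoplasmic
autofluorescence (strongest roughly in the 450–580 nm emission window under
405 nm excitation) can mask cytoplasmic probes; the nuclear compartment is
largely free of it. Three supporting readouts are implemented alongside the
imaging assay: X-Gal (SABG) histochemical staining, spectral
(lambda-stack) autofluorescence profiling, and flow-cytometric quadrant
gating of isolated nuclei.

## Nuclear segmentation (`nucleiseg`)

Pipeline: Gaussian smoothing (σ = 1 px default) → global threshold → area
filter → optional watershed split → consecutive relabeling in raster-scan
order (deterministic tie-break).

* **Threshold.** Otsu by default: parameter-free and invariant under
  uniform intensity rescaling, which makes counts comparable across
  exposure settings. A fixed threshold is available.
* **Empty-plane guard.** Otsu always bisects *something*; on a signal-free
  plane it bisects read noise and fabricates hundreds of speckle objects.
  The guard requires the threshold to exceed the plane median by
  `min_otsu_contrast` (default 5) robust standard deviations
  (1.4826 × MAD); otherwise the plane is declared empty. A genuinely
  constant plane raises an error naming the field. The guard assumes
  sparse foreground (background majority), which holds for nuclei at assay
  densities.
* **Area filter.** Defaults: minimum = area of a disk at half the
  quiescent nucleus radius (≈ 28 px² at r = 6), maximum = 10× the
  senescent nucleus area (≈ 2 540 px² at r = 9); rejects debris and merged
  clumps symmetrically. Raising `min_area` can only remove objects, never
  add them (tested as a monotonicity property).
* **Touching nuclei.** Distance-transform watershed seeded at h-maxima
  (depth `watershed_h`, default 1 px). Off by default: the screening
  readout assumes sub-confluent wells, and on non-touching objects the
  pipeline is equivalent to plain connected components (tested against a
  `scipy.ndimage.label` oracle).
* **Double positives.** Objects detected in both channels within 5 px of
  centroid are flagged and reported, not reassigned — the assay design
  assumes disjoint labels, so violations should surface rather than be
  silently resolved.

## Scoring (`senolysis`)

The replicate unit is the well; fields within a well are summed before
statistics. Fold change is the ratio of condition mean to vehicle mean per
channel; its SD is the replicate SD normalised by the vehicle mean.
Significance uses the unpaired two-tailed **pooled-variance** Student's
t-test (the classical test; Welch available via flag). Conventions: two
zero-variance groups with equal means give p = 1; a zero vehicle mean makes
the fold change undefined and raises an error rather than returning ∞.

The verdict needs an operational meaning for "quiescent count unaffected":
`quiescent_drop_limit` (default 0.2) is that tolerance. Senolytic ⇔ RFP FC
< 1 at p < α while GFP passes the unaffected test; toxic ⇔ both channels
significantly below 1 − δ; quiescent-selective ⇔ only GFP; inert
otherwise, so classification is total. No multiple-testing correction by
default (per-comparison tests are standard for small validation panels);
Benjamini–Hochberg is a flag for plate-scale screens.

## SABG quantification (`sabg`)

RGB brightfield images are converted to an HSB stack by the standard
hexcone formula (exact on the RGB cube corners, hue of zero-saturation
pixels fixed at 0). Each slice is thresholded — hue window 170–280° for
the cyan–blue X-Gal product, saturation ≥ 0.25, brightness 0.15–0.95 — and
the three masks are combined by per-pixel conjunction ("overlapping
parts" read as intersection, the only reading under which overlap is
meaningful). Connected components (8-connectivity, the common
particle-analysis default) of area ≥ 20 px² become clusters; cluster
intensity is mean saturation. The numeric thresholds are package defaults
calibrated on the simulator, not published values, and are fully exposed.
The % positive metric supports two entry modes because total-cell counting
practice varies: explicit cell centroids (a cell is positive iff a cluster
pixel lies within `assign_radius`, default 15 px) or a bare total count
(approximate, flagged in the report).

## Spectral profiling (`spectral`)

A lambda stack holds one plane per emission window; the per-ROI spectrum is
the mean intensity of each plane over the ROI (linear in the stack, local
to the ROI). The wavelength axis for a (start, stop, count) spec is an
evenly spaced inclusive grid — e.g. 404–644 nm in 32 channels, step
240/31 ≈ 7.74 nm; the true per-channel bandwidth of spectral detectors is
instrument-specific, so the even grid is a recorded convention. ROIs are
supplied, not auto-segmented (they are drawn manually in practice); a
convenience derives the cytoplasmic ROI as a dilation ring around a
nuclear mask. The peak band is the contiguous interval around the argmax
where the baseline-subtracted signal stays above a fraction (default 0.5 →
discrete FWHM; for a Gaussian, 2σ√(2 ln 2)) of the peak — an explicit
package convention, since reported "peak bands" rarely define one.
`compare_compartments` reports per-wavelength group means, senescent −
control differences per compartment, and the contiguous interval (around
the largest cytoplasmic difference) where the cytoplasmic difference
exceeds `exceedance_ratio` (default 2) × |nuclear difference| and is
positive.

## Flow gating (`flowgate`)

Events are gated on DAPI (`dapi_min`) to select intact nuclei, then
assigned to four quadrants by one threshold per fluorophore. Frequencies
are fractions of intact events and always close to 1; absolute counts are
reported alongside because frequencies are compositional — killing RFP⁺
nuclei inflates the GFP⁺ *fraction* at constant GFP⁺ *count*, and the
report must let both be tested. Auto-thresholding histograms
log10(1 + x) (flow intensities are log-distributed), smooths, and places
the threshold at the valley between the two largest modes; modes closer
than half a decade are treated as noise on a single population, and
unimodal channels fall back to the fixed threshold with a warning.

## Synthetic data (`synthgen`)

Every simulator is a pure function of (config, seed) — identical inputs
give bit-identical outputs — and records its planted truth so downstream
recovery is scorable without hidden state.

* **Co-culture fields.** Nuclei are Gaussian-edged disks (erf edge profile,
  σ = 1 px), intensity mean 1000 a.u. with 10% CV, on background 100 a.u.
  with Gaussian read noise (default σ = 10). Senescent radius default 9 px
  vs quiescent 6 px — the 1.5 ratio is a free parameter standing in for
  the qualitative nuclear enlargement of senescence. Non-touching
  placement enforces center distance > r₁ + r₂ + 5 px margin (the margin
  keeps blurred edges separable after thresholding); placement failure
  after 2 000 rejections per object raises an error. Each senescent cell
  adds a broad Gaussian halo (σ = 2.5 r) to a separate `autofluor`
  channel, with optional bleed-through fractions into the fluorophore
  channels to reproduce the masking problem; bleed is off by default.
* **Senolysis experiments.** Per-well seeded counts are jittered by a
  multiplicative Normal(1, `well_cv`) factor (default CV 10%); treated
  wells then apply per-cell Bernoulli survival. `render=False` skips image
  rendering and yields counts only, which is what the statistical power
  analyses consume.
* **SABG fields.** Blue clusters (hue 240°, saturation 0.8) alpha-blended
  onto a near-white background; planted area is the hard-disk pixel count
  before edge softening (edge σ = 0.8 px). Negative cell centroids are
  kept clear of clusters so the planted positive fraction is unambiguous.
* **Lambda stacks.** Per-compartment emission is spatial mask × Gaussian in
  wavelength; nuclear disks and cytoplasmic annuli are disjoint by
  construction.
* **Flow events.** Log-normal clusters: negatives at 10^1.5 a.u., positives
  `separation` decades higher (default 2), log-SD 0.25; debris has low
  DAPI. At 2-decade separation the midpoint threshold misclassifies
  < 0.1% (4σ Gaussian tail on the log scale).

What the simulators deliberately omit: chromatin texture, PSF/optics,
uneven illumination, cell-cycle and SASP dynamics, spectral detector
bandwidth structure, flow compensation artifacts. Passing recovery tests
therefore demonstrates correctness of the measurement logic under the
stated geometric and statistical model, not robustness to every real-world
imaging pathology.

## Problem sizes and numerical choices

The recovery studies run at the assay's working scale chosen for a desk
machine: 100 co-culture fields (1024² px, 20–200 nuclei per channel, read
noise at one fifth of nuclear intensity), 100 + 100 simulated experiments
for power and type-I rates, 50 SABG fields of 12 clusters, 32-channel
stacks, 10⁴-event flow tables plus 200 × 10³-event closure runs. All
randomness flows from explicit integer seeds (numpy `default_rng`;
sub-seeds drawn below 2³¹). Known limitations: the SABG defaults assume
blue-range staining on a bright background and will need re-calibration
for other chromogens; the Otsu contrast guard assumes background-majority
planes; auto flow thresholds assume roughly balanced bimodality and should
be replaced by fixed gates for heavily skewed mixtures.
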