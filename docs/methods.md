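# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of the package. It states only what the test suite and
`scripts/acceptance.py` actually compute.

## The measurement model

A combinatorial-labeling FISH experiment encodes taxa in *sets* of
fluorophores: probes at nested taxonomic ranks (domain → class → genus)
hybridize simultaneously, so a genus-level cell carries its genus, class and
domain dyes at once. The shipped panel has six dyes and seven probes; the
two broad-range probes covering *Verrucomicrobia*/*Planctomycetes* share one
dye by design and are never distinguished. Where the published panel lists
alternative dyes for a probe, the default fixes one assignment (Atto532 for
the near-universal domain probe, Dy490 for the *Alphaproteobacteria* probe)
so that no dye is reused; the concrete dye→probe map is a required field of
any user panel config.

Decoding returns the taxon whose barcode is the **largest** fluorophore set
contained in the observed positive set (genus beats class beats domain).
An empty set is background; a positive set containing no barcode — notably
the domain dye alone — is an *unidentified bacterium*. Ties between equally
specific contained barcodes are unresolvable and also map to unidentified.

Probe specificity screening slides the probe's reverse complement along
sense-strand reference sequences (FISH probes are antisense to the rRNA) and
takes the ungapped minimum Hamming distance. The acceptance rule is a
perfect match to every target (a config fraction can relax "every" to
"most") and at least two mismatches to every off-target. All mismatches
count equally; position or thermodynamic weighting is out of scope.

## Synthetic scenes

The generator reproduces the statistical structure the analysis assumes,
not the optics of a particular instrument.

* **Geometry.** The reference field is 212.55 µm × 212.55 µm at 2048 × 2048
  px (0.1038 µm/px); smaller fields keep the pixel size and scale expected
  counts by area. Spectral stacks use B = 32 emission bins (a typical
  lambda-mode detector; the bin count is free).
* **Placement.** Per taxon: homogeneous Poisson, Thomas cluster process
  (Poisson parents, Poisson(µ = 15) offspring displaced by an isotropic
  Gaussian with σ = 2 µm — clusters visibly up to ~10–15 µm across), or
  filaments as smoothed random walks (default 50 µm long, 0.7 µm wide).
  A new cell is redrawn when more than 10% of its area would overlap
  already-placed biomass: cells may touch and partially occlude, but the
  ground truth stays countable — at substantially higher allowed overlap a
  fixed fraction of clustered cells is irrecoverable by *any*
  intensity-based segmentation, which would make round-trip validation
  meaningless rather than informative.
* **Cell shapes and sizes.** Ellipses with per-taxon area (mean, SD from
  the published survey: 0.60, 0.53, 0.30, 1.62 µm²) truncated positive, and
  aspect ratios 1–1.5 (cocci), 2–4 (*Alphaproteobacteria* rods), 3–5
  (*Bacteroidetes* pieces). The survey's *Bacteroidetes* rows count
  segmented pieces, not whole filaments, so the site presets model that
  taxon as elongated pieces with the published per-object area; the
  filament process remains available and is validated geometrically.
* **Optics.** Each cell's pixels carry an ellipsoidal brightness dome
  (1 at the centre, 0.5 at the rim) and the per-dye abundance maps are
  blurred with a σ = 0.08 µm Gaussian — a minimal stand-in for the
  point-spread envelope that gives every cell a single interior intensity
  maximum and keeps micron-scale rods wider than one pixel. Full 3-D PSF /
  confocal sectioning physics is a non-goal.
* **Brightness and noise.** Per-cell brightness is log-normal with CV 0.3
  (unit mean). Per-dye amplitudes are set so the dye's peak emission bin
  sits at `snr` × the background noise scale √(background + σ_read²);
  defaults: background 20 counts/bin, read noise σ = 3, SNR 10. Shot noise
  is Poisson on the total signal, read noise Gaussian, and the stack is
  clipped to 16 bits. An optional toggle adds bright broad-spectrum blobs
  as autofluorescent nuisance objects.

What passing round-trip tests therefore show: the chain is correct and
well-calibrated *under these conditions* — realistic densities, clustering,
cell-size and brightness spread, shot noise. What they do not show:
robustness to uneven illumination, spectral bleed beyond the reference
model, kelp autofluorescence structure, tissue curvature, or focus drift in
real micrographs.

## Unmixing

Reference spectra are the mean of the brightest pixels (total intensity
above the 0.99 quantile) of a single-dye control image, after subtracting
the per-bin 5th percentile as background, normalized to unit sum. Rows must
be pairwise distinct and the matrix full row rank. Per-pixel abundances are
non-negative least squares (physical default); a vectorized unconstrained
solve handles all pixels and only those with negative components are
re-solved with NNLS, which leaves the constrained optimum unchanged. Plain
least squares is available for parity testing, and with a square full-rank
spectral matrix unmix∘mix is the identity to machine precision.

## Segmentation (ImageJ dialect)

Median 3×3 (replicate padding) → threshold → maxima-based splitting →
4-connected labeling → small-object removal. Conventions:

* **IsoData** iterates `t ← (mean(values ≤ t) + mean(values > t))/2` from
  the global mean; float images are first quantized to a 256-bin histogram
  (the ImageJ dialect), integer images iterate on exact values. Constant
  images have no threshold and raise.
* **Bernsen** thresholds at the local mid-gray (max+min)/2 over a disk
  window; windows whose contrast is below the floor resolve uniformly by
  comparing the mid-gray with half the image's dynamic range. Default
  radius 9 px: the window should bracket one cell plus background, and the
  smallest cells here are ~3 × 14 px rods — with much larger windows the
  local mid-gray is set by brighter neighbours and dim cells vanish. On
  float channels the working contrast floor is max(configured, 6× the
  channel's robust noise SD), since an absolute 8-bit-era constant is
  meaningless on abundance scales.
* **Maxima splitting** retains regional maxima whose morphological dynamics
  (height above the highest saddle toward a higher maximum — the
  prominence) reach the tolerance, then cuts watershed lines between them.
  The tolerance defaults to a per-channel multiplier of the channel noise
  SD: 2.0 generally, 0.75 for the densely clustered coccoid
  *Granulosicoccus* channel. One global tolerance cannot both split
  touching cocci and avoid shredding long filament-piece ridges; per-channel
  noise tolerance is exactly the knob ImageJ analysts set per channel.
  Exactly equal twin maxima are a degenerate tie: dynamics are defined
  against a *higher* maximum, and both peaks survive.
* **Small objects** below 0.05 µm² (~4–5 px) are removed. The cut is kept
  below half of the smallest mean cell area because local thresholding
  retains only the upper part of a dim cell's dome; a 0.1 µm² cut measurably
  deletes the dim tail of the 0.30 µm² *Alphaproteobacteria*.
* Labeling is 4-connected so 1-px watershed lines separate particles.

## Identification

ROIs are measured in every unmixed channel (mean over the ROI pixel set;
area = pixel count × pixel size²). The pipeline first subtracts each
channel's median (the unmixed share of the flat autofluorescent background)
and requires an ROI's own-channel mean to exceed 3× the channel noise SD —
without these, constant offsets and zero-signal fragments defeat a pure
ratio rule. The documented cross-reaction (the *Alphaproteobacteria* probe
marking cells that are positive for the *Verrucomicrobia* domain probes and
negative for the near-universal one) is excluded by a config-driven rule.

The conclusiveness criterion is inclusive: own-channel mean ≥ 2× the mean
in every *other* leaf-taxon channel. Channels inside the ROI's own barcode
and the near-universal domain channels are not compared against — a
*Granulosicoccus* cell is legitimately bright in the class and domain
channels, and a rule counting those would reject every correctly labeled
cell. Ambiguous ROIs are flagged and retained on request, and only
conclusive cells enter counts, densities and abundances.

## Summary statistics

Densities are mean per-image counts divided by the exact field area
(212.55 × 10⁻⁴ cm)². Site/tissue ratios divide unrounded group means and
round to integer at the end; SDs are sample SDs (n−1) across fields.
Fields in a group that contain zero cells of a taxon count as zeros rather
than being dropped. Biofilm thickness is the per-column foreground count of
a cross-section mask times the pixel size; the summary reports the maximum
and the modal 1-µm bin, and an empty mask is a valid all-zero profile.

Of the fifteen published density entries, nine are exactly reproducible
from the printed mean counts at three significant figures; the remainder
differ in the third digit because the original table evidently divided
unrounded counts. The same holds for the printed integer ratios: 194, 110,
288, 157, 53 (and 183) follow from the printed means; 118, 458, 192 and 263
do not. Tests assert only the arithmetically consistent entries.

## Linear-dipole pair correlation

For masks a, b with area fractions p_a, p_b, the estimator throws dipoles
of length r at uniform random position and orientation, keeps those with
both endpoints inside the image (minus-sampling), and scores endpoint
membership at the containing pixel, symmetrized over both ordered endpoint
assignments (this halves the Monte Carlo variance at no cost);
g(r) = P(hit)/(p_a·p_b). Defaults follow the published settings: 0.15 µm
bins to 50 µm, very small objects and cross-taxon overlap removed as noise,
10⁵ dipoles per bin, seeds recorded. An exhaustive mode enumerates all
ordered pixel-centre pairs per bin (via FFT over integer offsets) and is
the deterministic oracle; at sub-pixel dipole lengths the two modes differ
by construction, because a continuous dipole can land both endpoints in one
pixel while pixel-pair enumeration cannot.

**Same-object exclusion.** The plain estimator of any stationary binary
mask is maximal at r → 0 — set covariance peaks at zero lag — so its peak
location reads out object size, not arrangement. Published curves for these
biofilms peak at 1–1.5 µm, which is the signature of an *inter-object*
statistic: dipoles whose endpoints fall in the same connected object are
not counted as hits. The package implements both: the plain estimator is
the default and the oracle-checked contract; `exclude_same_object=True` is
used for scene-level arrangement analysis, where hard-core spacing between
cells produces the sub-micron anti-correlation and the micron-scale peak
whose FWHM above the g = 1 baseline estimates cluster size. Normalization
uses area fractions computed after noise exclusion, on the analyzed masks.

Aggregation averages curves within an individual first, then across
individuals, with a percentile bootstrap (individuals resampled, 1000
replicates) for the 95% band. Peak statistics take the bin-centre of the
maximum (ties → smallest distance) and linearly interpolate the crossings
of 1 + (g_max − 1)/2; a curve never exceeding 1 has no peak and is flagged
rather than raising. Filament-dominated taxa are excluded from arrangement
runs by default (their flattened in-preparation geometry is not their in
vivo arrangement); an override flag exists.

## Problem sizes

Validation and acceptance runs use 512 px (53.1 µm) fields — 1/16 of the
reference field at identical pixel size and density — 50 000–100 000
dipoles per bin, correlation ranges of 10–15 µm, and 2–3 scenes per
ensemble. These sizes put every statistic in its asymptotic regime (counts
of hundreds of cells per scene, Monte Carlo standard errors of ~0.03 on g)
while keeping the full suite fast; all of them are parameters, and the
reference 2048-px geometry is the default for real data.

## Known limitations

* The 2× conclusiveness factor, the noise floor (3×), the Bernsen window
  and the per-channel maxima tolerances are calibrated on the synthetic
  conditions above; real micrographs will need per-dataset adjustment of
  exactly these config fields.
* The unmixing model is strictly linear with a flat background; detector
  gain weighting per bin and bleed-through beyond the reference spectra are
  not modeled.
* Thomas-process parents are not themselves spatially structured; real
  cluster positions may follow host-surface features.
* 3-D: z-stacks are processed plane by plane; there is no volumetric
  segmentation or 3-D dipole analysis.
* The filament model validates geometry (length, width, area) but
  filamentous ground truth is not used for count-recovery claims, since
  crossing threads merge under any 2-D segmentation.
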