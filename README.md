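# clasifish

Quantification of combinatorially labeled, spectrally imaged FISH
micrographs of host-surface microbiomes — built around the bull-kelp
(*Nereocystis luetkeana*) blade biofilm, where four bacterial groups
(*Granulosicoccus*, *Alphaproteobacteria*, *Bacteroidetes*, and
*Verrucomicrobia*/*Planctomycetes*) are identified simultaneously by nested
rRNA probes carrying combinations of one to three fluorophores.

The package is aimed at microbial ecologists who have (or want to prototype
against) lambda-mode confocal stacks of multiplexed FISH preparations and
need the full measurement chain, testable end to end:

1. **Spectral unmixing** — per-pixel non-negative least squares
   `min ‖aS − y‖², a ≥ 0` against a reference matrix `S` (dye × spectral
   bin) fitted from single-dye control images.
2. **Segmentation** — the classic FIJI chain: 3×3 median filter, IsoData
   (intermeans fixed point `t = (µ_low(t) + µ_high(t))/2`) or Bernsen
   local mid-gray thresholding, watershed "segmented particles" seeded at
   intensity maxima of prominence ≥ h, and small-object removal.
3. **Barcode decoding** — each ROI is assigned the taxon whose fluorophore
   set is the largest barcode contained in its positive channels, with a
   cross-reaction exclusion rule and a conclusiveness criterion: mean
   intensity in the expected taxon channel ≥ 2× every other taxon channel.
4. **Community statistics** — per-taxon counts, areas, cells/cm² over the
   212.55 µm field of view, site/tissue ratios, relative abundance,
   z-stratified abundance, and cross-section biofilm thickness profiles.
5. **Spatial arrangement** — the linear-dipole estimator of the pair
   cross-correlation `g(r)`: segments of length `r` thrown at random
   position/orientation, endpoint co-occurrence normalized by the product
   of area fractions (`g > 1` attraction, `= 1` random, `< 1` repulsion),
   with per-individual aggregation, bootstrap 95% CIs, and peak/FWHM
   cluster-size statistics.
6. **Synthetic scenes** — a ground-truthed generator (Poisson, Thomas
   cluster, and filament processes; combinatorial labeling; mixed emission
   spectra; Poisson + read noise) parameterized to the published survey
   conditions, so every stage above is validated by round-trip recovery.

## Worked example

```sh
python examples/simulate_and_recover.py
```

```
Field: 53.1 um square, 512 px, SNR 10
taxon                             truth  found   error
Alphaproteobacteria                 198    182   -8.1%
Bacteroidetes                        89     90   +1.1%
Granulosicoccus                     141    134   -5.0%
Verrucomicrobia/Planctomycetes      153    151   -1.3%

Total recovered density: 1.97e+07 cells/cm^2
```

The script simulates a kelp-tip field at the published densities, renders
the 32-bin spectral stack at SNR 10, and runs unmixing → segmentation →
classification; recovered counts sit within ten percent of the generator's
ground truth with no cross-taxon confusion, and the implied density matches
the ~2×10⁷ cells/cm² scale of tip tissue.

Other examples: `decode_barcodes.py` (barcode table, decoding, probe
specificity screen), `density_table.py` (cells/cm² and tip:base ratios from
the published mean counts), `spatial_correlation.py` (linear-dipole
autocorrelation of clustered *Granulosicoccus*, peak ≈ 1.5–2 µm, FWHM
≈ 2–3 µm).

A thin CLI wraps the same library calls:

```sh
clasifish simulate --preset tip --px 512 --seed 1 --out scratch/demo
clasifish run --config run.yaml
```

## Layout

```
src/clasifish/      panel, synth, unmix, segment, identify, quantify,
                    dipole, pipeline, plotting, cli, io, constants
examples/           one short narrative script per capability
tests/              pytest suite incl. acceptance criteria
docs/methods.md     models, parameters, numerical choices, limitations
```
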