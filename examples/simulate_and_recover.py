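"""Round-trip: simulate a kelp-tip biofilm image and recover the community.

Builds a 512 x 512 px synthetic field at the published tip-tissue densities,
renders the spectral stack at SNR 10, then runs the full analysis chain
(unmix -> segment -> classify) and compares recovered per-taxon counts with
the generator's ground truth.
"""

from clasifish import FOVGeometry, analyze_image, density_per_cm2, make_fixtures

image, scene, panel, spectra = make_fixtures("tip", seed=1, px=512, snr=10.0)
truth = scene.taxon_counts()
table, masks, report = analyze_image(image, panel, spectra)
got = table.groupby("taxon").size().to_dict()

print(f"Field: {scene.config.fov_um:.1f} um square, "
      f"{scene.config.px} px, SNR {scene.config.snr:g}")
print(f"{'taxon':32s} {'truth':>6s} {'found':>6s} {'error':>7s}")
for taxon, n in sorted(truth.items()):
    k = got.get(taxon, 0)
    print(f"{taxon:32s} {n:6d} {k:6d} {100 * (k - n) / n:+6.1f}%")

geom = FOVGeometry(side_um=scene.config.fov_um, px=scene.config.px)
print(f"\nTotal recovered density: "
      f"{density_per_cm2(len(table), geom):.3g} cells/cm^2")
print("(tip-tissue fields in the survey average ~2.2e7 cells/cm^2; errors of"
      " a few percent come from touching cells and the dim-cell tail)")
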