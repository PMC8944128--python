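"""Linear-dipole autocorrelation of clustered cells.

Samples three kelp-tip scenes whose *Granulosicoccus* population is
Thomas-clustered (2 um cluster scale), measures the inter-object
pair-correlation curve of each ground-truth mask, aggregates them as the
study aggregates fields per kelp individual, and reports the peak distance
and full width at half maximum — the cluster-size readout.
"""

import numpy as np

from clasifish import (
    DipoleCurve,
    DipoleSettings,
    aggregate,
    dipole_correlation,
    peak_stats,
    preset_config,
    sample_scene,
)

curves = {}
for seed in (1, 2, 3):
    config = preset_config("tip", px=512, seed=seed)
    scene = sample_scene(config)
    mask = scene.taxon_mask("Granulosicoccus")
    settings = DipoleSettings(
        max_distance_um=15.0, step_um=0.15, n_dipoles_per_bin=50_000,
        exclude_same_object=True, seed=seed,
    )
    curves[f"kelp{seed}"] = [
        dipole_correlation(mask, mask, settings, config.pixel_size_um,
                           apply_noise_exclusion=True)
    ]
    print(f"scene {seed}: {int(mask.sum())} foreground px, "
          f"area fraction {mask.mean():.3f}")

ensemble = aggregate(curves, seed=0)
stats = peak_stats(DipoleCurve(
    ensemble.distance_um, ensemble.mean, np.ones_like(ensemble.mean),
    np.zeros_like(ensemble.mean), 1.0, 1.0,
))
print(f"\npeak autocorrelation g = {stats.peak_g:.2f} "
      f"at {stats.peak_distance_um:.2f} um")
print(f"FWHM above the g=1 baseline: {stats.fwhm_um:.2f} um")
print("(g > 1 = attraction; the peak distance ~1-2 um and FWHM ~1-3 um"
      " reflect single-taxon clusters, as seen on kelp-tip biofilms)")
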