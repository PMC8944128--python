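"""Cell-density and site-ratio arithmetic over the 212.55 um field of view.

Converts the survey's published per-image mean counts into cells/cm^2 and
site/tissue ratios — the summary statistics behind the finding that older
(tip) tissue carries ~200x the bacterial load of young (base) tissue.
"""

from clasifish import FOVGeometry, count_ratio, density_per_cm2
from clasifish import constants as C

geom = FOVGeometry()
print(f"FOV: {geom.side_um} um square = {geom.area_cm2:.4g} cm^2\n")

print(f"{'taxon':32s} {'tip/cm^2':>10s} {'base/cm^2':>10s} {'tip:base':>9s}")
for taxon in C.MAJOR_TAXA:
    tip = C.MEAN_COUNT_PER_FOV["tip"][taxon][0]
    base = C.MEAN_COUNT_PER_FOV["base"][taxon][0]
    print(f"{taxon:32s} {density_per_cm2(tip, geom):10.3g} "
          f"{density_per_cm2(base, geom):10.3g} {count_ratio(tip, base):9d}")

tip_total, base_total = C.TOTAL_COUNT_PER_FOV["tip"][0], C.TOTAL_COUNT_PER_FOV["base"][0]
squax_total = C.TOTAL_COUNT_PER_FOV["squaxin"][0]
print(f"\nfour taxa, tip:    {density_per_cm2(tip_total, geom):.3g} cells/cm^2")
print(f"four taxa, base:   {density_per_cm2(base_total, geom):.3g} cells/cm^2")
print(f"tip : base ratio   {count_ratio(tip_total, base_total)}")
print(f"tip : mid-blade    {count_ratio(tip_total, squax_total)}")
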