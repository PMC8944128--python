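"""Published survey values for the bull-kelp blade-surface biofilm.

These are the study conditions the synthetic generator emulates: per-image
mean cell counts and per-cell areas of the four dominant taxa on kelp blade
tissue from two sites (tip = older tissue and base = young tissue of blades
from the persistent Tatoosh Island population; mid-blade tissue from the
declining Squaxin Island population), measured on 212.55 x 212.55 um fields
of view at 2048 x 2048 px.
"""

FOV_SIDE_UM = 212.55
FOV_SIDE_PX = 2048
PIXEL_SIZE_UM = FOV_SIDE_UM / FOV_SIDE_PX  # 0.10378 um/px

GRANULOSICOCCUS = "Granulosicoccus"
VERRUCOMICROBIA = "Verrucomicrobia/Planctomycetes"
ALPHAPROTEOBACTERIA = "Alphaproteobacteria"
BACTEROIDETES = "Bacteroidetes"

MAJOR_TAXA = [GRANULOSICOCCUS, VERRUCOMICROBIA, ALPHAPROTEOBACTERIA, BACTEROIDETES]

# mean (SD) segmented-object area, um^2
CELL_AREA_UM2 = {
    GRANULOSICOCCUS: (0.60, 0.16),
    VERRUCOMICROBIA: (0.53, 0.08),
    ALPHAPROTEOBACTERIA: (0.30, 0.10),
    BACTEROIDETES: (1.62, 0.50),
}

# mean (SD) cell count per full field of view, by site/tissue preset
MEAN_COUNT_PER_FOV = {
    "tip": {
        GRANULOSICOCCUS: (2921.2, 1853.5),
        VERRUCOMICROBIA: (2449.9, 1174.0),
        ALPHAPROTEOBACTERIA: (2879.0, 1783.1),
        BACTEROIDETES: (1645.4, 982.6),
    },
    "base": {
        GRANULOSICOCCUS: (24.9, 29.9),
        VERRUCOMICROBIA: (5.4, 9.2),
        ALPHAPROTEOBACTERIA: (10.0, 20.4),
        BACTEROIDETES: (10.5, 21.3),
    },
    "squaxin": {
        GRANULOSICOCCUS: (15.3, 17.5),
        VERRUCOMICROBIA: (13.4, 16.0),
        ALPHAPROTEOBACTERIA: (54.7, 85.7),
        BACTEROIDETES: (6.3, 13.3),
    },
}

# four-major-taxa totals per FOV (mean, SD)
TOTAL_COUNT_PER_FOV = {
    "tip": (9813.2, 4058.7),
    "base": (50.7, 49.1),
    "squaxin": (89.6, 121.0),
}
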