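"""Ground-truthed synthetic biofilm scenes and spectral images.

The generator emulates the statistical structure of a micron-scale epiphytic
biofilm imaged by spectral confocal microscopy: Poisson or Thomas-clustered
placement of elliptical cells with taxon-specific areas and aspect ratios,
filamentous taxa as smoothed random walks, combinatorial fluorophore labeling
per taxon barcode, mixed emission spectra, autofluorescent background, and
Poisson + Gaussian read noise with 16-bit clipping.  Every scene carries a
full ground truth (cell records plus per-taxon label masks) so the complete
analysis chain can be validated by round-trip recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from . import constants as C
from .panel import ProbePanel, default_panel
from .unmix import ReferenceSpectra

__all__ = [
    "TaxonModel",
    "SceneConfig",
    "SyntheticScene",
    "SpectralImage",
    "sample_scene",
    "render_spectral",
    "ground_truth_table",
    "synthetic_reference_spectra",
    "preset_config",
]


@dataclass
class SpectralImage:
    """H x W x B stack of 16-bit spectral intensities with pixel size in um."""

    data: np.ndarray
    pixel_size_um: float
    n_bins: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("spectral image must be H x W x B")
        self.n_bins = self.data.shape[2]


@dataclass
class TaxonModel:
    """Spatial and optical model for one taxon.

    process: "poisson" (complete spatial randomness), "thomas" (Poisson
    parents with Gaussian-scattered offspring; single-taxon clusters), or
    "filament" (smoothed random-walk threads).  ``area_um2`` is the
    (mean, SD) per-object area; ``aspect_range`` the cell aspect ratio range.
    ``barcode`` is the fluorophore set the taxon lights up with.
    """

    taxon: str
    expected_count_per_fov: float
    barcode: frozenset[str]
    process: str = "poisson"
    area_um2: tuple[float, float] = (0.6, 0.15)
    aspect_range: tuple[float, float] = (1.0, 1.5)
    cluster_mean_offspring: float = 15.0
    cluster_radius_um: float = 2.0
    filament_length_um: float = 50.0
    filament_width_um: float = 0.7
    filament_curvature: float = 0.25

    def __post_init__(self) -> None:
        if self.expected_count_per_fov < 0:
            raise ValueError("expected_count_per_fov must be >= 0")
        if self.process not in ("poisson", "thomas", "filament"):
            raise ValueError(f"unknown process {self.process!r}")
        if self.area_um2[0] <= 0:
            raise ValueError("mean cell area must be > 0")
        self.barcode = frozenset(self.barcode)

    def mean_object_area_um2(self) -> float:
        if self.process == "filament":
            return self.filament_length_um * self.filament_width_um
        return self.area_um2[0]


@dataclass
class SceneConfig:
    """Field geometry, community composition, optics and noise for one scene."""

    taxa: list[TaxonModel]
    fov_um: float = C.FOV_SIDE_UM
    px: int = C.FOV_SIDE_PX
    background_level: float = 20.0
    read_noise_sd: float = 3.0
    poisson_noise: bool = True
    snr: float = 10.0
    brightness_cv: float = 0.3
    max_overlap_fraction: float = 0.1
    psf_sigma_um: float = 0.08
    n_autofluor_blobs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fov_um <= 0:
            raise ValueError("fov_um must be > 0")
        if self.px < 64:
            raise ValueError("px must be >= 64")

    @property
    def pixel_size_um(self) -> float:
        return self.fov_um / self.px

    def scaled(self, px: int) -> "SceneConfig":
        """Same pixel size and densities on a smaller/larger field."""
        factor = (px / self.px) ** 2
        taxa = [
            replace(t, expected_count_per_fov=t.expected_count_per_fov * factor)
            for t in self.taxa
        ]
        return replace(self, taxa=taxa, px=px, fov_um=self.fov_um * px / self.px)


@dataclass
class SyntheticScene:
    """Sampled cell geometries plus per-taxon ground-truth label masks.

    ``profiles`` hold the within-cell intensity weight (a dome peaking at the
    cell centre, 0.5 at the rim) that stands in for the optical point-spread
    envelope: it gives every cell a single interior intensity maximum, as in
    real confocal data.
    """

    cells: pd.DataFrame  # cell_id, taxon, area_um2, centroid_x_um, centroid_y_um
    masks: dict[str, np.ndarray]  # taxon -> int32 label image (cell_id)
    config: SceneConfig
    profiles: dict[str, np.ndarray] | None = None

    def taxon_counts(self) -> dict[str, int]:
        return self.cells.groupby("taxon").size().to_dict()

    def taxon_mask(self, taxon: str) -> np.ndarray:
        return self.masks[taxon] > 0


# ---------------------------------------------------------------------------
# geometry rasterization


def _raster_ellipse(rng, area_um2, aspect_range, px, pixel_size, center=None):
    """Pixel coordinates of a random-orientation ellipse of the given area."""
    area = -1.0
    mean, sd = area_um2
    while area <= 0:
        area = rng.normal(mean, sd)
    aspect = rng.uniform(*aspect_range)
    b_um = math.sqrt(area / (math.pi * aspect))
    a_um = aspect * b_um
    theta = rng.uniform(0, math.pi)
    if center is None:
        center = rng.uniform(0, px, size=2)
    a_px = max(a_um / pixel_size, 0.5)
    b_px = max(b_um / pixel_size, 0.5)
    rr, cc = draw_ellipse(
        center[0], center[1], a_px, b_px, rotation=theta, shape=(px, px)
    )
    # ellipsoidal brightness dome (1 at centre, 0.5 at rim): one intensity
    # maximum per cell, as the optics produce
    dy = rr - center[0]
    dx = cc - center[1]
    u = (dy * math.cos(theta) - dx * math.sin(theta)) / a_px
    v = (dy * math.sin(theta) + dx * math.cos(theta)) / b_px
    rho2 = np.clip(u**2 + v**2, 0.0, 1.0)
    weights = (0.5 + 0.5 * np.sqrt(1.0 - rho2)).astype(np.float32)
    return rr, cc, center, weights


def _raster_filament(rng, model: TaxonModel, px, pixel_size):
    """Smoothed random-walk thread of the configured length and width."""
    step_um = 0.5
    n_steps = max(int(model.filament_length_um / step_um), 2)
    pos = rng.uniform(0, px, size=2)
    heading = rng.uniform(0, 2 * math.pi)
    pts = [pos.copy()]
    step_px = step_um / pixel_size
    for _ in range(n_steps):
        heading += rng.normal(0.0, model.filament_curvature)
        pos = pos + step_px * np.array([math.sin(heading), math.cos(heading)])
        pts.append(pos.copy())
    pts = np.array(pts)
    # densify and stamp, then dilate to the filament width
    dense = []
    for p, q in zip(pts[:-1], pts[1:]):
        seg = np.linspace(p, q, max(int(np.hypot(*(q - p)) * 2), 2))
        dense.append(seg)
    dense = np.vstack(dense)
    mask = np.zeros((px, px), dtype=bool)
    idx = np.round(dense).astype(int)
    keep = (idx[:, 0] >= 0) & (idx[:, 0] < px) & (idx[:, 1] >= 0) & (idx[:, 1] < px)
    idx = idx[keep]
    if idx.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int), pts.mean(axis=0)
    mask[idx[:, 0], idx[:, 1]] = True
    half_w = max(int(round(model.filament_width_um / 2 / pixel_size)), 1)
    mask = ndimage.binary_dilation(mask, structure=_disk(half_w))
    rr, cc = np.nonzero(mask)
    return rr, cc, dense.mean(axis=0)


def _dome_weights(rr: np.ndarray, cc: np.ndarray, px: int) -> np.ndarray:
    """Within-cell intensity dome: 1 at the centre, 0.5 at the rim.

    Computed from the Euclidean distance to the cell boundary on the cell's
    bounding box, so touching cells keep distinct intensity maxima.
    """
    if rr.size == 0:
        return np.empty(0, dtype=np.float32)
    r0, r1 = rr.min(), rr.max()
    c0, c1 = cc.min(), cc.max()
    box = np.zeros((r1 - r0 + 3, c1 - c0 + 3), dtype=bool)
    box[rr - r0 + 1, cc - c0 + 1] = True
    edt = ndimage.distance_transform_edt(box)
    peak = edt.max()
    w = 0.5 + 0.5 * edt[rr - r0 + 1, cc - c0 + 1] / max(peak, 1.0)
    return w.astype(np.float32)


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2) <= radius**2


def _sample_centers(rng, model: TaxonModel, px: int, pixel_size: float):
    """Candidate cell centers (px coords) for one taxon's point process."""
    if model.process == "thomas":
        mu = model.cluster_mean_offspring
        lam_parents = model.expected_count_per_fov / mu
        n_parents = rng.poisson(lam_parents)
        sigma_px = model.cluster_radius_um / pixel_size
        centers = []
        for _ in range(n_parents):
            parent = rng.uniform(0, px, size=2)
            for _ in range(rng.poisson(mu)):
                centers.append(parent + rng.normal(0, sigma_px, size=2))
        centers = [c for c in centers if 0 <= c[0] < px and 0 <= c[1] < px]
        return centers
    n = rng.poisson(model.expected_count_per_fov)
    return [rng.uniform(0, px, size=2) for _ in range(n)]


def sample_scene(config: SceneConfig) -> SyntheticScene:
    """Sample a ground-truthed scene: cell placement with overlap control.

    Counts per taxon are Poisson (or Thomas-compound) at the configured
    expectations.  Later-drawn cells may touch existing ones but are redrawn
    (up to a retry cap) when more than ``max_overlap_fraction`` of their area
    would overlap already-placed biomass, so ground truth stays countable.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    px, pixel_size = config.px, config.pixel_size_um
    fov_area = config.fov_um**2
    planned = sum(
        t.expected_count_per_fov * t.mean_object_area_um2() for t in config.taxa
    )
    if planned > 0.5 * fov_area:
        raise ValueError(
            f"expected coverage {planned / fov_area:.0%} exceeds 50%: "
            "biofilm would be unresolvable"
        )
    occupied = np.zeros((px, px), dtype=bool)
    masks = {t.taxon: np.zeros((px, px), dtype=np.int32) for t in config.taxa}
    profiles = {t.taxon: np.zeros((px, px), dtype=np.float32) for t in config.taxa}
    records = []
    cell_id = 0
    for model in config.taxa:
        if model.process == "filament":
            n = rng.poisson(model.expected_count_per_fov)
            for _ in range(n):
                rr, cc, center = _raster_filament(rng, model, px, pixel_size)
                if rr.size == 0:
                    continue
                cell_id += 1
                occupied[rr, cc] = True
                masks[model.taxon][rr, cc] = cell_id
                profiles[model.taxon][rr, cc] = _dome_weights(rr, cc, px)
                records.append(
                    (
                        cell_id,
                        model.taxon,
                        rr.size * pixel_size**2,
                        float(center[1]) * pixel_size,
                        float(center[0]) * pixel_size,
                    )
                )
            continue
        centers = _sample_centers(rng, model, px, pixel_size)
        for center in centers:
            placed = False
            for attempt in range(30):
                jitter = center if attempt == 0 else center + rng.normal(0, 2, 2)
                rr, cc, _, weights = _raster_ellipse(
                    rng, model.area_um2, model.aspect_range, px, pixel_size, jitter
                )
                if rr.size == 0:
                    continue
                overlap = occupied[rr, cc].mean()
                if overlap <= config.max_overlap_fraction:
                    placed = True
                    break
            if not placed:
                continue
            cell_id += 1
            occupied[rr, cc] = True
            masks[model.taxon][rr, cc] = cell_id
            profiles[model.taxon][rr, cc] = weights
            records.append(
                (
                    cell_id,
                    model.taxon,
                    rr.size * pixel_size**2,
                    float(np.mean(cc)) * pixel_size,
                    float(np.mean(rr)) * pixel_size,
                )
            )
    cells = pd.DataFrame(
        records,
        columns=["cell_id", "taxon", "area_um2", "centroid_x_um", "centroid_y_um"],
    )
    return SyntheticScene(cells=cells, masks=masks, config=config, profiles=profiles)


def synthetic_reference_spectra(
    dyes: list[str], n_bins: int = 32
) -> ReferenceSpectra:
    """Plausible, well-separated Gaussian emission spectra, one peak per dye.

    Peaks are evenly staggered across the spectral range with a width of two
    bins; deterministic so fixtures are reproducible without a seed.
    """
    F = len(dyes)
    bins = np.arange(n_bins)
    rows = []
    for i in range(F):
        peak = (i + 1) * n_bins / (F + 1)
        rows.append(np.exp(-0.5 * ((bins - peak) / 2.0) ** 2))
    return ReferenceSpectra(np.stack(rows), list(dyes))


def render_spectral(
    scene: SyntheticScene,
    panel: ProbePanel,
    spectra: ReferenceSpectra,
    config: SceneConfig | None = None,
    noise: bool = True,
) -> SpectralImage:
    """Forward-model a spectral stack from a scene.

    Each cell's pixels emit the sum of its barcode dyes' reference spectra
    scaled by a per-cell log-normal brightness, on top of a flat
    autofluorescent background; Poisson shot noise and Gaussian read noise
    are applied and the result is clipped to 16 bits.  Per-dye amplitudes are
    set so that the peak emission bin of each dye sits at ``config.snr``
    times the background noise scale.
    """
    config = config or scene.config
    rng = np.random.default_rng(config.seed + 1)
    px = config.px
    F = len(spectra.dyes)
    models = {t.taxon: t for t in config.taxa}
    for model in models.values():
        missing = model.barcode - set(spectra.dyes)
        if missing:
            raise ValueError(
                f"dye(s) {sorted(missing)} in barcode of {model.taxon} "
                "missing from reference spectra"
            )
    # noise-free configs still need a finite brightness scale (1 count)
    noise_scale = max(
        math.sqrt(config.background_level + config.read_noise_sd**2), 1.0
    )
    peak_weight = spectra.matrix.max(axis=1)  # per dye
    amplitudes = config.snr * noise_scale / peak_weight
    abundance = np.zeros((px, px, F), dtype=np.float32)
    sigma = math.sqrt(math.log(1 + config.brightness_cv**2))
    for taxon, mask in scene.masks.items():
        model = models[taxon]
        dye_idx = [spectra.dyes.index(d) for d in model.barcode]
        ids = scene.cells.loc[scene.cells.taxon == taxon, "cell_id"].to_numpy()
        if ids.size == 0:
            continue
        # per-cell log-normal brightness with unit mean
        bright = rng.lognormal(-0.5 * sigma**2, sigma, size=int(ids.max()) + 1)
        inside = mask > 0
        cellb = bright[mask[inside]]
        if scene.profiles is not None:
            cellb = cellb * scene.profiles[taxon][inside]
        for j in dye_idx:
            abundance[inside, j] += (cellb * amplitudes[j]).astype(np.float32)
    if getattr(config, "psf_sigma_um", 0.0) > 0:
        sigma_px = config.psf_sigma_um / config.pixel_size_um
        for j in range(F):
            abundance[:, :, j] = ndimage.gaussian_filter(
                abundance[:, :, j], sigma_px
            )
    signal = abundance @ spectra.matrix.astype(np.float32)
    signal += config.background_level
    if config.n_autofluor_blobs:
        flat = np.full(spectra.n_bins, 1.0 / spectra.n_bins, dtype=np.float32)
        for _ in range(config.n_autofluor_blobs):
            r0 = rng.uniform(0, px, 2)
            rad = rng.uniform(5, 20)
            rr, cc = draw_ellipse(r0[0], r0[1], rad, rad, shape=(px, px))
            signal[rr, cc] += amplitudes.max() * 2 * flat
    if noise:
        signal = rng.poisson(signal).astype(np.float32) if config.poisson_noise else signal
        signal = signal + rng.normal(0, config.read_noise_sd, signal.shape)
    data = np.clip(np.round(signal), 0, 65535).astype(np.uint16)
    return SpectralImage(data=data, pixel_size_um=config.pixel_size_um)


def ground_truth_table(scene: SyntheticScene) -> pd.DataFrame:
    """Ground-truth cell table in the downstream CellTable schema."""
    df = scene.cells.copy()
    df.insert(0, "roi_id", df.pop("cell_id"))
    df["conclusive"] = True
    return df[
        ["roi_id", "taxon", "area_um2", "centroid_x_um", "centroid_y_um", "conclusive"]
    ]


def preset_config(
    preset: str,
    px: int = C.FOV_SIDE_PX,
    seed: int = 0,
    snr: float = 10.0,
    panel: ProbePanel | None = None,
) -> SceneConfig:
    """Scene configuration for a published site/tissue condition.

    Presets parameterize the four-taxon community at the survey's per-image
    mean counts and per-object areas ("tip", "base", "squaxin"), scaled to
    the requested image size at constant pixel size.  *Granulosicoccus* is
    Thomas-clustered (2 um cluster scale); the other taxa are Poisson.
    Bacteroidetes objects use the published per-object (segmented-piece)
    area with an elongated aspect, since whole filaments are not countable
    units in the survey's tables.
    """
    if preset not in C.MEAN_COUNT_PER_FOV:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(C.MEAN_COUNT_PER_FOV)}"
        )
    panel = panel or default_panel()
    counts = C.MEAN_COUNT_PER_FOV[preset]
    aspect = {
        C.GRANULOSICOCCUS: (1.0, 1.5),
        C.VERRUCOMICROBIA: (1.0, 1.5),
        C.ALPHAPROTEOBACTERIA: (2.0, 4.0),
        C.BACTEROIDETES: (3.0, 5.0),
    }
    taxa = []
    for taxon in C.MAJOR_TAXA:
        taxa.append(
            TaxonModel(
                taxon=taxon,
                expected_count_per_fov=counts[taxon][0],
                barcode=panel.barcodes[taxon],
                process="thomas" if taxon == C.GRANULOSICOCCUS else "poisson",
                area_um2=C.CELL_AREA_UM2[taxon],
                aspect_range=aspect[taxon],
                cluster_mean_offspring=15.0,
                cluster_radius_um=2.0,
            )
        )
    config = SceneConfig(taxa=taxa, seed=seed, snr=snr)
    if px != C.FOV_SIDE_PX:
        config = config.scaled(px)
        config.seed = seed
    return config
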