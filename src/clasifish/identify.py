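"""Per-ROI taxon assignment: intensity measurement, cross-reaction exclusion,
and the conclusive-identification rule.

Each segmented candidate cell (ROI) is measured in every unmixed dye channel.
An ROI segmented from a taxon's channel is *conclusively* identified when its
mean intensity in that taxon-specific channel is at least ``factor`` (default
2x) its mean intensity in every other taxon-specific channel.  The
near-universal domain probes define the barcode, not the discriminant, so
they are not compared against.  Known probe cross-reactions are excluded by
rule before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .panel import ProbePanel, decode_barcode
from .segment import LabelImage
from .unmix import ChannelStack

__all__ = [
    "ROIRecord",
    "CrossReactionRule",
    "measure_rois",
    "exclude_crossreactive",
    "classify_roi",
    "classify_all",
    "build_cell_table",
    "default_crossreaction_rules",
    "CELL_TABLE_COLUMNS",
]

AMBIGUOUS = "ambiguous"


@dataclass
class ROIRecord:
    """One segmented candidate cell with per-channel mean intensities."""

    roi_id: int
    source_channel: str  # taxon channel it was segmented from
    area_um2: float
    centroid_um: tuple[float, float]  # (x, y)
    mean_intensity: dict[str, float]
    conclusive: bool = False
    assigned_taxon: str = AMBIGUOUS

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("ROI area must be > 0")
        if any(v < 0 for v in self.mean_intensity.values()):
            raise ValueError("intensities must be >= 0")
        if self.conclusive and self.assigned_taxon == AMBIGUOUS:
            raise ValueError("conclusive ROI cannot be ambiguous")


@dataclass(frozen=True)
class CrossReactionRule:
    """Exclude ROIs whose domain-probe pattern contradicts their channel.

    An ROI segmented from ``offending_channel`` is removed when its mean
    intensity in ``marker_channel_absent`` (the channel its true taxon should
    light) is below that in ``marker_channel_present`` (the channel the
    cross-reacting cells actually light).
    """

    offending_channel: str
    marker_channel_present: str
    marker_channel_absent: str

    def __post_init__(self) -> None:
        names = {
            self.offending_channel,
            self.marker_channel_present,
            self.marker_channel_absent,
        }
        if len(names) != 3:
            raise ValueError("cross-reaction rule channels must be distinct")


def default_crossreaction_rules(panel: ProbePanel) -> list[CrossReactionRule]:
    """The documented cross-reaction: the Alphaproteobacteria probe reacting
    with cells labeled by the domain probes for Verrucomicrobia/Planctomycetes
    (positive for Eub338-II/III, negative for Eub338-I)."""
    eub1 = panel.dye_for_probe("Eub338-I")
    eub23 = panel.dye_for_probe("Eub338-II")
    alf = panel.dye_for_probe("Alf968")
    return [
        CrossReactionRule(
            offending_channel=alf,
            marker_channel_present=eub23,
            marker_channel_absent=eub1,
        )
    ]


def measure_rois(
    labels: LabelImage,
    channels: ChannelStack,
    source_channel: str,
) -> list[ROIRecord]:
    """One record per label with mean intensity over the ROI in every channel."""
    if labels.labels.shape != channels.abundances.shape[:2]:
        raise ValueError("label image and channel stack shapes differ")
    from scipy import ndimage as ndi

    px = labels.pixel_size_um
    records = []
    props = regionprops(labels.labels)
    lab = labels.labels
    index = np.arange(1, labels.n_labels + 1)
    per_dye = {
        dye: ndi.mean(channels.channel(dye), lab, index) if index.size else []
        for dye in channels.dyes
    }
    for k, prop in enumerate(props):
        cy, cx = prop.centroid
        records.append(
            ROIRecord(
                roi_id=int(prop.label),
                source_channel=source_channel,
                area_um2=prop.area * px**2,
                centroid_um=(cx * px, cy * px),
                mean_intensity={
                    dye: float(per_dye[dye][prop.label - 1]) for dye in channels.dyes
                },
            )
        )
    return records


def exclude_crossreactive(
    rois: list[ROIRecord],
    rules: list[CrossReactionRule],
    factor: float = 1.0,
) -> list[ROIRecord]:
    """Drop ROIs matching a cross-reaction pattern from their source channel."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    kept = []
    for roi in rois:
        excluded = False
        for rule in rules:
            if roi.source_channel != rule.offending_channel:
                continue
            present = roi.mean_intensity.get(rule.marker_channel_present, 0.0)
            absent = roi.mean_intensity.get(rule.marker_channel_absent, 0.0)
            if absent * factor < present:
                excluded = True
                break
        if not excluded:
            kept.append(roi)
    return kept


def classify_roi(
    roi: ROIRecord, panel: ProbePanel, factor: float = 2.0
) -> ROIRecord:
    """Apply the conclusive-identification rule to one ROI.

    The ROI's source channel is a taxon-specific dye.  It is conclusive iff
    its mean intensity there is >= ``factor`` times its intensity in every
    *other* taxon-specific channel (inclusive at exactly the factor); the
    assigned taxon is then the barcode decode of the source taxon's dye set.
    Comparisons never involve the near-universal domain channels.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    taxon_channels = {
        taxon: panel.taxon_channel(taxon) for taxon in panel.leaf_taxa()
    }
    # invert: which leaf taxon does the source channel belong to
    source_taxon = None
    for taxon, dye in taxon_channels.items():
        if dye == roi.source_channel:
            source_taxon = taxon
            break
    if source_taxon is None:
        raise ValueError(
            f"source channel {roi.source_channel!r} is not a taxon channel"
        )
    own = roi.mean_intensity.get(roi.source_channel, 0.0)
    own_code = panel.barcodes[source_taxon]
    others = [
        roi.mean_intensity.get(dye, 0.0)
        for taxon, dye in taxon_channels.items()
        if dye != roi.source_channel and dye not in own_code
    ]
    conclusive = own > 0 and all(own >= factor * other for other in others)
    assigned = (
        decode_barcode(panel.barcodes[source_taxon], panel)
        if conclusive
        else AMBIGUOUS
    )
    roi.conclusive = bool(conclusive)
    roi.assigned_taxon = assigned
    return roi


def classify_all(
    rois: list[ROIRecord], panel: ProbePanel, factor: float = 2.0
) -> list[ROIRecord]:
    return [classify_roi(r, panel, factor) for r in rois]


CELL_TABLE_COLUMNS = [
    "sample_id",
    "fov_id",
    "roi_id",
    "taxon",
    "area_um2",
    "centroid_x_um",
    "centroid_y_um",
    "conclusive",
]


def build_cell_table(
    rois: list[ROIRecord],
    fov_meta: dict | None = None,
    keep_ambiguous: bool = False,
) -> pd.DataFrame:
    """Assemble classified ROIs into the cell table.

    Quantification uses conclusively identified cells only; ambiguous ROIs
    can be retained (flagged) for audit with ``keep_ambiguous``.  ``fov_meta``
    supplies sample_id / fov_id / site / tissue annotations.
    """
    meta = fov_meta or {}
    rows = []
    for roi in rois:
        if not roi.conclusive and not keep_ambiguous:
            continue
        row = {
            "sample_id": meta.get("sample_id", ""),
            "fov_id": meta.get("fov_id", ""),
            "roi_id": roi.roi_id,
            "taxon": roi.assigned_taxon,
            "area_um2": roi.area_um2,
            "centroid_x_um": roi.centroid_um[0],
            "centroid_y_um": roi.centroid_um[1],
            "conclusive": roi.conclusive,
        }
        for dye, value in roi.mean_intensity.items():
            row[f"mean_{dye}"] = value
        for key in ("site", "tissue"):
            if key in meta:
                row[key] = meta[key]
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=CELL_TABLE_COLUMNS)
    return pd.DataFrame(rows)
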