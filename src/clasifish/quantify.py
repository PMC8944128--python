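"""Summary statistics over cell tables: counts, areas, densities, ratios,
relative abundance, z-stratified abundance, and biofilm thickness.

Densities are cells/cm^2 over the physical field of view; site/tissue ratios
are quotients of unrounded group mean counts, rounded to the nearest integer
at the end.  Relative abundance uses conclusively identified cells only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as C

__all__ = [
    "FOVGeometry",
    "ThicknessProfile",
    "density_per_cm2",
    "group_summary",
    "count_ratio",
    "relative_abundance",
    "z_profile",
    "thickness_profile",
]


@dataclass(frozen=True)
class FOVGeometry:
    """Physical field-of-view geometry; area in cm^2 derived exactly."""

    side_um: float = C.FOV_SIDE_UM
    px: int = C.FOV_SIDE_PX

    def __post_init__(self) -> None:
        if self.side_um <= 0:
            raise ValueError("FOV side must be > 0")

    @property
    def area_cm2(self) -> float:
        return (self.side_um * 1e-4) ** 2

    @property
    def pixel_size_um(self) -> float:
        return self.side_um / self.px


@dataclass
class ThicknessProfile:
    """Per-column biofilm thickness along a cross-section, in um."""

    thickness_um: np.ndarray
    max_um: float
    modal_bin_um: tuple[float, float]  # [lo, hi) of the most common 1-um bin


def density_per_cm2(mean_count: float, geom: FOVGeometry = FOVGeometry()) -> float:
    """Cells per cm^2 from a mean per-image count over the FOV area."""
    if mean_count < 0:
        raise ValueError("mean_count must be >= 0")
    return mean_count / geom.area_cm2


def count_ratio(mean_a: float, mean_b: float) -> int:
    """Ratio of two group mean counts, rounded to the nearest integer."""
    if mean_b <= 0:
        raise ValueError("denominator mean must be > 0")
    return int(round(mean_a / mean_b))


def group_summary(
    cells: pd.DataFrame,
    geom: FOVGeometry = FOVGeometry(),
    group_col: str = "site",
    ratio_pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per (group x taxon) mean/SD per-FOV count, mean area and density.

    Counts are computed per FOV (``fov_id``) first, then averaged within the
    group; SD is the sample SD (n-1) across FOVs.  ``ratio_pairs`` adds
    ``ratio_<a>_to_<b>`` columns with the integer-rounded quotient of the
    two groups' unrounded mean counts.
    """
    required = {group_col, "fov_id", "taxon", "area_um2"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    work = cells[cells.get("conclusive", True) == True]  # noqa: E712
    rows = []
    for (group, taxon), sub in work.groupby([group_col, "taxon"]):
        fovs = work[work[group_col] == group]["fov_id"].unique()
        per_fov = sub.groupby("fov_id").size().reindex(fovs, fill_value=0)
        mean_count = float(per_fov.mean())
        rows.append(
            {
                group_col: group,
                "taxon": taxon,
                "n_fov": len(fovs),
                "mean_count": mean_count,
                "sd_count": float(per_fov.std(ddof=1)) if len(fovs) > 1 else np.nan,
                "mean_area_um2": float(sub["area_um2"].mean()),
                "cells_per_cm2": density_per_cm2(mean_count, geom),
            }
        )
    report = pd.DataFrame(rows)
    if ratio_pairs:
        for a, b in ratio_pairs:
            col = f"ratio_{a}_to_{b}"
            values = []
            for _, row in report.iterrows():
                sel_a = report[(report[group_col] == a) & (report.taxon == row.taxon)]
                sel_b = report[(report[group_col] == b) & (report.taxon == row.taxon)]
                if row[group_col] == a and not sel_b.empty and sel_b.mean_count.iloc[0] > 0:
                    values.append(
                        count_ratio(row.mean_count, sel_b.mean_count.iloc[0])
                    )
                else:
                    values.append(np.nan)
            report[col] = values
    return report


def relative_abundance(cells: pd.DataFrame, per: str = "sample_id") -> pd.DataFrame:
    """Per-taxon fraction of conclusive cells within each sample.

    Fractions sum to 1 per sample; a sample with zero conclusive cells is
    flagged (NaN fractions) rather than silently dropped.
    """
    work = cells[cells.get("conclusive", True) == True]  # noqa: E712
    if work.empty:
        raise ValueError("no conclusive cells: relative abundance undefined")
    counts = work.groupby([per, "taxon"]).size().rename("count").reset_index()
    totals = counts.groupby(per)["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts


def z_profile(
    plane_tables: list[pd.DataFrame], near_index: int, far_index: int
) -> pd.DataFrame:
    """Per-taxon counts/fractions at a near-surface and a far plane.

    ``plane_tables`` is ordered by distance from the host surface.  Returns a
    table with per-taxon counts and fractions at the two selected planes and
    the near-to-far change in fraction.
    """
    n = len(plane_tables)
    if not (0 <= near_index < n and 0 <= far_index < n):
        raise IndexError("plane index out of range")
    out = []
    for name, idx in (("near", near_index), ("far", far_index)):
        table = plane_tables[idx]
        work = table[table.get("conclusive", True) == True]  # noqa: E712
        counts = work.groupby("taxon").size()
        total = counts.sum()
        for taxon, cnt in counts.items():
            out.append(
                {
                    "plane": name,
                    "taxon": taxon,
                    "count": int(cnt),
                    "fraction": cnt / total if total else np.nan,
                }
            )
    df = pd.DataFrame(out, columns=["plane", "taxon", "count", "fraction"])
    wide = df.pivot(index="taxon", columns="plane", values="fraction").fillna(0.0)
    for col in ("near", "far"):
        if col not in wide:
            wide[col] = 0.0
    wide["fraction_change"] = wide["far"] - wide["near"]
    return df.merge(
        wide["fraction_change"].reset_index(), on="taxon", how="left"
    )


def thickness_profile(
    biofilm_mask: np.ndarray, pixel_um: float
) -> ThicknessProfile:
    """Column-wise biofilm thickness of a binary cross-section mask.

    The host surface must run along the column axis; thickness per column is
    the biofilm pixel count times the pixel size.  The summary reports the
    maximum and the most common 1-um thickness bin.  An empty mask is valid
    (zero-thickness regions occur) and yields an all-zero profile.
    """
    biofilm_mask = np.asarray(biofilm_mask, dtype=bool)
    if biofilm_mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    thickness = biofilm_mask.sum(axis=0) * pixel_um
    max_um = float(thickness.max()) if thickness.size else 0.0
    edges = np.arange(0.0, max(max_um, 1.0) + 1.0, 1.0)
    hist, _ = np.histogram(thickness, bins=edges)
    k = int(np.argmax(hist))
    return ThicknessProfile(
        thickness_um=thickness,
        max_um=max_um,
        modal_bin_um=(float(edges[k]), float(edges[k + 1])),
    )
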