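"""File I/O: multi-page TIFF stacks with sidecar metadata, masks, tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .segment import LabelImage
from .synth import SpectralImage
from .unmix import ChannelStack

__all__ = [
    "write_spectral_tiff",
    "read_spectral_tiff",
    "write_channel_stack",
    "read_channel_stack",
    "write_label_tiff",
    "read_label_tiff",
    "write_mask_tiff",
    "read_mask_tiff",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_spectral_tiff(image: SpectralImage, path) -> None:
    """Spectral stack as one TIFF page per bin, pixel size in a sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(image.data, 2, 0))
    _sidecar(path).write_text(
        json.dumps(
            {"pixel_size_um": image.pixel_size_um, "n_bins": image.n_bins}
        )
    )


def read_spectral_tiff(path) -> SpectralImage:
    path = Path(path)
    data = np.moveaxis(tifffile.imread(path), 0, 2)
    meta = json.loads(_sidecar(path).read_text())
    return SpectralImage(data=data, pixel_size_um=meta["pixel_size_um"])


def write_channel_stack(stack: ChannelStack, path) -> None:
    """Unmixed dye channels as float TIFF pages (dye order in the sidecar)."""
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(stack.abundances.astype(np.float32), 2, 0))
    _sidecar(path).write_text(
        json.dumps({"dyes": stack.dyes, "pixel_size_um": stack.pixel_size_um})
    )


def read_channel_stack(path) -> ChannelStack:
    path = Path(path)
    data = np.moveaxis(tifffile.imread(path), 0, 2).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return ChannelStack(
        abundances=data,
        dyes=meta["dyes"],
        residual=np.zeros(data.shape[:2]),
        pixel_size_um=meta["pixel_size_um"],
    )


def write_label_tiff(labels: LabelImage, path) -> None:
    if labels.n_labels > 65535:
        raise ValueError("too many labels for 16-bit TIFF")
    path = Path(path)
    tifffile.imwrite(path, labels.labels.astype(np.uint16))
    _sidecar(path).write_text(json.dumps({"pixel_size_um": labels.pixel_size_um}))


def read_label_tiff(path) -> LabelImage:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return LabelImage(
        labels=tifffile.imread(path).astype(np.int32),
        pixel_size_um=meta["pixel_size_um"],
    )


def write_mask_tiff(mask: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), np.asarray(mask, dtype=bool).astype(np.uint8))


def read_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0
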