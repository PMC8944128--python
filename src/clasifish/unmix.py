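"""Linear spectral unmixing of lambda-mode confocal stacks.

A spectral image records, at every pixel, the emission intensity in B
wavelength bins under simultaneous multi-laser excitation.  With F dyes whose
normalized emission spectra form the rows of a reference matrix S (F x B), the
pixel spectrum y is modeled as y = a @ S + background, and unmixing recovers
the per-dye abundances a >= 0 by (non-negative) least squares per pixel.
Reference spectra are measured from single-dye control images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = ["ReferenceSpectra", "ChannelStack", "fit_reference_spectra", "unmix"]


@dataclass
class ReferenceSpectra:
    """Dye x spectral-bin matrix of emission weights, rows normalized to 1."""

    matrix: np.ndarray
    dyes: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.dyes):
            raise ValueError("matrix must be (n_dyes, n_bins)")
        if np.any(self.matrix < 0):
            raise ValueError("reference spectra must be non-negative")
        sums = self.matrix.sum(axis=1)
        if np.any(sums <= 0):
            bad = [d for d, s in zip(self.dyes, sums) if s <= 0]
            raise ValueError(f"all-zero spectrum for dye(s): {bad}")
        self.matrix = self.matrix / sums[:, None]
        for i in range(len(self.dyes)):
            for j in range(i + 1, len(self.dyes)):
                if np.allclose(self.matrix[i], self.matrix[j]):
                    raise ValueError(
                        f"identical spectra for {self.dyes[i]} and {self.dyes[j]}"
                    )

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def subset(self, dyes: list[str]) -> "ReferenceSpectra":
        idx = [self.dyes.index(d) for d in dyes]
        return ReferenceSpectra(self.matrix[idx], list(dyes))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.dyes).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ReferenceSpectra":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(float), list(df.index))


@dataclass
class ChannelStack:
    """Per-dye abundance images (H x W x F) plus the unmixing residual map."""

    abundances: np.ndarray
    dyes: list[str]
    residual: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if self.abundances.ndim != 3 or self.abundances.shape[2] != len(self.dyes):
            raise ValueError("abundances must be (H, W, n_dyes)")
        if self.residual.shape != self.abundances.shape[:2]:
            raise ValueError("residual map shape mismatch")

    def channel(self, dye: str) -> np.ndarray:
        return self.abundances[:, :, self.dyes.index(dye)]


def fit_reference_spectra(
    single_dye_images: list[tuple[str, np.ndarray]],
    brightness_quantile: float = 0.99,
) -> ReferenceSpectra:
    """Estimate each dye's emission spectrum from a single-dye control image.

    The spectrum is the mean over the brightest pixels (total intensity above
    ``brightness_quantile``), after subtracting the per-bin 5th percentile as
    a background estimate, then normalized to unit sum.
    """
    if not 0.0 < brightness_quantile < 1.0:
        raise ValueError("brightness_quantile must be in (0, 1)")
    dyes, rows = [], []
    for dye, img in single_dye_images:
        img = np.asarray(img, dtype=float)
        if img.ndim != 3:
            raise ValueError(f"{dye}: expected H x W x B spectral image")
        if not np.any(img > 0):
            raise ValueError(f"{dye}: image contains no signal")
        background = np.percentile(img, 5, axis=(0, 1))
        total = img.sum(axis=2)
        cutoff = np.quantile(total, brightness_quantile)
        bright = img[total >= cutoff]
        spectrum = np.clip(bright.mean(axis=0) - background, 0.0, None)
        if spectrum.sum() <= 0:
            raise ValueError(f"{dye}: no signal above background")
        dyes.append(dye)
        rows.append(spectrum)
    return ReferenceSpectra(np.stack(rows), dyes)


def unmix(
    image: np.ndarray,
    spectra: ReferenceSpectra,
    nonneg: bool = True,
    pixel_size_um: float = 1.0,
) -> ChannelStack:
    """Per-pixel least-squares unmixing of an H x W x B stack into dye channels.

    With ``nonneg`` (the default) abundances are constrained to be physical
    (>= 0) via NNLS; plain least squares is available for parity testing.
    A vectorized unconstrained solve handles every pixel first; only pixels
    whose unconstrained solution goes negative are re-solved with NNLS.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise ValueError("image must be H x W x B")
    H, W, B = image.shape
    if B != spectra.n_bins:
        raise ValueError(
            f"image has {B} spectral bins but spectra have {spectra.n_bins}"
        )
    S = spectra.matrix  # (F, B)
    if np.linalg.matrix_rank(S) < S.shape[0]:
        raise ValueError("reference spectra matrix is rank-deficient")
    Y = image.reshape(-1, B)
    # unconstrained LS: a = y @ pinv(S)  (solution of min ||a S - y||)
    A = Y @ np.linalg.pinv(S)
    if nonneg:
        neg = np.any(A < -1e-10 * max(1.0, float(np.abs(A).max())), axis=1)
        if np.any(neg):
            ST = S.T
            for i in np.flatnonzero(neg):
                A[i], _ = nnls(ST, Y[i])
        A = np.clip(A, 0.0, None)
    resid = np.linalg.norm(A @ S - Y, axis=1).reshape(H, W)
    return ChannelStack(
        abundances=A.reshape(H, W, S.shape[0]),
        dyes=list(spectra.dyes),
        residual=resid,
        pixel_size_um=pixel_size_um,
    )
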