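"""aCompCor nuisance modelling: Gaussian mask erosion and per-tissue
principal components from WM and CSF time series."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = ["NuisanceSet", "erode_mask", "acompcor"]


@dataclass
class NuisanceSet:
    """aCompCor components plus (optional) motion parameters.

    ``matrix`` concatenates motion then components — 16 columns at the
    default 6-motion + 2x5-component configuration.
    """

    components: np.ndarray       # (t, <=10): WM then CSF components
    component_names: list
    motion: np.ndarray | None = None   # (t, 6)
    motion_names: tuple = ("trans_x", "trans_y", "trans_z",
                           "rot_x", "rot_y", "rot_z")

    def __post_init__(self):
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape != (self.components.shape[0], 6):
                raise ValueError("motion must be (t, 6)")

    @property
    def names(self) -> list:
        names = list(self.motion_names) if self.motion is not None else []
        return names + list(self.component_names)

    @property
    def matrix(self) -> np.ndarray:
        if self.motion is None:
            return self.components
        return np.column_stack([self.motion, self.components])

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def with_motion(self, motion: np.ndarray) -> "NuisanceSet":
        return NuisanceSet(components=self.components,
                           component_names=self.component_names,
                           motion=motion)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


def erode_mask(
    mask: np.ndarray,
    sigma_mm: float = 0.8,
    threshold: float = 0.9,
    voxel_mm: float = 0.8,
) -> np.ndarray:
    """Erode a binary mask by Gaussian smoothing and re-binarization.

    The mask is smoothed with sigma = ``sigma_mm / voxel_mm`` voxels and
    kept where the smoothed value >= ``threshold``; the result is
    intersected with the input so erosion never grows the mask. A
    ``threshold`` of 0 returns the input unchanged.
    """
    mask = np.asarray(mask)
    if not np.isin(mask, [0, 1]).all():
        raise ValueError("mask must be binary")
    mask = mask.astype(bool)
    if threshold <= 0:
        return mask.copy()
    smoothed = ndimage.gaussian_filter(mask.astype(float), sigma=sigma_mm / voxel_mm)
    out = (smoothed >= threshold) & mask
    if not out.any():
        warnings.warn("erosion produced an empty mask")
    return out


def acompcor(
    series,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    n_per_tissue: int = 5,
    detrend: bool = True,
    standardize: bool = True,
) -> NuisanceSet:
    """Top principal components of WM and CSF voxel time series.

    Per tissue, voxel time series are linearly detrended and (by default)
    variance-normalized; the leading ``n_per_tissue`` left singular vectors
    of the time-by-voxel matrix are returned as unit-variance columns with
    non-negative skew. Rank-deficient tissues yield fewer components with a
    warning.
    """
    comps, names = [], []
    for tissue, mask in (("wm", wm_mask), ("csf", csf_mask)):
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"{tissue} mask is empty")
        c = _tissue_components(series.data[mask].T, n_per_tissue, detrend,
                               standardize, tissue)
        comps.append(c)
        names.extend(f"a_comp_cor_{tissue}_{i:02d}" for i in range(c.shape[1]))
    return NuisanceSet(components=np.column_stack(comps), component_names=names)


def _tissue_components(y, n_components, detrend, standardize, tissue):
    """SVD-based PCA of a (t, v) tissue matrix."""
    n_t, n_v = y.shape
    y = y - y.mean(axis=0)
    if detrend:
        t = np.arange(n_t, dtype=float)
        t = (t - t.mean()) / np.sqrt(np.sum((t - t.mean()) ** 2))
        y = y - np.outer(t, t @ y)
    if standardize:
        sd = y.std(axis=0)
        keep = sd > 0
        y = y[:, keep] / sd[keep]
        if y.shape[1] == 0:
            raise ValueError(f"{tissue} mask has no voxels with variance")
    u, s, _ = np.linalg.svd(y, full_matrices=False)
    tol = s.max() * max(y.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    n_keep = min(n_components, rank)
    if n_keep < n_components:
        warnings.warn(
            f"{tissue} data rank {rank} < requested {n_components} components;"
            f" returning {n_keep}"
        )
    out = np.empty((n_t, n_keep))
    for i in range(n_keep):
        c = u[:, i]
        c = c / c.std()
        if stats.skew(c) < 0:
            c = -c
        out[:, i] = c
    return out
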