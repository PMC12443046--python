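"""Depth-dependent sampling across hippocampal subfields.

Per vertex, 20 equidistant bins are laid on the straight segment through the
corresponding inner and outer surface points, validated against the
mid-thickness anchor; in Sub, CA1 and CA2 the line is extended by 10 further
bins beyond the inner surface (SRLM) at the same spacing. Bin 1 is the
deepest extension point, bin 11 the inner surface, bin 30 the outer surface.
DG/CA4 vertices are never sampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import (
    EXTENDED_SUBFIELDS,
    INNER_BIN,
    LABEL_CODES,
    N_DEPTH_BINS,
    N_TOTAL_BINS,
    SUBFIELD_CODES,
)

__all__ = ["DepthBins", "DepthProfileSet", "compute_depth_bins",
           "sample_profiles", "ztransform_profiles", "laminar_glm",
           "LaminarContrast"]

SAMPLED_SUBFIELDS = ("Sub", "CA1", "CA2", "CA3")


@dataclass
class DepthBins:
    """Per-vertex bin coordinates (world mm), NaN where a bin is absent."""

    coords: np.ndarray              # (V, 30, 3)
    valid_vertex: np.ndarray        # (V,) bool
    subfield_of_vertex: np.ndarray  # (V,) codes
    anchor: np.ndarray              # (V, 3) mid-thickness points
    spacing_mm: np.ndarray          # (V,) bin spacing along the segment
    n_excluded: int
    flipped: bool = False           # inner/outer order auto-corrected

    def vertices_of(self, subfield: str) -> np.ndarray:
        code = SUBFIELD_CODES[subfield]
        return np.flatnonzero(self.valid_vertex & (self.subfield_of_vertex == code))


def _srlm_side_score(points_mm, label_volume, affine):
    """Fraction of sample points landing on SRLM labels."""
    vox = np.linalg.inv(affine)[:3, :3] @ points_mm.T + np.linalg.inv(affine)[:3, 3:4]
    vals = ndimage.map_coordinates(
        (label_volume == LABEL_CODES["SRLM"]).astype(float), vox,
        order=0, mode="constant", cval=0.0,
    )
    return float(vals.mean())


def compute_depth_bins(
    surfaces: dict,
    subfield_of_vertex: np.ndarray,
    label_volume: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    anchor_tol_frac: float = 0.25,
) -> DepthBins:
    """Lay equidistant sample points along inner->outer vertex segments.

    Vertices whose mid-thickness point is not on the segment (within
    ``anchor_tol_frac`` of its length) and degenerate segments are flagged
    and excluded. If ``label_volume`` is given, inner/outer orientation is
    auto-detected from which side of the ribbon the SRLM lies on, so
    swapping the surface inputs does not change the output.
    """
    inner = np.asarray(surfaces["inner"], dtype=float)
    mid = np.asarray(surfaces["mid"], dtype=float)
    outer = np.asarray(surfaces["outer"], dtype=float)
    if not (inner.shape == mid.shape == outer.shape):
        raise ValueError("surfaces must have identical vertex counts")
    subfield_of_vertex = np.asarray(subfield_of_vertex)
    n_v = inner.shape[0]
    if subfield_of_vertex.shape[0] != n_v:
        raise ValueError("subfield_of_vertex length must match vertex count")

    flipped = False
    if label_volume is not None and affine is not None:
        # probe one spacing beyond each candidate inner surface: the SRLM
        # band must lie beyond the true inner surface
        d = outer - inner
        probe_in = inner - d / (N_DEPTH_BINS - 1)
        probe_out = outer + d / (N_DEPTH_BINS - 1)
        if _srlm_side_score(probe_out, label_volume, affine) > _srlm_side_score(
            probe_in, label_volume, affine
        ):
            inner, outer = outer, inner
            flipped = True

    d = outer - inner
    length = np.linalg.norm(d, axis=1)
    degenerate = length < 1e-9

    # anchor check: mid must lie on the segment near its midpoint
    midpoint = (inner + outer) / 2.0
    off = np.linalg.norm(mid - midpoint, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        bad_anchor = off > anchor_tol_frac * np.where(degenerate, np.inf, length)
    excluded = degenerate | bad_anchor
    is_dg = subfield_of_vertex == SUBFIELD_CODES["DG_CA4"]
    valid = ~excluded & ~is_dg
    if degenerate.any() or bad_anchor.any():
        warnings.warn(
            f"excluded {int(degenerate.sum())} degenerate and "
            f"{int(bad_anchor.sum())} anchor-failing vertices"
        )

    step = d / (N_DEPTH_BINS - 1)
    offsets = np.arange(1, N_TOTAL_BINS + 1) - INNER_BIN  # -10 .. +19
    coords = inner[:, None, :] + offsets[None, :, None] * step[:, None, :]

    ext_codes = [SUBFIELD_CODES[s] for s in EXTENDED_SUBFIELDS]
    no_ext = ~np.isin(subfield_of_vertex, ext_codes)
    coords[no_ext, : INNER_BIN - 1, :] = np.nan
    coords[~valid] = np.nan

    return DepthBins(
        coords=coords,
        valid_vertex=valid,
        subfield_of_vertex=subfield_of_vertex,
        anchor=mid,
        spacing_mm=np.linalg.norm(step, axis=1),
        n_excluded=int(excluded.sum()),
        flipped=flipped,
    )


@dataclass
class DepthProfileSet:
    """Per-subfield depth x (time or statistic) arrays.

    Rows follow the 1..30 bin convention; absent bins (1..10 for CA3) are
    NaN. DG/CA4 never appears.
    """

    profiles: dict                 # subfield -> (30, T) or (30,)
    sem: dict                      # subfield -> same shape, across vertices
    n_vertices: dict
    contrast: str = ""
    timestamp_ms: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def subfields(self):
        return list(self.profiles)

    def n_bins(self, subfield: str) -> int:
        return N_TOTAL_BINS if subfield in EXTENDED_SUBFIELDS else N_DEPTH_BINS


def sample_profiles(
    volume: np.ndarray,
    bins: DepthBins,
    affine: np.ndarray,
    contrast: str = "",
    timestamp_ms=None,
) -> DepthProfileSet:
    """Trilinear sampling of a 3D or 4D volume at the depth-bin coordinates,
    averaged over each subfield's vertices per depth.

    Out-of-bounds samples are flagged (NaN) and excluded from the averages;
    it is an error for every vertex to fall out of bounds.
    """
    volume = np.asarray(volume, dtype=float)
    is_4d = volume.ndim == 4
    inv = np.linalg.inv(affine)

    profiles, sems, n_vertices = {}, {}, {}
    any_in_bounds = False
    for sf in SAMPLED_SUBFIELDS:
        verts = bins.vertices_of(sf)
        if verts.size == 0:
            continue
        pts = bins.coords[verts]  # (v, 30, 3)
        finite = np.isfinite(pts[..., 0])
        vox = np.einsum("ij,vbj->vbi", inv[:3, :3], np.nan_to_num(pts)) + inv[:3, 3]
        coords = vox[finite].T  # (3, n)

        def _sample(vol3d):
            out = np.full(pts.shape[:2], np.nan)
            out[finite] = ndimage.map_coordinates(
                vol3d, coords, order=1, mode="constant", cval=np.nan
            )
            return out

        if is_4d:
            stack = np.stack([_sample(volume[..., t]) for t in range(volume.shape[-1])],
                             axis=-1)  # (v, 30, T)
        else:
            stack = _sample(volume)  # (v, 30)

        if np.isfinite(stack).any():
            any_in_bounds = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            prof = np.nanmean(stack, axis=0)
            sd = np.nanstd(stack, axis=0, ddof=1)
            n_ok = np.sum(np.isfinite(stack), axis=0)
        sem = np.where(n_ok > 1, sd / np.sqrt(np.maximum(n_ok, 1)), np.nan)
        profiles[sf] = prof
        sems[sf] = sem
        n_vertices[sf] = int(verts.size)

    if not any_in_bounds:
        raise ValueError("all depth-bin samples fall outside the volume")
    return DepthProfileSet(
        profiles=profiles,
        sem=sems,
        n_vertices=n_vertices,
        contrast=contrast,
        timestamp_ms=None if timestamp_ms is None else np.asarray(timestamp_ms, float),
        provenance={"interpolation": "trilinear", "flipped": bins.flipped,
                    "n_excluded_vertices": bins.n_excluded},
    )


def ztransform_profiles(
    pset: DepthProfileSet,
    design,
    tr_image_ms: float,
    delay_s: float = 0.0,
) -> DepthProfileSet:
    """Standardize each depth's time course by its math-trial baseline.

    Baseline volumes are those whose acquisition midpoint falls within
    ``[onset + delay_s, onset + duration + delay_s]`` of a math trial.
    Depths with zero baseline SD are flagged (NaN).
    """
    if pset.timestamp_ms is None:
        raise ValueError("profile set carries no timestamps")
    mid_s = (pset.timestamp_ms + tr_image_ms / 2.0) / 1000.0
    baseline = np.zeros(mid_s.size, dtype=bool)
    for onset, dur in design.trials("math"):
        baseline |= (mid_s >= onset + delay_s) & (mid_s <= onset + dur + delay_s)
    if baseline.sum() < 2:
        raise ValueError("fewer than 2 math-baseline volumes")

    profiles, sems = {}, {}
    for sf, prof in pset.profiles.items():
        mu = prof[:, baseline].mean(axis=1, keepdims=True)
        sd = prof[:, baseline].std(axis=1, ddof=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, (prof - mu) / sd, np.nan)
        profiles[sf] = z
        sems[sf] = np.full_like(z, np.nan)
    prov = dict(pset.provenance)
    prov["ztransform"] = {"delay_s": delay_s,
                          "baseline_indices": np.flatnonzero(baseline).tolist()}
    return DepthProfileSet(
        profiles=profiles, sem=sems, n_vertices=dict(pset.n_vertices),
        contrast=pset.contrast, timestamp_ms=pset.timestamp_ms, provenance=prov,
    )


@dataclass
class LaminarContrast:
    """Depth-wise memory-minus-math contrast per subfield."""

    contrast: dict   # subfield -> (30,)
    sem: dict        # across runs (NaN for a single run)
    baseline: dict   # constant-column beta per depth (for fractional units)
    negated_for_vaso: bool
    n_runs: int = 1


def laminar_glm(profile_sets, X) -> LaminarContrast:
    """OLS per depth bin; memory - math contrast per depth.

    ``profile_sets`` is one DepthProfileSet or a list (runs): run-level
    contrasts are averaged with SEM across runs. For ``vaso_corrected``
    profiles the contrast is negated before reporting.
    """
    if not isinstance(profile_sets, (list, tuple)):
        profile_sets = [profile_sets]
    pinv = np.linalg.pinv(X.matrix)
    c = np.zeros(X.n_columns)
    c[X.task_columns["memory"]] = 1.0
    if "math" in X.task_columns:
        c[X.task_columns["math"]] = -1.0
    i_const = X.names.index("constant")

    per_run, per_run_base = [], []
    negated = False
    for pset in profile_sets:
        if next(iter(pset.profiles.values())).shape[-1] != X.matrix.shape[0]:
            raise ValueError("profile time dimension does not match design rows")
        negated = pset.contrast == "vaso_corrected"
        run_c, run_b = {}, {}
        for sf, prof in pset.profiles.items():
            beta = pinv @ np.nan_to_num(prof.T)  # (p, 30); NaN depths -> 0
            con = c @ beta
            absent = ~np.isfinite(prof).any(axis=1)
            con[absent] = np.nan
            if negated:
                con = -con
            run_c[sf] = con
            base = beta[i_const].copy()
            base[absent] = np.nan
            run_b[sf] = base
        per_run.append(run_c)
        per_run_base.append(run_b)

    subfields = per_run[0].keys()
    n_runs = len(per_run)
    contrast, sem, baseline = {}, {}, {}
    for sf in subfields:
        stack = np.stack([r[sf] for r in per_run])
        contrast[sf] = stack.mean(axis=0)
        sem[sf] = (stack.std(axis=0, ddof=1) / np.sqrt(n_runs)
                   if n_runs > 1 else np.full(stack.shape[1], np.nan))
        baseline[sf] = np.stack([r[sf] for r in per_run_base]).mean(axis=0)
    return LaminarContrast(contrast=contrast, sem=sem, baseline=baseline,
                           negated_for_vaso=negated, n_runs=n_runs)
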