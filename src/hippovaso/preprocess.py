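"""Demultiplexing of interleaved series, steady-state trimming, slice
cropping, and BOLD-contamination correction by pairwise dynamic division."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ContrastSeries", "demultiplex", "interleave", "trim",
           "crop_slices", "bold_correct"]

CONTRASTS = ("nulled", "notnulled", "vaso_corrected", "bold")


@dataclass
class ContrastSeries:
    """Single-contrast 4D series with per-volume timestamps and provenance."""

    data: np.ndarray
    contrast: str
    timestamp_ms: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")
        self.timestamp_ms = np.asarray(self.timestamp_ms, dtype=float)
        if self.data.shape[-1] != self.timestamp_ms.size:
            raise ValueError("time dimension must match timestamps")
        if self.timestamp_ms.size > 1 and np.any(np.diff(self.timestamp_ms) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]


def demultiplex(series):
    """Split an interleaved series into (nulled, notnulled) halves.

    Requires strictly alternating tags starting with ``nulled`` and an even
    volume count; each output keeps its volumes' original timestamps.
    """
    tags = list(series.contrast_tag)
    n = len(tags)
    if n % 2:
        raise ValueError("interleaved series must have an even volume count")
    expected = ["nulled", "notnulled"] * (n // 2)
    if tags != expected:
        raise ValueError("contrast tags must strictly alternate nulled/notnulled")
    ts = np.asarray(series.timestamp_ms, dtype=float)
    nulled = ContrastSeries(
        data=series.data[..., 0::2].copy(),
        contrast="nulled",
        timestamp_ms=ts[0::2],
        provenance={"source": "demultiplex", "n_input_volumes": n},
    )
    notnulled = ContrastSeries(
        data=series.data[..., 1::2].copy(),
        contrast="notnulled",
        timestamp_ms=ts[1::2],
        provenance={"source": "demultiplex", "n_input_volumes": n},
    )
    return nulled, notnulled


def interleave(nulled: ContrastSeries, notnulled: ContrastSeries):
    """Inverse of :func:`demultiplex`: re-zip the two contrasts.

    Returns (data, tags, timestamps) in acquisition order.
    """
    if nulled.n_volumes != notnulled.n_volumes:
        raise ValueError("contrast series lengths differ")
    n = nulled.n_volumes
    data = np.empty(nulled.data.shape[:3] + (2 * n,), dtype=nulled.data.dtype)
    data[..., 0::2] = nulled.data
    data[..., 1::2] = notnulled.data
    ts = np.empty(2 * n)
    ts[0::2] = nulled.timestamp_ms
    ts[1::2] = notnulled.timestamp_ms
    return data, ["nulled", "notnulled"] * n, ts


def trim(series: ContrastSeries, n_head: int = 2, n_tail: int = 2) -> ContrastSeries:
    """Discard the first ``n_head`` and last ``n_tail`` volumes."""
    if n_head < 0 or n_tail < 0:
        raise ValueError("trim counts must be non-negative")
    if n_head + n_tail >= series.n_volumes:
        raise ValueError(
            f"cannot trim {n_head}+{n_tail} volumes from a "
            f"{series.n_volumes}-volume series"
        )
    stop = series.n_volumes - n_tail
    prov = dict(series.provenance)
    prov["n_discarded_head"] = prov.get("n_discarded_head", 0) + n_head
    prov["n_discarded_tail"] = prov.get("n_discarded_tail", 0) + n_tail
    return ContrastSeries(
        data=series.data[..., n_head:stop].copy(),
        contrast=series.contrast,
        timestamp_ms=series.timestamp_ms[n_head:stop],
        provenance=prov,
    )


def crop_slices(series: ContrastSeries, n_edge: int = 0, axis: int = 2) -> ContrastSeries:
    """Remove ``n_edge`` slices from each end of a spatial axis.

    Generic stand-in for discarding distorted slab-edge slices; default 0.
    """
    if n_edge == 0:
        return series
    if axis not in (0, 1, 2):
        raise ValueError("axis must be spatial (0, 1 or 2)")
    if 2 * n_edge >= series.data.shape[axis]:
        raise ValueError("cropping would remove all slices")
    sl = [slice(None)] * 4
    sl[axis] = slice(n_edge, series.data.shape[axis] - n_edge)
    prov = dict(series.provenance)
    prov["n_cropped_slices"] = {"axis": axis, "per_edge": n_edge}
    return ContrastSeries(
        data=series.data[tuple(sl)].copy(),
        contrast=series.contrast,
        timestamp_ms=series.timestamp_ms,
        provenance=prov,
    )


def bold_correct(
    nulled: ContrastSeries,
    notnulled: ContrastSeries,
    clip_range=(0.0, 5.0),
    denom_tol: float = 1e-6,
) -> ContrastSeries:
    """BOLD-contamination correction by pairwise dynamic division.

    vaso[k] = nulled[k] / notnulled[k] voxel-wise on the k-th pair, with no
    temporal interpolation. Near-zero denominators yield the fill value 0
    and are flagged in provenance; outputs are clipped to ``clip_range``.
    The output inherits the nulled series' timestamps.
    """
    if nulled.n_volumes != notnulled.n_volumes:
        raise ValueError("nulled and notnulled series lengths differ")
    lo, hi = clip_range
    denom = notnulled.data
    bad = np.abs(denom) <= denom_tol
    with np.errstate(divide="ignore", invalid="ignore"):
        vaso = np.where(bad, 0.0, nulled.data / np.where(bad, 1.0, denom))
    n_clipped = int(np.sum((vaso < lo) | (vaso > hi)))
    vaso = np.clip(vaso, lo, hi)
    prov = {
        "source": "bold_correct",
        "clip_range": [float(lo), float(hi)],
        "n_bad_denominator": int(bad.sum()),
        "n_clipped": max(n_clipped, 0),
        "n_discarded_head": nulled.provenance.get("n_discarded_head", 0),
        "n_discarded_tail": nulled.provenance.get("n_discarded_tail", 0),
    }
    return ContrastSeries(
        data=vaso,
        contrast="vaso_corrected",
        timestamp_ms=nulled.timestamp_ms.copy(),
        provenance=prov,
    )
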