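"""Voxel-wise GLM: canonical HRF, design construction, OLS fitting,
cluster-extent thresholding and subfield summaries.

The fitting is plain OLS (no prewhitening). High-pass filtering is done by
including a DCT drift basis in the design rather than filtering the data,
so that the model is exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "DesignMatrix",
    "StatMap",
    "canonical_hrf",
    "condition_regressor",
    "dct_basis",
    "build_design",
    "fit_glm",
    "cluster_threshold",
    "subfield_cluster_means",
    "friedman_test",
]

# Double-gamma parameterization: response mode 6 s, undershoot mode 16 s,
# peak-to-undershoot ratio 6, kernel length 32 s.
HRF_PEAK_S = 6.0
HRF_UNDERSHOOT_S = 16.0
HRF_RATIO = 6.0
HRF_LENGTH_S = 32.0


def canonical_hrf(dt_s: float, length_s: float = HRF_LENGTH_S) -> np.ndarray:
    """Sampled canonical double-gamma HRF, peak-normalized to 1.

    Gamma densities with unit scale and modes at 6 s (response) and 16 s
    (undershoot); the undershoot is divided by 6. ``h[0] == 0`` and
    ``max(h) == 1`` near t = 6 s.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    t = np.arange(0.0, length_s + dt_s / 2, dt_s)
    # mode of gamma(a, scale=1) is a - 1
    h = stats.gamma.pdf(t, a=HRF_PEAK_S + 1) - stats.gamma.pdf(
        t, a=HRF_UNDERSHOOT_S + 1
    ) / HRF_RATIO
    return h / h.max()


def condition_regressor(
    events,
    condition: str,
    timestamps_s: np.ndarray,
    dt_s: float = 0.1,
) -> np.ndarray:
    """HRF-convolved boxcar for one condition, sampled at ``timestamps_s``.

    The convolution kernel is area-normalized so a sustained block tends to
    a plateau of 1; event amplitudes are therefore fractional-signal-change
    units. Computed on a fine grid then linearly interpolated.
    """
    timestamps_s = np.asarray(timestamps_s, dtype=float)
    ev = [(o, d) for (o, d, c) in events if c == condition]
    t_end = max(
        timestamps_s.max() if timestamps_s.size else 0.0,
        max((o + d for o, d in ev), default=0.0),
    )
    grid = np.arange(0.0, t_end + HRF_LENGTH_S + dt_s, dt_s)
    box = np.zeros_like(grid)
    for onset, dur in ev:
        box[(grid >= onset) & (grid < onset + dur)] = 1.0
    kernel = canonical_hrf(dt_s)
    conv = np.convolve(box, kernel)[: grid.size] / kernel.sum()
    return np.interp(timestamps_s, grid, conv)


def dct_basis(n_frames: int, frame_times_s: np.ndarray, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift basis (excluding the constant term).

    Returns the k = 1..K columns with period >= ``cutoff_s`` over the scan
    length T, K = floor(2 T / cutoff).
    """
    t = np.asarray(frame_times_s, dtype=float)
    span = t[-1] - t[0]
    if t.size > 1:
        span += np.median(np.diff(t))
    n_k = int(np.floor(2.0 * span / cutoff_s))
    n_k = min(n_k, n_frames - 1)
    frame = np.arange(n_frames)
    cols = [
        np.sqrt(2.0 / n_frames) * np.cos(np.pi * k * (2 * frame + 1) / (2 * n_frames))
        for k in range(1, n_k + 1)
    ]
    if not cols:
        return np.empty((n_frames, 0))
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    """First-level design: task, drift, then nuisance columns."""

    matrix: np.ndarray  # (t, p)
    names: list
    task_columns: dict  # condition -> column index
    hp_cutoff_s: float
    hrf_params: dict = field(
        default_factory=lambda: {
            "peak_s": HRF_PEAK_S,
            "undershoot_s": HRF_UNDERSHOOT_S,
            "ratio": HRF_RATIO,
            "length_s": HRF_LENGTH_S,
        }
    )

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


def build_design(
    design,
    nuisance,
    timestamps_ms: np.ndarray,
    hp_cutoff_s: float = 128.0,
) -> DesignMatrix:
    """Assemble the t x p design matrix.

    Columns: one HRF-convolved boxcar per condition, a constant, a DCT
    drift basis up to ``hp_cutoff_s``, then nuisance columns (mean-centered).
    ``nuisance`` may be None, a NuisanceSet, or a (t, q) array.
    """
    timestamps_s = np.asarray(timestamps_ms, dtype=float) / 1000.0
    n_t = timestamps_s.size
    scan_end = timestamps_s[-1]

    events = list(design.events)
    kept, dropped = [], 0
    for onset, dur, cond in events:
        if onset >= scan_end:
            dropped += 1
            continue
        kept.append((onset, min(dur, scan_end - onset), cond))
    if dropped:
        warnings.warn(f"{dropped} event(s) beyond scan end truncated/dropped")

    conditions = []
    for _, _, cond in kept:
        if cond not in conditions:
            conditions.append(cond)
    if not conditions:
        raise ValueError("no task events fall within the scan")
    cols, names, task_columns = [], [], {}
    for cond in conditions:
        reg = condition_regressor(kept, cond, timestamps_s)
        if not np.any(reg):
            raise ValueError(f"task regressor {cond!r} is all zero")
        task_columns[cond] = len(cols)
        cols.append(reg)
        names.append(cond)

    cols.append(np.ones(n_t))
    names.append("constant")
    drift = dct_basis(n_t, timestamps_s, hp_cutoff_s)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"dct{k + 1}")

    if nuisance is not None:
        if hasattr(nuisance, "matrix"):
            nmat = nuisance.matrix
            nnames = list(nuisance.names)
        else:
            nmat = np.asarray(nuisance, dtype=float)
            nnames = [f"nuisance{i}" for i in range(nmat.shape[1])]
        if nmat.shape[0] != n_t:
            raise ValueError("nuisance rows do not match timestamps")
        for j in range(nmat.shape[1]):
            col = nmat[:, j] - nmat[:, j].mean()
            if not np.any(col):
                raise ValueError(f"nuisance column {nnames[j]!r} is all zero")
            cols.append(col)
            names.append(nnames[j])

    X = np.column_stack(cols)
    return DesignMatrix(matrix=X, names=names, task_columns=task_columns,
                        hp_cutoff_s=hp_cutoff_s)


@dataclass
class StatMap:
    beta: np.ndarray          # (x, y, z, p)
    contrast: np.ndarray      # (x, y, z) memory - math (sign per provenance)
    tmap: np.ndarray          # (x, y, z)
    sigma2: np.ndarray        # residual variance map
    df: int
    mask: np.ndarray
    baseline_mean: np.ndarray  # temporal mean, for percent-signal conversion
    names: list
    provenance: dict


def _ols(Y: np.ndarray, X: np.ndarray):
    """OLS for Y (t, v). Returns beta (p, v), sigma2 (v,), df, XtX_inv."""
    n_t, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the collinear columns for the error message
        _, r = np.linalg.qr(X)
        bad = [i for i in range(p) if abs(r[i, i]) < 1e-10 * abs(r).max()]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"suspect columns {bad}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = n_t - rank
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    return beta, sigma2, df, xtx_inv


def fit_glm(series, X: DesignMatrix, mask: np.ndarray) -> StatMap:
    """Voxel-wise OLS within ``mask``; contrast = beta_memory - beta_math.

    For ``vaso_corrected`` input the contrast (and t) are negated before
    reporting, since a CBV increase lowers the blood-nulled signal; the flip
    is recorded in provenance.
    """
    data = series.data
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if data.shape[-1] != X.matrix.shape[0]:
        raise ValueError("time dimension does not match design rows")
    Y = data[mask].T  # (t, v)
    beta, sigma2, df, xtx_inv = _ols(Y, X.matrix)

    c = np.zeros(X.n_columns)
    if "memory" in X.task_columns:
        c[X.task_columns["memory"]] = 1.0
    if "math" in X.task_columns:
        c[X.task_columns["math"]] = -1.0
    con = c @ beta
    var_c = sigma2 * float(c @ xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(var_c > 0, con / np.sqrt(var_c), 0.0)

    negated = getattr(series, "contrast", "") == "vaso_corrected"
    if negated:
        con = -con
        tvals = -tvals

    shape = data.shape[:3]
    out = StatMap(
        beta=_unmask(beta.T, mask, shape),
        contrast=_unmask3(con, mask, shape),
        tmap=_unmask3(tvals, mask, shape),
        sigma2=_unmask3(sigma2, mask, shape),
        df=df,
        mask=mask,
        baseline_mean=_unmask3(Y.mean(axis=0), mask, shape),
        names=list(X.names),
        provenance={"contrast": "memory-math", "negated_for_vaso": negated,
                    "df": df},
    )
    return out


def _unmask3(vals, mask, shape):
    out = np.full(shape, np.nan)
    out[mask] = vals
    return out


def _unmask(vals, mask, shape):
    out = np.full(shape + (vals.shape[1],), np.nan)
    out[mask] = vals
    return out


# 18-connectivity: faces + edges
_CLUSTER_STRUCTURE = ndimage.generate_binary_structure(3, 2)


def cluster_threshold(
    statmap: StatMap,
    gm_mask: np.ndarray,
    p_unc: float = 0.05,
    k: int = 20,
):
    """Cluster the GM-masked t map at an uncorrected one-sided threshold.

    Suprathreshold voxels are grouped with 18-connectivity; clusters with
    extent < ``k`` are removed. Returns (label volume, table).
    """
    gm_mask = np.asarray(gm_mask, dtype=bool)
    if gm_mask.shape != statmap.tmap.shape:
        raise ValueError("GM mask grid does not match t map")
    if not gm_mask.any():
        raise ValueError("empty GM mask")
    t_crit = stats.t.isf(p_unc, statmap.df)
    supra = (np.nan_to_num(statmap.tmap, nan=-np.inf) > t_crit) & gm_mask
    labels, n = ndimage.label(supra, structure=_CLUSTER_STRUCTURE)
    rows = []
    out = np.zeros_like(labels)
    next_id = 0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    order = np.argsort(sizes)[::-1]
    for idx in order:
        lab = idx + 1
        size = int(sizes[idx])
        if size < k:
            continue
        next_id += 1
        sel = labels == lab
        out[sel] = next_id
        tv = statmap.tmap[sel]
        peak_flat = np.argmax(tv)
        coords = np.argwhere(sel)[peak_flat]
        rows.append(
            {"cluster_id": next_id, "size": size,
             "peak_t": float(tv[peak_flat]),
             "peak_i": int(coords[0]), "peak_j": int(coords[1]),
             "peak_k": int(coords[2])}
        )
    table = pd.DataFrame(
        rows, columns=["cluster_id", "size", "peak_t", "peak_i", "peak_j", "peak_k"]
    )
    return out, table


def subfield_cluster_means(
    statmap: StatMap,
    cluster_labels: np.ndarray,
    label_volume: np.ndarray,
    subfield_codes: dict,
) -> pd.Series:
    """Mean percent signal change over cluster-overlapping subfield voxels.

    Values are contrast / baseline mean x 100 per voxel, averaged within
    cluster-and-subfield overlap. Empty overlap -> NaN (missing, not zero).
    """
    in_cluster = np.asarray(cluster_labels) > 0
    out = {}
    for name, code in subfield_codes.items():
        sel = in_cluster & (np.asarray(label_volume) == code)
        if not sel.any():
            out[name] = np.nan
            continue
        psc = 100.0 * statmap.contrast[sel] / statmap.baseline_mean[sel]
        out[name] = float(np.mean(psc))
    return pd.Series(out, name="mean_percent_signal_change")


def friedman_test(table: np.ndarray):
    """Friedman rank test over a subjects x conditions table.

    Average ranks for ties, with the standard tie correction; df = k - 1.
    Returns (chi2, df, p).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2D (subjects x conditions)")
    n, k = table.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if np.isnan(table).any():
        raise ValueError("missing cells are not allowed")
    ranks = np.apply_along_axis(stats.rankdata, 1, table)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    # tie correction
    tie_term = 0.0
    for row in table:
        _, counts = np.unique(row, return_counts=True)
        tie_term += np.sum(counts**3 - counts)
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0:
        chi2 = 0.0
    else:
        chi2 = chi2 / correction
    df = k - 1
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return float(chi2), df, p
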