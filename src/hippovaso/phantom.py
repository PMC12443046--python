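"""Synthetic hippocampal phantom: folded ribbon geometry, block task design,
and forward-simulated interleaved blood-nulled / not-nulled time series with
known ground truth.

The ribbon is a parametric C-shaped sheet (an annular arc extruded along z),
not an anatomically faithful hippocampus: it preserves the two properties the
depth-sampling algorithm needs — curvature and index-corresponding inner /
mid / outer surfaces. Subfield bands run along the arc; a blood-rich lamina
(SRLM) band sits radially inward of the inner surface under the extended
subfields; a WM shell sits outside the outer surface; a CSF block and a
bright-vessel cluster sit away from the ribbon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .glm import condition_regressor

__all__ = [
    "LABEL_CODES",
    "SUBFIELD_CODES",
    "EXTENDED_SUBFIELDS",
    "N_DEPTH_BINS",
    "N_EXT_BINS",
    "N_TOTAL_BINS",
    "AcquisitionParams",
    "GeometryParams",
    "GroundTruth",
    "TaskDesign",
    "HippocampalPhantom",
    "InterleavedSeries",
    "default_ground_truth",
    "build_phantom",
    "make_task_design",
    "make_motion_params",
    "simulate_interleaved",
    "inversion_efficiency",
    "nulling_time",
]

LABEL_CODES = {
    "background": 0,
    "Sub": 1,
    "CA1": 2,
    "CA2": 3,
    "CA3": 4,
    "DG_CA4": 5,
    "SRLM": 6,
    "WM": 7,
    "CSF": 8,
    "vessel": 9,
}
SUBFIELD_CODES = {k: LABEL_CODES[k] for k in ("Sub", "CA1", "CA2", "CA3", "DG_CA4")}
#: subfields whose sampling extends 10 bins beyond the inner surface
EXTENDED_SUBFIELDS = ("Sub", "CA1", "CA2")
SUBFIELD_ORDER = ("Sub", "CA1", "CA2", "CA3", "DG_CA4")

N_DEPTH_BINS = 20   # equidistant bins spanning inner -> outer
N_EXT_BINS = 10     # extension beyond the inner surface (SRLM)
N_TOTAL_BINS = N_DEPTH_BINS + N_EXT_BINS
# 1-based bin convention: 1 = deepest extension point, 11 = inner surface,
# 30 = outer surface. Spacing = thickness / 19 everywhere.
INNER_BIN = N_EXT_BINS + 1


@dataclass(frozen=True)
class AcquisitionParams:
    """Interleaved acquisition timing and inversion settings."""

    tr_readout_ms: float = 71.2
    tr_image_ms: float = 3000.0
    tr_pair_ms: float = 6000.0
    te_ms: float = 23.90
    ti1_ms: float = 1491.0
    n_timepoints: int = 308
    voxel_mm: float = 0.8
    rf_power_scale: float = 3.0
    t1_blood_ms: float = 2100.0

    def __post_init__(self):
        if self.tr_pair_ms != 2 * self.tr_image_ms:
            raise ValueError("tr_pair_ms must equal 2 * tr_image_ms")
        if not self.ti1_ms < self.tr_pair_ms:
            raise ValueError("ti1_ms must be shorter than tr_pair_ms")
        if self.n_timepoints % 2:
            raise ValueError("n_timepoints must be even")
        if self.rf_power_scale < 0:
            raise ValueError("rf_power_scale must be >= 0")

    @property
    def n_pairs(self) -> int:
        return self.n_timepoints // 2

    @property
    def duration_min(self) -> float:
        """Total run duration in minutes."""
        return self.n_timepoints * self.tr_image_ms / 60000.0

    @property
    def timestamps_ms(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.tr_image_ms


@dataclass(frozen=True)
class GeometryParams:
    mid_radius_vox: float = 12.0
    thickness_vox: float = 8.0
    wm_thickness_vox: float = 5.0
    arc_deg: float = 220.0
    z_fraction: float = 0.6
    n_theta: int = 55
    n_z: int = 8
    #: margin (voxels) past the deepest extension bin kept inside the SRLM
    #: band, and past the outer surface carried by the amplitude field, so
    #: trilinear sampling at the extreme bins never touches unlabelled voxels
    sampling_margin_vox: float = 1.8
    vessel_halfwidth_vox: int = 1

    @property
    def srlm_thickness_vox(self) -> float:
        return self.thickness_vox * N_EXT_BINS / (N_TOTAL_BINS - 1) + self.sampling_margin_vox


def _gaussian_bump(bins, center, sd, amplitude):
    return amplitude * np.exp(-0.5 * ((bins - center) / sd) ** 2)


@dataclass
class GroundTruth:
    """Simulated per-subfield laminar amplitudes and noise parameters.

    Profiles are indexed on the 1..30 bin convention (1..10 = SRLM
    extension); subfields without the extension carry 20-bin vectors on
    bins 11..30. Amplitudes are fractional signal changes at the sustained
    task response.
    """

    cbv_profile: dict
    bold_profile: dict
    drift_coeffs: tuple
    noise_sd: float
    inflow_amplitude_at_unit_power: float
    baseline: float = 100.0

    def __post_init__(self):
        for name, vec in list(self.cbv_profile.items()) + list(self.bold_profile.items()):
            expected = N_TOTAL_BINS if name in EXTENDED_SUBFIELDS else N_DEPTH_BINS
            if len(vec) != expected:
                raise ValueError(
                    f"profile for {name} has length {len(vec)}, expected {expected}"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def bins_of(self, subfield: str) -> np.ndarray:
        if subfield in EXTENDED_SUBFIELDS:
            return np.arange(1, N_TOTAL_BINS + 1, dtype=float)
        return np.arange(INNER_BIN, N_TOTAL_BINS + 1, dtype=float)


def default_ground_truth(noise_sd: float = 1.0) -> GroundTruth:
    """Distinct laminar fingerprints per subfield.

    CBV responses peak at mid-thickness in every subfield; BOLD responses
    are weighted toward the draining-surface side — the inner/SRLM side in
    Sub and CA1, the outer surface in CA2, and monotonically increasing
    toward the outer surface in CA3 — so the two contrasts peak at
    different depths.
    """
    b30 = np.arange(1, N_TOTAL_BINS + 1, dtype=float)
    b20 = np.arange(INNER_BIN, N_TOTAL_BINS + 1, dtype=float)
    mid = (INNER_BIN + N_TOTAL_BINS) / 2.0  # 20.5

    cbv = {
        "Sub": _gaussian_bump(b30, mid, 4.0, 0.055),
        "CA1": _gaussian_bump(b30, mid, 4.0, 0.050),
        "CA2": _gaussian_bump(b30, mid, 4.0, 0.045),
        "CA3": _gaussian_bump(b20, mid, 4.0, 0.040),
        "DG_CA4": _gaussian_bump(b20, mid, 4.0, 0.035),
    }
    bold = {
        "Sub": _gaussian_bump(b30, 10.0, 4.5, 0.060),
        "CA1": _gaussian_bump(b30, 10.0, 4.5, 0.055),
        "CA2": _gaussian_bump(b30, 10.0, 3.0, 0.018)
        + _gaussian_bump(b30, 30.0, 5.0, 0.050),
        "CA3": 0.010 + 0.040 * (b20 - INNER_BIN) / (N_DEPTH_BINS - 1),
        "DG_CA4": np.full(N_DEPTH_BINS, 0.030),
    }
    return GroundTruth(
        cbv_profile=cbv,
        bold_profile=bold,
        drift_coeffs=(0.01, -0.005),
        noise_sd=noise_sd,
        inflow_amplitude_at_unit_power=20.0,
    )


@dataclass
class HippocampalPhantom:
    label_volume: np.ndarray
    affine: np.ndarray
    surfaces: dict          # {"inner"|"mid"|"outer": (V, 3) world mm}
    faces: np.ndarray       # shared triangulation (F, 3)
    subfield_of_vertex: np.ndarray
    truth: GroundTruth
    geometry: GeometryParams
    voxel_mm: float
    # simulation helper fields: continuous bin coordinate and subfield band
    # per voxel over the radially extended range (NaN / 0 elsewhere)
    bin_coord: np.ndarray = field(repr=False, default=None)
    band_code: np.ndarray = field(repr=False, default=None)

    def mask(self, *names) -> np.ndarray:
        codes = [LABEL_CODES[n] for n in names]
        return np.isin(self.label_volume, codes)

    @property
    def gm_mask(self) -> np.ndarray:
        return self.mask("Sub", "CA1", "CA2", "CA3", "DG_CA4", "SRLM")


@dataclass
class TaskDesign:
    events: list  # (onset_s, duration_s, condition)
    n_trials_per_condition: int

    @property
    def total_span_s(self) -> float:
        return max(o + d for o, d, _ in self.events) + self._iti

    _iti: float = 0.0

    def trials(self, condition: str):
        return [(o, d) for o, d, c in self.events if c == condition]


@dataclass
class InterleavedSeries:
    data: np.ndarray              # (x, y, z, t)
    contrast_tag: list            # per-volume "nulled"/"notnulled"
    timestamp_ms: np.ndarray
    params: AcquisitionParams

    def __post_init__(self):
        if len(self.contrast_tag) != self.data.shape[-1]:
            raise ValueError("contrast_tag length must match time dimension")
        if np.any(np.diff(self.timestamp_ms) <= 0):
            raise ValueError("timestamps must be strictly increasing")


def build_phantom(
    grid_shape=(48, 48, 48),
    geometry: GeometryParams | None = None,
    seed: int = 0,
    truth: GroundTruth | None = None,
) -> HippocampalPhantom:
    """Construct the folded-ribbon phantom on an isotropic voxel grid.

    Deterministic given (grid_shape, geometry, truth); ``seed`` is kept for
    API symmetry with the simulator. Raises if the grid cannot contain the
    ribbon plus its SRLM/WM shells.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if any(s < 32 for s in grid_shape):
        raise ValueError("grid_shape must be >= 32 voxels per axis")
    geo = geometry or GeometryParams()
    truth = truth or default_ground_truth()
    nx, ny, nz = grid_shape
    voxel_mm = 0.8

    half_t = geo.thickness_vox / 2.0
    r_inner = geo.mid_radius_vox - half_t
    r_outer = geo.mid_radius_vox + half_t
    if r_inner - geo.srlm_thickness_vox < 1.0:
        raise ValueError("ribbon thickness too large for mid radius (SRLM underflows)")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    if cx - (r_outer + geo.wm_thickness_vox) < 1.0:
        raise ValueError("grid too small to contain ribbon at requested thickness")

    ix, iy, iz = np.indices(grid_shape)
    dx, dy = ix - cx, iy - cy
    r = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0

    gap = 360.0 - geo.arc_deg
    theta0 = gap / 2.0
    in_arc = (theta >= theta0) & (theta <= 360.0 - theta0)
    arc_u = np.clip((theta - theta0) / geo.arc_deg, 0.0, 1.0 - 1e-12)
    band_idx = np.minimum((arc_u * len(SUBFIELD_ORDER)).astype(int),
                          len(SUBFIELD_ORDER) - 1)

    z0 = int(round(nz * (1 - geo.z_fraction) / 2))
    z1 = nz - z0
    in_z = (iz >= z0) & (iz < z1)

    w = r - geo.mid_radius_vox  # signed radial depth; inner side negative
    labels = np.zeros(grid_shape, dtype=np.int16)

    gm = in_arc & in_z & (np.abs(w) <= half_t)
    for i, name in enumerate(SUBFIELD_ORDER):
        labels[gm & (band_idx == i)] = SUBFIELD_CODES[name]

    # SRLM band radially inward of the inner surface. Full depth under the
    # extended subfields; a thin support band under CA3/DG so trilinear
    # sampling at the inner surface stays inside labelled tissue.
    inward = in_arc & in_z & (w < -half_t)
    ext_band = np.isin(band_idx, [SUBFIELD_ORDER.index(n) for n in EXTENDED_SUBFIELDS])
    labels[inward & ext_band & (w >= -half_t - geo.srlm_thickness_vox)] = LABEL_CODES["SRLM"]
    labels[inward & ~ext_band & (w >= -half_t - 2.0)] = LABEL_CODES["SRLM"]

    labels[in_arc & in_z & (w > half_t) & (w <= half_t + geo.wm_thickness_vox)] = LABEL_CODES["WM"]

    # CSF block in the unused z slab below the ribbon
    csf_z1 = max(z0 - 2, 3)
    labels[int(cx) - 5:int(cx) + 5, int(cy) - 5:int(cy) + 5, 1:csf_z1] = LABEL_CODES["CSF"]

    # bright-vessel cluster in the arc gap (outside the ribbon)
    vx = int(round(cx + geo.mid_radius_vox))
    vy, vz = int(round(cy)), (z0 + z1) // 2
    hw = geo.vessel_halfwidth_vox
    labels[vx - hw:vx + hw + 1, vy - hw:vy + hw + 1, vz - hw:vz + hw + 1] = LABEL_CODES["vessel"]

    # continuous bin coordinate for the forward model: defined over the
    # extended radial range and clipped at the end bins so voxels just
    # outside the surfaces carry the boundary-bin amplitude (avoids
    # partial-volume bias when sampling at bins 1 and 30).
    m = geo.sampling_margin_vox
    ext_in = half_t * N_EXT_BINS / (N_TOTAL_BINS - 1) + m
    bin_coord = np.full(grid_shape, np.nan)
    band_code = np.zeros(grid_shape, dtype=np.int16)
    in_ext = in_arc & in_z & (w >= -half_t - ext_in) & (w <= half_t + m)
    bc = INNER_BIN + (N_DEPTH_BINS - 1) * (w + half_t) / geo.thickness_vox
    for i, name in enumerate(SUBFIELD_ORDER):
        lo = 1.0 if name in EXTENDED_SUBFIELDS else float(INNER_BIN)
        sel = in_ext & (band_idx == i)
        if name not in EXTENDED_SUBFIELDS:
            sel = sel & (w >= -half_t - m)
        bin_coord[sel] = np.clip(bc[sel], lo, float(N_TOTAL_BINS))
        band_code[sel] = SUBFIELD_CODES[name]

    # surfaces: vertex grid over (theta, z), radially collinear triples
    th = np.radians(np.linspace(theta0 + 2.0, 360.0 - theta0 - 2.0, geo.n_theta))
    zs = np.linspace(z0 + 2.0, z1 - 3.0, geo.n_z)
    tt, zz = np.meshgrid(th, zs, indexing="ij")
    ux, uy = np.cos(tt).ravel(), np.sin(tt).ravel()
    zf = zz.ravel()

    def shell(radius):
        pts = np.column_stack([cx + radius * ux, cy + radius * uy, zf])
        return pts * voxel_mm  # world = voxel index * voxel size (affine below)

    surfaces = {
        "inner": shell(r_inner),
        "mid": shell(geo.mid_radius_vox),
        "outer": shell(r_outer),
    }
    faces = _grid_faces(geo.n_theta, geo.n_z)

    th_deg = np.degrees(tt.ravel())
    v_u = np.clip((th_deg - theta0) / geo.arc_deg, 0.0, 1.0 - 1e-12)
    v_band = np.minimum((v_u * len(SUBFIELD_ORDER)).astype(int),
                        len(SUBFIELD_ORDER) - 1)
    subfield_of_vertex = np.array(
        [SUBFIELD_CODES[SUBFIELD_ORDER[i]] for i in v_band], dtype=np.int16
    )

    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return HippocampalPhantom(
        label_volume=labels,
        affine=affine,
        surfaces=surfaces,
        faces=faces,
        subfield_of_vertex=subfield_of_vertex,
        truth=truth,
        geometry=geo,
        voxel_mm=voxel_mm,
        bin_coord=bin_coord,
        band_code=band_code,
    )


def _grid_faces(n_u: int, n_v: int) -> np.ndarray:
    faces = []
    for i in range(n_u - 1):
        for j in range(n_v - 1):
            a = i * n_v + j
            b = a + n_v
            faces.append((a, b, a + 1))
            faces.append((b, b + 1, a + 1))
    return np.asarray(faces, dtype=np.int32)


def make_task_design(
    n_trials: int = 15,
    trial_s: float = 18.0,
    iti_s: float = 12.0,
    order_seed: int = 0,
) -> TaskDesign:
    """Randomized interleaving of memory and math trials.

    2 x n_trials events; consecutive onsets are (trial_s + iti_s) apart, so
    the total span is 2 x n_trials x (trial_s + iti_s).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(order_seed)
    conditions = ["memory"] * n_trials + ["math"] * n_trials
    rng.shuffle(conditions)
    events = [
        (i * (trial_s + iti_s), trial_s, cond) for i, cond in enumerate(conditions)
    ]
    td = TaskDesign(events=events, n_trials_per_condition=n_trials)
    td._iti = iti_s
    return td


def make_motion_params(n_t: int, seed: int = 0, scale: float = 0.05) -> np.ndarray:
    """Six smooth, small-amplitude motion regressors (t x 6).

    Low-order random cosine drifts — regressor plumbing only; no motion is
    applied to the simulated data.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n_t)
    # enough basis terms that the 6 columns are linearly independent
    basis = np.column_stack(
        [np.cos(np.pi * k * t) for k in range(1, 13)]
        + [np.sin(np.pi * k * t) for k in range(1, 13)]
    )
    coefs = rng.normal(0, scale, size=(basis.shape[1], 6))
    coefs *= np.exp(-0.3 * np.arange(basis.shape[1]))[:, None]  # smooth
    return basis @ coefs


def inversion_efficiency(rf_power_scale, k: float = 1.0):
    """Fraction of magnetization inverted: 1 - exp(-k * power).

    Monotone, saturating at 1, with efficiency(3) >= 0.95 at the default k.
    """
    p = np.asarray(rf_power_scale, dtype=float)
    if np.any(p < 0):
        raise ValueError("rf_power_scale must be >= 0")
    out = 1.0 - np.exp(-k * p)
    return float(out) if np.isscalar(rf_power_scale) else out


def nulling_time(t1_blood_ms: float, tr_pair_ms: float, efficiency: float) -> float:
    """Inversion time nulling steady-state blood magnetization.

    Solves 1 - (1 + e) exp(-TI/T1) + e exp(-TR/T1) = 0 for TI in
    (0, TR); closed form TI = T1 ln((1 + e) / (1 + e exp(-TR/T1))).
    """
    if t1_blood_ms <= 0:
        raise ValueError("t1_blood_ms must be positive")
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    ti = t1_blood_ms * math.log(
        (1.0 + efficiency) / (1.0 + efficiency * math.exp(-tr_pair_ms / t1_blood_ms))
    )
    if not 0 < ti < tr_pair_ms:
        raise ValueError("no nulling time in (0, TR): inconsistent parameters")
    return ti


def _amplitude_maps(phantom: HippocampalPhantom):
    """Per-voxel CBV and BOLD fractional amplitudes from the laminar truth,
    interpolated at each voxel's continuous bin coordinate."""
    a_cbv = np.zeros(phantom.label_volume.shape)
    a_bold = np.zeros(phantom.label_volume.shape)
    for name, code in SUBFIELD_CODES.items():
        sel = (phantom.band_code == code) & np.isfinite(phantom.bin_coord)
        if not sel.any():
            continue
        bins = phantom.truth.bins_of(name)
        a_cbv[sel] = np.interp(phantom.bin_coord[sel], bins,
                               phantom.truth.cbv_profile[name])
        a_bold[sel] = np.interp(phantom.bin_coord[sel], bins,
                                phantom.truth.bold_profile[name])
    return a_cbv, a_bold


def simulate_interleaved(
    phantom: HippocampalPhantom,
    design: TaskDesign,
    params: AcquisitionParams | None = None,
    seed: int = 0,
    noise_sd: float | None = None,
    with_drift: bool = True,
) -> InterleavedSeries:
    """Forward-simulate the alternating nulled / not-nulled 4D series.

    Per voxel with laminar amplitudes (c, b) and task response h(t):

        notnulled(t) = B (1 + b h) drift
        nulled(t)    = B (1 - c h) (1 + b h) drift   [+ inflow in vessels]

    plus Gaussian noise. The hemodynamic state h and the drift are evaluated
    once per pair (at the nulled volume's timestamp) and shared by both pair
    members, so pairwise division reproduces 1 - c h exactly at zero noise.
    The inflow term B_inflow (1 - inversion_efficiency(power)) rides on
    nulled volumes only.
    """
    params = params or AcquisitionParams()
    truth = phantom.truth
    sd = truth.noise_sd if noise_sd is None else noise_sd

    timestamps = params.timestamps_ms
    pair_t_s = timestamps[0::2] / 1000.0
    h = condition_regressor(design.events, "memory", pair_t_s)
    # math condition carries no simulated response (design decision): the
    # memory-vs-math contrast then equals the simulated amplitude.

    if with_drift:
        tau = 2.0 * pair_t_s / (timestamps[-1] / 1000.0) - 1.0
        c0, c1 = truth.drift_coeffs
        drift = 1.0 + c0 * tau + c1 * tau**2
    else:
        drift = np.ones_like(pair_t_s)

    a_cbv, a_bold = _amplitude_maps(phantom)
    base = np.where(phantom.label_volume > 0, truth.baseline, 0.0)
    vessel = phantom.label_volume == LABEL_CODES["vessel"]
    inflow = truth.inflow_amplitude_at_unit_power * (
        1.0 - inversion_efficiency(params.rf_power_scale)
    )

    shape = phantom.label_volume.shape
    data = np.empty(shape + (params.n_timepoints,))
    for k in range(params.n_pairs):
        bold_f = base * (1.0 + a_bold * h[k])
        nn = bold_f * drift[k]
        nu = bold_f * (1.0 - a_cbv * h[k]) * drift[k]
        nu[vessel] += inflow
        data[..., 2 * k] = nu
        data[..., 2 * k + 1] = nn
    if sd > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, sd, size=data.shape)

    tags = ["nulled", "notnulled"] * params.n_pairs
    return InterleavedSeries(
        data=data,
        contrast_tag=tags,
        timestamp_ms=timestamps.astype(float),
        params=params,
    )
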