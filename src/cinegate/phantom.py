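"""Dynamic 2D thorax phantom, parallel-beam projector, and filtered backprojection.

The phantom is a desk-scale analogue of a rodent thorax: a soft-tissue
disk, a myocardial ring whose inner (blood-pool) radius beats with the
cardiac phase, and an offset lung ellipse whose size follows the
respiratory phase.  A parallel-beam geometry replaces the cone-beam bench —
the gating science under study (how projection phase consistency and
angular regularity affect reconstruction) is geometry-independent, and the
2D setting keeps analytic oracles (chord lengths, ground-truth images)
tractable.

:func:`fbp_reconstruct` is a standard ramp-filtered backprojection with one
extension: each view is weighted by its local angular spacing, so the
irregular angle sets produced by retrospectively-gated acquisitions are
handled without rebinning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .gating import AcquisitionLog, GatingConfig, sort_phases
from .physio import ParameterError, RespTrace, TriggerTrain

__all__ = [
    "DynamicPhantom",
    "Sinogram",
    "render",
    "forward_project",
    "acquire",
    "fbp_reconstruct",
    "bin_reconstructions",
    "estimate_chamber_radius",
    "matched_prospective_sinogram",
]

_EPS = 1e-9


@dataclass(frozen=True)
class DynamicPhantom:
    """Parametric beating-thorax scene on the square [-1, 1]².

    Attributes
    ----------
    body_radius, body_mu
        Soft-tissue disk radius (scene units) and attenuation (arbitrary
        units per unit length).
    myo_outer, myo_inner_diastole, myo_mu, blood_mu
        Myocardial ring: fixed outer radius, diastolic inner radius, wall
        and blood-pool attenuations.  The inner radius contracts by
        ``cardiac_amp`` (fraction of the diastolic radius) at systole,
        following ``r(c) = r_d * (1 - amp * (1 - cos 2πc)/2)`` so phase 0
        is end diastole and phase 0.5 is end systole; the modulation is
        periodic in the cardiac phase.
    lung_center, lung_radii, lung_mu, resp_amp
        Offset lung ellipse whose radii scale with the respiratory phase.
    """

    body_radius: float = 0.9
    body_mu: float = 1.0
    center: tuple = (0.15, -0.1)
    myo_outer: float = 0.42
    myo_inner_diastole: float = 0.28
    myo_mu: float = 0.5
    blood_mu: float = 0.15
    cardiac_amp: float = 0.4
    lung_center: tuple = (-0.35, 0.25)
    lung_radii: tuple = (0.28, 0.2)
    lung_mu: float = -0.6
    resp_amp: float = 0.15

    def inner_radius(self, cardiac_frac: float) -> float:
        """Programmed blood-pool radius at a cardiac phase fraction."""
        c = float(cardiac_frac) % 1.0
        return self.myo_inner_diastole * (
            1.0 - self.cardiac_amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * c))
        )

    def lung_scale(self, resp_frac: float) -> float:
        r = float(resp_frac) % 1.0
        return 1.0 + self.resp_amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * r))


def render(
    phantom: DynamicPhantom,
    cardiac_frac: float = 0.0,
    resp_frac: float = 0.0,
    grid: int = 128,
) -> np.ndarray:
    """Rasterize the phantom attenuation map at the given phases.

    The image covers [-1, 1]² with ``grid`` pixels per side; attenuation is
    nonnegative everywhere and the rendering is deterministic at fixed
    phases.
    """
    if grid < 16:
        raise ParameterError("grid must be at least 16")
    coords = (np.arange(grid) + 0.5) / grid * 2.0 - 1.0
    x, y = np.meshgrid(coords, coords)

    body = x**2 + y**2 < phantom.body_radius**2

    ls = phantom.lung_scale(resp_frac)
    lx, ly = phantom.lung_center
    ra, rb = phantom.lung_radii
    lung = ((x - lx) / (ra * ls)) ** 2 + ((y - ly) / (rb * ls)) ** 2 < 1.0

    cx, cy = phantom.center
    rr = (x - cx) ** 2 + (y - cy) ** 2
    ring = rr < phantom.myo_outer**2
    inner = rr < phantom.inner_radius(cardiac_frac) ** 2

    # later assignments override earlier ones: lung and heart replace soft tissue
    img = np.zeros((grid, grid))
    img[body] = phantom.body_mu
    img[lung & body] = phantom.body_mu + phantom.lung_mu
    img[ring] = phantom.body_mu + phantom.myo_mu
    img[inner] = phantom.body_mu + phantom.blood_mu
    return np.clip(img, 0.0, None)


def forward_project(
    image: np.ndarray, angle_deg: float, n_detectors: int, fov: float = 2.0
) -> np.ndarray:
    """Parallel-beam line integrals of an image at one view angle.

    Rays are perpendicular to the detector, which spans ``fov`` scene units
    and is rotated ``angle_deg`` degrees (mathematically positive).
    Sampling is length-weighted: image values are interpolated linearly at
    equispaced points along each ray and summed times the step length, so a
    uniform disk of radius r and attenuation mu integrates to ~2·r·mu on
    the central ray.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ParameterError("image must be square 2D")
    if n_detectors < 8:
        raise ParameterError("need at least 8 detector elements")
    n = image.shape[0]
    pixel = fov / n
    theta = np.deg2rad(angle_deg)

    # detector coordinate s along (−sinθ, cosθ)... use standard convention:
    # ray direction d = (cosθ, sinθ), detector axis p = (−sinθ, cosθ)
    s = (np.arange(n_detectors) + 0.5) / n_detectors * fov - fov / 2.0
    step = pixel / 2.0
    half = fov / 2.0
    ell = np.arange(-half, half + step / 2.0, step)

    dx, dy = np.cos(theta), np.sin(theta)
    px, py = -np.sin(theta), np.cos(theta)
    xs = s[:, None] * px + ell[None, :] * dx
    ys = s[:, None] * py + ell[None, :] * dy

    # map scene coords to pixel indices (pixel centers at (i+0.5)*pixel - 1)
    ci = (ys + half) / pixel - 0.5
    cj = (xs + half) / pixel - 0.5
    vals = ndimage.map_coordinates(
        image, np.stack([ci.ravel(), cj.ravel()]), order=1, mode="constant", cval=0.0
    ).reshape(xs.shape)
    return vals.sum(axis=1) * step


@dataclass
class Sinogram:
    """Per-exposure projection rows with angles and phase labels."""

    angles: np.ndarray  # degrees, one per row
    data: np.ndarray  # (n_rows, n_detectors)
    fov: float = 2.0
    labels: pd.DataFrame | None = None  # optional per-row log fields

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.angles.size:
            raise ParameterError("one angle per sinogram row required")

    @property
    def n_detectors(self) -> int:
        return self.data.shape[1]

    def __len__(self) -> int:
        return self.data.shape[0]

    def select(self, row_mask) -> "Sinogram":
        labels = self.labels.loc[row_mask].reset_index(drop=True) if self.labels is not None else None
        return Sinogram(self.angles[row_mask], self.data[row_mask], self.fov, labels)


def acquire(
    phantom: DynamicPhantom,
    log: AcquisitionLog,
    cardiac: TriggerTrain,
    resp: RespTrace,
    n_detectors: int = 128,
    grid: int = 128,
    cfg: GatingConfig | None = None,
) -> Sinogram:
    """Expose the dynamic phantom according to an acquisition log.

    Each log row yields one sinogram row: the phantom is rendered at the
    cardiac/respiratory phases current at the exposure time and projected
    at the logged angle.  If the log's phase fields are unassigned they are
    filled by :func:`sort_phases` first, so rows carry bin labels for
    grouping.  Renderings are memoized on the (rounded) phase pair, which
    collapses gated logs at a fixed phase to a single rasterization.
    """
    if len(log) == 0:
        raise ParameterError("acquisition log is empty")
    if cfg is None:
        cfg = GatingConfig()
    df = log.df
    if df["cardiac_frac"].isna().any():
        df = sort_phases(log, cardiac, resp, cfg).df
    t = df["time_s"].to_numpy(float)
    if t[0] < cardiac.event_times[0] - _EPS or t[-1] > cardiac.event_times[-1] + _EPS:
        raise ParameterError("exposures fall outside the physiology time span")

    cache: dict = {}
    rows = np.empty((len(df), n_detectors))
    for i, row in enumerate(df.itertuples(index=False)):
        cfrac = 0.0 if np.isnan(row.cardiac_frac) else float(row.cardiac_frac)
        rfrac = 0.0 if np.isnan(row.resp_frac) else float(row.resp_frac)
        key = (round(cfrac, 6), round(rfrac, 6))
        if key not in cache:
            cache[key] = render(phantom, cfrac, rfrac, grid=grid)
        rows[i] = forward_project(cache[key], float(row.angle_deg), n_detectors)
    return Sinogram(
        df["angle_deg"].to_numpy(float), rows, fov=2.0, labels=df.reset_index(drop=True)
    )


def _ramp_filter(n: int, filter_name: str) -> np.ndarray:
    """Frequency response of the reconstruction filter (length n, fftfreq order)."""
    freqs = np.fft.fftfreq(n)
    resp = np.abs(freqs)
    if filter_name == "hann":
        resp *= 0.5 * (1.0 + np.cos(2.0 * np.pi * freqs))
    elif filter_name != "ramp":
        raise ParameterError(f"unknown filter {filter_name!r}")
    return resp


def fbp_reconstruct(
    sino: Sinogram, grid: int = 128, filter_name: str = "ramp"
) -> np.ndarray:
    """Filtered backprojection with local angular-spacing weights.

    Rows are ramp-filtered (optionally Hann-apodized) along the detector
    axis and backprojected with linear interpolation.  Each view's
    contribution is weighted by half the angular gap between its
    neighbours on the circle, which reduces to the usual uniform weight for
    equispaced views and compensates the clustered/denuded angle sets of
    retrospective gating.  Duplicate angles (multiple rotations) are
    averaged before weighting.
    """
    angles = np.mod(sino.angles, 360.0)
    uniq = np.unique(np.round(angles, 9))
    if uniq.size < 8:
        raise ParameterError(
            f"need at least 8 distinct view angles, got {uniq.size}"
        )

    # average rows sharing an angle
    order = np.argsort(angles, kind="stable")
    a_sorted = angles[order]
    d_sorted = sino.data[order]
    views = []
    i = 0
    while i < a_sorted.size:
        j = i
        while j < a_sorted.size and abs(a_sorted[j] - a_sorted[i]) < 1e-9:
            j += 1
        views.append((a_sorted[i], d_sorted[i:j].mean(axis=0)))
        i = j
    view_angles = np.array([v[0] for v in views])
    view_data = np.stack([v[1] for v in views])

    # local angular spacing on the circle, radians
    ext = np.concatenate(
        [[view_angles[-1] - 360.0], view_angles, [view_angles[0] + 360.0]]
    )
    weights = np.deg2rad((ext[2:] - ext[:-2]) / 2.0)

    n_det = sino.n_detectors
    pad = 1 << int(np.ceil(np.log2(2 * n_det)))
    filt = _ramp_filter(pad, filter_name)
    padded = np.zeros((view_data.shape[0], pad))
    padded[:, :n_det] = view_data
    filtered = np.real(np.fft.ifft(np.fft.fft(padded, axis=1) * filt, axis=1))[
        :, :n_det
    ]

    det_pitch = sino.fov / n_det
    s_coords = (np.arange(n_det) + 0.5) * det_pitch - sino.fov / 2.0
    coords = (np.arange(grid) + 0.5) / grid * 2.0 - 1.0
    x, y = np.meshgrid(coords, coords)

    recon = np.zeros((grid, grid))
    for ang, prof, w in zip(view_angles, filtered, weights):
        theta = np.deg2rad(ang)
        s = x * (-np.sin(theta)) + y * np.cos(theta)
        recon += w * np.interp(s, s_coords, prof, left=0.0, right=0.0)
    # full-circle data measures each line twice; normalize by 1/2 and by the
    # detector pitch of the discrete filter
    return recon / (2.0 * det_pitch)


def bin_reconstructions(
    sino: Sinogram, n_bins: int, grid: int = 128, filter_name: str = "ramp"
) -> dict:
    """Reconstruct each cardiac bin of a phase-labelled sinogram.

    Returns ``{bin_index: image}`` for every bin with at least 8 distinct
    angles; the desk-scale cine protocol.
    """
    if sino.labels is None or "cardiac_bin" not in sino.labels:
        raise ParameterError("sinogram rows carry no cardiac_bin labels")
    bins = sino.labels["cardiac_bin"].to_numpy(float)
    out = {}
    for b in range(n_bins):
        mask = bins == b
        if mask.sum() >= 8:
            out[b] = fbp_reconstruct(sino.select(mask), grid=grid, filter_name=filter_name)
    return out


def estimate_chamber_radius(
    recon: np.ndarray, phantom: DynamicPhantom, fov: float = 2.0
) -> float:
    """Blood-pool radius from a reconstruction, by thresholded area.

    Pixels inside the myocardial outer radius whose value lies below the
    midpoint between the blood-pool and wall attenuations are counted as
    chamber; the radius of the equivalent-area circle is returned (scene
    units).
    """
    grid = recon.shape[0]
    coords = (np.arange(grid) + 0.5) / grid * fov - fov / 2.0
    x, y = np.meshgrid(coords, coords)
    cx, cy = phantom.center
    inside = (x - cx) ** 2 + (y - cy) ** 2 < phantom.myo_outer**2
    threshold = phantom.body_mu + 0.5 * (phantom.blood_mu + phantom.myo_mu)
    chamber = inside & (recon < threshold)
    pixel_area = (fov / grid) ** 2
    return float(np.sqrt(chamber.sum() * pixel_area / np.pi))


def matched_prospective_sinogram(
    phantom: DynamicPhantom,
    cardiac_frac: float,
    n_views: int,
    n_detectors: int = 128,
    grid: int = 128,
    resp_frac: float = 0.0,
) -> Sinogram:
    """Ideal prospectively-gated sinogram: n equispaced views at one phase.

    The comparison partner for a retrospective phase bin at matched
    projection count: every view images the identical (phase-consistent)
    scene at constant angular steps.
    """
    angles = np.arange(n_views) * 360.0 / n_views
    truth = render(phantom, cardiac_frac, resp_frac, grid=grid)
    data = np.stack([forward_project(truth, a, n_detectors) for a in angles])
    return Sinogram(angles, data)
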