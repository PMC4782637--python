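"""Digital subtraction angiography: event sequence and functional analysis.

The DSA protocol suspends the ventilator at end expiration, acquires a
handful of pre-contrast frames synchronized to the R wave, averages them
into a mask, issues the injector command, and then acquires one frame per
heartbeat through the first pass of the bolus.  Subtraction of the mask
isolates the contrast signal, from which per-ROI time–attenuation curves
(TACs) are read out and analysed:

* :func:`fit_gamma_variate` — parametric first-pass bolus model,
* :func:`perfusion_index` — peak tissue enhancement over the arterial
  (aortic) area under the curve,
* :func:`patlak` — linearized two-compartment analysis whose regression
  slope estimates permeability (blood-to-tissue transfer) and whose
  intercept estimates residual blood volume (rbv).

A synthetic dynamic kidney scene (:class:`KidneyScene`) drives end-to-end
runs: the aorta carries a gamma-variate bolus Cb(t) and each tissue region
follows the Patlak model C(t) = rbv·Cb(t) + K·∫Cb, so the generating
(rbv, K) pair is the known ground truth of any recovery experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.integrate import cumulative_trapezoid

from .physio import ParameterError, RespTrace, TriggerTrain

__all__ = [
    "DsaProtocol",
    "DsaProtocolError",
    "ProjectionStack",
    "TimeAttenuationCurve",
    "GammaFit",
    "PatlakResult",
    "GammaBolus",
    "KidneyScene",
    "run_dsa_protocol",
    "make_mask",
    "subtract",
    "extract_tac",
    "fit_gamma_variate",
    "gamma_variate",
    "perfusion_index",
    "patlak",
    "make_patlak_tac",
    "synthesize_patlak_tacs",
    "synthesize_perfusion_tac",
]

_EPS = 1e-12


class DsaProtocolError(RuntimeError):
    """The protocol cannot be executed as configured."""


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or input is degenerate."""


@dataclass(frozen=True)
class DsaProtocol:
    """DSA run parameters.

    The default matches the kidney-perfusion protocol: 40 frames total, the
    first 6 pre-contrast (mask), one frame every heartbeat, a 1 mL bolus
    injected over 1 s, all inside a single breath hold.
    """

    n_total_frames: int = 40
    n_pre_frames: int = 6
    breath_hold: float = 7.0
    injection_volume_ml: float = 1.0
    injection_duration: float = 1.0
    frames_per_beat: int = 1
    hold_band: tuple = (5.0, 10.0)

    def __post_init__(self) -> None:
        if not 0 < self.n_pre_frames < self.n_total_frames:
            raise ParameterError("need 0 < n_pre_frames < n_total_frames")
        if self.frames_per_beat < 1:
            raise ParameterError("frames_per_beat must be >= 1")
        lo, hi = self.hold_band
        if not lo <= self.breath_hold <= hi:
            raise ParameterError(
                f"breath_hold {self.breath_hold:g}s outside the allowed band "
                f"[{lo:g}, {hi:g}]s"
            )

    @property
    def n_post_frames(self) -> int:
        return self.n_total_frames - self.n_pre_frames


@dataclass
class ProjectionStack:
    """Time-ordered 2D frames with acquisition metadata."""

    frames: np.ndarray  # (n_frames, ny, nx)
    frame_times: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise ParameterError("frames must be a (n, ny, nx) array")
        if self.frames.shape[0] != self.frame_times.size:
            raise ParameterError("one frame time per frame required")
        if self.frame_times.size >= 2 and np.any(np.diff(self.frame_times) <= 0):
            raise ParameterError("frame_times must be strictly increasing")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def to_tiff(self, path) -> None:
        """Write frames as a multi-frame TIFF plus a JSON metadata sidecar."""
        import tifffile

        tifffile.imwrite(path, self.frames.astype(np.float32))
        sidecar = str(path) + ".json"
        meta = {k: v for k, v in self.metadata.items() if _json_safe(v)}
        with open(sidecar, "w") as fh:
            json.dump(
                {"frame_times": self.frame_times.tolist(), "metadata": meta},
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_tiff(cls, path):
        import tifffile

        frames = tifffile.imread(path)
        with open(str(path) + ".json") as fh:
            side = json.load(fh)
        return cls(frames, np.asarray(side["frame_times"]), side.get("metadata", {}))


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


@dataclass
class TimeAttenuationCurve:
    """Per-heartbeat enhancement samples for one ROI, arbitrary units."""

    times: np.ndarray
    values: np.ndarray
    roi_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ParameterError("times and values must have equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ParameterError("TAC times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def peak(self) -> float:
        return float(np.max(self.values))

    @property
    def auc(self) -> float:
        """Trapezoidal area under the curve over the sampled span."""
        return float(np.trapezoid(self.values, self.times))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "enhancement": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, roi_label: str = ""):
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(float), df["enhancement"].to_numpy(float), roi_label)


@dataclass(frozen=True)
class GammaFit:
    """Gamma-variate bolus fit: peak amplitude, shape, scale, onset, residual."""

    amplitude: float
    alpha_g: float
    beta_g: float
    t0: float
    rss: float

    @property
    def peak_time(self) -> float:
        """Location of the fitted maximum, t0 + alpha_g * beta_g."""
        return self.t0 + self.alpha_g * self.beta_g

    def __call__(self, t) -> np.ndarray:
        return gamma_variate(t, self.amplitude, self.alpha_g, self.beta_g, self.t0)


@dataclass(frozen=True)
class PatlakResult:
    """Least-squares Patlak line: slope = permeability, intercept = rbv."""

    slope: float
    intercept: float
    r_squared: float
    points: np.ndarray  # (n, 2) of (x, y)

    @property
    def permeability(self) -> float:
        return self.slope

    @property
    def rbv(self) -> float:
        return self.intercept

    def to_csv(self, path) -> None:
        pd.DataFrame(self.points, columns=["patlak_x_s", "patlak_y"]).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# gamma-variate bolus model


def gamma_variate(t, amplitude, alpha_g, beta_g, t0=0.0):
    """Peak-normalized gamma-variate first-pass curve.

    ``f(t) = A * ((t - t0)/(alpha*beta))**alpha * exp(alpha - (t - t0)/beta)``
    for t > t0 and 0 otherwise; A is the peak height, attained at
    ``t0 + alpha*beta``.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    m = t > t0
    x = (t[m] - t0) / (alpha_g * beta_g)
    out[m] = amplitude * np.power(x, alpha_g) * np.exp(alpha_g * (1.0 - x))
    return out


@dataclass(frozen=True)
class GammaBolus:
    """Analytic gamma-variate bolus with closed-form cumulative integral.

    Used as the blood (aortic) concentration Cb(t) of the synthetic kidney
    scene.  Defaults model a fast rat aortic first pass: onset 0.25 s after
    injection, peak about 1.9 s after injection.
    """

    amplitude: float = 100.0
    alpha_g: float = 3.0
    beta_g: float = 0.55
    t0: float = 0.25

    def conc(self, tau) -> np.ndarray:
        """Concentration at time tau since injection (0 for tau <= t0)."""
        return gamma_variate(tau, self.amplitude, self.alpha_g, self.beta_g, self.t0)

    def cum(self, tau) -> np.ndarray:
        """Exact cumulative integral of :meth:`conc` from 0 to tau.

        With x = (tau - t0)/beta the integral is
        ``A * (e/alpha)**alpha * beta * Gamma(alpha+1) * P(alpha+1, x)``
        where P is the regularized lower incomplete gamma function.
        """
        tau = np.asarray(tau, dtype=float)
        x = np.clip((tau - self.t0) / self.beta_g, 0.0, None)
        a = self.alpha_g
        scale = (
            self.amplitude
            * (np.e / a) ** a
            * self.beta_g
            * special.gamma(a + 1.0)
        )
        return scale * special.gammainc(a + 1.0, x)


# ---------------------------------------------------------------------------
# dynamic kidney scene


@dataclass
class KidneyScene:
    """Planar dynamic phantom for DSA: aorta, renal cortex, renal medulla.

    Regions are rasterized on a ``grid x grid`` unit square.  After the
    injection instant the aorta region carries the bolus Cb(t) and each
    tissue region follows the Patlak model
    ``C(t) = rbv * Cb(t) + K * integral(Cb)`` with the region's generating
    (rbv, K).  Attenuation is the static anatomy plus these enhancements,
    so linear mask subtraction recovers the concentration curves exactly.
    The generating defaults are the cortex/medulla magnitudes of a rat
    kidney-perfusion study (arbitrary units).
    """

    grid: int = 64
    bolus: GammaBolus = field(default_factory=GammaBolus)
    rbv_cortex: float = 0.4228
    k_cortex: float = 0.0277
    rbv_medulla: float = 0.2178
    k_medulla: float = 0.0321
    background_mu: float = 0.2

    def __post_init__(self) -> None:
        n = self.grid
        y, x = np.mgrid[0:n, 0:n]
        x = (x + 0.5) / n
        y = (y + 0.5) / n
        self._aorta = (x - 0.18) ** 2 + (y - 0.5) ** 2 < 0.07**2
        kidney = ((x - 0.62) / 0.22) ** 2 + ((y - 0.5) / 0.30) ** 2
        medulla = ((x - 0.62) / 0.11) ** 2 + ((y - 0.5) / 0.15) ** 2
        self._cortex = (kidney < 1.0) & (medulla >= 1.0)
        self._medulla = medulla < 1.0
        self._anatomy = np.full((n, n), self.background_mu)
        self._anatomy[self._cortex] += 0.15
        self._anatomy[self._medulla] += 0.10
        self._anatomy[self._aorta] += 0.25

    def region_mask(self, name: str) -> np.ndarray:
        """Boolean pixel mask for ``"aorta"``, ``"cortex"`` or ``"medulla"``."""
        try:
            return {"aorta": self._aorta, "cortex": self._cortex, "medulla": self._medulla}[
                name
            ].copy()
        except KeyError:
            raise ParameterError(f"unknown region {name!r}") from None

    def blood_conc(self, tau: float) -> float:
        return float(self.bolus.conc(np.asarray(tau)))

    def tissue_conc(self, tau: float, rbv: float, k: float) -> float:
        cb = float(self.bolus.conc(np.asarray(tau)))
        cum = float(self.bolus.cum(np.asarray(tau)))
        return rbv * cb + k * cum

    def render(self, t: float, injection_time: float | None) -> np.ndarray:
        """Attenuation image at absolute time t; no contrast before injection."""
        img = self._anatomy.copy()
        if injection_time is None:
            return img
        tau = t - injection_time
        if tau <= 0:
            return img
        img[self._aorta] += self.blood_conc(tau)
        img[self._cortex] += self.tissue_conc(tau, self.rbv_cortex, self.k_cortex)
        img[self._medulla] += self.tissue_conc(tau, self.rbv_medulla, self.k_medulla)
        return img


# ---------------------------------------------------------------------------
# protocol execution and image-domain operations


def run_dsa_protocol(
    protocol: DsaProtocol,
    cardiac: TriggerTrain,
    resp: RespTrace,
    scene: KidneyScene,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ProjectionStack:
    """Execute the DSA event sequence against a dynamic scene.

    The run uses the first breath hold of ``resp``: pre-contrast frames are
    exposed at successive R peaks inside the hold (every
    ``frames_per_beat``-th beat), the injector command is issued at the
    last pre-contrast frame (the bolus concentration is exactly zero at the
    injection instant, so that frame is uncontaminated), and post-contrast
    frames follow one per beat.  Optional multiplicative Gaussian noise of
    relative standard deviation ``noise_sd`` models detector/physiologic
    fluctuation.

    Raises
    ------
    DsaProtocolError
        If the breath hold does not contain enough heartbeats for the
        frame budget; the message states the required hold duration.
    """
    if not resp.breath_holds:
        raise DsaProtocolError("respiration trace has no breath hold")
    hold_start, hold_end = resp.breath_holds[0]
    peaks = cardiac.event_times
    in_hold = peaks[(peaks >= hold_start) & (peaks <= hold_end)]
    needed = protocol.n_total_frames * protocol.frames_per_beat
    if in_hold.size < needed:
        mean_rr = float(np.mean(cardiac.intervals)) if len(cardiac) > 1 else float("nan")
        raise DsaProtocolError(
            f"breath hold of {hold_end - hold_start:g}s contains {in_hold.size} "
            f"beats but the protocol needs {needed}; a hold of at least "
            f"{needed * mean_rr:.2f}s is required"
        )
    frame_times = in_hold[:: protocol.frames_per_beat][: protocol.n_total_frames]
    injection_time = float(frame_times[protocol.n_pre_frames - 1])

    frames = np.stack([scene.render(t, injection_time) for t in frame_times])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames * (1.0 + noise_sd * rng.standard_normal(frames.shape))

    return ProjectionStack(
        frames,
        frame_times,
        metadata={
            "n_pre_frames": protocol.n_pre_frames,
            "n_post_frames": protocol.n_post_frames,
            "injection_time": injection_time,
            "hold": [float(hold_start), float(hold_end)],
            "ventilator_restart_time": float(hold_end),
            "frames_per_beat": protocol.frames_per_beat,
        },
    )


def make_mask(pre_frames) -> np.ndarray:
    """Average the pre-contrast frames into the subtraction mask."""
    frames = [np.asarray(f, dtype=float) for f in pre_frames]
    if not frames:
        raise ParameterError("no pre-contrast frames")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ParameterError("pre-contrast frames have mismatched shapes")
    return np.mean(np.stack(frames), axis=0)


def subtract(frames, mask: np.ndarray, mode: str = "linear") -> np.ndarray:
    """Subtract the mask from each frame.

    ``linear`` returns ``frame - mask`` (direct enhancement); ``log``
    returns ``ln(mask) - ln(frame)``, the line-integral contrast signal of
    transmission imaging, and requires strictly positive intensities.
    """
    frames = np.asarray(frames, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[1:] != mask.shape:
        raise ParameterError("frame and mask shapes differ")
    if mode == "linear":
        return frames - mask
    if mode == "log":
        if np.any(frames <= 0) or np.any(mask <= 0):
            raise ParameterError("log subtraction requires strictly positive pixels")
        return np.log(mask)[None] - np.log(frames)
    raise ParameterError(f"unknown subtraction mode {mode!r}")


def subtract_stack(stack: ProjectionStack, mode: str = "linear") -> ProjectionStack:
    """Mask-subtract a full DSA stack: average its pre frames, subtract, keep post."""
    n_pre = int(stack.metadata.get("n_pre_frames", 0))
    if not 0 < n_pre < len(stack):
        raise ParameterError("stack metadata lacks a valid n_pre_frames")
    mask = make_mask(stack.frames[:n_pre])
    sub = subtract(stack.frames, mask, mode=mode)
    return ProjectionStack(sub, stack.frame_times, dict(stack.metadata))


def extract_tac(stack: ProjectionStack, roi: np.ndarray, label: str = "") -> TimeAttenuationCurve:
    """Mean subtracted intensity over an ROI, one sample per frame."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stack.frames.shape[1:]:
        raise ParameterError("ROI shape does not match frames")
    if not roi.any():
        raise ParameterError("ROI is empty")
    values = stack.frames[:, roi].mean(axis=1)
    return TimeAttenuationCurve(stack.frame_times, values, roi_label=label)


# ---------------------------------------------------------------------------
# functional analysis


def fit_gamma_variate(tac: TimeAttenuationCurve) -> GammaFit:
    """Nonlinear least-squares gamma-variate fit of the first-pass portion.

    The fitted form is the peak-normalized gamma variate (see
    :func:`gamma_variate`), initialized from moments: onset at the first
    sample exceeding 10% of the peak, shape from the default first-pass
    value, scale from the peak position.  Samples after the curve first
    falls back below 10% of the peak are excluded (recirculation guard).
    """
    if len(tac) < 5:
        raise ParameterError("need at least 5 samples to fit")
    v = tac.values
    t = tac.times
    if not np.any(v > 0):
        raise ParameterError("all-zero or nonpositive TAC")

    ipk = int(np.argmax(v))
    peak = v[ipk]
    above = np.flatnonzero(v >= 0.1 * peak)
    i_on = above[0]
    i_end = len(v)
    for i in range(ipk + 1, len(v)):
        if v[i] < 0.1 * peak:
            i_end = i + 1
            break
    tf, vf = t[:i_end], v[:i_end]

    t0_0 = t[i_on - 1] if i_on > 0 else t[i_on] - (t[1] - t[0])
    alpha0 = 3.0
    beta0 = max((t[ipk] - t0_0) / alpha0, 1e-3)
    p0 = [peak, alpha0, beta0, t0_0]
    lower = [0.0, 0.05, 1e-4, t[0] - (t[-1] - t[0])]
    upper = [10.0 * peak, 50.0, 10.0 * (t[-1] - t[0]), t[ipk]]
    try:
        popt, _ = optimize.curve_fit(
            gamma_variate, tf, vf, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"gamma-variate fit did not converge: {exc}") from exc
    resid = vf - gamma_variate(tf, *popt)
    return GammaFit(
        amplitude=float(popt[0]),
        alpha_g=float(popt[1]),
        beta_g=float(popt[2]),
        t0=float(popt[3]),
        rss=float(np.sum(resid**2)),
    )


def perfusion_index(tissue: TimeAttenuationCurve, aorta: TimeAttenuationCurve) -> float:
    """Peak tissue enhancement divided by the aortic area under the curve.

    A unit-free perfusion surrogate (per second, arbitrary units); invariant
    under common rescaling of both curves.
    """
    auc = aorta.auc
    if auc <= 0:
        raise ParameterError("aortic AUC must be positive")
    return tissue.peak / auc


def patlak(
    tissue: TimeAttenuationCurve,
    blood: TimeAttenuationCurve,
    fit_window=None,
) -> PatlakResult:
    """Patlak analysis of a tissue TAC against the blood (aortic) TAC.

    Plots ``y = C(t)/Cb(t)`` against ``x = (∫0^t Cb dτ)/Cb(t)`` (trapezoidal
    integral over the sampled curve, with concentrations taken as zero
    before the first sample) and fits an ordinary least-squares line: the
    slope estimates permeability (transfer constant, per second) and the
    intercept the residual blood volume fraction.

    ``fit_window`` selects the samples entering the regression (an index
    array or slice); by default all samples after the bolus peak of Cb
    where Cb > 0 are used, the quasi-equilibrium phase of the first pass.
    """
    if not np.allclose(tissue.times, blood.times):
        raise ParameterError("tissue and blood TACs must share a time grid")
    t = blood.times
    cb = blood.values
    c = tissue.values
    cum = cumulative_trapezoid(cb, t, initial=0.0)

    if fit_window is None:
        idx = np.arange(len(t))
        idx = idx[(idx > np.argmax(cb)) & (cb[idx] > 0)]
    else:
        idx = np.arange(len(t))[fit_window]
    if np.any(cb[idx] <= 0):
        raise ParameterError("blood concentration must be positive on the fit window")
    if idx.size < 2:
        raise FitError("fewer than 2 usable Patlak points")

    x = cum[idx] / cb[idx]
    y = c[idx] / cb[idx]
    res = stats.linregress(x, y)
    return PatlakResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        points=np.column_stack([x, y]),
    )


# ---------------------------------------------------------------------------
# synthetic TAC generators


def _beat_times(n_samples: int, mean_rr: float) -> np.ndarray:
    return np.arange(n_samples) * mean_rr


def synthesize_patlak_tacs(
    rbv: float,
    k: float,
    n_beats: int = 34,
    mean_rr: float = 0.145,
    bolus: GammaBolus | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "tissue",
):
    """Generate (tissue, blood) TAC pair obeying the Patlak model exactly.

    One sample per heartbeat for ``n_beats`` beats after injection (time 0),
    blood curve from the analytic bolus, tissue curve
    ``C = rbv*Cb + K*∫Cb`` with the exact cumulative integral.  Optional
    multiplicative Gaussian noise of relative sd ``noise_sd`` is applied
    independently to both curves.
    """
    if bolus is None:
        bolus = GammaBolus()
    t = _beat_times(n_beats + 1, mean_rr)  # include the injection instant
    cb = bolus.conc(t)
    c = rbv * cb + k * bolus.cum(t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cb = cb * (1.0 + noise_sd * rng.standard_normal(cb.shape))
        c = c * (1.0 + noise_sd * rng.standard_normal(c.shape))
    return (
        TimeAttenuationCurve(t, c, roi_label=label),
        TimeAttenuationCurve(t, cb, roi_label="aorta"),
    )


def synthesize_perfusion_tac(
    target_index: float,
    aorta: TimeAttenuationCurve,
    alpha_g: float = 3.0,
    beta_g: float = 0.55,
    t0: float = 0.35,
    label: str = "tissue",
) -> TimeAttenuationCurve:
    """Tissue bolus scaled so that peak/AUC(aorta) equals ``target_index``.

    Round-trips a requested perfusion index by construction: the returned
    curve is a gamma-variate whose amplitude is ``target_index * AUC``.
    """
    auc = aorta.auc
    if auc <= 0:
        raise ParameterError("aortic AUC must be positive")
    shape = gamma_variate(aorta.times, 1.0, alpha_g, beta_g, t0)
    peak = float(np.max(shape))
    if peak <= 0:
        raise ParameterError("tissue bolus peaks outside the sampled span")
    values = shape * (target_index * auc / peak)
    return TimeAttenuationCurve(aorta.times, values, roi_label=label)


def make_patlak_tac(
    rbv: float, k: float, blood: TimeAttenuationCurve, label: str = "tissue"
) -> TimeAttenuationCurve:
    """Tissue TAC following the Patlak model for an arbitrary sampled Cb.

    Uses the trapezoidal cumulative integral of the given blood curve, so
    the construction is model-exact on the shared sample grid.
    """
    cum = cumulative_trapezoid(blood.values, blood.times, initial=0.0)
    return TimeAttenuationCurve(
        blood.times, rbv * blood.values + k * cum, roi_label=label
    )
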