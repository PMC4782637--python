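"""Cardiorespiratory gating sequencers for rotational micro-CT acquisition.

Three acquisition strategies are simulated, each producing an
:class:`AcquisitionLog`:

* :func:`prospective_sequence` — exposures fired in real time at the
  coincidence of a selected cardiac phase delay (a percentage of the RR
  interval) and a respiratory phase window; one exposure per angle, so the
  projection set has constant angular steps.  :func:`prospective_cine`
  repeats the sequence for every cardiac phase, acquiring full angular sets
  sequentially.
* :func:`retrospective_acquire` — a free-running pacer exposes at a fixed
  frame rate during continuous 360° rotations; cardiac/respiratory phases
  are assigned afterwards by :func:`sort_phases` (temporal registration to
  the R-peak train), yielding an irregular angular distribution per phase
  bin.
* :func:`fpg_sequence` — fast prospective gating: all requested cardiac
  phases are acquired in rapid succession at each angle, with per-beat
  delays computed from an exponentially-weighted moving-average prediction
  of the next RR interval (:func:`ema_predict`), then the gantry rotates.

Angles are degrees in [0, 360), rotation mathematically positive; times are
seconds from acquisition start.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .physio import ParameterError, RespTrace, TriggerTrain

__all__ = [
    "GatingConfig",
    "AcquisitionLog",
    "GatingTimeoutError",
    "prospective_sequence",
    "prospective_cine",
    "retrospective_acquire",
    "sort_phases",
    "ema_predict",
    "ema_series",
    "fpg_sequence",
]

_EPS = 1e-9

#: Detector readout ceiling, frames/second.
MAX_FRAME_RATE = 10.0

LOG_COLUMNS = [
    "time_s",
    "angle_deg",
    "rotation",
    "cardiac_frac",
    "cardiac_bin",
    "resp_frac",
    "target_phase",
]


class GatingTimeoutError(RuntimeError):
    """Coincidence was not achieved before the time budget ran out."""

    def __init__(self, message: str, angle_index: int, n_acquired: int):
        super().__init__(message)
        self.angle_index = angle_index
        self.n_acquired = n_acquired


@dataclass(frozen=True)
class GatingConfig:
    """Acquisition-geometry and gating parameters shared by the sequencers.

    Attributes
    ----------
    n_phases
        Number N of cardiac phase bins; each bin spans 1/N of the RR
        interval (default 10, i.e. 10% bins).
    phase_fracs
        Cardiac phase delays expressed as fractions of the RR interval,
        sorted, unique, in [0, 1).  Defaults to N equispaced phases.
    angular_step, n_angles
        Gantry step (degrees) and number of angular positions;
        ``angular_step * n_angles`` must not exceed 360°.
    resp_window
        Respiratory gate as a (start, end) phase-fraction interval; the
        default (0.85, 1.0) is late/end expiration.
    ema_alpha
        Weight of the exponential moving average used to predict the next
        RR interval in fast prospective gating.
    min_frame_interval
        Detector dead time between exposures, seconds (0.1 s at the 10
        frames/s readout ceiling).
    rotation_settle
        Time for the rotation stage to reach the next angle, during which
        triggers are inhibited, seconds.
    n_rotations, frame_rate
        Retrospective pacer settings: number of continuous 360° rotations
        and pacer frame rate (capped at 10 frames/s by the detector).
    """

    n_phases: int = 10
    phase_fracs: tuple = ()
    angular_step: float = 1.0
    n_angles: int = 360
    resp_window: tuple = (0.85, 1.0)
    ema_alpha: float = 0.3
    min_frame_interval: float = 0.1
    rotation_settle: float = 0.1
    n_rotations: int = 1
    frame_rate: float = 10.0

    def __post_init__(self) -> None:
        if self.n_phases < 1:
            raise ParameterError("n_phases must be >= 1")
        fracs = tuple(self.phase_fracs) or tuple(
            i / self.n_phases for i in range(self.n_phases)
        )
        object.__setattr__(self, "phase_fracs", fracs)
        arr = np.asarray(fracs, dtype=float)
        if arr.size == 0:
            raise ParameterError("phase_fracs must be nonempty")
        if np.any(arr < 0) or np.any(arr >= 1):
            raise ParameterError("phase_fracs must lie in [0, 1)")
        if np.any(np.diff(arr) <= 0):
            raise ParameterError("phase_fracs must be sorted and unique")
        if self.angular_step <= 0 or self.n_angles < 1:
            raise ParameterError("angular geometry must be positive")
        if self.angular_step * self.n_angles > 360.0 + _EPS:
            raise ParameterError("angular_step * n_angles must not exceed 360 degrees")
        if not 0 < self.ema_alpha <= 1:
            raise ParameterError("ema_alpha must be in (0, 1]")
        if self.frame_rate <= 0 or self.frame_rate > MAX_FRAME_RATE + _EPS:
            raise ParameterError(
                f"frame_rate must be in (0, {MAX_FRAME_RATE}] frames/s (detector limit)"
            )
        if self.min_frame_interval < 0 or self.rotation_settle < 0:
            raise ParameterError("intervals must be nonnegative")
        if self.n_rotations < 1:
            raise ParameterError("n_rotations must be >= 1")
        lo, hi = self.resp_window
        if not (0 <= lo <= 1 and 0 <= hi <= 1 and lo <= hi):
            raise ParameterError("resp_window must satisfy 0 <= start <= end <= 1")


@dataclass
class AcquisitionLog:
    """Per-exposure acquisition records.

    Wraps a DataFrame with columns ``time_s, angle_deg, rotation,
    cardiac_frac, cardiac_bin, resp_frac, target_phase``; unassigned phase
    fields are NaN.  Exposure times are strictly increasing and at least
    ``min_frame_interval`` apart.
    """

    df: pd.DataFrame
    min_frame_interval: float = 0.0

    def __post_init__(self) -> None:
        missing = [c for c in LOG_COLUMNS if c not in self.df.columns]
        if missing:
            raise ParameterError(f"log missing columns {missing}")
        t = self.df["time_s"].to_numpy(float)
        if t.size >= 2:
            gaps = np.diff(t)
            if np.any(gaps <= 0):
                raise ParameterError("exposure times must be strictly increasing")
            if np.any(gaps < self.min_frame_interval - _EPS):
                raise ParameterError("exposures violate min_frame_interval")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df["time_s"].to_numpy(float)

    @property
    def angles(self) -> np.ndarray:
        return self.df["angle_deg"].to_numpy(float)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, min_frame_interval: float = 0.0):
        return cls(pd.read_csv(path), min_frame_interval=min_frame_interval)

    @classmethod
    def from_records(cls, records, min_frame_interval: float = 0.0):
        df = pd.DataFrame(records, columns=LOG_COLUMNS)
        return cls(df, min_frame_interval=min_frame_interval)


def _in_window(phase: float, window) -> bool:
    lo, hi = window
    return lo <= phase < hi


def prospective_sequence(
    cardiac: TriggerTrain,
    resp: RespTrace,
    cfg: GatingConfig,
    phase_index: int,
    max_time: float,
    start_time: float = 0.0,
) -> AcquisitionLog:
    """Prospective cardiorespiratory coincidence gating for one cardiac phase.

    For each beat, the candidate exposure time is the R peak plus the
    selected phase delay (``phase_fracs[phase_index]`` of that beat's RR
    interval).  The exposure fires only if the candidate also falls inside
    the respiratory window; the gantry then rotates one step and triggers
    are inhibited until the rotation settles.  Exactly one exposure is
    acquired per angle, at angles ``0, step, 2*step, ...``.

    Raises
    ------
    GatingTimeoutError
        If the coincidence for some angle is not achieved before
        ``max_time`` (for example with a zero-width respiratory window).
    """
    if not 0 <= phase_index < len(cfg.phase_fracs):
        raise ParameterError("phase_index out of range")
    if max_time <= 0:
        raise ParameterError("max_time must be positive")
    frac = cfg.phase_fracs[phase_index]
    peaks = cardiac.event_times
    inhibit = max(cfg.rotation_settle, cfg.min_frame_interval)

    records = []
    angle_idx = 0
    ready = start_time
    for k in range(len(peaks) - 1):
        r = peaks[k]
        rr = peaks[k + 1] - peaks[k]
        te = r + frac * rr
        if te > max_time:
            break
        if te < ready - _EPS:
            continue
        if _in_window(float(resp.phase(te)), cfg.resp_window):
            records.append(
                (
                    te,
                    (angle_idx * cfg.angular_step) % 360.0,
                    0,
                    frac,
                    min(int(frac * cfg.n_phases), cfg.n_phases - 1),
                    float(resp.phase(te)),
                    phase_index,
                )
            )
            ready = te + inhibit
            angle_idx += 1
            if angle_idx == cfg.n_angles:
                return AcquisitionLog.from_records(
                    records, min_frame_interval=cfg.min_frame_interval
                )
    raise GatingTimeoutError(
        f"prospective gating stalled at angle index {angle_idx} "
        f"({len(records)}/{cfg.n_angles} exposures before t={max_time:g}s)",
        angle_index=angle_idx,
        n_acquired=len(records),
    )


def prospective_cine(
    cardiac: TriggerTrain,
    resp: RespTrace,
    cfg: GatingConfig,
    max_time: float,
) -> AcquisitionLog:
    """Sequential full angular sets, one per cardiac phase delay.

    The classic cine protocol: acquire all angles at phase 0, then repeat
    the whole rotation for each further entry of ``phase_fracs``.  The
    per-phase set index is recorded in the ``rotation`` column.
    """
    logs = []
    start = 0.0
    for phase_index in range(len(cfg.phase_fracs)):
        log = prospective_sequence(
            cardiac, resp, cfg, phase_index, max_time, start_time=start
        )
        df = log.df.copy()
        df["rotation"] = phase_index
        logs.append(df)
        start = df["time_s"].iloc[-1] + max(cfg.rotation_settle, cfg.min_frame_interval)
    return AcquisitionLog(
        pd.concat(logs, ignore_index=True), min_frame_interval=cfg.min_frame_interval
    )


def retrospective_acquire(
    cardiac: TriggerTrain,
    resp: RespTrace,
    cfg: GatingConfig,
    rotation_duration: float,
) -> AcquisitionLog:
    """Free-running paced acquisition over continuous 360° rotations.

    A pacer exposes at the fixed period ``1/frame_rate`` throughout each of
    ``cfg.n_rotations`` rotations of duration ``rotation_duration``; the
    angle grows linearly with time within each rotation.  Cardiac and
    respiratory phase fields are left unassigned — they are filled in
    afterwards by :func:`sort_phases`.  ``cardiac`` and ``resp`` are
    accepted for interface symmetry with the gated sequencers; the pacer is
    free-running and does not consult them.
    """
    if rotation_duration <= 0:
        raise ParameterError("rotation_duration must be positive")
    period = 1.0 / cfg.frame_rate
    per_rot = int(np.floor(rotation_duration / period + _EPS))
    records = []
    for rot in range(cfg.n_rotations):
        t0 = rot * rotation_duration
        for k in range(per_rot):
            t = t0 + k * period
            angle = (360.0 * (t - t0) / rotation_duration) % 360.0
            records.append((t, angle, rot, np.nan, np.nan, np.nan, np.nan))
    return AcquisitionLog.from_records(records, min_frame_interval=period - _EPS)


def sort_phases(
    log: AcquisitionLog,
    cardiac: TriggerTrain,
    resp: RespTrace,
    cfg: GatingConfig,
) -> AcquisitionLog:
    """Post-hoc temporal registration of exposures to the ECG.

    For each exposure at time t, the enclosing beat is the most recent R
    peak at or before t; the cardiac phase fraction is the elapsed time
    since that peak divided by the beat's RR interval, and the bin is
    ``floor(frac * N)`` clamped to N−1 (half-open bins ``[k/N, (k+1)/N)``).
    Exposures before the first R peak or after the last one (where the RR
    interval is undefined) keep NaN phase fields.
    """
    peaks = cardiac.event_times
    if peaks.size == 0:
        raise ParameterError("cardiac trigger train is empty")
    df = log.df.copy()
    t = df["time_s"].to_numpy(float)
    idx = np.searchsorted(peaks, t, side="right") - 1
    valid = (idx >= 0) & (idx < peaks.size - 1)
    frac = np.full(t.shape, np.nan)
    safe = np.clip(idx, 0, max(peaks.size - 2, 0))
    rr = peaks[safe + 1] - peaks[safe]
    frac[valid] = (t[valid] - peaks[safe[valid]]) / rr[valid]
    bins = np.full(t.shape, np.nan)
    bins[valid] = np.minimum(
        np.floor(frac[valid] * cfg.n_phases), cfg.n_phases - 1
    )
    df["cardiac_frac"] = frac
    df["cardiac_bin"] = bins
    df["resp_frac"] = np.atleast_1d(resp.phase(t))
    return AcquisitionLog(df, min_frame_interval=log.min_frame_interval)


def ema_series(rr_history, alpha: float) -> np.ndarray:
    """Exponential-moving-average predictions p_k for each prefix of the history.

    ``p_1 = rr_1`` and ``p_k = alpha * rr_k + (1 - alpha) * p_{k-1}``.
    """
    rr = np.asarray(rr_history, dtype=float)
    if rr.size == 0:
        raise ParameterError("rr_history is empty")
    if not 0 < alpha <= 1:
        raise ParameterError("alpha must be in (0, 1]")
    out = np.empty_like(rr)
    out[0] = rr[0]
    for k in range(1, rr.size):
        out[k] = alpha * rr[k] + (1.0 - alpha) * out[k - 1]
    return out


def ema_predict(rr_history, alpha: float) -> float:
    """Predicted next RR interval: the EMA of the observed intervals."""
    return float(ema_series(rr_history, alpha)[-1])


def fpg_sequence(
    cardiac: TriggerTrain,
    cfg: GatingConfig,
    max_time: float,
) -> AcquisitionLog:
    """Fast prospective gating: all cardiac phases per angle, then rotate.

    At each R peak the elapsed interval updates an exponential moving
    average that predicts the next RR; pending phase delays are scheduled
    at ``R + frac * predicted_RR``.  Phases whose exposure would violate
    the detector dead time (``min_frame_interval``) are deferred to the
    earliest feasible later beat, preserving phase order.  When every entry
    of ``phase_fracs`` has been acquired at the current angle a rotation
    trigger is emitted and acquisition resumes at the next angle, so the
    completed log has exactly ``n_angles * len(phase_fracs)`` exposures at
    constant angular steps.
    """
    if max_time <= 0:
        raise ParameterError("max_time must be positive")
    peaks = cardiac.event_times
    if peaks.size < 3:
        raise ParameterError("cardiac train too short for RR prediction")

    alpha = cfg.ema_alpha
    records = []
    last_t = -np.inf
    rot_ready = 0.0
    k = 1  # beat index: beat k starts at peaks[k]; first observed RR ends there
    pred = peaks[1] - peaks[0]

    def advance_beat():
        nonlocal k, pred
        k += 1
        if k >= peaks.size:
            raise GatingTimeoutError(
                f"fast prospective gating ran out of beats: "
                f"{len(records)} exposures, "
                f"{len(records) // len(cfg.phase_fracs)} complete angles of "
                f"{cfg.n_angles}",
                angle_index=len(records) // len(cfg.phase_fracs),
                n_acquired=len(records),
            )
        rr = peaks[k] - peaks[k - 1]
        pred = alpha * rr + (1.0 - alpha) * pred

    for angle_idx in range(cfg.n_angles):
        angle = (angle_idx * cfg.angular_step) % 360.0
        for j, frac in enumerate(cfg.phase_fracs):
            while True:
                te = peaks[k] + frac * pred
                if te > max_time:
                    raise GatingTimeoutError(
                        f"fast prospective gating exceeded t={max_time:g}s at "
                        f"angle index {angle_idx} ({len(records)} exposures)",
                        angle_index=angle_idx,
                        n_acquired=len(records),
                    )
                if te >= last_t + cfg.min_frame_interval - _EPS and te >= rot_ready:
                    break
                advance_beat()
            records.append(
                (
                    te,
                    angle,
                    0,
                    frac,
                    min(int(frac * cfg.n_phases), cfg.n_phases - 1),
                    np.nan,
                    j,
                )
            )
            last_t = te
        rot_ready = last_t + cfg.rotation_settle
    return AcquisitionLog.from_records(
        records, min_frame_interval=cfg.min_frame_interval
    )
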