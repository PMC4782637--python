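"""Synthetic cardiorespiratory physiology and TTL-style trigger synthesis.

In the gated-acquisition chain a physiologic monitor conditions the ECG and
respiration signals and a threshold comparator converts them to TTL pulses:
one pulse per R peak (cardiac) or per breath (respiratory).  Downstream
sequencers consume only those pulse trains, so this module models the
physiology at the level that matters for gating:

* :func:`simulate_ecg` — an R-peak point process with configurable RR
  interval and beat-to-beat Gaussian jitter (irregular heart rates),
* :func:`simulate_ventilated_respiration` — a mechanical-ventilator breath
  schedule with inspiration fraction and programmable breath holds that
  freeze the animal at end expiration,
* :func:`detect_triggers` — the rising-edge comparator with a refractory
  period, operating on any sampled waveform.

Times are continuous seconds from acquisition start.  Waveforms are sampled
at a uniform rate (default 1 kHz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParameterError",
    "TriggerTrain",
    "CardiacTrace",
    "RespTrace",
    "simulate_ecg",
    "simulate_ventilated_respiration",
    "detect_triggers",
    "impulse_train",
]

_EPS = 1e-9


class ParameterError(ValueError):
    """Invalid parameter or degenerate input to a simulation routine."""


@dataclass(frozen=True)
class TriggerTrain:
    """Ordered TTL event times emulating the comparator output.

    Parameters
    ----------
    event_times
        Strictly increasing event times in seconds.
    refractory
        Minimum spacing enforced between events, seconds.
    source
        ``"cardiac"`` or ``"respiratory"``.
    """

    event_times: np.ndarray
    refractory: float = 0.0
    source: str = "cardiac"

    def __post_init__(self) -> None:
        times = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", times)
        if times.ndim != 1:
            raise ParameterError("event_times must be one-dimensional")
        if self.refractory < 0:
            raise ParameterError("refractory must be >= 0")
        if self.source not in ("cardiac", "respiratory"):
            raise ParameterError(f"unknown trigger source {self.source!r}")
        if times.size >= 2:
            gaps = np.diff(times)
            if np.any(gaps <= 0):
                raise ParameterError("event_times must be strictly increasing")
            if np.any(gaps < self.refractory - _EPS):
                raise ParameterError("event spacing violates refractory period")

    def __len__(self) -> int:
        return int(self.event_times.size)

    @property
    def intervals(self) -> np.ndarray:
        """Inter-event intervals (RR intervals for a cardiac train), seconds."""
        return np.diff(self.event_times)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.event_times, "value": 1.0}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, refractory: float = 0.0, source: str = "cardiac"):
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(float), refractory=refractory, source=source)


@dataclass(frozen=True)
class CardiacTrace:
    """R-peak times of a simulated ECG.

    ``r_peak_times`` are strictly increasing; with ``rr_jitter_sd == 0`` the
    RR intervals are all exactly ``mean_rr``.
    """

    r_peak_times: np.ndarray
    mean_rr: float
    rr_jitter_sd: float
    seed: int

    def __post_init__(self) -> None:
        times = np.asarray(self.r_peak_times, dtype=float)
        object.__setattr__(self, "r_peak_times", times)
        if times.size >= 2 and np.any(np.diff(times) <= 0):
            raise ParameterError("r_peak_times must be strictly increasing")

    @property
    def rr_intervals(self) -> np.ndarray:
        return np.diff(self.r_peak_times)

    def trigger_train(self, refractory: float = 0.0) -> TriggerTrain:
        """The idealized TTL train a comparator would emit: one pulse per R peak."""
        return TriggerTrain(self.r_peak_times, refractory=refractory, source="cardiac")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.r_peak_times, "value": 1.0}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class RespTrace:
    """A ventilator-driven respiration schedule.

    Phase convention: phase 0 is breath onset (start of inspiration), which
    coincides with the end-expiratory baseline; inspiration occupies
    ``[0, insp_fraction)`` of each cycle, expiration the remainder.  During a
    breath hold the ventilator is stopped at end expiration, so
    :meth:`phase` is frozen at the end-expiratory value 0.0 and the lung
    waveform sits at baseline.
    """

    cycle_times: np.ndarray
    rate: float
    insp_fraction: float
    breath_holds: tuple = ()
    duration: float = 0.0

    def __post_init__(self) -> None:
        times = np.asarray(self.cycle_times, dtype=float)
        object.__setattr__(self, "cycle_times", times)
        object.__setattr__(self, "breath_holds", tuple(tuple(h) for h in self.breath_holds))
        if times.size >= 2 and np.any(np.diff(times) <= 0):
            raise ParameterError("cycle_times must be strictly increasing")
        for start, end in self.breath_holds:
            if np.any((times > start) & (times < end)):
                raise ParameterError("a breath cycle starts inside a hold interval")

    @property
    def period(self) -> float:
        """Breath period, seconds."""
        return 60.0 / self.rate

    def phase(self, t) -> np.ndarray:
        """Respiratory phase fraction in [0, 1) at time(s) ``t``.

        Between the completion of one cycle and the start of the next (a
        breath hold), the phase is the frozen end-expiratory value 0.0.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.cycle_times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.cycle_times) - 1)
        start = self.cycle_times[idx]
        frac = (t - start) / self.period
        frac = np.where((frac >= 0.0) & (frac < 1.0), frac, 0.0)
        return frac if frac.size > 1 else frac.reshape(())

    # alias matching the "phase function" vocabulary used by the sequencers
    phase_fn = phase

    def in_hold(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros(t.shape, dtype=bool)
        for start, end in self.breath_holds:
            out |= (t >= start) & (t < end)
        return out if out.size > 1 else out.reshape(())

    def waveform(self, fs: float = 1000.0):
        """Sampled piecewise-linear lung-volume surrogate.

        Rises linearly over inspiration, falls linearly over expiration,
        baseline 0 during holds.  Returns ``(times, values)``.
        """
        times = np.arange(0.0, self.duration + 0.5 / fs, 1.0 / fs)
        ph = np.atleast_1d(self.phase(times))
        f = self.insp_fraction
        values = np.where(ph < f, ph / f, (1.0 - ph) / (1.0 - f))
        return times, values

    def to_csv(self, path, fs: float = 1000.0) -> None:
        times, values = self.waveform(fs)
        pd.DataFrame({"time_s": times, "value": values}).to_csv(path, index=False)


def simulate_ecg(
    duration: float, mean_rr: float, rr_jitter_sd: float = 0.0, seed: int = 0
) -> CardiacTrace:
    """Simulate an R-peak train covering ``[0, duration]`` seconds.

    RR intervals are drawn as ``mean_rr + N(0, rr_jitter_sd)``; the jitter
    standard deviation must stay below ``mean_rr / 3`` so intervals remain
    positive (draws are additionally clipped at 5% of ``mean_rr`` as a
    safety floor).  The same seed always reproduces the same trace.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    if mean_rr <= 0:
        raise ParameterError("mean_rr must be positive")
    if rr_jitter_sd < 0 or rr_jitter_sd >= mean_rr / 3:
        raise ParameterError("rr_jitter_sd must satisfy 0 <= sd < mean_rr/3")

    rng = np.random.default_rng(seed)
    times = [0.0]
    t = 0.0
    while t <= duration + _EPS:
        rr = mean_rr
        if rr_jitter_sd > 0:
            rr = max(mean_rr + rng.normal(0.0, rr_jitter_sd), 0.05 * mean_rr)
        t += rr
        if t <= duration + _EPS:
            times.append(t)
    return CardiacTrace(
        np.asarray(times), mean_rr=mean_rr, rr_jitter_sd=rr_jitter_sd, seed=seed
    )


def simulate_ventilated_respiration(
    duration: float,
    rate: float,
    insp_fraction: float = 0.5,
    breath_holds=(),
) -> RespTrace:
    """Simulate the ventilator schedule: regular breaths plus breath holds.

    Breaths recur with period ``60/rate`` seconds.  A hold interval
    ``(start, end)`` suspends the ventilator at end expiration: no cycle
    starts inside the interval and the next breath begins at ``end`` (the
    ventilator restart).
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    if rate <= 0:
        raise ParameterError("rate must be positive")
    if not 0 < insp_fraction < 1:
        raise ParameterError("insp_fraction must be in (0, 1)")
    holds = sorted(tuple(h) for h in breath_holds)
    for (s0, e0), (s1, e1) in zip(holds, holds[1:]):
        if s1 < e0:
            raise ParameterError("breath_holds must be disjoint")
    for s, e in holds:
        if e <= s:
            raise ParameterError("hold end must exceed hold start")
        if s < 0 or e > duration:
            raise ParameterError("breath_holds must lie inside [0, duration]")

    period = 60.0 / rate
    cycles = []
    t = 0.0
    while t <= duration + _EPS:
        for s, e in holds:
            if s - _EPS <= t < e:
                t = e
                break
        if t > duration + _EPS:
            break
        cycles.append(t)
        t += period
    return RespTrace(
        np.asarray(cycles),
        rate=rate,
        insp_fraction=insp_fraction,
        breath_holds=tuple(holds),
        duration=duration,
    )


def detect_triggers(
    times,
    values,
    threshold: float,
    refractory: float = 0.0,
    source: str = "cardiac",
) -> TriggerTrain:
    """Rising-edge threshold comparator with a refractory period.

    Emits one event at every upward crossing of ``threshold`` (sample below
    threshold followed by sample at/above it); crossings within
    ``refractory`` seconds of the previous accepted event are suppressed.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0 or values.size == 0:
        raise ParameterError("waveform is empty")
    if times.shape != values.shape:
        raise ParameterError("times and values must have equal length")
    if refractory < 0:
        raise ParameterError("refractory must be >= 0")
    if times.size >= 3:
        dt = np.diff(times)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ParameterError("waveform must be uniformly sampled")

    above = values >= threshold
    crossing = np.flatnonzero(~above[:-1] & above[1:]) + 1
    events = []
    last = -np.inf
    for i in crossing:
        if times[i] - last >= refractory - _EPS:
            events.append(times[i])
            last = times[i]
    return TriggerTrain(np.asarray(events), refractory=refractory, source=source)


def impulse_train(event_times, duration: float, fs: float = 1000.0):
    """Sample an ideal impulse train: 1.0 at the sample nearest each event.

    Convenience for exercising :func:`detect_triggers` against a known
    point process.  Returns ``(times, values)``.
    """
    times = np.arange(0.0, duration + 0.5 / fs, 1.0 / fs)
    values = np.zeros_like(times)
    idx = np.clip(np.round(np.asarray(event_times) * fs).astype(int), 0, times.size - 1)
    values[idx] = 1.0
    return times, values
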