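"""Synthetic acquisition chain: posture schedule -> strain -> ADC counts.

Stands in for the wearable hardware: a strain gauge on the lower back wired
as one leg of a voltage divider, read by a microcontroller ADC (10-bit,
0-1023) at 50 Hz, with the firmware reporting each sample as the trailing
rolling average of the previous two seconds.

A session is an ordered schedule of held postures.  Each posture maps to a
nominal back-strain fraction (upright sitting deforms the gauge least, severe
hunchback most, 0-10% strain nominally).  The simulator builds a
piecewise-constant strain trace with linear ramps between postures, adds an
Ornstein-Uhlenbeck body-jitter process, pushes the strain through the
log-normal sensor model (clamped at the 220 MOhm meter ceiling), converts the
divider voltage to integer counts, adds white measurement noise, and applies
the firmware rolling average.  All randomness is seeded; with both noise
standard deviations at zero the chain is fully deterministic.

The fixed divider resistor sits on the measured leg, so a drop in sensor
resistance (more strain) raises the reported counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .labels import POSTURES
from .sensor import PiezoParams, resistance

__all__ = [
    "DEFAULT_STRAIN_MAP",
    "SessionPlan",
    "CircuitConfig",
    "NoiseConfig",
    "RawTrace",
    "AcquisitionError",
    "posture_strain",
    "default_sensor",
    "default_plan",
    "simulate_session",
    "generate_dataset",
]

#: Nominal strain fraction induced at the gauge by each held posture.
DEFAULT_STRAIN_MAP = {
    "normal": 0.01,
    "slight_hunchback": 0.05,
    "severe_hunchback": 0.09,
}

#: Multimeter ceiling: resistances above this report as the ceiling (Ohm).
R_MAX = 220e6
#: Lowest strain the model is evaluated at; the log-normal form is singular at 0.
EPS_FLOOR = 1e-4


class AcquisitionError(ValueError):
    """Invalid session plan or configuration."""


def posture_strain(label: str, mapping: Mapping[str, float] | None = None) -> float:
    """Nominal strain fraction for a posture label.

    The default mapping places the three postures at 1%, 5% and 9% strain,
    inside the 0-10% range the gauge is designed for, and is strictly
    increasing with hunchback severity.
    """
    mapping = DEFAULT_STRAIN_MAP if mapping is None else mapping
    try:
        return float(mapping[label])
    except KeyError:
        raise AcquisitionError(f"unknown posture label {label!r}") from None


def default_sensor() -> PiezoParams:
    """Sensor parameters representative of the optimized composition.

    Shape a = 1.5 with c = 0.006 * exp(a^2) puts the critical strain at
    0.006, matching the selected 11% NiNs / 2.0% NCCF cell, so the whole
    0.01-0.09 posture range lies on the decreasing (working) branch.  The
    amplitude d = 1.1e4 Ohm*strain sets the working resistance near 1 MOhm
    mid-range, matched to the default divider resistor.
    """
    a = 1.5
    return PiezoParams(a=a, c=0.006 * float(np.exp(a * a)), d=1.1e4)


@dataclass(frozen=True)
class SessionPlan:
    """Ordered schedule of held postures with ramped transitions."""

    segments: tuple
    transition_s: float = 1.0

    def __init__(self, segments: Sequence[tuple[str, float]], transition_s: float = 1.0):
        segments = tuple((str(lbl), float(dur)) for lbl, dur in segments)
        if not segments:
            raise AcquisitionError("session plan needs at least one segment")
        for lbl, dur in segments:
            if lbl not in POSTURES:
                raise AcquisitionError(f"unknown posture label {lbl!r}")
            if dur <= 0:
                raise AcquisitionError("segment durations must be > 0")
        if transition_s < 0:
            raise AcquisitionError("transition_s must be >= 0")
        object.__setattr__(self, "segments", segments)
        object.__setattr__(self, "transition_s", float(transition_s))

    @property
    def duration_s(self) -> float:
        return sum(d for _, d in self.segments)


def default_plan() -> SessionPlan:
    """The standard test protocol: each posture held 10 s, in severity order."""
    return SessionPlan([(p, 10.0) for p in POSTURES])


@dataclass(frozen=True)
class CircuitConfig:
    """Voltage divider + ADC front end.

    The fixed resistor (default 1 MOhm, the geometric middle of the sensor's
    working resistance range) is on the measured leg: v = Vs * Rf / (Rf + R).
    """

    supply_v: float = 5.0
    r_fixed: float = 1e6
    adc_bits: int = 10
    sample_hz: float = 50.0
    rolling_window_s: float = 2.0

    def __post_init__(self):
        if not (self.supply_v > 0 and self.r_fixed > 0 and self.sample_hz > 0
                and self.rolling_window_s > 0):
            raise AcquisitionError("circuit values must be positive")
        if not (8 <= int(self.adc_bits) <= 16):
            raise AcquisitionError("adc_bits must lie in [8, 16]")

    @property
    def adc_max(self) -> int:
        return 2 ** int(self.adc_bits) - 1


@dataclass(frozen=True)
class NoiseConfig:
    """Body jitter (OU process on strain) plus white ADC measurement noise.

    Defaults model gentle postural sway (0.2% strain SD with a 1 s
    correlation time) and a 2-count electronics noise floor.
    """

    jitter_sd: float = 0.002
    jitter_corr_s: float = 1.0
    meas_sd_counts: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.jitter_sd < 0 or self.meas_sd_counts < 0:
            raise AcquisitionError("noise SDs must be >= 0")
        if self.jitter_corr_s <= 0:
            raise AcquisitionError("jitter_corr_s must be > 0")
        if self.seed is None:
            raise AcquisitionError("a seed is mandatory for stochastic simulation")


@dataclass(frozen=True)
class RawTrace:
    """One simulated session record: times, integer ADC counts, labels."""

    t: np.ndarray
    counts: np.ndarray
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "count": self.counts, "label": self.labels})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RawTrace":
        df = pd.read_csv(path)
        return cls(
            t=df["t_s"].to_numpy(float),
            counts=df["count"].to_numpy(int),
            labels=df["label"].to_numpy(object),
        )


def _nominal_profile(plan: SessionPlan, sample_hz: float,
                     mapping: Mapping[str, float]):
    """Per-sample nominal strain and label arrays for a plan.

    Each segment owns its time span; a transition ramp occupies the first
    ``transition_s`` of every segment after the first, interpolating linearly
    from the previous posture's strain.
    """
    n = int(round(plan.duration_s * sample_hz))
    t = np.arange(n) / sample_hz
    strain = np.empty(n)
    labels = np.empty(n, dtype=object)
    start = 0.0
    prev_eps = None
    for lbl, dur in plan.segments:
        eps = posture_strain(lbl, mapping)
        in_seg = (t >= start) & (t < start + dur)
        strain[in_seg] = eps
        labels[in_seg] = lbl
        if prev_eps is not None and plan.transition_s > 0:
            ramp = in_seg & (t < start + min(plan.transition_s, dur))
            frac = (t[ramp] - start) / plan.transition_s
            strain[ramp] = prev_eps + (eps - prev_eps) * frac
        prev_eps = eps
        start += dur
    return t, strain, labels


def _ou_jitter(n: int, dt: float, sd: float, corr_s: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path (exact discretization)."""
    if sd == 0:
        return np.zeros(n)
    phi = np.exp(-dt / corr_s)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    shocks = rng.normal(0.0, 1.0, n)
    x[0] = sd * shocks[0]
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov_sd * shocks[i]
    return x


def _trailing_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Trailing (causal) rolling mean; warm-up averages the samples seen so far."""
    s = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    idx = np.arange(1, len(x) + 1)
    lo = np.maximum(idx - window, 0)
    return (s[idx] - s[lo]) / (idx - lo)


def simulate_session(plan: SessionPlan,
                     sensor: PiezoParams | None = None,
                     circuit: CircuitConfig | None = None,
                     noise: NoiseConfig | None = None,
                     strain_map: Mapping[str, float] | None = None) -> RawTrace:
    """Run one session through the full acquisition chain.

    Pipeline per sample: nominal strain (+ ramps) + OU jitter, floored at
    ``EPS_FLOOR``; sensor resistance clamped at ``R_MAX``; divider voltage;
    ideal integer counts; + white measurement noise; clip to ADC range; then
    the firmware's trailing rolling average (rounded back to integer counts).
    Identical seeds give identical traces.
    """
    sensor = default_sensor() if sensor is None else sensor
    circuit = CircuitConfig() if circuit is None else circuit
    noise = NoiseConfig() if noise is None else noise
    mapping = DEFAULT_STRAIN_MAP if strain_map is None else strain_map

    t, strain, labels = _nominal_profile(plan, circuit.sample_hz, mapping)
    rng = np.random.default_rng(noise.seed)
    strain = strain + _ou_jitter(len(t), 1.0 / circuit.sample_hz,
                                 noise.jitter_sd, noise.jitter_corr_s, rng)
    strain = np.maximum(strain, EPS_FLOOR)

    r = np.minimum(resistance(strain, sensor), R_MAX)
    v_frac = circuit.r_fixed / (circuit.r_fixed + r)
    counts = np.rint(v_frac * circuit.adc_max)
    counts = counts + rng.normal(0.0, noise.meas_sd_counts, len(counts))
    counts = np.clip(counts, 0, circuit.adc_max)

    window = max(1, int(round(circuit.rolling_window_s * circuit.sample_hz)))
    smoothed = _trailing_mean(counts, window)
    out = np.clip(np.rint(smoothed), 0, circuit.adc_max).astype(int)
    return RawTrace(t=t, counts=out, labels=labels)


def generate_dataset(n_sessions: int,
                     subject_variation: float = 0.10,
                     seed: int = 0,
                     plan: SessionPlan | None = None,
                     sensor: PiezoParams | None = None,
                     circuit: CircuitConfig | None = None,
                     noise: NoiseConfig | None = None) -> list[RawTrace]:
    """Simulate many sessions with inter-subject strain variability.

    Different bodies deform the gauge differently in the same posture, so
    each session perturbs every posture's nominal strain by an independent
    multiplicative log-normal factor with relative SD ``subject_variation``.
    Per-session noise seeds are spawned deterministically from ``seed``.
    """
    if n_sessions < 1:
        raise AcquisitionError("n_sessions must be >= 1")
    if subject_variation < 0:
        raise AcquisitionError("subject_variation must be >= 0")
    plan = default_plan() if plan is None else plan
    noise = NoiseConfig() if noise is None else noise

    root = np.random.SeedSequence(seed)
    traces = []
    for child in root.spawn(n_sessions):
        subj_rng = np.random.default_rng(child)
        factors = {
            lbl: float(np.exp(subj_rng.normal(0.0, subject_variation)))
            for lbl in POSTURES
        }
        mapping = {lbl: DEFAULT_STRAIN_MAP[lbl] * factors[lbl] for lbl in POSTURES}
        session_seed = int(child.generate_state(2)[1] % (2 ** 31))
        traces.append(
            simulate_session(plan, sensor=sensor, circuit=circuit,
                             noise=replace(noise, seed=session_seed),
                             strain_map=mapping)
        )
    return traces
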