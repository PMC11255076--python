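"""Synthetic interval-exercise ventilation traces.

The study this package models collected minute ventilation (VE) and
end-tidal CO2 (PetCO2) every 30 s from n = 7 subjects cycling through a
five-step protocol (rest 5 min; 40 W 6 min; 45% VO2max 6 min; 40 W 6 min;
80% VO2max 6 min) while breathing either air or 3% CO2.  No raw data were
published, so this module generates groups with the component structure the
analysis assumes:

    VE = resting baseline
       + exercise drive          (first-order rise to a work-rate amplitude)
       + chemoreflex component   (two-compartment response to the PetCO2
                                  deviation from baseline)
       + LTF component           (recovery segment only: an initial
                                  augmentation plus a delayed second-order
                                  step response)
       + subject offset + measurement noise

Every component is stored separately on each trace so pipeline stages can
be checked against ground truth.  Generation is a pure function of
(config, condition, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .chemoreflex import ChemoreflexParams, predict_ventilation
from .neuropool import CanonicalParams, step_response

__all__ = [
    "Segment",
    "ProtocolSpec",
    "ProtocolGrid",
    "GeneratorConfig",
    "TraceSet",
    "default_protocol",
    "build_protocol",
    "generate_subject",
    "generate_group",
    "SAMPLE_MIN",
    "AIR",
    "CO2_3PCT",
]

SAMPLE_MIN = 0.5  # 30-s sampling interval, in minutes
AIR = "air"
CO2_3PCT = "co2_3pct"

#: work-rate tags a segment may carry
WORKRATE_TAGS = ("rest", "w40", "light45", "heavy80")


@dataclass(frozen=True)
class Segment:
    label: str
    duration_min: float
    workrate: str
    fico2: float = 0.0

    def __post_init__(self) -> None:
        if self.workrate not in WORKRATE_TAGS:
            raise ValueError(f"unknown work-rate tag {self.workrate!r}")
        if self.duration_min <= 0:
            raise ValueError("segment duration must be positive")


@dataclass(frozen=True)
class ProtocolSpec:
    segments: tuple[Segment, ...]

    @property
    def total_min(self) -> float:
        return sum(s.duration_min for s in self.segments)


def default_protocol(fico2: float = 0.0) -> ProtocolSpec:
    """The five-step interval protocol: rest 5 min, 40 W 6 min, 45% VO2max
    6 min, 40 W recovery 6 min, 80% VO2max 6 min (29 min, 58 samples)."""
    return ProtocolSpec(
        segments=(
            Segment("rest", 5.0, "rest", fico2),
            Segment("w40_1", 6.0, "w40", fico2),
            Segment("light45", 6.0, "light45", fico2),
            Segment("w40_2", 6.0, "w40", fico2),
            Segment("heavy80", 6.0, "heavy80", fico2),
        )
    )


@dataclass(frozen=True)
class ProtocolGrid:
    """The 30-s sampling grid with per-sample segment annotation."""

    time_min: np.ndarray
    labels: np.ndarray  # segment label per sample
    workrates: np.ndarray  # work-rate tag per sample
    seg_start: Mapping[str, float]  # segment label -> start time (min)

    def segment_mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def segment_index(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def build_protocol(spec: ProtocolSpec) -> ProtocolGrid:
    """Lay the protocol out on the 30-s grid.

    Samples sit at t = 0, 0.5, ..., total - 0.5 min; each sample is labeled
    with the segment containing it (boundaries belong to the segment that
    starts there).  Durations must be positive multiples of 0.5 min so that
    segment boundaries align with the grid.
    """
    for seg in spec.segments:
        n = seg.duration_min / SAMPLE_MIN
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"segment {seg.label!r} duration {seg.duration_min} min does not "
                f"align with the {SAMPLE_MIN}-min sampling grid"
            )
    n_total = int(round(spec.total_min / SAMPLE_MIN))
    t = SAMPLE_MIN * np.arange(n_total)
    labels = np.empty(n_total, dtype=object)
    work = np.empty(n_total, dtype=object)
    starts: dict[str, float] = {}
    t0 = 0.0
    for seg in spec.segments:
        if seg.label in starts:
            raise ValueError(f"duplicate segment label {seg.label!r}")
        starts[seg.label] = t0
        sel = (t >= t0 - 1e-9) & (t < t0 + seg.duration_min - 1e-9)
        labels[sel] = seg.label
        work[sel] = seg.workrate
        t0 += seg.duration_min
    return ProtocolGrid(
        time_min=t, labels=labels.astype(str), workrates=work.astype(str), seg_start=starts
    )


def _default_drive_amplitudes() -> dict[str, float]:
    return {"rest": 0.0, "w40": 10.0, "light45": 22.0, "heavy80": 40.0}


def _default_ltf_truth() -> CanonicalParams:
    # second-order augmentation observed during the 40 W recovery segment:
    # initial augmentation 7.6 L/min, delayed (2 min) rise of amplitude 9
    return CanonicalParams(
        wn=0.375, zeta=0.7, A=0.0, B=9.0, baseline=7.6, onset_delay=2.0, time_unit="min"
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the generator needs, with study-condition defaults.

    PetCO2 deviation targets: breathing 3% CO2 raises PetCO2 by ~7 mmHg,
    sustained through all exercise segments; under air only a small
    (+1.5 mmHg) transient occurs during the first 2 min of each exercise
    step.  Exercise drive amplitudes (above rest) are 10 / 22 / 40 L/min for
    40 W / 45% VO2max / 80% VO2max with a 0.5-min rise time constant.  The
    LTF truth is applied only during the recovery 40 W segment.
    """

    protocol: ProtocolSpec = field(default_factory=default_protocol)
    chemo_truth: ChemoreflexParams = field(
        default_factory=lambda: ChemoreflexParams(Gc=2.0, Gp=1.0)
    )
    drive_amplitude_lpm: Mapping[str, float] = field(default_factory=_default_drive_amplitudes)
    drive_tau_min: float = 0.5
    pet_dev_co2_mmhg: float = 7.0
    pet_dev_air_mmhg: float = 1.5
    pet_air_transient_min: float = 2.0
    pet_tau_min: float = 0.5
    ltf_truth: CanonicalParams = field(default_factory=_default_ltf_truth)
    ltf_segment: str = "w40_2"
    rest_ve_lpm: float = 10.0
    pet_baseline_mmhg: float = 40.0
    subject_sd_lpm: float = 5.3
    noise_sd_lpm: float = 1.7
    pet_noise_sd_mmhg: float = 0.3
    n_subjects: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("subject_sd_lpm", "noise_sd_lpm", "pet_noise_sd_mmhg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ltf_truth.A != 0.0:
            raise ValueError("LTF truth must have A = 0 (three-parameter step fit)")

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


@dataclass
class TraceSet:
    """One subject's (or the group mean's) paired VE / PetCO2 record."""

    subject: str
    condition: str
    time_min: np.ndarray
    ve_lpm: np.ndarray
    petco2_mmhg: np.ndarray
    segments: np.ndarray
    components: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        n = len(self.time_min)
        if not (len(self.ve_lpm) == len(self.petco2_mmhg) == len(self.segments) == n):
            raise ValueError("all series must share one time grid")

    def grid(self) -> ProtocolGrid:
        starts: dict[str, float] = {}
        for t, lab in zip(self.time_min, self.segments):
            starts.setdefault(lab, float(t))
        return ProtocolGrid(
            time_min=self.time_min,
            labels=self.segments,
            workrates=self.segments,
            seg_start=starts,
        )


def _relax_to_targets(targets: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """First-order relaxation toward a piecewise-constant target profile.

    Exact exponential update per 30-s sample; target[k] is in effect on
    [t_k, t_k+1).  Output starts at targets[0] (assumed pre-protocol
    steady state).
    """
    out = np.empty_like(targets)
    out[0] = targets[0]
    decay = np.exp(-dt / tau)
    for k in range(len(targets) - 1):
        out[k + 1] = targets[k] + (out[k] - targets[k]) * decay
    return out


def _pet_deviation_targets(config: GeneratorConfig, grid: ProtocolGrid, condition: str) -> np.ndarray:
    t = grid.time_min
    target = np.zeros_like(t)
    if condition == CO2_3PCT:
        target[grid.workrates != "rest"] = config.pet_dev_co2_mmhg
    elif condition == AIR:
        for seg in config.protocol.segments:
            if seg.workrate == "rest":
                continue
            t0 = grid.seg_start[seg.label]
            sel = (t >= t0 - 1e-9) & (t < t0 + config.pet_air_transient_min - 1e-9)
            target[sel] = config.pet_dev_air_mmhg
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return target


def _drive_targets(config: GeneratorConfig, grid: ProtocolGrid) -> np.ndarray:
    return np.array([config.drive_amplitude_lpm[w] for w in grid.workrates], dtype=float)


def generate_subject(
    config: GeneratorConfig, condition: str, subject_seed: int, subject_id: str = "s1"
) -> TraceSet:
    """Generate one subject's trace; pure function of (config, condition, seed)."""
    rng = np.random.default_rng(subject_seed)
    grid = build_protocol(config.protocol)
    t = grid.time_min
    n = len(t)

    drive = _relax_to_targets(_drive_targets(config, grid), config.drive_tau_min, SAMPLE_MIN)
    pet_dev = _relax_to_targets(
        _pet_deviation_targets(config, grid, condition), config.pet_tau_min, SAMPLE_MIN
    )
    chemo = predict_ventilation(config.chemo_truth, pet_dev, dt=SAMPLE_MIN * 60.0)

    ltf = np.zeros(n)
    mask = grid.segment_mask(config.ltf_segment)
    if mask.any():
        t0 = grid.seg_start[config.ltf_segment]
        ltf[mask] = step_response(config.ltf_truth, t[mask] - t0)

    offset = rng.normal(0.0, config.subject_sd_lpm) if config.subject_sd_lpm > 0 else 0.0
    ve_noise = rng.normal(0.0, config.noise_sd_lpm, n) if config.noise_sd_lpm > 0 else np.zeros(n)
    pet_noise = (
        rng.normal(0.0, config.pet_noise_sd_mmhg, n)
        if config.pet_noise_sd_mmhg > 0
        else np.zeros(n)
    )

    rest = np.full(n, config.rest_ve_lpm)
    ve = rest + drive + chemo + ltf + offset + ve_noise
    ve = np.maximum(ve, 0.1)  # physical floor; never binds with defaults and noise off
    pet = config.pet_baseline_mmhg + pet_dev + pet_noise

    return TraceSet(
        subject=subject_id,
        condition=condition,
        time_min=t,
        ve_lpm=ve,
        petco2_mmhg=pet,
        segments=grid.labels,
        components={
            "rest": rest,
            "drive": drive,
            "chemo": chemo,
            "ltf": ltf,
            "offset": np.full(n, offset),
            "pet_dev": pet_dev,
        },
    )


def _group_mean(traces: Sequence[TraceSet]) -> TraceSet:
    first = traces[0]
    comp_keys = first.components.keys() if first.components else []
    return TraceSet(
        subject="group_mean",
        condition=first.condition,
        time_min=first.time_min.copy(),
        ve_lpm=np.mean([tr.ve_lpm for tr in traces], axis=0),
        petco2_mmhg=np.mean([tr.petco2_mmhg for tr in traces], axis=0),
        segments=first.segments.copy(),
        components={k: np.mean([tr.components[k] for tr in traces], axis=0) for k in comp_keys},
    )


def generate_group(
    config: GeneratorConfig, condition: str = CO2_3PCT
) -> tuple[list[TraceSet], TraceSet]:
    """Generate an n-subject group plus its pointwise group average.

    Subject seeds are derived deterministically from the master seed via a
    ``numpy.random.SeedSequence`` so the whole group is reproducible from
    ``config.seed`` alone.
    """
    child_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_subjects)
    traces = [
        generate_subject(config, condition, int(child_seeds[i]), subject_id=f"s{i + 1}")
        for i in range(config.n_subjects)
    ]
    return traces, _group_mean(traces)
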