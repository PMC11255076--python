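"""Excitatory/inhibitory neural-pool dynamics and their second-order canonical form.

The model describes respiratory motor output (integrated phrenic activity, or
minute ventilation via the phrenic-activity-as-ventilation assumption) as the
balance of a self-excitatory and a self-inhibitory neuronal population:

    t1 * dI1/dt = -I1 + C11*I1 - C21*I2 + D
    t2 * dI2/dt = -I2 + C12*I1 - C22*I2

where ``I1`` is the instantaneous average activity of the excitatory pool,
``I2`` that of the inhibitory pool, ``D`` a tonic (chemical) drive, and the
``Cij`` dimensionless interconnection strengths.  Eliminating ``I2`` yields a
second-order transfer function from drive to ``I1``,

    I1(s) = (A*s + B) / (s * ((s/wn)^2 + 2*zeta*(s/wn) + 1)),

whose step response has the familiar natural frequency ``wn`` and damping
coefficient ``zeta``.  The slowly developing, initially upward-curved rise of
ventilatory long-term facilitation (LTF) is fitted with exactly this step
response (with A fixed to 0), which is what distinguishes it from the
decaying-exponential (first-order) dynamics of short-term potentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterator, Sequence, Union

import numpy as np

__all__ = [
    "PoolParams",
    "PoolState",
    "PoolTrajectory",
    "CanonicalParams",
    "UnstablePoolError",
    "simulate_pools",
    "to_canonical",
    "step_response",
    "dc_gain",
]


class UnstablePoolError(ValueError):
    """Raised when K = C21*C12 - (C11-1)*(1+C22) <= 0: no finite steady state
    and no oscillator (canonical second-order) form exists."""


@dataclass(frozen=True)
class PoolParams:
    """Constants of the two-pool model.

    t1, t2 : effective time constants (min) for build-up/decay of the
        excitatory and inhibitory subpopulation activity.
    C11, C12, C21, C22 : dimensionless interaction constants.
    D : tonic drive (activity units).
    """

    t1: float
    t2: float
    C11: float
    C12: float
    C21: float
    C22: float
    D: float = 0.0

    def __post_init__(self) -> None:
        if not (self.t1 > 0 and self.t2 > 0):
            raise ValueError(f"time constants must be positive (t1={self.t1}, t2={self.t2})")

    @property
    def K(self) -> float:
        """Stability indicator; K > 0 is required for a finite steady state."""
        return self.C21 * self.C12 - (self.C11 - 1.0) * (1.0 + self.C22)

    @property
    def stable(self) -> bool:
        return self.K > 0 and (self.t1 * (1 + self.C22) - self.t2 * (self.C11 - 1)) > 0

    def system_matrix(self) -> np.ndarray:
        """State matrix M of d[I1,I2]/dt = M @ [I1,I2] + [D/t1, 0]."""
        return np.array(
            [
                [(self.C11 - 1.0) / self.t1, -self.C21 / self.t1],
                [self.C12 / self.t2, -(1.0 + self.C22) / self.t2],
            ]
        )

    def steady_state(self) -> tuple[float, float]:
        """Fixed point (I1*, I2*) for constant drive D; requires K > 0."""
        if self.K <= 0:
            raise UnstablePoolError(f"K = {self.K} <= 0: pools have no finite steady state")
        i1 = self.D * (1.0 + self.C22) / self.K
        i2 = self.C12 * i1 / (1.0 + self.C22)
        return i1, i2


@dataclass(frozen=True)
class PoolState:
    """Instantaneous pool activities at time t (min). Negative excursions are
    permitted: the model is linear and unclamped."""

    I1: float
    I2: float
    t: float = 0.0


@dataclass
class PoolTrajectory:
    """Numerically integrated (I1, I2) trajectory on a uniform time grid."""

    t: np.ndarray
    I1: np.ndarray
    I2: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def __iter__(self) -> Iterator[PoolState]:
        for ti, a, b in zip(self.t, self.I1, self.I2):
            yield PoolState(I1=float(a), I2=float(b), t=float(ti))

    def __getitem__(self, i: int) -> PoolState:
        return PoolState(I1=float(self.I1[i]), I2=float(self.I2[i]), t=float(self.t[i]))


@dataclass(frozen=True)
class CanonicalParams:
    """Second-order description of the step response.

    wn : natural frequency (rad per `time_unit`).
    zeta : damping coefficient (dimensionless).
    A : numerator rate coefficient (activity * time); fixed to 0 in LTF fits.
    B : steady-state step amplitude (activity units or L/min).
    baseline : offset added to the response (same units as B).
    onset_delay : pure time shift before the step response begins (`time_unit`).
    time_unit : unit wn and onset_delay are expressed in ("min" or "s");
        carried explicitly because animal phrenic fits are per second while
        the human recovery-segment fits are per minute.
    """

    wn: float
    zeta: float
    A: float = 0.0
    B: float = 0.0
    baseline: float = 0.0
    onset_delay: float = 0.0
    time_unit: str = "min"

    def __post_init__(self) -> None:
        if not self.wn > 0:
            raise ValueError(f"wn must be positive, got {self.wn}")
        if not self.zeta > 0:
            raise ValueError(f"zeta must be positive, got {self.zeta}")
        if not np.isfinite(self.B):
            raise ValueError("B must be finite")

    def with_(self, **kw) -> "CanonicalParams":
        return replace(self, **kw)


DriveLike = Union[float, Callable[[float], float], Sequence[float], np.ndarray]


def _drive_function(drive: DriveLike, duration: float, dt: float) -> Callable[[float], float]:
    if callable(drive):
        return drive
    if np.isscalar(drive):
        d = float(drive)  # type: ignore[arg-type]
        return lambda t: d
    arr = np.asarray(drive, dtype=float)
    grid = np.linspace(0.0, duration, len(arr))
    return lambda t: float(np.interp(t, grid, arr))


def simulate_pools(
    params: PoolParams,
    drive: DriveLike,
    initial: PoolState = PoolState(0.0, 0.0),
    duration: float = 10.0,
    dt: float = 0.01,
) -> PoolTrajectory:
    """Integrate the two-pool ODEs with a classical fixed-step RK4 scheme.

    ``drive`` may be a constant, a callable D(t), or an array sampled
    uniformly on [0, duration].  The default dt = 0.01 min is small enough
    that halving it changes trajectories by < 1e-6 for the parameter ranges
    used here.

    Raises
    ------
    ValueError
        If duration/dt are invalid.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    if not (0 < dt <= duration):
        raise ValueError("dt must satisfy 0 < dt <= duration")

    dfun = _drive_function(drive, duration, dt)
    m = params.system_matrix()
    b = np.array([1.0 / params.t1, 0.0])

    n_steps = int(round(duration / dt))
    t = initial.t + dt * np.arange(n_steps + 1)
    out = np.empty((n_steps + 1, 2))
    y = np.array([initial.I1, initial.I2], dtype=float)
    out[0] = y

    def f(ti: float, yi: np.ndarray) -> np.ndarray:
        return m @ yi + b * dfun(ti)

    for i in range(n_steps):
        ti = t[i]
        k1 = f(ti, y)
        k2 = f(ti + dt / 2, y + dt / 2 * k1)
        k3 = f(ti + dt / 2, y + dt / 2 * k2)
        k4 = f(ti + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i + 1] = y

    if params.K <= 0 and not np.all(np.isfinite(out)):
        import warnings

        warnings.warn("K <= 0: pool activities diverged during integration", RuntimeWarning)
    return PoolTrajectory(t=t, I1=out[:, 0], I2=out[:, 1])


def to_canonical(params: PoolParams) -> CanonicalParams:
    """Map pool constants to the canonical second-order form.

    wn^2 = K / (t1*t2)
    zeta = [t1*(1+C22) - t2*(C11-1)] / (2*wn*t1*t2)
    A    = D*t2 / K
    B    = D*(1+C22) / K

    so that -zeta*wn +/- wn*sqrt(zeta^2-1) are exactly the eigenvalues of the
    2x2 system matrix (roots of t1*t2*s^2 + [t1(1+C22) - t2(C11-1)]*s + K).

    Raises
    ------
    UnstablePoolError
        If K <= 0 (no oscillator form).
    """
    k = params.K
    if k <= 0:
        raise UnstablePoolError(f"K = {k} <= 0: no second-order oscillator form")
    t1, t2 = params.t1, params.t2
    wn = np.sqrt(k / (t1 * t2))
    damp_coeff = t1 * (1.0 + params.C22) - t2 * (params.C11 - 1.0)
    zeta = damp_coeff / (2.0 * wn * t1 * t2)
    if zeta <= 0:
        raise UnstablePoolError(f"non-positive damping (zeta = {zeta}): pools are unstable")
    return CanonicalParams(
        wn=float(wn),
        zeta=float(zeta),
        A=params.D * t2 / k,
        B=params.D * (1.0 + params.C22) / k,
        baseline=0.0,
        onset_delay=0.0,
        time_unit="min",
    )


def _unit_step_and_impulse(wn: float, zeta: float, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit step response and impulse response of wn^2/(s^2+2*zeta*wn*s+wn^2).

    Closed forms per damping regime; t must be >= 0.
    """
    if zeta < 1.0:
        wd = wn * np.sqrt(1.0 - zeta**2)
        e = np.exp(-zeta * wn * t)
        step = 1.0 - e * (np.cos(wd * t) + (zeta * wn / wd) * np.sin(wd * t))
        imp = (wn**2 / wd) * e * np.sin(wd * t)
    elif zeta == 1.0:
        e = np.exp(-wn * t)
        step = 1.0 - (1.0 + wn * t) * e
        imp = wn**2 * t * e
    else:
        s = wn * np.sqrt(zeta**2 - 1.0)
        r1 = -zeta * wn + s
        r2 = -zeta * wn - s
        e1, e2 = np.exp(r1 * t), np.exp(r2 * t)
        step = 1.0 + (r2 * e1 - r1 * e2) / (r1 - r2)
        imp = wn**2 * (e1 - e2) / (r1 - r2)
    return step, imp


def step_response(params: CanonicalParams, times: Sequence[float]) -> np.ndarray:
    """Evaluate baseline + delayed second-order step response at `times`.

    Before ``onset_delay`` the output equals ``baseline``.  For t' = t -
    onset_delay >= 0 the response is

        baseline + B * u(t') + A * h(t')

    where u is the unit step response and h the impulse response of the
    normalized denominator — the A*s numerator term contributes A*h(t') and
    nothing at steady state, so the asymptote is always baseline + B.
    All damping regimes (zeta < 1, = 1, > 1) are supported.
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be non-decreasing")
    tp = t - params.onset_delay
    out = np.full(t.shape, params.baseline, dtype=float)
    active = tp >= 0
    if np.any(active):
        u, h = _unit_step_and_impulse(params.wn, params.zeta, tp[active])
        out[active] += params.B * u + params.A * h
    return out


def dc_gain(params: CanonicalParams) -> float:
    """Steady-state step amplitude: the final value of the step response
    above baseline.  The A*s term vanishes at steady state, so this is B."""
    return params.B
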