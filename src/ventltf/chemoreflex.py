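"""Two-compartment chemoreflex model of CO2-driven ventilation.

Ventilatory response to a PetCO2 deviation from baseline is modeled as the
sum of a central (brainstem, slow) and a peripheral (carotid body, fast)
first-order compartment, each with its own gain, time constant and transport
delay:

    tau_c * dxc/dt = -xc + Gc * dPet(t - delay_c)
    tau_p * dxp/dt = -xp + Gp * dPet(t - delay_p)
    dVE(t) = xc(t) + xp(t)

Because all signals are deviations from baseline, chemoreceptor thresholds
and set-points drop out.  Only the gains Gc and Gp are treated as free
parameters in fitting; the dynamics (tau_c = 120 s, tau_p = 15 s, delays
10 s / 6 s) are fixed, configurable defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = ["ChemoreflexParams", "predict_ventilation", "inspired_pco2"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChemoreflexParams:
    """Central/peripheral chemoreflex gains and fixed dynamics.

    Gc, Gp : steady-state gains, (L/min)/mmHg.  Fits may hit the zero bound.
    tau_c, tau_p : compartment time constants (s); central is the slower one.
    delay_c, delay_p : transport delays (s).
    """

    Gc: float
    Gp: float
    tau_c: float = 120.0
    tau_p: float = 15.0
    delay_c: float = 10.0
    delay_p: float = 6.0

    def __post_init__(self) -> None:
        if self.Gc < 0 or self.Gp < 0:
            raise ValueError(f"gains must be non-negative (Gc={self.Gc}, Gp={self.Gp})")
        if not (self.tau_c > self.tau_p > 0):
            raise ValueError(
                f"time constants must satisfy tau_c > tau_p > 0 "
                f"(tau_c={self.tau_c}, tau_p={self.tau_p})"
            )
        if self.delay_c < 0 or self.delay_p < 0:
            raise ValueError("delays must be non-negative")

    @property
    def total_gain(self) -> float:
        """Steady-state ventilation change per mmHg of sustained PetCO2 rise."""
        return self.Gc + self.Gp

    def with_gains(self, Gc: float, Gp: float) -> "ChemoreflexParams":
        return replace(self, Gc=Gc, Gp=Gp)


def _first_order_delayed(
    u: np.ndarray,
    t: np.ndarray,
    gain: float,
    tau: float,
    delay: float,
    h: float,
) -> np.ndarray:
    """Response of tau*x' = -x + gain*u(t - delay) on the uniform grid t.

    The delayed input is built by linear interpolation into the history
    (zero deviation before t[0], supporting sub-sample delays) and the ODE is
    advanced with the exact exponential update for piecewise-linear input.
    """
    ud = np.interp(t - delay, t, u, left=0.0)
    alpha = np.exp(-h / tau)
    x = np.empty_like(ud)
    x[0] = 0.0
    # exact step for input linear on [t_k, t_k+1]:
    # x1 = (x0 - G*u0 + G*tau*m)*alpha + G*u1 - G*tau*m,  m = (u1-u0)/h
    for k in range(len(ud) - 1):
        m = (ud[k + 1] - ud[k]) / h
        x[k + 1] = (x[k] - gain * ud[k] + gain * tau * m) * alpha + gain * ud[k + 1] - gain * tau * m
    return x


def predict_ventilation(
    params: ChemoreflexParams,
    dpet: Sequence[float],
    dt: float,
    n_substeps: int | None = None,
) -> np.ndarray:
    """Predict the ventilation deviation (L/min) driven by a PetCO2 deviation.

    Parameters
    ----------
    params :
        Chemoreflex gains and dynamics.
    dpet :
        PetCO2 deviation from baseline (mmHg), uniformly sampled; assumed
        zero before t = 0.
    dt :
        Sampling interval of `dpet` in seconds.
    n_substeps :
        Internal upsampling factor.  The input is linearly interpolated onto
        a finer grid so the fast (peripheral) compartment is resolved; by
        default enough substeps are used that the substep is <= tau_p/10.

    Returns
    -------
    ndarray of the same length as `dpet`: the summed central + peripheral
    ventilation deviation, sampled on the input grid.  For a sustained step
    of height dP the asymptote is (Gc + Gp) * dP.
    """
    u = np.asarray(dpet, dtype=float)
    if u.ndim != 1:
        raise ValueError("dpet must be one-dimensional")
    if not dt > 0:
        raise ValueError("dt must be positive")
    if len(u) < 2:
        return np.zeros_like(u)

    longest_delay = max(params.delay_c, params.delay_p)
    if (len(u) - 1) * dt < longest_delay:
        logger.info(
            "dpet record (%.1f s) shorter than longest delay (%.1f s); "
            "history padded with zeros",
            (len(u) - 1) * dt,
            longest_delay,
        )

    if n_substeps is None:
        n_substeps = max(1, int(np.ceil(dt / (params.tau_p / 10.0))))
    n_fine = (len(u) - 1) * n_substeps + 1
    t_fine = np.linspace(0.0, (len(u) - 1) * dt, n_fine)
    t_coarse = np.arange(len(u)) * dt
    u_fine = np.interp(t_fine, t_coarse, u)
    h = dt / n_substeps

    xc = _first_order_delayed(u_fine, t_fine, params.Gc, params.tau_c, params.delay_c, h)
    xp = _first_order_delayed(u_fine, t_fine, params.Gp, params.tau_p, params.delay_p, h)
    return (xc + xp)[::n_substeps]


def inspired_pco2(fico2: float, pb: float = 760.0, ph2o: float = 47.0) -> float:
    """Partial pressure of inspired CO2 in the lung (mmHg).

    P_ICO2 = FICO2 * (Pb - PH2O): the inspired dry-gas fraction times
    barometric pressure corrected for water-vapor saturation at body
    temperature.  For 3% CO2 at sea level this is about 21 mmHg — far below
    the ~70 mmHg arterial level where CO2 narcosis depresses ventilation.
    """
    if not 0.0 <= fico2 <= 1.0:
        raise ValueError(f"fico2 must be in [0, 1], got {fico2}")
    if not pb > ph2o >= 0:
        raise ValueError(f"require pb > ph2o >= 0 (pb={pb}, ph2o={ph2o})")
    return fico2 * (pb - ph2o)
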