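"""Canonical Hodgkin-Huxley squid-axon model, used as an independent oracle.

The four-ODE model with the 1952 parameter set (modern voltage convention,
rest near -65 mV) validates the spike-detection and feature machinery
independently of any c-OECN calibration: tonic spiking, latency and
refractoriness of the squid axon are textbook behaviours, so the detectors
must find them here.

Internally the equations are integrated in the conventional mV/ms/(uA/cm^2)
units; the returned trace is converted to SI (V, s, and currents in A for a
nominal 1 cm^2 of membrane) so it is interchangeable with circuit traces for
the analysis layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .circuit import SimulationTrace
from .stimuli import StimulusProgram

__all__ = ["HHParams", "gating_rates", "gating_steady_state", "hh_simulate",
           "HH_BATTERY_OVERRIDES"]


@dataclass(frozen=True)
class HHParams:
    """Canonical squid-axon parameters (modern convention, units in names)."""

    C_m: float = 1.0        # uF/cm^2
    g_Na: float = 120.0     # mS/cm^2
    g_K: float = 36.0       # mS/cm^2
    g_L: float = 0.3        # mS/cm^2
    E_Na: float = 50.0      # mV
    E_K: float = -77.0      # mV
    E_L: float = -54.387    # mV

    def __post_init__(self) -> None:
        if min(self.g_Na, self.g_K, self.g_L) <= 0:
            raise ValueError("conductances must be > 0")


def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with its removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-7
    safe = np.where(small, 1.0, x)
    return np.where(small, y * (1.0 + x / (2.0 * y)),
                    safe / (1.0 - np.exp(-safe / y)))


def gating_rates(V):
    """Voltage-dependent rate constants (1/ms) for m, h, n at V (mV)."""
    a_m = 0.1 * _vtrap(V + 40.0, 10.0)
    b_m = 4.0 * np.exp(-(V + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(V + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    a_n = 0.01 * _vtrap(V + 55.0, 10.0)
    b_n = 0.125 * np.exp(-(V + 65.0) / 80.0)
    return (a_m, b_m), (a_h, b_h), (a_n, b_n)


def gating_steady_state(V):
    """(m_inf, h_inf, n_inf) = alpha/(alpha+beta) at membrane voltage V (mV)."""
    (am, bm), (ah, bh), (an, bn) = gating_rates(V)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def hh_simulate(p: HHParams, stim: StimulusProgram, t_span: float,
                rtol: float = 1e-8, atol: float = 1e-10,
                dt_out: float = 2e-5, V0: float = -65.0) -> SimulationTrace:
    """Integrate the HH equations; stimulus amplitudes in A per cm^2-membrane.

    A program amplitude of ``10e-6`` (10 uA) drives the canonical model with
    10 uA/cm^2.  Gating variables start at their steady state for ``V0``.
    """
    if t_span <= 0:
        raise ValueError("t_span must be > 0")
    m0, h0, n0 = gating_steady_state(V0)
    y0 = [V0, m0, h0, n0]

    def rhs(t_ms, y):
        V, m, h, n = y
        (am, bm), (ah, bh), (an, bn) = gating_rates(V)
        I_Na = p.g_Na * m ** 3 * h * (V - p.E_Na)
        I_K = p.g_K * n ** 4 * (V - p.E_K)
        I_L = p.g_L * (V - p.E_L)
        I_in = stim.evaluate(t_ms * 1e-3) * 1e6  # A -> uA/cm^2
        dV = (I_in - I_Na - I_K - I_L) / p.C_m
        return [dV, am * (1 - m) - bm * m, ah * (1 - h) - bh * h,
                an * (1 - n) - bn * n]

    T_ms = t_span * 1e3
    t_eval = np.arange(0.0, T_ms + dt_out * 1e3 / 2, dt_out * 1e3)
    sol = solve_ivp(rhs, (0.0, T_ms), y0, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"HH integration failed: {sol.message}")
    V, m, h, n = sol.y
    I_Na = p.g_Na * m ** 3 * h * (V - p.E_Na)   # uA/cm^2
    I_K = p.g_K * n ** 4 * (V - p.E_K)
    t_s = sol.t * 1e-3
    meta = {"model": "hodgkin_huxley_1952", "gating": {
        "m": m, "h": h, "n": n}, "seed": None if stim.noise is None
        else stim.noise.seed}
    return SimulationTrace(t=t_s, V_mem=V * 1e-3, V_gk=n,  # V_gk slot: n gate
                           I_in=np.asarray(stim.evaluate(t_s), float),
                           I_Na=-I_Na * 1e-6, I_K=I_K * 1e-6, metadata=meta)


# Battery protocol settings matched to the squid axon's scales: ~ms spikes,
# uA/cm^2 drive, detection threshold between rest (-65 mV) and peak (+40 mV).
HH_BATTERY_OVERRIDES: dict[str, dict] = {
    "tonic": dict(amplitude=10e-6, T=0.2),
    "latency": dict(amplitudes=(2.6e-6, 4e-6, 8e-6), width=0.02, T=0.1,
                    t_on=0.02),
    "refractoriness": dict(amplitude=12e-6, width=0.002,
                           gaps=(0.004, 0.008, 0.012, 0.02), T=0.08,
                           t_on=0.01),
}
HH_THRESHOLD = -0.010  # V
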