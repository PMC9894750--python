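"""Steady-state device laws for the c-OECN building blocks.

The neuron is assembled from three elements:

* an *antiambipolar* Na-OECT whose drain current rises and then falls with
  gate voltage (a Gaussian-shaped transfer curve), playing the role of the
  activating/inactivating sodium channel;
* a conventional monotone K-OECT (thicker, higher-current film) playing the
  delayed-rectifier potassium channel;
* an inverting amplifier that maps the membrane voltage onto the Na-OECT
  gate so that a rising membrane voltage sweeps the gate *down* through the
  transfer-curve peak.

Two interchangeable laws are provided for the Na-OECT: a phenomenological
Gaussian (the default, matching the measured transfer-curve shape) and a
physically motivated two-species law in which a mobile singly-charged
species converts to a low-mobility multiply-charged species above a second
onset voltage.  All laws are pure functions, vectorised over their voltage
arguments, and continuous.

Units are SI throughout: volts, amperes, farads, ohms, seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ParameterDomainError",
    "AntiambipolarParams",
    "OECTParams",
    "AmplifierParams",
    "antiambipolar_current",
    "two_species_current",
    "oect_current",
    "amplifier_output",
    "oect_step_response",
    "rise_time_10_90",
    "switching_time",
    "read_transfer_csv",
    "fit_antiambipolar",
]


class ParameterDomainError(ValueError):
    """Raised when device parameters leave their physical domain."""


@dataclass(frozen=True)
class AntiambipolarParams:
    """Parameters of the antiambipolar (Na-type) OECT transfer law.

    The Gaussian form is

        I(V_G, V_DS) = I_peak(V_DS) * exp(-(V_G - V_P(V_DS))^2 / (2 sigma^2))
                       * tanh(V_DS / V_DS_lin)

    with ``sigma = sigma_rise`` below the peak and ``sigma_fall`` above it,
    and an affine drain-bias dependence around ``V_DS_ref``:

        I_peak(V_DS) = I_peak0 + k_peak * (V_DS - V_DS_ref)
        V_P(V_DS)    = V_P0    + k_VP   * (V_DS - V_DS_ref)
        sigma(V_DS)  = sigma   * (1 + k_sigma * (V_DS - V_DS_ref))

    The ``tanh`` factor (width ``V_DS_lin``, default 50 mV) is a linear-regime
    roll-off: it is ~1 at the reference drain bias but guarantees zero current
    at zero drain bias, which the circuit needs when the membrane voltage
    approaches the sodium battery E_Na.

    The alternative two-species form uses a standard transistor drain factor
    with threshold ``V_Na_s`` and a gate-dependent effective mobility
    prefactor that drops from ``mu_Na_s`` to ``mu_Na_m`` (logistic conversion
    of width ``w_m`` centred at ``V_Na_m``), reproducing the rise-then-fall
    shape when ``mu_Na_m << mu_Na_s``.
    """

    I_peak0: float          # A, peak current at V_DS_ref
    V_P0: float             # V, gate voltage of the peak at V_DS_ref
    sigma_rise: float       # V, Gaussian width below the peak
    sigma_fall: float       # V, Gaussian width above the peak
    V_DS_ref: float = 0.325  # V, reference drain bias
    k_peak: float = 0.0     # A/V, peak-current sensitivity to V_DS
    k_VP: float = 0.0       # dimensionless, V_P shift per volt of V_DS
    k_sigma: float = 0.0    # 1/V, relative width growth per volt of V_DS
    V_DS_lin: float = 0.05  # V, linear-regime roll-off width
    # two-species alternative
    V_Na_s: float = 0.55    # V, threshold of the singly-charged species
    mu_Na_s: float = 2.0e-4  # A/V^2, prefactor of the singly-charged species
    V_Na_m: float = 1.05    # V, onset of multiply-charged conversion
    mu_Na_m: float = 1.0e-5  # A/V^2, prefactor after conversion
    w_m: float = 0.06       # V, conversion width
    form: str = "gaussian"  # "gaussian" | "two_species"

    def __post_init__(self) -> None:
        if self.I_peak0 <= 0:
            raise ParameterDomainError("I_peak0 must be > 0")
        if self.sigma_rise <= 0 or self.sigma_fall <= 0:
            raise ParameterDomainError("sigma_rise and sigma_fall must be > 0")
        if self.w_m <= 0:
            raise ParameterDomainError("w_m must be > 0")
        if not self.mu_Na_m < self.mu_Na_s:
            raise ParameterDomainError("mu_Na_m must be < mu_Na_s")
        if not self.V_Na_m > self.V_Na_s:
            raise ParameterDomainError("V_Na_m must be > V_Na_s")
        if self.form not in ("gaussian", "two_species"):
            raise ParameterDomainError(f"unknown form {self.form!r}")

    def with_modulation(self, V_P0: float, I_peak0: float) -> "AntiambipolarParams":
        """Return a copy with electrolyte-modulated peak position and height."""
        return replace(self, V_P0=V_P0, I_peak0=I_peak0)


@dataclass(frozen=True)
class OECTParams:
    """Parameters of the monotone (K-type) OECT.

    ``V_T`` is the threshold voltage (V_K of the potassium transistor) and
    ``K_g`` the transconductance prefactor W*d*mu*C*/L.  ``C_g`` and
    ``R_g_intrinsic`` form the intrinsic first-order gate lag that sets the
    device's ms-scale switching time; in the neuron the same gate capacitance
    is charged through the external delay resistor R_dk.

    ``V_ss`` is an optional subthreshold (weak-inversion) swing parameter:
    when positive, the hard overdrive ``max(V_GS - V_T, 0)`` is replaced by
    the softplus ``V_ss * ln(1 + exp((V_GS - V_T)/V_ss))``, giving the
    exponential off-current tail real electrochemical transistors show.  The
    default of 0 keeps the ideal hard-threshold law.
    """

    V_T: float              # V
    K_g: float              # A/V^2
    C_g: float = 1.0e-7     # F
    R_g_intrinsic: float = 3.0e3  # Ohm
    V_ss: float = 0.0       # V (0 => hard threshold)

    def __post_init__(self) -> None:
        if self.K_g <= 0:
            raise ParameterDomainError("K_g must be > 0")
        if self.C_g <= 0:
            raise ParameterDomainError("C_g must be > 0")
        if self.V_ss < 0:
            raise ParameterDomainError("V_ss must be >= 0")


@dataclass(frozen=True)
class AmplifierParams:
    """Saturating linear inverting amplifier V_out = clamp(gain*V_in + offset)."""

    gain: float = -2.424
    offset: float = 1.624   # V
    rail_low: float = 0.5   # V
    rail_high: float = 1.4  # V

    def __post_init__(self) -> None:
        if self.gain >= 0:
            raise ParameterDomainError("amplifier gain must be negative (inverting)")
        if not self.rail_low < self.rail_high:
            raise ParameterDomainError("rail_low must be < rail_high")


def _maybe_scalar(x: np.ndarray) -> np.ndarray | float:
    return float(x) if np.ndim(x) == 0 else x


def antiambipolar_current(V_G, V_DS, p: AntiambipolarParams):
    """Drain current of the antiambipolar OECT (Gaussian form).

    Unimodal in ``V_G`` with its maximum at ``V_P(V_DS)``; non-negative;
    vectorised over ``V_G`` and ``V_DS``.
    """
    V_G = np.asarray(V_G, dtype=float)
    V_DS = np.asarray(V_DS, dtype=float)
    if np.any(V_DS < 0):
        raise ParameterDomainError("V_DS must be >= 0")
    d = V_DS - p.V_DS_ref
    ipk = p.I_peak0 + p.k_peak * d
    if np.any(ipk < 0):
        raise ParameterDomainError(
            "computed peak current is negative at this drain bias")
    vp = p.V_P0 + p.k_VP * d
    wscale = 1.0 + p.k_sigma * d
    if np.any(wscale <= 0):
        raise ParameterDomainError("computed Gaussian width is non-positive")
    sigma = np.where(V_G < vp, p.sigma_rise, p.sigma_fall) * wscale
    drain = np.tanh(V_DS / p.V_DS_lin) if p.V_DS_lin > 0 else 1.0
    I = ipk * np.exp(-0.5 * ((V_G - vp) / sigma) ** 2) * drain
    return _maybe_scalar(I)


def two_species_current(V_G, V_DS, p: AntiambipolarParams):
    """Drain current of the two-species antiambipolar law.

    A standard transistor drain factor with threshold ``V_Na_s`` is scaled by
    an effective prefactor that converts from ``mu_Na_s`` to ``mu_Na_m``
    above ``V_Na_m``; non-monotone in V_G when ``mu_Na_m << mu_Na_s``.
    """
    V_G = np.asarray(V_G, dtype=float)
    V_DS = np.asarray(V_DS, dtype=float)
    if np.any(V_DS < 0):
        raise ParameterDomainError("V_DS must be >= 0")
    V_ov = V_G - p.V_Na_s
    lin = (V_ov - V_DS / 2.0) * V_DS
    sat = V_ov ** 2 / 2.0
    g = np.where(V_ov <= 0, 0.0, np.where(V_DS < V_ov, lin, sat))
    mu_eff = p.mu_Na_s + (p.mu_Na_m - p.mu_Na_s) * expit((V_G - p.V_Na_m) / p.w_m)
    return _maybe_scalar(mu_eff * g)


def na_current(V_G, V_DS, p: AntiambipolarParams):
    """Dispatch on ``p.form`` between the Gaussian and two-species laws."""
    if p.form == "two_species":
        return two_species_current(V_G, V_DS, p)
    return antiambipolar_current(V_G, V_DS, p)


def oect_current(V_GS, V_DS, p: OECTParams):
    """Standard monotone OECT/transistor drain current.

    Zero below threshold; ``K_g*((V_GS-V_T)*V_DS - V_DS^2/2)`` in the linear
    regime; ``K_g*(V_GS-V_T)^2/2`` in saturation.  Monotone non-decreasing in
    both arguments and continuous across the regime boundary.
    """
    V_GS = np.asarray(V_GS, dtype=float)
    V_DS = np.asarray(V_DS, dtype=float)
    if np.any(V_DS < 0):
        raise ParameterDomainError("V_DS must be >= 0")
    V_ov = V_GS - p.V_T
    if p.V_ss > 0:
        # weak-inversion tail: softplus effective overdrive
        V_ov = p.V_ss * np.logaddexp(0.0, V_ov / p.V_ss)
    lin = (V_ov - V_DS / 2.0) * V_DS
    sat = V_ov ** 2 / 2.0
    I = p.K_g * np.where(V_ov <= 0, 0.0, np.where(V_DS < V_ov, lin, sat))
    return _maybe_scalar(I)


def amplifier_output(V_in, p: AmplifierParams):
    """Inverting amplifier with supply rails: clamp(gain*V_in + offset)."""
    V_in = np.asarray(V_in, dtype=float)
    return _maybe_scalar(np.clip(p.gain * V_in + p.offset, p.rail_low, p.rail_high))


# ---------------------------------------------------------------------------
# Switching-time (gate step response) utilities


def oect_step_response(p: OECTParams, V_from: float, V_to: float, V_DS: float,
                       t) -> np.ndarray:
    """Drain current after a gate step, through the intrinsic gate RC.

    The gate node follows ``V_g(t) = V_to + (V_from - V_to) exp(-t/tau)`` with
    ``tau = R_g_intrinsic * C_g``; the static current law is applied to the
    lagged gate voltage.
    """
    t = np.asarray(t, dtype=float)
    tau = p.R_g_intrinsic * p.C_g
    V_g = V_to + (V_from - V_to) * np.exp(-t / tau)
    return np.asarray(oect_current(V_g, V_DS, p))


def rise_time_10_90(t: np.ndarray, y: np.ndarray) -> float:
    """10-90% rise time of a monotone-ish step response, by interpolation."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    y0, y1 = y[0], y[-1]
    if y1 <= y0:
        raise ValueError("response does not rise")
    lo = y0 + 0.1 * (y1 - y0)
    hi = y0 + 0.9 * (y1 - y0)
    t_lo = float(np.interp(lo, y, t))
    t_hi = float(np.interp(hi, y, t))
    return t_hi - t_lo


def switching_time(p: OECTParams, V_DS: float = 0.3, overdrive: float = 0.3,
                   n: int = 4000) -> float:
    """10-90% turn-on time of the drain current for a gate step.

    The gate is stepped from below threshold to ``V_T + overdrive`` at fixed
    drain bias, through the intrinsic gate RC.
    """
    tau = p.R_g_intrinsic * p.C_g
    t = np.linspace(0.0, 10.0 * tau, n)
    I = oect_step_response(p, p.V_T - 0.1, p.V_T + overdrive, V_DS, t)
    return rise_time_10_90(t, I)


# ---------------------------------------------------------------------------
# Transfer-curve table I/O and fitting

_TRANSFER_COLUMNS = ("V_G_V", "V_DS_V", "I_D_A")


def read_transfer_csv(path) -> pd.DataFrame:
    """Read a measured/synthetic transfer-curve table (V_G_V, V_DS_V, I_D_A)."""
    df = pd.read_csv(path)
    missing = [c for c in _TRANSFER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"transfer-curve CSV missing columns: {missing}")
    return df


def fit_antiambipolar(table: pd.DataFrame,
                      V_DS_ref: float | None = None) -> AntiambipolarParams:
    """Least-squares fit of the Gaussian antiambipolar law to a transfer table.

    Fits (I_peak0, V_P0, sigma_rise, sigma_fall, k_peak, k_VP, k_sigma) around
    ``V_DS_ref`` (default: the median drain bias in the table).
    """
    from scipy.optimize import least_squares

    vg = table["V_G_V"].to_numpy(float)
    vds = table["V_DS_V"].to_numpy(float)
    idr = table["I_D_A"].to_numpy(float)
    if V_DS_ref is None:
        V_DS_ref = float(np.median(vds))
    i0 = max(idr.max(), 1e-12)
    vp0 = float(vg[np.argmax(idr)])
    span = max(np.ptp(vg) / 6.0, 1e-3)

    def build(theta):
        ipk, vp, sr, sf, kp, kv, ks = theta
        return AntiambipolarParams(
            I_peak0=abs(ipk) + 1e-15, V_P0=vp, sigma_rise=abs(sr) + 1e-6,
            sigma_fall=abs(sf) + 1e-6, V_DS_ref=V_DS_ref, k_peak=kp,
            k_VP=kv, k_sigma=ks)

    def resid(theta):
        try:
            model = antiambipolar_current(vg, vds, build(theta))
        except ParameterDomainError:
            return np.full_like(idr, 1e3)
        return (np.asarray(model) - idr) / i0

    sol = least_squares(resid, x0=[i0, vp0, span, span, 0.0, 0.0, 0.0],
                        xtol=1e-12, ftol=1e-12)
    return build(sol.x)
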