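"""The c-OECN two-node circuit: assembly, equilibria and time integration.

The membrane node (voltage ``V_mem``, capacitance ``C_mem + C_int``) is
charged by the input current and the antiambipolar Na-OECT, and discharged
by the K-OECT and a small leak:

    (C_mem + C_int) dV_mem/dt = I_in(t) + I_Na - I_K - G_L (V_mem - E_L)
    R_dk C_gK       dV_gk/dt  = V_mem - V_gk

The inverting amplifier maps V_mem to the Na-OECT gate, so a rising membrane
voltage sweeps the gate down through the transfer-curve peak V_P: the sodium
current first grows (regenerative depolarisation) and then collapses
(inactivation).  The K-OECT gate ``V_gk`` follows V_mem through the delay
resistor R_dk into the K gate capacitance, so the potassium current peaks
*after* the sodium surge and repolarises the node, overshooting below rest
(hyperpolarisation) because the potassium current is larger and persists.
Effective drain biases float with the membrane: ``E_Na - V_mem`` for the
Na-OECT and ``V_mem - E_K`` for the K-OECT.

Integration uses adaptive LSODA by default (the Gaussian nonlinearity plus
ms-scale lags make the system moderately stiff); a fixed-step RK4 path is
used for noisy inputs and for bit-reproducible regression runs, including a
vectorised variant that advances a whole ensemble of noise seeds at once.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import __version__
from .devices import (AmplifierParams, AntiambipolarParams, OECTParams,
                      amplifier_output, na_current, oect_current)
from .electrolyte import Electrolyte, modulated_k_VT, modulated_na_params
from .stimuli import StimulusProgram

__all__ = [
    "CircuitParams",
    "CircuitState",
    "SolverSettings",
    "SimulationTrace",
    "circuit_rhs",
    "simulate",
    "simulate_ensemble",
    "resting_state",
    "supply_power",
]


@dataclass(frozen=True)
class CircuitParams:
    """Full parameterisation of the c-OECN circuit.

    ``C_mem`` is the optional external membrane capacitor; when it is zero
    the intrinsic device capacitance ``C_int`` alone integrates the input
    (the high-frequency operating mode).  ``R_dk`` with the K-OECT gate
    capacitance sets the potassium delay.  A small leak (``G_L`` to ``E_L``)
    fixes the resting point.  ``C_gNa`` is the Na-OECT gate capacitance seen
    by the amplifier output stage; it only enters the power bookkeeping.
    """

    na: AntiambipolarParams
    k: OECTParams
    amplifier: AmplifierParams = AmplifierParams()
    E_Na: float = 0.5       # V
    E_K: float = -0.050     # V
    C_mem: float = 1.0e-6   # F (external; 0 => intrinsic only)
    C_int: float = 1.0e-8   # F (intrinsic membrane-node capacitance)
    R_dk: float = 470e3     # Ohm
    G_L: float = 1.0e-6     # S
    E_L: float = 0.175      # V
    C_gNa: float = 5.0e-8   # F (amplifier load, power bookkeeping only)
    na_electrolyte: Electrolyte | None = None
    k_electrolyte: Electrolyte | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.C_mem + self.C_int <= 0:
            raise ValueError("C_mem + C_int must be > 0")
        if self.R_dk <= 0:
            raise ValueError("R_dk must be > 0")
        if self.E_Na <= 0:
            raise ValueError("E_Na must be > 0")

    @property
    def C_total(self) -> float:
        return self.C_mem + self.C_int

    @property
    def C_gK(self) -> float:
        """K-OECT gate capacitance (the delay capacitance)."""
        return self.k.C_g

    def effective_na(self) -> AntiambipolarParams:
        """Na-OECT parameters after electrolyte modulation."""
        return modulated_na_params(self.na, self.na_electrolyte)

    def effective_k(self) -> OECTParams:
        """K-OECT parameters after electrolyte modulation of V_K."""
        return replace(self.k, V_T=modulated_k_VT(self.k, self.k_electrolyte))

    def digest(self) -> str:
        """Stable hash of the full parameter set (for run manifests)."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class CircuitState:
    """Dynamic state: membrane voltage and the delayed K-OECT gate voltage."""

    V_mem: float
    V_gk: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V_mem, self.V_gk], dtype=float)


@dataclass(frozen=True)
class SolverSettings:
    """Integrator configuration.

    ``method`` is "lsoda" (adaptive, default) or "rk4" (fixed step ``dt``,
    bit-reproducible, automatically selected when the stimulus carries
    noise).  ``dt_out`` is the dense output sampling interval.
    """

    method: str = "lsoda"
    rtol: float = 1e-7
    atol: float = 1e-10
    dt: float = 2.0e-5      # s, rk4 step
    dt_out: float = 5.0e-5  # s, output sampling
    max_step: float = np.inf

    def __post_init__(self) -> None:
        if self.method not in ("lsoda", "rk4"):
            raise ValueError(f"unknown solver method {self.method!r}")
        if self.rtol <= 0 or self.atol <= 0 or self.dt <= 0 or self.dt_out <= 0:
            raise ValueError("solver tolerances and steps must be > 0")


@dataclass
class SimulationTrace:
    """Time series of a run plus the metadata needed to reproduce it."""

    t: np.ndarray
    V_mem: np.ndarray
    V_gk: np.ndarray
    I_in: np.ndarray
    I_Na: np.ndarray
    I_K: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("V_mem", "V_gk", "I_in", "I_Na", "I_K"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array {name} length mismatch")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("trace time axis must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.t, "V_mem_V": self.V_mem, "V_gk_V": self.V_gk,
            "I_in_A": self.I_in, "I_Na_A": self.I_Na, "I_K_A": self.I_K})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class _Resolved:
    """Circuit with electrolyte modulation folded into plain parameters."""

    def __init__(self, p: CircuitParams):
        self.p = p
        self.na = p.effective_na()
        self.k = p.effective_k()
        self.amp = p.amplifier
        self.C = p.C_total
        self.tau_gk = p.R_dk * p.C_gK

    def currents(self, V_mem, V_gk):
        V_G = amplifier_output(V_mem, self.amp)
        I_Na = na_current(V_G, np.maximum(self.p.E_Na - V_mem, 0.0), self.na)
        I_K = oect_current(V_gk - self.p.E_K,
                           np.maximum(V_mem - self.p.E_K, 0.0), self.k)
        return I_Na, I_K

    def rhs(self, t, y, stim: StimulusProgram):
        V_mem, V_gk = y[0], y[1]
        I_Na, I_K = self.currents(V_mem, V_gk)
        I_in = stim.evaluate(t)
        dVm = (I_in + I_Na - I_K
               - self.p.G_L * (V_mem - self.p.E_L)) / self.C
        dVgk = (V_mem - V_gk) / self.tau_gk
        return np.array([dVm, dVgk])


def circuit_rhs(state, t: float, p: CircuitParams,
                stim: StimulusProgram | None = None) -> np.ndarray:
    """Time derivative of (V_mem, V_gk); pure function of (state, t).

    ``state`` may be a :class:`CircuitState`, a length-2 array, or a (2, N)
    array of stacked states.
    """
    y = state.as_array() if isinstance(state, CircuitState) else np.asarray(state, float)
    if not np.all(np.isfinite(y)):
        bad = "V_mem" if not np.all(np.isfinite(np.atleast_1d(y[0]))) else "V_gk"
        raise FloatingPointError(f"non-finite circuit state at node {bad}")
    if stim is None:
        stim = StimulusProgram()
    return _Resolved(p).rhs(t, y, stim)


def _metadata(p: CircuitParams, stim: StimulusProgram,
              solver: SolverSettings) -> dict:
    return {
        "config_digest": p.digest(),
        "config_label": p.label,
        "solver": asdict(solver),
        "seed": None if stim.noise is None else stim.noise.seed,
        "coecn_version": __version__,
    }


def _finish(res: _Resolved, t: np.ndarray, y: np.ndarray,
            stim: StimulusProgram, meta: dict) -> SimulationTrace:
    I_Na, I_K = res.currents(y[0], y[1])
    return SimulationTrace(t=t, V_mem=y[0], V_gk=y[1],
                           I_in=np.asarray(stim.evaluate(t), float),
                           I_Na=np.asarray(I_Na, float),
                           I_K=np.asarray(I_K, float), metadata=meta)


def _rk4(res: _Resolved, y0: np.ndarray, stim: StimulusProgram, T: float,
         dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step classic RK4; y0 is (2,) or (2, N) for an ensemble."""
    n = int(round(T / dt))
    t = np.arange(n + 1) * dt
    y = np.asarray(y0, float).copy()
    out = np.empty((n + 1,) + y.shape)
    out[0] = y
    f = res.rhs
    for i in range(n):
        ti = t[i]
        k1 = f(ti, y, stim)
        k2 = f(ti + dt / 2, y + dt / 2 * k1, stim)
        k3 = f(ti + dt / 2, y + dt / 2 * k2, stim)
        k4 = f(ti + dt, y + dt * k3, stim)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i + 1] = y
    return t, np.moveaxis(out, 0, 1)


def simulate(p: CircuitParams, stim: StimulusProgram, t_span: float,
             solver: SolverSettings | None = None,
             state0: CircuitState | None = None) -> SimulationTrace:
    """Integrate the circuit for ``t_span`` seconds from rest (or state0).

    Deterministic for fixed parameters, seed and solver settings.  With a
    noisy stimulus the fixed-step RK4 path is used so that the realised noise
    path does not depend on adaptive step selection.
    """
    if t_span <= 0:
        raise ValueError("t_span must be > 0")
    solver = solver or SolverSettings()
    res = _Resolved(p)
    if state0 is None:
        state0 = resting_state(p)
    y0 = state0.as_array()
    meta = _metadata(p, stim, solver)

    noisy = stim.noise is not None and stim.noise.sigma > 0
    if solver.method == "rk4" or noisy:
        t, y = _rk4(res, y0, stim, t_span, solver.dt)
        stride = max(1, int(round(solver.dt_out / solver.dt)))
        return _finish(res, t[::stride], y[:, ::stride], stim, meta)

    t_eval = np.arange(0.0, t_span + solver.dt_out / 2, solver.dt_out)
    t_eval = t_eval[t_eval <= t_span]
    # integrate piecewise between stimulus discontinuities so the adaptive
    # solver cannot step over a short pulse while coasting at equilibrium
    breaks = sorted({0.0, t_span} | {
        t for seg in stim.segments for t in (seg.t_start, seg.t_end)
        if 0.0 < t < t_span})
    ts, ys = [], []
    y = y0
    nfev = 0
    for a, b in zip(breaks, breaks[1:]):
        chunk = t_eval[(t_eval >= a) & (t_eval <= b)]
        if chunk.size == 0 or chunk[0] > a:
            chunk = np.concatenate([[a], chunk])
        sol = solve_ivp(lambda t, y: res.rhs(t, y, stim), (a, b), y,
                        method="LSODA", t_eval=chunk, rtol=solver.rtol,
                        atol=solver.atol, max_step=solver.max_step)
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t = "
                f"{sol.t[-1] if sol.t.size else a:.6g} s: {sol.message}")
        nfev += int(sol.nfev)
        keep = sol.t < b if b < t_span else np.ones(sol.t.size, bool)
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])
        y = sol.y[:, -1]
    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    # drop duplicated chunk-boundary samples
    uniq = np.concatenate([[True], np.diff(t_all) > 0])
    meta["solver_nfev"] = nfev
    return _finish(res, t_all[uniq], y_all[:, uniq], stim, meta)


def simulate_ensemble(p: CircuitParams, stims: list[StimulusProgram],
                      t_span: float,
                      solver: SolverSettings | None = None,
                      state0: CircuitState | None = None) -> list[SimulationTrace]:
    """Integrate one circuit under many stimulus realisations at once.

    All programs must share segment structure (they typically differ only in
    the noise seed).  Fixed-step RK4, vectorised across the ensemble.
    """
    solver = solver or SolverSettings(method="rk4")
    res = _Resolved(p)
    if state0 is None:
        state0 = resting_state(p)
    n = len(stims)
    y0 = np.tile(state0.as_array()[:, None], (1, n))

    dt = solver.dt
    nsteps = int(round(t_span / dt))
    # stimulus values pre-evaluated at the RK4 half-step grid, per member
    t_half = np.arange(2 * nsteps + 1) * (dt / 2)
    S = np.stack([s.evaluate(t_half) for s in stims])  # (n, 2*nsteps+1)

    class _Tab:
        def evaluate(self, t):
            idx = int(round(t / (dt / 2)))
            return S[:, min(idx, S.shape[1] - 1)]

    t, y = _rk4(res, y0, _Tab(), t_span, dt)
    stride = max(1, int(round(solver.dt_out / dt)))
    t_out = t[::stride]
    traces = []
    for j, s in enumerate(stims):
        meta = _metadata(p, s, solver)
        traces.append(_finish(res, t_out, y[:, ::stride, j], s, meta))
    return traces


def _jacobian(res: _Resolved, y: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    J = np.empty((2, 2))
    stim = StimulusProgram()
    f0 = res.rhs(0.0, y, stim)
    for j in range(2):
        dy = y.copy()
        dy[j] += eps
        J[:, j] = (res.rhs(0.0, dy, stim) - f0) / eps
    return J


def resting_state(p: CircuitParams, require_stable: bool = True) -> CircuitState:
    """Stable zero-input equilibrium of the circuit.

    Solves ``circuit_rhs = 0`` by a damped Newton iteration (scipy hybr)
    from V_mem = E_L and, if that fails, from a grid of starting voltages;
    the returned state is verified linearly stable (both eigenvalues of the
    2x2 Jacobian in the left half-plane).
    """
    res = _Resolved(p)
    stim = StimulusProgram()
    starts = [p.E_L] + list(np.linspace(p.E_K, 0.45, 10))
    for v0 in starts:
        sol = root(lambda y: res.rhs(0.0, y, stim), np.array([v0, v0]),
                   method="hybr", tol=1e-14)
        if not sol.success:
            continue
        y = sol.x
        if np.max(np.abs(res.rhs(0.0, y, stim))) > 1e-6:
            continue
        lam = np.linalg.eigvals(_jacobian(res, y))
        if not require_stable or np.all(lam.real < 0):
            return CircuitState(V_mem=float(y[0]), V_gk=float(y[1]))
    raise RuntimeError(
        "no stable resting state found; review circuit parameters "
        "(leak, thresholds, peak currents)")


def supply_power(trace: SimulationTrace, p: CircuitParams) -> np.ndarray:
    """Instantaneous supply power of the circuit along a trace.

    ``P(t) = |E_Na I_Na| + |E_K I_K| + V_rail_high |C_gNa dV_G/dt|`` — the
    two battery branches plus the amplifier output stage, whose current is
    modelled as the Na-OECT gate charging current.
    """
    V_G = np.asarray(amplifier_output(trace.V_mem, p.amplifier), float)
    dVG = np.gradient(V_G, trace.t)
    P_amp = p.amplifier.rail_high * np.abs(p.C_gNa * dVG)
    return (np.abs(p.E_Na * trace.I_Na) + np.abs(p.E_K * trace.I_K) + P_amp)
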