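"""Experiment suites: class-switch scans, chemical modulation, event sensing.

These functions reproduce, from configuration alone, the higher-level
behaviours of the reference neuron:

* sweeping the potassium battery E_K switches the excitability class in the
  order class 1 -> class 2 -> class 3 (phasic bursting, then phasic
  spiking) as the K-OECT turns on earlier;
* raising the Ca2+ concentration in the K-OECT electrolyte lowers the
  threshold V_K and produces the same class sequence (threshold and battery
  shifts are equivalent for a transistor in saturation);
* scanning an analyte concentration (NaCl, glutamine) yields an event-based
  sensing decision — spiking or quiescent per concentration — and a
  reported threshold concentration;
* a GABA step instantly and reversibly inhibits spiking by collapsing the
  sodium peak current.

"Spiking" for sensing decisions means at least ``min_spikes`` detected
spikes (default 3) in the analysis window, which makes the decision robust
to onset transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .circuit import CircuitParams, SimulationTrace, SolverSettings, simulate
from .electrolyte import Electrolyte, make_modulator
from .features import (DEFAULT_THRESHOLD, classify_excitability, detect_spikes,
                       f_I_curve)
from .stimuli import StimulusProgram, constant, step

__all__ = [
    "SensingRule", "SensingReport",
    "run_class_switch_scan", "run_ca_modulation",
    "run_concentration_scan", "run_gaba_inhibition",
]

_CLASS_I_GRID = (0.5e-6, 1e-6, 1.5e-6, 2e-6, 3e-6, 4.5e-6, 6e-6)


def _classify(p: CircuitParams, I_grid, T_fi: float, T_onset_run: float,
              threshold: float, solver: SolverSettings | None) -> str:
    rates = f_I_curve(p, I_grid, T=T_fi, threshold=threshold, solver=solver)
    # the onset (phasic) probe uses the strongest grid amplitude: a class-3
    # neuron spikes only at stimulus onset even for strong steps, while a
    # class-2 neuron spikes tonically there
    onset = simulate(p, step(float(max(I_grid)), t_on=0.25,
                             duration=T_onset_run - 0.25),
                     T_onset_run, solver=solver)
    return classify_excitability(rates, onset, threshold)


def run_class_switch_scan(base: CircuitParams, E_K_grid,
                          I_grid=_CLASS_I_GRID, T_fi: float = 4.0,
                          T_onset_run: float = 3.5,
                          threshold: float = DEFAULT_THRESHOLD,
                          solver: SolverSettings | None = None) -> list[str]:
    """Excitability class at each potassium battery value E_K (V)."""
    labels = []
    for ek in np.asarray(E_K_grid, dtype=float):
        if not -0.1 <= ek <= 0.0:
            raise ValueError(f"E_K = {ek} V outside the scan band [-0.1, 0] V")
        labels.append(_classify(replace(base, E_K=float(ek)), I_grid, T_fi,
                                T_onset_run, threshold, solver))
    return labels


def run_ca_modulation(base: CircuitParams, ca_grid_mM,
                      dVK_coeff: float = -0.010,
                      I_grid=_CLASS_I_GRID, T_fi: float = 4.0,
                      T_onset_run: float = 3.5,
                      threshold: float = DEFAULT_THRESHOLD,
                      solver: SolverSettings | None = None) -> list[str]:
    """Excitability class at each Ca2+ concentration routed to the K-OECT.

    Ca2+ shifts the K-OECT threshold by ``dVK_coeff`` (V/mM, negative), which
    is equivalent to making E_K more negative by the same amount.
    """
    labels = []
    for c in np.asarray(ca_grid_mM, dtype=float):
        elec = Electrolyte(
            modulators=(make_modulator("Ca2+", float(c), dVK_coeff=dVK_coeff),),
            target="K_OECT")
        labels.append(_classify(replace(base, k_electrolyte=elec), I_grid,
                                T_fi, T_onset_run, threshold, solver))
    return labels


@dataclass(frozen=True)
class SensingRule:
    """Concentration scan and decision convention for one analyte.

    ``convention`` picks the reported threshold: "largest_nonspiking" (the
    highest quiescent concentration, used for above-window sensors) or
    "lowest_nonspiking" (the lowest quiescent concentration, used for
    below-window sensors).
    """

    analyte: str                      # "NaCl" (ion) or a modulator name
    grid_mM: tuple                    # ascending concentrations, mM
    amplitude: float = 2e-6           # A, constant drive
    window: float = 3.0               # s
    min_spikes: int = 3
    convention: str = "largest_nonspiking"

    def __post_init__(self) -> None:
        g = tuple(float(c) for c in self.grid_mM)
        if any(b <= a for a, b in zip(g, g[1:])):
            raise ValueError("grid must be sorted ascending")
        if self.convention not in ("largest_nonspiking", "lowest_nonspiking"):
            raise ValueError(f"unknown convention {self.convention!r}")
        object.__setattr__(self, "grid_mM", g)


@dataclass
class SensingReport:
    """Per-concentration spiking decisions and the reported threshold (mM)."""

    analyte: str
    concentrations_mM: list
    spiking: list
    spike_counts: list
    threshold_mM: float | None
    convention: str


def _apply_analyte(base: CircuitParams, analyte: str,
                   conc_mM: float) -> CircuitParams:
    elec = base.na_electrolyte or Electrolyte(target="Na_OECT")
    if any(i.name == analyte or (analyte == "NaCl" and i.name == "Na+")
           for i in elec.ions):
        name = "Na+" if analyte == "NaCl" else analyte
        return replace(base, na_electrolyte=elec.with_ion_concentration(
            name, conc_mM))
    # otherwise treat the analyte as a modulator; keep its configured
    # coefficients if one is already present
    existing = {m.name: m for m in elec.modulators}
    if analyte in existing:
        mod = replace(existing[analyte], concentration=conc_mM)
    else:
        mod = make_modulator(analyte, conc_mM)
    return replace(base, na_electrolyte=elec.with_modulator(mod))


def run_concentration_scan(base: CircuitParams, rule: SensingRule,
                           threshold: float = DEFAULT_THRESHOLD,
                           solver: SolverSettings | None = None) -> SensingReport:
    """Simulate the neuron at each analyte concentration and decide spiking."""
    spiking, counts = [], []
    for c in rule.grid_mM:
        p = _apply_analyte(base, rule.analyte, c)
        trace = simulate(p, constant(rule.amplitude), rule.window,
                         solver=solver)
        n = len(detect_spikes(trace, threshold))
        counts.append(n)
        spiking.append(n >= rule.min_spikes)
    non_spiking = [c for c, s in zip(rule.grid_mM, spiking) if not s]
    if not non_spiking:
        thr = None
    elif rule.convention == "largest_nonspiking":
        thr = max(non_spiking)
    else:
        thr = min(non_spiking)
    return SensingReport(analyte=rule.analyte,
                         concentrations_mM=list(rule.grid_mM),
                         spiking=spiking, spike_counts=counts,
                         threshold_mM=thr, convention=rule.convention)


def run_gaba_inhibition(base: CircuitParams, gaba_step_mM: float,
                        t_on: float = 2.0, t_off: float | None = None,
                        T: float = 4.0, amplitude: float = 2e-6,
                        threshold: float = DEFAULT_THRESHOLD,
                        solver: SolverSettings | None = None):
    """Spiking run with a GABA step applied at ``t_on`` (removed at t_off).

    Concentrations are piecewise-constant per simulation segment, so the run
    is split at the application (and optional removal) time and the state is
    carried across.  Returns ``(trace, inhibited)`` where ``inhibited`` means
    spikes were present before ``t_on`` and absent after one pre-step period.
    """
    from .circuit import CircuitState

    stim = constant(amplitude)
    seg1 = simulate(base, stim, t_on, solver=solver)
    state = CircuitState(V_mem=float(seg1.V_mem[-1]), V_gk=float(seg1.V_gk[-1]))
    p_gaba = _apply_analyte(base, "GABA", gaba_step_mM)
    t2_end = T if t_off is None else t_off
    seg2 = simulate(p_gaba, stim, t2_end - t_on, solver=solver, state0=state)
    parts = [seg1, seg2]
    offsets = [0.0, t_on]
    if t_off is not None:
        state2 = CircuitState(V_mem=float(seg2.V_mem[-1]),
                              V_gk=float(seg2.V_gk[-1]))
        seg3 = simulate(base, stim, T - t_off, solver=solver, state0=state2)
        parts.append(seg3)
        offsets.append(t_off)

    t = np.concatenate([tr.t[:-1] + off for tr, off in zip(parts, offsets)]
                       + [[T]])
    def cat(name):
        return np.concatenate([getattr(tr, name)[:-1] for tr in parts]
                              + [[getattr(parts[-1], name)[-1]]])
    trace = SimulationTrace(t=t, V_mem=cat("V_mem"), V_gk=cat("V_gk"),
                            I_in=cat("I_in"), I_Na=cat("I_Na"), I_K=cat("I_K"),
                            metadata={**seg1.metadata,
                                      "gaba_step_mM": gaba_step_mM,
                                      "t_on_s": t_on, "t_off_s": t_off})

    before = detect_spikes(seg1, threshold).spike_times
    inhibited = False
    if before.size >= 2:
        # allow 1.5 pre-step periods of grace for the spike already in
        # flight when the modulator arrives
        period = float(np.mean(np.diff(before)))
        after = detect_spikes(seg2, threshold).spike_times
        inhibited = not np.any(after > 1.5 * period)
    return trace, inhibited
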