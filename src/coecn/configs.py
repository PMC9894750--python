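"""Reference circuit configurations and YAML config I/O.

Three reference operating points are shipped:

* **config-a** — external ``C_mem = 1 uF`` and ``R_dk = 470 kOhm``; the
  slow (~5 Hz) neuron used for the pulsed feature protocols.
* **config-b** — no external capacitor (the intrinsic membrane-node
  capacitance alone integrates the input); spikes near 80 Hz and carries
  the energy-per-spike bookkeeping.
* **config-c** — config-b devices with a retuned (OECT-style) amplifier
  stage; spikes near 100 Hz.

plus the event-sensing configurations (NaCl window above 25 mM; glutamine
low-concentration window below ~900 uM; glutamine tonic neuron with a ~1 mM
cutoff).  Device constants in these configurations are calibration values
chosen to reproduce the printed operating points of the reference circuit;
they are not measured single-device parameters.

User configurations are plain YAML with unit-suffixed keys (see
``coecn/data/example_config.yaml``); unknown keys are rejected with a
schema error listing the offending names.
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from .circuit import CircuitParams, SolverSettings
from .devices import AmplifierParams, AntiambipolarParams, OECTParams
from .electrolyte import Electrolyte, IonSpecies, Modulator, make_modulator
from .stimuli import NoiseSpec, Segment, StimulusProgram

__all__ = [
    "config_a", "config_b", "config_c",
    "sensing_nacl", "sensing_glutamine_low", "glutamine_tonic",
    "get_config", "list_configs", "load_config", "ConfigError",
]


# --- Config-A: the ~5 Hz reference neuron -------------------------------
#
# All device constants below are calibration values: they realise the
# printed operating points of the reference circuit (0.175 V rest, ~0.34 V
# spike peak, 5 Hz tonic rate at 2 uA, the E_K-driven excitability-class
# sequence) rather than being measured single-device parameters.

NA_OECT_A = AntiambipolarParams(
    I_peak0=10e-6,      # A (wide-channel Na-OECT)
    V_P0=0.87,          # V
    sigma_rise=0.03,    # V
    sigma_fall=0.03,    # V
    V_DS_ref=0.325,     # V  (E_Na - V_rest)
    k_peak=10e-6,       # A/V
    k_VP=0.05,
    k_sigma=0.1,
)

K_OECT_A = OECTParams(
    V_T=0.245,          # V
    K_g=0.4,            # A/V^2 (thicker, wider, higher-current film)
    C_g=7.0e-7,         # F (gate capacitance; with R_dk sets the K delay)
    R_g_intrinsic=420.0,  # Ohm (intrinsic gate resistance; ms switching)
)

AMP_A = AmplifierParams(gain=-2.424, offset=1.624, rail_low=0.5, rail_high=1.4)


def config_a(E_K: float = -0.050) -> CircuitParams:
    """~5 Hz reference neuron (C_mem = 1 uF, R_dk = 470 kOhm)."""
    return CircuitParams(
        na=NA_OECT_A, k=K_OECT_A, amplifier=AMP_A,
        E_Na=0.5, E_K=E_K, C_mem=1.0e-6, C_int=1.5e-7, R_dk=470e3,
        G_L=6.0e-6, E_L=0.175, C_gNa=5.0e-8, label="config-a")


def config_b() -> CircuitParams:
    """~80 Hz neuron: external capacitor removed, intrinsic C_int only.

    Uses the narrow-channel Na-OECT (half the peak current of config-a's
    wide device) and a proportionally weaker K-OECT, a shorter delay
    resistor, and the shallow end of the potassium battery range (-12 mV).
    ``C_gNa`` here is the Na-OECT gate capacitance seen by the amplifier
    output stage, which dominates the supply-power bookkeeping.
    """
    a = config_a()
    return replace(
        a,
        C_mem=0.0, C_int=1.0e-7, R_dk=19.5e3, E_K=-0.012, C_gNa=1.37e-7,
        na=replace(a.na, I_peak0=5e-6, k_peak=5e-6),
        k=replace(a.k, K_g=0.24),
        label="config-b")


def config_c() -> CircuitParams:
    """~100 Hz variant: config-b devices with a retuned (OECT) amplifier."""
    return replace(
        config_b(),
        amplifier=AmplifierParams(gain=-2.8, offset=1.655,
                                  rail_low=0.5, rail_high=1.4),
        C_int=9.0e-8,
        label="config-c")


# --- Event-sensing configurations ---------------------------------------


def sensing_nacl() -> CircuitParams:
    """NaCl event sensor: quiescent at <= 25 mM, spiking above.

    The fitted V_P concentration slope (0.6 V/decade) places the transfer
    curve's peak above the resting gate voltage at low NaCl, so the sodium
    branch can no longer be activated by depolarisation and the neuron
    stays quiescent; at high NaCl the peak returns to its operating
    position and tonic spiking resumes.
    """
    na_elec = Electrolyte(
        ions=(IonSpecies("Na+", z=1, concentration=100.0,
                         slope=0.60, c_ref=100.0),),
        target="Na_OECT")
    return replace(config_a(), na_electrolyte=na_elec, label="sensing-nacl")


def glutamine_tonic() -> CircuitParams:
    """Tonic neuron inhibited by glutamine (cutoff near 1 mM)."""
    na_elec = Electrolyte(
        modulators=(make_modulator("glutamine", 0.0),), target="Na_OECT")
    return replace(config_a(), na_electrolyte=na_elec, label="glutamine-tonic")


def sensing_glutamine_low() -> CircuitParams:
    """Low-window glutamine sensor: spikes below ~900 uM only."""
    na_elec = Electrolyte(
        modulators=(make_modulator("glutamine", 0.0, dVP_coeff=-0.080),),
        target="Na_OECT")
    return replace(config_a(), na_electrolyte=na_elec,
                   label="sensing-glutamine-low")


_REGISTRY = {
    "config-a": config_a,
    "config-b": config_b,
    "config-c": config_c,
    "sensing-nacl": sensing_nacl,
    "glutamine-tonic": glutamine_tonic,
    "sensing-glutamine-low": sensing_glutamine_low,
}

# Output sampling matched to each configuration's spike width.
_SOLVERS = {
    "config-a": SolverSettings(dt_out=5e-5),
    "config-b": SolverSettings(dt_out=5e-6, dt=5e-6),
    "config-c": SolverSettings(dt_out=5e-6, dt=5e-6),
}


def list_configs() -> list[str]:
    return sorted(_REGISTRY)


def get_config(name: str) -> CircuitParams:
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown configuration {name!r}; available: {list_configs()}")


def default_solver(name: str) -> SolverSettings:
    return _SOLVERS.get(name, SolverSettings())


# --- YAML config schema --------------------------------------------------


class ConfigError(ValueError):
    """Raised for unknown or malformed configuration keys."""


_SCHEMA = {
    "base": str,
    "circuit": {"E_Na_V", "E_K_V", "C_mem_F", "C_int_F", "R_dk_Ohm",
                "G_L_S", "E_L_V", "C_gNa_F", "label"},
    "na_oect": {"I_peak0_A", "V_P0_V", "sigma_rise_V", "sigma_fall_V",
                "V_DS_ref_V", "k_peak_A_per_V", "k_VP", "k_sigma_per_V",
                "V_DS_lin_V", "V_Na_s_V", "mu_Na_s_A_per_V2", "V_Na_m_V",
                "mu_Na_m_A_per_V2", "w_m_V", "form"},
    "k_oect": {"V_T_V", "K_g_A_per_V2", "C_g_F", "R_g_Ohm"},
    "amplifier": {"gain", "offset_V", "rail_low_V", "rail_high_V"},
    "electrolytes": None,  # validated structurally below
    "stimulus": {"baseline_A", "segments", "noise"},
    "simulation": {"t_end_s", "method", "rtol", "atol", "dt_s", "dt_out_s"},
}

_SEGMENT_KEYS = {"t_start_s", "duration_s", "kind", "amplitude_A",
                 "amplitude_end_A"}
_NOISE_KEYS = {"model", "sigma_A", "tau_s", "seed", "dt_s"}
_ION_KEYS = {"name", "z", "conc_mM", "slope_V_per_decade", "c_ref_mM"}
_MOD_KEYS = {"name", "conc_mM", "dVP_V_per_mM", "peak_atten_per_mM",
             "dVK_V_per_mM"}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {unknown}")


def _electrolyte_from(block: dict, target: str, where: str) -> Electrolyte:
    _check_keys(block, {"ions", "modulators"}, where)
    ions = []
    for i, d in enumerate(block.get("ions", []) or []):
        _check_keys(d, _ION_KEYS, f"{where}.ions[{i}]")
        ions.append(IonSpecies(
            name=d["name"], z=int(d.get("z", 1)),
            concentration=float(d.get("conc_mM", 100.0)),
            slope=float(d.get("slope_V_per_decade", 0.059)),
            c_ref=float(d.get("c_ref_mM", 100.0))))
    mods = []
    for i, d in enumerate(block.get("modulators", []) or []):
        _check_keys(d, _MOD_KEYS, f"{where}.modulators[{i}]")
        overrides = {}
        if "dVP_V_per_mM" in d:
            overrides["dVP_coeff"] = float(d["dVP_V_per_mM"])
        if "peak_atten_per_mM" in d:
            overrides["peak_atten"] = float(d["peak_atten_per_mM"])
        if "dVK_V_per_mM" in d:
            overrides["dVK_coeff"] = float(d["dVK_V_per_mM"])
        mods.append(make_modulator(d["name"], float(d.get("conc_mM", 0.0)),
                                   **overrides))
    return Electrolyte(ions=tuple(ions), modulators=tuple(mods), target=target)


def load_config(path) -> tuple[CircuitParams, StimulusProgram, SolverSettings]:
    """Load a YAML experiment configuration.

    Returns ``(circuit, stimulus, solver, t_end_s)``.  Raises
    :class:`ConfigError` naming any unknown key.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")
    _check_keys(doc, set(_SCHEMA), "config")

    base_name = doc.get("base", "config-a")
    if base_name not in _REGISTRY:
        raise ConfigError(
            f"unknown base configuration {base_name!r}; available: {list_configs()}")
    p = _REGISTRY[base_name]()
    solver = default_solver(base_name)

    if "na_oect" in doc:
        blk = doc["na_oect"]
        _check_keys(blk, _SCHEMA["na_oect"], "na_oect")
        ren = {"I_peak0_A": "I_peak0", "V_P0_V": "V_P0",
               "sigma_rise_V": "sigma_rise", "sigma_fall_V": "sigma_fall",
               "V_DS_ref_V": "V_DS_ref", "k_peak_A_per_V": "k_peak",
               "k_VP": "k_VP", "k_sigma_per_V": "k_sigma",
               "V_DS_lin_V": "V_DS_lin", "V_Na_s_V": "V_Na_s",
               "mu_Na_s_A_per_V2": "mu_Na_s", "V_Na_m_V": "V_Na_m",
               "mu_Na_m_A_per_V2": "mu_Na_m", "w_m_V": "w_m", "form": "form"}
        p = replace(p, na=replace(p.na, **{ren[k]: v for k, v in blk.items()}))
    if "k_oect" in doc:
        blk = doc["k_oect"]
        _check_keys(blk, _SCHEMA["k_oect"], "k_oect")
        ren = {"V_T_V": "V_T", "K_g_A_per_V2": "K_g", "C_g_F": "C_g",
               "R_g_Ohm": "R_g_intrinsic"}
        p = replace(p, k=replace(p.k, **{ren[k]: v for k, v in blk.items()}))
    if "amplifier" in doc:
        blk = doc["amplifier"]
        _check_keys(blk, _SCHEMA["amplifier"], "amplifier")
        ren = {"gain": "gain", "offset_V": "offset", "rail_low_V": "rail_low",
               "rail_high_V": "rail_high"}
        p = replace(p, amplifier=replace(
            p.amplifier, **{ren[k]: v for k, v in blk.items()}))
    if "circuit" in doc:
        blk = doc["circuit"]
        _check_keys(blk, _SCHEMA["circuit"], "circuit")
        ren = {"E_Na_V": "E_Na", "E_K_V": "E_K", "C_mem_F": "C_mem",
               "C_int_F": "C_int", "R_dk_Ohm": "R_dk", "G_L_S": "G_L",
               "E_L_V": "E_L", "C_gNa_F": "C_gNa", "label": "label"}
        p = replace(p, **{ren[k]: v for k, v in blk.items()})
    if "electrolytes" in doc:
        blk = doc["electrolytes"] or {}
        _check_keys(blk, {"na", "k"}, "electrolytes")
        if "na" in blk:
            p = replace(p, na_electrolyte=_electrolyte_from(
                blk["na"], "Na_OECT", "electrolytes.na"))
        if "k" in blk:
            p = replace(p, k_electrolyte=_electrolyte_from(
                blk["k"], "K_OECT", "electrolytes.k"))

    stim = StimulusProgram(baseline=2e-6)
    if "stimulus" in doc:
        blk = doc["stimulus"]
        _check_keys(blk, _SCHEMA["stimulus"], "stimulus")
        segs = []
        for i, d in enumerate(blk.get("segments", []) or []):
            _check_keys(d, _SEGMENT_KEYS, f"stimulus.segments[{i}]")
            segs.append(Segment(
                t_start=float(d["t_start_s"]), duration=float(d["duration_s"]),
                kind=d.get("kind", "constant"),
                amplitude=float(d.get("amplitude_A", 0.0)),
                amplitude_end=(None if d.get("amplitude_end_A") is None
                               else float(d["amplitude_end_A"]))))
        noise = None
        if blk.get("noise"):
            d = blk["noise"]
            _check_keys(d, _NOISE_KEYS, "stimulus.noise")
            noise = NoiseSpec(model=d.get("model", "ou"),
                              sigma=float(d.get("sigma_A", 0.0)),
                              tau=float(d.get("tau_s", 0.01)),
                              seed=int(d.get("seed", 0)),
                              dt=float(d.get("dt_s", 1e-4)))
        stim = StimulusProgram(segments=tuple(segs),
                               baseline=float(blk.get("baseline_A", 0.0)),
                               noise=noise)

    t_end = 5.0
    if "simulation" in doc:
        blk = doc["simulation"]
        _check_keys(blk, _SCHEMA["simulation"], "simulation")
        t_end = float(blk.get("t_end_s", t_end))
        solver = replace(
            solver,
            method=blk.get("method", solver.method),
            rtol=float(blk.get("rtol", solver.rtol)),
            atol=float(blk.get("atol", solver.atol)),
            dt=float(blk.get("dt_s", solver.dt)),
            dt_out=float(blk.get("dt_out_s", solver.dt_out)))
    return p, stim, solver, t_end
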