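"""Electrolyte composition and its effect on device parameters.

The antiambipolar transfer curve of the Na-OECT is ion tunable: the gate
voltage of its current peak (V_P) shifts with the ion content of the
electrolyte, and amino acids / neurotransmitters (GABA, glutamine, dopamine)
both shift V_P and attenuate the peak current.  Divalent ions such as Ca2+
shift thresholds roughly half as much per decade as monovalent ions.  The
K-OECT threshold V_K is shifted by Ca2+ routed to its electrolyte.

The mapping used here is deliberately phenomenological:

* ions act log-linearly (Nernstian), ``dV_P = -(s/z) log10(c/c_ref)`` per
  species with slope ``s`` (default 0.059 V/decade) and valence ``z``;
* modulator molecules act linearly in concentration on V_P and V_K, and
  multiplicatively (with a floor at zero) on the peak current.

Slopes and coefficients are per-species configuration values so that fitted
numbers can replace the defaults.  Concentrations are piecewise-constant per
simulation segment; no diffusion or depletion dynamics are modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .devices import AntiambipolarParams, OECTParams

__all__ = [
    "IonSpecies",
    "Modulator",
    "Electrolyte",
    "MODULATOR_DEFAULTS",
    "make_modulator",
    "effective_VP",
    "effective_peak_current",
    "effective_VK",
    "modulated_na_params",
    "modulated_k_VT",
]


@dataclass(frozen=True)
class IonSpecies:
    """An ionic species in the electrolyte.

    ``slope`` is the V_P shift per decade of concentration (V/decade); the
    shift is divided by the valence ``z``.
    """

    name: str
    z: int = 1
    concentration: float = 100.0  # mM
    slope: float = 0.059          # V/decade
    c_ref: float = 100.0          # mM

    def __post_init__(self) -> None:
        if self.z not in (1, 2):
            raise ValueError("valence z must be 1 or 2")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.c_ref <= 0:
            raise ValueError("c_ref must be > 0")


# Reference modulator coefficients.  Acetylcholine is a measured no-op
# (3.3 mM in 100 mM NaCl leaves V_P unchanged); the GABA, glutamine and Ca2+
# numbers are calibration constants chosen so that the shipped reference
# neuron reproduces the qualitative endpoint behaviours (instant GABA
# inhibition, glutamine spiking cutoff near 1 mM, Ca2+-driven class switch).
MODULATOR_DEFAULTS: dict[str, dict[str, float]] = {
    "acetylcholine": dict(dVP_coeff=0.0, peak_atten=0.0, dVK_coeff=0.0),
    "dopamine": dict(dVP_coeff=-0.010, peak_atten=0.02, dVK_coeff=0.0),
    "GABA": dict(dVP_coeff=-0.050, peak_atten=0.45, dVK_coeff=0.0),
    "glutamine": dict(dVP_coeff=-0.070, peak_atten=0.15, dVK_coeff=0.0),
    "Ca2+": dict(dVP_coeff=0.0, peak_atten=0.0, dVK_coeff=-0.010),
}


@dataclass(frozen=True)
class Modulator:
    """A neurotransmitter/amino-acid modulator and its effect coefficients.

    ``dVP_coeff`` (V/mM) shifts the Na-OECT V_P, ``peak_atten`` (1/mM) is the
    fractional peak-current reduction per mM (saturating at full
    suppression), ``dVK_coeff`` (V/mM) shifts the K-OECT threshold.
    """

    name: str
    concentration: float = 0.0    # mM
    dVP_coeff: float = 0.0        # V/mM
    peak_atten: float = 0.0       # 1/mM
    dVK_coeff: float = 0.0        # V/mM

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.peak_atten < 0:
            raise ValueError("peak_atten must be >= 0")


def make_modulator(name: str, concentration: float, **overrides) -> Modulator:
    """Build a modulator from the reference coefficient table."""
    coeffs = dict(MODULATOR_DEFAULTS.get(name, {}))
    coeffs.update(overrides)
    return Modulator(name=name, concentration=concentration, **coeffs)


@dataclass(frozen=True)
class Electrolyte:
    """Electrolyte composition routed to one device (Na_OECT or K_OECT)."""

    ions: tuple[IonSpecies, ...] = ()
    modulators: tuple[Modulator, ...] = ()
    target: str = "Na_OECT"

    def __post_init__(self) -> None:
        if self.target not in ("Na_OECT", "K_OECT"):
            raise ValueError("target must be 'Na_OECT' or 'K_OECT'")
        names = [i.name for i in self.ions] + [m.name for m in self.modulators]
        if len(names) != len(set(names)):
            raise ValueError("at most one entry per species name per target")
        object.__setattr__(self, "ions", tuple(self.ions))
        object.__setattr__(self, "modulators", tuple(self.modulators))

    def with_modulator(self, mod: Modulator) -> "Electrolyte":
        """Return a copy with ``mod`` added or replaced by name."""
        rest = tuple(m for m in self.modulators if m.name != mod.name)
        return replace(self, modulators=rest + (mod,))

    def with_ion_concentration(self, name: str, concentration: float) -> "Electrolyte":
        ions = tuple(replace(i, concentration=concentration) if i.name == name else i
                     for i in self.ions)
        if not any(i.name == name for i in ions):
            raise KeyError(f"no ion named {name!r} in electrolyte")
        return replace(self, ions=ions)


def effective_VP(base: AntiambipolarParams, e: Electrolyte) -> float:
    """Electrolyte-shifted gate voltage of the antiambipolar current peak.

    ``V_P = V_P0 - sum_ions (s_i/z_i) log10(c_i/c_ref_i)
          + sum_modulators dVP_coeff_j * conc_j``
    """
    if e.target != "Na_OECT":
        raise ValueError("effective_VP applies to the Na_OECT electrolyte")
    vp = base.V_P0
    for ion in e.ions:
        if ion.concentration <= 0:
            raise ValueError(
                f"ion {ion.name!r} concentration must be > 0 (log undefined)")
        vp -= (ion.slope / ion.z) * math.log10(ion.concentration / ion.c_ref)
    for mod in e.modulators:
        vp += mod.dVP_coeff * mod.concentration
    return vp


def effective_peak_current(base: AntiambipolarParams, e: Electrolyte) -> float:
    """Modulator-attenuated peak current, in [0, I_peak0]."""
    if e.target != "Na_OECT":
        raise ValueError("effective_peak_current applies to the Na_OECT electrolyte")
    ipk = base.I_peak0
    for mod in e.modulators:
        ipk *= max(0.0, 1.0 - mod.peak_atten * mod.concentration)
    return ipk


def effective_VK(base: OECTParams, e: Electrolyte) -> float:
    """Modulator-shifted K-OECT threshold (Ca2+ makes it more negative)."""
    if e.target != "K_OECT":
        raise ValueError("effective_VK applies to the K_OECT electrolyte")
    vk = base.V_T
    for mod in e.modulators:
        vk += mod.dVK_coeff * mod.concentration
    return vk


def modulated_na_params(base: AntiambipolarParams,
                        e: Electrolyte | None) -> AntiambipolarParams:
    """Apply an electrolyte to the Na-OECT parameters (V_P and peak current)."""
    if e is None:
        return base
    return base.with_modulation(effective_VP(base, e),
                                effective_peak_current(base, e))


def modulated_k_VT(base: OECTParams, e: Electrolyte | None) -> float:
    """Effective K-OECT threshold after electrolyte modulation."""
    return base.V_T if e is None else effective_VK(base, e)
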