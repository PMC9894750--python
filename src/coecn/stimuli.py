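"""Input-current programs: constants, steps, ramps, pulse pairs and noise.

A :class:`StimulusProgram` is a baseline current plus an ordered list of
non-overlapping segments (constant or ramp) and an optional seeded noise
process.  Noise is generated on a fixed internal grid (default 0.1 ms) from
the seed — Ornstein-Uhlenbeck via its exact discretisation, or white — and
linearly interpolated, so that evaluation is a pure, reproducible function
of ``(program, t)`` independent of the integrator's step sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Segment", "NoiseSpec", "StimulusProgram", "protocol_library"]


@dataclass(frozen=True)
class Segment:
    """One piece of the input program, active on [t_start, t_start+duration)."""

    t_start: float
    duration: float
    kind: str = "constant"        # "constant" | "ramp"
    amplitude: float = 0.0        # A (ramp: start amplitude)
    amplitude_end: float | None = None  # A (ramp only)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0")
        if self.kind not in ("constant", "ramp"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.kind == "ramp" and self.amplitude_end is None:
            raise ValueError("ramp segment needs amplitude_end")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration

    def value(self, t: np.ndarray) -> np.ndarray:
        active = (t >= self.t_start) & (t < self.t_end)
        if self.kind == "constant":
            return np.where(active, self.amplitude, 0.0)
        frac = np.clip((t - self.t_start) / self.duration, 0.0, 1.0)
        ramp = self.amplitude + (self.amplitude_end - self.amplitude) * frac
        return np.where(active, ramp, 0.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Seeded noise on a fixed grid: white or Ornstein-Uhlenbeck (OU)."""

    model: str = "ou"    # "ou" | "white"
    sigma: float = 0.0   # A (stationary std)
    tau: float = 0.01    # s (OU correlation time)
    seed: int = 0
    dt: float = 1e-4     # s, internal noise grid

    def __post_init__(self) -> None:
        if self.model not in ("ou", "white"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be > 0")

    def path(self, t_max: float) -> tuple[np.ndarray, np.ndarray]:
        """Noise samples on the grid [0, >=t_max].

        Draws are sequential from the seed, so extending ``t_max`` preserves
        the earlier samples exactly.
        """
        n = int(math.ceil(t_max / self.dt)) + 2
        grid = np.arange(n) * self.dt
        rng = np.random.default_rng(self.seed)
        xi = rng.standard_normal(n)
        if self.sigma == 0.0:
            return grid, np.zeros(n)
        if self.model == "white":
            return grid, self.sigma * xi
        a = math.exp(-self.dt / self.tau)
        b = self.sigma * math.sqrt(1.0 - a * a)
        x = np.empty(n)
        x[0] = self.sigma * xi[0]  # stationary initial condition
        for i in range(1, n):
            x[i] = a * x[i - 1] + b * xi[i]
        return grid, x


@dataclass(frozen=True)
class StimulusProgram:
    """Baseline + segments + optional seeded noise; defined for all t >= 0."""

    segments: tuple[Segment, ...] = ()
    baseline: float = 0.0
    noise: NoiseSpec | None = None

    def __post_init__(self) -> None:
        segs = tuple(sorted(self.segments, key=lambda s: s.t_start))
        for a, b in zip(segs, segs[1:]):
            if b.t_start < a.t_end - 1e-15:
                raise ValueError("stimulus segments overlap")
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "_noise_cache", None)

    def _noise_values(self, t: np.ndarray) -> np.ndarray:
        if self.noise is None or self.noise.sigma == 0.0:
            return np.zeros_like(t)
        t_max = float(np.max(t)) if t.size else 0.0
        cache = object.__getattribute__(self, "_noise_cache")
        if cache is None or cache[0][-1] < t_max:
            cache = self.noise.path(max(t_max, 1.0))
            object.__setattr__(self, "_noise_cache", cache)
        grid, vals = cache
        return np.interp(t, grid, vals)

    def evaluate(self, t):
        """Input current at time(s) ``t`` (pure function of program and t)."""
        t_arr = np.asarray(t, dtype=float)
        out = np.full_like(t_arr, self.baseline, dtype=float)
        for seg in self.segments:
            out = out + seg.value(t_arr)
        out = out + self._noise_values(t_arr)
        return float(out) if np.ndim(t) == 0 else out

    @property
    def t_last(self) -> float:
        """End of the last segment (0 if there are none)."""
        return max((s.t_end for s in self.segments), default=0.0)

    def with_noise(self, noise: NoiseSpec | None) -> "StimulusProgram":
        return replace(self, noise=noise)


# ---------------------------------------------------------------------------
# Protocol templates for the neural-feature battery


def constant(amplitude: float) -> StimulusProgram:
    return StimulusProgram(baseline=amplitude)


def step(amplitude: float, t_on: float = 0.5, duration: float = 3.0,
         baseline: float = 0.0) -> StimulusProgram:
    return StimulusProgram(
        segments=(Segment(t_on, duration, "constant", amplitude),),
        baseline=baseline)


def paired_pulse(amplitude: float, width: float, gap: float,
                 t_on: float = 0.5, baseline: float = 0.0) -> StimulusProgram:
    """Two identical pulses; ``gap`` is the quiet interval between them.

    The same template serves the integration (subthreshold amplitudes),
    refractoriness and resonance (suprathreshold amplitudes) protocols.
    """
    s1 = Segment(t_on, width, "constant", amplitude)
    s2 = Segment(t_on + width + gap, width, "constant", amplitude)
    return StimulusProgram(segments=(s1, s2), baseline=baseline)


def ramp(amplitude: float, t_on: float = 0.5, rise: float = 2.0,
         hold: float = 1.0, baseline: float = 0.0) -> StimulusProgram:
    segs = (Segment(t_on, rise, "ramp", 0.0, amplitude),
            Segment(t_on + rise, hold, "constant", amplitude))
    return StimulusProgram(segments=segs, baseline=baseline)


def ramp_vs_step(amplitude: float, t_on: float = 0.5, rise: float = 2.0,
                 hold: float = 1.0,
                 baseline: float = 0.0) -> tuple[StimulusProgram, StimulusProgram]:
    """Equal-endpoint pair for the accommodation test (slow ramp vs step)."""
    r = ramp(amplitude, t_on, rise, hold, baseline)
    s = step(amplitude, t_on, rise + hold, baseline)
    return r, s


def negative_release(amplitude: float, width: float = 0.5, t_on: float = 0.5,
                     baseline: float = 0.0) -> StimulusProgram:
    """Hyperpolarising pulse whose release may trigger a rebound spike."""
    return StimulusProgram(
        segments=(Segment(t_on, width, "constant", -abs(amplitude)),),
        baseline=baseline)


def pre_negative_test(test_amplitude: float, test_width: float,
                      neg_amplitude: float, neg_width: float,
                      gap: float = 0.02, t_on: float = 0.5,
                      baseline: float = 0.0) -> StimulusProgram:
    """Negative conditioning pulse followed by a positive test pulse."""
    s1 = Segment(t_on, neg_width, "constant", -abs(neg_amplitude))
    s2 = Segment(t_on + neg_width + gap, test_width, "constant", test_amplitude)
    return StimulusProgram(segments=(s1, s2), baseline=baseline)


def protocol_library() -> dict:
    """Named constructors for the stimulus templates of the feature battery."""
    return {
        "constant": constant,
        "step": step,
        "paired_pulse": paired_pulse,
        "ramp": ramp,
        "ramp_vs_step": ramp_vs_step,
        "negative_release": negative_release,
        "pre_negative_test": pre_negative_test,
    }
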