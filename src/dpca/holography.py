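"""Hologram formation and four-step phase-shifting field extraction.

The recorded hologram intensity is the interference of an object wave O and
a reference wave R:

    I = |O|**2 + |R|**2 + O* R + O R*

Shifting the reference phase by ``delta`` multiplies the cross terms by
``exp(+/- i delta)``.  Recording four frames at shifts 0, pi/2, pi, 3pi/2
isolates the ``O R*`` term exactly:

    O R* = [(I_0 - I_pi) + i (I_{3pi/2} - I_{pi/2})] / 4

whose angle is the measured phase ``phi_o + phi_a`` wherever |O||R| > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synthgen import GridConvention

__all__ = [
    "ComplexField",
    "HologramStack",
    "FOUR_STEP_SHIFTS",
    "form_hologram",
    "record_four_step",
    "extract_field_four_step",
]

FOUR_STEP_SHIFTS: tuple[float, ...] = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)


@dataclass(frozen=True)
class ComplexField:
    """A 2D complex optical field (dimensionless amplitude) on a pixel grid."""

    values: np.ndarray
    grid: GridConvention

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.complex128)
        object.__setattr__(self, "values", v)
        if v.shape != self.grid.shape:
            raise ValueError(f"field shape {v.shape} != grid {self.grid.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("complex field must be finite")

    @classmethod
    def from_phase(cls, phase: np.ndarray, amplitude: float | np.ndarray = 1.0) -> "ComplexField":
        phase = np.asarray(phase, dtype=np.float64)
        grid = GridConvention(height=phase.shape[0], width=phase.shape[1])
        return cls(values=np.asarray(amplitude) * np.exp(1j * phase), grid=grid)


@dataclass(frozen=True)
class HologramStack:
    """Ordered intensity frames with the reference-phase shift of each."""

    frames: tuple[np.ndarray, ...]
    shifts: tuple[float, ...]

    def __post_init__(self) -> None:
        frames = tuple(np.asarray(f, dtype=np.float64) for f in self.frames)
        object.__setattr__(self, "frames", frames)
        if len(frames) != len(self.shifts):
            raise ValueError("number of frames must equal number of shifts")
        shape = frames[0].shape
        for f in frames:
            if f.shape != shape:
                raise ValueError("all frames must share one shape")
            if np.any(f < -1e-9):
                raise ValueError("hologram intensities must be nonnegative")


def form_hologram(
    object_wave: ComplexField, reference_wave: ComplexField, shift: float = 0.0
) -> np.ndarray:
    """Interfere O with a phase-shifted reference; returns real intensity.

    The shift retards the reference phase (``R -> R exp(-i shift)``) so the
    ``O R*`` cross term picks up ``exp(+i shift)``; this sign pairs with
    :func:`extract_field_four_step` to recover ``O R*`` rather than its
    conjugate.
    """
    if object_wave.values.shape != reference_wave.values.shape:
        raise ValueError("object and reference shapes must match")
    o = object_wave.values
    r = reference_wave.values * np.exp(-1j * shift)
    intensity = np.abs(o) ** 2 + np.abs(r) ** 2 + 2.0 * np.real(o * np.conj(r))
    return np.maximum(intensity, 0.0)


def record_four_step(
    object_wave: ComplexField, reference_wave: ComplexField
) -> HologramStack:
    """Record the canonical four-frame phase-shifting stack."""
    frames = tuple(
        form_hologram(object_wave, reference_wave, shift) for shift in FOUR_STEP_SHIFTS
    )
    return HologramStack(frames=frames, shifts=FOUR_STEP_SHIFTS)


def extract_field_four_step(stack: HologramStack) -> ComplexField:
    """Recover ``O R*`` from a four-step stack at shifts (0, pi/2, pi, 3pi/2)."""
    if len(stack.frames) != 4:
        raise ValueError("four-step extraction needs exactly four frames")
    if not np.allclose(stack.shifts, FOUR_STEP_SHIFTS, atol=1e-12):
        raise ValueError(f"shifts must be {FOUR_STEP_SHIFTS}, got {stack.shifts}")
    i0, i1, i2, i3 = stack.frames
    field = ((i0 - i2) + 1j * (i3 - i1)) / 4.0
    grid = GridConvention(height=field.shape[0], width=field.shape[1])
    return ComplexField(values=field, grid=grid)
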