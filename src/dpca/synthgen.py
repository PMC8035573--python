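"""Synthetic phase-image generation for digital holographic microscopy.

A DHM measurement delivers a phase map ``phi = phi_o + phi_a`` — the object
(sample) phase superimposed with the slowly varying aberration phase of the
optical train (tilt, defocus, astigmatism, coma, ...).  This module builds
both parts synthetically so every downstream stage of the compensation
pipeline can be exercised without experimental data:

* polynomial aberration surfaces ``phi_a = sum_{k,l} P[k,l] * x**k * y**l``
  over the raw pixel-index grid,
* a stand-in sample phase made of a smooth Gaussian spot plus a sharp binary
  letter pattern,
* phase wrapping into ``(-pi, pi]`` and reproducible additive Gaussian noise.

Coordinates follow the image convention used throughout the package:
``x`` is the 0-based column index, ``y`` the 0-based row index, unit pixel
spacing, origin at the top-left corner.  Coefficients therefore carry units
of radians per pixel**(k+l).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GridConvention",
    "AberrationSpec",
    "SampleSpec",
    "PhaseImage",
    "phase_image_from_array",
    "eval_polynomial_aberration",
    "make_sample_phase",
    "wrap_phase",
    "wrap_array",
    "add_noise",
    "letters_mask",
]


@dataclass(frozen=True)
class GridConvention:
    """Pixel-index grid: x = column index, y = row index, unit spacing.

    No centering and no physical pixel-pitch scaling are applied; x ranges
    over ``0..width-1`` and y over ``0..height-1``.
    """

    height: int = 512
    width: int = 512

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError("grid dimensions must be at least 2x2")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Return broadcastable ``(x, y)`` index arrays (column, row)."""
        x = np.arange(self.width, dtype=np.float64)[None, :]
        y = np.arange(self.height, dtype=np.float64)[:, None]
        return x, y


@dataclass(frozen=True)
class PhaseImage:
    """A 2D phase map in radians with an explicit wrapped/unwrapped flag."""

    values: np.ndarray
    wrapped: bool
    grid: GridConvention

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.shape != self.grid.shape:
            raise ValueError(
                f"phase shape {v.shape} does not match grid {self.grid.shape}"
            )
        if self.wrapped and (np.any(v > np.pi) or np.any(v <= -np.pi)):
            raise ValueError("wrapped phase must lie in (-pi, pi]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def with_values(self, values: np.ndarray, wrapped: bool | None = None) -> "PhaseImage":
        return PhaseImage(
            values=np.asarray(values, dtype=np.float64),
            wrapped=self.wrapped if wrapped is None else wrapped,
            grid=self.grid,
        )


def phase_image_from_array(values: np.ndarray, wrapped: bool = False) -> PhaseImage:
    """Wrap a bare array into a :class:`PhaseImage` with a matching grid."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("phase image must be 2D")
    grid = GridConvention(height=values.shape[0], width=values.shape[1])
    return PhaseImage(values=values, wrapped=wrapped, grid=grid)


class AberrationSpec:
    """Sparse polynomial aberration: ``phi_a = sum P[k,l] * x**k * y**l``.

    A term is a *cross term* iff both exponents are nonzero; those are the
    terms a rank-1 (PC1) reconstruction of ``exp(i*phi)`` cannot represent,
    because ``x**k * y**l`` with ``k, l > 0`` is not of the form
    ``f(x) + g(y)``.

    Parameters
    ----------
    coefficients
        Mapping from ``(k, l)`` exponent pairs to coefficients in
        radians / pixel**(k+l).
    """

    def __init__(self, coefficients: Mapping[tuple[int, int], float]):
        coeffs: dict[tuple[int, int], float] = {}
        for key, value in coefficients.items():
            k, l = int(key[0]), int(key[1])
            if k < 0 or l < 0:
                raise ValueError(f"polynomial orders must be nonnegative, got {(k, l)}")
            if (k, l) in coeffs:
                raise ValueError(f"duplicate exponent pair {(k, l)}")
            coeffs[(k, l)] = float(value)
        self._coeffs = coeffs

    @property
    def coefficients(self) -> dict[tuple[int, int], float]:
        return dict(self._coeffs)

    @property
    def K(self) -> int:
        return max((k for k, _ in self._coeffs), default=0)

    @property
    def L(self) -> int:
        return max((l for _, l in self._coeffs), default=0)

    def __len__(self) -> int:
        return len(self._coeffs)

    def __getitem__(self, key: tuple[int, int]) -> float:
        return self._coeffs.get((int(key[0]), int(key[1])), 0.0)

    @staticmethod
    def is_cross(k: int, l: int) -> bool:
        return k != 0 and l != 0

    def cross_terms(self) -> dict[tuple[int, int], float]:
        return {kl: p for kl, p in self._coeffs.items() if self.is_cross(*kl)}

    def non_cross_terms(self) -> dict[tuple[int, int], float]:
        return {kl: p for kl, p in self._coeffs.items() if not self.is_cross(*kl)}

    def scaled(self, factor: float) -> "AberrationSpec":
        return AberrationSpec({kl: factor * p for kl, p in self._coeffs.items()})

    def __add__(self, other: "AberrationSpec") -> "AberrationSpec":
        merged = dict(self._coeffs)
        for kl, p in other._coeffs.items():
            merged[kl] = merged.get(kl, 0.0) + p
        return AberrationSpec(merged)

    def to_yaml_dict(self) -> dict[str, float]:
        """Serializable form with ``"k,l"`` string keys."""
        return {f"{k},{l}": p for (k, l), p in sorted(self._coeffs.items())}

    @classmethod
    def from_yaml_dict(cls, data: Mapping[str, float]) -> "AberrationSpec":
        coeffs = {}
        for key, value in data.items():
            k_str, l_str = str(key).split(",")
            coeffs[(int(k_str), int(l_str))] = float(value)
        return cls(coeffs)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        terms = ", ".join(f"({k},{l}): {p:g}" for (k, l), p in sorted(self._coeffs.items()))
        return f"AberrationSpec({{{terms}}})"


@dataclass
class SampleSpec:
    """Stand-in object phase: a Gaussian spot plus a sharp binary step.

    The Gaussian emulates a gradually varying specimen (e.g. a rounded cell
    body); the binary mask emulates a sharply bounded phase step (rendered
    letters by default).  Heights are in radians, lengths in pixels.
    """

    gaussian_peak: float = 1.0
    gaussian_sigma: float = 50.0
    gaussian_center: tuple[float, float] | None = None  # (row, col); None = image center
    mask_height: float = 1.5
    mask: np.ndarray | None = None  # binary {0,1}; None = no step pattern

    def __post_init__(self) -> None:
        if self.gaussian_peak < 0:
            raise ValueError("gaussian_peak must be >= 0")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.mask is not None:
            m = np.asarray(self.mask)
            if not np.isin(m, (0, 1)).all():
                raise ValueError("mask pixels must be 0 or 1")
            self.mask = m.astype(np.float64)


# 5x7 bitmap glyphs for the procedural letter pattern.  A fixed raster (not
# font rendering) keeps the generated sample phase bit-identical everywhere.
_GLYPHS: dict[str, tuple[str, ...]] = {
    "d": ("....#", "....#", ".####", "#...#", "#...#", "#...#", ".####"),
    "-": (".....", ".....", ".....", "#####", ".....", ".....", "....."),
    "P": ("####.", "#...#", "#...#", "####.", "#....", "#....", "#...."),
    "C": (".####", "#....", "#....", "#....", "#....", "#....", ".####"),
    "A": (".###.", "#...#", "#...#", "#####", "#...#", "#...#", "#...#"),
}


def letters_mask(
    grid: GridConvention,
    text: str = "d-PCA",
    scale: int = 8,
    top_left: tuple[int, int] | None = None,
) -> np.ndarray:
    """Render ``text`` as a binary {0,1} mask on the given grid.

    Glyphs come from a built-in 5x7 raster, magnified ``scale`` times with
    one glyph-column of spacing.  By default the block is centered in the
    lower half of the image so it does not coincide with a centered Gaussian
    spot.  Unknown characters raise ``KeyError``.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    cols = []
    for i, ch in enumerate(text):
        glyph = np.array([[c == "#" for c in row] for row in _GLYPHS[ch]], dtype=np.float64)
        if i > 0:
            cols.append(np.zeros((7, 1)))
        cols.append(glyph)
    block = np.concatenate(cols, axis=1)
    block = np.kron(block, np.ones((scale, scale)))
    h, w = block.shape
    if h > grid.height or w > grid.width:
        raise ValueError("letter block does not fit on the grid")
    if top_left is None:
        r0 = min(grid.height - h, grid.height // 2 + grid.height // 8)
        c0 = (grid.width - w) // 2
    else:
        r0, c0 = top_left
        if r0 < 0 or c0 < 0 or r0 + h > grid.height or c0 + w > grid.width:
            raise ValueError("letter block out of bounds")
    mask = np.zeros(grid.shape, dtype=np.float64)
    mask[r0 : r0 + h, c0 : c0 + w] = block
    return mask


def eval_polynomial_aberration(spec: AberrationSpec, grid: GridConvention) -> PhaseImage:
    """Evaluate the polynomial aberration surface on the pixel grid.

    Returns an unwrapped :class:`PhaseImage` whose value at row ``y``,
    column ``x`` is ``sum_{k,l} P[k,l] * x**k * y**l`` exactly (up to
    floating-point rounding of the monomials).
    """
    if len(spec) == 0:
        raise ValueError("aberration spec must contain at least one term")
    x, y = grid.coords()
    surface = np.zeros(grid.shape, dtype=np.float64)
    for (k, l), p in spec.coefficients.items():
        surface += p * (x**k) * (y**l)
    return PhaseImage(values=surface, wrapped=False, grid=grid)


def make_sample_phase(spec: SampleSpec, grid: GridConvention) -> PhaseImage:
    """Build the object phase: Gaussian spot + binary step pattern."""
    x, y = grid.coords()
    if spec.gaussian_center is None:
        r0, c0 = (grid.height - 1) / 2.0, (grid.width - 1) / 2.0
    else:
        r0, c0 = spec.gaussian_center
    r2 = (y - r0) ** 2 + (x - c0) ** 2
    phase = spec.gaussian_peak * np.exp(-r2 / (2.0 * spec.gaussian_sigma**2))
    if spec.mask is not None:
        if spec.mask.shape != grid.shape:
            raise ValueError(
                f"mask shape {spec.mask.shape} does not match grid {grid.shape}"
            )
        phase = phase + spec.mask_height * spec.mask
    return PhaseImage(values=phase, wrapped=False, grid=grid)


def wrap_array(values: np.ndarray) -> np.ndarray:
    """Wrap raw phase values into ``(-pi, pi]`` (congruent mod 2*pi)."""
    return np.pi - np.mod(np.pi - np.asarray(values, dtype=np.float64), 2.0 * np.pi)


def wrap_phase(phase: PhaseImage) -> PhaseImage:
    """Wrap a phase image into the ``(-pi, pi]`` interval."""
    return PhaseImage(values=wrap_array(phase.values), wrapped=True, grid=phase.grid)


def add_noise(phase: PhaseImage, sigma: float, seed: int) -> PhaseImage:
    """Add i.i.d. zero-mean Gaussian phase noise, reproducible per seed."""
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if sigma == 0:
        return phase
    rng = np.random.default_rng(seed)
    noisy = phase.values + rng.normal(0.0, sigma, size=phase.shape)
    if phase.wrapped:
        return PhaseImage(values=wrap_array(noisy), wrapped=True, grid=phase.grid)
    return phase.with_values(noisy)
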