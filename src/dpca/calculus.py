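"""Forward differences and their exact cumulative-sum inverses.

Differentiating a phase map turns a cross term ``P * x**k * y**l`` into a
non-cross term: the k-fold forward difference along x of ``x**k`` is the
constant ``k!`` exactly on an integer grid, so the k-th x-derivative of the
cross term is ``P * k! * y**l`` — separable, hence visible to a rank-1
estimate.  Differences use unit pixel spacing with no division (diff /
cumsum semantics), so derivatives here are finite differences and the
factorial identity is exact rather than asymptotic.

Each difference discards the first row/column; that vector is saved in a
:class:`BoundaryRecord` and later re-used as the initial data of the
cumulative sum, making ``integrate`` the exact inverse of
``partial_derivative``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly

from .synthgen import PhaseImage, phase_image_from_array

__all__ = ["BoundaryRecord", "boundary_smooth", "partial_derivative", "integrate"]

_AXES = {"x": 1, "y": 0}


@dataclass(frozen=True)
class BoundaryRecord:
    """First rows/columns captured before each successive difference.

    ``saved[m]`` is the leading vector along ``axis`` of the m-th
    intermediate derivative (``saved[0]`` from the original image).  Each
    vector has length equal to the image extent along the *other* axis,
    which differencing leaves untouched.
    """

    axis: str  # "x" (columns) or "y" (rows)
    order: int
    saved: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError("axis must be 'x' or 'y'")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if len(self.saved) != self.order:
            raise ValueError("record must hold exactly `order` boundary vectors")
        object.__setattr__(
            self, "saved", tuple(np.asarray(v, dtype=np.float64) for v in self.saved)
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "axis": self.axis,
                "order": self.order,
                "saved": [v.tolist() for v in self.saved],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BoundaryRecord":
        data = json.loads(text)
        return cls(
            axis=data["axis"],
            order=int(data["order"]),
            saved=tuple(np.asarray(v, dtype=np.float64) for v in data["saved"]),
        )


def _fit_vector(values: np.ndarray, degree: int) -> np.ndarray:
    idx = np.arange(values.size, dtype=np.float64)
    return npoly.Polynomial.fit(idx, values, deg=degree)(idx)


def boundary_smooth(phase: PhaseImage, j: int, fit_degree: int = 5) -> PhaseImage:
    """Replace the first ``j`` rows and columns with their 1D polynomial fits.

    The leading rows/columns seed both the difference and the cumulative
    sum, so noise there propagates into every recovered pixel; smoothing
    them first contains that.  Interior pixels are returned bit-identical.
    """
    if j < 1:
        raise ValueError("j must be >= 1")
    if fit_degree < 1:
        raise ValueError("fit_degree must be >= 1")
    h, w = phase.shape
    if j >= h or j >= w:
        raise ValueError("j must be smaller than both image extents")
    out = phase.values.copy()
    for r in range(j):
        out[r, :] = _fit_vector(out[r, :], fit_degree)
    for c in range(j):
        out[:, c] = _fit_vector(out[:, c], fit_degree)
    return phase.with_values(out)


def partial_derivative(
    phase: PhaseImage, axis: str, order: int
) -> tuple[np.ndarray, BoundaryRecord]:
    """j successive forward differences along ``axis`` with boundary capture.

    ``out[i] = in[i+1] - in[i]`` along the chosen axis; before each
    difference the current leading vector is appended to the returned
    :class:`BoundaryRecord`.  The extent along ``axis`` shrinks by one per
    difference.  Requires an unwrapped input — differencing wrapped phase
    would turn 2*pi seams into spurious spikes.
    """
    if phase.wrapped:
        raise ValueError("phase must be unwrapped before differentiation")
    if axis not in _AXES:
        raise ValueError("axis must be 'x' or 'y'")
    if order < 1:
        raise ValueError("order must be >= 1")
    ax = _AXES[axis]
    if phase.shape[ax] <= order:
        raise ValueError("image extent along axis must exceed the derivative order")
    current = phase.values
    saved = []
    for _ in range(order):
        saved.append(np.take(current, 0, axis=ax).copy())
        current = np.diff(current, axis=ax)
    record = BoundaryRecord(axis=axis, order=order, saved=tuple(saved))
    return current, record


def integrate(derivative: np.ndarray, record: BoundaryRecord) -> PhaseImage:
    """Invert :func:`partial_derivative` by cumulative sums with saved seeds.

    Each saved boundary vector, applied in reverse capture order, is
    prepended as the initial value of one cumulative sum; the output
    regains one pixel of extent per step.  Round trips are exact to
    floating-point summation error.
    """
    derivative = np.asarray(derivative, dtype=np.float64)
    ax = _AXES[record.axis]
    other = 1 - ax
    current = derivative
    for boundary in reversed(record.saved):
        if boundary.shape[0] != current.shape[other]:
            raise ValueError("boundary vector length does not match surface")
        if ax == 1:
            seed = boundary[:, None]
            current = np.concatenate(
                [seed, seed + np.cumsum(current, axis=1)], axis=1
            )
        else:
            seed = boundary[None, :]
            current = np.concatenate(
                [seed, seed + np.cumsum(current, axis=0)], axis=0
            )
    return phase_image_from_array(current, wrapped=False)
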