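"""Phase wrapping and unwrapping utilities.

Measured phase is only known modulo 2*pi, in ``(-pi, pi]``.  Differentiation
and polynomial fitting both need the continuous surface, so the pipeline
unwraps before its first derivative and unwraps the 1D singular-vector
phases inside the PCA reconstruction.  Exactness holds under the Itoh
condition: the true phase changes by less than pi between adjacent pixels.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.restoration import unwrap_phase as _skimage_unwrap

from .synthgen import PhaseImage, wrap_array

__all__ = ["unwrap_2d", "unwrap_1d"]

logger = logging.getLogger(__name__)


def unwrap_2d(wrapped: PhaseImage) -> PhaseImage:
    """Unwrap a 2D phase image into a continuous surface.

    Output is congruent to the input modulo 2*pi pointwise.  For inputs that
    are wrapped versions of a smooth surface (adjacent-pixel true differences
    below pi) the surface is recovered up to a single global 2*pi*integer
    offset.  Pathological inputs (residues) yield a best-effort result.
    """
    values = wrapped.values
    if not wrapped.wrapped:
        logger.debug("unwrap_2d called on an already-unwrapped image; pass-through")
        return wrapped
    # skimage expects [-pi, pi); our convention is (-pi, pi].  Exact +pi values
    # are congruent to -pi, so map them down before unwrapping.
    v = np.where(values == np.pi, -np.pi, values)
    unwrapped = np.asarray(_skimage_unwrap(v), dtype=np.float64)
    # Restore exact mod-2pi congruence with the original (-pi, pi] samples.
    unwrapped += wrap_array(values - unwrapped)
    return PhaseImage(values=unwrapped, wrapped=False, grid=wrapped.grid)


def unwrap_1d(wrapped_vector: np.ndarray) -> np.ndarray:
    """Itoh 1D unwrapping: remove jumps larger than pi between neighbours.

    Exact (up to a global 2*pi*integer) when the underlying signal satisfies
    the Itoh condition; a true jump above pi is necessarily altered.
    """
    return np.unwrap(np.asarray(wrapped_vector, dtype=np.float64))
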