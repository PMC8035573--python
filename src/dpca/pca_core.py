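"""Rank-1 SVD ("PC1") estimation of separable phase backgrounds.

The complex field ``M = exp(i*phi)`` of a separable phase
``phi(y, x) = f(y) + g(x)`` factorises exactly as an outer product
``exp(i f(y)) * exp(i g(x))`` — a rank-1 matrix.  Its first singular
triplet therefore carries the whole background, and the 1D phases of the
two dominant singular vectors are ``f`` and ``g`` up to a shared constant.
Non-separable (cross-term) phases like ``x**2 * y`` spread over several
comparable singular values and defeat this reconstruction; that failure is
what the derivative trick in :mod:`dpca.pipeline` repairs.

No mean-centering is applied before the SVD: centering would destroy the
rank-1 factorisation of the phase exponential that the estimate relies on.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly

from .phaseutils import unwrap_1d
from .synthgen import GridConvention, PhaseImage

__all__ = ["PCAResult", "variance_spectrum", "estimate_separable_aberration"]

logger = logging.getLogger(__name__)

_DEGENERATE_GAP = 1e-12


@dataclass(frozen=True)
class PCAResult:
    """Outcome of a rank-1 background estimate.

    Attributes
    ----------
    variance_fractions
        Squared singular values of ``exp(i*phi)`` normalised to fractions
        (descending, summing to 1) — the share of variance per component.
    u_phase, v_phase
        Polynomial-smoothed unwrapped phases of the first left/right
        singular vectors (radians); lengths equal the image height/width.
        The shared constant (piston) of the rank-1 product is assigned
        wholly to ``v_phase``.
    fit_degree
        Degree of the 1D least-squares fits applied to both vectors.
    reconstructed
        Separable surface ``u_phase[y] + v_phase[x]`` as a
        :class:`PhaseImage` (unwrapped, exact outer sum by construction).
    """

    variance_fractions: np.ndarray
    u_phase: np.ndarray
    v_phase: np.ndarray
    fit_degree: int
    reconstructed: PhaseImage

    def to_json_dict(self) -> dict:
        """Compact QC summary (leading fractions and fitted profiles)."""
        return {
            "variance_fractions": self.variance_fractions[:20].tolist(),
            "fit_degree": self.fit_degree,
            "u_phase_fit": self.u_phase.tolist(),
            "v_phase_fit": self.v_phase.tolist(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict())


def _complex_field(phase: PhaseImage) -> np.ndarray:
    values = phase.values
    if not np.all(np.isfinite(values)):
        raise ValueError("phase contains non-finite values")
    return np.exp(1j * values)


def variance_spectrum(phase: PhaseImage) -> np.ndarray:
    """Per-component variance fractions of the field ``exp(i*phi)``.

    Wrapped and unwrapped inputs give identical spectra since only the
    phase exponential enters.  Fractions are descending and sum to 1.
    """
    s = np.linalg.svd(_complex_field(phase), compute_uv=False)
    power = s**2
    return power / power.sum()


def _fit_profile(values: np.ndarray, degree: int) -> np.ndarray:
    """Ordinary least-squares polynomial fit evaluated back on the index grid."""
    idx = np.arange(values.size, dtype=np.float64)
    # Fit on a scaled domain for conditioning; evaluate on the pixel indices.
    series = npoly.Polynomial.fit(idx, values, deg=degree)
    return series(idx)


def estimate_separable_aberration(phase: PhaseImage, fit_degree: int = 5) -> PCAResult:
    """Estimate the separable background of ``phi`` from the first SVD component.

    Procedure: SVD of ``exp(i*phi)``; take the first left and right singular
    vectors; unwrap their 1D phases; replace each with its ordinary
    least-squares polynomial fit of ``fit_degree`` (this is what suppresses
    noise and any sample-phase leakage into PC1); reconstruct the separable
    surface as the outer sum of the two fitted profiles.
    """
    if fit_degree < 1:
        raise ValueError("fit_degree must be >= 1")
    h, w = phase.shape
    if h < fit_degree + 1 or w < fit_degree + 1:
        raise ValueError("image too small for the requested fit degree")

    field = _complex_field(phase)
    u, s, vh = np.linalg.svd(field, full_matrices=False)
    if s[0] - s[1] < _DEGENERATE_GAP:
        warnings.warn(
            "leading singular values are degenerate; PC1 is not unique",
            RuntimeWarning,
            stacklevel=2,
        )
    power = s**2
    fractions = power / power.sum()

    # angle(vh[0]) == angle(conj(v1)): the rank-1 product u1*s1*v1^H has phase
    # angle(u1[y]) + angle(conj(v1)[x]), so these two profiles sum to the
    # separable background directly.
    u_phase = unwrap_1d(np.angle(u[:, 0]))
    v_phase = unwrap_1d(np.angle(vh[0, :]))
    u_fit = _fit_profile(u_phase, fit_degree)
    v_fit = _fit_profile(v_phase, fit_degree)

    # Piston convention: the constant part of the product goes to v_phase.
    piston = u_fit[0]
    u_fit = u_fit - piston
    v_fit = v_fit + piston

    reconstructed = PhaseImage(
        values=u_fit[:, None] + v_fit[None, :],
        wrapped=False,
        grid=phase.grid,
    )
    return PCAResult(
        variance_fractions=fractions,
        u_phase=u_fit,
        v_phase=v_fit,
        fit_degree=fit_degree,
        reconstructed=reconstructed,
    )
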