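"""The dPCA compensation loop: schedule over derivative order and direction.

A single compensation step at derivative order ``j`` along direction ``d``:

1. smooth the first ``j`` rows/columns (they seed diff and cumsum),
2. take ``j`` forward differences along ``d``, saving boundary vectors,
3. estimate the separable background of the derivative by rank-1 SVD with
   polynomial-smoothed singular-vector phases,
4. integrate the estimate back with the saved boundary data,
5. subtract: ``phi' = phi - phi_a``.

``j = 0`` degenerates to a conventional PCA step (no derivative/integral),
which handles non-cross aberrations only.  The default ladder
``(1,x), (1,y), (2,x), (2,y)`` covers cross terms up to fourth order, since
a term ``x**k * y**l`` becomes non-cross after ``min(k, l)`` differences
along the matching direction.  Progress is scored by the standard
deviation of sample-free background regions after each step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly

from .calculus import boundary_smooth, integrate, partial_derivative
from .pca_core import PCAResult, estimate_separable_aberration
from .phaseutils import unwrap_2d
from .synthgen import AberrationSpec, PhaseImage

__all__ = [
    "IterationPlan",
    "BackgroundRegion",
    "StepRecord",
    "CompensationReport",
    "compensate_step",
    "dpca_run",
    "background_std",
    "fit_polynomial_surface_2d",
    "default_border_region",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IterationPlan:
    """Ordered (j, d) schedule for the compensation loop.

    ``steps=None`` builds the default alternating ladder
    ``(1,x),(1,y),...,(max_order,x),(max_order,y)``.  ``include_pca0``
    prepends a conventional PCA pass (j=0), recommended as a cheap first
    attempt because it is less noise-sensitive than derivative steps.
    """

    max_order: int = 2
    include_pca0: bool = True
    steps: tuple[tuple[int, str], ...] | None = None

    def __post_init__(self) -> None:
        if self.steps is None:
            ladder = tuple(
                (j, d) for j in range(1, self.max_order + 1) for d in ("x", "y")
            )
            object.__setattr__(self, "steps", ladder)
        else:
            object.__setattr__(self, "steps", tuple((int(j), str(d)) for j, d in self.steps))
        for j, d in self.steps:
            if j < 1 or d not in ("x", "y"):
                raise ValueError(f"invalid plan step {(j, d)}")
        if len(self.steps) == 0 and not self.include_pca0:
            raise ValueError("iteration plan must contain at least one step")

    def schedule(self) -> tuple[tuple[int, str | None], ...]:
        """Full execution order, with the optional (0, None) pre-pass."""
        pre: tuple[tuple[int, str | None], ...] = ((0, None),) if self.include_pca0 else ()
        return pre + tuple(self.steps)


@dataclass(frozen=True)
class BackgroundRegion:
    """Union of half-open pixel boxes ``(row0, col0, row1, col1)``."""

    rectangles: tuple[tuple[int, int, int, int], ...]

    def __post_init__(self) -> None:
        rects = tuple(tuple(int(v) for v in r) for r in self.rectangles)
        object.__setattr__(self, "rectangles", rects)
        if not rects:
            raise ValueError("background region must contain at least one box")
        for r0, c0, r1, c1 in rects:
            if r1 <= r0 or c1 <= c0 or r0 < 0 or c0 < 0:
                raise ValueError(f"invalid rectangle {(r0, c0, r1, c1)}")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        for r0, c0, r1, c1 in self.rectangles:
            if r1 > shape[0] or c1 > shape[1]:
                raise ValueError("background rectangle exceeds image bounds")
            m[r0:r1, c0:c1] = True
        if not m.any():
            raise ValueError("background region is empty")
        return m


def default_border_region(shape: tuple[int, int], margin_fraction: float = 0.1) -> BackgroundRegion:
    """A border frame of the given fractional thickness.

    Used when no explicit background is supplied: the specimen is assumed
    roughly centered, leaving the frame sample-free.
    """
    h, w = shape
    mr = max(1, int(round(margin_fraction * h)))
    mc = max(1, int(round(margin_fraction * w)))
    return BackgroundRegion(
        rectangles=(
            (0, 0, mr, w),
            (h - mr, 0, h, w),
            (mr, 0, h - mr, mc),
            (mr, w - mc, h - mr, w),
        )
    )


def background_std(phase: PhaseImage, region: BackgroundRegion) -> float:
    """Standard deviation over the region union after removing its mean."""
    values = phase.values[region.mask(phase.shape)]
    return float(np.std(values))


def fit_polynomial_surface_2d(phase: PhaseImage, K: int, L: int) -> AberrationSpec:
    """Ordinary least-squares fit of ``sum P[k,l] x**k y**l`` to a surface.

    Exact (to round-off) for noise-free polynomial inputs of compatible
    degree; used to read recovered aberration surfaces back into
    coefficients.  Coordinates are scaled to [0, 1] internally for
    conditioning and the coefficients rescaled to raw pixel units.
    """
    h, w = phase.shape
    if (K + 1) * (L + 1) > h * w:
        raise ValueError("more coefficients than pixels")
    sx = float(max(w - 1, 1))
    sy = float(max(h - 1, 1))
    x = (np.arange(w, dtype=np.float64) / sx)[None, :] * np.ones((h, 1))
    y = (np.arange(h, dtype=np.float64) / sy)[:, None] * np.ones((1, w))
    design = npoly.polyvander2d(x.ravel(), y.ravel(), [K, L])
    coef, _, rank, _ = np.linalg.lstsq(design, phase.values.ravel(), rcond=None)
    if rank < (K + 1) * (L + 1):
        raise ValueError("rank-deficient polynomial design matrix")
    coeffs = {}
    for k in range(K + 1):
        for l in range(L + 1):
            coeffs[(k, l)] = coef[k * (L + 1) + l] / (sx**k * sy**l)
    return AberrationSpec(coeffs)


def compensate_step(
    phase: PhaseImage,
    j: int,
    d: str | None,
    fit_degree: int = 5,
    boundary_mode: str = "measured",
) -> tuple[PhaseImage, PhaseImage, PCAResult]:
    """One compensation step; returns (phi', recovered phi_a, PCA result).

    ``j = 0`` applies the rank-1 estimate directly to the phase (``d`` is
    ignored).  For ``j >= 1`` the estimate is made on the j-th forward
    difference along ``d`` and integrated back with the saved boundary
    data.  ``boundary_mode``:

    - ``"measured"``: seed the integral with the boundary vectors captured
      from the (smoothed) measured phase.  Faithful to the diff/cumsum
      bookkeeping, but any sample phase on the image border leaks into the
      recovered background there.
    - ``"extrapolated"``: replace each captured boundary vector with its
      own 1D polynomial fit, suppressing border sample leakage.
    """
    if phase.wrapped:
        raise ValueError("compensate_step expects an unwrapped phase")
    if boundary_mode not in ("measured", "extrapolated"):
        raise ValueError("boundary_mode must be 'measured' or 'extrapolated'")
    if j == 0:
        result = estimate_separable_aberration(phase, fit_degree=fit_degree)
        aberration = result.reconstructed
    else:
        if d not in ("x", "y"):
            raise ValueError("derivative direction must be 'x' or 'y'")
        smoothed = boundary_smooth(phase, j, fit_degree=fit_degree)
        derivative, record = partial_derivative(smoothed, axis=d, order=j)
        if boundary_mode == "extrapolated":
            idx_fit = lambda v: npoly.Polynomial.fit(
                np.arange(v.size, dtype=np.float64), v, deg=fit_degree
            )(np.arange(v.size, dtype=np.float64))
            record = type(record)(
                axis=record.axis,
                order=record.order,
                saved=tuple(idx_fit(v) for v in record.saved),
            )
        deriv_image = PhaseImage(
            values=derivative,
            wrapped=False,
            grid=type(phase.grid)(height=derivative.shape[0], width=derivative.shape[1]),
        )
        result = estimate_separable_aberration(deriv_image, fit_degree=fit_degree)
        # The separable estimate is only defined modulo 2*pi (it comes from
        # exp(i*phase)); a stray 2*pi offset would integrate to a huge
        # parabolic surface, so snap to the branch of the measured derivative.
        recon = result.reconstructed.values
        offset = 2 * np.pi * np.round(np.median(derivative - recon) / (2 * np.pi))
        aberration = integrate(recon + offset, record)
    compensated = phase.with_values(phase.values - aberration.values)
    return compensated, aberration, result


@dataclass(frozen=True)
class StepRecord:
    """One executed step of the loop and its evaluation."""

    j: int
    d: str | None
    variance_fractions: np.ndarray  # leading fractions of the step's PCA
    aberration: PhaseImage  # background recovered by this step
    background_std: float  # after subtracting this step's background

    def summary(self) -> dict:
        return {
            "j": self.j,
            "d": self.d,
            "variance_fractions": self.variance_fractions[:10].tolist(),
            "background_std": self.background_std,
        }


@dataclass(frozen=True)
class CompensationReport:
    """Full record of a compensation run.

    ``total_aberration`` is the sum of all per-step recovered backgrounds
    with the final piston removed; ``final_phase`` is the input minus that
    total (piston retained, since absolute phase offsets are physically
    meaningless anyway).
    """

    steps: tuple[StepRecord, ...]
    final_phase: PhaseImage
    total_aberration: PhaseImage
    stop_reason: str

    @property
    def std_trace(self) -> np.ndarray:
        return np.array([s.background_std for s in self.steps])

    def to_json_dict(self) -> dict:
        return {
            "steps": [s.summary() for s in self.steps],
            "std_trace": self.std_trace.tolist(),
            "stop_reason": self.stop_reason,
        }


def dpca_run(
    phase: PhaseImage,
    plan: IterationPlan | None = None,
    region: BackgroundRegion | None = None,
    std_threshold: float | None = 0.1,
    improvement_floor: float | None = 0.05,
    fit_degree: int = 5,
    boundary_mode: str = "measured",
) -> CompensationReport:
    """Run the full compensation schedule with background-STD evaluation.

    The phase is unwrapped once if it arrives wrapped and kept unwrapped
    throughout (each step subtracts a continuous surface, so no re-wrapping
    occurs).  After every step the background STD is evaluated; the loop
    stops early when it falls below ``std_threshold`` or when the relative
    improvement drops below ``improvement_floor``; a step that makes the
    background *worse* (its derivative was not PC1-dominated, so the
    subtraction injected estimation error) is reverted before stopping.
    Pass ``None`` for both criteria to disable evaluation-driven control
    ("no-stop" mode runs the complete plan, mimicking manual evaluation).
    """
    if plan is None:
        plan = IterationPlan()
    if region is None:
        region = default_border_region(phase.shape)

    current = unwrap_2d(phase) if phase.wrapped else phase
    total = np.zeros(phase.shape, dtype=np.float64)
    records: list[StepRecord] = []
    stop_reason = "plan exhausted"
    prev_std = background_std(current, region)

    for j, d in plan.schedule():
        previous = current
        current, aberration, result = compensate_step(
            current, j, d, fit_degree=fit_degree, boundary_mode=boundary_mode
        )
        std = background_std(current, region)
        records.append(
            StepRecord(
                j=j,
                d=d,
                variance_fractions=result.variance_fractions,
                aberration=aberration,
                background_std=std,
            )
        )
        logger.info(
            "step j=%d d=%s: PC1 fraction %.4f, background STD %.3e rad",
            j, d, result.variance_fractions[0], std,
        )
        if std_threshold is not None and std < std_threshold:
            total += aberration.values
            stop_reason = f"background STD {std:.3e} below threshold {std_threshold:g}"
            break
        if improvement_floor is not None and std >= prev_std:
            # a step that flattens nothing only injects its estimation error;
            # decline the subtraction and finish
            current = previous
            stop_reason = (
                f"step (j={j}, d={d}) did not improve background STD "
                f"({prev_std:.3e} -> {std:.3e}); step reverted"
            )
            break
        total += aberration.values
        if (
            improvement_floor is not None
            and prev_std > 0
            and (prev_std - std) / prev_std < improvement_floor
        ):
            stop_reason = (
                f"relative improvement below {improvement_floor:.0%} "
                f"({prev_std:.3e} -> {std:.3e})"
            )
            break
        prev_std = std

    total -= total.mean()  # report the background up to piston
    report = CompensationReport(
        steps=tuple(records),
        final_phase=current,
        total_aberration=phase.with_values(total, wrapped=False),
        stop_reason=stop_reason,
    )
    logger.info("compensation finished: %s", stop_reason)
    return report
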