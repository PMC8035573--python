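"""File I/O: float TIFF phase maps, hologram stacks, YAML run configuration.

Phase maps travel as single-channel 32-bit float TIFF in radians; hologram
stacks as 4-page float TIFF with the reference shifts in a JSON sidecar;
run configuration as YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from .holography import HologramStack
from .pipeline import BackgroundRegion, IterationPlan
from .synthgen import AberrationSpec, GridConvention, PhaseImage, SampleSpec

__all__ = [
    "read_phase_tiff",
    "write_phase_tiff",
    "read_hologram_stack",
    "write_hologram_stack",
    "RunConfig",
    "load_config",
]


def write_phase_tiff(path: str | Path, phase: PhaseImage) -> None:
    tifffile.imwrite(str(path), phase.values.astype(np.float32))


def read_phase_tiff(path: str | Path, wrapped: bool = False) -> PhaseImage:
    values = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D phase map")
    grid = GridConvention(height=values.shape[0], width=values.shape[1])
    return PhaseImage(values=values, wrapped=wrapped, grid=grid)


def write_hologram_stack(path: str | Path, stack: HologramStack) -> None:
    path = Path(path)
    tifffile.imwrite(
        str(path),
        np.stack(stack.frames).astype(np.float32),
        photometric="minisblack",
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"shifts": list(stack.shifts)}))


def read_hologram_stack(path: str | Path) -> HologramStack:
    path = Path(path)
    frames = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected a multi-page hologram stack")
    sidecar = path.with_suffix(path.suffix + ".json")
    shifts = tuple(json.loads(sidecar.read_text())["shifts"])
    return HologramStack(frames=tuple(frames), shifts=shifts)


@dataclass
class RunConfig:
    """Parsed YAML run configuration with package defaults filled in."""

    grid: GridConvention = field(default_factory=GridConvention)
    aberration: AberrationSpec | None = None
    sample: SampleSpec | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    plan: IterationPlan = field(default_factory=IterationPlan)
    fit_degree: int = 5
    std_threshold: float | None = 0.1
    improvement_floor: float | None = 0.05
    background: BackgroundRegion | None = None
    boundary_mode: str = "measured"
    letters: dict[str, Any] = field(default_factory=dict)


def _parse_plan(data: dict[str, Any]) -> IterationPlan:
    steps = data.get("steps")
    return IterationPlan(
        max_order=int(data.get("max_order", 2)),
        include_pca0=bool(data.get("include_pca0", True)),
        steps=tuple((int(j), str(d)) for j, d in steps) if steps else None,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration.

    Recognised keys: ``grid {height, width}``, ``aberration`` (mapping of
    ``"k,l"`` to coefficient), ``sample`` (gaussian_peak, gaussian_sigma,
    gaussian_center, mask_height, letters {text, scale}), ``noise {sigma}``,
    ``seed``, ``plan {max_order, include_pca0, steps}``, ``fit_degree``,
    ``std_threshold``, ``improvement_floor``, ``background`` (list of
    [row0, col0, row1, col1] boxes), ``boundary_mode``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}

    cfg = RunConfig()
    if "grid" in data:
        cfg.grid = GridConvention(
            height=int(data["grid"].get("height", 512)),
            width=int(data["grid"].get("width", 512)),
        )
    if "aberration" in data and data["aberration"]:
        cfg.aberration = AberrationSpec.from_yaml_dict(data["aberration"])
    if "sample" in data and data["sample"] is not None:
        s = data["sample"]
        center = s.get("gaussian_center")
        cfg.sample = SampleSpec(
            gaussian_peak=float(s.get("gaussian_peak", 1.0)),
            gaussian_sigma=float(s.get("gaussian_sigma", 50.0)),
            gaussian_center=tuple(center) if center else None,
            mask_height=float(s.get("mask_height", 1.5)),
        )
        cfg.letters = dict(s.get("letters") or {})
    if "noise" in data and data["noise"]:
        cfg.noise_sigma = float(data["noise"].get("sigma", 0.0))
    cfg.seed = int(data.get("seed", 0))
    if "plan" in data and data["plan"]:
        cfg.plan = _parse_plan(data["plan"])
    cfg.fit_degree = int(data.get("fit_degree", 5))
    if "std_threshold" in data:
        v = data["std_threshold"]
        cfg.std_threshold = None if v is None else float(v)
    if "improvement_floor" in data:
        v = data["improvement_floor"]
        cfg.improvement_floor = None if v is None else float(v)
    if "background" in data and data["background"]:
        cfg.background = BackgroundRegion(
            rectangles=tuple(tuple(int(v) for v in box) for box in data["background"])
        )
    cfg.boundary_mode = str(data.get("boundary_mode", "measured"))
    return cfg
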