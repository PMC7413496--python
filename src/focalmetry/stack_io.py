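"""Image containers with physical sampling, TIFF round trips and run config.

Conventions used everywhere in the package:

* stacks are indexed ``(z, y, x)``, 0-based, page 0 = shallowest plane;
* movies are indexed ``(t, y, x)``;
* physical steps are micrometres per pixel/step and must be supplied
  explicitly when the file carries no metadata — there are no silent
  defaults, because a wrong step silently rescales every FWHM downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import FormatError, ValidationError


@dataclass
class ImageStack:
    """A 3D intensity array (z, y, x) with lateral/axial sampling in um."""

    voxels: np.ndarray
    lateral_step_um: float
    axial_step_um: float

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or 0 in self.voxels.shape:
            raise ValidationError(f"stack must be a non-empty 3D (z,y,x) array, got shape {self.voxels.shape}")
        if self.lateral_step_um <= 0 or self.axial_step_um <= 0:
            raise ValidationError("physical steps must be positive")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise ValidationError("intensities must be finite and >= 0")

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]


@dataclass
class Movie:
    """A time-lapse (t, y, x) with frame interval in seconds."""

    frames: np.ndarray
    frame_interval_s: float
    lateral_step_um: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or 0 in self.frames.shape:
            raise ValidationError(f"movie must be a non-empty 3D (t,y,x) array, got shape {self.frames.shape}")
        if self.frame_interval_s <= 0 or self.lateral_step_um <= 0:
            raise ValidationError("frame interval and lateral step must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValidationError("intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _read_pages(path) -> np.ndarray:
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            for i, p in enumerate(tif.pages):
                if p.shape != tif.pages[0].shape:
                    raise FormatError(f"page {i} has shape {p.shape}, expected {tif.pages[0].shape}")
        arr = tif.asarray()
        meta = tif.imagej_metadata or {}
    if arr.ndim == 2:
        arr = arr[None]
    return arr, meta


def read_stack(path, lateral_step_um: float | None = None, axial_step_um: float | None = None) -> ImageStack:
    """Read a multi-page TIFF as an ImageStack (page 0 = shallowest plane).

    Explicit steps override embedded ImageJ metadata; if neither source
    provides a step a :class:`ValidationError` is raised.
    """
    arr, meta = _read_pages(path)
    if axial_step_um is None:
        axial_step_um = meta.get("spacing")
    if lateral_step_um is None:
        lateral_step_um = meta.get("lateral_step_um")
    if lateral_step_um is None or axial_step_um is None:
        raise ValidationError(f"{path}: physical steps absent from metadata and not supplied explicitly")
    return ImageStack(arr.astype(float), float(lateral_step_um), float(axial_step_um))


def write_stack(stack: ImageStack, path) -> None:
    """Write a multi-page TIFF with ImageJ-dialect voxel-size metadata."""
    data = stack.voxels
    if np.allclose(data, np.round(data)) and data.min() >= 0 and data.max() < 2**16:
        data = data.astype(np.uint16)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / stack.lateral_step_um, 1.0 / stack.lateral_step_um),
        metadata={
            "spacing": stack.axial_step_um,
            "unit": "um",
            "lateral_step_um": stack.lateral_step_um,
        },
    )


def read_movie(path, lateral_step_um: float | None = None, frame_interval_s: float | None = None) -> Movie:
    arr, meta = _read_pages(path)
    if frame_interval_s is None:
        frame_interval_s = meta.get("finterval")
    if lateral_step_um is None:
        lateral_step_um = meta.get("lateral_step_um")
    if lateral_step_um is None or frame_interval_s is None:
        raise ValidationError(f"{path}: frame interval / pixel size absent and not supplied explicitly")
    return Movie(arr.astype(float), float(frame_interval_s), float(lateral_step_um))


def write_movie(movie: Movie, path) -> None:
    data = movie.frames
    if np.allclose(data, np.round(data)) and data.min() >= 0 and data.max() < 2**16:
        data = data.astype(np.uint16)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / movie.lateral_step_um, 1.0 / movie.lateral_step_um),
        metadata={
            "finterval": movie.frame_interval_s,
            "unit": "um",
            "lateral_step_um": movie.lateral_step_um,
        },
    )


# ---------------------------------------------------------------------------
# Run configuration


class _StrictLoader(yaml.SafeLoader):
    """YAML loader that rejects duplicate mapping keys."""


def _strict_mapping(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise FormatError(f"duplicate key {key!r} in config")
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_StrictLoader.add_constructor(yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_mapping)


@dataclass
class ConditionConfig:
    fill_mode: str
    immersion_ri: float
    depth_um: float
    n_beads: int = 15
    label: str | None = None


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    seed: int = 0
    mode: str = "free_center"  # Gaussian-fit centre handling
    min_area: int = 20  # ROI area threshold (strictly greater survives)
    k_lowest: int = 100  # lowest-intensity pixels per plane for background
    connectivity: int = 8
    simulate: bool = True
    conditions: list[ConditionConfig] = field(default_factory=list)
    reference_index: int = 0
    reference_ri: float = 1.33
    n_planes: int = 21
    amplitude_a: float = 4.0
    amplitude_b: float = 1.0
    extrapolate: bool = False

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "conditions"}
        d["conditions"] = [
            {k: v for k, v in c.__dict__.items() if v is not None} for c in self.conditions
        ]
        return d


_ALLOWED_KEYS = {
    "seed", "mode", "min_area", "k_lowest", "connectivity", "simulate",
    "conditions", "reference_index", "reference_ri", "n_planes",
    "amplitude_a", "amplitude_b", "extrapolate",
}
_CONDITION_KEYS = {"fill_mode", "immersion_ri", "depth_um", "n_beads", "label"}


def parse_run_config(raw: dict) -> RunConfig:
    """Validate a raw mapping into a RunConfig, listing every violation."""
    problems: list[str] = []
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")
    conditions = []
    for i, c in enumerate(raw.get("conditions", []) or []):
        local: list[str] = []
        bad = set(c) - _CONDITION_KEYS
        if bad:
            problems.append(f"conditions[{i}]: unknown keys {sorted(bad)}")
            continue
        missing = {"fill_mode", "immersion_ri", "depth_um"} - set(c)
        if missing:
            problems.append(f"conditions[{i}]: missing keys {sorted(missing)}")
            continue
        if c["fill_mode"] not in ("overfill", "underfill"):
            local.append(f"conditions[{i}]: fill_mode must be overfill/underfill")
        if not 1.30 <= float(c["immersion_ri"]) <= 1.40:
            local.append(f"conditions[{i}]: immersion_ri {c['immersion_ri']} outside [1.30, 1.40]")
        if float(c["depth_um"]) < 0:
            local.append(f"conditions[{i}]: depth_um must be >= 0")
        problems.extend(local)
        if not local:
            conditions.append(ConditionConfig(
                fill_mode=c["fill_mode"], immersion_ri=float(c["immersion_ri"]),
                depth_um=float(c["depth_um"]), n_beads=int(c.get("n_beads", 15)),
                label=c.get("label"),
            ))
    scalars = {k: raw[k] for k in raw if k in _ALLOWED_KEYS and k != "conditions"}
    cfg = RunConfig(conditions=conditions)
    for k, v in scalars.items():
        setattr(cfg, k, v)
    if cfg.mode not in ("free_center", "fixed_center"):
        problems.append(f"mode must be free_center or fixed_center, got {cfg.mode!r}")
    if cfg.min_area < 0:
        problems.append("min_area must be >= 0")
    if cfg.k_lowest < 1:
        problems.append("k_lowest must be >= 1")
    if cfg.connectivity not in (4, 8):
        problems.append("connectivity must be 4 or 8")
    if cfg.n_planes < 1:
        problems.append("n_planes must be >= 1")
    if problems:
        raise ValidationError("invalid run config: " + "; ".join(problems))
    return cfg


def load_run_config(path) -> RunConfig:
    text = Path(path).read_text()
    raw = yaml.load(text, Loader=_StrictLoader)
    if raw is None:
        raw = {}
    return parse_run_config(raw)


def save_run_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
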