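"""Objective/beam geometry and the phenomenological focal-volume model.

Two-photon focal volumes are axially elongated ellipsoids whose size grows
with imaging depth (spherical aberration accumulates along the excitation
path) and with the refractive-index mismatch between the immersion liquid
and the specimen.  This module encodes

* the entrance-pupil geometry of an infinity-corrected objective and the
  over/underfill classification of the excitation beam,
* a table of measured effective bead-image widths (FWHM) per pupil-fill
  mode and depth, interpolated linearly in depth, and
* a deliberately simple quadratic RI-mismatch response used by the
  synthetic-data generator (not a diffraction computation).

Widths are in micrometres, beam/pupil diameters in millimetres throughout.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .errors import RangeError, ValidationError

#: FWHM of a Gaussian with unit standard deviation.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class FillMode(str, Enum):
    """Whether the excitation beam over- or under-fills the entrance pupil."""

    OVERFILL = "overfill"
    UNDERFILL = "underfill"


@dataclass(frozen=True)
class ObjectiveSpec:
    """An infinity-corrected objective (magnification, NA, tube lens)."""

    magnification: float
    numerical_aperture: float
    tube_focal_length_mm: float = 180.0  # Olympus tube-lens convention

    def __post_init__(self):
        if self.magnification <= 0 or self.tube_focal_length_mm <= 0:
            raise ValidationError("objective magnification and tube focal length must be positive")
        if not 0 < self.numerical_aperture < 1.7:
            raise ValidationError(f"numerical aperture {self.numerical_aperture} outside (0, 1.7)")


@dataclass(frozen=True)
class BeamConfig:
    """Excitation beam at the entrance-pupil plane."""

    beam_diameter_mm: float
    fill_mode: FillMode

    def __post_init__(self):
        if self.beam_diameter_mm <= 0:
            raise ValidationError("beam diameter must be positive")
        object.__setattr__(self, "fill_mode", FillMode(self.fill_mode))


@dataclass(frozen=True)
class ImagingCondition:
    """Immersion RI, pupil-fill mode and imaging depth for one acquisition."""

    immersion_ri: float
    fill_mode: FillMode
    depth_um: float

    def __post_init__(self):
        if not 1.30 <= self.immersion_ri <= 1.40:
            raise ValidationError(f"immersion RI {self.immersion_ri} outside [1.30, 1.40]")
        if self.depth_um < 0:
            raise ValidationError("depth must be >= 0")
        object.__setattr__(self, "fill_mode", FillMode(self.fill_mode))

    @classmethod
    def standard(cls, depth_um: float) -> "ImagingCondition":
        """Condition S: overfilled pupil, water immersion (n = 1.33)."""
        return cls(1.33, FillMode.OVERFILL, depth_um)

    @classmethod
    def enhanced(cls, depth_um: float) -> "ImagingCondition":
        """Condition E: underfilled pupil, n = 1.36 immersion liquid."""
        return cls(1.36, FillMode.UNDERFILL, depth_um)

    def to_dict(self) -> dict:
        return {
            "immersion_ri": self.immersion_ri,
            "fill_mode": self.fill_mode.value,
            "depth_um": self.depth_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImagingCondition":
        return cls(float(d["immersion_ri"]), FillMode(d["fill_mode"]), float(d["depth_um"]))


@dataclass(frozen=True)
class PSFSpec:
    """Effective focal-volume widths (FWHM) along the lateral and axial axes."""

    fwhm_lateral_um: float
    fwhm_axial_um: float

    def __post_init__(self):
        if not self.fwhm_lateral_um > 0:
            raise ValidationError("lateral FWHM must be positive")
        if self.fwhm_axial_um < self.fwhm_lateral_um:
            raise ValidationError("axial FWHM must be >= lateral FWHM (two-photon focal volumes are elongated)")

    @property
    def sigma_lateral_um(self) -> float:
        return self.fwhm_lateral_um / FWHM_PER_SIGMA

    @property
    def sigma_axial_um(self) -> float:
        return self.fwhm_axial_um / FWHM_PER_SIGMA

    def scaled(self, lateral_factor: float, axial_factor: float) -> "PSFSpec":
        return PSFSpec(self.fwhm_lateral_um * lateral_factor, self.fwhm_axial_um * axial_factor)


@dataclass(frozen=True)
class AberrationModelParams:
    """Quadratic RI-mismatch response of the synthetic focal-volume model.

    Per-axis inflation factor is ``1 + gain * depth_um * (n - optimal_ri)**2``;
    at ``n == optimal_ri`` the depth preset is returned unchanged.  The gains
    are simulator knobs (units um^-1 RI^-2), not physical constants; the
    axial default gives a 1.3x axial inflation at |n - optimal| = 0.025 and
    300 um depth.
    """

    optimal_ri: float = 1.355
    axial_mismatch_gain: float = 1.6
    lateral_mismatch_gain: float = 1.6 / 3.0

    def __post_init__(self):
        if self.axial_mismatch_gain < 0 or self.lateral_mismatch_gain < 0:
            raise ValidationError("mismatch gains must be >= 0")

    def to_dict(self) -> dict:
        return {
            "optimal_ri": self.optimal_ri,
            "axial_mismatch_gain": self.axial_mismatch_gain,
            "lateral_mismatch_gain": self.lateral_mismatch_gain,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AberrationModelParams":
        return cls(**{k: float(v) for k, v in d.items()})


def pupil_diameter(objective: ObjectiveSpec) -> float:
    """Entrance-pupil diameter in mm: ``2 * NA * f_tube / M``."""
    return 2.0 * objective.numerical_aperture * objective.tube_focal_length_mm / objective.magnification


def fill_fraction(beam: BeamConfig, objective: ObjectiveSpec) -> float:
    """Fraction of the entrance-pupil diameter filled by the beam.

    A fraction > 1 means the pupil is overfilled (beam truncated by the
    aperture, full NA used); <= 1 means underfilled (lower effective NA,
    more power transmitted).
    """
    return beam.beam_diameter_mm / pupil_diameter(objective)


def classify_fill(fraction: float) -> FillMode:
    return FillMode.OVERFILL if fraction > 1.0 else FillMode.UNDERFILL


def _load_preset_table() -> pd.DataFrame:
    ref = importlib.resources.files("focalmetry") / "data" / "psf_presets.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


_PRESETS: pd.DataFrame | None = None


def preset_table() -> pd.DataFrame:
    """The shipped per-condition effective-width table (copy)."""
    global _PRESETS
    if _PRESETS is None:
        _PRESETS = _load_preset_table()
    return _PRESETS.copy()


def psf_preset(condition: ImagingCondition, *, extrapolate: bool = False) -> PSFSpec:
    """Effective bead-image widths for a fill mode and depth.

    Anchored at the measured depths (100, 200, 300 um) and linearly
    interpolated in depth between them.  Depths outside the anchor range
    raise unless ``extrapolate=True`` (sub-resolution beads could not be
    followed much past 300 um, so extrapolated values are a guess).
    """
    table = preset_table()
    sub = table[table["fill_mode"] == condition.fill_mode.value].sort_values("depth_um")
    depths = sub["depth_um"].to_numpy(dtype=float)
    d = condition.depth_um
    if (d < depths.min() or d > depths.max()) and not extrapolate:
        raise RangeError(
            f"depth {d} um outside anchor range [{depths.min():g}, {depths.max():g}] "
            "(pass extrapolate=True to allow)"
        )
    d_clamped = d
    xy = np.interp(d_clamped, depths, sub["fwhm_xy_um"].to_numpy(dtype=float))
    z = np.interp(d_clamped, depths, sub["fwhm_z_um"].to_numpy(dtype=float))
    if extrapolate and (d < depths.min() or d > depths.max()):
        # linear extrapolation from the nearest pair of anchors
        if d > depths.max():
            i0, i1 = -2, -1
        else:
            i0, i1 = 0, 1
        for col, out in (("fwhm_xy_um", "xy"), ("fwhm_z_um", "z")):
            y = sub[col].to_numpy(dtype=float)
            slope = (y[i1] - y[i0]) / (depths[i1] - depths[i0])
            val = y[i1] + slope * (d - depths[i1]) if d > depths.max() else y[i0] + slope * (d - depths[i0])
            if out == "xy":
                xy = val
            else:
                z = val
    return PSFSpec(float(xy), float(z))


def psf_model(
    condition: ImagingCondition,
    params: AberrationModelParams = AberrationModelParams(),
    *,
    extrapolate: bool = False,
) -> PSFSpec:
    """Depth preset inflated by the quadratic RI-mismatch response.

    Reduces exactly to :func:`psf_preset` at ``n == optimal_ri`` or when the
    gains are zero; for fixed depth the axial width is strictly increasing
    in ``|n - optimal_ri|`` when the axial gain is positive.
    """
    base = psf_preset(condition, extrapolate=extrapolate)
    dn2 = (condition.immersion_ri - params.optimal_ri) ** 2
    lat = 1.0 + params.lateral_mismatch_gain * condition.depth_um * dn2
    ax = 1.0 + params.axial_mismatch_gain * condition.depth_um * dn2
    return base.scaled(lat, ax)
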