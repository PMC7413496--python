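"""Background/signal estimation and Brenner-gradient contrast scoring.

The background of a stack is the pooled mean of the k lowest-intensity
pixels of every plane (k = 100 on a 21-plane stack pools 2100 pixels); the
signal is each plane's mean raw intensity minus that background.  Contrast
uses the Brenner gradient, the sum of squared intensity differences between
pixels two apart along the horizontal axis — a classical focus measure
that drops monotonically under defocus/blur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stack_io import ImageStack


@dataclass
class QualityReport:
    background: float
    per_plane_signal: np.ndarray
    mean_signal: float
    brenner_per_plane: np.ndarray
    normalized_contrast: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "plane": np.arange(len(self.per_plane_signal)),
                "signal": self.per_plane_signal,
                "brenner": self.brenner_per_plane,
            }
        )
        df.attrs["background"] = self.background
        df.attrs["mean_signal"] = self.mean_signal
        return df


def estimate_background(stack: ImageStack, k_lowest: int = 100) -> float:
    """Pooled mean of each plane's ``k_lowest`` lowest-intensity pixels.

    Every plane contributes exactly ``k_lowest`` pixels (ties broken by
    scan order), so a 21-plane stack pools 21 * 100 = 2100 pixels.
    """
    if k_lowest < 1:
        raise ValidationError("k_lowest must be >= 1")
    planes = stack.voxels
    npix = planes.shape[1] * planes.shape[2]
    if npix < k_lowest:
        raise ValidationError(f"plane has {npix} pixels < k_lowest={k_lowest}")
    flat = planes.reshape(planes.shape[0], -1)
    # stable sort keeps scan order among ties; value-wise the mean is
    # tie-order independent anyway
    lowest = np.sort(flat, axis=1, kind="stable")[:, :k_lowest]
    return float(lowest.mean())


def signal_intensity(stack: ImageStack, background: float) -> tuple[np.ndarray, float]:
    """Per-plane mean raw intensity minus background, and the overall mean.

    Negative per-plane values are possible in noise and reported as-is.
    """
    if not np.isfinite(background):
        raise ValidationError("background must be finite")
    per_plane = stack.voxels.mean(axis=(1, 2)) - background
    return per_plane, float(per_plane.mean())


def brenner_gradient(plane: np.ndarray, step: int = 2) -> float:
    """Sum over pixels of (I(x+step, y) - I(x, y))^2, horizontal axis only.

    Raw sum, no normalisation by pixel count; consumers normalise
    explicitly when comparing differently sized images.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ValidationError(f"plane must be 2D, got ndim={plane.ndim}")
    if plane.shape[1] <= step:
        raise ValidationError(f"plane width {plane.shape[1]} must exceed step {step}")
    diff = plane[:, step:] - plane[:, :-step]
    return float(np.sum(diff**2))


def brenner_per_plane(stack: ImageStack, step: int = 2) -> np.ndarray:
    return np.array([brenner_gradient(p, step) for p in stack.voxels])


def normalized_contrast(values, reference_index: int) -> np.ndarray:
    """Each condition's contrast divided by the reference condition's."""
    values = np.asarray(values, dtype=float)
    ref = values[reference_index]
    if ref == 0:
        raise ZeroDivisionError("reference contrast is zero")
    return values / ref


def quality_report(stack: ImageStack, k_lowest: int = 100, step: int = 2) -> QualityReport:
    bg = estimate_background(stack, k_lowest)
    per_plane, mean_sig = signal_intensity(stack, bg)
    brenner = brenner_per_plane(stack, step)
    return QualityReport(bg, per_plane, mean_sig, brenner)
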