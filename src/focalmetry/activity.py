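"""Spontaneous calcium-activity extraction from time-lapse movies.

Four-step procedure:

1. subtract the scalar blood-vessel background (mean over vessel pixels,
   pooled over all frames) from every pixel;
2. compute the per-pixel baseline as the minimum-intensity projection over
   time;
3. subtract the baseline to obtain the dF movie;
4. binarize each frame of dF with Otsu's threshold, take connected
   components, and keep foreground areas strictly larger than ``min_area``
   (default 20) pixels as ROIs; ROIs from different frames that share
   pixels are merged (union of pixels, earliest onset frame kept).

dF is reported in raw counts (not dF/F); per-ROI traces are the mean dF
over the ROI's pixels at each frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import ValidationError
from .stack_io import Movie


@dataclass
class ActivityROI:
    pixels: np.ndarray  # (n, 2) int (y, x), sorted by scan order
    area: int
    first_frame: int

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class ActivityTrace:
    roi: ActivityROI
    delta_f: np.ndarray  # counts per frame
    max_delta_f: float
    baseline_f: float


def subtract_vessel_background(movie: Movie, vessel_mask: np.ndarray) -> Movie:
    """Subtract the pooled mean intensity of vessel pixels; clip at 0."""
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if vessel_mask.shape != movie.frames.shape[1:]:
        raise ValidationError(
            f"vessel mask shape {vessel_mask.shape} != frame shape {movie.frames.shape[1:]}"
        )
    if not vessel_mask.any():
        raise ValidationError("vessel mask is empty")
    bg = float(movie.frames[:, vessel_mask].mean())
    return replace(movie, frames=np.clip(movie.frames - bg, 0.0, None))


def baseline_min_projection(movie: Movie) -> np.ndarray:
    """Per-pixel minimum over time (the lowest basal fluorescence)."""
    if movie.n_frames < 2:
        raise ValidationError("baseline undefined for a single-frame movie")
    return movie.frames.min(axis=0)


def delta_f(movie: Movie, baseline: np.ndarray) -> Movie:
    """Frame-wise, pixel-wise subtraction of the baseline image."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != movie.frames.shape[1:]:
        raise ValidationError(
            f"baseline shape {baseline.shape} != frame shape {movie.frames.shape[1:]}"
        )
    return replace(movie, frames=movie.frames - baseline[None])


def _frame_rois(frame, min_area, connectivity, threshold, max_foreground_fraction):
    if np.ptp(frame) == 0:
        warnings.warn("constant dF frame skipped (Otsu undefined)", stacklevel=3)
        return []
    thr = threshold_otsu(frame, nbins=256) if threshold is None else threshold
    fg = frame > thr
    if threshold is None and fg.mean() > max_foreground_fraction:
        # Otsu split a structureless (noise-only) frame; no sparse activity
        warnings.warn("dF frame without sparse foreground skipped", stacklevel=3)
        return []
    labels = label(fg, connectivity=2 if connectivity == 8 else 1)
    out = []
    for region in regionprops(labels):
        if region.area > min_area:
            out.append(np.array(sorted(map(tuple, region.coords))))
    return out


def extract_rois(
    dmovie: Movie,
    min_area: int = 20,
    connectivity: int = 8,
    *,
    per_frame: bool = True,
    threshold: float | None = None,
    max_foreground_fraction: float = 0.3,
) -> list[ActivityROI]:
    """Otsu-threshold each dF frame, keep components larger than
    ``min_area`` pixels, merge overlapping ROIs across frames.

    ``per_frame=False`` thresholds the maximum projection of dF instead (a
    single aggregate segmentation).  ``threshold`` overrides Otsu with a
    fixed value.  Frames that are constant, or whose Otsu foreground
    exceeds ``max_foreground_fraction`` of the frame (no sparse activity to
    separate), are skipped with a warning rather than an error.
    """
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")
    if not np.all(np.isfinite(dmovie.frames)):
        raise ValidationError("dF movie must be finite")

    candidates: list[tuple[int, np.ndarray]] = []  # (first_frame, pixels)
    if per_frame:
        for t in range(dmovie.n_frames):
            for pix in _frame_rois(
                dmovie.frames[t], min_area, connectivity, threshold, max_foreground_fraction
            ):
                candidates.append((t, pix))
    else:
        proj = dmovie.frames.max(axis=0)
        for pix in _frame_rois(proj, min_area, connectivity, threshold, max_foreground_fraction):
            candidates.append((0, pix))

    # merge by pixel overlap (union-find over candidate ROIs)
    parent = list(range(len(candidates)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    shape = dmovie.frames.shape[1:]
    owner = -np.ones(shape, dtype=int)
    for i, (_, pix) in enumerate(candidates):
        roots = {find(owner[y, x]) for y, x in pix if owner[y, x] >= 0}
        ri = find(i)
        for r in roots:
            parent[r] = ri
        for y, x in pix:
            owner[y, x] = ri

    groups: dict[int, list[int]] = {}
    for i in range(len(candidates)):
        groups.setdefault(find(i), []).append(i)

    rois = []
    for members in groups.values():
        first = min(candidates[i][0] for i in members)
        pix = np.array(sorted({(int(y), int(x)) for i in members for y, x in candidates[i][1]}))
        rois.append(ActivityROI(pix, len(pix), first))
    rois.sort(key=lambda r: (r.first_frame, tuple(r.pixels[0])))
    return rois


def roi_traces(
    dmovie: Movie, rois: list[ActivityROI], baseline: np.ndarray | None = None
) -> list[ActivityTrace]:
    """Mean dF over each ROI's pixels per frame, with the max recorded."""
    traces = []
    for roi in rois:
        ys, xs = roi.pixels[:, 0], roi.pixels[:, 1]
        if ys.max() >= dmovie.frames.shape[1] or xs.max() >= dmovie.frames.shape[2]:
            raise ValidationError("ROI pixels outside frame bounds")
        tr = dmovie.frames[:, ys, xs].mean(axis=1)
        base = float(baseline[ys, xs].mean()) if baseline is not None else 0.0
        traces.append(ActivityTrace(roi, tr, float(tr.max()), base))
    return traces


def condition_fold_change(traces_a: list[ActivityTrace], traces_b: list[ActivityTrace]) -> float:
    """Ratio of mean max-dF, condition a over condition b."""
    if not traces_a or not traces_b:
        raise ValidationError("both trace lists must be non-empty")
    mb = float(np.mean([t.max_delta_f for t in traces_b]))
    if mb == 0:
        raise ZeroDivisionError("condition b has zero mean max dF")
    ma = float(np.mean([t.max_delta_f for t in traces_a]))
    return ma / mb


def extract_activity(
    movie: Movie,
    vessel_mask: np.ndarray,
    min_area: int = 20,
    connectivity: int = 8,
    **roi_kwargs,
) -> tuple[list[ActivityROI], list[ActivityTrace]]:
    """Run the full four-step pipeline on one movie."""
    sub = subtract_vessel_background(movie, vessel_mask)
    base = baseline_min_projection(sub)
    dmov = delta_f(sub, base)
    rois = extract_rois(dmov, min_area=min_area, connectivity=connectivity, **roi_kwargs)
    traces = roi_traces(dmov, rois, baseline=base)
    return rois, traces


def auto_vessel_mask(movie: Movie, percentile: float = 5.0) -> np.ndarray:
    """Optional helper: lowest-percentile pixels of the temporal mean.

    Off by default in pipelines — vessel regions are normally supplied by
    the user (drawn masks or config geometry).
    """
    mean_img = movie.frames.mean(axis=0)
    thr = np.percentile(mean_img, percentile)
    return mean_img <= thr
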