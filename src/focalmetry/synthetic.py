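"""Synthetic bead stacks, neurite-like structure stacks and calcium movies.

Every generator returns the rendered data together with its ground truth so
the measurement pipeline can be validated quantitatively without animal
data.  All randomness flows through a single integer seed; a fixed seed
gives bit-identical output.

Bead rendering convention
-------------------------
The requested :class:`~focalmetry.optics.PSFSpec` is the *measured effective
width* of the bead image (bead convolved with the focal volume), matching
how the shipped preset table was produced.  Sub-resolution beads (<= 0.4 um)
are therefore rendered as anisotropic Gaussians at exactly the requested
FWHMs — no bead-size deconvolution is attempted, and the axial difference
this hides is below 0.15%.  Resolution-scale beads (e.g. 1.0 um) are
rendered by the exact uniform-ball x Gaussian convolution (disk-slice
quadrature using the noncentral-chi-square closed form for disk x 2D
Gaussian), so their rendered widths exceed the nominal focal-volume widths,
as real microbead images do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .errors import PlacementError, ValidationError
from .optics import FWHM_PER_SIGMA, ImagingCondition, PSFSpec
from .stack_io import ImageStack, Movie

#: Beads at or below this diameter are treated as sub-resolution and
#: rendered at exactly the requested effective widths.
SUB_RESOLUTION_DIAMETER_UM = 0.4


@dataclass
class BeadFieldParams:
    """Geometry, sampling and noise for one synthetic bead stack.

    Defaults mirror the acquisition the preset table came from: 0.05 um
    lateral pixels, 0.25 um z-steps, 200-nm beads.  ``fwhm_cv`` is the
    bead-to-bead scatter (multiplicative, per axis) that real preparations
    show; ``jitter_sd_um`` is a rigid per-plane lateral displacement
    standing in for heartbeat/breathing motion.
    """

    stack_shape: tuple[int, int, int] = (56, 80, 80)
    lateral_step_um: float = 0.05
    axial_step_um: float = 0.25
    n_beads: int = 1
    bead_diameter_um: float = 0.2
    min_separation_um: float = 2.0
    peak_photons: float = 200.0
    baseline_photons: float = 5.0
    read_noise_sd: float = 2.0
    jitter_sd_um: float = 0.05
    fwhm_cv: float = 0.05
    seed: int = 0
    noise: bool = True
    jitter: bool = True

    def __post_init__(self):
        if self.lateral_step_um <= 0 or self.axial_step_um <= 0:
            raise ValidationError("sampling steps must be positive")
        if self.n_beads < 0:
            raise ValidationError("n_beads must be >= 0")
        if self.min_separation_um <= self.bead_diameter_um:
            raise ValidationError("min_separation must exceed bead diameter")


@dataclass
class BeadGroundTruth:
    """True subvoxel centers and per-bead effective widths."""

    centers_um: np.ndarray  # (n, 3) physical (z, y, x) positions
    true_fwhm: list[PSFSpec]
    condition: ImagingCondition | None = None
    jitter_um: np.ndarray | None = None  # (n_planes, 2) lateral (y, x) shifts


def _margins_um(params: BeadFieldParams, psf: PSFSpec) -> tuple[float, float]:
    """Keep beads far enough from faces that measurement windows fit,
    with a cushion for peak-voxel displacement by noise and jitter."""
    ax = max(4.0, 1.2 * psf.fwhm_axial_um) + 3.0 * params.axial_step_um
    lat = max(1.5, 1.8 * psf.fwhm_lateral_um) + 6.0 * params.lateral_step_um
    return ax, lat


def _place_beads(params: BeadFieldParams, psf: PSFSpec, rng: np.random.Generator) -> np.ndarray:
    nz, ny, nx = params.stack_shape
    extent = np.array([nz * params.axial_step_um, ny * params.lateral_step_um, nx * params.lateral_step_um])
    m_ax, m_lat = _margins_um(params, psf)
    lo = np.array([m_ax, m_lat, m_lat])
    hi = extent - lo
    if np.any(hi <= lo):
        raise PlacementError(
            f"stack extent {extent} um cannot hold beads with margins {lo} um"
        )
    centers: list[np.ndarray] = []
    attempts = 0
    max_attempts = max(10 * params.n_beads, 10)
    while len(centers) < params.n_beads:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed {len(centers)}/{params.n_beads} beads after {attempts} attempts; "
                "reduce n_beads or min_separation"
            )
        attempts += 1
        c = lo + rng.random(3) * (hi - lo)
        if all(np.linalg.norm(c - p) >= params.min_separation_um for p in centers):
            centers.append(c)
    return np.array(centers).reshape(-1, 3)


def _ball_gauss_profile_factory(radius_um: float, sigma_lat: float, sigma_ax: float):
    """Exact uniform ball x anisotropic Gaussian, vectorised per z-plane.

    The ball is sliced into disks along z (Gauss-Legendre nodes); each disk
    convolved with the isotropic lateral Gaussian has the closed form
    P(|Rice| <= R) = ncx2.cdf(R^2/s^2, 2, rho^2/s^2).  The z Gaussian then
    weights the slices.  Output is normalised to 1 at the ball centre.
    """
    nodes, weights = np.polynomial.legendre.leggauss(24)
    w = nodes * radius_um
    wt = weights * radius_um
    rw2 = np.maximum(radius_um**2 - w**2, 0.0)

    def evaluate(rho2: np.ndarray, dz: np.ndarray) -> np.ndarray:
        # rho2: (ny, nx) squared lateral distance; dz: (nz,) axial offsets
        disk = stats.ncx2.cdf(rw2[:, None] / sigma_lat**2, 2, rho2.reshape(1, -1) / sigma_lat**2)
        gz = np.exp(-((dz[:, None] - w[None, :]) ** 2) / (2 * sigma_ax**2)) * wt[None, :]
        out = gz @ disk  # (nz, npix)
        peak_disk = stats.ncx2.cdf(rw2 / sigma_lat**2, 2, 0.0)
        peak = float(np.sum(np.exp(-(w**2) / (2 * sigma_ax**2)) * wt * peak_disk))
        return (out / peak).reshape(len(dz), *rho2.shape)

    return evaluate


def _render_bead(
    signal: np.ndarray,
    center_um: np.ndarray,
    psf: PSFSpec,
    params: BeadFieldParams,
    jitter_um: np.ndarray | None,
) -> None:
    """Add one bead (peak-normalised, scaled by peak_photons) into ``signal``."""
    nz, ny, nx = signal.shape
    dz_step, dl = params.axial_step_um, params.lateral_step_um
    sig_lat, sig_ax = psf.sigma_lateral_um, psf.sigma_axial_um
    cz, cy, cx = center_um

    # restrict to a window of +-5 sigma around the centre
    half_ax = 5.0 * sig_ax + params.bead_diameter_um
    half_lat = 5.0 * sig_lat + params.bead_diameter_um + 4 * params.jitter_sd_um
    z0 = max(0, int(np.floor((cz - half_ax) / dz_step)))
    z1 = min(nz, int(np.ceil((cz + half_ax) / dz_step)) + 1)
    y0 = max(0, int(np.floor((cy - half_lat) / dl)))
    y1 = min(ny, int(np.ceil((cy + half_lat) / dl)) + 1)
    x0 = max(0, int(np.floor((cx - half_lat) / dl)))
    x1 = min(nx, int(np.ceil((cx + half_lat) / dl)) + 1)

    zpos = np.arange(z0, z1) * dz_step
    ypos = np.arange(y0, y1) * dl
    xpos = np.arange(x0, x1) * dl
    jy = jitter_um[z0:z1, 0] if jitter_um is not None else np.zeros(z1 - z0)
    jx = jitter_um[z0:z1, 1] if jitter_um is not None else np.zeros(z1 - z0)

    if params.bead_diameter_um <= SUB_RESOLUTION_DIAMETER_UM:
        # effective Gaussian at exactly the requested widths; separable,
        # jitter shifts the lateral centre per plane
        gz = np.exp(-((zpos - cz) ** 2) / (2 * sig_ax**2))
        dy = ypos[None, :] - (cy + jy)[:, None]  # (nz_w, ny_w)
        dx = xpos[None, :] - (cx + jx)[:, None]
        gy = np.exp(-(dy**2) / (2 * sig_lat**2))
        gx = np.exp(-(dx**2) / (2 * sig_lat**2))
        bead = gz[:, None, None] * gy[:, :, None] * gx[:, None, :]
    else:
        profile = _ball_gauss_profile_factory(params.bead_diameter_um / 2.0, sig_lat, sig_ax)
        bead = np.empty((z1 - z0, y1 - y0, x1 - x0))
        for k in range(z1 - z0):
            ddy = ypos - (cy + jy[k])
            ddx = xpos - (cx + jx[k])
            rho2 = ddy[:, None] ** 2 + ddx[None, :] ** 2
            bead[k] = profile(rho2, np.array([zpos[k] - cz]))[0]
    signal[z0:z1, y0:y1, x0:x1] += params.peak_photons * bead


def generate_bead_stack(
    params: BeadFieldParams,
    psf: PSFSpec,
    condition: ImagingCondition | None = None,
) -> tuple[ImageStack, BeadGroundTruth]:
    """Render a bead field imaged with the given effective focal volume.

    Returns the noisy stack and the ground truth (subvoxel centers, the
    per-bead true widths after bead-to-bead scatter, per-plane jitter).
    """
    rng = np.random.default_rng(params.seed)
    centers = _place_beads(params, psf, rng)

    true_fwhm: list[PSFSpec] = []
    for _ in range(params.n_beads):
        f_lat = psf.fwhm_lateral_um * max(0.5, 1.0 + params.fwhm_cv * rng.standard_normal())
        f_ax = psf.fwhm_axial_um * max(0.5, 1.0 + params.fwhm_cv * rng.standard_normal())
        true_fwhm.append(PSFSpec(f_lat, max(f_ax, f_lat)))

    nz = params.stack_shape[0]
    jitter = None
    if params.jitter and params.jitter_sd_um > 0:
        jitter = rng.normal(0.0, params.jitter_sd_um, size=(nz, 2))

    signal = np.zeros(params.stack_shape, dtype=float)
    for c, f in zip(centers, true_fwhm):
        _render_bead(signal, c, f, params, jitter)

    expected = signal + params.baseline_photons
    if params.noise:
        counts = rng.poisson(expected).astype(float)
        counts += rng.normal(0.0, params.read_noise_sd, size=counts.shape)
        counts = np.clip(counts, 0.0, None)
    else:
        counts = expected
    stack = ImageStack(counts, params.lateral_step_um, params.axial_step_um)
    truth = BeadGroundTruth(centers, true_fwhm, condition, jitter)
    return stack, truth


# ---------------------------------------------------------------------------
# Neurite-like structure stacks (contrast-metric fixtures)


@dataclass
class StructureFieldParams:
    """Dendrite-like filaments with spine-like protrusions.

    Defaults give a 21-plane field like the cortical comparison stacks.
    """

    stack_shape: tuple[int, int, int] = (21, 128, 128)
    lateral_step_um: float = 0.25
    axial_step_um: float = 0.5
    n_filaments: int = 6
    filament_radius_um: float = 0.5
    spine_radius_um: float = 0.25
    spines_per_filament: int = 3
    peak_photons: float = 120.0
    baseline_photons: float = 10.0
    read_noise_sd: float = 2.0
    seed: int = 0
    noise: bool = True


def generate_structure_stack(
    params: StructureFieldParams, psf: PSFSpec
) -> tuple[ImageStack, ImageStack]:
    """Render filaments blurred by the focal volume; also return the
    blur-free reference at the same sampling."""
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.stack_shape
    steps = np.array([params.axial_step_um, params.lateral_step_um, params.lateral_step_um])
    extent = np.array(params.stack_shape) * steps

    # voxel-centre physical coordinates
    zz, yy, xx = np.meshgrid(
        np.arange(nz) * steps[0], np.arange(ny) * steps[1], np.arange(nx) * steps[2], indexing="ij"
    )
    coords = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)

    structure = np.zeros(nz * ny * nx, dtype=float)
    from scipy.spatial import cKDTree

    for _ in range(params.n_filaments):
        p0 = rng.random(3) * extent
        direction = rng.standard_normal(3)
        direction[0] *= 0.3  # filaments run mostly in-plane
        direction /= np.linalg.norm(direction)
        length = 0.7 * extent.max()
        npts = int(length / (0.5 * min(steps))) + 2
        t = np.linspace(-length / 2, length / 2, npts)
        pts = p0 + t[:, None] * direction
        keep = np.all((pts >= 0) & (pts <= extent), axis=1)
        pts = pts[keep]
        if len(pts) < 2:
            continue
        # spine-like protrusions: short stubs off the shaft
        spine_pts = []
        for _ in range(params.spines_per_filament):
            base = pts[rng.integers(0, len(pts))]
            nvec = rng.standard_normal(3)
            nvec -= nvec @ direction * direction
            nvec /= max(np.linalg.norm(nvec), 1e-9)
            stub = base + np.linspace(0, 1.0, 6)[:, None] * nvec
            spine_pts.append(stub)
        tree = cKDTree(pts)
        d, _ = tree.query(coords, k=1)
        structure += np.exp(-((d / params.filament_radius_um) ** 4))
        if spine_pts:
            tree_s = cKDTree(np.vstack(spine_pts))
            ds, _ = tree_s.query(coords, k=1)
            structure += 0.8 * np.exp(-((ds / params.spine_radius_um) ** 4))

    structure = structure.reshape(nz, ny, nx)
    if structure.max() > 0:
        structure = structure / structure.max()
    reference = params.baseline_photons + params.peak_photons * structure

    sig_vox = (
        psf.sigma_axial_um / params.axial_step_um,
        psf.sigma_lateral_um / params.lateral_step_um,
        psf.sigma_lateral_um / params.lateral_step_um,
    )
    blurred = ndimage.gaussian_filter(structure, sigma=sig_vox, mode="nearest")
    expected = params.baseline_photons + params.peak_photons * blurred
    if params.noise:
        counts = rng.poisson(expected).astype(float)
        counts += rng.normal(0.0, params.read_noise_sd, size=counts.shape)
        counts = np.clip(counts, 0.0, None)
    else:
        counts = expected
    stack = ImageStack(counts, params.lateral_step_um, params.axial_step_um)
    ref = ImageStack(reference, params.lateral_step_um, params.axial_step_um)
    return stack, ref


# ---------------------------------------------------------------------------
# Calcium movies


@dataclass
class CalciumEvent:
    cell: int
    pixels: np.ndarray  # (n, 2) int (y, x)
    onset_frame: int
    amplitude_counts: float
    is_distractor: bool

    @property
    def area(self) -> int:
        return len(self.pixels)


@dataclass
class CalciumGroundTruth:
    events: list[CalciumEvent]
    vessel_mask: np.ndarray  # bool (y, x)
    cell_masks: np.ndarray  # int label image, 0 = background


@dataclass
class CalciumMovieParams:
    """Astrocyte-like spontaneous-activity movie over a dark-vessel field.

    ``event_rate`` is events per cell per 100 frames.  True events occupy a
    contiguous region of > ``min_true_area - 1`` pixels; distractors are
    kept at or below 20 pixels so the downstream area filter is exercised.
    """

    frame_shape: tuple[int, int] = (96, 96)
    n_frames: int = 60
    frame_interval_s: float = 1.0
    lateral_step_um: float = 0.5
    n_cells: int = 6
    event_rate: float = 8.0
    event_amplitude: float = 2.0  # dF/F relative to cell baseline
    true_area_range: tuple[int, int] = (25, 60)
    distractor_area_range: tuple[int, int] = (10, 20)
    n_distractors: int = 2
    decay_tau_frames: float = 3.0
    vessel_fraction: float = 0.15
    baseline_f: float = 50.0
    tissue_background: float = 10.0
    vessel_background: float = 2.0
    noise_sd: float = 2.0
    seed: int = 0
    noise: bool = True

    def __post_init__(self):
        if self.event_rate < 0 or self.event_amplitude < 0:
            raise ValidationError("event rate and amplitude must be >= 0")
        if not 0 <= self.vessel_fraction < 1:
            raise ValidationError("vessel_fraction must be in [0, 1)")


def _grow_region(mask: np.ndarray, seed_yx: tuple[int, int], area: int, rng) -> np.ndarray:
    """Grow a connected region of exactly ``area`` pixels inside ``mask``."""
    ny, nx = mask.shape
    chosen = [seed_yx]
    in_region = {seed_yx}
    frontier = [seed_yx]
    while len(chosen) < area:
        candidates = []
        for (y, x) in frontier:
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                p = (y + dy, x + dx)
                if 0 <= p[0] < ny and 0 <= p[1] < nx and mask[p] and p not in in_region:
                    candidates.append(p)
        candidates = sorted(set(candidates))
        if not candidates:
            break
        take = min(len(candidates), area - len(chosen))
        idx = rng.permutation(len(candidates))[:take]
        for i in sorted(idx):
            p = candidates[i]
            chosen.append(p)
            in_region.add(p)
        frontier = [candidates[i] for i in sorted(idx)]
    return np.array(chosen[:area])


def generate_calcium_movie(params: CalciumMovieParams) -> tuple[Movie, CalciumGroundTruth]:
    """Render static cells, a dark vessel band and transient events.

    Event time course: one-frame rise to the full amplitude, exponential
    decay with ``decay_tau_frames``.  Event pixel sets never overlap the
    vessel; distractor events reuse the same kinetics at <= 20 pixels.
    """
    rng = np.random.default_rng(params.seed)
    ny, nx = params.frame_shape

    # vessel: a vertical band with a sinusoidal wiggle
    width = max(1, int(round(params.vessel_fraction * nx)))
    x0 = int(0.1 * nx)
    yy, xx = np.mgrid[0:ny, 0:nx]
    wiggle = (0.05 * nx * np.sin(2 * np.pi * yy / ny)).astype(int)
    vessel = (xx >= x0 + wiggle) & (xx < x0 + wiggle + width)

    # cells: disk-shaped, disjoint, off the vessel
    cell_masks = np.zeros((ny, nx), dtype=int)
    radius = 8
    placed = 0
    attempts = 0
    while placed < params.n_cells and attempts < 50 * max(params.n_cells, 1):
        attempts += 1
        cy = rng.integers(radius + 1, ny - radius - 1)
        cx = rng.integers(radius + 1, nx - radius - 1)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        # a 2-px halo keeps cells disconnected under 8-connectivity
        halo = (yy - cy) ** 2 + (xx - cx) ** 2 <= (radius + 2) ** 2
        if np.any(vessel[disk]) or np.any(cell_masks[halo] > 0):
            continue
        placed += 1
        cell_masks[disk] = placed
    if placed < params.n_cells:
        raise PlacementError(f"placed {placed}/{params.n_cells} cells; frame too crowded")

    base = np.full((ny, nx), params.tissue_background, dtype=float)
    base[cell_masks > 0] = params.baseline_f
    base[vessel] = params.vessel_background

    movie = np.repeat(base[None], params.n_frames, axis=0)

    events: list[CalciumEvent] = []
    expected_per_cell = params.event_rate * params.n_frames / 100.0
    for cell in range(1, placed + 1):
        n_ev = rng.poisson(expected_per_cell)
        mask = cell_masks == cell
        for _ in range(n_ev):
            area = int(rng.integers(params.true_area_range[0], params.true_area_range[1] + 1))
            ys, xs = np.nonzero(mask)
            j = rng.integers(0, len(ys))
            pixels = _grow_region(mask, (int(ys[j]), int(xs[j])), area, rng)
            onset = int(rng.integers(0, params.n_frames))
            amp = params.event_amplitude * params.baseline_f
            events.append(CalciumEvent(cell, pixels, onset, amp, False))

    # sub-threshold distractors in the tissue between cells, so they can
    # never merge with a true event's pixel set
    tissue = (cell_masks == 0) & ~vessel
    tissue[:2, :] = tissue[-2:, :] = False
    tissue[:, :2] = tissue[:, -2:] = False
    for _ in range(params.n_distractors):
        area = int(rng.integers(params.distractor_area_range[0], params.distractor_area_range[1] + 1))
        mask = tissue
        ys, xs = np.nonzero(mask)
        j = rng.integers(0, len(ys))
        pixels = _grow_region(mask, (int(ys[j]), int(xs[j])), area, rng)
        onset = int(rng.integers(0, params.n_frames))
        amp = params.event_amplitude * params.baseline_f
        events.append(CalciumEvent(0, pixels, onset, amp, True))

    t = np.arange(params.n_frames)
    for ev in events:
        kin = np.zeros(params.n_frames)
        after = t >= ev.onset_frame
        kin[after] = np.exp(-(t[after] - ev.onset_frame) / params.decay_tau_frames)
        for (y, x) in ev.pixels:
            movie[:, y, x] += ev.amplitude_counts * kin

    if params.noise:
        movie = movie + rng.normal(0.0, params.noise_sd, size=movie.shape)
        movie = np.clip(movie, 0.0, None)

    out = Movie(movie, params.frame_interval_s, params.lateral_step_um)
    return out, CalciumGroundTruth(events, vessel, cell_masks)
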