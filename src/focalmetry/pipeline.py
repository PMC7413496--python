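"""End-to-end runs: simulate -> measure -> compare -> test.

Each run consumes a validated :class:`~focalmetry.stack_io.RunConfig`,
derives all randomness from its single seed (split deterministically per
stage and condition), and optionally writes TSV outputs plus a manifest
recording the seed, package version and a hash of every file produced.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import condition_fold_change, extract_activity
from .errors import EmptyResultError, ValidationError
from .group_stats import (
    PairwiseTestResult,
    bonferroni,
    dscf_all_pairs,
    friedman_test,
    results_table,
    welch_t_test,
)
from .metrology import (
    BeadDetection,
    BeadMeasurement,
    ConditionSummary,
    FitMode,
    detect_beads,
    measure_bead,
    refine_peak,
    summarize_condition,
    summary_table,
)
from .optics import AberrationModelParams, ImagingCondition, PSFSpec, psf_model, psf_preset
from .quality import normalized_contrast, quality_report
from .stack_io import RunConfig
from .synthetic import (
    BeadFieldParams,
    CalciumMovieParams,
    StructureFieldParams,
    generate_bead_stack,
    generate_calcium_movie,
    generate_structure_stack,
)


@dataclass
class RunManifest:
    seed: int
    version: str
    config: dict
    outputs: dict = field(default_factory=dict)
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def record(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[name] = {"path": str(path), "sha256": digest}

    def write(self, path: Path) -> None:
        self.finished = time.time()
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def measure_bead_stacks(
    stacks,
    mode: FitMode = FitMode.FREE_CENTER,
    min_separation_um: float = 2.0,
    axial_window_um: float | None = None,
    psf: PSFSpec | None = None,
) -> list[BeadMeasurement]:
    """Detect and measure every isolated bead across a list of stacks.

    Detection runs on a lightly smoothed copy (1-voxel Gaussian) so the
    chosen peak voxel is not the noise-selected maximum — taking the
    profile through the raw argmax inflates the centre sample and biases
    fitted widths low.  Measurement always uses the raw voxels.
    """
    from scipy import ndimage as ndi

    from .stack_io import ImageStack

    measurements: list[BeadMeasurement] = []
    for stack in stacks:
        smoothed = ndi.gaussian_filter(stack.voxels, sigma=1.0, mode="nearest")
        sm = ImageStack(smoothed, stack.lateral_step_um, stack.axial_step_um)
        bg = float(np.median(smoothed))
        floor = bg + 0.25 * (float(smoothed.max()) - bg)
        window = 4.0 if axial_window_um is None else axial_window_um
        margins = (window, 1.5)
        # the local-max neighbourhood must cover one (elongated) bead image
        peak_window = None
        if psf is not None:
            peak_window = (0.75 * psf.fwhm_axial_um, max(0.5, 1.5 * psf.fwhm_lateral_um))
        detections = detect_beads(sm, floor, min_separation_um, margins, peak_window)
        for det in detections:
            if det.isolation_ok:
                refined = BeadDetection(
                    refine_peak(stack, det.peak_voxel), det.peak_intensity, True
                )
                measurements.append(
                    measure_bead(stack, refined, mode, axial_window_um=axial_window_um)
                )
    return measurements


def simulation_truth(
    condition: ImagingCondition,
    reference_ri: float = 1.33,
    aberration: AberrationModelParams | None = None,
    extrapolate: bool = False,
) -> PSFSpec:
    """Ground-truth effective widths used when simulating a condition.

    The preset table holds the widths measured at the reference immersion
    RI, so the RI response of the quadratic mismatch model is applied as a
    ratio relative to that reference: at ``n == reference_ri`` the preset
    is returned exactly, and moving the RI toward the model's optimum
    contracts the simulated focal volume, as adjusting the immersion
    liquid does in practice.
    """
    ab = aberration or AberrationModelParams()
    ref = ImagingCondition(reference_ri, condition.fill_mode, condition.depth_um)
    m = psf_model(condition, ab, extrapolate=extrapolate)
    m_ref = psf_model(ref, ab, extrapolate=extrapolate)
    preset = psf_preset(condition, extrapolate=extrapolate)
    return preset.scaled(
        m.fwhm_lateral_um / m_ref.fwhm_lateral_um, m.fwhm_axial_um / m_ref.fwhm_axial_um
    )


def simulate_condition_measurements(
    condition: ImagingCondition,
    n_beads: int,
    seed: int,
    mode: FitMode = FitMode.FREE_CENTER,
    params: BeadFieldParams | None = None,
    psf: PSFSpec | None = None,
    reference_ri: float = 1.33,
    aberration: AberrationModelParams | None = None,
    extrapolate: bool = False,
) -> list[BeadMeasurement]:
    """Generate ``n_beads`` single-bead stacks for a condition and measure them.

    One stack per bead mirrors how independent beads are sampled in a real
    preparation and keeps each fit isolated.  ``psf`` overrides the
    default ground truth from :func:`simulation_truth`.
    """
    if psf is None:
        psf = simulation_truth(condition, reference_ri, aberration, extrapolate)
    base = params or BeadFieldParams()
    # fold the condition into the entropy so different conditions draw
    # independent bead populations even under the same top-level seed
    entropy = (
        int(seed),
        int(round(condition.depth_um * 1000)),
        int(round(condition.immersion_ri * 1000)),
        0 if condition.fill_mode.value == "overfill" else 1,
    )
    ss = np.random.SeedSequence(entropy)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_beads)]
    stacks = []
    for s in seeds:
        p = BeadFieldParams(**{**base.__dict__, "n_beads": 1, "seed": s})
        stack, _ = generate_bead_stack(p, psf, condition)
        stacks.append(stack)
    return measure_bead_stacks(
        stacks, mode, axial_window_um=max(4.0, 1.1 * psf.fwhm_axial_um), psf=psf
    )


@dataclass
class PSFEvaluationResult:
    summaries: list[ConditionSummary]
    measurements: dict[int, list[BeadMeasurement]]  # by condition index
    welch: list[PairwiseTestResult]
    manifest: RunManifest | None = None

    def summary_frame(self) -> pd.DataFrame:
        return summary_table(self.summaries)


def run_psf_evaluation(config: RunConfig, out_dir=None) -> PSFEvaluationResult:
    """Per-condition bead simulation, FWHM measurement and Welch testing.

    Within each (fill_mode, depth) group, every RI is tested against the
    reference RI (default 1.33) on axial FWHMs, Bonferroni-corrected over
    the number of comparisons in the group.
    """
    if not config.conditions:
        raise ValidationError("config lists no conditions")
    if not config.simulate:
        raise ValidationError("only simulate=true runs are supported without input stacks")
    mode = FitMode(config.mode)
    seeds = _spawn_seeds(config.seed, len(config.conditions))
    summaries: list[ConditionSummary] = []
    measurements: dict[int, list[BeadMeasurement]] = {}
    for i, cc in enumerate(config.conditions):
        cond = ImagingCondition(cc.immersion_ri, cc.fill_mode, cc.depth_um)
        ms = simulate_condition_measurements(
            cond, cc.n_beads, seeds[i], mode,
            reference_ri=config.reference_ri, extrapolate=config.extrapolate,
        )
        if not ms:
            continue
        measurements[i] = ms
        summaries.append(summarize_condition(ms, cond))
    if not summaries:
        raise EmptyResultError("no beads measured in any condition")

    # Welch vs the reference RI within each (fill_mode, depth) group
    welch: list[PairwiseTestResult] = []
    groups: dict[tuple, dict[float, int]] = {}
    for i, cc in enumerate(config.conditions):
        if i in measurements:
            groups.setdefault((cc.fill_mode, cc.depth_um), {})[cc.immersion_ri] = i
    for key, by_ri in groups.items():
        if config.reference_ri not in by_ri or len(by_ri) < 2:
            continue
        ref = [m.fwhm_z_um for m in measurements[by_ri[config.reference_ri]]]
        pairs = [(ri, idx) for ri, idx in sorted(by_ri.items()) if ri != config.reference_ri]
        results = []
        for ri, idx in pairs:
            other = [m.fwhm_z_um for m in measurements[idx]]
            r = welch_t_test(other, ref)
            results.append((ri, idx, r))
        adj = bonferroni([r.p_value for _, _, r in results], len(results))
        for (ri, idx, r), ap in zip(results, adj):
            welch.append(
                PairwiseTestResult(
                    r.statistic, r.p_value, r.degrees_of_freedom, float(ap),
                    method="welch_bonferroni", pair=(by_ri[config.reference_ri], idx),
                )
            )

    manifest = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = RunManifest(config.seed, __version__, config.to_dict())
        sp = out_dir / "psf_summary.tsv"
        summary_table(summaries).to_csv(sp, sep="\t", index=False)
        manifest.record("psf_summary", sp)
        wp = out_dir / "psf_welch.tsv"
        results_table(welch).to_csv(wp, sep="\t", index=False)
        manifest.record("psf_welch", wp)
        manifest.write(out_dir / "manifest.json")
    return PSFEvaluationResult(summaries, measurements, welch, manifest)


@dataclass
class QualityComparisonResult:
    reports: list
    friedman_brenner: PairwiseTestResult
    friedman_signal: PairwiseTestResult
    dscf_brenner: list[PairwiseTestResult]
    normalized_contrast: np.ndarray
    manifest: RunManifest | None = None


def run_quality_comparison(config: RunConfig, out_dir=None) -> QualityComparisonResult:
    """Image-quality comparison of >= 2 conditions over the same structure.

    All conditions share one structure geometry (same structure seed) and
    differ in their focal volume, excitation efficiency and noise stream.
    Because two-photon excitation efficiency falls as the focal volume
    grows, each condition's structure brightness is scaled by the ratio of
    the reference condition's effective focal volume (lateral^2 x axial) to
    its own — a tighter focus images the same structure brighter and
    sharper.  Per-plane Brenner gradients feed a Friedman test (planes as
    blocks, conditions as treatments) with DSCF all-pairs post-hoc;
    contrasts are normalised to the configured reference condition.
    """
    if len(config.conditions) < 2:
        raise ValidationError("quality comparison needs >= 2 conditions")
    structure_seed, *noise_seeds = _spawn_seeds(config.seed, len(config.conditions) + 1)
    psfs = []
    for cc in config.conditions:
        cond = ImagingCondition(cc.immersion_ri, cc.fill_mode, cc.depth_um)
        psfs.append(simulation_truth(cond, config.reference_ri, extrapolate=config.extrapolate))
    volumes = np.array([p.fwhm_lateral_um**2 * p.fwhm_axial_um for p in psfs])
    brightness = volumes[config.reference_index] / volumes
    reports = []
    for i, cc in enumerate(config.conditions):
        psf = psfs[i]
        base = StructureFieldParams()
        params = StructureFieldParams(
            stack_shape=(config.n_planes, 128, 128), seed=structure_seed, noise=False,
            peak_photons=base.peak_photons * float(brightness[i]),
        )
        # shared geometry: the structure seed fixes filament placement; the
        # per-condition noise stream is drawn from a derived generator
        stack, _ = generate_structure_stack(params, psf)
        rng = np.random.default_rng(noise_seeds[i])
        noisy = np.clip(
            rng.poisson(stack.voxels).astype(float)
            + rng.normal(0, params.read_noise_sd, stack.voxels.shape),
            0, None,
        )
        stack.voxels = noisy
        reports.append(quality_report(stack, k_lowest=config.k_lowest))
    n_planes = {len(r.brenner_per_plane) for r in reports}
    if len(n_planes) != 1:
        raise ValidationError("conditions have mismatched plane counts")

    brenner = np.column_stack([r.brenner_per_plane for r in reports])
    signal = np.column_stack([r.per_plane_signal for r in reports])
    fr_b = friedman_test(brenner)
    fr_s = friedman_test(signal)
    dscf = dscf_all_pairs([brenner[:, j] for j in range(brenner.shape[1])])
    contrast = normalized_contrast(brenner.mean(axis=0), config.reference_index)
    for i, r in enumerate(reports):
        r.normalized_contrast = float(contrast[i])

    manifest = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = RunManifest(config.seed, __version__, config.to_dict())
        rows = []
        for i, r in enumerate(reports):
            for p in range(len(r.per_plane_signal)):
                rows.append(
                    {
                        "condition": i,
                        "plane": p,
                        "signal": r.per_plane_signal[p],
                        "brenner": r.brenner_per_plane[p],
                    }
                )
        qp = out_dir / "quality_per_plane.tsv"
        pd.DataFrame(rows).to_csv(qp, sep="\t", index=False)
        manifest.record("quality_per_plane", qp)
        sp = out_dir / "quality_stats.tsv"
        results_table([fr_b, fr_s] + dscf).to_csv(sp, sep="\t", index=False)
        manifest.record("quality_stats", sp)
        manifest.write(out_dir / "manifest.json")
    return QualityComparisonResult(reports, fr_b, fr_s, dscf, contrast, manifest)


@dataclass
class ActivityAnalysisResult:
    rois_a: list
    rois_b: list
    traces_a: list
    traces_b: list
    fold_change: float
    manifest: RunManifest | None = None


def run_activity_analysis(config: RunConfig, out_dir=None) -> ActivityAnalysisResult:
    """Calcium-activity comparison of two conditions a and b.

    Both movies share the same cell/vessel geometry and event schedule
    (same seed) and differ only in event amplitude, so ROI counts should
    match and the dF fold change should track the amplitude ratio.
    """
    (seed,) = _spawn_seeds(config.seed, 1)
    pa = CalciumMovieParams(seed=seed, event_amplitude=config.amplitude_a)
    pb = CalciumMovieParams(seed=seed, event_amplitude=config.amplitude_b)
    movie_a, truth_a = generate_calcium_movie(pa)
    movie_b, truth_b = generate_calcium_movie(pb)
    rois_a, traces_a = extract_activity(
        movie_a, truth_a.vessel_mask, config.min_area, config.connectivity
    )
    rois_b, traces_b = extract_activity(
        movie_b, truth_b.vessel_mask, config.min_area, config.connectivity
    )
    fold = condition_fold_change(traces_a, traces_b)

    manifest = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = RunManifest(config.seed, __version__, config.to_dict())
        rows = []
        for label, rois in (("a", rois_a), ("b", rois_b)):
            for i, roi in enumerate(rois):
                ys, xs = roi.pixels[:, 0], roi.pixels[:, 1]
                rows.append(
                    {
                        "condition": label,
                        "roi": i,
                        "area": roi.area,
                        "first_frame": roi.first_frame,
                        "bbox": f"{ys.min()},{xs.min()},{ys.max()},{xs.max()}",
                    }
                )
        rp = out_dir / "activity_rois.tsv"
        pd.DataFrame(rows).to_csv(rp, sep="\t", index=False)
        manifest.record("activity_rois", rp)
        tp = out_dir / "activity_traces.tsv"
        tr_rows = []
        for label, traces in (("a", traces_a), ("b", traces_b)):
            for i, t in enumerate(traces):
                for f, dfv in enumerate(t.delta_f):
                    tr_rows.append({"condition": label, "roi": i, "frame": f, "delta_f": dfv})
        pd.DataFrame(tr_rows).to_csv(tp, sep="\t", index=False)
        manifest.record("activity_traces", tp)
        manifest.write(out_dir / "manifest.json")
    return ActivityAnalysisResult(rois_a, rois_b, traces_a, traces_b, fold, manifest)
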