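"""Spontaneous calcium-activity extraction and condition comparison.

Generates two movies with identical cell geometry and event schedule but a
4:1 transient-amplitude ratio, runs the vessel-background / minimum-
projection / Otsu / area-filter pipeline on both, and reports the dF fold
change between conditions.
"""

import warnings

from focalmetry import CalciumMovieParams, condition_fold_change, extract_activity, generate_calcium_movie

traces = {}
for label, amplitude in (("enhanced", 4.0), ("standard", 1.0)):
    params = CalciumMovieParams(seed=7, event_amplitude=amplitude)
    movie, truth = generate_calcium_movie(params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # activity-free frames are skipped
        rois, tr = extract_activity(movie, truth.vessel_mask)
    traces[label] = tr
    n_true = sum(not e.is_distractor for e in truth.events)
    n_dis = sum(e.is_distractor for e in truth.events)
    print(
        f"{label:>9}: {len(rois)} ROIs from {n_true} planted events "
        f"({n_dis} sub-threshold distractors planted), "
        f"mean max dF = {sum(t.max_delta_f for t in tr) / len(tr):.1f} counts"
    )

fold = condition_fold_change(traces["enhanced"], traces["standard"])
print(f"dF fold change (enhanced / standard): {fold:.2f}")
# The fold change tracks the 4:1 amplitude ratio; the small deficit below
# 4 is the noise pedestal that minimum-projection baselines add to both
# conditions equally.
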