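"""Entrance-pupil geometry and beam fill classification.

The effective NA of a laser-scanning objective depends on how much of its
entrance pupil the excitation beam covers.  This computes the pupil
diameter of a 25x / NA 1.05 objective (180 mm tube lens) and classifies
two beam diameters.
"""

from focalmetry import BeamConfig, ObjectiveSpec, classify_fill, fill_fraction, pupil_diameter

objective = ObjectiveSpec(magnification=25, numerical_aperture=1.05)
print(f"entrance-pupil diameter: {pupil_diameter(objective):.2f} mm")

for beam_mm in (17.4, 10.8):
    beam = BeamConfig(beam_mm, "overfill" if beam_mm > 15 else "underfill")
    frac = fill_fraction(beam, objective)
    print(f"beam {beam_mm:5.1f} mm -> {100 * frac:6.1f}% of the pupil ({classify_fill(frac).value})")

# A fraction above 100% (overfill) uses the objective's full NA; below
# 100% (underfill) trades resolution for transmitted laser power.
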