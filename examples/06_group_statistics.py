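"""The statistics toolkit: Welch/Bonferroni and Friedman + DSCF.

Compares axial FWHM samples between two conditions with Welch's t-test,
adjusts a family of such tests with Bonferroni, and runs the Friedman +
DSCF machinery on a small block design.
"""

import numpy as np

from focalmetry import bonferroni, dscf_all_pairs, friedman_test, welch_t_test

rng = np.random.default_rng(0)
shallow = rng.normal(2.16, 0.19, 15)  # axial FWHMs, 100 um depth
deep = rng.normal(4.14, 0.63, 11)  # axial FWHMs, 300 um depth
res = welch_t_test(deep, shallow)
print(f"Welch: t = {res.statistic:.2f}, df = {res.degrees_of_freedom:.1f}, p = {res.p_value:.2g}")

family = [res.p_value, 0.03, 0.2]
print("Bonferroni-adjusted:", np.round(bonferroni(family), 4))

# block design: 21 planes (blocks) x 3 conditions (treatments)
blocks = rng.normal(0, 1, (21, 3)) + np.array([0.0, 0.6, 1.2])
fr = friedman_test(blocks)
print(f"Friedman: chi2 = {fr.statistic:.2f}, df = {fr.degrees_of_freedom:.0f}, p = {fr.p_value:.2g}")
for r in dscf_all_pairs([blocks[:, j] for j in range(3)]):
    print(f"  DSCF pair {r.pair}: W* = {r.statistic:.2f}, p = {r.p_value:.3g}")
# The Friedman test asks whether any condition differs across the planes;
# DSCF then locates which pairs differ without assuming normality.
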