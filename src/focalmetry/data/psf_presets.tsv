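# Measured effective bead-image widths (mean FWHM, 200-nm beads, in vivo,
# water immersion n=1.33) per pupil-fill mode and imaging depth.
# Columns: fill_mode	depth_um	fwhm_xy_um	fwhm_z_um
# version: 1
fill_mode	depth_um	fwhm_xy_um	fwhm_z_um
overfill	100	0.41	2.16
overfill	200	0.40	2.33
overfill	300	0.53	4.14
underfill	100	0.44	2.68
underfill	200	0.50	2.87
underfill	300	0.58	4.51
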