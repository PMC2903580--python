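"""Estimate the full 3D strain tensor from a single long-axis slice.

One slice of 3D displacement cannot constrain the out-of-plane column of
the deformation gradient directly; tissue incompressibility, the
forward/inverse tensor combination and the torsion pre-estimate recover
it. The errors against the analytic truth show how well: every tensor
element is accurate to better than 0.03 except the in-plane shear F21,
whose fast transmural variation is attenuated by the smoothing area.
"""

from lvstrain import run_table_1_2

rep_f, rep_e = run_table_1_2(area_mm2=25.0)

print("deformation-gradient errors (local frame, 25 mm^2 smoothing area):")
print(rep_f.table.round(4).to_string(index=False))
print()
print("RCL strain errors:")
print(rep_e.table.round(4).to_string(index=False))
print()
print("Reading the tables: 'variation_magnitude' is the RMS departure of the")
print("analytic element from the identity tensor, 'rms_error' the RMS of the")
print("estimate minus truth, and their ratio the relative error. E_RC has no")
print("relative error (NaN) because its analytic value is identically zero.")
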