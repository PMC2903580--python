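"""How displacement noise and the smoothing area trade off.

Gaussian noise (SD expressed relative to the peak displacement) is added
to the phantom slice, and the relative RMS strain errors are averaged
over independent noise seeds. A small smoothing area tracks sharp
strain gradients better when the data are clean, but a larger area wins
once the noise dominates -- and the out-of-plane strain E_CC degrades
fastest, reflecting the single-slice singularity.
"""

from lvstrain import run_table_3

table = run_table_3(areas=(25.0, 15.0), sigmas=(0.0, 0.01, 0.02),
                    n_seeds=3, seed=7)
pivot = table.pivot_table(index=["area_mm2", "sigma_rel"],
                          columns="component", values="relative_rms_pct")
print("relative RMS strain error (%) by smoothing area and noise level:")
print(pivot.round(1).to_string())
print()
print("Errors grow with noise for every component; compare the 15 and")
print("25 mm^2 rows at sigma = 0.02 to see the larger area take over.")
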