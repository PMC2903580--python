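"""From wrapped phase images to smoothed displacement.

Displacement-encoded MRI stores motion as phase; this example builds a
synthetic wrapped-phase stack, unwraps it by region growing, converts it
to millimetres with the encoding sensitivity k_e, and applies the plus-
median and temporal-Fourier smoothing used before differentiation.
"""

import numpy as np

from lvstrain.preprocess import (
    PhaseField,
    median_filter_plus,
    phase_to_displacement,
    smooth_displacement_time,
    unwrap_phase,
)

# a displacement ramp reaching 12 mm, encoded at k_e = 0.8 cycles/cm:
# the true phase exceeds pi and wraps
ke = np.array([0.80, 0.80, 0.93])
nt, nr, nc = 13, 20, 20
times = 30.0 * np.arange(nt)
u_true_mm = np.zeros((nt, nr, nc, 3))
ramp = np.linspace(0, 12.0, nc)  # mm along the row direction
wave = np.sin(np.pi * times / 390.0) ** 2
u_true_mm[..., 0] = wave[:, None, None] * ramp

phase_true = 2 * np.pi * ke * (u_true_mm / 10.0)  # mm -> cm
wrapped = np.angle(np.exp(1j * phase_true))
print(f"true phase range: [{phase_true.min():.2f}, {phase_true.max():.2f}] rad"
      f" -> wrapped into (-pi, pi]")

pf = PhaseField(phase=wrapped, ke=ke, mask=np.ones((nr, nc), bool),
                spacing=1.5, times=times)
field = phase_to_displacement(unwrap_phase(pf))
err = np.abs(field.displacements - u_true_mm).max()
print(f"recovered displacement, max error vs truth: {err:.2e} mm")

field.displacements += 0.05 * np.random.default_rng(0).standard_normal(
    field.displacements.shape
)
smoothed = smooth_displacement_time(median_filter_plus(field), order=5)
resid = np.abs(smoothed.displacements - u_true_mm).max()
print(f"after plus-median + 5th-order temporal Fourier smoothing of noisy "
      f"data: max deviation {resid:.3f} mm")
print("(the temporal basis keeps frequencies up to five times the heart "
      "rate, enough for physiological motion)")
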