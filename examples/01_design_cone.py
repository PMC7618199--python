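"""Design the in vivo cone readout and verify it honors the gradient limits.

Builds the two-stage cone (60 deg half-angle, stage separation m=0.5,
curvature power n=3) for 1.13 mm isotropic resolution, solves the twist
scaling A so the time-optimal traversal lasts 10 ms under conservative
hardware limits, and prints the realized waveform figures.
"""

from dataclasses import replace

import numpy as np

from conetraj import (
    ConeParams,
    HardwareLimits,
    base_cone,
    resample_adc,
    solve_twist_scaling,
    stage1_cone_angle,
    time_optimal_waveform,
)

limits = HardwareLimits(g_max=11.64, s_max=61.54, raster_time=10.0)
cone = ConeParams(theta=60.0, m=0.5, n=3.0, A=0.0,
                  k_max=1.0 / (2.0 * 1.13), readout_duration=10.0)

print(f"nominal resolution : {cone.nominal_resolution_mm:.2f} mm "
      f"(k_max = {cone.k_max:.4f} 1/mm)")
print(f"stage-1 cone angle : {stage1_cone_angle(cone):.2f} deg "
      f"(opens to {cone.theta:.0f} deg at the trajectory end)")

A = solve_twist_scaling(cone, limits)
curve = base_cone(replace(cone, A=A), 4000)
wave = time_optimal_waveform(curve, limits)
k_adc, t_adc = resample_adc(wave, dwell=2.0)

print(f"twist scaling A    : {A:.2f} rad "
      f"({A / (2 * np.pi):.1f} azimuthal turns over the readout)")
print(f"readout duration   : {wave.duration_ms:.2f} ms (target 10 ms)")
print(f"max |g|            : {wave.max_gradient():.2f} mT/m  (limit {limits.g_max})")
print(f"max slew           : {wave.max_slew():.2f} T/m/s (limit {limits.s_max})")
print(f"ADC samples        : {len(t_adc)} at 2 us dwell, "
      f"endpoint |k| = {np.linalg.norm(k_adc[-1]):.4f} 1/mm")
print()
print("The waveform rides the slew limit through the twisted central region")
print("and the amplitude limit further out; both stay inside the protocol")
print("limits, so the trajectory is playable as designed.")
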