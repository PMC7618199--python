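"""Simulate a dynamic multi-coil acquisition and reconstruct it two ways.

Generates a dynamic vessel/perfusion series, acquires it shot by shot along
a scheduled cone trajectory, then reconstructs angiographic (full k-space,
short window) and perfusion (central k-space, long window) frames from the
SAME raw data — first with the density-compensated adjoint, then with
locally-low-rank (LLR) regularization.  Scales are reduced (16^3 grid,
2 repeats) so the example runs in about a minute.
"""

import numpy as np

from conetraj import (
    ConeParams,
    DigitalPhantom,
    LLRConfig,
    ProtocolParams,
    base_cone,
    build_schedule,
    dual_reconstruct,
    make_coil_model,
    make_dynamic_series,
    make_vessel_phantom,
    simulate_acquisition,
)

n = 16
protocol = ProtocolParams(tr=14.7, train_duration=2116.8, readout_time=10.0)
schedule = build_schedule(protocol, n_repeats=2, seed=5)

cone = ConeParams(theta=60.0, m=0.5, n=3.0, A=8.0, k_max=0.5, readout_duration=1.0)
base_samples = base_cone(cone, 400).points[::8]

vessel = make_vessel_phantom(32, 1.0, seed=2)
vol = vessel.volume[8:24, 8:24, 8:24]
series = make_dynamic_series(
    (DigitalPhantom(vol, 1.0, vol != 0, "vessel"), None), n_frames=12
)
coil = make_coil_model(n, n_coils=4, seed=1)

frame_of_shot = (schedule.shot_start_times() // 176.4).astype(int)
data = np.empty((4, schedule.n_shots, base_samples.shape[0]), complex)
for s in range(schedule.n_shots):
    coords = base_samples @ schedule.rotations[s].T
    ph = DigitalPhantom(series[frame_of_shot[s]], 1.0, vol != 0, "vessel")
    data[:, s, :] = simulate_acquisition(ph, coil, coords, noise_sigma=0.05, seed=s)
print(f"simulated {schedule.n_shots} shots x {base_samples.shape[0]} samples x 4 coils")

angio, perf = dual_reconstruct(
    data, schedule, base_samples, coil.sensitivities, 1.0,
    angio_window=176.4, perf_window=352.8, perf_radius=1.0 / 3.0,
)
print(f"adjoint: {angio.shape[0]} angio frames at {angio.shape[1]}^3, "
      f"{perf.shape[0]} perfusion frames at {perf.shape[1]}^3")

angio_llr, _ = dual_reconstruct(
    data, schedule, base_samples, coil.sensitivities, 1.0,
    angio_window=176.4, perf_window=352.8, perf_radius=1.0 / 3.0,
    mode="llr", llr_config=LLRConfig(lam=0.1, patch=5, max_iter=40),
)

bg = ~(vol != 0)
def bg_power(x):
    mag = np.abs(x) / np.abs(x).max()
    return np.mean(mag[:, bg] ** 2)

print(f"background power, adjoint: {bg_power(angio):.2e}")
print(f"background power, LLR    : {bg_power(angio_llr):.2e}")
print()
print("The LLR reconstruction exploits the complementary golden-ratio")
print("sampling across frames: aliasing incoherent in time is suppressed,")
print("so less energy lands outside the true vessel support.")
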