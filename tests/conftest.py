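import numpy as np
import pytest

from conetraj import (
    ConeParams,
    HardwareLimits,
    ProtocolParams,
    base_cone,
    build_schedule,
    solve_twist_scaling,
    time_optimal_waveform,
)

RESOLUTION_MM = 1.13
K_MAX = 1.0 / (2.0 * RESOLUTION_MM)


@pytest.fixture(scope="session")
def protocol_limits() -> HardwareLimits:
    """The conservative gradient limits of the reference protocol."""
    return HardwareLimits(g_max=11.64, s_max=61.54, raster_time=10.0)


@pytest.fixture(scope="session")
def invivo_cone() -> ConeParams:
    """The selected in vivo design: 60 deg cone, two-stage, n=3, 10 ms readout."""
    return ConeParams(theta=60.0, m=0.5, n=3.0, A=0.0, k_max=K_MAX,
                      readout_duration=10.0)


@pytest.fixture(scope="session")
def invivo_waveform(invivo_cone, protocol_limits):
    """Fully designed in vivo readout: twist solved, then time-optimally timed."""
    a = solve_twist_scaling(invivo_cone, protocol_limits)
    from dataclasses import replace
    curve = base_cone(replace(invivo_cone, A=a), 4000)
    return time_optimal_waveform(curve, protocol_limits)


@pytest.fixture(scope="session")
def cone_protocol() -> ProtocolParams:
    """Matched-TR protocol timing: TR 14.7 ms, 2116.8 ms readout train."""
    return ProtocolParams(tr=14.7, train_duration=2116.8, readout_time=10.0)


@pytest.fixture(scope="session")
def small_schedule(cone_protocol):
    return build_schedule(cone_protocol, n_repeats=2, seed=7)


def cartesian_coords(n: int, voxel: float = 1.0) -> np.ndarray:
    """Full Cartesian sampling of an n^3 grid, (n^3, 3) in 1/mm."""
    f = (np.arange(n) - n // 2) / (n * voxel)
    return np.stack(np.meshgrid(f, f, f, indexing="ij"), axis=-1).reshape(-1, 3)


def direct_dft(coords: np.ndarray, image: np.ndarray, voxel: float = 1.0) -> np.ndarray:
    """Brute-force type-2 DFT oracle: y_s = sum_r x(r) exp(-2 pi i k_s . r)."""
    n = image.shape[0]
    idx = (np.arange(n) - n // 2) * voxel
    r = np.stack(np.meshgrid(idx, idx, idx, indexing="ij"), -1).reshape(-1, 3)
    return np.exp(-2j * np.pi * coords @ r.T) @ image.ravel()


def cap_discrepancy(axes: np.ndarray, rng: np.random.Generator, n_caps: int = 400) -> float:
    """Spherical-cap discrepancy estimate: max |empirical - true cap fraction|."""
    centers = rng.standard_normal((n_caps, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    heights = rng.uniform(-1.0, 1.0, n_caps)  # cap boundary plane offset
    inside = (axes @ centers.T) >= heights[None, :]
    frac = inside.mean(axis=0)
    true = (1.0 - heights) / 2.0  # cap area fraction on the unit sphere
    return float(np.max(np.abs(frac - true)))
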