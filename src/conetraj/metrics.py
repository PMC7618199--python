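"""Trajectory quality metrics: density compensation, PSF/FWHM, pseudo-replica
effective SNR and signal-to-aliasing power ratio (SAPR).

These quantify how a sampling pattern behaves under a density-compensated
adjoint NUFFT reconstruction: the PSF full width at half maximum measures
spatial resolution, the pseudo-replica method measures how acquisition noise
propagates into the image (compensated for resolution by the FWHM-volume
product), and SAPR measures aliasing energy deposited outside the true
object support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nufft import NUFFT3


class MetricUndefinedError(RuntimeError):
    """The metric is undefined for this input (e.g. non-decaying PSF profile)."""


@dataclass(frozen=True)
class SAPRInputs:
    """Image and disjoint foreground/background masks for the SAPR ratio."""

    image: np.ndarray
    foreground_mask: np.ndarray
    background_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.foreground_mask & self.background_mask):
            raise ValueError("foreground and background masks must be disjoint")
        if not self.foreground_mask.any():
            raise ValueError("foreground mask is empty")
        if not self.background_mask.any():
            raise ValueError("background mask is empty")


@dataclass(frozen=True)
class TrajectoryMetrics:
    """FWHM (mm and voxels, per axis), effective SNR and SAPR."""

    fwhm_mm: tuple[float, float, float]
    fwhm_voxels: tuple[float, float, float]
    eff_snr: float
    sapr: float


def hann_window(k_radius: np.ndarray, k_max: float) -> np.ndarray:
    """Radial Hann apodization w(|k|) = 0.5*(1 + cos(pi*|k|/k_max))."""
    r = np.clip(np.asarray(k_radius, dtype=float) / k_max, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * r))


def density_compensation(
    samples: np.ndarray,
    matrix,
    voxel_size=1.0,
    n_iter: int = 20,
    nufft: NUFFT3 | None = None,
    verbose: bool = False,
) -> np.ndarray:
    """Iterative gridding-based density compensation weights (Pipe-Menon).

    Fixed-point iteration ``w <- w / (P P^H w)`` where P is the gridding
    interpolation operator; 20 iterations by default, convergence (max
    relative update) available via ``verbose``.  The fixed point scales
    inversely with local sample multiplicity: duplicating every sample
    halves every weight.  The result is normalized so the weighted adjoint
    of all-ones data yields a PSF with unit peak; for fully sampled
    Cartesian data the weighted adjoint is then quantitatively the inverse
    DFT.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < 1:
        raise ValueError("need at least one sample for density compensation")
    op = nufft if nufft is not None else NUFFT3(samples, matrix, voxel_size)
    w = np.ones(op.n_samples)
    for it in range(n_iter):
        d = op.interp_gram(w)
        d = np.maximum(d, 1e-30)
        w_new = w / d
        delta = float(np.max(np.abs(w_new - w) / np.maximum(np.abs(w), 1e-30)))
        w = w_new
        if verbose:
            print(f"density compensation iter {it + 1}: max rel update {delta:.3e}")
    peak = float(np.max(np.abs(op.adjoint(w.astype(complex)))))
    if peak > 0:
        w = w / peak
    return w


def psf(
    samples: np.ndarray,
    weights: np.ndarray,
    matrix,
    voxel_size=1.0,
    hann: bool = False,
    k_max: float | None = None,
    nufft: NUFFT3 | None = None,
) -> np.ndarray:
    """Point spread function of a sampling pattern (peak-normalized magnitude).

    Density-compensated adjoint NUFFT of unit data; optionally the data are
    first multiplied by a radial Hann window (which broadens the main lobe
    but suppresses ringing).  Warns if the grid cannot contain the main lobe.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.shape[0] != samples.shape[0]:
        raise ValueError("weights length must match sample count")
    op = nufft if nufft is not None else NUFFT3(samples, matrix, voxel_size)
    # a grid of only a few voxels per main lobe cannot contain the PSF peak
    km = float(np.max(np.linalg.norm(samples, axis=1)))
    fov = min(n * v for n, v in zip(op.matrix, op.voxel))
    if km > 0 and 1.0 / (2.0 * km) > fov / 8.0:
        warnings.warn("matrix too small for k_max; the PSF main lobe will wrap")
    data = weights.astype(complex)
    if hann:
        radius = np.linalg.norm(samples, axis=1)
        km = k_max if k_max is not None else float(radius.max())
        data = data * hann_window(radius, km)
    vol = np.abs(op.adjoint(data))
    peak = vol.max()
    if peak <= 0:
        raise MetricUndefinedError("PSF is identically zero")
    return vol / peak


def _interp_profile(profile: np.ndarray, zoom: int = 8) -> np.ndarray:
    """Band-limited interpolation of a 1D profile by Fourier zero-padding."""
    n = profile.shape[0]
    spec = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(profile)))
    big = np.zeros(n * zoom, dtype=complex)
    lo = n * zoom // 2 - n // 2
    big[lo:lo + n] = spec
    out = np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(big))) * zoom
    return out.real


def fwhm(psf_volume: np.ndarray, voxel_size=1.0, zoom: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Full width at half maximum of the PSF peak along the three axes.

    The profile through the global peak along each cardinal axis is
    interpolated by ``zoom``-fold Fourier zero-padding; the half-maximum
    crossings on both sides of the peak are located by linear interpolation.

    Returns
    -------
    fwhm_mm : (3,) array
    fwhm_voxels : (3,) array

    Raises
    ------
    MetricUndefinedError
        If the peak touches the volume boundary or a profile never crosses
        half maximum.
    """
    vol = np.asarray(psf_volume, dtype=float)
    voxel = np.broadcast_to(voxel_size, 3).astype(float)
    peak_idx = np.unravel_index(np.argmax(vol), vol.shape)
    for d, (p, n) in enumerate(zip(peak_idx, vol.shape)):
        if p == 0 or p == n - 1:
            raise MetricUndefinedError(f"PSF peak lies on the volume boundary (axis {d})")

    widths_vox = np.empty(3)
    for d in range(3):
        sl = list(peak_idx)
        sl[d] = slice(None)
        profile = vol[tuple(sl)]
        fine = _interp_profile(profile, zoom)
        pk = int(np.argmax(fine))
        half = fine[pk] / 2.0

        def crossing(direction: int) -> float:
            i = pk
            while 0 <= i + direction < fine.shape[0]:
                j = i + direction
                if fine[j] < half:
                    frac = (fine[i] - half) / (fine[i] - fine[j])
                    return i + direction * frac
                i = j
            raise MetricUndefinedError(
                f"PSF profile along axis {d} never falls below half maximum"
            )

        widths_vox[d] = abs(crossing(+1) - crossing(-1)) / zoom
    return widths_vox * voxel, widths_vox


def effective_snr(
    forward_data: np.ndarray,
    samples: np.ndarray,
    weights: np.ndarray,
    foreground_mask: np.ndarray,
    noise_sigma: float,
    n_replicas: int = 64,
    seed: int = 0,
    matrix=None,
    voxel_size=1.0,
    nufft: NUFFT3 | None = None,
    fwhm_voxels: np.ndarray | None = None,
) -> float:
    """Pseudo-replica effective SNR, compensated by the FWHM volume.

    Many replicas of the data with independent complex Gaussian noise
    (std ``noise_sigma`` per complex sample) are reconstructed by the
    weighted adjoint; the per-voxel standard deviation of the complex
    reconstructions, averaged over the foreground, is the noise; the mean
    noiseless foreground magnitude is the signal.  The ratio is divided by
    the product of the three axis FWHMs in voxels (a voxel-volume proxy), so
    trajectories cannot trade resolution for apparent SNR.
    """
    if n_replicas < 2:
        raise ValueError("n_replicas must be >= 2")
    if noise_sigma <= 0:
        raise ValueError("noise_sigma must be > 0")
    foreground_mask = np.asarray(foreground_mask, dtype=bool)
    if not foreground_mask.any():
        raise ValueError("foreground mask is empty")

    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    op = nufft if nufft is not None else NUFFT3(samples, matrix, voxel_size)
    weights = np.asarray(weights, dtype=float).ravel()
    data = np.asarray(forward_data, dtype=complex).ravel()

    recon0 = op.adjoint(weights * data)
    signal = float(np.mean(np.abs(recon0[foreground_mask])))

    rng = np.random.default_rng(seed)
    ref = recon0[foreground_mask]
    acc2 = np.zeros(ref.shape)
    for _ in range(n_replicas):
        noise = noise_sigma * (rng.standard_normal(data.shape)
                               + 1j * rng.standard_normal(data.shape)) / np.sqrt(2.0)
        rec = op.adjoint(weights * (data + noise))[foreground_mask]
        acc2 = acc2 + np.abs(rec - ref) ** 2
    noise_std = np.sqrt(acc2 / n_replicas)
    noise_level = float(np.mean(noise_std))
    if noise_level <= 0:
        raise MetricUndefinedError("replica noise level is zero")

    if fwhm_voxels is None:
        psf_vol = psf(samples, weights, op.matrix, op.voxel, nufft=op)
        _, fwhm_voxels = fwhm(psf_vol, op.voxel)
    volume_factor = float(np.prod(fwhm_voxels))
    return (signal / noise_level) / volume_factor


def sapr(inputs: SAPRInputs) -> float:
    """Signal-to-aliasing power ratio.

    Mean |image|^2 over the foreground divided by mean |image|^2 over the
    background; returns +inf with a warning when background power is zero.
    """
    img = np.abs(np.asarray(inputs.image))
    p_fg = float(np.mean(img[inputs.foreground_mask] ** 2))
    p_bg = float(np.mean(img[inputs.background_mask] ** 2))
    if p_bg == 0.0:
        warnings.warn("background power is zero; SAPR is infinite")
        return float(np.inf)
    return p_fg / p_bg
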