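"""Experiment configuration, file round-trips and the parameter sweep driver.

An :class:`ExperimentConfig` bundles everything needed to reproduce a run —
cone parameters, hardware limits, protocol timing, schedule seed, phantom and
reconstruction settings — and round-trips losslessly through YAML.  Every
sweep writes its resolved configuration next to its outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cones import ConeParams, base_cone, solve_twist_scaling
from .gradients import HardwareLimits, time_optimal_waveform, resample_adc
from .schedule import ProtocolParams, build_schedule, bin_frames
from .metrics import density_compensation, psf, fwhm, effective_snr, sapr, SAPRInputs
from .nufft import NUFFT3


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved settings for one experiment; YAML round-trip is lossless."""

    cone: dict = field(default_factory=lambda: {
        "theta": 60.0, "m": 0.5, "n": 3.0, "A": 0.0,
        "k_max": 1.0 / (2.0 * 1.13), "readout_duration": 10.0,
    })
    limits: dict = field(default_factory=lambda: {
        "g_max": 11.64, "s_max": 61.54, "raster_time": 10.0, "gamma": 42.5764,
    })
    protocol: dict = field(default_factory=lambda: {
        "tr": 14.7, "train_duration": 2116.8, "readout_time": 10.0,
    })
    n_repeats: int = 48
    schedule_seed: int = 1234
    phantom: dict = field(default_factory=lambda: {"matrix": 64, "voxel_size": 1.13})
    recon: dict = field(default_factory=lambda: {
        "lam": 0.1, "patch": 5, "angio_window": 176.4,
        "perf_window": 352.8, "perf_radius": 1.0 / 3.0,
    })
    output_dir: str = "."

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        except (yaml.YAMLError, UnicodeDecodeError, OSError) as exc:
            raise FormatError(f"not a valid YAML config: {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise FormatError(f"config root must be a mapping: {path}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys {sorted(unknown)} in {path}")
        return cls(**raw)

    def cone_params(self) -> ConeParams:
        return ConeParams(**self.cone)

    def hardware_limits(self) -> HardwareLimits:
        return HardwareLimits(**self.limits)

    def protocol_params(self) -> ProtocolParams:
        return ProtocolParams(**self.protocol)


def save_nifti(volume: np.ndarray, voxel_size: float, path, description: str = "") -> None:
    """Write a 3D/4D volume as NIfTI with voxel size in the header."""
    import nibabel as nib

    vol = np.asarray(volume)
    if np.iscomplexobj(vol):
        vol = np.abs(vol)
    if vol.ndim == 4:  # (frames, x, y, z) -> NIfTI (x, y, z, t)
        vol = np.moveaxis(vol, 0, -1)
    affine = np.diag([voxel_size] * 3 + [1.0])
    img = nib.Nifti1Image(vol.astype(np.float32), affine)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, float]:
    """Read a NIfTI volume; returns (data, voxel_size)."""
    import nibabel as nib

    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:
        raise FormatError(f"not a readable NIfTI file: {path}: {exc}") from exc
    voxel = float(img.header.get_zooms()[0])
    if data.ndim == 4:
        data = np.moveaxis(data, -1, 0)
    return data, voxel


def design_trajectory(cone: ConeParams, limits: HardwareLimits,
                      dwell_us: float = 2.0, num_samples: int = 4000):
    """Solve twist scaling for the target duration, time the waveform and
    return (params_with_A, waveform, adc_samples, adc_times)."""
    a = solve_twist_scaling(cone, limits, num_samples=num_samples)
    curve = base_cone(dataclasses.replace(cone, A=a), num_samples)
    wave = time_optimal_waveform(curve, limits)
    k_adc, t_adc = resample_adc(wave, dwell_us)
    return dataclasses.replace(cone, A=a), wave, k_adc, t_adc


def _sweep_one(
    theta: float, m: float, n: float, readout_ms: float,
    config: ExperimentConfig,
    binning: str,
    n_repeats: int,
    psf_matrix: int,
    dwell_us: float,
    compute_snr: bool,
) -> dict:
    from . import phantoms as ph

    limits = config.hardware_limits()
    k_max = config.cone["k_max"]
    cone = ConeParams(theta=theta, m=m, n=n, A=0.0, k_max=k_max,
                      readout_duration=readout_ms)
    cone, wave, k_adc, _ = design_trajectory(cone, limits, dwell_us=dwell_us)

    protocol = config.protocol_params()
    schedule = build_schedule(protocol, n_repeats, config.schedule_seed)

    if binning == "angio":
        window = config.recon["angio_window"]
        frac, half = 1.0, True
    else:
        window = config.recon["perf_window"]
        frac, half = config.recon["perf_radius"], False
    bins = bin_frames(schedule, temporal_window=window,
                      k_radius_fraction=frac, half_shots=half)

    radius = np.linalg.norm(k_adc, axis=1)
    keep = radius <= frac * k_max * (1 + 1e-12)
    shots = bins.frames[0]
    coords = np.concatenate([k_adc[keep] @ schedule.rotations[s].T for s in shots])

    grid_n = max(8, int(round(psf_matrix * frac)))
    voxel = 1.0 / (2.0 * frac * k_max)
    op = NUFFT3(coords, grid_n, voxel)
    w = density_compensation(coords, grid_n, voxel, nufft=op)
    vol = psf(coords, w, grid_n, voxel, nufft=op)
    fw_mm, fw_vox = fwhm(vol, voxel)

    row = {
        "theta_deg": theta, "m": m, "n": n, "readout_ms": readout_ms,
        "binning": binning, "A": cone.A, "duration_ms": wave.duration_ms,
        "n_shots_frame": len(shots), "n_samples_frame": coords.shape[0],
        "fwhm_x_mm": fw_mm[0], "fwhm_y_mm": fw_mm[1], "fwhm_z_mm": fw_mm[2],
        "eff_snr": np.nan, "sapr": np.nan, "error": "",
    }
    if compute_snr:
        kind = "vessel" if binning == "angio" else "perfusion"
        seed = int(config.phantom.get("seed", 0))
        if kind == "vessel":
            phm = ph.make_vessel_phantom(grid_n, voxel, seed=seed)
        else:
            phm = ph.make_perfusion_phantom(grid_n, voxel, seed=seed)
        coil = ph.CoilModel(np.ones((1,) + phm.matrix, dtype=complex))
        data = ph.simulate_acquisition(phm, coil, coords, nuffts=op)[0]
        sigma = 0.02 * float(np.abs(data).max())
        row["eff_snr"] = effective_snr(
            data, coords, w, phm.foreground_mask, sigma,
            n_replicas=16, seed=seed, nufft=op, fwhm_voxels=fw_vox,
        )
        rec = np.abs(op.adjoint(w * data))
        row["sapr"] = sapr(SAPRInputs(rec, phm.foreground_mask, ~phm.foreground_mask))
    return row


def run_sweep(
    config: ExperimentConfig,
    thetas=(60.0,), ms=(0.5,), ns=(3.0,), readouts=(10.0,),
    out_csv=None,
    n_repeats: int = 8,
    psf_matrix: int = 48,
    dwell_us: float = 10.0,
    compute_snr: bool = False,
) -> pd.DataFrame:
    """Full-factorial trajectory-quality sweep over (theta, m, n, readout).

    One row per (parameter combination, binning mode in {angio, perfusion}).
    Resumable: if ``out_csv`` exists, already-computed rows are skipped.
    Individual combination failures are recorded in the ``error`` column and
    the sweep continues.  ``n_repeats``/``psf_matrix``/``dwell_us`` control
    the evaluation scale (defaults are desk-scale, far below a full protocol).
    """
    if not (len(thetas) and len(ms) and len(ns) and len(readouts)):
        raise ValueError("parameter grid must be non-empty")
    done = pd.DataFrame()
    key_cols = ["theta_deg", "m", "n", "readout_ms", "binning"]
    if out_csv is not None and Path(out_csv).exists():
        done = pd.read_csv(out_csv)

    rows = list(done.to_dict("records"))
    for theta in thetas:
        for m in ms:
            for n in ns:
                for ro in readouts:
                    for binning in ("angio", "perfusion"):
                        key = (theta, m, n, ro, binning)
                        if len(done) and (
                            (done[key_cols] == pd.Series(dict(zip(key_cols, key)))).all(axis=1)
                        ).any():
                            continue
                        try:
                            row = _sweep_one(theta, m, n, ro, config, binning,
                                             n_repeats, psf_matrix, dwell_us, compute_snr)
                        except Exception as exc:  # record and continue
                            row = dict(zip(key_cols, key))
                            row["error"] = f"{type(exc).__name__}: {exc}"
                        rows.append(row)
                        if out_csv is not None:
                            pd.DataFrame(rows).to_csv(out_csv, index=False)
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
        cfg_path = Path(out_csv).with_suffix(".config.yaml")
        config.to_yaml(cfg_path)
    return df
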