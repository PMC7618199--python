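"""3D golden-ratio shot ordering and spatiotemporal frame binning.

Each readout (shot) is the base cone rotated so its axis points along a
direction from the 3D golden-means sequence, then spun about that axis by a
random angle.  Incrementing the golden index first across repeats and then
across TRs keeps any contiguous index window — and therefore any temporal
binning that groups shots across repeats — near-uniform on the sphere.

The two golden means are phi2 = the real root of x^3 + x = 1 (~0.6823278)
and phi1 = phi2^2 (~0.4655712); the shot axis for index i is
z = 2*frac(i*phi1) - 1, azimuth = 2*pi*frac(i*phi2), covering the full
sphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

# real root of x^3 + x - 1 = 0 via Cardano; phi1 = phi2**2
_D = np.sqrt(31.0 / 108.0)
PHI2 = float(np.cbrt(0.5 + _D) + np.cbrt(0.5 - _D))
PHI1 = PHI2 ** 2


class ProtocolError(ValueError):
    """Inconsistent protocol timing (non-integer readout count etc.)."""


@dataclass(frozen=True)
class ProtocolParams:
    """Readout-train timing after each labeling preparation.

    Attributes
    ----------
    tr : float
        Repetition time between consecutive readouts, ms.
    train_duration : float
        Total readout train duration after each preparation, ms.  Must be an
        integer multiple of ``tr``.
    readout_time : float
        Per-shot ADC duration, ms.
    flip_schedule : array or None
        Per-TR flip angles in degrees, carried as data only.
    """

    tr: float
    train_duration: float
    readout_time: float
    flip_schedule: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.train_duration <= 0 or self.readout_time <= 0:
            raise ProtocolError("tr, train_duration and readout_time must be > 0")
        ratio = self.train_duration / self.tr
        if abs(ratio - round(ratio)) > 1e-9 * ratio:
            raise ProtocolError(
                f"train_duration/tr = {ratio} is not an integer readout count"
            )
        if self.flip_schedule is not None and len(self.flip_schedule) != self.n_tr:
            raise ProtocolError("flip_schedule length must equal the number of TRs")

    @property
    def n_tr(self) -> int:
        """Number of readouts after each preparation."""
        return int(round(self.train_duration / self.tr))


@dataclass(frozen=True)
class ShotSchedule:
    """Per-shot rotations and (repeat, TR) labels.

    ``rotations[s]`` maps the canonical z-axis base cone into its scheduled
    orientation; ``golden_index[s]`` drives the golden-means axis;
    ``spin_angle[s]`` is the extra random rotation about the cone axis.
    Shot s corresponds to repeat ``repeat_index[s]`` and TR ``tr_index[s]``.
    """

    n_repeats: int
    n_tr: int
    rotations: np.ndarray      # (S, 3, 3)
    golden_index: np.ndarray   # (S,)
    spin_angle: np.ndarray     # (S,)
    repeat_index: np.ndarray   # (S,)
    tr_index: np.ndarray       # (S,)
    protocol: ProtocolParams
    seed: int

    @property
    def n_shots(self) -> int:
        return self.n_repeats * self.n_tr

    def shot_start_times(self) -> np.ndarray:
        """TR start time (ms, within the train) of every shot."""
        return self.tr_index * self.protocol.tr


@dataclass(frozen=True)
class FrameBinning:
    """Grouping of shots (and optionally their samples) into temporal frames."""

    temporal_window: float
    k_radius_fraction: float
    frames: list[np.ndarray]                   # per-frame shot indices
    sample_subsets: list[list[np.ndarray]] | None = None  # per-frame per-shot sample indices

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def golden_axis(i) -> np.ndarray:
    """Unit axis vector(s) for golden index i (scalar or array).

    z = 2*frac(i*phi1) - 1, azimuth = 2*pi*frac(i*phi2); i = 0 maps to the
    south pole (0, 0, -1).
    """
    i = np.asarray(i, dtype=float)
    z = 2.0 * np.mod(i * PHI1, 1.0) - 1.0
    phi = 2.0 * np.pi * np.mod(i * PHI2, 1.0)
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=-1)


def _rotation_to_axis(axis: np.ndarray, spin: float) -> np.ndarray:
    """Rotation taking e_z to ``axis``, preceded by a spin about e_z.

    The spin about the cone's own (z) axis is applied first, then the axis
    alignment, so the net effect is an azimuthal spin about the final axis.
    """
    from scipy.spatial.transform import Rotation

    z = np.array([0.0, 0.0, 1.0])
    a = axis / np.linalg.norm(axis)
    v = np.cross(z, a)
    s = np.linalg.norm(v)
    c = float(np.dot(z, a))
    if s < 1e-12:
        align = np.eye(3) if c > 0 else Rotation.from_rotvec([np.pi, 0, 0]).as_matrix()
    else:
        align = Rotation.from_rotvec(v / s * np.arctan2(s, c)).as_matrix()
    spin_mat = Rotation.from_rotvec([0.0, 0.0, spin]).as_matrix()
    return align @ spin_mat


def build_schedule(
    protocol: ProtocolParams,
    n_repeats: int,
    seed: int,
    index_order: str = "repeats_first",
) -> ShotSchedule:
    """Assign golden-ratio rotations to every (repeat, TR) shot.

    Shot at (repeat r, TR t) receives golden index ``i = t*n_repeats + r``
    (repeat varies fastest: the ordering increments golden rotations first
    across repeats and then across time), axis ``golden_axis(i)``, and a
    seeded uniform random spin about the axis.  Deterministic given the seed.

    ``index_order="time_first"`` toggles the alternative ``i = r*n_tr + t``.
    """
    if n_repeats < 1:
        raise ProtocolError(f"n_repeats must be >= 1, got {n_repeats}")
    n_tr = protocol.n_tr
    n_shots = n_repeats * n_tr

    t_idx, r_idx = np.meshgrid(np.arange(n_tr), np.arange(n_repeats), indexing="ij")
    t_idx, r_idx = t_idx.ravel(), r_idx.ravel()
    if index_order == "repeats_first":
        gold = t_idx * n_repeats + r_idx
    elif index_order == "time_first":
        gold = r_idx * n_tr + t_idx
    else:
        raise ValueError(f"unknown index_order {index_order!r}")

    rng = np.random.default_rng(seed)
    # spin drawn in golden-index order so the schedule is invariant to layout
    spins_by_gold = rng.uniform(0.0, 2.0 * np.pi, size=n_shots)
    spin = spins_by_gold[gold]

    axes = golden_axis(gold)
    rotations = np.empty((n_shots, 3, 3))
    for s in range(n_shots):
        rotations[s] = _rotation_to_axis(axes[s], spin[s])

    return ShotSchedule(
        n_repeats=n_repeats, n_tr=n_tr, rotations=rotations,
        golden_index=gold, spin_angle=spin,
        repeat_index=r_idx, tr_index=t_idx,
        protocol=protocol, seed=seed,
    )


def bin_frames(
    schedule: ShotSchedule,
    samples: np.ndarray | None = None,
    temporal_window: float = None,
    k_radius_fraction: float = 1.0,
    k_max: float | None = None,
    half_shots: bool = False,
    allow_truncation: bool = False,
) -> FrameBinning:
    """Group shots into temporal frames, optionally restricting k radius.

    A frame collects all shots (across repeats) whose TR start time falls in
    its window; with ``k_radius_fraction < 1`` only samples with
    ``|k| <= k_radius_fraction * k_max`` are retained (``samples`` is the
    (n_adc, 3) per-shot base sample array; the radius is rotation-invariant
    so the base samples suffice).  ``half_shots=True`` keeps only the first
    half of the repeats in each window (the angiographic convention of using
    half the shots), preserving golden-index contiguity.

    Raises / warns
    --------------
    ProtocolError if the window does not divide the train (unless
    ``allow_truncation``); a window longer than the train falls back to one
    frame with a warning.
    """
    train = schedule.protocol.train_duration
    if temporal_window is None or temporal_window <= 0:
        raise ProtocolError("temporal_window must be > 0 ms")
    if not (0.0 < k_radius_fraction <= 1.0):
        raise ProtocolError(f"k_radius_fraction must be in (0, 1], got {k_radius_fraction}")
    if temporal_window > train * (1 + 1e-9):
        warnings.warn("temporal window exceeds the readout train; using a single frame")
        temporal_window = train
    ratio = train / temporal_window
    if abs(ratio - round(ratio)) > 1e-6 * ratio and not allow_truncation:
        raise ProtocolError(
            f"temporal_window {temporal_window} ms does not divide the "
            f"{train} ms train; pass allow_truncation=True to drop the remainder"
        )
    n_frames = int(np.floor(train / temporal_window + 1e-9))

    start = schedule.shot_start_times()
    repeat_keep = (
        schedule.repeat_index < (schedule.n_repeats + 1) // 2
        if half_shots else np.ones(schedule.n_shots, dtype=bool)
    )

    frames: list[np.ndarray] = []
    for f in range(n_frames):
        lo, hi = f * temporal_window, (f + 1) * temporal_window
        in_window = (start >= lo - 1e-9) & (start < hi - 1e-9)
        frames.append(np.nonzero(in_window & repeat_keep)[0])

    sample_subsets = None
    if samples is not None:
        if k_max is None:
            k_max = float(np.max(np.linalg.norm(samples, axis=1)))
        radius = np.linalg.norm(samples, axis=1)
        keep = np.nonzero(radius <= k_radius_fraction * k_max * (1 + 1e-12))[0]
        sample_subsets = [[keep for _ in fr] for fr in frames]

    return FrameBinning(
        temporal_window=temporal_window,
        k_radius_fraction=k_radius_fraction,
        frames=frames,
        sample_subsets=sample_subsets,
    )


def protocol_arithmetic(
    protocol: ProtocolParams,
    k_max: float | None = None,
    windows: tuple[float, ...] = (),
    radius_fractions: tuple[float, ...] = (),
) -> dict:
    """Pure arithmetic consistency report for a protocol.

    Returns n_tr, train duration, frame counts at the given temporal
    windows, and nominal resolutions at the given k-radius fractions
    (resolution at fraction f = (1/(2*k_max)) / f).
    """
    out = {
        "tr_ms": protocol.tr,
        "train_duration_ms": protocol.train_duration,
        "n_tr": protocol.n_tr,
        "readout_time_ms": protocol.readout_time,
    }
    for w in windows:
        out[f"n_frames_at_{w}ms"] = int(np.floor(protocol.train_duration / w + 1e-9))
    if k_max is not None:
        res = 1.0 / (2.0 * k_max)
        out["nominal_resolution_mm"] = res
        for f in radius_fractions:
            out[f"nominal_resolution_mm_at_f{f:g}"] = res / f
    return out


def schedule_to_hdf5(schedule: ShotSchedule, path) -> None:
    """Write /schedule/{rotations,golden_index,spin_angle} with attributes."""
    import h5py

    with h5py.File(path, "a") as f:
        for name in ("schedule/rotations", "schedule/golden_index", "schedule/spin_angle"):
            if name in f:
                del f[name]
        f.create_dataset("schedule/rotations", data=schedule.rotations)
        f.create_dataset("schedule/golden_index", data=schedule.golden_index)
        f.create_dataset("schedule/spin_angle", data=schedule.spin_angle)
        grp = f["schedule"]
        grp.attrs["n_repeats"] = schedule.n_repeats
        grp.attrs["n_tr"] = schedule.n_tr
        grp.attrs["tr_ms"] = schedule.protocol.tr
        grp.attrs["seed"] = schedule.seed


def schedule_from_hdf5(path, readout_time: float = 10.0) -> ShotSchedule:
    """Read back a schedule written by :func:`schedule_to_hdf5`."""
    import h5py

    with h5py.File(path, "r") as f:
        grp = f["schedule"]
        rotations = grp["rotations"][()]
        gold = grp["golden_index"][()]
        spin = grp["spin_angle"][()]
        n_repeats = int(grp.attrs["n_repeats"])
        n_tr = int(grp.attrs["n_tr"])
        tr = float(grp.attrs["tr_ms"])
        seed = int(grp.attrs["seed"])
    protocol = ProtocolParams(tr=tr, train_duration=tr * n_tr, readout_time=readout_time)
    t_idx, r_idx = np.meshgrid(np.arange(n_tr), np.arange(n_repeats), indexing="ij")
    return ShotSchedule(
        n_repeats=n_repeats, n_tr=n_tr, rotations=rotations,
        golden_index=gold, spin_angle=spin,
        repeat_index=r_idx.ravel(), tr_index=t_idx.ravel(),
        protocol=protocol, seed=seed,
    )
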