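"""Forward model: phase projection, ptychographic scans and absorbed dose.

Geometry
--------
The beam at 0 degrees travels along ``+x``; the rotation axis is ``z`` and the
detector axis within a projection row is the rotated ``y`` axis, so a
projection image has axes ``(z, u)`` with ``u`` the in-plane detector
coordinate.  For a (counter-clockwise about z) rotation angle ``theta`` a
sample point ``(y, x)`` (relative to the volume centre) maps to

    u = (y - c) cos(theta) - (x - c) sin(theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import AcquisitionPlan, DeformationModel, TissuePhantom

__all__ = [
    "PhaseProjectionSet",
    "DiffractionScan",
    "DoseRecord",
    "warp_volume",
    "project",
    "simulate_ptycho_scan",
    "absorbed_dose",
    "acquire_series",
]

KEV_TO_JOULE = 1.602176634e-16  # J per keV
DEFAULT_K_PHASE = 1e-3  # radians per (density unit * nm); configurable gauge


@dataclass
class PhaseProjectionSet:
    """Per-angle phase projections with dose/time bookkeeping.

    Projections are stored in acquisition order, which is subtomogram
    interlaced rather than angle sorted; ``times`` are cumulative dose
    fractions and therefore non-decreasing in storage order.
    """

    projections: np.ndarray  # (n, Z, U) radians
    angles: np.ndarray  # degrees, acquisition order
    times: np.ndarray  # dose fraction in [0, 1], non-decreasing
    pixel_size: float  # nm
    per_projection_dose: np.ndarray | None = None  # Gy
    n_subtomos: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.projections = np.asarray(self.projections, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        n = len(self.projections)
        if not (len(self.angles) == len(self.times) == n):
            raise ValueError("projections, angles and times must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.projections)

    def subset(self, idx: np.ndarray) -> "PhaseProjectionSet":
        dose = None if self.per_projection_dose is None else self.per_projection_dose[idx]
        return PhaseProjectionSet(
            projections=self.projections[idx],
            angles=self.angles[idx],
            times=self.times[idx],
            pixel_size=self.pixel_size,
            per_projection_dose=dose,
            n_subtomos=1,
            meta=dict(self.meta),
        )


@dataclass
class DiffractionScan:
    """Far-field intensity patterns (photon counts) from a ptychographic scan."""

    patterns: np.ndarray  # (n, P, P), >= 0
    positions: np.ndarray  # (n, 2) integer (y, x) top-left patch corners
    probe_truth: np.ndarray | None = None  # complex, for fixtures
    object_truth: np.ndarray | None = None
    detector_pixels: int = 0
    photons_per_exposure: float | None = None

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        if np.any(self.patterns < 0):
            raise ValueError("intensities must be non-negative")
        self.detector_pixels = int(self.patterns.shape[-1])


@dataclass
class DoseRecord:
    """Inputs and result of the absorbed-dose estimate."""

    flux: float  # photons / s
    photon_energy: float  # keV
    exposure_total: float  # s
    fraction_absorbed: float
    electron_moles: float  # mol of electrons in the sample
    molar_mass_per_electron: float = 1.9  # g / mol, resin+stain mixture convention
    volume_um3: float | None = None
    dose: float = 0.0  # Gy


# ---------------------------------------------------------------------------
# warping and projection


def _identity_grid(shape) -> np.ndarray:
    return np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    )


def warp_volume(volume: np.ndarray, displacement: np.ndarray, order: int = 1) -> np.ndarray:
    """Apply a material displacement field to a volume.

    ``displacement`` has shape ``(3, z, y, x)`` in voxels and moves material
    forward: a feature at ``p`` in ``volume`` appears near ``p + displacement(p)``
    in the output (first-order pull-back: output(x) = volume(x - d(x))).
    """
    if displacement.shape != (3,) + volume.shape:
        raise ValueError("displacement shape must be (3,) + volume.shape")
    coords = _identity_grid(volume.shape) - displacement
    return ndimage.map_coordinates(volume, coords, order=order, mode="nearest")


def project(
    phantom: TissuePhantom | np.ndarray,
    angle_deg: float,
    deformation: np.ndarray | None = None,
    k_phase: float = DEFAULT_K_PHASE,
    voxel_size: float | None = None,
) -> np.ndarray:
    """Phase projection of a (possibly deformed) volume at one angle.

    The volume is warped by ``deformation`` (if given), rotated about ``z``
    by ``angle_deg`` and integrated along the beam axis; the line integral is
    scaled by ``voxel_size * k_phase`` so phase is proportional to projected
    density.
    """
    if isinstance(phantom, TissuePhantom):
        vol = phantom.density
        voxel_size = phantom.voxel_size if voxel_size is None else voxel_size
    else:
        vol = np.asarray(phantom, dtype=float)
        voxel_size = 1.0 if voxel_size is None else voxel_size
    if deformation is not None:
        vol = warp_volume(vol, deformation)

    nz, ny, nx = vol.shape
    theta = np.deg2rad(angle_deg)
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    cu, cs = cy, cx
    u = np.arange(ny, dtype=float) - cu
    s = np.arange(nx, dtype=float) - cs
    uu, ss = np.meshgrid(u, s, indexing="ij")
    yy = cy + uu * np.cos(theta) + ss * np.sin(theta)
    xx = cx - uu * np.sin(theta) + ss * np.cos(theta)
    zz = np.broadcast_to(np.arange(nz, dtype=float)[:, None, None], (nz, ny, nx))
    coords = np.stack(
        [zz, np.broadcast_to(yy, (nz, ny, nx)), np.broadcast_to(xx, (nz, ny, nx))]
    )
    rotated = ndimage.map_coordinates(vol, coords, order=1, mode="constant", cval=0.0)
    return rotated.sum(axis=2) * voxel_size * k_phase


# ---------------------------------------------------------------------------
# ptychographic scan simulation


def simulate_ptycho_scan(
    object_field: np.ndarray,
    probe: np.ndarray,
    positions: np.ndarray,
    photons_per_exposure: float | None = 1e5,
    rng_seed: int = 0,
    overlap_warn: float = 0.6,
) -> DiffractionScan:
    """Simulate far-field diffraction patterns of a scanned complex object.

    The probe is normalized to unit power so each noiseless pattern integrates
    to ``photons_per_exposure`` for a pure-phase object; patterns are Poisson
    sampled unless ``photons_per_exposure`` is None (noiseless).

    ``object_field`` may be a real phase map (radians, converted to
    ``exp(i*phase)``) or a complex transmission.  ``positions`` are integer
    (y, x) top-left corners of the probe-sized patch.
    """
    obj = np.asarray(object_field)
    if not np.iscomplexobj(obj):
        obj = np.exp(1j * obj.astype(float))
    probe = np.asarray(probe, dtype=complex)
    p = probe.shape[0]
    if probe.shape[0] != probe.shape[1]:
        raise ValueError("probe must be square")
    if p > min(obj.shape):
        raise ValueError("probe must be smaller than the object")
    power = np.sqrt((np.abs(probe) ** 2).sum())
    probe = probe / max(power, 1e-30)
    if photons_per_exposure is not None:
        probe = probe * np.sqrt(photons_per_exposure)

    positions = np.asarray(np.round(positions), dtype=int)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("positions must be (n, 2)")
    if (positions < 0).any() or (positions[:, 0] + p > obj.shape[0]).any() or (
        positions[:, 1] + p > obj.shape[1]
    ).any():
        raise ValueError("scan positions out of object bounds")

    _check_overlap(positions, p, overlap_warn)

    rng = np.random.default_rng(rng_seed)
    patterns = np.empty((len(positions), p, p))
    for i, (py, px) in enumerate(positions):
        exit_wave = probe * obj[py:py + p, px:px + p]
        intensity = np.abs(np.fft.fft2(exit_wave, norm="ortho")) ** 2
        if photons_per_exposure is None:
            patterns[i] = intensity
        else:
            patterns[i] = rng.poisson(intensity)
    return DiffractionScan(
        patterns=patterns,
        positions=positions,
        probe_truth=probe,
        object_truth=obj,
        photons_per_exposure=photons_per_exposure,
    )


def _check_overlap(positions: np.ndarray, probe_size: int, threshold: float) -> None:
    import warnings

    if len(positions) < 2:
        return
    from scipy.spatial import cKDTree

    tree = cKDTree(positions)
    d, _ = tree.query(positions, k=2)
    overlap = 1.0 - float(d[:, 1].mean()) / probe_size
    if overlap < threshold:
        warnings.warn(
            f"mean linear overlap {overlap:.2f} below {threshold:.2f}; "
            "retrieval may not converge",
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# dose


def absorbed_dose(
    flux: float,
    photon_energy_kev: float,
    exposure_total: float,
    fraction_absorbed: float,
    electron_moles: float,
    molar_mass_per_electron: float = 1.9,
) -> float:
    """Absorbed dose in Gy: energy absorbed divided by sample mass.

    dose = flux * exposure * fraction_absorbed * E_photon[J] / mass[kg], with
    mass obtained from the electron inventory via the mean molar mass per
    electron (grams per mole of electrons).
    """
    for name, v in [
        ("flux", flux),
        ("photon_energy_kev", photon_energy_kev),
        ("exposure_total", exposure_total),
        ("fraction_absorbed", fraction_absorbed),
        ("electron_moles", electron_moles),
        ("molar_mass_per_electron", molar_mass_per_electron),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if fraction_absorbed > 1:
        raise ValueError("fraction_absorbed must be <= 1")
    mass_kg = electron_moles * molar_mass_per_electron * 1e-3
    if mass_kg <= 0:
        raise ValueError("sample mass must be positive")
    energy_j = flux * exposure_total * fraction_absorbed * photon_energy_kev * KEV_TO_JOULE
    return energy_j / mass_kg


def dose_record(
    flux: float,
    photon_energy_kev: float,
    exposure_total: float,
    fraction_absorbed: float,
    electron_moles: float,
    molar_mass_per_electron: float = 1.9,
    volume_um3: float | None = None,
) -> DoseRecord:
    dose = absorbed_dose(
        flux, photon_energy_kev, exposure_total, fraction_absorbed,
        electron_moles, molar_mass_per_electron,
    )
    return DoseRecord(
        flux=flux,
        photon_energy=photon_energy_kev,
        exposure_total=exposure_total,
        fraction_absorbed=fraction_absorbed,
        electron_moles=electron_moles,
        molar_mass_per_electron=molar_mass_per_electron,
        volume_um3=volume_um3,
        dose=dose,
    )


# ---------------------------------------------------------------------------
# series acquisition


def acquire_series(
    phantom: TissuePhantom,
    deformation_model: DeformationModel | None,
    plan: AcquisitionPlan,
    k_phase: float = DEFAULT_K_PHASE,
    fraction_absorbed: float = 0.05,
    electron_moles: float = 1e-12,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
) -> PhaseProjectionSet:
    """Acquire phase projections in subtomogram-interlaced order.

    The deformation is evaluated at each projection's cumulative dose
    fraction ``t_i = i / (n - 1)`` (0 at the first projection, 1 at the last).
    ``noise_sigma`` adds white Gaussian phase noise emulating a finite photon
    budget without running the full ptychographic chain.
    """
    order = plan.acquisition_order()
    n = plan.n_projections
    times = np.arange(n) / max(n - 1, 1)
    total_dose = absorbed_dose(
        plan.flux, plan.photon_energy, plan.exposure * n,
        fraction_absorbed, electron_moles,
    )
    rng = np.random.default_rng(rng_seed)
    projections = []
    angles = []
    for i, angle_idx in enumerate(order):
        t = times[i]
        field = None
        if deformation_model is not None and deformation_model.amplitude > 0:
            field = deformation_model.at(t)
        p = project(phantom, plan.angles[angle_idx], field, k_phase=k_phase)
        if noise_sigma > 0:
            p = p + rng.normal(0.0, noise_sigma, p.shape)
        projections.append(p)
        angles.append(plan.angles[angle_idx])

    per_dose = np.full(n, total_dose / n)
    return PhaseProjectionSet(
        projections=np.asarray(projections),
        angles=np.asarray(angles),
        times=times,
        pixel_size=phantom.voxel_size,
        per_projection_dose=per_dose,
        n_subtomos=plan.n_subtomos,
        meta={"k_phase": k_phase, "total_dose": total_dose},
    )
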