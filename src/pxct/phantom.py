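"""Synthetic tissue phantoms, deformation models, scan plans and score fixtures.

Everything here is seeded and deterministic so that downstream stages
(projection, phase retrieval, tomography, metrics, synapse scoring) can be
exercised without any external data.

Conventions
-----------
* Axis order is ``(z, y, x)``; the tomographic rotation axis is ``z``.
* Voxel indexing is 0-based; physical positions are in nanometres,
  displacement fields in voxels.
* Deformation is parameterized by the fraction of total delivered dose in
  ``[0, 1]`` (dose and wall time are mapped linearly within a scan).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "TissuePhantom",
    "DeformationModel",
    "AcquisitionPlan",
    "ScoreArray",
    "make_phantom",
    "make_deformation",
    "fermat_spiral",
    "make_score_array",
]

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: semantic voxel labels
LABEL_BACKGROUND = 0
LABEL_NEURITE = 1
LABEL_MITOCHONDRION = 2
LABEL_NUCLEUS = 3
LABEL_SYNAPSE = 4

DEFAULT_DENSITIES = {
    "background": 1.0,
    "neurite": 1.35,
    "mitochondrion": 1.9,
    "nucleus": 1.6,
    "synapse": 2.4,
}


@dataclass
class TissuePhantom:
    """Voxelized density with semantic labels and ground-truth synapse points."""

    density: np.ndarray  # (z, y, x), >= 0, arbitrary electron-density units
    labels: np.ndarray  # same shape, integer semantic classes
    synapses: np.ndarray  # (n, 3) positions in nm, (z, y, x)
    voxel_size: float  # nm per voxel, isotropic
    rng_seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density.shape != self.labels.shape:
            raise ValueError("density and labels must have identical shapes")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape


@dataclass
class DeformationModel:
    """Smooth displacement fields indexed by dose fraction.

    ``control_fields[i]`` has shape ``(3, z, y, x)`` (components ordered z, y, x,
    in voxels) and describes the material displacement accumulated at dose
    fraction ``control_times[i]``.  The field at ``control_times[0]`` is the
    zero reference state.
    """

    control_fields: list[np.ndarray]
    control_times: np.ndarray
    amplitude: float
    smoothness: float
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.control_times = np.asarray(self.control_times, dtype=float)
        if np.any(np.diff(self.control_times) <= 0):
            raise ValueError("control_times must be strictly increasing")
        if len(self.control_fields) != len(self.control_times):
            raise ValueError("one control field per control time required")

    def at(self, t: float) -> np.ndarray:
        """Displacement field at dose fraction ``t`` (piecewise linear, clamped)."""
        times = self.control_times
        if t <= times[0]:
            return self.control_fields[0]
        if t >= times[-1]:
            return self.control_fields[-1]
        j = int(np.searchsorted(times, t, side="right"))
        t0, t1 = times[j - 1], times[j]
        w = (t - t0) / (t1 - t0)
        return (1.0 - w) * self.control_fields[j - 1] + w * self.control_fields[j]


@dataclass
class AcquisitionPlan:
    """Projection angles, subtomogram interleaving and per-point scan layout."""

    angles: np.ndarray  # degrees, strictly increasing, equally spaced in [0, 180)
    n_subtomos: int = 1
    scan_step: float = 1.0  # um
    exposure: float = 0.05  # s per scan point
    flux: float = 7e8  # photons / s
    photon_energy: float = 6.2  # keV
    scan_positions: list[np.ndarray] | None = None  # one (n, 2) array per projection

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.size < 1:
            raise ValueError("need at least one projection angle")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.angles.size > 1:
            spacings = np.diff(self.angles)
            if np.ptp(spacings) > 1e-9:
                raise ValueError("angles must be equally spaced to within 1e-9 deg")
        if self.n_subtomos < 1:
            raise ValueError("n_subtomos must be >= 1")

    @property
    def n_projections(self) -> int:
        return int(self.angles.size)

    def acquisition_order(self) -> np.ndarray:
        """Indices into ``angles`` in the order they are acquired.

        Subtomogram-interlaced: subtomogram ``j`` collects the angle indices
        congruent to ``j`` modulo ``n_subtomos`` so each subtomogram sparsely
        spans the half-circle while occupying a contiguous dose window.
        """
        k = self.n_subtomos
        idx = np.arange(self.n_projections)
        return np.concatenate([idx[idx % k == j] for j in range(k)])


def equispaced_angles(n: int, start: float = 0.0, stop: float = 180.0) -> np.ndarray:
    """``n`` equally spaced angles in ``[start, stop)`` degrees."""
    return start + (stop - start) * np.arange(n) / n


@dataclass
class ScoreArray:
    """Annotator confidence scores: (region, annotator, modality), values 0-4.

    Modality axis: index 0 is the ground-truth (EM) modality, index 1 the
    evaluated (X-ray) modality.  0 codes a missing response.
    """

    scores: np.ndarray
    region_centers: np.ndarray  # (n_regions, 3) nm
    true_flags: np.ndarray  # (n_regions,) bool, ground-truth synapse presence

    def __post_init__(self) -> None:
        if not np.isin(self.scores, [0, 1, 2, 3, 4]).all():
            raise ValueError("scores must take values in {0,1,2,3,4}")


# ---------------------------------------------------------------------------
# phantom generation


def _carve_ball(grid: np.ndarray, center: np.ndarray, radii: Sequence[float], value: int) -> None:
    """Set ``value`` inside an axis-aligned ellipsoid, clipped to the grid."""
    lo = np.maximum(np.floor(center - np.max(radii) - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + np.max(radii) + 2).astype(int), grid.shape)
    if np.any(hi <= lo):
        return
    zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    )
    sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[d2 <= 1.0] = value


def _random_walk_tube(shape, rng, radius, persistence=0.85, margin=3):
    """Persistent random-walk path through the volume; returns path points."""
    pos = rng.uniform(margin, np.asarray(shape) - margin)
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    path = [pos.copy()]
    n_steps = int(2.5 * max(shape))
    for _ in range(n_steps):
        kick = rng.standard_normal(3)
        kick /= np.linalg.norm(kick)
        direction = persistence * direction + (1 - persistence) * kick
        direction /= np.linalg.norm(direction)
        pos = pos + direction
        # reflect at the walls to keep tubes inside
        for a in range(3):
            if pos[a] < margin or pos[a] > shape[a] - margin:
                direction[a] = -direction[a]
                pos[a] = np.clip(pos[a], margin, shape[a] - margin)
        path.append(pos.copy())
    return np.asarray(path)


def make_phantom(
    size_voxels: int | tuple[int, int, int] = 64,
    voxel_size_nm: float = 30.0,
    feature_densities: dict | None = None,
    n_neurites: int = 6,
    n_mitochondria: int = 8,
    n_nuclei: int = 1,
    n_synapses: int = 12,
    neurite_radius: float = 2.5,
    texture: float = 0.0,
    pillar_radius_frac: float | None = 0.46,
    rng_seed: int = 0,
) -> TissuePhantom:
    """Generate a seeded stained-tissue phantom.

    Neurites are tubes carved along persistent random walks, mitochondria and
    nuclei are ellipsoids, and synapses are small high-density puncta apposed
    to neurite surfaces.  A feature class with density 0 is skipped entirely,
    so all-zero ``feature_densities`` yields a uniform background volume.

    The sample is confined to a cylindrical pillar about the rotation axis
    (``pillar_radius_frac`` of the grid size; None disables) so projections
    at arbitrary angles see the full sample, as for a milled pillar.

    ``texture`` adds a smooth multiplicative random modulation (fractional
    amplitude) which gives volumes enough local structure for optical-flow
    fixtures; it defaults to off so density histograms stay strictly modal.
    """
    if np.isscalar(size_voxels):
        shape = (int(size_voxels),) * 3
    else:
        shape = tuple(int(s) for s in size_voxels)
    if min(shape) < 32:
        raise ValueError(f"phantom size {shape} too small; need >= 32 voxels per axis")
    dens_map = dict(DEFAULT_DENSITIES)
    if feature_densities is not None:
        dens_map.update(feature_densities)
    if any(v < 0 for v in dens_map.values()):
        raise ValueError("feature densities must be non-negative")

    rng = np.random.default_rng(rng_seed)
    labels = np.zeros(shape, dtype=np.int8)
    neurite_paths = []

    pillar_mask = None
    if pillar_radius_frac is not None:
        cy, cx = (shape[1] - 1) / 2.0, (shape[2] - 1) / 2.0
        yy, xx = np.mgrid[: shape[1], : shape[2]]
        radius = pillar_radius_frac * min(shape[1], shape[2])
        pillar_mask = (np.hypot(yy - cy, xx - cx) <= radius)[None, :, :]

    if dens_map["neurite"] > 0 and n_neurites > 0:
        for _ in range(n_neurites):
            path = _random_walk_tube(shape, rng, neurite_radius)
            neurite_paths.append(path)
            for p in path[::2]:
                _carve_ball(labels, p, (neurite_radius,) * 3, LABEL_NEURITE)

    if dens_map["nucleus"] > 0 and n_nuclei > 0:
        for _ in range(n_nuclei):
            c = rng.uniform(0.25, 0.75, 3) * np.asarray(shape)
            radii = rng.uniform(0.12, 0.2, 3) * np.asarray(shape)
            _carve_ball(labels, c, radii, LABEL_NUCLEUS)

    if dens_map["mitochondrion"] > 0 and n_mitochondria > 0:
        for _ in range(n_mitochondria):
            c = rng.uniform(4, np.asarray(shape) - 4)
            radii = rng.uniform(1.5, 3.5, 3)
            _carve_ball(labels, c, radii, LABEL_MITOCHONDRION)

    synapse_points = []
    if dens_map["synapse"] > 0 and n_synapses > 0:
        if not neurite_paths:
            raise ValueError("cannot place synapses without neurites (density or count is zero)")
        syn_radius = max(1.0, neurite_radius * 0.6)
        cy, cx = (shape[1] - 1) / 2.0, (shape[2] - 1) / 2.0
        r_max = (
            pillar_radius_frac * min(shape[1], shape[2]) - syn_radius - 1
            if pillar_radius_frac is not None
            else np.inf
        )
        for _ in range(n_synapses):
            path = neurite_paths[rng.integers(len(neurite_paths))]
            p = path[rng.integers(len(path))]
            offset = rng.standard_normal(3)
            offset /= np.linalg.norm(offset)
            c = p + offset * (neurite_radius + syn_radius * 0.5)
            c = np.clip(c, 1, np.asarray(shape) - 2)
            # keep puncta inside the pillar support
            rad = np.hypot(c[1] - cy, c[2] - cx)
            if rad > r_max:
                c[1] = cy + (c[1] - cy) * r_max / rad
                c[2] = cx + (c[2] - cx) * r_max / rad
            _carve_ball(labels, c, (syn_radius,) * 3, LABEL_SYNAPSE)
            # guarantee label support at the recorded point
            labels[tuple(np.round(c).astype(int))] = LABEL_SYNAPSE
            synapse_points.append(c * voxel_size_nm)
    synapses = np.asarray(synapse_points, dtype=float).reshape(-1, 3)

    lut = np.array(
        [
            dens_map["background"],
            dens_map["neurite"],
            dens_map["mitochondrion"],
            dens_map["nucleus"],
            dens_map["synapse"],
        ]
    )
    density = lut[labels]
    if texture > 0:
        noise = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
        noise /= max(np.abs(noise).max(), 1e-12)
        density = density * (1.0 + texture * noise)
    if pillar_mask is not None:
        density = density * pillar_mask
        labels = labels * pillar_mask
    density = np.ascontiguousarray(density, dtype=np.float64)

    return TissuePhantom(
        density=density,
        labels=labels,
        synapses=synapses,
        voxel_size=float(voxel_size_nm),
        rng_seed=int(rng_seed),
        params={
            "feature_densities": dens_map,
            "n_neurites": n_neurites,
            "n_mitochondria": n_mitochondria,
            "n_nuclei": n_nuclei,
            "n_synapses": n_synapses,
            "texture": texture,
        },
    )


# ---------------------------------------------------------------------------
# deformation


def make_deformation(
    control_times: Sequence[float],
    amplitude: float,
    smoothness: float,
    shape: tuple[int, int, int],
    rng_seed: int = 0,
) -> DeformationModel:
    """Smooth random displacement trajectory over dose fractions.

    The fields form a random walk in field space (low-pass filtered Gaussian
    increments), so deformation accumulates with dose.  The whole trajectory
    is rescaled so the maximum displacement norm over all control times equals
    ``amplitude`` exactly; the field at ``control_times[0]`` is zero.

    ``smoothness`` is the 1/e autocorrelation length of each field component
    in voxels (the Gaussian filter sigma is ``smoothness / 2``).
    """
    times = np.asarray(control_times, dtype=float)
    if times[0] != 0.0:
        raise ValueError("control_times must start at 0 (zero-deformation reference)")
    if np.any(np.diff(times) <= 0):
        raise ValueError("control_times must be strictly increasing")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")

    rng = np.random.default_rng(rng_seed)
    sigma = max(smoothness / 2.0, 1e-6)
    fields = [np.zeros((3,) + tuple(shape))]
    current = np.zeros((3,) + tuple(shape))
    for _ in times[1:]:
        incr = np.stack(
            [ndimage.gaussian_filter(rng.standard_normal(shape), sigma) for _ in range(3)]
        )
        current = current + incr
        fields.append(current.copy())

    if amplitude > 0 and len(fields) > 1:
        peak = max(np.sqrt((f ** 2).sum(axis=0)).max() for f in fields[1:])
        scale = amplitude / max(peak, 1e-30)
        fields = [f * scale for f in fields]
    elif amplitude == 0:
        fields = [np.zeros_like(f) for f in fields]

    return DeformationModel(
        control_fields=fields,
        control_times=times,
        amplitude=float(amplitude),
        smoothness=float(smoothness),
        rng_seed=int(rng_seed),
    )


# ---------------------------------------------------------------------------
# scan geometry


def fermat_spiral(n_points: int, step: float) -> np.ndarray:
    """Fermat-spiral scan positions with mean nearest-neighbour spacing ~ step.

    Point ``k`` sits at radius ``c * sqrt(k)`` and azimuth ``k * golden_angle``.
    For the golden-angle Fermat spiral the large-n mean nearest-neighbour
    distance approaches ``c * sqrt(pi)``-ish packing; rather than rely on the
    asymptotic constant we calibrate ``c`` numerically against the empirical
    mean nearest-neighbour distance at unit scale.

    Returns an ``(n_points, 2)`` array of (y, x) positions centred at 0.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if step <= 0:
        raise ValueError("step must be > 0")
    k = np.arange(n_points, dtype=float)
    r = np.sqrt(k)
    theta = k * GOLDEN_ANGLE
    pts = np.column_stack([r * np.sin(theta), r * np.cos(theta)])
    if n_points == 1:
        return pts * 0.0
    d = _mean_nn_distance(pts)
    return pts * (step / d)


def _mean_nn_distance(pts: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    return float(dists[:, 1].mean())


# ---------------------------------------------------------------------------
# annotator score fixtures


def make_score_array(
    n_regions: int,
    n_annotators: int,
    true_flags: Sequence[bool] | None = None,
    sensitivity: float = 0.9,
    specificity: float = 0.9,
    dropout_rate: float = 0.0,
    synapse_fraction: float = 0.4,
    region_extent_nm: float = 10_000.0,
    rng_seed: int = 0,
) -> ScoreArray:
    """Simulate confidence scores for the randomized-ROI detection task.

    For a region that truly contains a synapse an annotator gives a high score
    (3 or 4) with probability ``sensitivity`` per modality, otherwise a low
    score (1 or 2); for empty regions low scores come with probability
    ``specificity``.  Dropped responses are coded 0.
    """
    for name, v in [("sensitivity", sensitivity), ("specificity", specificity),
                    ("dropout_rate", dropout_rate)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    if true_flags is None:
        flags = rng.random(n_regions) < synapse_fraction
    else:
        flags = np.asarray(true_flags, dtype=bool)
        if flags.size != n_regions:
            raise ValueError("true_flags length must equal n_regions")

    scores = np.zeros((n_regions, n_annotators, 2), dtype=np.int8)
    for m in range(2):
        correct = rng.random((n_regions, n_annotators)) < np.where(
            flags[:, None], sensitivity, specificity
        )
        said_synapse = np.where(correct, flags[:, None], ~flags[:, None])
        hi = rng.integers(3, 5, size=(n_regions, n_annotators))
        lo = rng.integers(1, 3, size=(n_regions, n_annotators))
        scores[:, :, m] = np.where(said_synapse, hi, lo)
    drop = rng.random(scores.shape) < dropout_rate
    scores[drop] = 0

    centers = rng.uniform(0, region_extent_nm, size=(n_regions, 3))
    return ScoreArray(scores=scores, region_centers=centers, true_flags=flags)
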