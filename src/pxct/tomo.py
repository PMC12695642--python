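"""Tomographic reconstruction: alignment, filtered back projection and the
nonrigid (deformation-compensated) pipeline.

Nonrigid reconstruction follows the subtomogram strategy: the half-circle of
projections is split into interlaced angular subsets, each reconstructed as a
low-resolution snapshot of a contiguous dose window; dense 3D optical flow
between snapshots estimates the deformation, which is interpolated in time to
every projection and compensated during back projection (warp-accumulate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .forward import PhaseProjectionSet, warp_volume
from .phantom import DeformationModel

__all__ = [
    "Tomogram",
    "FlowField",
    "align_projections",
    "fbp",
    "split_subtomograms",
    "merge_subtomograms",
    "estimate_flow",
    "interpolate_flows",
    "invert_displacement",
    "nonrigid_reconstruct",
]

FILTERS = ("hann", "ramlak")


@dataclass
class Tomogram:
    volume: np.ndarray  # (z, y, x)
    voxel_size: float  # nm
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.volume)):
            raise ValueError("tomogram contains non-finite values")


@dataclass
class FlowField:
    displacement: np.ndarray  # (3, z, y, x) voxels
    pair: tuple[int, int] = (0, 0)
    pyramid_levels: int = 1

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("flow field contains non-finite values")


# ---------------------------------------------------------------------------
# projection filtering and back projection


def _ramp_response(size: int, filter_name: str) -> np.ndarray:
    """Frequency response of the discrete ramp (Ram-Lak) filter, optionally
    Hann windowed.  Uses the standard band-limited real-space kernel so the
    DC behaviour is correct."""
    n = np.concatenate(
        (
            np.arange(1, size / 2 + 1, 2, dtype=int),
            np.arange(size / 2 - 1, 0, -2, dtype=int),
        )
    )
    f = np.zeros(size)
    f[0] = 0.25
    f[1::2] = -1.0 / (np.pi * n) ** 2
    response = 2.0 * np.real(np.fft.fft(f))
    if filter_name == "hann":
        response *= np.fft.fftshift(np.hanning(size))
    elif filter_name != "ramlak":
        raise ValueError(f"unknown filter {filter_name!r}; choose from {FILTERS}")
    return response


def filter_projections(projections: np.ndarray, filter_name: str = "hann") -> np.ndarray:
    """Ramp-filter a stack of (n, Z, U) projections along the detector axis."""
    if filter_name not in FILTERS:
        raise ValueError(f"unknown filter {filter_name!r}; choose from {FILTERS}")
    n_u = projections.shape[-1]
    size = max(64, int(2 ** np.ceil(np.log2(2 * n_u))))
    response = _ramp_response(size, filter_name)
    padded = np.zeros(projections.shape[:-1] + (size,))
    padded[..., :n_u] = projections
    filtered = np.real(np.fft.ifft(np.fft.fft(padded, axis=-1) * response, axis=-1))
    return filtered[..., :n_u]


def backproject(filtered_proj: np.ndarray, angle_deg: float, n_x: int | None = None) -> np.ndarray:
    """Smear one filtered (Z, U) projection back through a (Z, Y, X) volume."""
    nz, nu = filtered_proj.shape
    ny = nu
    nx = ny if n_x is None else n_x
    theta = np.deg2rad(angle_deg)
    cy, cx, cu = (ny - 1) / 2.0, (nx - 1) / 2.0, (nu - 1) / 2.0
    y = np.arange(ny, dtype=float)[:, None] - cy
    x = np.arange(nx, dtype=float)[None, :] - cx
    u = cu + y * np.cos(theta) - x * np.sin(theta)
    u = np.clip(u, 0.0, nu - 1.0)
    u0 = np.floor(u).astype(int)
    u1 = np.minimum(u0 + 1, nu - 1)
    w = u - u0
    return filtered_proj[:, u0] * (1.0 - w) + filtered_proj[:, u1] * w


def fbp(
    projection_set: PhaseProjectionSet,
    filter: str = "hann",
) -> Tomogram:
    """Filtered back projection over the half-circle (rigid reconstruction)."""
    projs = projection_set.projections
    n = len(projs)
    if n == 0:
        raise ValueError("no projections to reconstruct")
    filtered = filter_projections(projs, filter)
    nz, nu = projs.shape[1:]
    vol = np.zeros((nz, nu, nu))
    for p, angle in zip(filtered, projection_set.angles):
        vol += backproject(p, angle)
    vol *= np.pi / (2.0 * n)
    return Tomogram(
        volume=vol,
        voxel_size=projection_set.pixel_size,
        provenance={
            "angles": np.sort(projection_set.angles).tolist(),
            "filter": filter,
            "mode": "rigid",
        },
    )


# ---------------------------------------------------------------------------
# projection alignment (simplified consistency approach)


def align_projections(
    projection_set: PhaseProjectionSet,
) -> tuple[PhaseProjectionSet, np.ndarray]:
    """Estimate and remove per-projection (z, u) shifts.

    Vertical shifts are recovered by cross-correlating each projection's
    mass profile along the rotation axis against the stack median profile
    (per-slice projected mass is invariant under rotation, so the profiles
    form a consistent reference even for objects that are not compact in z).
    Horizontal shifts come from the residual of a sinusoid fit to the
    in-plane centre of mass across angles (the centre of mass of a rotating
    rigid body traces ``A cos(theta) + B sin(theta) + C``).
    Returns the resampled set and the (n, 2) estimated shifts.
    """
    projs = projection_set.projections
    n = len(projs)
    if n < 3:
        raise ValueError("need at least 3 projections to align")
    weights = projs - projs.min(axis=(1, 2), keepdims=True)
    totals = weights.sum(axis=(1, 2))
    if np.any(totals <= 0):
        raise ValueError("degenerate (constant) projection encountered")
    nz, nu = projs.shape[1:]
    u_idx = np.arange(nu)[None, None, :]
    u_com = (weights * u_idx).sum(axis=(1, 2)) / totals

    profiles = weights.sum(axis=2)
    profiles = profiles - profiles.mean(axis=1, keepdims=True)
    reference = np.median(profiles, axis=0)
    dz = np.array([_profile_shift(p, reference, nz // 4) for p in profiles])
    dz -= dz.mean()
    theta = np.deg2rad(projection_set.angles)
    basis = np.column_stack([np.cos(theta), np.sin(theta), np.ones(n)])
    coef, *_ = np.linalg.lstsq(basis, u_com, rcond=None)
    du = u_com - basis @ coef

    shifts = np.column_stack([dz, du])
    shifted = np.empty_like(projs)
    for i in range(n):
        shifted[i] = ndimage.shift(projs[i], -shifts[i], order=1, mode="nearest")
    out = PhaseProjectionSet(
        projections=shifted,
        angles=projection_set.angles.copy(),
        times=projection_set.times.copy(),
        pixel_size=projection_set.pixel_size,
        per_projection_dose=projection_set.per_projection_dose,
        n_subtomos=projection_set.n_subtomos,
        meta=dict(projection_set.meta),
    )
    return out, shifts


def _profile_shift(profile: np.ndarray, reference: np.ndarray, max_shift: int) -> float:
    """Sub-sample shift of ``profile`` relative to ``reference`` (1D, parabola
    refinement of the cross-correlation peak)."""
    lags = np.arange(-max_shift, max_shift + 1)
    scores = np.empty(lags.size)
    for i, lag in enumerate(lags):
        # normalized correlation over the valid overlap only, so larger lags
        # are not penalized by lost samples
        if lag >= 0:
            a, b = profile[lag:], reference[: profile.size - lag]
        else:
            a, b = profile[:lag], reference[-lag:]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
        scores[i] = float((a @ b) / denom) if denom > 0 else 0.0
    k = int(np.argmax(scores))
    if 0 < k < lags.size - 1:
        denom = scores[k - 1] - 2 * scores[k] + scores[k + 1]
        if denom < 0:
            return float(lags[k] + 0.5 * (scores[k - 1] - scores[k + 1]) / denom)
    return float(lags[k])


# ---------------------------------------------------------------------------
# subtomogram splitting


def split_subtomograms(projection_set: PhaseProjectionSet, k: int) -> list[PhaseProjectionSet]:
    """Interlaced angular split into ``k`` sparse 0-180 degree subsets.

    Subtomogram ``j`` receives the projections whose sorted-angle index is
    congruent to ``j`` modulo ``k``; when the series was acquired with a
    matching interlace each subset covers a contiguous dose window while
    still spanning the full angular half-circle.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranks = np.argsort(np.argsort(projection_set.angles, kind="stable"), kind="stable")
    subsets = []
    for j in range(k):
        idx = np.nonzero(ranks % k == j)[0]
        sub = projection_set.subset(idx)
        sub.meta["parent_indices"] = idx
        sub.meta["subtomo_index"] = j
        subsets.append(sub)
    return subsets


def merge_subtomograms(subsets: list[PhaseProjectionSet]) -> PhaseProjectionSet:
    """Inverse of :func:`split_subtomograms` (restores original order/metadata)."""
    idx = np.concatenate([s.meta["parent_indices"] for s in subsets])
    order = np.argsort(idx)
    projections = np.concatenate([s.projections for s in subsets])[order]
    angles = np.concatenate([s.angles for s in subsets])[order]
    times = np.concatenate([s.times for s in subsets])[order]
    dose = None
    if subsets[0].per_projection_dose is not None:
        dose = np.concatenate([s.per_projection_dose for s in subsets])[order]
    meta = dict(subsets[0].meta)
    meta.pop("parent_indices", None)
    meta.pop("subtomo_index", None)
    return PhaseProjectionSet(
        projections=projections,
        angles=angles,
        times=times,
        pixel_size=subsets[0].pixel_size,
        per_projection_dose=dose,
        n_subtomos=len(subsets),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# 3D optical flow (multiresolution Horn-Schunck)


def _downsample(vol: np.ndarray) -> np.ndarray:
    smoothed = ndimage.gaussian_filter(vol, 1.0)
    return ndimage.zoom(smoothed, 0.5, order=1, prefilter=False)


def _zoom_volume(vol: np.ndarray, factor: float) -> np.ndarray:
    if factor < 1.0:
        vol = ndimage.gaussian_filter(vol, 0.5 / factor)
    return ndimage.zoom(vol, factor, order=1, prefilter=False)


def _upsample_flow(flow: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    factors = [t / s for t, s in zip(shape, flow.shape[1:])]
    out = np.stack(
        [ndimage.zoom(flow[c], factors, order=1, prefilter=False) for c in range(3)]
    )
    for c in range(3):
        out[c] *= factors[c]
    return out


def estimate_flow(
    volume_a: np.ndarray,
    volume_b: np.ndarray,
    pyramid_levels: int = 3,
    regularization: float = 0.5,
    n_iters: int = 60,
    n_warps: int = 3,
    boundary_margin: int = 2,
    presmooth: float = 0.0,
    pair: tuple[int, int] = (0, 1),
) -> FlowField:
    """Dense displacement from ``volume_a`` to ``volume_b``.

    Variational (Horn-Schunck style) estimation with a brightness-constancy
    data term and quadratic smoothness, solved coarse-to-fine with
    incremental warping.  The returned field ``F`` satisfies
    ``warp_volume(volume_a, F) ~= volume_b``, i.e. it uses the same material
    displacement convention as the deformation models in this package.
    """
    if volume_a.shape != volume_b.shape:
        raise ValueError("volumes must have identical shapes")
    a = np.asarray(volume_a, dtype=float)
    b = np.asarray(volume_b, dtype=float)
    if presmooth > 0:  # suppress streak/photon noise before differencing
        a = ndimage.gaussian_filter(a, presmooth)
        b = ndimage.gaussian_filter(b, presmooth)
    scale = a.std() + 1e-30
    offset = a.mean()
    a = (a - offset) / scale
    b = (b - offset) / scale

    pyr_a, pyr_b = [a], [b]
    for _ in range(pyramid_levels - 1):
        if min(pyr_a[-1].shape) < 12:
            break
        pyr_a.append(_downsample(pyr_a[-1]))
        pyr_b.append(_downsample(pyr_b[-1]))

    alpha2 = float(regularization) ** 2
    flow = np.zeros((3,) + pyr_a[-1].shape)
    for level in range(len(pyr_a) - 1, -1, -1):
        al, bl = pyr_a[level], pyr_b[level]
        if flow.shape[1:] != al.shape:
            flow = _upsample_flow(flow, al.shape)
        for _ in range(n_warps):
            aw = warp_volume(al, flow)
            gz, gy, gx = np.gradient((aw + bl) / 2.0)
            c = aw - bl
            g2 = gz * gz + gy * gy + gx * gx
            denom = alpha2 + g2
            dz = np.zeros_like(al)
            dy = np.zeros_like(al)
            dx = np.zeros_like(al)
            for _ in range(n_iters):
                mz = ndimage.uniform_filter(dz, 3)
                my = ndimage.uniform_filter(dy, 3)
                mx = ndimage.uniform_filter(dx, 3)
                r = (gz * mz + gy * my + gx * mx - c) / denom
                dz = mz - gz * r
                dy = my - gy * r
                dx = mx - gx * r
            flow = flow + np.stack([dz, dy, dx])

    if boundary_margin > 0:
        m = boundary_margin
        mask = np.zeros(a.shape, dtype=bool)
        mask[m:-m, m:-m, m:-m] = True
        flow *= mask
    return FlowField(displacement=flow, pair=pair, pyramid_levels=len(pyr_a))


def interpolate_flows(
    flow_nodes: list[np.ndarray | FlowField],
    node_times: np.ndarray,
    query_times: np.ndarray,
) -> list[np.ndarray]:
    """Componentwise piecewise-linear interpolation of flows in time.

    Queries outside the node range are clamped to the nearest node; node-time
    queries return the node field exactly.
    """
    fields = [f.displacement if isinstance(f, FlowField) else np.asarray(f) for f in flow_nodes]
    node_times = np.asarray(node_times, dtype=float)
    if len(fields) != node_times.size:
        raise ValueError("one node field per node time required")
    if len(fields) == 0:
        raise ValueError("need at least one flow node")
    if len(fields) > 1 and np.any(np.diff(node_times) <= 0):
        raise ValueError("node_times must be strictly increasing")
    out = []
    for t in np.atleast_1d(query_times):
        if len(fields) == 1 or t <= node_times[0]:
            out.append(fields[0].copy() if t <= node_times[0] else fields[-1].copy())
            continue
        if t >= node_times[-1]:
            out.append(fields[-1].copy())
            continue
        j = int(np.searchsorted(node_times, t, side="right"))
        t0, t1 = node_times[j - 1], node_times[j]
        w = (t - t0) / (t1 - t0)
        out.append((1.0 - w) * fields[j - 1] + w * fields[j])
    return out


def invert_displacement(
    displacement: np.ndarray, n_iter: int = 5, tol: float = 0.01
) -> np.ndarray:
    """Inverse displacement by fixed-point iteration.

    Solves ``e(y) = d(y + e(y))`` so that mapping by ``-e`` undoes the
    material displacement ``d`` to first order.
    """
    grid = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in displacement.shape[1:]], indexing="ij")
    )
    e = np.zeros_like(displacement)
    for _ in range(n_iter):
        coords = grid + e
        e_new = np.stack(
            [
                ndimage.map_coordinates(displacement[c], coords, order=1, mode="nearest")
                for c in range(3)
            ]
        )
        delta = np.max(np.abs(e_new - e))
        e = e_new
        if delta < tol:
            break
    return e


# ---------------------------------------------------------------------------
# nonrigid reconstruction


def nonrigid_reconstruct(
    projection_set: PhaseProjectionSet,
    k_subtomos: int = 4,
    n_outer_iters: int = 1,
    filter: str = "hann",
    true_deformation: DeformationModel | None = None,
    flow_params: dict | None = None,
    flow_downsample: int = 1,
) -> Tomogram:
    """Deformation-compensated reconstruction.

    Pipeline: (1) rigid FBP of each interlaced subtomogram; (2) 3D optical
    flow from the reference (first, lowest-dose) subtomogram to every other
    one; (3) temporal interpolation of the flows to every projection; (4)
    warp-accumulate back projection -- each filtered projection is back
    projected and the partial volume warped by the inverse of its flow before
    accumulation.  ``n_outer_iters > 1`` re-estimates the flows against the
    improved reconstruction.

    When ``true_deformation`` is supplied, flow estimation is skipped and the
    known fields are used directly (oracle mode).
    """
    projs = projection_set.projections
    n = len(projs)
    if n == 0:
        raise ValueError("no projections to reconstruct")
    if true_deformation is None and k_subtomos < 2:
        raise ValueError("k_subtomos must be >= 2 to estimate deformation")
    flow_params = dict(flow_params or {})

    filtered = filter_projections(projs, filter)
    times = projection_set.times

    if true_deformation is not None:
        node_times = true_deformation.control_times
        inv_nodes = [invert_displacement(f) for f in true_deformation.control_fields]
        per_proj_inverses = interpolate_flows(inv_nodes, node_times, times)
        volume = _warp_accumulate(filtered, projection_set.angles, per_proj_inverses)
        fields_id = "true"
    else:
        subsets = split_subtomograms(projection_set, k_subtomos)
        sub_vols = [fbp(s, filter).volume for s in subsets]
        node_times = np.array([float(s.times.mean()) for s in subsets])
        order = np.argsort(node_times)
        node_times = node_times[order]
        sub_vols = [sub_vols[i] for i in order]
        reference = sub_vols[0]
        full_shape = sub_vols[0].shape
        ds = max(int(flow_downsample), 1)
        for _ in range(max(n_outer_iters, 1)):
            inv_nodes = [np.zeros((3,) + full_shape)]
            ref_est = _zoom_volume(reference, 1.0 / ds) if ds > 1 else reference
            for j in range(1, len(sub_vols)):
                moving = _zoom_volume(sub_vols[j], 1.0 / ds) if ds > 1 else sub_vols[j]
                flow = estimate_flow(
                    ref_est, moving, pair=(0, j), **flow_params
                ).displacement
                if ds > 1:
                    flow = _upsample_flow(flow, full_shape)
                inv_nodes.append(invert_displacement(flow))
            per_proj_inverses = interpolate_flows(inv_nodes, node_times, times)
            volume = _warp_accumulate(filtered, projection_set.angles, per_proj_inverses)
            reference = volume
        fields_id = f"estimated(k={k_subtomos}, outer={n_outer_iters})"

    return Tomogram(
        volume=volume,
        voxel_size=projection_set.pixel_size,
        provenance={
            "angles": np.sort(projection_set.angles).tolist(),
            "filter": filter,
            "mode": "nonrigid",
            "deformation_fields": fields_id,
        },
    )


def _warp_accumulate(
    filtered: np.ndarray, angles: np.ndarray, per_proj_inverses: list[np.ndarray]
) -> np.ndarray:
    """Back-project each filtered projection and warp the partial volume back
    to the reference state by the (pre-inverted, time-interpolated)
    displacement before accumulating.  Inverse fields are computed at the
    deformation nodes and linearly interpolated in time, which matches the
    per-projection inverse to first order in the displacement."""
    n = len(filtered)
    nz, nu = filtered.shape[1:]
    vol = np.zeros((nz, nu, nu))
    for p, angle, e in zip(filtered, angles, per_proj_inverses):
        partial = backproject(p, angle)
        if np.any(e):
            partial = warp_volume(partial, -e)
        vol += partial
    vol *= np.pi / (2.0 * n)
    return vol
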