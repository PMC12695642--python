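"""Ptychographic phase retrieval: difference map and maximum-likelihood refinement.

The difference map alternates the overlap (factorization into probe and
object) and Fourier-magnitude projections; the refinement stage minimizes an
amplitude-domain Gaussian approximation of the photon likelihood with
nonlinear conjugate gradients and a backtracking line search, optionally with
multiple mutually incoherent probe modes.

Global phase offset and linear phase ramps are gauge freedoms of the model;
quality metrics must be computed after ramp alignment (`remove_phase_ramp`,
`phase_rms_error`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import DiffractionScan

__all__ = [
    "PtychoResult",
    "difference_map",
    "ml_refine",
    "remove_phase_ramp",
    "phase_rms_error",
    "phase_correlation",
    "default_probe",
]

_EPS = 1e-12


@dataclass
class PtychoResult:
    object_estimate: np.ndarray  # complex 2D
    probe_estimates: list[np.ndarray]  # >= 1 complex modes
    iterations_run: dict = field(default_factory=dict)
    data_error: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def probe(self) -> np.ndarray:
        return self.probe_estimates[0]


def default_probe(size: int, aperture_frac: float = 0.35) -> np.ndarray:
    """Circular-aperture probe propagated by an FFT (generic focused beam)."""
    y, x = np.mgrid[:size, :size] - (size - 1) / 2.0
    aperture = (np.hypot(y, x) <= aperture_frac * size / 2.0).astype(complex)
    probe = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(aperture)))
    return probe / np.sqrt((np.abs(probe) ** 2).sum() + _EPS)


def _patches(obj: np.ndarray, positions: np.ndarray, p: int) -> np.ndarray:
    return np.stack([obj[py:py + p, px:px + p] for py, px in positions])


def _accumulate(target: np.ndarray, positions: np.ndarray, patches: np.ndarray) -> None:
    p = patches.shape[-1]
    for (py, px), patch in zip(positions, patches):
        target[py:py + p, px:px + p] += patch


def _amplitude_error(psi: np.ndarray, amplitudes: np.ndarray) -> float:
    model = np.abs(np.fft.fft2(psi, norm="ortho"))
    return float(np.sqrt(np.mean((model - amplitudes) ** 2)))


def _overlap_update(psi, obj, probe, positions, n_inner=2, update_probe=True):
    p = probe.shape[0]
    for _ in range(n_inner):
        num = np.zeros_like(obj)
        den = np.zeros(obj.shape, dtype=float)
        conj_p = np.conj(probe)
        w = np.abs(probe) ** 2
        _accumulate(num, positions, conj_p[None] * psi)
        _accumulate(den, positions, np.broadcast_to(w, psi.shape).copy())
        obj = num / (den + 1e-8 * den.max() + _EPS)
        if update_probe:
            obj_patches = _patches(obj, positions, p)
            probe = (np.conj(obj_patches) * psi).sum(axis=0) / (
                (np.abs(obj_patches) ** 2).sum(axis=0) + _EPS
            )
    return obj, probe


def difference_map(
    scan: DiffractionScan,
    probe_init: np.ndarray | None = None,
    object_init: np.ndarray | None = None,
    n_iter: int = 300,
    object_shape: tuple[int, int] | None = None,
    update_probe: bool = True,
    probe_update_start: int = 20,
) -> PtychoResult:
    """Difference-map retrieval of complex object and probe from a scan.

    With ``n_iter = 0`` the initialization is returned unchanged.  The
    returned ``data_error`` history is the RMS Fourier-amplitude mismatch.
    The probe is held fixed for the first ``probe_update_start`` iterations
    so a noisy early object estimate cannot destabilize the joint update.
    """
    if len(scan.patterns) == 0:
        raise ValueError("empty scan")
    amplitudes = np.sqrt(scan.patterns)
    positions = scan.positions
    p = scan.detector_pixels
    if probe_init is None:
        probe_init = default_probe(p)
    probe = np.array(probe_init, dtype=complex)
    if object_init is None:
        if object_shape is None:
            object_shape = (
                int(positions[:, 0].max()) + p,
                int(positions[:, 1].max()) + p,
            )
        obj = np.ones(object_shape, dtype=complex)
    else:
        obj = np.array(object_init, dtype=complex)

    if n_iter == 0:
        return PtychoResult(obj, [probe], {"dm": 0}, np.empty(0))

    psi = probe[None] * _patches(obj, positions, p)
    errors = []
    for it in range(n_iter):
        do_probe = update_probe and it >= probe_update_start
        obj, probe = _overlap_update(psi, obj, probe, positions, update_probe=do_probe)
        psi_o = probe[None] * _patches(obj, positions, p)
        reflected = 2.0 * psi_o - psi
        f = np.fft.fft2(reflected, norm="ortho")
        f *= amplitudes / (np.abs(f) + _EPS)
        psi_f = np.fft.ifft2(f, norm="ortho")
        psi = psi + psi_f - psi_o
        errors.append(_amplitude_error(psi_o, amplitudes))
    obj, probe = _overlap_update(psi, obj, probe, positions, update_probe=update_probe)
    return PtychoResult(obj, [probe], {"dm": n_iter}, np.asarray(errors))


# ---------------------------------------------------------------------------
# maximum-likelihood refinement


def _ml_loss_grad(obj, probes, positions, amplitudes, want_grad=True):
    p = probes[0].shape[0]
    obj_patches = _patches(obj, positions, p)
    psi = np.stack([m[None] * obj_patches for m in probes])  # (M, n, p, p)
    f = np.fft.fft2(psi, norm="ortho")
    intensity = (np.abs(f) ** 2).sum(axis=0)
    model_amp = np.sqrt(intensity + _EPS)
    resid = model_amp - amplitudes
    loss = float((resid ** 2).sum())
    if not want_grad:
        return loss, None, None
    factor = resid / model_amp  # (n, p, p)
    chi = np.fft.ifft2(factor[None] * f, norm="ortho")
    grad_obj = np.zeros_like(obj)
    for m, probe in enumerate(probes):
        _accumulate(grad_obj, positions, np.conj(probe)[None] * chi[m])
    grad_probes = [
        (np.conj(obj_patches) * chi[m]).sum(axis=0) for m in range(len(probes))
    ]
    return loss, grad_obj, grad_probes


def _preconditioners(obj, probes, positions):
    """Illumination/object power maps used as a diagonal metric.

    Without this the probe block (touched by every pattern) dominates the
    joint gradient and the object barely moves.
    """
    p = probes[0].shape[0]
    illum = np.zeros(obj.shape, dtype=float)
    power = sum(np.abs(m) ** 2 for m in probes)
    _accumulate(illum, positions, np.broadcast_to(power, (len(positions), p, p)).copy())
    obj_patches = _patches(obj, positions, p)
    obj_power = (np.abs(obj_patches) ** 2).sum(axis=0)
    illum = illum + 0.05 * illum.max() + _EPS
    obj_power = obj_power + 0.05 * obj_power.max() + _EPS
    return illum, obj_power


def ml_refine(
    scan: DiffractionScan,
    warm_start: PtychoResult,
    n_iter: int = 200,
    n_probe_modes: int = 1,
    rng_seed: int = 0,
) -> PtychoResult:
    """Conjugate-gradient refinement of the amplitude (Gaussian) likelihood.

    Extra probe modes beyond the warm start are seeded as weak random
    perturbations of the primary mode (~1% power).  The line search only
    accepts decreasing steps, so the loss history is non-increasing.
    """
    if n_probe_modes < 1:
        raise ValueError("n_probe_modes must be >= 1")
    amplitudes = np.sqrt(scan.patterns)
    positions = scan.positions
    obj = np.array(warm_start.object_estimate, dtype=complex)
    probes = [np.array(m, dtype=complex) for m in warm_start.probe_estimates]
    rng = np.random.default_rng(rng_seed)
    while len(probes) < n_probe_modes:
        seed_mode = probes[0] * 0.1 * (
            rng.standard_normal(probes[0].shape)
            + 1j * rng.standard_normal(probes[0].shape)
        )
        probes.append(seed_mode)
    probes = probes[:n_probe_modes]

    loss, g_obj, g_probes = _ml_loss_grad(obj, probes, positions, amplitudes)
    illum, obj_power = _preconditioners(obj, probes, positions)
    pg_obj = g_obj / illum
    pg_probes = [g / obj_power for g in g_probes]
    d_obj, d_probes = -pg_obj, [-g for g in pg_probes]
    step = 1.0
    errors = []
    for it in range(n_iter):
        g_dot_d = _real_dot(g_obj, d_obj) + sum(
            _real_dot(g, d) for g, d in zip(g_probes, d_probes)
        )
        if g_dot_d >= 0:  # not a descent direction: restart
            d_obj, d_probes = -pg_obj, [-g for g in pg_probes]
            g_dot_d = _real_dot(g_obj, d_obj) + sum(
                _real_dot(g, d) for g, d in zip(g_probes, d_probes)
            )
        t = step
        accepted = False
        for _ in range(30):
            trial_obj = obj + t * d_obj
            trial_probes = [p + t * d for p, d in zip(probes, d_probes)]
            trial_loss, _, _ = _ml_loss_grad(
                trial_obj, trial_probes, positions, amplitudes, want_grad=False
            )
            if trial_loss <= loss + 1e-4 * t * g_dot_d:
                accepted = True
                break
            t *= 0.5
        if accepted:
            obj, probes = trial_obj, trial_probes
            step = min(t * 2.0, 1e3)
            new_loss, ng_obj, ng_probes = _ml_loss_grad(obj, probes, positions, amplitudes)
            if it % 10 == 9:  # refresh the metric occasionally
                illum, obj_power = _preconditioners(obj, probes, positions)
            npg_obj = ng_obj / illum
            npg_probes = [g / obj_power for g in ng_probes]
            # preconditioned Polak-Ribiere
            num = _real_dot(npg_obj, ng_obj - g_obj) + sum(
                _real_dot(npg, ng - g)
                for npg, ng, g in zip(npg_probes, ng_probes, g_probes)
            )
            den = _real_dot(pg_obj, g_obj) + sum(
                _real_dot(pg, g) for pg, g in zip(pg_probes, g_probes)
            )
            beta = max(num / (den + _EPS), 0.0)
            d_obj = -npg_obj + beta * d_obj
            d_probes = [-npg + beta * d for npg, d in zip(npg_probes, d_probes)]
            loss, g_obj, g_probes = new_loss, ng_obj, ng_probes
            pg_obj, pg_probes = npg_obj, npg_probes
        errors.append(np.sqrt(loss / amplitudes.size))

    iterations = dict(warm_start.iterations_run)
    iterations["ml"] = n_iter
    return PtychoResult(obj, probes, iterations, np.asarray(errors))


def _real_dot(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.real(np.vdot(a, b)))


def _norm2(a: np.ndarray) -> float:
    return float(np.real(np.vdot(a, a)))


# ---------------------------------------------------------------------------
# post-processing


def _plane_fit(image: np.ndarray, weights: np.ndarray | None = None):
    ny, nx = image.shape
    y, x = np.mgrid[:ny, :nx]
    basis = np.column_stack([np.ones(image.size), x.ravel(), y.ravel()])
    rhs = image.ravel()
    if weights is not None:
        w = np.sqrt(weights.ravel())
        coef, *_ = np.linalg.lstsq(basis * w[:, None], rhs * w, rcond=None)
    else:
        coef, *_ = np.linalg.lstsq(basis, rhs, rcond=None)
    return (coef[0] + coef[1] * x + coef[2] * y), coef


def remove_phase_ramp(phase_image: np.ndarray) -> np.ndarray:
    """Subtract the least-squares constant + linear phase components.

    The result has (numerically) zero mean and zero first moments, and the
    operation is idempotent.
    """
    phase_image = np.asarray(phase_image, dtype=float)
    if not np.all(np.isfinite(phase_image)):
        raise ValueError("phase image must be finite")
    plane, _ = _plane_fit(phase_image)
    return phase_image - plane


def phase_rms_error(
    recovered: np.ndarray, truth: np.ndarray, crop: int = 0
) -> float:
    """RMS phase discrepancy after removing the constant/linear gauge."""
    diff = np.angle(np.asarray(recovered, complex) * np.conj(np.asarray(truth, complex)))
    if crop:
        diff = diff[crop:-crop, crop:-crop]
    return float(np.sqrt(np.mean(remove_phase_ramp(diff) ** 2)))


def phase_correlation(recovered: np.ndarray, truth: np.ndarray, crop: int = 0) -> float:
    """Pearson correlation of ramp-aligned phases."""
    a = np.angle(np.asarray(recovered, complex))
    b = np.angle(np.asarray(truth, complex))
    if crop:
        a = a[crop:-crop, crop:-crop]
        b = b[crop:-crop, crop:-crop]
    a = remove_phase_ramp(a)
    b = remove_phase_ramp(b)
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0:
        return 1.0
    return float((a * b).sum() / denom)
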