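"""Resolution metrics: Fourier ring/shell correlation, information-bit
thresholds, split-half resolution workflow and the dose-resolution power law.

Resolution convention: curves are binned in shells one Fourier voxel wide;
the resolution is read at the first downward crossing of the threshold curve
(linear interpolation in frequency) and reported as half-pitch,
``voxel_size / (2 * f_crossing)`` with ``f_crossing`` in cycles/voxel.  If the
curve never crosses, the band limit ``2 * voxel_size`` is reported and the
curve is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .forward import PhaseProjectionSet

__all__ = [
    "FSCCurve",
    "DosePoint",
    "PowerLawFit",
    "frc",
    "fsc",
    "bit_threshold",
    "fsc_split_half",
    "fit_dose_resolution",
]


@dataclass
class FSCCurve:
    shell_freqs: np.ndarray  # cycles / voxel, bin centres
    correlation: np.ndarray
    n_per_shell: np.ndarray
    threshold: np.ndarray
    criterion: str  # "one_bit" | "half_bit"
    resolution_nm: float
    voxel_size: float
    crossed: bool = True
    snr: float = 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "freq": self.shell_freqs,
                "correlation": self.correlation,
                "threshold": self.threshold,
                "n": self.n_per_shell,
            }
        )


@dataclass
class DosePoint:
    dose: float  # Gy
    resolution: float  # nm
    series_id: str = ""
    mode: str = "rigid"  # rigid | nonrigid


@dataclass
class PowerLawFit:
    """resolution = a / dose**(1/4), slope fixed; 95% observational bounds."""

    a: float
    exponent: float
    sigma_log: float
    n_points: int
    t_quantile: float
    points: list = field(default_factory=list)

    def predict(self, dose: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(dose, float) ** (-self.exponent)

    def prediction_band(self, dose: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nonsimultaneous 95% observational bounds for a fresh point."""
        center = np.log(self.predict(dose))
        half = self.t_quantile * self.sigma_log * np.sqrt(1.0 + 1.0 / self.n_points)
        return np.exp(center - half), np.exp(center + half)


# ---------------------------------------------------------------------------
# shell machinery


def _soft_spherical_mask(shape, edge_frac: float = 0.05) -> np.ndarray:
    grids = [np.arange(s, dtype=float) - (s - 1) / 2.0 for s in shape]
    r = np.sqrt(sum((g / (s / 2.0)) ** 2 for g, s in zip(np.meshgrid(*grids, indexing="ij"), shape)))
    inner = 1.0 - edge_frac
    mask = np.clip((1.0 - r) / edge_frac, 0.0, 1.0)
    mask[r <= inner] = 1.0
    return 0.5 - 0.5 * np.cos(np.pi * mask)


def _shell_correlation(a: np.ndarray, b: np.ndarray, apodize: bool):
    if a.shape != b.shape:
        raise ValueError("inputs must have identical shapes")
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if apodize:
        mask = _soft_spherical_mask(a.shape)
        a = (a - a.mean()) * mask
        b = (b - b.mean()) * mask
    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    freqs = np.meshgrid(*[np.fft.fftfreq(s) for s in a.shape], indexing="ij")
    r = np.sqrt(sum(f ** 2 for f in freqs))
    n_half = min(a.shape) // 2
    # shells one Fourier voxel wide: shell s covers radius [s-0.5, s+0.5) voxels
    shell_idx = np.round(r * min(a.shape)).astype(int)
    shell_idx = np.minimum(shell_idx, n_half)
    num = np.bincount(shell_idx.ravel(), np.real(fa * np.conj(fb)).ravel(), n_half + 1)
    pa = np.bincount(shell_idx.ravel(), (np.abs(fa) ** 2).ravel(), n_half + 1)
    pb = np.bincount(shell_idx.ravel(), (np.abs(fb) ** 2).ravel(), n_half + 1)
    counts = np.bincount(shell_idx.ravel(), minlength=n_half + 1)
    corr = num / (np.sqrt(pa * pb) + 1e-300)
    shell_freqs = np.arange(n_half + 1) / min(a.shape)
    return shell_freqs, corr, counts


def bit_threshold(
    bits: float, n_per_shell: np.ndarray, normalization: str = "half"
) -> tuple[np.ndarray, float]:
    """Per-shell correlation threshold for an information criterion of ``bits``.

    The full-dataset SNR is ``2**bits - 1``; with ``normalization='half'`` the
    per-compared-image SNR (half of that) enters the threshold formula

        T_s = (SNR + 2 sqrt(SNR)/sqrt(n_s) + 1/sqrt(n_s))
              / (SNR + 2 sqrt(SNR)/sqrt(n_s) + 1)

    Returns the threshold curve and the SNR value used.
    """
    if bits <= 0:
        raise ValueError("bits must be > 0")
    n = np.maximum(np.asarray(n_per_shell, dtype=float), 1.0)
    snr_total = 2.0 ** bits - 1.0
    if normalization == "half":
        snr = snr_total / 2.0
    elif normalization == "full":
        snr = snr_total
    else:
        raise ValueError("normalization must be 'half' or 'full'")
    root = 2.0 * np.sqrt(snr) / np.sqrt(n)
    threshold = (snr + root + 1.0 / np.sqrt(n)) / (snr + root + 1.0)
    return threshold, snr


_CRITERIA = {
    # criterion -> (bits, normalization used in the threshold formula)
    "one_bit": (1.0, "half"),
    "half_bit": (0.5, "half"),
}


def _resolve(shell_freqs, corr, threshold, voxel_size):
    """First downward threshold crossing -> half-pitch resolution in nm."""
    diff = corr - threshold
    crossed = False
    f_cross = shell_freqs[-1]
    for s in range(1, len(diff)):  # DC shell excluded from the search
        if diff[s] < 0.0 and diff[s - 1] >= 0.0:
            f0, f1 = shell_freqs[s - 1], shell_freqs[s]
            d0, d1 = diff[s - 1], diff[s]
            f_cross = f0 + (f1 - f0) * d0 / (d0 - d1)
            crossed = True
            break
    if not crossed:
        return 2.0 * voxel_size, False
    # a crossing interpolated into the DC shell means no significant signal;
    # clamp to half the first shell frequency instead of dividing by zero
    f_cross = max(f_cross, 0.5 * shell_freqs[1])
    return voxel_size / (2.0 * f_cross), True


def _curve(a, b, criterion, voxel_size, apodize):
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {sorted(_CRITERIA)}")
    bits, normalization = _CRITERIA[criterion]
    shell_freqs, corr, counts = _shell_correlation(a, b, apodize)
    threshold, snr = bit_threshold(bits, counts, normalization)
    resolution, crossed = _resolve(shell_freqs, corr, threshold, voxel_size)
    return FSCCurve(
        shell_freqs=shell_freqs,
        correlation=corr,
        n_per_shell=counts,
        threshold=threshold,
        criterion=criterion,
        resolution_nm=resolution,
        voxel_size=voxel_size,
        crossed=crossed,
        snr=snr,
    )


def frc(
    image_a: np.ndarray,
    image_b: np.ndarray,
    criterion: str = "one_bit",
    pixel_size: float = 1.0,
    apodize: bool = True,
) -> FSCCurve:
    """2D Fourier ring correlation between two independent images."""
    if np.asarray(image_a).ndim != 2:
        raise ValueError("frc expects 2D images")
    return _curve(image_a, image_b, criterion, pixel_size, apodize)


def fsc(
    volume_a: np.ndarray,
    volume_b: np.ndarray,
    criterion: str = "half_bit",
    voxel_size: float = 1.0,
    apodize: bool = True,
) -> FSCCurve:
    """3D Fourier shell correlation between two independent volumes."""
    if np.asarray(volume_a).ndim != 3:
        raise ValueError("fsc expects 3D volumes")
    return _curve(volume_a, volume_b, criterion, voxel_size, apodize)


# ---------------------------------------------------------------------------
# split-half resolution workflow


def fsc_split_half(
    projection_set: PhaseProjectionSet,
    recon_config: dict | None = None,
    criterion: str = "half_bit",
) -> FSCCurve:
    """Split-half FSC resolution of a tomographic dataset.

    The projections are split by sorted-angle parity into two independently
    reconstructed halves (each with doubled angular spacing); the volumes are
    compared shell-wise and the threshold crossing converted to nm.

    ``recon_config`` keys: ``mode`` ("rigid"|"nonrigid"), ``filter``,
    ``k_subtomos``, ``n_outer_iters``, ``flow_params``, ``true_deformation``.
    """
    from . import tomo

    cfg = {"mode": "rigid", "filter": "hann"}
    cfg.update(recon_config or {})
    n = len(projection_set)
    if n < 8:
        raise ValueError("need at least 8 projections for a split-half FSC")

    ranks = np.argsort(np.argsort(projection_set.angles, kind="stable"), kind="stable")
    halves = []
    for parity in (0, 1):
        idx = np.nonzero(ranks % 2 == parity)[0]
        half = projection_set.subset(idx)
        if cfg["mode"] == "rigid":
            vol = tomo.fbp(half, cfg["filter"]).volume
        elif cfg["mode"] == "nonrigid":
            vol = tomo.nonrigid_reconstruct(
                half,
                k_subtomos=cfg.get("k_subtomos", 4),
                n_outer_iters=cfg.get("n_outer_iters", 1),
                filter=cfg["filter"],
                true_deformation=cfg.get("true_deformation"),
                flow_params=cfg.get("flow_params"),
                flow_downsample=cfg.get("flow_downsample", 1),
            ).volume
        else:
            raise ValueError("mode must be 'rigid' or 'nonrigid'")
        halves.append(vol)
    return fsc(
        halves[0], halves[1], criterion=criterion, voxel_size=projection_set.pixel_size
    )


# ---------------------------------------------------------------------------
# dose-resolution power law


def fit_dose_resolution(points: list[DosePoint] | np.ndarray) -> PowerLawFit:
    """Fit ``resolution = a / dose**(1/4)`` with the exponent held fixed.

    Least squares in log space reduces to the mean of
    ``log(res) + 1/4 log(dose)``; the 95% prediction band uses the residual
    variance with a Student-t quantile and nonsimultaneous observational
    bounds (variance inflated by ``1 + 1/n`` for a fresh point).
    """
    if isinstance(points, np.ndarray):
        pts = [DosePoint(dose=float(d), resolution=float(r)) for d, r in points]
    else:
        pts = list(points)
    doses = np.array([p.dose for p in pts], dtype=float)
    res = np.array([p.resolution for p in pts], dtype=float)
    if doses.size < 2 or np.unique(doses).size < 2:
        raise ValueError("need at least 2 points with distinct doses")
    if np.any(doses <= 0) or np.any(res <= 0):
        raise ValueError("doses and resolutions must be positive")
    exponent = 0.25
    log_a_samples = np.log(res) + exponent * np.log(doses)
    log_a = float(log_a_samples.mean())
    n = doses.size
    resid = log_a_samples - log_a
    dof = max(n - 1, 1)
    sigma = float(np.sqrt((resid ** 2).sum() / dof))
    t_q = float(stats.t.ppf(0.975, dof))
    return PowerLawFit(
        a=float(np.exp(log_a)),
        exponent=exponent,
        sigma_log=sigma,
        n_points=n,
        t_quantile=t_q,
        points=pts,
    )


def plot_dose_resolution(fit: PowerLawFit, path=None):
    """Log-log chart of dose points, fitted power law and 95% band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    doses = np.array([p.dose for p in fit.points])
    res = np.array([p.resolution for p in fit.points])
    grid = np.geomspace(doses.min() / 2, doses.max() * 2, 100)
    lo, hi = fit.prediction_band(grid)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.fill_between(grid, lo, hi, alpha=0.25, color="purple", label="95% prediction")
    ax.plot(grid, fit.predict(grid), color="gray", label=f"a={fit.a:.3g} / dose^1/4")
    ax.scatter(doses, res, s=18, zorder=3)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("resolution (nm)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
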