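"""Declarative experiment configuration with lossless JSON round trips."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["ExperimentConfig"]


@dataclass
class ExperimentConfig:
    """All knobs of a desk-scale experiment; every seed is explicit."""

    # phantom
    phantom_size: int = 64
    voxel_size_nm: float = 30.0
    n_synapses: int = 12
    texture: float = 0.3
    phantom_seed: int = 0
    # deformation
    deform_amplitude: float = 0.0
    deform_smoothness: float = 16.0
    deform_n_controls: int = 5
    deform_seed: int = 0
    # acquisition plan
    n_projections: int = 96
    n_subtomos: int = 4
    scan_step_um: float = 1.0
    exposure_s: float = 0.05
    flux: float = 7e8
    photon_energy_kev: float = 6.2
    photon_budgets: list[float] = field(default_factory=lambda: [1e4, 1.6e5])
    fraction_absorbed: float = 0.05
    electron_moles: float = 1e-12
    noise_seed: int = 0
    # reconstruction
    filter: str = "hann"
    mode: str = "rigid"  # rigid | nonrigid
    n_outer_iters: int = 1
    # metrics
    criterion: str = "half_bit"
    apodize: bool = True
    # captcha simulation
    n_regions: int = 250
    n_annotators: int = 3
    sensitivity: float = 0.85
    specificity: float = 0.9
    dropout_rate: float = 0.02
    min_xcorr: float = 0.4
    score_cut: float = 2.5
    n_bootstrap: int = 1000
    captcha_seed: int = 0
    # bookkeeping
    output_dir: str = "scratch/experiment"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        try:
            data = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed config {path}: line {exc.lineno}, col {exc.colno}") from exc
        return cls.from_dict(data)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
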