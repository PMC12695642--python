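"""I/O helpers: TIFF volumes with JSON sidecars, HDF5 projection containers,
CSV annotations and curves.  Units are normalized at the boundary (positions
and resolutions in nm, angles in degrees, dose in Gy)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .forward import PhaseProjectionSet
from .phantom import TissuePhantom
from .synapse import NodeAnnotation

__all__ = [
    "save_volume",
    "load_volume",
    "save_phantom",
    "load_phantom",
    "save_projection_set",
    "load_projection_set",
    "save_annotations_csv",
    "load_annotations_csv",
    "save_synapses_csv",
    "load_synapses_csv",
    "save_fsc_curve_csv",
]


def save_volume(path, volume: np.ndarray, voxel_size: float = 1.0, meta: dict | None = None):
    """Multi-page TIFF stack plus a JSON sidecar with voxel size and metadata."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(volume, dtype=np.float32))
    sidecar = {"voxel_size_nm": float(voxel_size), "shape": list(np.shape(volume))}
    sidecar.update(meta or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_volume(path) -> tuple[np.ndarray, dict]:
    import tifffile

    path = Path(path)
    volume = np.asarray(tifffile.imread(path))
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return volume, meta


def save_phantom(path, phantom: TissuePhantom):
    save_volume(
        path,
        phantom.density,
        phantom.voxel_size,
        {"rng_seed": phantom.rng_seed, "params": phantom.params},
    )
    save_synapses_csv(Path(path).with_suffix(".synapses.csv"), phantom.synapses)


def load_phantom(path) -> tuple[np.ndarray, dict, np.ndarray]:
    volume, meta = load_volume(path)
    syn_path = Path(path).with_suffix(".synapses.csv")
    synapses = load_synapses_csv(syn_path) if syn_path.exists() else np.empty((0, 3))
    return volume, meta, synapses


def save_projection_set(path, pset: PhaseProjectionSet):
    """Hierarchical container: /projections, /angles, /times, /dose, /meta."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("projections", data=pset.projections.astype(np.float32))
        f.create_dataset("angles", data=pset.angles)
        f.create_dataset("times", data=pset.times)
        if pset.per_projection_dose is not None:
            f.create_dataset("dose", data=pset.per_projection_dose)
        meta = f.create_group("meta")
        meta.attrs["pixel_size_nm"] = pset.pixel_size
        meta.attrs["n_subtomos"] = pset.n_subtomos
        meta.attrs["extra"] = json.dumps(pset.meta, default=str)


def load_projection_set(path) -> PhaseProjectionSet:
    import h5py

    try:
        with h5py.File(path, "r") as f:
            projections = np.asarray(f["projections"], dtype=float)
            angles = np.asarray(f["angles"])
            times = np.asarray(f["times"])
            dose = np.asarray(f["dose"]) if "dose" in f else None
            meta_grp = f["meta"]
            pixel_size = float(meta_grp.attrs["pixel_size_nm"])
            n_subtomos = int(meta_grp.attrs["n_subtomos"])
            extra = json.loads(meta_grp.attrs.get("extra", "{}"))
    except OSError as exc:
        raise ValueError(f"cannot parse projection container {path}: {exc}") from exc
    return PhaseProjectionSet(
        projections=projections,
        angles=angles,
        times=times,
        pixel_size=pixel_size,
        per_projection_dose=dose,
        n_subtomos=n_subtomos,
        meta=extra,
    )


# ---------------------------------------------------------------------------
# CSV


def save_synapses_csv(path, synapses_nm: np.ndarray):
    import pandas as pd

    synapses_nm = np.asarray(synapses_nm, dtype=float).reshape(-1, 3)
    df = pd.DataFrame(synapses_nm, columns=["z_nm", "y_nm", "x_nm"])
    df.insert(0, "id", np.arange(len(df)))
    df.to_csv(path, index=False)


def load_synapses_csv(path) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(path)
    return df[["z_nm", "y_nm", "x_nm"]].to_numpy(dtype=float)


_UNIT_FACTORS = {"nm": 1.0, "um": 1000.0, "µm": 1000.0}


def save_annotations_csv(path, nodes: list[NodeAnnotation]):
    import pandas as pd

    df = pd.DataFrame(
        {
            "z_nm": [n.position[0] for n in nodes],
            "y_nm": [n.position[1] for n in nodes],
            "x_nm": [n.position[2] for n in nodes],
            "pass": [n.pass_index for n in nodes],
            "annotator": [n.annotator_id for n in nodes],
            "modality": [n.modality for n in nodes],
            "dendrite": [n.dendrite_id for n in nodes],
        }
    )
    df.to_csv(path, index=False)


def load_annotations_csv(path) -> list[NodeAnnotation]:
    """Read node annotations; coordinate columns may be suffixed _nm or _um."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {}
    for axis in ("z", "y", "x"):
        for unit, factor in _UNIT_FACTORS.items():
            name = f"{axis}_{unit}"
            if name in df.columns:
                cols[axis] = df[name].to_numpy(dtype=float) * factor
                break
        else:
            raise ValueError(f"missing coordinate column for axis {axis!r} in {path}")
    nodes = []
    for i in range(len(df)):
        dendrite = df["dendrite"].iloc[i] if "dendrite" in df.columns else None
        if dendrite is not None and (isinstance(dendrite, float) and np.isnan(dendrite)):
            dendrite = None
        nodes.append(
            NodeAnnotation(
                position=(cols["z"][i], cols["y"][i], cols["x"][i]),
                pass_index=int(df["pass"].iloc[i]) if "pass" in df.columns else 1,
                annotator_id=str(df["annotator"].iloc[i]) if "annotator" in df.columns else "a0",
                modality=str(df["modality"].iloc[i]) if "modality" in df.columns else "em",
                dendrite_id=None if dendrite is None else int(dendrite),
            )
        )
    return nodes


def save_fsc_curve_csv(path, curve):
    curve.to_frame().to_csv(path, index=False)
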