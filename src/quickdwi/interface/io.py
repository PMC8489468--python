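"""NIfTI input/output and the on-disk layout of simulated stacks.

Single 2D/3D images go to plain ``.nii`` files (float32).  A full
acquired stack is exploded into one file per (b-value, direction,
acquisition) with the suffix convention ``<prefix>_b0900_d1_a2.nii``,
plus a JSON sidecar recording the acquisition protocol so the 5-axis
tensor can be reassembled exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from ..acquisition import AcquisitionProtocol, ClinicalImage, DWIStack

__all__ = [
    "read_nifti",
    "write_nifti",
    "write_stack",
    "read_stack",
    "write_clinical",
    "read_clinical",
    "write_ground_truth",
    "save_phantom_spec",
    "load_phantom_spec",
]


def write_nifti(image: np.ndarray, path: str | Path) -> Path:
    """Write a 2D or 3D array as float32 NIfTI (identity affine)."""
    image = np.asarray(image)
    if image.ndim > 3:
        raise ValueError(
            f"write_nifti supports <= 3 axes, got {image.ndim}; use write_stack"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(image.astype(np.float32), np.eye(4)), str(path))
    return path


def read_nifti(path: str | Path) -> np.ndarray:
    """Read a NIfTI file back as a float32 array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim > 3:
        raise ValueError(f"{path}: arrays with more than 3 axes are not supported here")
    return data


def write_ground_truth(gt, out_dir: str | Path) -> list[Path]:
    """Export GroundTruth as multi-file NIfTI (s0, adc, one roi per lesion)."""
    out_dir = Path(out_dir)
    paths = [
        write_nifti(gt.s0_map, out_dir / "s0.nii"),
        write_nifti(gt.adc_map, out_dir / "adc.nii"),
    ]
    if gt.adc_dir_maps is not None:
        for j in range(3):
            paths.append(write_nifti(gt.adc_dir_maps[j], out_dir / f"adc_dir{j}.nii"))
    for label, mask in gt.roi_masks.items():
        paths.append(write_nifti(mask.astype(np.float32), out_dir / f"roi_{label}.nii"))
    return paths


def save_phantom_spec(spec, path: str | Path) -> Path:
    """Serialize a PhantomSpec to YAML."""
    import yaml

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))
    return path


def load_phantom_spec(path: str | Path):
    import yaml

    from ..phantom import PhantomSpec

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such phantom spec: {path}")
    return PhantomSpec.from_dict(yaml.safe_load(path.read_text()))


def _protocol_dict(p: AcquisitionProtocol) -> dict:
    return dict(
        b_values=list(p.b_values),
        n_directions=p.n_directions,
        n_acquisitions=p.n_acquisitions,
        noise_sigma=p.noise_sigma,
        intensity_ceiling=p.intensity_ceiling,
        seed=p.seed,
    )


def _protocol_from_dict(d: dict) -> AcquisitionProtocol:
    return AcquisitionProtocol(
        b_values=tuple(d["b_values"]),
        n_directions=d["n_directions"],
        n_acquisitions=d["n_acquisitions"],
        noise_sigma=d["noise_sigma"],
        intensity_ceiling=d["intensity_ceiling"],
        seed=d["seed"],
    )


def _suffix(b: float, direction: int, acquisition: int) -> str:
    return f"b{int(round(b)):04d}_d{direction}_a{acquisition}"


def write_stack(stack: DWIStack, out_dir: str | Path, prefix: str = "dwi") -> list[Path]:
    """Explode a DWIStack into per-image NIfTIs plus a protocol sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    p = stack.protocol
    for ib, b in enumerate(p.b_values):
        for j in range(p.n_directions):
            for a in range(p.n_acquisitions):
                f = out_dir / f"{prefix}_{_suffix(b, j, a)}.nii"
                write_nifti(stack.data[ib, j, a], f)
                paths.append(f)
    sidecar = out_dir / f"{prefix}_protocol.json"
    sidecar.write_text(json.dumps(_protocol_dict(p), indent=2))
    paths.append(sidecar)
    return paths


def read_stack(in_dir: str | Path, prefix: str = "dwi") -> DWIStack:
    """Reassemble a DWIStack written by :func:`write_stack`."""
    in_dir = Path(in_dir)
    sidecar = in_dir / f"{prefix}_protocol.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"no protocol sidecar: {sidecar}")
    protocol = _protocol_from_dict(json.loads(sidecar.read_text()))
    first = read_nifti(in_dir / f"{prefix}_{_suffix(protocol.b_values[0], 0, 0)}.nii")
    data = np.empty(
        (len(protocol.b_values), protocol.n_directions, protocol.n_acquisitions)
        + first.shape
    )
    for ib, b in enumerate(protocol.b_values):
        for j in range(protocol.n_directions):
            for a in range(protocol.n_acquisitions):
                data[ib, j, a] = read_nifti(in_dir / f"{prefix}_{_suffix(b, j, a)}.nii")
    return DWIStack(data=data, protocol=protocol)


def write_clinical(clin: ClinicalImage, out_dir: str | Path, prefix: str = "clinical") -> list[Path]:
    """One NIfTI per b-value plus a sidecar with NOA and protocol."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ib, b in enumerate(clin.protocol.b_values):
        f = out_dir / f"{prefix}_b{int(round(b)):04d}.nii"
        write_nifti(clin.data[ib], f)
        paths.append(f)
    sidecar = out_dir / f"{prefix}_meta.json"
    sidecar.write_text(
        json.dumps(dict(noa=clin.noa, protocol=_protocol_dict(clin.protocol)), indent=2)
    )
    paths.append(sidecar)
    return paths


def read_clinical(in_dir: str | Path, prefix: str = "clinical") -> ClinicalImage:
    in_dir = Path(in_dir)
    sidecar = in_dir / f"{prefix}_meta.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"no clinical sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    protocol = _protocol_from_dict(meta["protocol"])
    imgs = [
        read_nifti(in_dir / f"{prefix}_b{int(round(b)):04d}.nii")
        for b in protocol.b_values
    ]
    return ClinicalImage(data=np.stack(imgs).astype(float), noa=meta["noa"], protocol=protocol)
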