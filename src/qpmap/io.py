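"""NIfTI volume I/O, protocol files, and run configuration.

Volumes are NIfTI-1 with RAS+ affines; all volumes of one subject share grid
and affine. Protocol files are YAML with PLDs in milliseconds (converted to
seconds here, the single conversion point) and physical constants defaulted
to the standard labeling values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .fitting import FitConfig, FitResult
from .model import AcquisitionSpec, Encode, PhysicalConstants

__all__ = [
    "Volume",
    "default_affine",
    "read_volume",
    "write_volume",
    "check_series",
    "load_protocol",
    "load_default_protocol",
    "write_fit_result",
]

_PROTOCOL_KEYS = {"delta_s", "epsilon", "lambda_ml_per_g", "r1a_per_s", "b_crush", "encodes"}
_ENCODE_KEYS = {"pld_ms", "b", "nex"}


@dataclass
class Volume:
    """3-D or 4-D array with its affine (NIfTI-1 semantics)."""

    data: np.ndarray
    affine: np.ndarray

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return tuple(float(v) for v in np.linalg.norm(self.affine[:3, :3], axis=0))


def default_affine(voxel_size=(1.9, 1.9, 4.0)) -> np.ndarray:
    """RAS+ affine with the given voxel size, centred at the origin."""
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def read_volume(path) -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected a 3-D or 4-D volume, got {data.ndim}-D")
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"{path}: affine is singular")
    return Volume(data=data, affine=affine)


def write_volume(v: Volume, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(v.data), v.affine), str(path))


def check_series(v: Volume, spec: AcquisitionSpec) -> None:
    """Require the 4-D series to have one frame per protocol encode."""
    if v.data.ndim != 4:
        raise ValueError(f"series must be 4-D, got {v.data.ndim}-D")
    if v.data.shape[-1] != len(spec):
        raise ValueError(
            f"series has {v.data.shape[-1]} frames but the protocol has "
            f"{len(spec)} encodes"
        )


def _spec_from_dict(doc: dict) -> AcquisitionSpec:
    unknown = set(doc) - _PROTOCOL_KEYS
    if unknown:
        raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
    if not doc.get("encodes"):
        raise ValueError("protocol must list at least one encode")
    constants = PhysicalConstants(
        delta=float(doc.get("delta_s", 1.5)),
        epsilon=float(doc.get("epsilon", 0.6)),
        lam=float(doc.get("lambda_ml_per_g", 0.9)),
        r1a=float(doc.get("r1a_per_s", 0.6)),
    )
    b_crush = float(doc.get("b_crush", 10.0))
    encodes = []
    for i, e in enumerate(doc["encodes"]):
        unknown = set(e) - _ENCODE_KEYS
        if unknown:
            raise ValueError(f"encode {i}: unknown keys {sorted(unknown)}")
        if "pld_ms" not in e:
            raise ValueError(f"encode {i}: missing pld_ms")
        pld_ms = float(e["pld_ms"])
        if pld_ms <= 0:
            raise ValueError(f"encode {i}: PLD must be positive, got {pld_ms} ms")
        b = float(e.get("b", 0.0))
        encodes.append(Encode(pld=pld_ms / 1000.0, b=b, nex=int(e.get("nex", 1)),
                              crush=b >= b_crush))
    return AcquisitionSpec(constants=constants, encodes=tuple(encodes))


def load_protocol(path) -> AcquisitionSpec:
    """Read an acquisition protocol from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: protocol file must be a mapping")
    return _spec_from_dict(doc)


def load_default_protocol() -> AcquisitionSpec:
    """The shipped 10-encode default protocol."""
    text = resources.files("qpmap").joinpath("data/protocol_default.yaml").read_text()
    return _spec_from_dict(yaml.safe_load(text))


def write_fit_result(res: FitResult, affine: np.ndarray, outdir,
                     cfg: FitConfig | None = None) -> dict:
    """Write kw/cbf/att maps plus a JSON sidecar; returns the sidecar dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, vol in (("kw", res.kw_map), ("cbf", res.cbf_map), ("att", res.att_map),
                      ("iterations", res.iterations.astype(np.int32)),
                      ("converged", res.converged.astype(np.uint8))):
        write_volume(Volume(vol, affine), outdir / f"{name}.nii.gz")
    sidecar = {
        "mu_used": res.mu_used,
        "n_converged": int(res.converged.sum()),
        "n_fitted": int((res.final_cost > 0).sum()),
        "config": None if cfg is None else {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg).items()
        },
    }
    (outdir / "fit.json").write_text(json.dumps(sidecar, indent=2))
    return sidecar
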