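"""File I/O: NIfTI-1 vector fields, long-format TSV tables, YAML config.

Grids are 0-based and row-major; coordinates in mm, times in ms. A
displacement field is written as one NIfTI-1 file per displacement
component (time as the 4th dimension; the affine carries the pixel
spacing and plane pose) plus a mask volume and a JSON sidecar with the
generating parameters -- or, alternatively, as a single long-format
delimited table.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .fields import DisplacementField

__all__ = [
    "AnalysisConfig",
    "write_displacement_nifti",
    "read_displacement_nifti",
    "write_displacement_tsv",
    "read_displacement_tsv",
    "write_strain_tsv",
    "write_provenance",
]

_COMPONENTS = ("ux", "uy", "uz")


@dataclass
class AnalysisConfig:
    """Pipeline configuration, parsed from a single YAML/JSON file."""

    smoothing_area_mm2: float = 20.0
    median_enabled: bool = True
    fourier_order: int = 5
    outlier_sd_mult: float = 2.0
    abs_strain_cap: float = 1.0
    moving_avg_cm: float = 1.0
    peak_window_ms: tuple[float, float] = (330.0, 450.0)
    ke_inplane: float = 0.80
    ke_throughplane: float = 0.93
    min_points: int = 10
    enforce_det: bool = True
    seed: int = 0
    extra: dict[str, Any] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("smoothing_area_mm2", "outlier_sd_mult", "abs_strain_cap",
                     "moving_avg_cm", "ke_inplane", "ke_throughplane"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.peak_window_ms = tuple(self.peak_window_ms)

    @classmethod
    def load(cls, path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def save(self, path) -> None:
        data = asdict(self)
        extra = data.pop("extra")
        data.update(extra)
        data["peak_window_ms"] = list(self.peak_window_ms)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _affine(field: DisplacementField) -> np.ndarray:
    """Affine mapping voxel (i, j) to mm position on the slice plane."""
    meta = field.metadata
    if "plane_axes" in meta:
        a1 = np.asarray(meta["plane_axes"][0], float)
        a2 = np.asarray(meta["plane_axes"][1], float)
    else:
        # infer from the position grid
        a1 = field.ref_positions[1, 0] - field.ref_positions[0, 0]
        a2 = field.ref_positions[0, 1] - field.ref_positions[0, 0]
        a1 = a1 / np.linalg.norm(a1)
        a2 = a2 / np.linalg.norm(a2)
    origin = field.ref_positions[0, 0]
    aff = np.eye(4)
    aff[:3, 0] = a1 * field.spacing
    aff[:3, 1] = a2 * field.spacing
    aff[:3, 2] = field.slice_normal
    aff[:3, 3] = origin
    return aff


def write_displacement_nifti(field: DisplacementField, prefix) -> list[Path]:
    """One NIfTI per component (+mask) plus a JSON sidecar; returns paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(field)
    written = []
    for c, name in enumerate(_COMPONENTS):
        vol = np.transpose(field.displacements[..., c], (1, 2, 0))[:, :, None, :]
        img = nib.Nifti1Image(np.nan_to_num(vol, nan=0.0).astype(np.float32), aff)
        path = prefix.with_name(prefix.name + f"_{name}.nii")
        nib.save(img, str(path))
        written.append(path)
    mask_img = nib.Nifti1Image(
        field.mask.astype(np.uint8)[:, :, None], aff
    )
    mask_path = prefix.with_name(prefix.name + "_mask.nii")
    nib.save(mask_img, str(mask_path))
    written.append(mask_path)
    sidecar = {
        "times_ms": field.times.tolist(),
        "spacing_mm": field.spacing,
        "slice_normal": field.slice_normal.tolist(),
        "metadata": _jsonable(field.metadata),
    }
    json_path = prefix.with_name(prefix.name + ".json")
    json_path.write_text(json.dumps(sidecar, indent=1))
    written.append(json_path)
    return written


def read_displacement_nifti(prefix) -> DisplacementField:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_name(prefix.name + ".json").read_text())
    vols = []
    for name in _COMPONENTS:
        img = nib.load(str(prefix.with_name(prefix.name + f"_{name}.nii")))
        vols.append(np.asarray(img.dataobj, dtype=float)[:, :, 0, :])
    aff = img.affine
    disp = np.stack(vols, axis=-1)  # (nr, nc, nt, 3)
    disp = np.transpose(disp, (2, 0, 1, 3))
    mask_img = nib.load(str(prefix.with_name(prefix.name + "_mask.nii")))
    mask = np.asarray(mask_img.dataobj) [:, :, 0].astype(bool)
    nr, nc = mask.shape
    ii, jj = np.mgrid[0:nr, 0:nc]
    voxels = np.stack([ii, jj, np.zeros_like(ii)], axis=-1).astype(float)
    pos = voxels @ aff[:3, :3].T + aff[:3, 3]
    return DisplacementField(
        ref_positions=pos,
        displacements=disp,
        mask=mask,
        spacing=float(sidecar["spacing_mm"]),
        slice_normal=np.asarray(sidecar["slice_normal"], float),
        times=np.asarray(sidecar["times_ms"], float),
        metadata=sidecar.get("metadata", {}),
    )


def write_displacement_tsv(field: DisplacementField, path) -> None:
    """Long-format table: i, j, t_ms, X, Y, Z, ux, uy, uz, mask."""
    nr, nc = field.grid_shape
    ii, jj = np.mgrid[0:nr, 0:nc]
    rows = []
    for it, t in enumerate(field.times):
        df = pd.DataFrame(
            {
                "i": ii.ravel(),
                "j": jj.ravel(),
                "t_ms": t,
                "X": field.ref_positions[..., 0].ravel(),
                "Y": field.ref_positions[..., 1].ravel(),
                "Z": field.ref_positions[..., 2].ravel(),
                "ux": field.displacements[it, ..., 0].ravel(),
                "uy": field.displacements[it, ..., 1].ravel(),
                "uz": field.displacements[it, ..., 2].ravel(),
                "mask": field.mask.ravel().astype(int),
            }
        )
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    header = (
        f"# spacing_mm={field.spacing!r} "
        f"slice_normal={field.slice_normal.tolist()!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        out.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_displacement_tsv(path) -> DisplacementField:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh, sep="\t")
    meta = {}
    for tok in header.lstrip("# ").split(" slice_normal="):
        tok = tok.strip()
        if tok.startswith("spacing_mm="):
            meta["spacing"] = float(eval(tok.split("=", 1)[1]))
        elif tok:
            meta["slice_normal"] = np.asarray(eval(tok), float)
    nr = int(df["i"].max()) + 1
    nc = int(df["j"].max()) + 1
    times = np.sort(df["t_ms"].unique())
    pos = np.full((nr, nc, 3), np.nan)
    mask = np.zeros((nr, nc), dtype=bool)
    disp = np.full((len(times), nr, nc, 3), np.nan)
    t_index = {t: k for k, t in enumerate(times)}
    i = df["i"].to_numpy()
    j = df["j"].to_numpy()
    k = df["t_ms"].map(t_index).to_numpy()
    pos[i, j] = df[["X", "Y", "Z"]].to_numpy()
    mask[i, j] = df["mask"].to_numpy().astype(bool)
    disp[k, i, j] = df[["ux", "uy", "uz"]].to_numpy()
    return DisplacementField(
        ref_positions=pos,
        displacements=disp,
        mask=mask,
        spacing=meta.get("spacing", 1.0),
        slice_normal=meta.get("slice_normal", np.array([0.0, 1.0, 0.0])),
        times=times,
    )


def write_strain_tsv(sf, path) -> None:
    """Long-format strain table: i, j, t_ms, six RCL components, voided."""
    from .strain import RCL_INDEX

    nr, nc = sf.mask.shape
    ii, jj = np.mgrid[0:nr, 0:nc]
    keep = sf.mask.ravel()
    data = {
        "i": ii.ravel()[keep],
        "j": jj.ravel()[keep],
        "t_ms": sf.t_ms,
    }
    for name, (a, b) in RCL_INDEX.items():
        data[name] = sf.E_rcl[..., a, b].ravel()[keep]
    data["voided"] = sf.voided.ravel()[keep].astype(int)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.17g")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_provenance(path, config: dict | None = None, seed: int | None = None,
                     **extra) -> None:
    """Machine-readable provenance record written alongside outputs."""
    import platform
    from importlib.metadata import version, PackageNotFoundError

    try:
        pkg_version = version("lvstrain")
    except PackageNotFoundError:
        pkg_version = "unknown"
    record = {
        "package": "lvstrain",
        "version": pkg_version,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": _jsonable(config or {}),
        "seed": seed,
    }
    record.update(_jsonable(extra))
    Path(path).write_text(json.dumps(record, indent=1))
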