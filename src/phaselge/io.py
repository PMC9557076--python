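"""On-disk formats.

Images and masks are NIfTI (nibabel); one 4D file per cardiac phase for
multi-TI stacks (rows x cols x 1 x TI), one 3D file per quantity for maps
and synthesized stacks (rows x cols x phases).  TI tables travel as CSV
sidecars (phase_index, ti_index, ti_ms) — inversion times are never
inferred from NIfTI headers.  Every directory gets a JSON sidecar with
layout and provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fitting import T1StarMaps
from .simulate import MultiTIStack
from .synthesis import SynthLGEStack

__all__ = [
    "save_stack", "load_stack",
    "save_maps", "load_maps",
    "save_synth", "load_synth",
    "save_mask", "load_mask",
    "write_ti_csv", "read_ti_csv",
]

_AFFINE = np.eye(4)


def _write_nii(path: Path, array: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(array, np.float64), _AFFINE), str(path))


def _read_nii(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_ti_csv(path, ti_ms: np.ndarray) -> None:
    n_p, n_t = ti_ms.shape
    pd.DataFrame(
        {
            "phase_index": np.repeat(np.arange(n_p), n_t),
            "ti_index": np.tile(np.arange(n_t), n_p),
            "ti_ms": ti_ms.ravel(),
        }
    ).to_csv(path, index=False)


def read_ti_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("phase_index", "ti_index", "ti_ms"):
        if col not in df.columns:
            raise ValueError(f"TI CSV missing column {col!r}")
    n_p = int(df["phase_index"].max()) + 1
    n_t = int(df["ti_index"].max()) + 1
    if len(df) != n_p * n_t:
        raise ValueError("TI CSV row count does not match phase/TI grid")
    ti = np.full((n_p, n_t), np.nan)
    ti[df["phase_index"], df["ti_index"]] = df["ti_ms"]
    if np.any(~np.isfinite(ti)):
        raise ValueError("TI CSV has missing (phase, ti) entries")
    return ti


def save_stack(stack: MultiTIStack, outdir, prefix: str = "stack") -> Path:
    """Write one 4D NIfTI per phase plus TI CSV and JSON sidecar; returns
    the sidecar path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for p in range(stack.n_phases):
        f = f"{prefix}_phase{p:03d}.nii"
        # rows x cols x 1 x TI, TI along the 4th axis
        _write_nii(outdir / f, np.moveaxis(stack.data[p], 0, -1)[:, :, None, :])
        files.append(f)
    write_ti_csv(outdir / f"{prefix}_ti.csv", stack.ti_ms)
    sidecar = outdir / f"{prefix}.json"
    sidecar.write_text(json.dumps({
        "layout": "one 4D file per phase, TI along axis 3",
        "files": files,
        "ti_csv": f"{prefix}_ti.csv",
        "n_phases": stack.n_phases,
        "n_ti": stack.n_ti,
        "meta": stack.meta,
    }, indent=2))
    return sidecar


def load_stack(sidecar_path) -> MultiTIStack:
    sidecar_path = Path(sidecar_path)
    info = json.loads(sidecar_path.read_text())
    root = sidecar_path.parent
    ti = read_ti_csv(root / info["ti_csv"])
    data = []
    for f in info["files"]:
        vol = _read_nii(root / f)  # rows x cols x 1 x TI
        data.append(np.moveaxis(vol[:, :, 0, :], -1, 0))
    arr = np.stack(data)
    if arr.shape[:2] != ti.shape:
        raise ValueError("TI CSV does not match image files (count mismatch)")
    return MultiTIStack(arr, ti, meta=info.get("meta", {}))


_MAP_NAMES = ("t1_star", "a", "sse", "polarity", "converged", "mask")


def save_maps(maps: T1StarMaps, outdir, prefix: str = "maps") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrays = {
        "t1_star": maps.t1_star_map,
        "a": maps.a_map,
        "sse": maps.sse_map,
        "polarity": maps.polarity_map.astype(float),
        "converged": maps.converged_map.astype(float),
    }
    for name, arr in arrays.items():
        _write_nii(outdir / f"{prefix}_{name}.nii", np.moveaxis(arr, 0, -1))
    _write_nii(outdir / f"{prefix}_mask.nii", maps.mask.astype(float))
    write_ti_csv(outdir / f"{prefix}_ti.csv", maps.ti_ms)
    sidecar = outdir / f"{prefix}.json"
    sidecar.write_text(json.dumps({
        "layout": "one 3D file per quantity, phase along axis 2",
        "quantities": list(_MAP_NAMES),
        "prefix": prefix,
        "ti_csv": f"{prefix}_ti.csv",
        "n_phases": maps.n_phases,
    }, indent=2))
    return sidecar


def load_maps(sidecar_path) -> T1StarMaps:
    sidecar_path = Path(sidecar_path)
    info = json.loads(sidecar_path.read_text())
    root, prefix = sidecar_path.parent, info["prefix"]

    def vol(name):
        return np.moveaxis(_read_nii(root / f"{prefix}_{name}.nii"), -1, 0)

    return T1StarMaps(
        a_map=vol("a"),
        t1_star_map=vol("t1_star"),
        sse_map=vol("sse"),
        polarity_map=vol("polarity").astype(int),
        converged_map=vol("converged").astype(bool),
        mask=_read_nii(root / f"{prefix}_mask.nii").astype(bool),
        ti_ms=read_ti_csv(root / info["ti_csv"]),
    )


def save_synth(synth: SynthLGEStack, outdir, prefix: str = "synth") -> Path:
    """Multi-frame NIfTI ordered by phase (cinematographic review) plus a
    JSON sidecar recording T_syn and provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_nii(outdir / f"{prefix}.nii", np.moveaxis(synth.data, 0, -1))
    sidecar = outdir / f"{prefix}.json"
    sidecar.write_text(json.dumps({
        "t_syn_ms": synth.t_syn_ms,
        "mode": synth.mode,
        "n_phases": synth.n_phases,
        "provenance": synth.provenance,
    }, indent=2))
    return sidecar


def load_synth(sidecar_path) -> SynthLGEStack:
    sidecar_path = Path(sidecar_path)
    info = json.loads(sidecar_path.read_text())
    prefix = sidecar_path.stem
    data = np.moveaxis(_read_nii(sidecar_path.parent / f"{prefix}.nii"), -1, 0)
    return SynthLGEStack(
        data=data,
        t_syn_ms=info["t_syn_ms"],
        mode=info["mode"],
        provenance=info.get("provenance", {}),
    )


def save_mask(mask: np.ndarray, path) -> None:
    _write_nii(Path(path), np.asarray(mask, bool).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    return _read_nii(Path(path)) > 0.5
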