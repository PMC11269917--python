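"""File I/O: HDF5 volumes, NIfTI maps, TSV waveforms, JSON reports.

HDF5 layout: ``/data`` (complex multi-echo array), ``/echo_times_s``, and
``/meta/*`` attributes carrying provenance (scheme, seeds, SNR,
normalization scale, config hash, package version).  Quantitative maps are
additionally exportable as NIfTI-1 with voxel spacing from the volume.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .girf import GradientWaveform
from .silico import MultiEchoVolume

__all__ = [
    "provenance",
    "save_volume_h5",
    "load_volume_h5",
    "save_maps_nifti",
    "save_report_json",
    "load_report_json",
    "save_waveform_tsv",
    "load_waveform_tsv",
]


def _package_version() -> str:
    from . import __version__

    return __version__


def provenance(config: dict | None = None, seed: int | None = None) -> dict:
    """Provenance block: deterministic config hash, seed, package version."""
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "config_hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
        "seed": seed,
        "package_version": _package_version(),
    }


def save_volume_h5(path, vol: MultiEchoVolume, config: dict | None = None,
                   seed: int | None = None) -> None:
    meta = dict(vol.meta)
    meta.update(provenance(config, seed))
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=vol.data.astype(np.complex128))
        f.create_dataset("echo_times_s", data=vol.echo_times_s)
        f.create_dataset("voxel_size_mm", data=np.asarray(vol.voxel_size_mm, float))
        g = f.create_group("meta")
        for k, v in meta.items():
            if v is None:
                continue
            if isinstance(v, (list, tuple, np.ndarray)):
                g.create_dataset(k, data=np.asarray(v))
            else:
                g.attrs[k] = v


def load_volume_h5(path) -> MultiEchoVolume:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        te = f["echo_times_s"][()]
        vox = tuple(f["voxel_size_mm"][()]) if "voxel_size_mm" in f else (1.5, 1.5, 1.5)
        meta = {}
        if "meta" in f:
            meta.update({k: _from_h5(v) for k, v in f["meta"].attrs.items()})
            for k in f["meta"]:
                meta[k] = f["meta"][k][()].tolist()
    return MultiEchoVolume(data, te, vox, meta)


def _from_h5(v):
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.generic):
        return v.item()
    return v


def save_maps_nifti(prefix, result, voxel_size_mm=(1.5, 1.5, 1.5)) -> list[str]:
    """Write PDFF/R2*/B0/residual maps as NIfTI-1 files ``<prefix>_<name>.nii``."""
    prefix = str(prefix)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    written = []
    for name, arr in (
        ("pdff", result.pdff_map),
        ("r2star", result.r2star_map),
        ("b0", result.f0_map),
        ("residual", result.residual_map),
    ):
        p = f"{prefix}_{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(arr, np.float32), affine), p)
        written.append(p)
    return written


def save_report_json(path, report: dict, config: dict | None = None,
                     seed: int | None = None) -> None:
    out = {"provenance": provenance(config, seed)}
    out.update(_jsonable(report))
    Path(path).write_text(json.dumps(out, indent=2))


def load_report_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_waveform_tsv(path, wave: GradientWaveform) -> None:
    """TSV columns: time_s then one gradient column (mT/m) per axis."""
    header = "time_s\t" + "\t".join(f"G{a}_mT_m" for a in wave.axes)
    table = np.column_stack([wave.times()] + list(wave.samples))
    np.savetxt(path, table, delimiter="\t", header=header, comments="")


def load_waveform_tsv(path) -> GradientWaveform:
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
    table = np.loadtxt(path, delimiter="\t", skiprows=1)
    table = np.atleast_2d(table)
    t = table[:, 0]
    dt = float(np.mean(np.diff(t))) if t.size > 1 else 1e-5
    axes = tuple(h.split("_")[0][1:] for h in header[1:])
    return GradientWaveform(dt, table[:, 1:].T, axes)
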