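"""Readers/writers for the study's on-disk formats.

NIfTI volumes (LGE intensities, ROI masks), CSV contour tables, multi-page
16-bit TIFF movies with a JSON acquisition sidecar, CSV mapping points plus
OFF/PLY meshes, and long-format histology CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cmr import LGEVolume, WallContours
from .eam import EAMStudy
from .optical import OpticalRecording

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_contours_csv",
    "load_contours_csv",
    "save_optical_tiff",
    "load_optical_tiff",
    "save_eam",
    "load_eam",
    "save_histology_csv",
    "load_histology_csv",
]


def save_nifti(volume: LGEVolume, path) -> None:
    import nibabel as nib

    affine = np.diag([*volume.voxel_size, 1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))


def load_nifti(path) -> LGEVolume:
    import nibabel as nib

    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LGEVolume(np.asarray(img.dataobj, dtype=float), voxel_size)


def load_nifti_mask(path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).dataobj) > 0.5


def save_contours_csv(contours: WallContours, path) -> None:
    contours.to_dataframe().to_csv(path, index=False)


def load_contours_csv(path) -> WallContours:
    return WallContours.from_dataframe(pd.read_csv(path))


def save_optical_tiff(rec: OpticalRecording, tiff_path, sidecar_path) -> None:
    import tifffile

    frames = np.clip(np.rint(rec.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(tiff_path), frames, photometric="minisblack")
    sidecar = {
        "frame_interval_ms": rec.frame_interval,
        "pixel_size_mm": rec.pixel_size,
        "stimulus_times_ms": list(map(float, rec.stimulus_times)),
        "cycle_length_ms": rec.cycle_length,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def load_optical_tiff(tiff_path, sidecar_path) -> OpticalRecording:
    import tifffile

    frames = tifffile.imread(str(tiff_path))
    meta = json.loads(Path(sidecar_path).read_text())
    return OpticalRecording(
        frames=frames,
        frame_interval=float(meta["frame_interval_ms"]),
        pixel_size=float(meta["pixel_size_mm"]),
        stimulus_times=np.asarray(meta["stimulus_times_ms"], dtype=float),
        cycle_length=float(meta["cycle_length_ms"]),
    )


def save_eam(study: EAMStudy, points_path, mesh_path) -> None:
    import trimesh

    pd.DataFrame(
        {
            "x_mm": study.points[:, 0],
            "y_mm": study.points[:, 1],
            "z_mm": study.points[:, 2],
            "bipolar_mV": study.amplitudes,
        }
    ).to_csv(points_path, index=False)
    mesh = trimesh.Trimesh(vertices=study.vertices, faces=study.faces, process=False)
    mesh.export(str(mesh_path))


def load_eam(points_path, mesh_path, fill_threshold: float = 5.0) -> EAMStudy:
    import trimesh

    df = pd.read_csv(points_path)
    mesh = trimesh.load(str(mesh_path), process=False)
    return EAMStudy(
        points=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        amplitudes=df["bipolar_mV"].to_numpy(),
        vertices=np.asarray(mesh.vertices),
        faces=np.asarray(mesh.faces),
        fill_threshold=fill_threshold,
    )


def save_histology_csv(sections: pd.DataFrame, path) -> None:
    sections.to_csv(path, index=False)


def load_histology_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
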