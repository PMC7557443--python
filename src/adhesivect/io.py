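"""Reading and writing of volumes, masks and tabular artifacts.

Volumes travel as multi-page TIFF stacks (page = depth slice) or MetaImage
``.mha`` files; the isotropic voxel size in mm is recorded in the TIFF
resolution tags / MetaImage spacing and recovered at load time. Masks are
8-bit TIFFs (255 = adhesive). Width tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from .volume import AdhesiveMask, ThicknessMap, Volume3D

_MM_PER_CM = 10.0


def write_volume(path: str | Path, volume: Volume3D) -> None:
    path = Path(path)
    if path.suffix.lower() == ".mha":
        img = sitk.GetImageFromArray(np.asarray(volume.voxels))
        img.SetSpacing((volume.voxel_size,) * 3)
        sitk.WriteImage(img, str(path))
    else:
        # TIFF resolution tags are pixels per unit; store pixels/cm.
        ppcm = _MM_PER_CM / volume.voxel_size
        tifffile.imwrite(
            path,
            np.asarray(volume.voxels),
            resolution=(ppcm, ppcm),
            resolutionunit="CENTIMETER",
            metadata={"voxel_size_mm": volume.voxel_size, "axes": "ZYX"},
        )


def read_volume(path: str | Path) -> Volume3D:
    path = Path(path)
    if path.suffix.lower() == ".mha":
        img = sitk.ReadImage(str(path))
        spacing = img.GetSpacing()
        if not np.allclose(spacing, spacing[0], rtol=1e-6):
            raise ValueError(f"anisotropic voxels not supported: {spacing}")
        return Volume3D(sitk.GetArrayFromImage(img), float(spacing[0]))
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        vs = _voxel_size_from_tiff(tif)
    if data.ndim == 2:
        data = data[None]
    return Volume3D(data, vs)


def _voxel_size_from_tiff(tif: tifffile.TiffFile) -> float:
    meta = tif.shaped_metadata or tif.imagej_metadata
    if meta:
        entries = meta if isinstance(meta, (list, tuple)) else [meta]
        for entry in entries:
            if isinstance(entry, dict) and "voxel_size_mm" in entry:
                return float(entry["voxel_size_mm"])
    page = tif.pages[0]
    res = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if res is not None and unit is not None and unit.value == 3:  # centimetre
        num, den = res.value
        return _MM_PER_CM * den / num
    raise ValueError("TIFF lacks voxel size metadata (voxel_size_mm or cm resolution)")


def write_mask(path: str | Path, mask: AdhesiveMask) -> None:
    vol = Volume3D(mask.mask.astype(np.uint8) * 255, mask.voxel_size)
    write_volume(path, vol)


def read_mask(path: str | Path) -> AdhesiveMask:
    vol = read_volume(path)
    return AdhesiveMask(vol.voxels > 0, vol.voxel_size)


def write_thickness_map(path: str | Path, tmap: ThicknessMap) -> None:
    vol = Volume3D(tmap.values.astype(np.float32), tmap.voxel_size)
    write_volume(path, vol)


def read_thickness_map(path: str | Path) -> ThicknessMap:
    vol = read_volume(path)
    return ThicknessMap(vol.voxels.astype(np.float64), vol.voxel_size)


def write_width_records_csv(path: str | Path, records) -> None:
    """Width records to CSV with header group,sample,area,method,width_mm."""
    rows = [
        {
            "group": r.group,
            "sample": r.sample,
            "area": r.area,
            "method": r.method,
            "width_mm": r.width,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_width_records_csv(path: str | Path):
    from .stats import WidthRecord

    df = pd.read_csv(path)
    return [
        WidthRecord(
            group=int(row.group),
            sample=int(row.sample),
            area=str(row.area),
            method=str(row.method),
            width=float(row.width_mm),
        )
        for row in df.itertuples()
    ]


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
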