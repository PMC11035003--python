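"""Reading and writing ADC maps and ROI masks.

Two on-disk formats are supported:

* NIfTI (``.nii`` / ``.nii.gz``) via nibabel, float32 pixels in
  10^-3 mm^2/s, pixel spacing in the affine (default).
* 16-bit PNG plus a JSON sidecar (``<name>.json``) holding the pixel
  spacing (mm) and the intensity scale factor mapping stored integers
  back to 10^-3 mm^2/s.

Masks use the same container with 0/1 values.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .features import ADCMap, ROIMask


def write_adc_map(path: str | Path, pixels: np.ndarray,
                  spacing: tuple[float, float] = (1.0, 1.0)) -> None:
    path = Path(path)
    pixels = np.asarray(pixels, dtype=np.float32)
    if path.suffix == ".png":
        peak = float(pixels.max())
        scale = (65535.0 / peak) if peak > 0 else 1.0
        img = np.round(pixels * scale).astype(np.uint16)
        Image.fromarray(img).save(path)
        sidecar = {"spacing_mm": list(spacing), "scale_to_units": 1.0 / scale}
        path.with_suffix(".json").write_text(json.dumps(sidecar))
    else:
        affine = np.diag([spacing[0], spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(pixels, affine), str(path))


def read_adc_map(path: str | Path, patient_id: str = "",
                 timepoint: str = "pre") -> ADCMap:
    path = Path(path)
    if path.suffix == ".png":
        img = np.asarray(Image.open(path), dtype=float)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        pixels = img * sidecar["scale_to_units"]
        spacing = tuple(sidecar["spacing_mm"])
    else:
        nii = nib.load(str(path))
        pixels = np.asarray(nii.dataobj, dtype=float)
        if pixels.ndim == 3 and pixels.shape[2] == 1:
            pixels = pixels[:, :, 0]
        zooms = nii.header.get_zooms()
        spacing = (float(zooms[0]), float(zooms[1]))
    return ADCMap(pixels=pixels, spacing=spacing,
                  patient_id=patient_id, timepoint=timepoint)


def write_mask(path: str | Path, mask: np.ndarray,
               spacing: tuple[float, float] = (1.0, 1.0)) -> None:
    path = Path(path)
    arr = np.asarray(mask).astype(np.uint8)
    if path.suffix == ".png":
        Image.fromarray(arr * 255, mode="L").save(path)
    else:
        affine = np.diag([spacing[0], spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(arr, affine), str(path))


def read_mask(path: str | Path, reader_id: str = "reader1") -> ROIMask:
    path = Path(path)
    if path.suffix == ".png":
        arr = np.asarray(Image.open(path)) > 0
    else:
        arr = np.asarray(nib.load(str(path)).dataobj)
        if arr.ndim == 3 and arr.shape[2] == 1:
            arr = arr[:, :, 0]
        arr = arr > 0
    return ROIMask(mask=arr, reader_id=reader_id)
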