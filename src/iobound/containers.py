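"""On-disk containers: HDF5 ensembles and k-space files, NIfTI import.

Ensemble files hold ``images`` (N, H, W), optional ``masks`` (N, H, W,
bool) and the attribute ``pixel_size_mm``.  K-space files hold ``kspace``
(N, C, H, W, complex), ``mask`` (the phase-encode line selector),
``label`` (0 = H0, 1 = H1, -1 = unknown) and the attrs ``sigma`` and ``R``
— naming inspired by ISMRMRD raw-data conventions.
"""

from __future__ import annotations

from typing import Optional, Sequence

import h5py
import numpy as np

from .phantoms import ObjectImage
from .sense import KspaceData, SamplingMask

__all__ = ["save_ensemble", "load_ensemble", "save_kspace", "load_kspace",
           "load_nifti_ensemble"]

_LABEL_TO_INT = {"H0": 0, "H1": 1, "unknown": -1}
_INT_TO_LABEL = {v: k for k, v in _LABEL_TO_INT.items()}


def save_ensemble(path: str, images: Sequence[ObjectImage]) -> None:
    """Write a list of objects (and their masks, when present) to HDF5."""
    pixels = np.stack([im.pixels for im in images])
    has_masks = all(im.tissue_mask is not None for im in images)
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=pixels)
        if has_masks:
            f.create_dataset("masks",
                             data=np.stack([im.tissue_mask for im in images]))
        f.attrs["pixel_size_mm"] = images[0].pixel_size_mm


def load_ensemble(path: str) -> list[ObjectImage]:
    with h5py.File(path, "r") as f:
        pixels = f["images"][...]
        masks = f["masks"][...] if "masks" in f else None
        pixel_size = float(f.attrs.get("pixel_size_mm", 1.0))
    return [ObjectImage(pixels[i], pixel_size_mm=pixel_size,
                        tissue_mask=None if masks is None else masks[i])
            for i in range(pixels.shape[0])]


def save_kspace(path: str, data: Sequence[KspaceData]) -> None:
    samples = np.stack([d.samples for d in data])
    labels = np.array([_LABEL_TO_INT[d.hypothesis_label] for d in data])
    mask = data[0].mask
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=samples)
        f.create_dataset("mask", data=mask.line_selector)
        f.create_dataset("label", data=labels)
        f.attrs["sigma"] = data[0].noise_sigma
        f.attrs["R"] = mask.acceleration
        f.attrs["offset"] = mask.offset
        f.attrs["center_fraction"] = mask.center_fraction


def load_kspace(path: str) -> list[KspaceData]:
    with h5py.File(path, "r") as f:
        samples = f["kspace"][...]
        selector = f["mask"][...].astype(bool)
        labels = f["label"][...]
        sigma = float(f.attrs["sigma"])
        mask = SamplingMask(selector, acceleration=float(f.attrs["R"]),
                            offset=int(f.attrs.get("offset", 0)),
                            center_fraction=float(
                                f.attrs.get("center_fraction", 0.0)))
    return [KspaceData(samples[i], mask=mask,
                       hypothesis_label=_INT_TO_LABEL[int(labels[i])],
                       noise_sigma=sigma)
            for i in range(samples.shape[0])]


def load_nifti_ensemble(path: str, pixel_size_mm: Optional[float] = None
                        ) -> list[ObjectImage]:
    """Import a user-supplied NIfTI volume as a 2-D image ensemble.

    A 3-D volume is split along its last axis into 2-D slices; pixel size
    defaults to the NIfTI in-plane voxel size.
    """
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj).squeeze()
    if pixel_size_mm is None:
        pixel_size_mm = float(img.header.get_zooms()[0])
    if data.ndim == 2:
        data = data[..., None]
    if data.ndim != 3:
        raise ValueError("expected a 2-D image or a 3-D stack of slices")
    return [ObjectImage(np.asarray(data[..., i], dtype=float),
                        pixel_size_mm=pixel_size_mm)
            for i in range(data.shape[-1])]
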