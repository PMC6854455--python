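"""NIfTI and tabular I/O for confidence-set analyses.

Voxel coordinates are 0-based array indices; affines from the input
headers are carried through untouched (the method is lattice-native, no
resampling).  Binary masks are written as unsigned 8-bit, floating
outputs as 32-bit.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .confidence_sets import ConfidenceSets
from .glm import DesignSpec
from .lattice import FieldLattice


def read_image_stack(
    paths: str | Path | Sequence[str | Path],
    mask_path: str | Path | None = None,
):
    """Read subject images: a list of 3D volumes or one 4D volume.

    The observation mask is the user mask (if given) intersected with the
    conjunction of finite-value masks of all subjects.

    Returns
    -------
    data : ndarray, shape (N, ...)
    mask : boolean ndarray
    affine : ndarray (4, 4)
    """
    if isinstance(paths, (str, Path)):
        img = nib.load(str(paths))
        arr = np.asarray(img.dataobj, dtype=float)
        if arr.ndim != 4:
            raise ValueError(f"{paths}: expected a 4D volume, got {arr.ndim}D")
        data = np.moveaxis(arr, -1, 0)
        affine = img.affine
    else:
        imgs = [nib.load(str(p)) for p in paths]
        shapes = {im.shape for im in imgs}
        if len(shapes) > 1:
            raise ValueError(f"subject images differ in shape: {sorted(shapes)}")
        affines = np.stack([im.affine for im in imgs])
        if not np.allclose(affines, affines[0], atol=1e-4):
            raise ValueError("subject images differ in affine")
        data = np.stack([np.asarray(im.dataobj, dtype=float) for im in imgs])
        affine = imgs[0].affine

    mask = np.all(np.isfinite(data), axis=0)
    if mask_path is not None:
        m_img = nib.load(str(mask_path))
        if m_img.shape != data.shape[1:]:
            raise ValueError(
                f"mask shape {m_img.shape} != image shape {data.shape[1:]}"
            )
        mask &= np.asarray(m_img.dataobj) > 0
    data = np.nan_to_num(data, nan=0.0, posinf=0.0, neginf=0.0)
    return data, mask, affine


def read_design(design_path: str | Path, contrast: Sequence[float] | str | Path,
                ) -> DesignSpec:
    """Design matrix from a headered CSV (subjects in rows) plus contrast.

    ``contrast`` is either a sequence of p numbers or a path to a one-row
    headerless CSV/text file.
    """
    X = pd.read_csv(design_path).to_numpy(dtype=float)
    if isinstance(contrast, (str, Path)):
        w = np.loadtxt(str(contrast), delimiter=",", ndmin=1)
    else:
        w = np.asarray(list(contrast), dtype=float)
    return DesignSpec(X, w)


def write_field(field: FieldLattice | np.ndarray, path: str | Path,
                affine: np.ndarray | None = None) -> None:
    arr = field.values if isinstance(field, FieldLattice) else np.asarray(field)
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), str(path))


def write_confidence_sets(
    cs: ConfidenceSets, prefix: str | Path, affine: np.ndarray | None = None
) -> dict[str, Path]:
    """Write the set triple as binary masks + a nesting label map + sidecar.

    Produces ``<prefix>_upper.nii.gz``, ``_point_estimate.nii.gz``,
    ``_lower.nii.gz`` (uint8 masks), ``_labels.nii.gz`` (0 none, 1 lower
    only, 2 point estimate, 3 upper) and ``<prefix>.json`` recording the
    settings (c, alpha, k, B, multiplier, variant, seed).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    up, pe, lo = cs.masks()
    out = {}
    for name, arr in (("upper", up), ("point_estimate", pe), ("lower", lo)):
        p = prefix.parent / f"{prefix.name}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(np.uint8), affine), str(p))
        out[name] = p
    p = prefix.parent / f"{prefix.name}_labels.nii.gz"
    nib.save(nib.Nifti1Image(cs.label_map(), affine), str(p))
    out["labels"] = p
    sidecar = {"c": cs.c, "alpha": cs.alpha, "k": cs.k}
    if cs.settings:
        sidecar.update({k: v for k, v in cs.settings.items()
                        if isinstance(v, (int, float, str, type(None)))})
    p = prefix.parent / f"{prefix.name}.json"
    p.write_text(json.dumps(sidecar, indent=2))
    out["sidecar"] = p
    return out


def read_label_map(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decode a nesting label map back into (upper, point-estimate, lower)."""
    labels = np.asarray(nib.load(str(path)).dataobj).astype(np.uint8)
    return labels >= 3, labels >= 2, labels >= 1
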