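"""Semi-automatic tumor delineation on late subtraction images.

The workflow mirrors a radiology reading: a coarse bounding volume of
interest (VOI) is drawn around the lesion, an Otsu threshold is computed
from the subtraction-image voxels inside the VOI on each axial slice, and
marching squares extracts the iso-contours at that level; the filled
contours, united across slices, form the tumor mask.  Necrotic regions
are removed by an explicit exclusion mask (produced elsewhere, e.g. from
ADC maps), never inferred here.
"""

from __future__ import annotations

import warnings
from typing import Optional, Union

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .containers import TumorMask, VolumeImage

__all__ = ["segment_tumor", "tumor_volume", "box_to_mask"]


def box_to_mask(box: dict, grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Convert an axis-aligned voxel box {'x': [lo, hi], ...} (hi exclusive)
    into a boolean mask on the given grid."""
    mask = np.zeros(grid_shape, dtype=bool)
    sl = []
    for axis, n in zip("xyz", grid_shape):
        lo, hi = box[axis]
        if not 0 <= lo < hi <= n:
            raise ValueError(f"box axis {axis} [{lo}, {hi}) outside grid of {n}")
        sl.append(slice(int(lo), int(hi)))
    mask[tuple(sl)] = True
    return mask


def _fill_contours_2d(plane: np.ndarray, level: float) -> np.ndarray:
    """Marching-squares contours at `level`, filled.

    The plane is padded with a below-threshold border so contours touching
    the edge close along the boundary.
    """
    pad = np.pad(plane, 1, mode="constant", constant_values=plane.min() - 1.0)
    contours = measure.find_contours(pad, level=level)
    filled = np.zeros(plane.shape, dtype=bool)
    if not contours:
        return filled
    # sample points at pixel centers of the padded frame, then un-pad
    shape = pad.shape
    for contour in contours:
        inside = measure.grid_points_in_poly(shape, contour)
        filled |= inside[1:-1, 1:-1]
    # grid_points_in_poly with overlapping nested contours just unions;
    # interior holes are intentionally kept filled (necrosis is handled by
    # the explicit exclusion mask)
    return filled


def segment_tumor(
    sub_image: VolumeImage,
    bounding_voi: Union[np.ndarray, dict],
    exclusion: Optional[np.ndarray] = None,
) -> TumorMask:
    """Delineate the tumor inside a bounding VOI on a subtraction image.

    Per axial (z) slice, the Otsu threshold of the VOI voxels of that slice
    sets the marching-squares iso-level; closed contours are filled and the
    result restricted to the VOI.  Slices whose VOI intensities are uniform
    (Otsu undefined) contribute an empty mask with a warning.  The optional
    exclusion mask is subtracted at the end.
    """
    img = sub_image.data
    if isinstance(bounding_voi, dict):
        voi = box_to_mask(bounding_voi, img.shape)
    else:
        voi = np.asarray(bounding_voi).astype(bool)
    if voi.shape != img.shape:
        raise ValueError("bounding VOI grid does not match image")
    if not voi.any():
        raise ValueError("bounding VOI is empty")

    mask = np.zeros(img.shape, dtype=bool)
    for z in range(img.shape[2]):
        voi_z = voi[:, :, z]
        if not voi_z.any():
            continue
        values = img[:, :, z][voi_z]
        if np.ptp(values) == 0:
            warnings.warn(
                f"slice {z}: uniform VOI intensity, Otsu undefined; "
                f"empty mask", stacklevel=2)
            continue
        try:
            level = threshold_otsu(values)
        except ValueError:
            warnings.warn(f"slice {z}: Otsu failed; empty mask", stacklevel=2)
            continue
        # crop to the VOI bounding box of this slice; outside-VOI pixels are
        # pushed below threshold so contours close along the VOI boundary
        rows = np.flatnonzero(voi_z.any(axis=1))
        cols = np.flatnonzero(voi_z.any(axis=0))
        r0, r1 = rows[0], rows[-1] + 1
        c0, c1 = cols[0], cols[-1] + 1
        crop = img[r0:r1, c0:c1, z].copy()
        crop[~voi_z[r0:r1, c0:c1]] = values.min()
        filled = _fill_contours_2d(crop, level)
        slice_mask = np.zeros_like(voi_z)
        slice_mask[r0:r1, c0:c1] = filled
        mask[:, :, z] = slice_mask & voi_z

    return TumorMask(data=mask, voxel_spacing=sub_image.voxel_spacing,
                     provenance="auto", exclusion_mask=exclusion)


def tumor_volume(mask: TumorMask) -> float:
    """Tumor volume in cm³: voxel count × voxel volume."""
    voxel_mm3 = float(np.prod(mask.voxel_spacing))
    return mask.n_voxels * voxel_mm3 / 1000.0
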