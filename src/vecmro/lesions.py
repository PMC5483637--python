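"""FLAIR hyperintensity (lesion) quantification.

White-matter lesions appear hyperintense on T2-FLAIR.  Candidate voxels
are flagged slice-wise: a voxel counts as hyperintense when its intensity
is at least ``z`` standard deviations above its slice's mean (statistics
computed over in-brain voxels of that slice only, so zero background does
not corrupt the threshold).  Burden is reported on an absolute (mm^3) and
relative (% of white-matter volume) scale; spatially distinct lesions are
connected components above a minimum volume.  Inter-rater agreement of
two lesion masks uses the Dice coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "LesionSummary",
    "hyperintensity_mask",
    "count_lesions",
    "lesion_burden",
    "dice",
    "summarize_lesions",
]

# Dice above this is conventionally called excellent inter-rater agreement.
EXCELLENT_AGREEMENT = 0.70

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class LesionSummary:
    absolute_volume_mm3: float
    relative_volume_pct: float
    distinct_count: int


def hyperintensity_mask(
    flair: np.ndarray, brain_mask: np.ndarray, z: float = 1.25
) -> np.ndarray:
    """Slice-wise intensity threshold: >= slice mean + z * slice SD.

    The slice axis is the third array axis.  Slices whose in-brain SD is
    zero (e.g. constant slices) flag nothing.  Invariant to per-slice
    affine intensity rescaling with positive gain.
    """
    vol = np.asarray(flair, dtype=float)
    brain = np.asarray(brain_mask, dtype=bool)
    if vol.shape != brain.shape:
        raise ValueError("flair and brain mask grids differ")
    if not brain.any():
        raise ValueError("brain mask is empty")
    out = np.zeros(vol.shape, dtype=bool)
    for k in range(vol.shape[2]):
        inb = brain[:, :, k]
        if not inb.any():
            continue
        vals = vol[:, :, k][inb]
        sd = vals.std()
        if sd == 0:
            continue
        thr = vals.mean() + z * sd
        out[:, :, k] = inb & (vol[:, :, k] >= thr)
    return out


def count_lesions(
    mask: np.ndarray,
    voxel_volume_mm3: float,
    min_volume_mm3: float = 3.0,
    connectivity: int = 26,
) -> int:
    """Number of connected components with volume >= ``min_volume_mm3``.

    ``connectivity`` is the 3D neighbourhood (6 faces, 18 faces+edges,
    26 faces+edges+corners; default 26 so diagonally touching blobs count
    as one lesion).
    """
    if voxel_volume_mm3 <= 0:
        raise ValueError("voxel volume must be positive")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    mask = np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n_comp = ndimage.label(mask, structure=structure)
    if n_comp == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    return int(np.sum(sizes * voxel_volume_mm3 >= min_volume_mm3))


def lesion_burden(
    mask: np.ndarray, voxel_volume_mm3: float, wm_volume_mm3: float
) -> tuple[float, float]:
    """(absolute mm^3, relative % of white-matter volume) of a lesion mask."""
    if voxel_volume_mm3 <= 0:
        raise ValueError("voxel volume must be positive")
    if wm_volume_mm3 <= 0:
        raise ValueError("white-matter volume must be positive")
    absolute = float(np.count_nonzero(mask) * voxel_volume_mm3)
    return absolute, 100.0 * absolute / wm_volume_mm3


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A & B| / (|A| + |B|); 1 iff identical non-empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask grids differ")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks are empty")
    return 2.0 * int((a & b).sum()) / (na + nb)


def summarize_lesions(
    mask: np.ndarray,
    voxel_volume_mm3: float,
    wm_volume_mm3: float,
    min_volume_mm3: float = 3.0,
    connectivity: int = 26,
) -> LesionSummary:
    """Burden and distinct count of a (possibly rater-edited) lesion mask."""
    absolute, relative = lesion_burden(mask, voxel_volume_mm3, wm_volume_mm3)
    return LesionSummary(
        absolute_volume_mm3=absolute,
        relative_volume_pct=relative,
        distinct_count=count_lesions(
            mask, voxel_volume_mm3, min_volume_mm3, connectivity
        ),
    )
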