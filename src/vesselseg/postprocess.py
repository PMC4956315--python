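"""Area-based denoising of the binary vessel map.

Small isolated components in the thresholded image are almost always
noise or pathology residue rather than vasculature, which is connected at
fundus-image scale.  Every connected component of at most
``max_removed_area`` pixels (default 30) is deleted; the default
8-connectivity keeps thin diagonal vessel segments in one piece.
"""

from __future__ import annotations

import numpy as np
from skimage.measure import label

__all__ = ["area_filter"]

_CONNECTIVITY = {4: 1, 8: 2}  # neighborhood -> skimage connectivity order


def area_filter(
    mask: np.ndarray, max_removed_area: int = 30, connectivity: int = 8
) -> np.ndarray:
    """Delete every connected component with area <= max_removed_area.

    Purely subtractive (output foreground is a subset of the input) and
    idempotent; components of max_removed_area + 1 pixels or more pass
    through untouched.
    """
    if max_removed_area < 0:
        raise ValueError("max_removed_area must be >= 0")
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask)
    fg = mask > 0
    labels, n = label(
        fg, connectivity=_CONNECTIVITY[connectivity], return_num=True
    )
    if n == 0:
        return np.zeros(mask.shape, dtype=np.uint8)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0  # background
    keep = sizes > max_removed_area
    return keep[labels].astype(np.uint8)
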