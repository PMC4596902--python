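"""Image input, band extraction, automatic thresholding and object labelling.

The acquisition protocol this pipeline targets produces photographs of a cut
grass bunch whose shoot tips have been painted white: near-white elliptical
cross-sections on a soil-coloured background.  Segmentation therefore reduces
to a single global threshold on the blue band, chosen automatically by the
maximum-average-edge-contrast criterion (Köhler 1981), followed by a
morphological opening and a small-object area filter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.morphology import disk

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledObjects",
    "read_image",
    "to_blue_band",
    "max_contrast_threshold",
    "open_and_label",
    "write_mask",
    "write_label_map",
    "segmentation_report",
]

#: 8-connectivity structuring element for foreground labelling.
_STRUCT8 = np.ones((3, 3), dtype=bool)


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (JPEG/PNG/TIFF) as an ``(H, W, 3)`` uint8 array.

    Grayscale inputs are replicated across the three bands; an alpha channel
    is dropped; higher bit depths are rescaled to [0, 255] with a warning.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific message
        raise ValueError(f"cannot read image file: {path}") from exc
    arr = np.asarray(arr)
    if arr.dtype != np.uint8:
        info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
        hi = float(info.max) if info is not None else float(max(arr.max(), 1))
        logger.warning("%s: %s depth rescaled to 8 bits", path.name, arr.dtype)
        arr = np.clip(arr.astype(np.float64) / hi * 255.0, 0, 255).round().astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"unsupported image shape {arr.shape} in {path}")
    return arr


_BAND_INDEX = {"red": 0, "green": 1, "blue": 2, "r": 0, "g": 1, "b": 2}


def to_blue_band(img: np.ndarray, band: str = "blue") -> np.ndarray:
    """Extract one colour band (default blue) as an ``(H, W)`` uint8 image.

    White paint is bright in every band while green vegetation is dark in
    blue, so the blue band gives the best paint/background contrast.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    try:
        idx = _BAND_INDEX[band.lower()]
    except KeyError:
        raise ValueError(f"unknown band {band!r}; expected red/green/blue") from None
    return np.ascontiguousarray(img[:, :, idx])


def _separating_pair_histogram(img: np.ndarray) -> np.ndarray:
    """256x256 histogram H[lo, hi] of 4-adjacent pixel pairs with lo < hi."""
    img = img.astype(np.int64)
    lo = np.concatenate(
        [
            np.minimum(img[:, :-1], img[:, 1:]).ravel(),
            np.minimum(img[:-1, :], img[1:, :]).ravel(),
        ]
    )
    hi = np.concatenate(
        [
            np.maximum(img[:, :-1], img[:, 1:]).ravel(),
            np.maximum(img[:-1, :], img[1:, :]).ravel(),
        ]
    )
    keep = lo != hi
    return np.bincount(lo[keep] * 256 + hi[keep], minlength=256 * 256).reshape(256, 256)


def max_contrast_threshold(img: np.ndarray) -> tuple[int, np.ndarray]:
    """Automatic threshold by Köhler's maximum-average-contrast criterion.

    A threshold ``s`` separates a 4-adjacent pixel pair ``(p, q)`` when
    ``min(I_p, I_q) <= s < max(I_p, I_q)``; the contrast that ``s`` assigns to
    the pair is ``min(|I_p - s|, |I_q - s|)``.  The chosen threshold maximises
    the mean contrast over all pairs it separates, with ties broken toward
    the lower threshold.  Returns ``(threshold, mask)`` with
    ``mask = img > threshold``.

    Raises ``ValueError`` for a constant image (no separating threshold).
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grey image")
    hist = _separating_pair_histogram(img)
    if hist.sum() == 0:
        raise ValueError("no threshold separates the image: image is constant")
    levels = np.arange(256)
    best_s, best_contrast = -1, -np.inf
    for s in range(0, 255):
        sub = hist[: s + 1, s + 1 :]
        n_pairs = sub.sum()
        if n_pairs == 0:
            continue
        # contrast weight of a (lo, hi) pair at s: min(s - lo, hi - s)
        weights = np.minimum.outer(s - levels[: s + 1], levels[s + 1 :] - s)
        mean_contrast = float((sub * weights).sum()) / n_pairs
        if mean_contrast > best_contrast:
            best_contrast, best_s = mean_contrast, s
    return best_s, img > best_s


@dataclass
class LabeledObjects:
    """Connected components of a segmented mask after opening and area filter.

    ``label_map`` holds 0 for background and contiguous ids 1..K for the
    surviving 8-connected components; ``areas`` and ``slices`` are indexed by
    object order (id ``k`` is ``areas[k-1]``).
    """

    label_map: np.ndarray
    areas: np.ndarray
    slices: list[tuple[slice, slice]]
    ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ids:
            self.ids = list(range(1, len(self.areas) + 1))

    @property
    def n_objects(self) -> int:
        return len(self.ids)

    def object_mask(self, object_id: int) -> tuple[np.ndarray, tuple[int, int]]:
        """Cropped boolean mask of one object and its (row, col) offset."""
        sl = self.slices[object_id - 1]
        return self.label_map[sl] == object_id, (sl[0].start, sl[1].start)

    def pixels(self, object_id: int) -> tuple[np.ndarray, np.ndarray]:
        """Absolute (rows, cols) coordinates of one object's pixels."""
        crop, (r0, c0) = self.object_mask(object_id)
        r, c = np.nonzero(crop)
        return r + r0, c + c0


def open_and_label(
    mask: np.ndarray, min_area: int = 200, opening_radius: int = 1
) -> LabeledObjects:
    """Morphological opening, 8-connected labelling and small-object removal.

    Components with fewer than ``min_area`` pixels after the opening are
    discarded (the pipeline default of 200 px rejects thin cut leaves and
    debris before classification); survivors are relabelled 1..K in scan
    order.  ``opening_radius=0`` skips the opening.
    """
    mask = np.asarray(mask, dtype=bool)
    if opening_radius > 0:
        mask = ndimage.binary_opening(mask, structure=disk(opening_radius))
    lab, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return LabeledObjects(lab.astype(np.int32), np.empty(0, dtype=np.int64), [])
    areas = np.bincount(lab.ravel())[1:]
    keep = np.flatnonzero(areas >= min_area) + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    lab = remap[lab]
    all_slices = ndimage.find_objects(lab)
    return LabeledObjects(lab, areas[keep - 1], all_slices)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (255 = object of interest)."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def write_label_map(label_map: np.ndarray, path: str | Path) -> None:
    """Write a label map as 16-bit PNG."""
    if label_map.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 objects; cannot store as 16-bit PNG")
    iio.imwrite(Path(path), label_map.astype(np.uint16))


def segmentation_report(
    threshold: int, objects: LabeledObjects, image_name: str | None = None
) -> dict:
    """JSON-serialisable per-image segmentation summary."""
    report = {
        "threshold": int(threshold),
        "n_objects": objects.n_objects,
        "areas": [int(a) for a in objects.areas],
    }
    if image_name is not None:
        report = {"image": image_name, **report}
    return report


def save_segmentation_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
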