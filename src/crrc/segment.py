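"""Cell segmentation from high-contrast transmitted-light frames.

The workflow expects images that have already been contrast-enhanced so
cells appear as bright objects on a dark background (the regime produced
by out-of-focus acquisition plus thresholding on the microscope).  Contour
determination is classical: a global threshold, 8-connected component
labeling, and a radius range filter (default 3-12 um) that keeps single
cells while discarding debris and fused clusters.  Detection accuracy can
be scored against reference centroids by greedy one-to-one matching.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skimage import filters, measure

__all__ = [
    "threshold_image",
    "label_cells",
    "segment_stack",
    "filter_by_radius",
    "detection_accuracy",
    "DETECTION_COLUMNS",
]

#: Schema of a detection table: one row per segmented cell.
#: centroid (row, col) is 0-based with pixel centers at integers;
#: equivalent radius is that of the equal-area circle, in um.
DETECTION_COLUMNS = ["frame", "label", "row", "col", "area_px", "radius_um"]


def threshold_image(image: np.ndarray, method: str = "otsu", **params) -> np.ndarray:
    """Binarize an image; foreground = pixels strictly above the threshold.

    Parameters
    ----------
    method : {"otsu", "fixed", "percentile"}
        "otsu" maximizes inter-class variance; "fixed" uses
        ``params["threshold"]`` (for parity with a manually thresholded
        acquisition); "percentile" uses ``params["percentile"]`` of the
        intensity distribution.

    A constant image cannot be thresholded automatically: an empty
    foreground is returned with a warning.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if method == "fixed":
        thresh = float(params["threshold"])
    elif method == "percentile":
        thresh = float(np.percentile(image, float(params.get("percentile", 90.0))))
    elif method == "otsu":
        if image.min() == image.max():
            warnings.warn("constant image: automatic threshold is degenerate, returning empty foreground")
            return np.zeros(image.shape, dtype=bool)
        thresh = filters.threshold_otsu(image)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return image > thresh


def label_cells(
    binary: np.ndarray, pixel_size: float, connectivity: int = 2, frame: int = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label connected foreground components and measure each cell.

    Returns the label mask (0 = background, 1..n = cells, 8-connected by
    default, ``connectivity`` in the scikit-image convention: 2 = 8-connected)
    and a detection table with centroid, pixel area, and equivalent radius
    ``sqrt(area / pi) * pixel_size`` in um.
    """
    labels = measure.label(np.asarray(binary, dtype=bool), connectivity=connectivity)
    props = measure.regionprops(labels)
    rows = [
        {
            "frame": frame,
            "label": p.label,
            "row": p.centroid[0],
            "col": p.centroid[1],
            "area_px": float(p.area),
            "radius_um": float(np.sqrt(p.area / np.pi) * pixel_size),
        }
        for p in props
    ]
    det = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    return labels, det


def segment_stack(
    frames: np.ndarray,
    pixel_size: float,
    method: str = "otsu",
    r_min: float = 3.0,
    r_max: float = 12.0,
    **params,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Threshold + label + radius-filter every frame of a stack.

    The label masks retain *all* components; the returned detection table
    is radius-filtered, so downstream stages address surviving cells via
    (frame, label).
    """
    masks = np.zeros(np.asarray(frames).shape, dtype=np.int32)
    tables = []
    for j, frame in enumerate(frames):
        binary = threshold_image(frame, method=method, **params)
        labels, det = label_cells(binary, pixel_size, frame=j)
        masks[j] = labels
        tables.append(filter_by_radius(det, r_min=r_min, r_max=r_max))
    det = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=DETECTION_COLUMNS)
    return masks, det


def filter_by_radius(detections: pd.DataFrame, r_min: float = 3.0, r_max: float = 12.0) -> pd.DataFrame:
    """Keep single-cell detections: r_min <= equivalent radius <= r_max (closed interval).

    Excludes debris (too small) and fused clusters (too large); idempotent.
    """
    if r_min > r_max:
        raise ValueError(f"r_min ({r_min}) > r_max ({r_max})")
    keep = (detections["radius_um"] >= r_min) & (detections["radius_um"] <= r_max)
    return detections[keep].reset_index(drop=True)


def detection_accuracy(
    detections: np.ndarray, reference: np.ndarray, match_radius: float = 6.5
) -> float:
    """Percentage of reference cells correctly identified.

    Greedy one-to-one matching by ascending centroid distance: the closest
    (detection, reference) pair is matched first, both are removed, and so
    on while the distance is within ``match_radius`` (same units as the
    coordinates; default half a typical cell diameter in um).  Returns
    100 * matched / len(reference).
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be positive")
    reference = np.asarray(reference, dtype=float).reshape(-1, 2)
    if len(reference) == 0:
        raise ValueError("reference centroids are empty: accuracy undefined")
    detections = np.asarray(detections, dtype=float).reshape(-1, 2)
    if len(detections) == 0:
        return 0.0
    dist = np.hypot(
        detections[:, None, 0] - reference[None, :, 0],
        detections[:, None, 1] - reference[None, :, 1],
    )
    order = np.argsort(dist, axis=None, kind="stable")
    used_det = np.zeros(len(detections), dtype=bool)
    used_ref = np.zeros(len(reference), dtype=bool)
    matched = 0
    for flat in order:
        i, j = np.unravel_index(flat, dist.shape)
        if dist[i, j] > match_radius:
            break
        if used_det[i] or used_ref[j]:
            continue
        used_det[i] = used_ref[j] = True
        matched += 1
    return 100.0 * matched / len(reference)
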