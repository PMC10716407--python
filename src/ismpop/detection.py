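"""Reference morphological detector and six-class rule-based classifier.

This is a classical (non-learned) stand-in for a CNN detection stage: cells
are segmented by contrast against the flat ISM background, defocused
objects are rejected by a Laplacian sharpness score (which is what defines
the effective probe depth), and each in-focus region is classified from
interpretable shape/texture features implementing the published
morphological criteria of the six classes:

==== ======================= ==========================================
id   class                   discriminating morphology
==== ======================= ==========================================
1    viable                  pseudo-circular, homogeneous texture
2    apoptotic               irregular, shrunken, inhomogeneous
3    necrotic                swollen, near-perfect roundness, inhomogeneous
4    viable with bulges      distinct surface bulges
5    necrotic late stage     blurred discontinuity of the cell border
6    pair of viable cells    two attached lobes (mitotic twins)
==== ======================= ==========================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure
from skimage.feature import peak_local_max

from .core import BoundingBox, CellClass

__all__ = [
    "Detection",
    "FeatureVector",
    "Region",
    "DetectionParams",
    "ClassifierThresholds",
    "detect_candidates",
    "focus_filter",
    "extract_features",
    "classify_cell",
    "classify_frame",
    "read_detections",
    "write_detections",
    "read_voc_annotations",
]


@dataclass(frozen=True)
class Detection:
    """A localized, classified object in one frame."""

    box: BoundingBox
    class_id: int
    confidence: float = 1.0
    focus_score: float = 0.0

    def __post_init__(self) -> None:
        if int(self.class_id) not in {1, 2, 3, 4, 5, 6}:
            raise ValueError(f"class_id must be in 1..6, got {self.class_id}")


@dataclass(frozen=True)
class FeatureVector:
    """Morphological features of a segmented cell candidate.

    circularity
        4πA/P² of the binary mask, in (0, 1]; 1 for a perfect disc.
    texture_heterogeneity
        coefficient of variation of the interior grey levels (rim excluded).
    bulge_count
        number of contour convexity defects deeper than a fraction of the
        equivalent radius — lobed/bulged outlines score high.
    border_continuity
        minimum radial edge contrast along the contour divided by its
        median; a ruptured border (late necrosis) drives this toward 0.
    lobe_count
        number of distance-transform peaks; 2 for an attached cell pair.
    """

    circularity: float
    texture_heterogeneity: float
    bulge_count: int
    border_continuity: float
    lobe_count: int

    def __post_init__(self) -> None:
        if not (0.0 < self.circularity <= 1.0):
            raise ValueError("circularity must lie in (0, 1]")
        if self.texture_heterogeneity < 0:
            raise ValueError("texture_heterogeneity must be >= 0")
        if self.bulge_count < 0 or self.lobe_count < 1:
            raise ValueError("bulge_count >= 0 and lobe_count >= 1 required")


@dataclass
class Region:
    """A candidate region: local boolean mask plus its frame placement."""

    mask: np.ndarray          # bool, local window
    x0: int                   # top-left corner of the window in the frame
    y0: int
    area: int
    touches_border: bool
    focus_score: float = float("nan")

    def bounding_box(self, frame_shape: tuple[int, int]) -> BoundingBox:
        H, W = frame_shape
        ys, xs = np.nonzero(self.mask)
        bx0, bx1 = self.x0 + xs.min(), self.x0 + xs.max() + 1
        by0, by1 = self.y0 + ys.min(), self.y0 + ys.max() + 1
        return BoundingBox(
            cx=(bx0 + bx1) / 2.0 / W,
            cy=(by0 + by1) / 2.0 / H,
            w=(bx1 - bx0) / W,
            h=(by1 - by0) / H,
        )

    def frame_mask_slices(self) -> tuple[slice, slice]:
        h, w = self.mask.shape
        return slice(self.y0, self.y0 + h), slice(self.x0, self.x0 + w)


@dataclass(frozen=True)
class DetectionParams:
    """Segmentation parameters.

    ``expected_area_px`` is the nominal single-cell area used by the
    half-body rule: border-touching regions showing less than half of it
    are dropped, mirroring the labelling convention for peripheral cells.
    """

    background_level: float | None = None   # None -> frame median
    min_area_px: int = 1500
    max_area_px: int = 60000
    threshold_k: float = 5.0        # multiples of the robust noise sd
    min_threshold: float = 8.0      # grey-level floor of the threshold
    expected_area_px: float = 7000.0

    def __post_init__(self) -> None:
        if self.min_area_px <= 0 or self.max_area_px <= self.min_area_px:
            raise ValueError("need 0 < min_area_px < max_area_px")


def detect_candidates(frame: np.ndarray, params: DetectionParams | None = None) -> list[Region]:
    """Segment candidate cell regions by contrast against the background.

    Pixels with ``|I - background|`` above an adaptive threshold (a multiple
    of the robust background noise) are grouped into connected components,
    hole-filled and area-filtered.  Border-touching components showing less
    than half the expected cell area are discarded.
    """
    params = params or DetectionParams()
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D image")
    f = frame.astype(float)
    bg = float(np.median(f)) if params.background_level is None else params.background_level
    diff = np.abs(f - bg)
    # robust noise scale from the median absolute deviation
    mad = float(np.median(np.abs(diff - np.median(diff))))
    noise_sd = 1.4826 * mad
    thresh = max(params.threshold_k * noise_sd, params.min_threshold)
    binary = diff > thresh
    # opening removes isolated noise pixels before component analysis
    binary = ndimage.binary_opening(binary, structure=np.ones((3, 3)))
    binary = ndimage.binary_closing(binary, structure=np.ones((3, 3)))
    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary)
    if n == 0:
        return []
    regions: list[Region] = []
    H, W = frame.shape
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        ys, xs = sl
        lab = labels[sl]
        # recover this component's label id from the slice
        ids, counts = np.unique(lab[lab > 0], return_counts=True)
        lid = ids[np.argmax(counts)]
        mask = lab == lid
        area = int(mask.sum())
        # 2-px margin: morphological opening can erode the outermost pixels
        # of a region genuinely clipped by the frame edge
        touches = (ys.start <= 2 or xs.start <= 2
                   or ys.stop >= H - 2 or xs.stop >= W - 2)
        if touches and area < 0.5 * params.expected_area_px:
            continue
        if area < params.min_area_px or area > params.max_area_px:
            continue
        regions.append(Region(mask=mask, x0=xs.start, y0=ys.start, area=area,
                              touches_border=touches))
    return regions


DEFAULT_FOCUS_THRESHOLD = 0.085


def focus_filter(
    candidates: Sequence[Region],
    frame: np.ndarray,
    threshold: float = DEFAULT_FOCUS_THRESHOLD,
    noise_floor: float = 25.0,
) -> list[Region]:
    """Keep candidates whose sharpness exceeds ``threshold``.

    The focus score is the variance of the Laplacian of the lightly
    smoothed frame over the region, normalized by the region's intensity
    variance (with a ``noise_floor`` stabilizer so flat low-contrast blobs
    cannot score high on pixel noise alone).  Sharp membranes produce
    large Laplacian excursions, defocused ones do not; raising the
    threshold therefore shrinks the effective probe depth monotonically.
    """
    if threshold <= 0:
        raise ValueError("focus threshold must be > 0")
    f = ndimage.gaussian_filter(frame.astype(float), 1.0)
    lap = ndimage.laplace(f)
    kept: list[Region] = []
    for reg in candidates:
        sy, sx = reg.frame_mask_slices()
        vals_l = lap[sy, sx][reg.mask]
        vals_i = f[sy, sx][reg.mask]
        score = float(np.var(vals_l)) / (float(np.var(vals_i)) + noise_floor)
        reg.focus_score = score
        if score >= threshold:
            kept.append(reg)
    return kept


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds of the ordered classification rules.

    Defaults were calibrated once against the renderer's class templates
    and frozen; every threshold is configuration-exposed.
    """

    circularity_high: float = 0.92     # round vs irregular split
    texture_high: float = 0.065        # interior CoV above which a cell is inhomogeneous
    bulge_count_min: int = 4           # convexity defects needed for the bulged class
    bulge_depth_frac: float = 0.10     # defect depth threshold, fraction of r_eq
    border_rupture: float = 0.25       # min/median edge contrast below -> ruptured
    lobe_min_distance_frac: float = 0.6  # peak separation, fraction of r_eq
    lobe_threshold_rel: float = 0.6    # relative distance-transform peak height


def _largest_contour(mask: np.ndarray) -> np.ndarray:
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("degenerate region: no contour found")
    c = max(contours, key=len)
    return c - 1.0     # undo padding; (row, col) coordinates


def _convexity_defects(contour: np.ndarray, depth_threshold: float) -> int:
    """Count contour concavities deeper than ``depth_threshold`` pixels."""
    pts = contour[:, ::-1]           # (x, y)
    if len(pts) < 8:
        return 0
    try:
        hull = ConvexHull(pts)
    except Exception:
        return 0
    hv = np.sort(hull.vertices)
    n = len(pts)
    defects = 0
    for i in range(len(hv)):
        a = hv[i]
        b = hv[(i + 1) % len(hv)]
        seg = np.arange(a, b + 1) if b > a else np.concatenate([np.arange(a, n), np.arange(0, b + 1)])
        if len(seg) < 3:
            continue
        p0, p1 = pts[a], pts[b]
        edge = p1 - p0
        norm = np.hypot(*edge)
        if norm < 1e-9:
            continue
        # perpendicular distance of the in-between contour points to the hull edge
        rel = pts[seg] - p0
        dist = np.abs(rel[:, 0] * edge[1] - rel[:, 1] * edge[0]) / norm
        if float(dist.max()) > depth_threshold:
            defects += 1
    return defects


def _border_continuity(mask: np.ndarray, patch: np.ndarray, contour: np.ndarray) -> float:
    """Minimum/median radial edge contrast along the contour."""
    cy, cx = ndimage.center_of_mass(mask)
    sm = ndimage.gaussian_filter(patch.astype(float), 1.0)
    h, w = patch.shape
    samples = []
    step = max(1, len(contour) // 180)
    for row, col in contour[::step]:
        dy, dx = row - cy, col - cx
        d = math.hypot(dy, dx)
        if d < 1e-6:
            continue
        uy, ux = dy / d, dx / d
        ri = (row - 3.0 * uy, col - 3.0 * ux)
        ro = (row + 3.0 * uy, col + 3.0 * ux)
        yi, xi = int(round(ri[0])), int(round(ri[1]))
        yo, xo = int(round(ro[0])), int(round(ro[1]))
        if not (0 <= yi < h and 0 <= xi < w and 0 <= yo < h and 0 <= xo < w):
            continue
        samples.append(abs(sm[yi, xi] - sm[yo, xo]))
    if len(samples) < 8:
        return 1.0
    prof = np.asarray(samples)
    # smooth the angular profile so a single noisy sample cannot fake a rupture
    kernel = np.ones(5) / 5.0
    prof = np.convolve(np.concatenate([prof[-2:], prof, prof[:2]]), kernel, mode="valid")
    med = float(np.median(prof))
    if med < 1e-9:
        return 1.0
    return float(prof.min() / med)


def _lobe_count(mask: np.ndarray, thresholds: ClassifierThresholds) -> int:
    dist = ndimage.distance_transform_edt(np.pad(mask, 1))
    dist = ndimage.gaussian_filter(dist, 1.5)
    r_eq = math.sqrt(mask.sum() / math.pi)
    min_dist = max(3, int(thresholds.lobe_min_distance_frac * r_eq))
    peaks = peak_local_max(
        dist,
        min_distance=min_dist,
        threshold_rel=thresholds.lobe_threshold_rel,
        exclude_border=False,
    )
    return max(1, len(peaks))


def extract_features(
    region: Region,
    frame: np.ndarray,
    thresholds: ClassifierThresholds | None = None,
) -> FeatureVector:
    """Compute the morphological feature vector of a segmented candidate."""
    thresholds = thresholds or ClassifierThresholds()
    mask = region.mask
    if mask.sum() < 16:
        raise ValueError("degenerate region: too few pixels for features")
    sy, sx = region.frame_mask_slices()
    patch = frame[sy, sx].astype(float)

    area = float(mask.sum())
    perimeter = float(measure.perimeter_crofton(mask, directions=4))
    circularity = min(1.0, 4.0 * math.pi * area / max(perimeter, 1e-9) ** 2)

    # erode well past the rim's tail so its darkening does not masquerade
    # as cytoplasmic inhomogeneity
    interior = ndimage.binary_erosion(mask, iterations=8)
    if interior.sum() < 8:
        interior = ndimage.binary_erosion(mask, iterations=2)
    vals = patch[interior] if interior.sum() >= 8 else patch[mask]
    mean = float(np.mean(vals))
    texture = float(np.std(vals)) / max(abs(mean), 1e-9)

    contour = _largest_contour(mask)
    r_eq = math.sqrt(area / math.pi)
    bulges = _convexity_defects(contour, thresholds.bulge_depth_frac * r_eq)
    border = _border_continuity(mask, patch, contour)
    lobes = _lobe_count(mask, thresholds)

    return FeatureVector(
        circularity=circularity,
        texture_heterogeneity=texture,
        bulge_count=bulges,
        border_continuity=border,
        lobe_count=lobes,
    )


def classify_cell(f: FeatureVector, thresholds: ClassifierThresholds | None = None) -> CellClass:
    """Apply the ordered morphological decision rules.

    (i) two or more lobes → pair; (ii) ruptured border → late necrotic;
    (iii) enough deep bulges → viable with bulges; (iv) inhomogeneous and
    round → necrotic; (v) inhomogeneous and irregular → apoptotic;
    (vi) otherwise → viable.  The rules are total: every feature vector
    maps to a class.
    """
    t = thresholds or ClassifierThresholds()
    if f.lobe_count >= 2:
        return CellClass.PAIR
    if f.border_continuity < t.border_rupture:
        return CellClass.NECROTIC_LATE
    if f.bulge_count >= t.bulge_count_min:
        return CellClass.VIABLE_BULGES
    if f.texture_heterogeneity >= t.texture_high:
        if f.circularity >= t.circularity_high:
            return CellClass.NECROTIC
        return CellClass.APOPTOTIC
    return CellClass.VIABLE


def classify_frame(
    frame: np.ndarray,
    detection_params: DetectionParams | None = None,
    focus_threshold: float = DEFAULT_FOCUS_THRESHOLD,
    thresholds: ClassifierThresholds | None = None,
) -> list[Detection]:
    """Full reference pipeline on one frame: segment, focus-filter, classify."""
    regions = detect_candidates(frame, detection_params)
    regions = focus_filter(regions, frame, focus_threshold)
    detections: list[Detection] = []
    for reg in regions:
        feats = extract_features(reg, frame, thresholds)
        cls = classify_cell(feats, thresholds)
        detections.append(
            Detection(
                box=reg.bounding_box(frame.shape),
                class_id=int(cls),
                confidence=1.0,
                focus_score=reg.focus_score,
            )
        )
    return detections


# --------------------------------------------------------------------------
# Annotation / detection file formats
# --------------------------------------------------------------------------

def write_detections(detections: Sequence[Detection], path) -> None:
    """Write darknet-format lines ``class_id cx cy w h confidence``.

    Class ids are 0-based on disk (darknet convention) and 1-based in
    memory.
    """
    lines = []
    for d in detections:
        lines.append(
            f"{int(d.class_id) - 1} {d.box.cx:.6f} {d.box.cy:.6f} "
            f"{d.box.w:.6f} {d.box.h:.6f} {d.confidence:.6f}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_detections(path) -> list[Detection]:
    """Read a darknet text file; the confidence column is optional."""
    path = Path(path)
    detections: list[Detection] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise ValueError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
        try:
            cls = int(parts[0])
            cx, cy, w, h = (float(v) for v in parts[1:5])
            conf = float(parts[5]) if len(parts) == 6 else 1.0
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed line {line!r}") from exc
        detections.append(
            Detection(box=BoundingBox(cx, cy, w, h), class_id=cls + 1, confidence=conf)
        )
    return detections


def read_voc_annotations(path, frame_width: int, frame_height: int) -> list[Detection]:
    """Read a PASCAL-VOC XML annotation file (read-only interop).

    Object names must be integer class ids (1-based) or ``class_<k>``.
    """
    import xml.etree.ElementTree as ET

    root = ET.parse(str(path)).getroot()
    out: list[Detection] = []
    for obj in root.iter("object"):
        name = obj.findtext("name", default="").strip()
        cls = int(name.removeprefix("class_")) if name else 0
        bb = obj.find("bndbox")
        if bb is None:
            continue
        x1 = float(bb.findtext("xmin"))
        y1 = float(bb.findtext("ymin"))
        x2 = float(bb.findtext("xmax"))
        y2 = float(bb.findtext("ymax"))
        out.append(
            Detection(
                box=BoundingBox(
                    cx=(x1 + x2) / 2.0 / frame_width,
                    cy=(y1 + y2) / 2.0 / frame_height,
                    w=(x2 - x1) / frame_width,
                    h=(y2 - y1) / frame_height,
                ),
                class_id=cls,
            )
        )
    return out
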