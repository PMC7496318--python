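"""Measurement of denticle-belt positions from dark-field larval images.

The pipeline mirrors the classic measurement procedure for first-instar
larvae: the larva is segmented from the dark background, rotated so its
long axis is horizontal with the anterior (tapered) end on the left,
cropped to its bounding box, and the eight abdominal denticle belts are
located as bright transverse bands in the axial intensity profile.  Belt
borders are sub-pixel half-maximum crossings of the smoothed profile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, transform

from .exceptions import (
    AmbiguityError,
    DetectionError,
    InvalidAnnotationError,
    InvalidArgumentError,
    OrientationError,
    SegmentationError,
)

__all__ = [
    "LarvaImage",
    "BeltAnnotation",
    "orient_larva",
    "detect_belts",
    "measure_positions",
    "measure_image",
]


@dataclass
class LarvaImage:
    """A 2-D grayscale larval image.

    Attributes
    ----------
    pixels : ndarray
        2-D float intensity grid (dark background, bright body).
    pixel_size_um : float
        Micrometers per pixel; 1.0 when the physical scale is unknown.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidArgumentError("LarvaImage.pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidArgumentError("LarvaImage intensities must be finite")


@dataclass
class BeltAnnotation:
    """Axial coordinates (in px along the body axis) of body ends and belts.

    ``belts`` holds eight ``(anterior_px, posterior_px)`` pairs ordered from
    anterior to posterior.  Coordinates may be sub-pixel.
    """

    body_anterior_px: float
    body_posterior_px: float
    belts: list = field(default_factory=list)

    def __post_init__(self):
        seq = [self.body_anterior_px]
        for a, p in self.belts:
            seq.extend([a, p])
        seq.append(self.body_posterior_px)
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise InvalidAnnotationError(
                "annotation violates ordering: body_anterior < belt borders ... < body_posterior"
            )

    @property
    def n_belts(self):
        return len(self.belts)

    def to_json(self, path=None):
        obj = {
            "body_anterior_px": self.body_anterior_px,
            "body_posterior_px": self.body_posterior_px,
            "belts": [[float(a), float(p)] for a, p in self.belts],
        }
        if path is None:
            return json.dumps(obj, indent=1)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, source):
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(obj["body_anterior_px"], obj["body_posterior_px"], [tuple(b) for b in obj["belts"]])


def _foreground_mask(pixels):
    """Threshold and return (mask, n_large_regions, largest_region_mask)."""
    finite = pixels[np.isfinite(pixels)]
    if finite.size == 0 or finite.max() - finite.min() < 1e-12:
        raise SegmentationError("image has no contrast; no foreground region found")
    # three intensity classes are expected (background, body, belts); the
    # lowest split separates the body from the dark field.  Plain Otsu would
    # split body from belts once the background is cropped away.
    try:
        thr = filters.threshold_multiotsu(pixels, classes=3)[0]
    except ValueError:
        thr = filters.threshold_otsu(pixels)
    mask = pixels > thr
    if not mask.any():
        raise SegmentationError("no foreground region after thresholding")
    labels = measure.label(mask)
    props = measure.regionprops(labels)
    areas = np.array([p.area for p in props])
    big = areas >= 0.05 * areas.max()
    if big.sum() > 1:
        raise SegmentationError(f"{int(big.sum())} large foreground regions found; expected one larva")
    keep = props[int(np.argmax(areas))]
    return labels == keep.label, keep


def orient_larva(image, despeckle=False):
    """Standardise a larval image: horizontal body, anterior left, cropped.

    The body is segmented by Otsu thresholding; the image is rotated so the
    region's principal axis is horizontal, then cropped to the body bounding
    box.  Anterior/posterior is decided by the body thickness profile: the
    anterior (head) end is tapered, hence thinner on average.

    Parameters
    ----------
    image : LarvaImage
    despeckle : bool
        Apply a radius-1 median filter before segmentation (stands in for
        manual clean-up of debris and bubbles).

    Returns
    -------
    LarvaImage
        Standardised image (same pixel size).
    """
    px = image.pixels
    if despeckle:
        px = ndimage.median_filter(px, size=3)
    mask, props = _foreground_mask(px)
    # rotate so the principal axis is horizontal.  regionprops orientation
    # is the angle between the major axis and the *row* axis.
    angle_deg = 90.0 - np.degrees(props.orientation)
    rotated = transform.rotate(px, angle_deg, resize=True, order=1, preserve_range=True, cval=float(np.median(px[~mask])))
    mask2, props2 = _foreground_mask(rotated)
    r0, c0, r1, c1 = props2.bbox
    crop = rotated[r0:r1, c0:c1]
    cmask = mask2[r0:r1, c0:c1]
    # anterior = thinner end, by mean body thickness in each terminal quarter
    thickness = cmask.sum(axis=0).astype(float)
    q = max(1, crop.shape[1] // 4)
    left, right = thickness[:q].mean(), thickness[-q:].mean()
    if not np.isfinite(left) or not np.isfinite(right) or left + right == 0:
        raise OrientationError("cannot resolve anterior end: empty thickness profile")
    if left > right:
        crop = crop[:, ::-1]
    return LarvaImage(np.ascontiguousarray(crop), image.pixel_size_um)


def _half_max_edges(profile, peak, lo, hi, base):
    """Sub-pixel half-maximum crossings around ``peak`` within [lo, hi].

    ``base`` is the body-plateau intensity (shared by all belts); using it
    instead of the local minimum keeps the half level correct for the
    first and last belts, whose outer flanks run into the tapered,
    low-intensity larval ends.
    """
    half = base + 0.5 * (profile[peak] - base)
    i = peak
    while i > lo and profile[i - 1] > half:
        i -= 1
    if i == lo:
        left = float(lo)
    else:
        left = (i - 1) + (half - profile[i - 1]) / (profile[i] - profile[i - 1])
    j = peak
    while j < hi and profile[j + 1] > half:
        j += 1
    if j == hi:
        right = float(hi)
    else:
        right = j + (profile[j] - half) / (profile[j] - profile[j + 1])
    return left, right


def detect_belts(image, expected_n=8, smooth_sigma=2.0):
    """Locate denticle-belt borders on a standardised larval image.

    The axial profile is the column-wise mean intensity over body rows,
    smoothed with a Gaussian.  The ``expected_n`` most prominent peaks are
    taken as belts and each belt's borders are the half-maximum crossings
    of its peak.

    Returns
    -------
    BeltAnnotation

    Raises
    ------
    DetectionError
        If fewer than ``expected_n`` bands are found (``.found`` reports
        the count).
    AmbiguityError
        If adjacent bands overlap after edge extraction.
    """
    from scipy.signal import find_peaks

    px = image.pixels
    mask, props = _foreground_mask(px)
    rows = mask.any(axis=1)
    profile = px[rows].mean(axis=0)
    smooth = ndimage.gaussian_filter1d(profile, smooth_sigma)
    span = smooth.max() - smooth.min()
    peaks, info = find_peaks(smooth, prominence=0.05 * span)
    if len(peaks) < expected_n:
        raise DetectionError(
            f"found {len(peaks)} candidate belts, expected {expected_n}", found=len(peaks), expected=expected_n
        )
    order = np.argsort(info["prominences"])[::-1][:expected_n]
    chosen = np.sort(peaks[order])
    # valley (local minimum of the smoothed profile) between consecutive peaks
    # bounds each belt's half-max search
    edges = []
    bounds = [0]
    valley_levels = []
    for a, b in zip(chosen, chosen[1:]):
        bounds.append(a + int(np.argmin(smooth[a:b + 1])))
        valley_levels.append(smooth[a:b + 1].min())
    bounds.append(len(smooth) - 1)
    base = float(np.median(valley_levels))  # body-plateau intensity
    for k, pk in enumerate(chosen):
        left, right = _half_max_edges(smooth, int(pk), int(bounds[k]), int(bounds[k + 1]), base)
        edges.append((left, right))
    # half-pixel shift: a crossing between pixel centres i and i+1 sits at
    # continuous coordinate i+1 when pixel i+1 is the first inside the band
    edges = [(a + 0.5, p + 0.5) for a, p in edges]
    for (a0, p0), (a1, p1) in zip(edges, edges[1:]):
        if p0 >= a1:
            raise AmbiguityError("detected belt bands overlap; cannot assign unique borders")
    cols = np.flatnonzero(mask.any(axis=0))
    return BeltAnnotation(float(cols[0]), float(cols[-1]) + 1.0, edges)


def measure_positions(annotation, pixel_size_um=1.0, species="", larva_id=""):
    """Convert a belt annotation to physical distances.

    ``X_anterior[i]`` is the distance from the anterior body border to belt
    i's anterior border; ``Y`` is total body length.  Relative segment
    position is ``X_anterior / Y``.

    Returns
    -------
    segmorph.simulate.LarvaMeasurement
    """
    from .simulate import LarvaMeasurement

    if pixel_size_um <= 0:
        raise InvalidArgumentError("pixel_size_um must be positive")
    a0 = annotation.body_anterior_px
    xa = np.array([a - a0 for a, _ in annotation.belts]) * pixel_size_um
    xp = np.array([p - a0 for _, p in annotation.belts]) * pixel_size_um
    y = (annotation.body_posterior_px - a0) * pixel_size_um
    return LarvaMeasurement(species=species, larva_id=larva_id, x_anterior=xa, x_posterior=xp, body_length=y)


def measure_image(image, expected_n=8, despeckle=False, species="", larva_id=""):
    """Full single-image pipeline: orient, detect belts, measure."""
    std = orient_larva(image, despeckle=despeckle)
    ann = detect_belts(std, expected_n=expected_n)
    return measure_positions(ann, pixel_size_um=std.pixel_size_um, species=species, larva_id=larva_id)
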