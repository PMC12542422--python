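"""Nucleus segmentation, cytoplasm ring construction and feature extraction.

Nuclei are segmented from the (corrected) Hoechst channel by Gaussian
smoothing, Otsu thresholding, hole filling and a distance-transform
watershed to split touching nuclei.  The cytoplasm is approximated — as in
ring-based high-content assays — by dilating each nucleus by a fixed
physical width (default 6.5 µm) and assigning contested pixels to the
nearest nucleus.  Per-cell features summarize both compartments in both
channels, plus nucleolar-proxy statistics (top-decile intensity, its ratio
to the nuclear median, and a top-hat spot count) that separate nucleolar
from nucleoplasmic reporter patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk, white_tophat
from skimage.segmentation import watershed


class SegmentationError(ValueError):
    pass


#: Fixed feature order; the classifier schema is exactly this list.
FEATURE_COLUMNS: tuple[str, ...] = (
    "nucleus_area_um2",
    "nucleus_eccentricity",
    "nucleus_solidity",
    "nucleus_mean_hoechst",
    "nucleus_integrated_hoechst",
    "nucleus_sd_hoechst",
    "nucleus_mean_reporter",
    "nucleus_integrated_reporter",
    "nucleus_sd_reporter",
    "ring_mean_reporter",
    "ring_integrated_reporter",
    "top_decile_reporter",
    "top_decile_median_ratio",
    "spot_count",
    "nuclear_ring_ratio",
)


@dataclass
class LabelGrid:
    """Integer label image (0 = background, k > 0 = cell k) with pixel size."""

    labels: np.ndarray
    pixel_size_um: float
    border_labels: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise SegmentationError("label grid must be 2-D")
        if self.pixel_size_um <= 0:
            raise SegmentationError("pixel size must be positive")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


def _relabel_sequential(labels: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Keep the given labels, renumbered 1..N in ascending original order."""
    mapping = np.zeros(labels.max() + 1, dtype=np.int32)
    mapping[np.sort(keep)] = np.arange(1, len(keep) + 1, dtype=np.int32)
    return mapping[labels]


def segment_nuclei(
    hoechst: np.ndarray,
    pixel_size_um: float = 0.65,
    smooth_sigma_px: float = 1.0,
    min_area_um2: float = 30.0,
    max_area_um2: float = 800.0,
    expected_radius_um: float = 5.0,
) -> LabelGrid:
    """Segment nuclei from a single corrected Hoechst image.

    A constant image yields zero objects (not an error).  Objects outside the
    size window are removed; objects touching the image border are kept but
    flagged in ``border_labels``.
    """
    img = np.asarray(hoechst, dtype=float)
    if img.ndim != 2:
        raise SegmentationError("expected a single-channel 2-D image")
    out_empty = LabelGrid(np.zeros(img.shape, np.int32), pixel_size_um)
    if img.max() == img.min():
        return out_empty

    sm = ndimage.gaussian_filter(img, smooth_sigma_px) if smooth_sigma_px > 0 else img
    thr = threshold_otsu(sm)
    mask = sm > thr
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        return out_empty

    dist = ndimage.distance_transform_edt(mask)
    min_distance = max(1, int(round(expected_radius_um / pixel_size_um / 2)))
    coords = peak_local_max(dist, min_distance=min_distance, labels=mask, exclude_border=False)
    peaks = np.zeros(mask.shape, dtype=bool)
    peaks[tuple(coords.T)] = True
    markers, _ = ndimage.label(peaks)
    labels = watershed(-dist, markers, mask=mask).astype(np.int32)

    areas = np.bincount(labels.ravel())
    px2 = pixel_size_um**2
    candidates = np.flatnonzero(
        (areas * px2 >= min_area_um2) & (areas * px2 <= max_area_um2)
    )
    candidates = candidates[candidates > 0]
    labels = _relabel_sequential(labels, candidates)

    border = np.zeros(labels.max() + 1, dtype=bool)
    for edge in (labels[0], labels[-1], labels[:, 0], labels[:, -1]):
        border[np.unique(edge)] = True
    border_labels = frozenset(int(l) for l in np.flatnonzero(border) if l > 0)
    return LabelGrid(labels, pixel_size_um, border_labels)


def ring_width_px(width_um: float, pixel_size_um: float) -> int:
    return int(round(width_um / pixel_size_um))


def cytoplasm_rings(nuclei: LabelGrid, width_um: float = 6.5) -> LabelGrid:
    """Build the cytoplasm-ring label grid around segmented nuclei.

    Each nucleus is dilated by ``round(width_um / pixel_size)`` pixels
    (Euclidean); ring pixels are disjoint from all nuclei and contested
    pixels go to the nearest nucleus, ties to the lower label.
    """
    if width_um <= 0:
        raise SegmentationError("ring width must be positive")
    labels = nuclei.labels
    radius = ring_width_px(width_um, nuclei.pixel_size_um)
    n = nuclei.n_labels
    if n == 0:
        return LabelGrid(np.zeros_like(labels), nuclei.pixel_size_um, nuclei.border_labels)

    best_dist = np.full(labels.shape, np.inf)
    best_label = np.zeros(labels.shape, dtype=np.int32)
    for lab in range(1, n + 1):
        d = ndimage.distance_transform_edt(labels != lab)
        closer = d < best_dist  # strict: ties keep the earlier (lower) label
        best_dist[closer] = d[closer]
        best_label[closer] = lab
    ring = np.where((labels == 0) & (best_dist <= radius) & (best_dist > 0), best_label, 0)
    return LabelGrid(ring.astype(np.int32), nuclei.pixel_size_um, nuclei.border_labels)


def count_spots(
    image: np.ndarray,
    mask: np.ndarray,
    footprint_radius: int = 4,
    rel_threshold: float = 0.5,
    min_contrast: float = 1.0,
    min_area_px: int = 2,
    tophat: np.ndarray | None = None,
) -> int:
    """Count bright sub-compartment spots inside ``mask`` via a white top-hat.

    Purely relative rules (spot gate = ``min_contrast`` x the masked median;
    spot threshold = ``rel_threshold`` x the top-hat maximum) keep the count
    invariant under rescaling the channel by a constant.  A precomputed
    ``tophat`` of the full image may be passed to amortize the filter over
    many cells.
    """
    vals = image[mask]
    if vals.size == 0:
        return 0
    if tophat is None:
        tophat = white_tophat(np.asarray(image, dtype=float), footprint=disk(footprint_radius))
    peak = float(tophat[mask].max())
    gate = min_contrast * float(np.median(vals))
    if peak <= gate or peak <= 0:
        return 0
    spots = (tophat >= rel_threshold * peak) & mask
    lab, nspots = ndimage.label(spots)
    if min_area_px > 1 and nspots:
        sizes = np.bincount(lab.ravel())[1:]
        nspots = int((sizes >= min_area_px).sum())
    return int(nspots)


def extract_features(
    nuclei: LabelGrid,
    rings: LabelGrid,
    channels: np.ndarray,
    eps: float = 1e-6,
    provenance: dict | None = None,
) -> pd.DataFrame:
    """Per-cell feature table from nucleus and ring masks over both channels.

    ``channels`` is ``(2, H, W)`` with channel 0 = Hoechst, 1 = reporter.
    One row per label in the fixed :data:`FEATURE_COLUMNS` order plus
    ``label``, flags (``border_touching``, ``ring_missing``,
    ``low_denominator``) and any ``provenance`` key/values.  Ratio features
    are set to 0 and flagged when their denominator is below ``eps``.
    """
    channels = np.asarray(channels, dtype=float)
    if channels.ndim != 3 or channels.shape[0] != 2:
        raise SegmentationError("channels must be a (2, H, W) array")
    if channels.shape[1:] != nuclei.labels.shape or rings.labels.shape != nuclei.labels.shape:
        raise SegmentationError("channel and label grid shapes differ")
    hoechst, reporter = channels[0], channels[1]
    px2 = nuclei.pixel_size_um**2
    reporter_tophat = (
        white_tophat(reporter, footprint=disk(4)) if nuclei.n_labels else None
    )

    props = {p.label: p for p in regionprops(nuclei.labels)}
    rows = []
    for lab in range(1, nuclei.n_labels + 1):
        nmask = nuclei.labels == lab
        npix = int(nmask.sum())
        if npix == 0:
            continue
        rmask = rings.labels == lab
        p = props[lab]
        hv = hoechst[nmask]
        rv = reporter[nmask]
        median = float(np.median(rv))
        topdec_thr = np.quantile(rv, 0.9)
        topdec = float(rv[rv >= topdec_thr].mean())
        low_denominator = median <= eps
        ratio = 0.0 if low_denominator else topdec / median

        ring_missing = not rmask.any()
        ring_vals = reporter[rmask]
        ring_mean = 0.0 if ring_missing else float(ring_vals.mean())
        ring_sum = 0.0 if ring_missing else float(ring_vals.sum())
        if ring_missing or ring_mean <= eps:
            nuc_ring_ratio = 0.0
            low_denominator = low_denominator or not ring_missing
        else:
            nuc_ring_ratio = float(rv.mean()) / ring_mean

        row = {
            "label": lab,
            "nucleus_area_um2": npix * px2,
            "nucleus_eccentricity": float(p.eccentricity),
            "nucleus_solidity": float(p.solidity),
            "nucleus_mean_hoechst": float(hv.mean()),
            "nucleus_integrated_hoechst": float(hv.sum()),
            "nucleus_sd_hoechst": float(hv.std()),
            "nucleus_mean_reporter": float(rv.mean()),
            "nucleus_integrated_reporter": float(rv.sum()),
            "nucleus_sd_reporter": float(rv.std()),
            "ring_mean_reporter": ring_mean,
            "ring_integrated_reporter": ring_sum,
            "top_decile_reporter": topdec,
            "top_decile_median_ratio": ratio,
            "spot_count": count_spots(reporter, nmask, tophat=reporter_tophat),
            "nuclear_ring_ratio": nuc_ring_ratio,
            "border_touching": lab in nuclei.border_labels,
            "ring_missing": ring_missing,
            "low_denominator": low_denominator,
        }
        if provenance:
            row.update(provenance)
        rows.append(row)
    cols = (
        ["label", *FEATURE_COLUMNS, "border_touching", "ring_missing", "low_denominator"]
        + (list(provenance) if provenance else [])
    )
    return pd.DataFrame(rows, columns=cols)
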