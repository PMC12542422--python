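"""Retrospective illumination (vignetting) correction and focus filtering.

Model: an observed image is ``gain(x) * scene(x) + offset``, with a smooth
multiplicative gain field (the optical vignette) over a spatially uniform
additive camera term.  The gain is estimated from the per-pixel low quantile
of a stack of ordinary site images: because the scene background is
spatially uniform, the smoothed low-quantile field is the camera dark level
plus the vignetted background, so after subtracting the (scalar) dark level
its shape is the gain field itself.  This makes the two-term model
identifiable from modest stacks, which pixelwise regression-style
estimators are not — cell-occupancy noise dominates them.

The gain is normalized to mean 1, so corrected intensities are on the scale
of the field-average illumination (a global scale convention, not absolute
photon counts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.special import ndtri as _norm_ppf


class IlluminationError(ValueError):
    pass


@dataclass
class IlluminationModel:
    """Per-pixel gain (mean 1, strictly positive), additive offset, provenance."""

    gain: np.ndarray
    offset: np.ndarray
    n_images: int

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=np.float64)
        self.offset = np.asarray(self.offset, dtype=np.float64)
        if self.gain.shape != self.offset.shape:
            raise IlluminationError("gain and offset shapes differ")
        if np.any(self.gain <= 0):
            raise IlluminationError("gain must be strictly positive everywhere")

    def save(self, path) -> None:
        """Persist as a 2-page float32 TIFF plus a JSON sidecar."""
        path = Path(path)
        tifffile.imwrite(path, np.stack([self.gain, self.offset]).astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"n_images": self.n_images, "gain_mean": float(self.gain.mean())})
        )

    @classmethod
    def load(cls, path) -> "IlluminationModel":
        path = Path(path)
        pages = tifffile.imread(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(gain=pages[0], offset=pages[1], n_images=int(meta["n_images"]))


def estimate_illumination(
    stack,
    min_images: int = 50,
    quantile: float = 0.05,
    smooth_frac: float = 0.02,
    dark_level: float = 0.0,
) -> IlluminationModel:
    """Estimate gain/offset fields from a stack of site images.

    ``stack`` is ``(N, H, W)`` with N >= ``min_images``.  The per-pixel low
    ``quantile`` across the stack — a background-dominated statistic that is
    robust to cells crossing a pixel — is smoothed with a Gaussian of sigma
    ``smooth_frac`` of the image width; after subtracting ``dark_level``
    (the camera additive term, from dark frames or vendor specs; 0 treats it
    as part of the background) the field is normalized to mean 1 and used as
    the gain.

    A low quantile sits ``z_q`` noise SDs below the local background, which
    would exaggerate the estimated vignette where the background is dim;
    assuming shot-noise statistics (SD ~ sqrt(level)) the bias is removed by
    a short fixed-point iteration before normalization.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise IlluminationError(f"expected (N, H, W) stack, got shape {stack.shape}")
    n = stack.shape[0]
    if n < min_images:
        raise IlluminationError(f"need at least {min_images} images, got {n}")
    if np.allclose(stack, 0):
        raise IlluminationError("degenerate stack: all pixels zero")

    sigma = smooth_frac * stack.shape[2]
    dark = np.quantile(stack, quantile, axis=0)
    dark = ndimage.gaussian_filter(dark, sigma=sigma, mode="nearest")
    z_q = float(-_norm_ppf(quantile))
    if z_q > 0:  # de-bias the quantile's shot-noise floor
        level = dark
        for _ in range(3):
            level = dark + z_q * np.sqrt(np.clip(level, 0, None))
        dark = level
    gain = dark - dark_level
    if np.any(gain <= 0):
        raise IlluminationError(
            "dark level too high: background field not positive after subtraction"
        )
    gain = gain / gain.mean()
    offset = np.full_like(gain, dark_level)
    return IlluminationModel(gain=gain, offset=offset, n_images=n)


def correct_image(img, model: IlluminationModel) -> np.ndarray:
    """Apply ``(img - offset) / gain``, clipped at 0; returns float32."""
    img = np.asarray(img, dtype=float)
    if img.shape != model.gain.shape:
        raise IlluminationError(f"image shape {img.shape} != model shape {model.gain.shape}")
    out = (img - model.offset) / model.gain
    return np.clip(out, 0, None).astype(np.float32)


def sharpness_score(img) -> float:
    """Focus score: variance of the Laplacian."""
    return float(ndimage.laplace(np.asarray(img, dtype=float)).var())


def focus_filter(
    images: list[np.ndarray],
    rel_threshold: float = 0.2,
    names: list[str] | None = None,
) -> tuple[list[int], pd.DataFrame]:
    """Drop out-of-focus images relative to the batch.

    An image is rejected when its sharpness (variance of Laplacian) falls
    below ``rel_threshold`` times the batch median — a relative rule, so the
    decision is invariant to overall exposure.  A single image is always
    retained.  Returns (retained indices, per-image log with scores).
    """
    if len(images) == 0:
        raise IlluminationError("focus_filter needs at least one image")
    scores = np.array([sharpness_score(im) for im in images])
    if len(images) == 1:
        retained_mask = np.array([True])
        cutoff = float("nan")
    else:
        cutoff = float(np.median(scores) * rel_threshold)
        retained_mask = scores >= cutoff
    log = pd.DataFrame(
        {
            "name": names if names is not None else list(range(len(images))),
            "sharpness": scores,
            "cutoff": cutoff,
            "retained": retained_mask,
        }
    )
    return [i for i in range(len(images)) if retained_mask[i]], log
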