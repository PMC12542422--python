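"""Counter-assay quantification: DNA damage and proteasome/synthesis reporter.

Two measurements exclude common indirect routes to ribosome-biogenesis
phenotypes.  The DNA-damage assay scores the fraction of nuclei positive
for a phosphorylated-H2AX-style focal marker; positivity is an explicit,
configurable rule (sub-nuclear focus count or a control-calibrated nuclear
mean) replacing manual counting.  The degradation assay integrates a
nuclear GFP degron reporter per nucleus; the ratio of condition medians
(+auxin / -auxin) reads out proteasome-dependent turnover, and nuclear
levels without auxin reflect synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import LabelGrid, count_spots


class CounterAssayError(ValueError):
    pass


@dataclass
class CounterAssayResult:
    """Per-condition summary of a counter-assay quantification."""

    condition: str
    n_cells: int
    positive_fraction: float  # NaN when undefined
    threshold: float | None = None
    per_cell: pd.DataFrame | None = None
    median_intensity: float | None = None
    undefined_reason: str = ""


def calibrate_intensity_threshold(control_values, n_sd: float = 3.0) -> float:
    """Control mean + ``n_sd`` sample SDs; the relative positivity cutoff."""
    vals = np.asarray(control_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        raise CounterAssayError("threshold calibration needs at least two control cells")
    return float(vals.mean() + n_sd * vals.std(ddof=1))


def nuclear_marker_stats(
    nuclei: LabelGrid, channel: np.ndarray, subtract_background: bool = False
) -> pd.DataFrame:
    """Per-nucleus mean/integrated marker intensity and focal spot count.

    With ``subtract_background`` the median of the extranuclear pixels is
    removed before integrating, so integrated values reflect marker signal
    rather than area times camera background.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.shape != nuclei.labels.shape:
        raise CounterAssayError("channel and nucleus grid shapes differ")
    from skimage.morphology import disk, white_tophat

    bg = float(np.median(channel[nuclei.labels == 0])) if subtract_background else 0.0
    tophat = white_tophat(channel, footprint=disk(2)) if nuclei.n_labels else None
    rows = []
    for lab in range(1, nuclei.n_labels + 1):
        mask = nuclei.labels == lab
        if not mask.any():
            continue
        vals = channel[mask] - bg
        rows.append(
            {
                "label": lab,
                "mean_intensity": float(vals.mean()),
                "integrated_intensity": float(vals.sum()),
                "spot_count": count_spots(
                    channel, mask, footprint_radius=2, rel_threshold=0.3, tophat=tophat
                ),
            }
        )
    return pd.DataFrame(rows, columns=["label", "mean_intensity", "integrated_intensity", "spot_count"])


def h2ax_positive_fraction(
    nuclei: LabelGrid,
    channel: np.ndarray,
    min_spots: int = 5,
    mean_threshold: float | None = None,
    condition: str = "",
) -> CounterAssayResult:
    """Fraction of nuclei positive for the DNA-damage focal marker.

    A nucleus is positive when its focal spot count reaches ``min_spots`` OR
    (when ``mean_threshold`` is given, typically calibrated as solvent-control
    mean + 3 SD) its nuclear mean exceeds the threshold.  With no nuclei the
    fraction is undefined (NaN) with a reason.
    """
    stats = nuclear_marker_stats(nuclei, channel)
    n = len(stats)
    if n == 0:
        return CounterAssayResult(
            condition, 0, float("nan"), mean_threshold, stats, None, "no nuclei segmented"
        )
    positive = stats["spot_count"] >= min_spots
    if mean_threshold is not None:
        positive |= stats["mean_intensity"] > mean_threshold
    stats = stats.assign(positive=positive)
    return CounterAssayResult(
        condition=condition,
        n_cells=n,
        positive_fraction=float(positive.mean()),
        threshold=mean_threshold,
        per_cell=stats,
    )


def nuclear_gfp_levels(
    nuclei: LabelGrid,
    gfp: np.ndarray,
    positive_threshold: float | None = None,
    condition: str = "",
) -> CounterAssayResult:
    """Per-nucleus integrated GFP of the degron reporter, with summaries.

    Returns the per-cell integrated intensities, the condition median, and —
    when ``positive_threshold`` is given (calibrated from an uninduced or
    control condition) — the GFP-positive fraction.  The extranuclear median
    is subtracted before integration, so camera background does not scale
    with nuclear area.
    """
    stats = nuclear_marker_stats(nuclei, gfp, subtract_background=True)
    n = len(stats)
    if n == 0:
        return CounterAssayResult(
            condition, 0, float("nan"), positive_threshold, stats, None, "no nuclei segmented"
        )
    frac = float("nan")
    if positive_threshold is not None:
        frac = float((stats["integrated_intensity"] > positive_threshold).mean())
    return CounterAssayResult(
        condition=condition,
        n_cells=n,
        positive_fraction=frac,
        threshold=positive_threshold,
        per_cell=stats,
        median_intensity=float(stats["integrated_intensity"].median()),
    )


def degradation_ratio(plus_auxin: CounterAssayResult, minus_auxin: CounterAssayResult) -> float:
    """Median integrated GFP ratio (+auxin / -auxin); ~1 means no turnover."""
    if not plus_auxin.median_intensity or not minus_auxin.median_intensity:
        raise CounterAssayError("both conditions need a defined median GFP level")
    return plus_auxin.median_intensity / minus_auxin.median_intensity
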