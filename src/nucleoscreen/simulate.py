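"""Synthetic 384-well screen generator.

Emulates the statistical structure of an imaging-based translocation screen:
plate layouts with control columns, per-well phenotype-class mixtures driven
by a compound "activity", rendered two-channel site images (Hoechst +
reporter) with vignetting and Poisson–Gaussian noise, and a fast "table mode"
that produces classifier-level per-well class counts for whole screens.

The per-well class distribution is a mixture ``p = (1 - a) * p_ctrl + a *
p_act`` where ``a`` is the activity of the compound in the well for the given
readout.  Solvent (DMSO) wells have activity 0 plus a small Beta-distributed
per-well jitter, so the negative-control null has nonzero variance — which
the mean + 5 SD hit threshold downstream requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phenotypes import N_CLASSES, PHENOTYPE_CLASSES
from .platemap import (
    LIBRARY_COLUMNS,
    N_ROWS,
    POSITIVE_CONTROL_PREFIX,
    ROLE_DMSO,
    ROLE_EMPTY,
    ROLE_LIBRARY,
    PlateMap,
    empty_plate_frame,
)

READOUTS: tuple[str, ...] = ("enp1_minus_lmb", "enp1_plus_lmb", "rps2_yfp", "rpl29_gfp")

#: The six positive-control compounds placed in the control columns.
POSITIVE_CONTROLS: tuple[str, ...] = (
    "actinomycin_d",
    "bortezomib",
    "cx_5461",
    "cycloheximide",
    "mg132",
    "silvestrol",
)

# Baseline (solvent) and fully-active class-probability vectors per readout,
# in canonical class order.  The screened biology: without LMB the reporter
# (ENP1) sits in nucleoli at steady state and disperses to the nucleoplasm
# when rRNA transcription stops; with LMB it is nucleoplasmic in controls and
# retained in nucleoli when nucleolar pre-40S assembly fails; the ribosomal-
# protein reporters are cytoplasmic in controls and accumulate in the nucleus
# when subunit maturation is blocked.  Per-class baseline frequencies are not
# published; these defaults keep 82% of cells in scoreable interphase classes.
DEFAULT_P_CTRL: dict[str, np.ndarray] = {
    "enp1_minus_lmb": np.array([0.70, 0.10, 0.02, 0.00, 0.05, 0.03, 0.05, 0.05]),
    "enp1_plus_lmb": np.array([0.03, 0.10, 0.69, 0.00, 0.05, 0.03, 0.05, 0.05]),
    "rps2_yfp": np.array([0.04, 0.04, 0.02, 0.72, 0.05, 0.03, 0.05, 0.05]),
    "rpl29_gfp": np.array([0.04, 0.04, 0.02, 0.72, 0.05, 0.03, 0.05, 0.05]),
}
DEFAULT_P_ACT: dict[str, np.ndarray] = {
    "enp1_minus_lmb": np.array([0.05, 0.10, 0.67, 0.00, 0.05, 0.03, 0.05, 0.05]),
    "enp1_plus_lmb": np.array([0.69, 0.10, 0.03, 0.00, 0.05, 0.03, 0.05, 0.05]),
    "rps2_yfp": np.array([0.30, 0.30, 0.12, 0.10, 0.05, 0.03, 0.05, 0.05]),
    "rpl29_gfp": np.array([0.30, 0.30, 0.12, 0.10, 0.05, 0.03, 0.05, 0.05]),
}

# Class-conditional reporter rendering levels (relative to reporter_scale):
# (nucleoli, nucleoplasm, cytoplasm ring).
REPORTER_LEVELS: dict[str, tuple[float, float, float]] = {
    "nucleolar": (1.0, 0.25, 0.2),
    "nucleolar_nucleoplasmic": (1.0, 0.8, 0.2),
    "nucleoplasmic": (0.3, 0.9, 0.2),
    "cytoplasmic": (0.5, 0.3, 1.0),
    "mitotic": (0.4, 0.4, 0.4),
    "apoptotic": (0.2, 0.2, 0.2),
    "no_signal": (0.0, 0.0, 0.0),
    "missegmented": (1.0, 0.25, 0.2),
}


class LayoutCapacityError(ValueError):
    """More compounds than library wells available."""


class SimulationError(ValueError):
    pass


def _check_probability_vector(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (N_CLASSES,):
        raise SimulationError(f"{name}: expected length-{N_CLASSES} vector, got shape {p.shape}")
    if np.any(p < 0) or not math.isclose(float(p.sum()), 1.0, abs_tol=1e-8):
        raise SimulationError(f"{name}: not a probability vector (sum {p.sum():.6g})")
    return p


# ---------------------------------------------------------------------------
# Plate layout
# ---------------------------------------------------------------------------

def build_screen_layout(
    compound_ids: list[str],
    controls: tuple[str, ...] = POSITIVE_CONTROLS,
    plates: int = 4,
    conc_uM: float = 1.0,
    plate_prefix: str = "plate",
) -> list[PlateMap]:
    """Distribute library compounds over ``plates`` 384-well plates.

    Library compounds fill the 20 inner columns row-major, one well each;
    control columns 1 and 23 hold the solvent (DMSO) control and columns 2
    and 24 cycle through the positive controls; unfilled library wells are
    marked ``empty``.
    """
    capacity = plates * N_ROWS * len(LIBRARY_COLUMNS)
    n = len(compound_ids)
    if n > capacity:
        raise LayoutCapacityError(
            f"{n} compounds exceed capacity {capacity} of {plates} plate(s) "
            f"by {n - capacity}"
        )
    if len(set(compound_ids)) != n:
        raise SimulationError("compound_ids contains duplicates")

    maps = []
    it = iter(compound_ids)
    exhausted = False
    for p in range(plates):
        df = empty_plate_frame()
        df = df.set_index("well", drop=False)
        for r in range(N_ROWS):
            # solvent control in columns 1 and 23
            for c in (1, 23):
                w = f"{chr(ord('A') + r)}{c:02d}"
                df.loc[w, ["role", "compound_id", "conc_uM"]] = [ROLE_DMSO, "DMSO", 0.0]
            # positive controls cycle down columns 2 and 24
            for j, c in enumerate((2, 24)):
                if controls:
                    name = controls[(r + j * N_ROWS) % len(controls)]
                    w = f"{chr(ord('A') + r)}{c:02d}"
                    df.loc[w, ["role", "compound_id", "conc_uM"]] = [
                        POSITIVE_CONTROL_PREFIX + name,
                        name,
                        conc_uM,
                    ]
        if not exhausted:
            for r in range(N_ROWS):
                for c in LIBRARY_COLUMNS:
                    cid = next(it, None)
                    if cid is None:
                        exhausted = True
                        break
                    w = f"{chr(ord('A') + r)}{c:02d}"
                    df.loc[w, ["role", "compound_id", "conc_uM"]] = [ROLE_LIBRARY, cid, conc_uM]
                if exhausted:
                    break
        maps.append(PlateMap(plate_id=f"{plate_prefix}{p + 1}", wells=df.reset_index(drop=True)))
    return maps


# ---------------------------------------------------------------------------
# Effect model
# ---------------------------------------------------------------------------

@dataclass
class EffectModel:
    """Compound activities and class-probability endpoints per readout.

    ``activity`` maps ``(compound_id, readout)`` to ``a`` in [0, 1]; unlisted
    pairs are inactive (a = 0).  Positive-control wells get
    ``control_activity`` on every readout.  ``jitter_mean`` is the mean of the
    Beta-distributed per-well activity jitter (concentration
    ``jitter_concentration``) added as ``a + j * (1 - a)``.
    """

    p_ctrl: dict[str, np.ndarray] = field(default_factory=lambda: dict(DEFAULT_P_CTRL))
    p_act: dict[str, np.ndarray] = field(default_factory=lambda: dict(DEFAULT_P_ACT))
    activity: dict[tuple[str, str], float] = field(default_factory=dict)
    control_activity: float = 0.9
    jitter_mean: float = 0.02
    jitter_concentration: float = 100.0

    def __post_init__(self) -> None:
        for r in self.p_ctrl:
            self.p_ctrl[r] = _check_probability_vector(self.p_ctrl[r], f"p_ctrl[{r}]")
        for r in self.p_act:
            self.p_act[r] = _check_probability_vector(self.p_act[r], f"p_act[{r}]")
        for (cid, r), a in self.activity.items():
            if not 0.0 <= a <= 1.0:
                raise SimulationError(f"activity[{cid}, {r}] = {a} outside [0, 1]")

    @property
    def readouts(self) -> tuple[str, ...]:
        return tuple(self.p_ctrl)

    def base_activity(self, role: str, compound_id: str, readout: str) -> float | None:
        """Nominal activity for a well; ``None`` means no cells (empty well)."""
        if role == ROLE_EMPTY:
            return None
        if role == ROLE_DMSO:
            return 0.0
        if role.startswith(POSITIVE_CONTROL_PREFIX):
            return self.control_activity
        return float(self.activity.get((compound_id, readout), 0.0))

    def jitter(self, rng: np.random.Generator) -> float:
        m, c = self.jitter_mean, self.jitter_concentration
        if m <= 0:
            return 0.0
        return float(rng.beta(m * c, (1.0 - m) * c))

    def well_probs(self, readout: str, activity: float, rng: np.random.Generator) -> np.ndarray:
        """Class mixture for one well, with per-well activity jitter applied."""
        a = activity + self.jitter(rng) * (1.0 - activity)
        p = (1.0 - a) * self.p_ctrl[readout] + a * self.p_act[readout]
        return _check_probability_vector(p, f"mixture[{readout}]")


def example_hit_panel() -> dict[tuple[str, str], float]:
    """Readout-specific activities for the ten seeded hit compounds.

    Mirrors the functional categories of the screen's hits: topoisomerase
    poisons disperse the -LMB reporter to the nucleoplasm, purine-synthesis
    inhibitors act alike, proteasome inhibitors retain it in nucleoli under
    LMB and drive nuclear accumulation of the ribosomal-protein reporters,
    and the translation inhibitor acts on the +LMB readout.
    """
    panel: dict[tuple[str, str], float] = {}
    for cid in ("doxorubicin", "daunorubicin", "idarubicin", "epirubicin", "mitoxantrone"):
        panel[(cid, "enp1_minus_lmb")] = 0.9
        panel[(cid, "rpl29_gfp")] = 0.7
    for cid in ("mycophenolic_acid", "mycophenolate_mofetil"):
        panel[(cid, "enp1_minus_lmb")] = 0.75
    for cid in ("bortezomib_lib", "carfilzomib"):
        panel[(cid, "enp1_plus_lmb")] = 0.9
        panel[(cid, "rps2_yfp")] = 0.8
        panel[(cid, "rpl29_gfp")] = 0.8
    panel[("emetine", "enp1_plus_lmb")] = 0.85
    return panel


# ---------------------------------------------------------------------------
# Per-cell sampling and rendering
# ---------------------------------------------------------------------------

@dataclass
class OpticsConfig:
    """Rendering geometry, intensity scales and noise for one imaged site."""

    pixel_size_um: float = 0.65
    field_px: tuple[int, int] = (256, 256)
    background: float = 20.0
    hoechst_scale: float = 600.0
    reporter_scale: float = 600.0
    vignette: bool = True
    vignette_strength: float = 0.3  # gain drop at the field corner
    offset: float = 10.0  # additive camera term, applied with the vignette
    gain_field: np.ndarray | None = None  # overrides the radial gain if set
    noise: bool = True
    gaussian_sd: float = 2.0

    @property
    def field_um(self) -> tuple[float, float]:
        return (self.field_px[0] * self.pixel_size_um, self.field_px[1] * self.pixel_size_um)

    def gain(self) -> np.ndarray:
        """Multiplicative illumination field (1 at center, 1 - strength at corners)."""
        h, w = self.field_px
        if self.gain_field is not None:
            g = np.asarray(self.gain_field, dtype=float)
            if g.shape != (h, w):
                raise SimulationError(f"gain_field shape {g.shape} != field {self.field_px}")
            return g
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy**2 + cx**2)
        return 1.0 - self.vignette_strength * r2


@dataclass
class CellSpec:
    """Geometry and intensity recipe for one rendered cell."""

    center_um: tuple[float, float]  # (y, x)
    nucleus_radius_um: float
    true_class: str
    nucleoli: list[tuple[float, float, float]]  # (dy, dx, radius), µm, nucleus-relative
    hoechst_level: float
    reporter_levels: tuple[float, float, float]  # (nucleoli, nucleoplasm, ring)


def _make_nucleoli(rng: np.random.Generator, nucleus_radius: float) -> list[tuple[float, float, float]]:
    n = int(rng.integers(2, 5))
    out = []
    for _ in range(n):
        rad = float(rng.uniform(1.0, 1.7))
        rho = rng.uniform(0, max(nucleus_radius - rad - 0.5, 0.1))
        theta = rng.uniform(0, 2 * np.pi)
        out.append((float(rho * np.sin(theta)), float(rho * np.cos(theta)), rad))
    return out


def sample_well_cells(
    class_probs,
    n_cells: int,
    seed: int | np.random.Generator,
    optics: OpticsConfig | None = None,
    packing: float = 0.9,
    max_tries: int = 200,
) -> list[CellSpec]:
    """Draw cells for one imaged site/well from a class mixture.

    Classes are multinomial draws from ``class_probs``; positions are placed
    by dart throwing so that centers keep ``packing * (r_i + r_j)`` apart
    (best effort within ``max_tries`` attempts per cell).  Deterministic for
    a fixed seed.
    """
    if n_cells < 0:
        raise SimulationError("n_cells must be >= 0")
    p = _check_probability_vector(class_probs, "class_probs")
    optics = optics or OpticsConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fy, fx = optics.field_um

    classes = rng.choice(N_CLASSES, size=n_cells, p=p)
    placed: list[CellSpec] = []
    centers = np.empty((n_cells, 2))
    radii = np.empty(n_cells)
    for k in range(n_cells):
        cls = PHENOTYPE_CLASSES[int(classes[k])]
        radius = float(np.clip(rng.normal(5.0, 0.5), 3.5, 6.5))
        if cls == "mitotic":
            radius *= 0.6
        margin = 2.2 * radius
        for _ in range(max_tries):
            cy = float(rng.uniform(margin, fy - margin))
            cx = float(rng.uniform(margin, fx - margin))
            if k == 0:
                break
            d2 = (centers[:k, 0] - cy) ** 2 + (centers[:k, 1] - cx) ** 2
            if np.all(d2 >= (packing * (radius + radii[:k])) ** 2):
                break
        # fall through with the last candidate: overlap allowed past max_tries
        centers[k] = (cy, cx)
        radii[k] = radius
        levels = REPORTER_LEVELS[cls]
        hoechst = float(rng.normal(1.0, 0.05))
        if cls == "mitotic":
            hoechst *= 2.5
        elif cls == "apoptotic":
            hoechst *= 1.3
        nucleoli = []
        if cls in ("nucleolar", "nucleolar_nucleoplasmic", "nucleoplasmic", "cytoplasmic",
                   "no_signal", "missegmented"):
            nucleoli = _make_nucleoli(rng, radius)
        placed.append(
            CellSpec(
                center_um=(cy, cx),
                nucleus_radius_um=radius,
                true_class=cls,
                nucleoli=nucleoli,
                hoechst_level=hoechst,
                reporter_levels=levels,
            )
        )
    return placed


def _disk(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    mask = np.zeros((h, w), dtype=bool)
    if y0 >= y1 or x0 >= x1:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


def _render_cell(
    cell: CellSpec, optics: OpticsConfig, hoechst: np.ndarray, reporter: np.ndarray,
    labels: np.ndarray, label: int, rng: np.random.Generator,
) -> None:
    px = optics.pixel_size_um
    h, w = optics.field_px
    cy, cx = cell.center_um[0] / px, cell.center_um[1] / px
    r = cell.nucleus_radius_um / px
    cls = cell.true_class
    lv_nucleoli, lv_np, lv_ring = cell.reporter_levels
    rs, hs = optics.reporter_scale, optics.hoechst_scale

    if cls == "apoptotic":
        nuc = np.zeros((h, w), dtype=bool)
        for i in range(4):
            theta = rng.uniform(0, 2 * np.pi)
            rho = rng.uniform(0.3, 1.0) * r
            nuc |= _disk(h, w, cy + rho * np.sin(theta), cx + rho * np.cos(theta), 0.35 * r)
    elif cls == "missegmented":
        theta = rng.uniform(0, 2 * np.pi)
        d = 1.1 * r
        nuc = _disk(h, w, cy, cx, r) | _disk(
            h, w, cy + d * np.sin(theta), cx + d * np.cos(theta), 0.9 * r
        )
    else:
        nuc = _disk(h, w, cy, cx, r)

    hoechst[nuc] += cell.hoechst_level * hs
    free = labels == 0
    labels[nuc & free] = label

    if cls == "mitotic":
        cellbody = _disk(h, w, cy, cx, 1.6 * r)
        reporter[cellbody] += lv_np * rs
        return
    if cls == "apoptotic":
        reporter[nuc] += lv_np * rs
        return
    if cls == "no_signal":
        return

    cyto = _disk(h, w, cy, cx, 2.0 * r) & ~nuc
    reporter[cyto] += lv_ring * rs
    reporter[nuc] += lv_np * rs
    for dy, dx, rad in cell.nucleoli:
        ncl = _disk(h, w, cy + dy / px, cx + dx / px, rad / px) & nuc
        reporter[ncl] += (lv_nucleoli - lv_np) * rs


def render_site(
    cells: list[CellSpec],
    optics: OpticsConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render one site: returns ``(image, labels, truth)``.

    ``image`` is a float32 stack ``(2, H, W)`` with channel 0 = Hoechst and
    channel 1 = reporter; ``labels`` is the ground-truth nucleus label grid
    (int32, one label per cell, first cell wins contested pixels); ``truth``
    has one row per cell (label, true class, geometry).
    """
    optics = optics or OpticsConfig()
    if optics.pixel_size_um <= 0:
        raise SimulationError("pixel size must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = optics.field_px
    fy, fx = optics.field_um
    for c in cells:
        if not (0 <= c.center_um[0] <= fy and 0 <= c.center_um[1] <= fx):
            raise SimulationError(f"cell center {c.center_um} outside field {optics.field_um}")

    hoechst = np.full((h, w), optics.background, dtype=float)
    reporter = np.full((h, w), optics.background, dtype=float)
    labels = np.zeros((h, w), dtype=np.int32)
    recs = []
    for i, cell in enumerate(cells, start=1):
        _render_cell(cell, optics, hoechst, reporter, labels, i, rng)
        recs.append(
            {
                "label": i,
                "true_class": cell.true_class,
                "center_y_um": cell.center_um[0],
                "center_x_um": cell.center_um[1],
                "nucleus_radius_um": cell.nucleus_radius_um,
            }
        )
    img = np.stack([hoechst, reporter])

    if optics.vignette or optics.gain_field is not None:
        g = optics.gain()
        img = img * g[None] + optics.offset
    if optics.noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
        img = img + rng.normal(0.0, optics.gaussian_sd, size=img.shape)
        img = np.clip(img, 0, None)

    truth = pd.DataFrame(
        recs, columns=["label", "true_class", "center_y_um", "center_x_um", "nucleus_radius_um"]
    )
    return img.astype(np.float32), labels, truth


# ---------------------------------------------------------------------------
# Table mode: whole screens without rendering
# ---------------------------------------------------------------------------

def identity_confusion() -> np.ndarray:
    return np.eye(N_CLASSES)


def simulate_screen_tables(
    layouts: list[PlateMap],
    effect: EffectModel,
    cells_per_well: float = 360.0,
    confusion: np.ndarray | None = None,
    replicates: int = 3,
    seed: int = 0,
    readouts: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Simulate per-well class-count tables for a whole multi-readout screen.

    True classes are drawn per well from the effect-model mixture (cell count
    Poisson around ``cells_per_well``, matching the imaged fraction of a
    seeded well) and then perturbed through the classifier ``confusion``
    matrix (rows = true class, columns = observed class; identity by
    default).  The output schema matches what per-cell classification plus
    class counting produce in image mode: one row per (readout, replicate,
    plate, well) with the eight class-count columns.
    """
    if replicates < 1:
        raise SimulationError("replicates must be >= 1")
    conf = identity_confusion() if confusion is None else np.asarray(confusion, dtype=float)
    if conf.shape != (N_CLASSES, N_CLASSES):
        raise SimulationError(f"confusion matrix must be {N_CLASSES}x{N_CLASSES}")
    if np.any(conf < 0) or not np.allclose(conf.sum(axis=1), 1.0, atol=1e-8):
        raise SimulationError("confusion matrix rows must be probability vectors")
    readouts = readouts or effect.readouts

    rng = np.random.default_rng(seed)
    rows = []
    for readout in readouts:
        for rep in range(1, replicates + 1):
            for pm in layouts:
                for rec in pm.wells.itertuples(index=False):
                    a = effect.base_activity(rec.role, rec.compound_id, readout)
                    meta = {
                        "readout": readout,
                        "replicate": rep,
                        "plate": pm.plate_id,
                        "well": rec.well,
                        "role": rec.role,
                        "compound_id": rec.compound_id,
                        "conc_uM": rec.conc_uM,
                    }
                    if a is None:
                        counts = np.zeros(N_CLASSES, dtype=int)
                    else:
                        p = effect.well_probs(readout, a, rng)
                        n = int(rng.poisson(cells_per_well))
                        true_counts = rng.multinomial(n, p)
                        counts = np.zeros(N_CLASSES, dtype=int)
                        for c in range(N_CLASSES):
                            if true_counts[c]:
                                counts += rng.multinomial(int(true_counts[c]), conf[c])
                    rows.append({**meta, **dict(zip(PHENOTYPE_CLASSES, counts.tolist()))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Counter-assay scenes
# ---------------------------------------------------------------------------

def simulate_dna_damage_site(
    n_cells: int,
    positive_fraction: float,
    seed: int | np.random.Generator = 0,
    optics: OpticsConfig | None = None,
    foci_per_positive: int = 10,
    focus_level: float = 1.0,
    diffuse_level: float = 0.08,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a DNA-damage counter-assay site (Hoechst + damage-marker channel).

    A deterministic count ``round(positive_fraction * n_cells)`` of nuclei get
    ``foci_per_positive`` bright sub-nuclear foci; the rest carry only a faint
    diffuse marker level.  Returns (image, ground-truth labels, truth table
    with a ``positive`` column).
    """
    optics = optics or OpticsConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.zeros(N_CLASSES)
    p[PHENOTYPE_CLASSES.index("no_signal")] = 1.0
    cells = sample_well_cells(p, n_cells, rng, optics=optics)
    img, labels, truth = render_site(cells, optics=replace(optics, noise=False, vignette=False), seed=rng)
    hoechst, marker = img[0].astype(float), np.full(optics.field_px, optics.background, dtype=float)

    n_pos = int(round(positive_fraction * n_cells))
    positive = np.zeros(n_cells, dtype=bool)
    positive[:n_pos] = True
    px = optics.pixel_size_um
    for i, cell in enumerate(cells):
        cy, cx = cell.center_um[0] / px, cell.center_um[1] / px
        r = cell.nucleus_radius_um / px
        nuc = labels == (i + 1)
        marker[nuc] += diffuse_level * optics.reporter_scale
        if positive[i]:
            # discrete puncta: rejection-sampled so foci do not stack
            centers: list[tuple[float, float]] = []
            focus_r = 0.6 / px
            tries = 0
            while len(centers) < foci_per_positive and tries < 100 * foci_per_positive:
                tries += 1
                theta = rng.uniform(0, 2 * np.pi)
                rho = rng.uniform(0, 0.8 * r)
                fy, fx = cy + rho * np.sin(theta), cx + rho * np.cos(theta)
                if all((fy - y) ** 2 + (fx - x) ** 2 >= (3 * focus_r) ** 2 for y, x in centers):
                    centers.append((fy, fx))
            for fy, fx in centers:
                focus = _disk(*optics.field_px, fy, fx, focus_r)
                marker[focus & nuc] += focus_level * optics.reporter_scale
    img = np.stack([hoechst, marker])
    if optics.noise:
        img = np.clip(rng.poisson(np.clip(img, 0, None)).astype(float)
                      + rng.normal(0, optics.gaussian_sd, img.shape), 0, None)
    truth = truth.assign(positive=positive)
    return img.astype(np.float32), labels, truth


def simulate_degron_reporter_site(
    n_cells: int,
    gfp_level: float,
    seed: int | np.random.Generator = 0,
    optics: OpticsConfig | None = None,
    level_cv: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a nuclear degron-reporter site (Hoechst + nuclear GFP channel).

    Per-cell GFP is lognormal around ``gfp_level`` (coefficient of variation
    ``level_cv``) and uniform within the nucleus, emulating an NLS-tagged
    reporter whose abundance reflects synthesis/degradation balance.
    """
    optics = optics or OpticsConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.zeros(N_CLASSES)
    p[PHENOTYPE_CLASSES.index("no_signal")] = 1.0
    cells = sample_well_cells(p, n_cells, rng, optics=optics)
    img, labels, truth = render_site(cells, optics=replace(optics, noise=False, vignette=False), seed=rng)
    hoechst = img[0].astype(float)
    gfp = np.full(optics.field_px, optics.background, dtype=float)
    sigma = math.sqrt(math.log(1.0 + level_cv**2))
    per_cell = gfp_level * rng.lognormal(-0.5 * sigma**2, sigma, size=n_cells)
    for i in range(n_cells):
        gfp[labels == (i + 1)] += per_cell[i] * optics.reporter_scale
    img = np.stack([hoechst, gfp])
    if optics.noise:
        img = np.clip(rng.poisson(np.clip(img, 0, None)).astype(float)
                      + rng.normal(0, optics.gaussian_sd, img.shape), 0, None)
    truth = truth.assign(gfp_level=per_cell)
    return img.astype(np.float32), labels, truth
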