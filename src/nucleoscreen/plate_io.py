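"""Screen configuration, orchestration and artifact I/O.

One :class:`ScreenConfig` drives the whole pipeline end to end in either of
two modes: ``tables`` simulates classifier-level per-well class counts for a
full multi-plate screen directly, while ``images`` renders site images and
runs them through illumination correction, focus filtering, segmentation,
feature extraction and classification before the shared statistics stage
(hit rates, z', 5-SD thresholds, hit calling, QC).  Every written artifact
carries the config hash and seed, so an unchanged config reproduces outputs
exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .classifier import ClassifierModel, classify_cells, train_classifier
from .illumination import correct_image, estimate_illumination, focus_filter
from .phenotypes import N_CLASSES
from .platemap import PlateMap, load_plate_maps, save_plate_maps
from .screen_stats import (
    HitCallReport,
    call_hits,
    class_counts,
    default_readout_specs,
    hit_rate_table,
    qc_report,
    threshold_table,
    zprime_report,
)
from .segmentation import LabelGrid, cytoplasm_rings, extract_features, segment_nuclei

logger = logging.getLogger("nucleoscreen")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and well."""


@dataclass
class ScreenConfig:
    """All knobs of a simulated screen run."""

    mode: str = "tables"  # "tables" | "images"
    seed: int = 1
    readouts: tuple[str, ...] = sim.READOUTS
    plates: int = 4
    replicates: int = 3
    n_compounds: int = 1172
    compound_ids: tuple[str, ...] | None = None  # overrides n_compounds
    active_compounds: dict = field(default_factory=dict)  # {cid: {readout: a}}
    control_activity: float = 0.9
    jitter_mean: float = 0.02
    cells_per_well: float = 360.0
    conc_uM: float = 1.0
    # image mode
    sites_per_well: int = 9
    cells_per_site_mean: float = 40.0
    field_px: int = 256
    pixel_size_um: float = 0.65
    ring_width_um: float = 6.5
    min_illum_images: int = 50
    row_subset: tuple[str, ...] | None = None  # e.g. ("A", "B") to shrink image mode
    train_cells: int = 800
    exclude_border_cells: bool = True
    # statistics
    threshold_n_sd: float = 5.0
    replicate_rule_k: int = 2
    enp1_minus_lmb_denominator: str = "methods_table"

    def __post_init__(self) -> None:
        if self.mode not in ("tables", "images"):
            raise PipelineError(f"unknown mode {self.mode!r}")
        if self.threshold_n_sd <= 0 or self.ring_width_um <= 0:
            raise PipelineError("threshold multiplier and ring width must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for k in ("readouts", "compound_ids", "row_subset"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass
class ScreenResults:
    """Everything one screen run produces."""

    config: ScreenConfig
    layouts: list[PlateMap]
    cells: pd.DataFrame | None  # per-cell table (image mode only)
    counts: pd.DataFrame
    rates: pd.DataFrame
    thresholds: pd.DataFrame
    zprime: pd.DataFrame
    hitcall: HitCallReport
    qc: dict
    provenance: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_plate_maps(self.layouts, out / "plate_maps.csv")
        if self.cells is not None:
            self.cells.to_csv(out / "cells.csv", index=False)
        self.counts.to_csv(out / "class_counts.csv", index=False)
        self.rates.to_csv(out / "hit_rates.csv", index=False)
        self.thresholds.to_csv(out / "thresholds.csv", index=False)
        self.zprime.to_csv(out / "zprime.csv", index=False)
        self.hitcall.to_json(out / "hit_calls.json")
        self.qc["cells"].to_csv(out / "qc_cells.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=1, sort_keys=True))


def _effect_from_config(config: ScreenConfig) -> sim.EffectModel:
    activity = {
        (cid, readout): float(a)
        for cid, per_readout in config.active_compounds.items()
        for readout, a in per_readout.items()
    }
    p_ctrl = {r: sim.DEFAULT_P_CTRL[r] for r in config.readouts}
    p_act = {r: sim.DEFAULT_P_ACT[r] for r in config.readouts}
    return sim.EffectModel(
        p_ctrl=p_ctrl,
        p_act=p_act,
        activity=activity,
        control_activity=config.control_activity,
        jitter_mean=config.jitter_mean,
    )


def _layouts_from_config(config: ScreenConfig) -> list[PlateMap]:
    if config.compound_ids is not None:
        compounds = list(config.compound_ids)
    else:
        width = len(str(max(config.n_compounds, 1)))
        compounds = [f"compound_{i + 1:0{width}d}" for i in range(config.n_compounds)]
    for cid in config.active_compounds:
        if cid not in compounds:
            raise PipelineError(f"active compound {cid!r} is not in the library")
    return sim.build_screen_layout(
        compounds, sim.POSITIVE_CONTROLS, plates=config.plates, conc_uM=config.conc_uM
    )


def make_training_features(
    optics: sim.OpticsConfig,
    n_cells: int = 800,
    seed: int = 0,
    ring_width_um: float = 6.5,
) -> pd.DataFrame:
    """Labeled feature table from rendered cells with ground-truth masks.

    Cells are drawn uniformly over the eight classes and features are
    extracted on the simulator's true nucleus labels — the stand-in for the
    manual annotation that seeds supervised classification in a real screen.
    Returns features plus a ``true_class`` column.
    """
    rng = np.random.default_rng(seed)
    p_uniform = np.full(N_CLASSES, 1.0 / N_CLASSES)
    per_site = 30
    frames = []
    total = 0
    while total < n_cells:
        n = min(per_site, n_cells - total)
        cells = sim.sample_well_cells(p_uniform, n, rng, optics=optics)
        img, labels, truth = sim.render_site(cells, optics=optics, seed=rng)
        grid = LabelGrid(labels, optics.pixel_size_um)
        rings = cytoplasm_rings(grid, ring_width_um)
        feats = extract_features(grid, rings, img)
        feats = feats.merge(truth[["label", "true_class"]], on="label")
        frames.append(feats)
        total += n
    return pd.concat(frames, ignore_index=True)


def train_default_classifier(config: ScreenConfig, seed: int) -> ClassifierModel:
    optics = sim.OpticsConfig(
        pixel_size_um=config.pixel_size_um,
        field_px=(config.field_px, config.field_px),
        vignette=False,
    )
    feats = make_training_features(
        optics, n_cells=config.train_cells, seed=seed, ring_width_um=config.ring_width_um
    )
    return train_classifier(feats, feats["true_class"], seed=seed)


def _simulate_image_mode_cells(
    config: ScreenConfig,
    layouts: list[PlateMap],
    effect: sim.EffectModel,
    model: ClassifierModel,
    seed: int,
) -> pd.DataFrame:
    """Render, correct, segment, extract and classify every imaged site."""
    rng = np.random.default_rng(seed)
    optics = sim.OpticsConfig(
        pixel_size_um=config.pixel_size_um, field_px=(config.field_px, config.field_px)
    )
    all_cells = []
    for readout in config.readouts:
        for rep in range(1, config.replicates + 1):
            for pm in layouts:
                wells = pm.wells
                if config.row_subset is not None:
                    wells = wells[wells["well"].str[0].isin(config.row_subset)]
                # render all sites of this (readout, replicate, plate) batch
                sites = []  # (well rec, site index, image, probs)
                for rec in wells.itertuples(index=False):
                    a = effect.base_activity(rec.role, rec.compound_id, readout)
                    if a is None:
                        continue
                    probs = effect.well_probs(readout, a, rng)
                    for s in range(1, config.sites_per_well + 1):
                        n = int(rng.poisson(config.cells_per_site_mean))
                        cells = sim.sample_well_cells(probs, n, rng, optics=optics)
                        img, _, _ = sim.render_site(cells, optics=optics, seed=rng)
                        sites.append((rec, s, img))
                if not sites:
                    continue
                try:
                    models = [
                        estimate_illumination(
                            np.stack([img[ch] for _, _, img in sites]),
                            min_images=config.min_illum_images,
                            dark_level=optics.offset,
                        )
                        for ch in (0, 1)
                    ]
                except Exception as err:
                    raise PipelineError(
                        f"illumination estimation failed for {readout} rep {rep} "
                        f"plate {pm.plate_id}: {err}"
                    ) from err
                corrected = [
                    np.stack([correct_image(img[ch], models[ch]) for ch in (0, 1)])
                    for _, _, img in sites
                ]
                keep, _ = focus_filter([c[0] for c in corrected])
                for idx in keep:
                    rec, s, _ = sites[idx]
                    img = corrected[idx]
                    try:
                        grid = segment_nuclei(img[0], pixel_size_um=config.pixel_size_um)
                        rings = cytoplasm_rings(grid, config.ring_width_um)
                        feats = extract_features(
                            grid,
                            rings,
                            img,
                            provenance={
                                "readout": readout,
                                "replicate": rep,
                                "plate": pm.plate_id,
                                "well": rec.well,
                                "site": s,
                                "role": rec.role,
                                "compound_id": rec.compound_id,
                                "conc_uM": rec.conc_uM,
                            },
                        )
                    except Exception as err:
                        raise PipelineError(
                            f"segmentation failed at {readout} rep {rep} plate "
                            f"{pm.plate_id} well {rec.well} site {s}: {err}"
                        ) from err
                    if len(feats) == 0:
                        continue
                    if config.exclude_border_cells:
                        feats = feats[~feats["border_touching"]].reset_index(drop=True)
                    if len(feats) == 0:
                        continue
                    pred = classify_cells(model, feats)
                    feats = feats.assign(predicted_class=pred["predicted_class"].to_numpy())
                    all_cells.append(feats)
    if not all_cells:
        raise PipelineError("image mode produced no cells; check the well subset")
    return pd.concat(all_cells, ignore_index=True)


def run_screen_analysis(
    config: ScreenConfig, out_dir=None, classifier: ClassifierModel | None = None
) -> ScreenResults:
    """Run the configured screen end to end and return all result tables."""
    logger.info("screen run: mode=%s seed=%d hash=%s", config.mode, config.seed, config.hash())
    root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)]

    layouts = _layouts_from_config(config)
    effect = _effect_from_config(config)

    cells = None
    if config.mode == "tables":
        counts = sim.simulate_screen_tables(
            layouts,
            effect,
            cells_per_well=config.cells_per_well,
            replicates=config.replicates,
            seed=seeds[0],
            readouts=config.readouts,
        )
        if config.row_subset is not None:
            counts = counts[counts["well"].str[0].isin(config.row_subset)]
            counts = counts.reset_index(drop=True)
    else:
        model = classifier or train_default_classifier(config, seed=seeds[1])
        cells = _simulate_image_mode_cells(config, layouts, effect, model, seed=seeds[0])
        counts = class_counts(cells)

    specs = default_readout_specs(config.enp1_minus_lmb_denominator)
    rates = hit_rate_table(counts, specs)
    thresholds = threshold_table(rates, n_sd=config.threshold_n_sd)
    zp = zprime_report(rates)
    hitcall = call_hits(
        rates, thresholds, k=config.replicate_rule_k, n_replicates=config.replicates
    )
    qc = qc_report(counts, rates)
    provenance = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "mode": config.mode,
        "config": config.to_dict(),
    }
    results = ScreenResults(
        config=config,
        layouts=layouts,
        cells=cells,
        counts=counts,
        rates=rates,
        thresholds=thresholds,
        zprime=zp,
        hitcall=hitcall,
        qc=qc,
        provenance=provenance,
    )
    if out_dir is not None:
        results.write(out_dir)
    return results


__all__ = [
    "PipelineError",
    "ScreenConfig",
    "ScreenResults",
    "load_plate_maps",
    "make_training_features",
    "run_screen_analysis",
    "train_default_classifier",
]
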