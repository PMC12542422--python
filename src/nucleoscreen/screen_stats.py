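"""Screen statistics: readout hit rates, z'-factor QC and 5-SD hit calling.

A readout maps the eight phenotype classes onto hit, non-hit and excluded
sets; the per-well hit rate is hits / (hits + non-hits), with mitotic,
apoptotic, signal-free and missegmented cells never counted.  Assay quality
is summarized by the z'-factor

    z' = 1 - 3 * (sigma_pos + sigma_neg) / |mu_pos - mu_neg|

between positive-control and solvent (DMSO) well hit rates.  Hits are
called per replicate against a threshold of DMSO mean + 5 SD, and a
compound is a final hit for a readout when at least k of N replicates
exceed the threshold (default 2 of 3); the screen-level hit list is the
union over readouts.  Sample standard deviations (n - 1) are used
throughout, matching the small numbers of control wells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenotypes import EXCLUDED_CLASSES, PHENOTYPE_CLASSES, validate_classes
from .platemap import POSITIVE_CONTROL_PREFIX, ROLE_DMSO, ROLE_LIBRARY


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ReadoutSpec:
    """Hit / non-hit / excluded class sets for one readout."""

    name: str
    hit: frozenset[str]
    non_hit: frozenset[str]
    excluded: frozenset[str] = frozenset(EXCLUDED_CLASSES)

    def __post_init__(self) -> None:
        validate_classes(self.hit | self.non_hit | self.excluded)
        if self.hit & self.non_hit or self.hit & self.excluded or self.non_hit & self.excluded:
            raise StatsError(f"readout {self.name}: hit/non-hit/excluded sets overlap")


def default_readout_specs(
    enp1_minus_lmb_denominator: str = "methods_table",
) -> dict[str, ReadoutSpec]:
    """The four screen readouts with their class mappings.

    For the -LMB readout the published description of the denominator is
    ambiguous; ``methods_table`` (default) counts nucleolar and
    nucleolar/nucleoplasmic cells as non-hits, ``results_text`` only
    nucleolar cells, and ``all_interphase`` every interphase class.
    """
    minus_non_hit = {
        "methods_table": {"nucleolar", "nucleolar_nucleoplasmic"},
        "results_text": {"nucleolar"},
        "all_interphase": {"nucleolar", "nucleolar_nucleoplasmic", "cytoplasmic"},
    }
    try:
        non_hit = minus_non_hit[enp1_minus_lmb_denominator]
    except KeyError:
        raise StatsError(
            f"unknown denominator variant {enp1_minus_lmb_denominator!r}"
        ) from None
    nuclear = {"nucleolar", "nucleolar_nucleoplasmic", "nucleoplasmic"}
    return {
        "enp1_minus_lmb": ReadoutSpec(
            "enp1_minus_lmb", frozenset({"nucleoplasmic"}), frozenset(non_hit)
        ),
        "enp1_plus_lmb": ReadoutSpec(
            "enp1_plus_lmb",
            frozenset({"nucleolar"}),
            frozenset({"nucleolar_nucleoplasmic", "nucleoplasmic"}),
        ),
        "rps2_yfp": ReadoutSpec("rps2_yfp", frozenset(nuclear), frozenset({"cytoplasmic"})),
        "rpl29_gfp": ReadoutSpec("rpl29_gfp", frozenset(nuclear), frozenset({"cytoplasmic"})),
    }


# ---------------------------------------------------------------------------
# Counting and rates
# ---------------------------------------------------------------------------

def class_counts(
    cells: pd.DataFrame,
    keys: tuple[str, ...] = ("readout", "replicate", "plate", "well"),
    class_col: str = "predicted_class",
) -> pd.DataFrame:
    """Per-well class-count table from a per-cell table (sites pooled).

    Output: one row per key combination with the eight class-count columns;
    metadata columns (``role``, ``compound_id``, ``conc_uM``) are carried
    through when present.
    """
    if len(cells) == 0:
        return pd.DataFrame(columns=[*keys, *PHENOTYPE_CLASSES])
    validate_classes(cells[class_col].unique())
    wide = (
        cells.groupby([*keys, class_col], sort=True)
        .size()
        .unstack(class_col, fill_value=0)
        .reindex(columns=list(PHENOTYPE_CLASSES), fill_value=0)
        .reset_index()
    )
    meta_cols = [c for c in ("role", "compound_id", "conc_uM") if c in cells.columns]
    if meta_cols:
        meta = cells.groupby(list(keys), sort=True)[meta_cols].first().reset_index()
        wide = meta.merge(wide, on=list(keys))
    wide.columns.name = None
    return wide


def readout_hit_rate(counts: pd.DataFrame, spec: ReadoutSpec) -> pd.DataFrame:
    """Per-well hit rates for one readout from a class-count table.

    Adds ``hit_count``, ``non_hit_count``, ``n_classified`` (all eight
    classes), ``hit_rate`` (NaN with ``undefined_reason`` when the
    denominator hits + non-hits is zero).
    """
    out = counts.copy()
    hit = out[sorted(spec.hit)].sum(axis=1)
    non_hit = out[sorted(spec.non_hit)].sum(axis=1)
    denom = hit + non_hit
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(denom > 0, hit / np.maximum(denom, 1), np.nan)
    out["hit_count"] = hit.astype(int)
    out["non_hit_count"] = non_hit.astype(int)
    out["n_classified"] = out[list(PHENOTYPE_CLASSES)].sum(axis=1).astype(int)
    out["hit_rate"] = rate
    out["undefined_reason"] = np.where(denom > 0, "", "no hit/non-hit cells")
    return out


def hit_rate_table(
    counts: pd.DataFrame, specs: dict[str, ReadoutSpec] | None = None
) -> pd.DataFrame:
    """Apply each readout's spec to its own rows of a multi-readout table."""
    specs = specs or default_readout_specs()
    parts = []
    for readout, grp in counts.groupby("readout", sort=True):
        if readout not in specs:
            raise StatsError(f"no readout spec for {readout!r}")
        parts.append(readout_hit_rate(grp, specs[readout]))
    return pd.concat(parts, ignore_index=True) if parts else counts


# ---------------------------------------------------------------------------
# z' and thresholds
# ---------------------------------------------------------------------------

def zprime(pos_rates, neg_rates) -> float:
    """z'-factor between two well populations (sample SDs, n - 1).

    Returns NaN (the undefined flag) when the group means coincide; raises
    for groups smaller than two, where the sample SD does not exist.
    """
    pos = np.asarray(pos_rates, dtype=float)
    neg = np.asarray(neg_rates, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise StatsError("z' needs at least two values in each group")
    mu_p, mu_n = pos.mean(), neg.mean()
    if mu_p == mu_n:
        return float("nan")
    return float(1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / abs(mu_p - mu_n))


def dmso_threshold(dmso_rates, n_sd: float = 5.0) -> float:
    """Hit-calling threshold: DMSO mean + ``n_sd`` sample SDs."""
    rates = np.asarray(dmso_rates, dtype=float)
    rates = rates[~np.isnan(rates)]
    if len(rates) < 2:
        raise StatsError("threshold needs at least two DMSO wells")
    return float(rates.mean() + n_sd * rates.std(ddof=1))


def zprime_report(rates: pd.DataFrame) -> pd.DataFrame:
    """z' per (readout, replicate, positive control), control wells pooled
    across plates, against the pooled DMSO wells."""
    rows = []
    for (readout, rep), grp in rates.groupby(["readout", "replicate"], sort=True):
        neg = grp.loc[grp["role"] == ROLE_DMSO, "hit_rate"].dropna().to_numpy()
        ctl = grp[grp["role"].str.startswith(POSITIVE_CONTROL_PREFIX, na=False)]
        for role, cgrp in ctl.groupby("role", sort=True):
            pos = cgrp["hit_rate"].dropna().to_numpy()
            rows.append(
                {
                    "readout": readout,
                    "replicate": rep,
                    "control": role[len(POSITIVE_CONTROL_PREFIX):],
                    "mu_pos": pos.mean() if len(pos) else np.nan,
                    "sd_pos": pos.std(ddof=1) if len(pos) > 1 else np.nan,
                    "mu_neg": neg.mean() if len(neg) else np.nan,
                    "sd_neg": neg.std(ddof=1) if len(neg) > 1 else np.nan,
                    "n_pos": len(pos),
                    "n_neg": len(neg),
                    "zprime": zprime(pos, neg) if len(pos) > 1 and len(neg) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def threshold_table(rates: pd.DataFrame, n_sd: float = 5.0) -> pd.DataFrame:
    """Per (readout, replicate) DMSO mean, SD and the mean + n_sd * SD cutoff."""
    rows = []
    for (readout, rep), grp in rates.groupby(["readout", "replicate"], sort=True):
        dmso = grp.loc[grp["role"] == ROLE_DMSO, "hit_rate"].dropna().to_numpy()
        if len(dmso) < 2:
            raise StatsError(f"readout {readout} replicate {rep}: fewer than two DMSO wells")
        rows.append(
            {
                "readout": readout,
                "replicate": rep,
                "dmso_mean": float(dmso.mean()),
                "dmso_sd": float(dmso.std(ddof=1)),
                "threshold": dmso_threshold(dmso, n_sd=n_sd),
                "n_dmso": len(dmso),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hit calling
# ---------------------------------------------------------------------------

@dataclass
class HitCallReport:
    """Thresholds, per-replicate flags, per-readout and union hit lists."""

    thresholds: pd.DataFrame
    flags: pd.DataFrame
    per_readout_hits: dict[str, list[str]]
    hits: list[str]
    incomplete: list[dict] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "thresholds": self.thresholds.to_dict(orient="records"),
            "per_readout_hits": self.per_readout_hits,
            "hits": self.hits,
            "incomplete": self.incomplete,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def call_hits(
    rates: pd.DataFrame,
    thresholds: pd.DataFrame | None = None,
    k: int = 2,
    n_replicates: int | None = None,
    n_sd: float = 5.0,
) -> HitCallReport:
    """Call compound hits from library-well hit rates.

    A replicate flags a compound when its well's rate exceeds that
    replicate's threshold (undefined rates never count); a compound is a hit
    for a readout when at least ``k`` of the expected ``n_replicates`` flag
    it.  Compounds with any missing or undefined replicate rate are logged
    as incomplete and excluded from the final list.
    """
    thresholds = threshold_table(rates, n_sd=n_sd) if thresholds is None else thresholds
    lib = rates[rates["role"] == ROLE_LIBRARY].copy()
    thr_map = {
        (t.readout, t.replicate): t.threshold for t in thresholds.itertuples(index=False)
    }
    missing_thr = set(zip(lib["readout"], lib["replicate"])) - set(thr_map)
    if missing_thr:
        raise StatsError(f"no threshold for {sorted(missing_thr)}")
    expected_n = n_replicates or int(rates["replicate"].nunique())

    lib["threshold"] = [thr_map[(r, p)] for r, p in zip(lib["readout"], lib["replicate"])]
    lib["defined"] = ~lib["hit_rate"].isna()
    lib["above"] = lib["defined"] & (lib["hit_rate"] > lib["threshold"])

    per_readout: dict[str, list[str]] = {}
    incomplete: list[dict] = []
    for (readout, cid), grp in lib.groupby(["readout", "compound_id"], sort=True):
        n_defined = int(grp["defined"].sum())
        if n_defined < expected_n:
            incomplete.append(
                {
                    "readout": readout,
                    "compound_id": cid,
                    "replicates_defined": n_defined,
                    "replicates_expected": expected_n,
                }
            )
            continue
        if int(grp["above"].sum()) >= k:
            per_readout.setdefault(readout, []).append(cid)
    for readout in per_readout:
        per_readout[readout] = sorted(per_readout[readout])
    union = sorted({cid for lst in per_readout.values() for cid in lst})
    flag_cols = [
        "readout", "replicate", "plate", "well", "compound_id",
        "hit_rate", "threshold", "defined", "above",
    ]
    return HitCallReport(
        thresholds=thresholds,
        flags=lib[[c for c in flag_cols if c in lib.columns]].reset_index(drop=True),
        per_readout_hits=per_readout,
        hits=union,
        incomplete=incomplete,
    )


# ---------------------------------------------------------------------------
# QC summary
# ---------------------------------------------------------------------------

def qc_report(counts: pd.DataFrame, rates: pd.DataFrame | None = None) -> dict:
    """Replicate-level QC: classified-cell counts and z' per positive control.

    ``cells``: per (readout, replicate) mean and sample SD of per-well
    classified-cell counts (SD is NaN and flagged when only one well).
    ``zprime``: the per-control z' table when ``rates`` is given.
    """
    df = counts.copy()
    df["n_classified"] = df[list(PHENOTYPE_CLASSES)].sum(axis=1)
    rows = []
    for (readout, rep), grp in df.groupby(["readout", "replicate"], sort=True):
        n = grp["n_classified"].to_numpy(dtype=float)
        rows.append(
            {
                "readout": readout,
                "replicate": rep,
                "n_wells": len(n),
                "mean_cells": float(n.mean()),
                "sd_cells": float(n.std(ddof=1)) if len(n) > 1 else np.nan,
                "single_well": len(n) == 1,
                "total_cells": int(n.sum()),
            }
        )
    report = {"cells": pd.DataFrame(rows)}
    if rates is not None:
        report["zprime"] = zprime_report(rates)
    return report
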