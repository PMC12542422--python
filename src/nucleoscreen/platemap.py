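"""384-well plate maps: layout conventions, validation and CSV round-trip.

Wells are named letter row ``A``–``P`` plus zero-padded column ``01``–``24``
(``A01`` … ``P24``).  Columns 1, 2, 23 and 24 are reserved for controls
(solvent and positive-control compounds); the 20 inner columns hold library
compounds, one compound per well across the whole screen.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

ROWS = "ABCDEFGHIJKLMNOP"
N_ROWS = len(ROWS)
N_COLS = 24
CONTROL_COLUMNS = (1, 2, 23, 24)
LIBRARY_COLUMNS = tuple(c for c in range(1, N_COLS + 1) if c not in CONTROL_COLUMNS)
WELLS_PER_PLATE = N_ROWS * N_COLS

ROLE_LIBRARY = "library"
ROLE_DMSO = "dmso"
ROLE_EMPTY = "empty"
POSITIVE_CONTROL_PREFIX = "positive_control:"

_WELL_RE = re.compile(r"^([A-P])(\d{2})$")

PLATE_MAP_COLUMNS = ("plate", "well", "role", "compound_id", "conc_uM")


class PlateMapError(ValueError):
    """Malformed plate map (bad well id, duplicate well, invalid role)."""


def well_name(row_index: int, column: int) -> str:
    """``(0, 1) -> "A01"``; row index 0-based, column 1-based."""
    if not (0 <= row_index < N_ROWS and 1 <= column <= N_COLS):
        raise PlateMapError(f"well position out of range: row {row_index}, column {column}")
    return f"{ROWS[row_index]}{column:02d}"


def parse_well(name: str) -> tuple[int, int]:
    """``"A01" -> (0, 1)``.  Raises :class:`PlateMapError` for anything else."""
    m = _WELL_RE.match(str(name).strip())
    if not m:
        raise PlateMapError(f"malformed well id {name!r} (expected A01..P24)")
    row_index = ROWS.index(m.group(1))
    column = int(m.group(2))
    if not 1 <= column <= N_COLS:
        raise PlateMapError(f"malformed well id {name!r}: column out of range")
    return row_index, column


def is_control_column(column: int) -> bool:
    return column in CONTROL_COLUMNS


def _validate_role(role: str) -> None:
    if role in (ROLE_LIBRARY, ROLE_DMSO, ROLE_EMPTY):
        return
    if role.startswith(POSITIVE_CONTROL_PREFIX) and len(role) > len(POSITIVE_CONTROL_PREFIX):
        return
    raise PlateMapError(f"invalid well role {role!r}")


@dataclass
class PlateMap:
    """One 384-well plate: per-well role, compound identity and concentration.

    ``wells`` is a DataFrame with columns ``well, row, column, role,
    compound_id, conc_uM`` and one row per populated well (all 384 wells are
    always present; unused library wells carry role ``empty``).
    """

    plate_id: str
    wells: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.wells
        missing = set(("well", "role", "compound_id", "conc_uM")) - set(df.columns)
        if missing:
            raise PlateMapError(f"plate {self.plate_id}: missing columns {sorted(missing)}")
        if len(df) != WELLS_PER_PLATE:
            raise PlateMapError(
                f"plate {self.plate_id}: expected {WELLS_PER_PLATE} wells, got {len(df)}"
            )
        seen = set()
        for rec in df.itertuples(index=False):
            row_index, column = parse_well(rec.well)
            if rec.well in seen:
                raise PlateMapError(f"plate {self.plate_id}: duplicate well {rec.well}")
            seen.add(rec.well)
            _validate_role(rec.role)
            if column in CONTROL_COLUMNS and rec.role == ROLE_LIBRARY:
                raise PlateMapError(
                    f"plate {self.plate_id}: library compound in control column at {rec.well}"
                )

    @property
    def library_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == ROLE_LIBRARY]

    @property
    def dmso_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == ROLE_DMSO]

    def positive_control_wells(self, name: str | None = None) -> pd.DataFrame:
        mask = self.wells["role"].str.startswith(POSITIVE_CONTROL_PREFIX)
        if name is not None:
            mask &= self.wells["role"] == POSITIVE_CONTROL_PREFIX + name
        return self.wells[mask]

    def to_frame(self) -> pd.DataFrame:
        out = self.wells.copy()
        out.insert(0, "plate", self.plate_id)
        return out[list(PLATE_MAP_COLUMNS)]


def plate_maps_to_frame(maps: list[PlateMap]) -> pd.DataFrame:
    return pd.concat([m.to_frame() for m in maps], ignore_index=True)


def save_plate_maps(maps: list[PlateMap], path) -> None:
    """Write plate maps as CSV, one row per well."""
    plate_maps_to_frame(maps).to_csv(path, index=False)


def load_plate_maps(path) -> list[PlateMap]:
    """Read plate maps from CSV, validating well ids, roles and duplicates.

    Raises :class:`PlateMapError` naming the offending row.
    """
    df = pd.read_csv(path, dtype={"plate": str, "well": str, "role": str, "compound_id": str})
    missing = set(PLATE_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise PlateMapError(f"{path}: missing columns {sorted(missing)}")
    df["compound_id"] = df["compound_id"].fillna("")
    maps = []
    for plate_id, grp in df.groupby("plate", sort=True):
        seen: dict[str, int] = {}
        rows, cols = [], []
        for i, rec in enumerate(grp.itertuples(index=False)):
            try:
                r, c = parse_well(rec.well)
                _validate_role(rec.role)
            except PlateMapError as err:
                raise PlateMapError(f"{path}: plate {plate_id} row {i}: {err}") from None
            if rec.well in seen:
                raise PlateMapError(
                    f"{path}: duplicate (plate, well) = ({plate_id}, {rec.well})"
                )
            seen[rec.well] = i
            rows.append(r)
            cols.append(c)
        wells = grp.drop(columns=["plate"]).reset_index(drop=True)
        wells["row"] = rows
        wells["column"] = cols
        maps.append(PlateMap(plate_id=str(plate_id), wells=wells))
    return maps


def empty_plate_frame() -> pd.DataFrame:
    """All-384-well skeleton with role ``empty`` everywhere."""
    recs = []
    for r in range(N_ROWS):
        for c in range(1, N_COLS + 1):
            recs.append((well_name(r, c), r, c, ROLE_EMPTY, "", 0.0))
    return pd.DataFrame(recs, columns=["well", "row", "column", "role", "compound_id", "conc_uM"])
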