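"""Build/test interface plumbing: picklists, plate layouts, assay ingestion.

A proposed batch of designs becomes a picklist (which promoter/RBS parts to
pipette for each construct, replicate by replicate) and a plate layout
mapping 96-well coordinates back to design points.  The canonical round —
46 designs x 4 biological replicates plus no-inoculation and empty-plasmid
controls in 4 replicates each — fills exactly two 96-well plates.

After the assay, a results CSV (OD600 and A472 per well) is joined back to
designs through the layout.  No-inoculation wells define a per-plate blank
subtracted from both channels; lycopene production is then expressed per
gram dry cell weight using the E. coli conversion 0.36 g/L DCW per OD600
unit: ``titer_proxy = A472 / (0.36 * OD600)``.  Wells whose corrected OD600
indicates failed growth are excluded (not zeroed — the normalization would
explode) and reported.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gridspace import DesignPoint, PartsLibrary, ValidationError, parts_for_point
from .landscapes import Observation
from .acquisition import BatchProposal

__all__ = [
    "PlateLayout",
    "AssayRecord",
    "NormalizationConstants",
    "ControlSpec",
    "emit_picklist",
    "parse_assay",
    "normalize_titer",
    "aggregate_to_observations",
]

WELL_ROWS = string.ascii_uppercase[:8]           # A..H
WELLS_96 = [f"{r}{c}" for r in WELL_ROWS for c in range(1, 13)]  # row-major

BLANK = "no_inoculation"        # OD blank: medium only
EMPTY_PLASMID = "empty_plasmid"  # production control: no pathway


@dataclass(frozen=True)
class ControlSpec:
    """Plate controls appended after the designs (tag -> replicates)."""

    blanks: int = 4
    empty_plasmid: int = 4


@dataclass(frozen=True)
class WellAssignment:
    kind: str                      # "design" | BLANK | EMPTY_PLASMID
    point: DesignPoint | None
    replicate: int                 # 1-based


@dataclass
class PlateLayout:
    """One 96-well plate: well id -> assignment."""

    plate_id: str
    wells: dict[str, WellAssignment] = field(default_factory=dict)

    def assign(self, well: str, assignment: WellAssignment) -> None:
        if well in self.wells:
            raise ValidationError(f"well {well} on {self.plate_id} assigned twice")
        if well not in WELLS_96:
            raise ValidationError(f"{well} is not a 96-well coordinate")
        self.wells[well] = assignment

    def to_dict(self) -> dict:
        return {
            self.plate_id: {
                w: {"kind": a.kind,
                    "point": list(a.point.coords) if a.point else None,
                    "replicate": a.replicate}
                for w, a in self.wells.items()
            }
        }

    @classmethod
    def from_dict(cls, plate_id: str, wells: dict) -> "PlateLayout":
        layout = cls(plate_id=plate_id)
        for w, a in wells.items():
            layout.assign(w, WellAssignment(
                kind=a["kind"],
                point=DesignPoint(a["point"]) if a["point"] else None,
                replicate=int(a["replicate"])))
        return layout


@dataclass(frozen=True)
class AssayRecord:
    """One well's measurements after blank correction."""

    plate_id: str
    well: str
    od600: float
    a472: float
    kind: str
    point: DesignPoint | None
    replicate: int
    blank_corrected: bool = True
    clamped: bool = False          # a corrected channel went negative


@dataclass(frozen=True)
class NormalizationConstants:
    """Assay-to-titer conversion constants."""

    dcw_per_od: float = 0.36       # g/L dry cell weight per OD600 unit
    od_floor: float = 0.01         # below this, growth is considered failed

    def __post_init__(self):
        if self.dcw_per_od <= 0:
            raise ValidationError("dcw_per_od must be positive")


def emit_picklist(
    proposal: BatchProposal | Sequence[DesignPoint],
    library: PartsLibrary,
    replicates: int = 4,
    controls: ControlSpec = ControlSpec(),
    plate_prefix: str = "P",
) -> tuple[pd.DataFrame, list[PlateLayout]]:
    """Expand a batch into a pipetting picklist and 96-well plate layouts.

    Wells fill row-major A1 -> H12, a design's replicates adjacent,
    overflowing to additional plates; controls follow the designs.  The
    picklist has one row per (well, factor) part transfer for designs and
    one row per control well.
    """
    points = list(proposal.points if isinstance(proposal, BatchProposal) else proposal)
    if not points:
        raise ValidationError("cannot emit a picklist for an empty proposal")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")

    slots: list[WellAssignment] = []
    for p in points:
        parts_for_point(p, library)  # fail fast on library gaps
        for r in range(1, replicates + 1):
            slots.append(WellAssignment(kind="design", point=p, replicate=r))
    for r in range(1, controls.blanks + 1):
        slots.append(WellAssignment(kind=BLANK, point=None, replicate=r))
    for r in range(1, controls.empty_plasmid + 1):
        slots.append(WellAssignment(kind=EMPTY_PLASMID, point=None, replicate=r))

    layouts: list[PlateLayout] = []
    rows = []
    for i, assignment in enumerate(slots):
        plate_no, well_no = divmod(i, 96)
        if well_no == 0:
            layouts.append(PlateLayout(plate_id=f"{plate_prefix}{plate_no + 1}"))
        layout = layouts[-1]
        well = WELLS_96[well_no]
        layout.assign(well, assignment)
        if assignment.kind == "design":
            design_id = "D" + "-".join(str(c) for c in assignment.point.coords)
            for j, bundle in enumerate(parts_for_point(assignment.point, library)):
                rows.append({
                    "plate_id": layout.plate_id, "well": well,
                    "design_id": design_id, "factor": j + 1,
                    "level": assignment.point.coords[j],
                    "promoter_id": bundle.promoter_id, "rbs_id": bundle.rbs_id,
                    "replicate": assignment.replicate, "is_control": False,
                })
        else:
            rows.append({
                "plate_id": layout.plate_id, "well": well,
                "design_id": assignment.kind, "factor": 0, "level": 0,
                "promoter_id": "", "rbs_id": "",
                "replicate": assignment.replicate, "is_control": True,
            })
    return pd.DataFrame(rows), layouts


def parse_assay(csv_path, layouts: Sequence[PlateLayout]) -> list[AssayRecord]:
    """Join an assay CSV (plate_id, well, od600, a472) to the plate layouts.

    No-inoculation wells are averaged into a per-plate blank subtracted from
    both channels of every other well on that plate; a plate that carries no
    blank wells of its own (controls may all sit on the last plate of a
    round) uses the mean over every blank well of the run.  Corrected values
    that go negative are clamped to 0 and flagged.  Missing layout wells,
    duplicate rows, unknown wells and non-numeric values are hard errors.
    """
    df = pd.read_csv(csv_path)
    required = {"plate_id", "well", "od600", "a472"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValidationError(f"assay CSV missing columns: {sorted(missing_cols)}")

    by_plate = {layout.plate_id: layout for layout in layouts}
    seen: set[tuple[str, str]] = set()
    measured: dict[tuple[str, str], tuple[float, float]] = {}
    for row_no, row in enumerate(df.itertuples(), start=2):  # 1-based + header
        key = (str(row.plate_id), str(row.well))
        if key in seen:
            raise ValidationError(f"row {row_no}: duplicate well {key[1]} on {key[0]}")
        seen.add(key)
        if key[0] not in by_plate or key[1] not in by_plate[key[0]].wells:
            raise ValidationError(f"row {row_no}: unknown well {key[1]} on {key[0]}")
        try:
            od, a472 = float(row.od600), float(row.a472)
        except (TypeError, ValueError) as err:
            raise ValidationError(f"row {row_no}: non-numeric measurement") from err
        if not (np.isfinite(od) and np.isfinite(a472)):
            raise ValidationError(f"row {row_no}: non-finite measurement")
        measured[key] = (od, a472)

    missing_wells = [
        (layout.plate_id, w)
        for layout in layouts for w in layout.wells
        if (layout.plate_id, w) not in measured
    ]
    if missing_wells:
        listing = ", ".join(f"{p}:{w}" for p, w in missing_wells)
        raise ValidationError(f"assay CSV missing wells: {listing}")

    all_blanks = [(layout.plate_id, w)
                  for layout in layouts
                  for w, a in layout.wells.items() if a.kind == BLANK]
    global_blank = (
        tuple(float(np.mean([measured[k][c] for k in all_blanks]))
              for c in (0, 1))
        if all_blanks else (0.0, 0.0))

    records: list[AssayRecord] = []
    for layout in layouts:
        blank_keys = [w for w, a in layout.wells.items() if a.kind == BLANK]
        if blank_keys:
            blank_od = float(np.mean(
                [measured[(layout.plate_id, w)][0] for w in blank_keys]))
            blank_a472 = float(np.mean(
                [measured[(layout.plate_id, w)][1] for w in blank_keys]))
        else:
            blank_od, blank_a472 = global_blank
        for well, assignment in layout.wells.items():
            od, a472 = measured[(layout.plate_id, well)]
            if assignment.kind == BLANK:
                records.append(AssayRecord(
                    plate_id=layout.plate_id, well=well, od600=od, a472=a472,
                    kind=BLANK, point=None, replicate=assignment.replicate,
                    blank_corrected=False))
                continue
            od_c, a_c = od - blank_od, a472 - blank_a472
            clamped = od_c < 0 or a_c < 0
            records.append(AssayRecord(
                plate_id=layout.plate_id, well=well,
                od600=max(od_c, 0.0), a472=max(a_c, 0.0),
                kind=assignment.kind, point=assignment.point,
                replicate=assignment.replicate, clamped=clamped))
    return records


class FailedGrowth(Exception):
    """A well's corrected OD600 is at or below the growth floor."""


def normalize_titer(record: AssayRecord,
                    constants: NormalizationConstants = NormalizationConstants()) -> float:
    """Lycopene proxy per gram DCW: ``a472 / (dcw_per_od * od600)``.

    Raises :class:`FailedGrowth` when corrected OD600 is at or below the
    floor; callers exclude such replicates rather than crash or zero them.
    """
    if record.od600 <= constants.od_floor:
        raise FailedGrowth(
            f"{record.plate_id}:{record.well} od600={record.od600:.4f} "
            f"<= floor {constants.od_floor}")
    return float(record.a472 / (constants.dcw_per_od * record.od600))


def aggregate_to_observations(
    records: Sequence[AssayRecord],
    round_index: int = 0,
    constants: NormalizationConstants = NormalizationConstants(),
) -> tuple[list[Observation], dict]:
    """Group normalized titers by design into replicate-mean observations.

    Returns the observations plus a report of excluded failed-growth wells
    and of designs that lost every replicate (those block a lab-mode round).
    """
    by_point: dict[DesignPoint, list[float]] = {}
    failed: list[str] = []
    for rec in records:
        if rec.kind != "design":
            continue
        by_point.setdefault(rec.point, [])
        try:
            by_point[rec.point].append(normalize_titer(rec, constants))
        except FailedGrowth:
            failed.append(f"{rec.plate_id}:{rec.well}")
    observations = []
    missing: list[DesignPoint] = []
    for point, titers in by_point.items():
        if titers:
            observations.append(
                Observation.from_replicates(point, titers, round_index=round_index))
        else:
            missing.append(point)
    report = {"failed_wells": failed, "missing_designs": missing}
    return observations, report
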