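"""Shared data model, coordinate conventions, and cell-table I/O.

Conventions used throughout the package:

* pixel coordinates are ``(x, y)`` with ``x`` the column and ``y`` the row,
  0-based, origin at the top-left; sub-pixel centroids are allowed;
* inter-cell distances are Euclidean centroid-to-centroid in **pixels**
  unless an operation explicitly states microns;
* a pixel ``(x, y)`` covers the unit square ``[x, x+1) x [y, y+1)`` and its
  center is at ``(x + 0.5, y + 0.5)``.

Two imaging panels are supported.  The high-resolution (HR) panel covers
five immune-cell classes imaged in fixed 1024x1024 px fields of view at
0.1058 um/px; the highly multiplexed (HMP) panel covers five lymphocyte
classes imaged as whole-biopsy sections at 0.221 um/px with PD1 / ICOS /
FoxP3 (and optionally TCRdelta) marker flags.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping, shape
from shapely.ops import unary_union


class Mode(str, enum.Enum):
    """Imaging mode: discrete HR fields of view or whole HMP sections."""

    HR_ROI = "HR_ROI"
    HMP_SECTION = "HMP_SECTION"


class Outcome(str, enum.Enum):
    """Renal outcome group of the biopsied patient.

    ``ESRD_current`` marks patients in renal failure at (or within two weeks
    of) biopsy; two-group analyses pool them with ``ESRD_pos``.
    """

    ESRD_neg = "ESRD_neg"
    ESRD_pos = "ESRD_pos"
    ESRD_current = "ESRD_current"
    unknown = "unknown"


#: Cell classes available in each imaging panel.
PANELS: dict[str, tuple[str, ...]] = {
    "HR": ("B", "CD4neg_T", "CD4pos_T", "pDC", "mDC"),
    "HMP": ("CD4_T", "CD8_T", "DN_T", "B", "plasma"),
}

#: Marker flags that may be attached to a cell.
MARKERS: tuple[str, ...] = ("PD1", "ICOS", "FOXP3", "TCRdelta")

#: Default pixel sizes (um/px) by mode.
DEFAULT_PIXEL_SIZE = {Mode.HR_ROI: 0.1058, Mode.HMP_SECTION: 0.221}


class CellTableFormatError(ValueError):
    """A cell table file is malformed (missing column, bad value)."""


class CellValidationError(ValueError):
    """A cell record violates a data-model invariant."""


def panel_for_mode(mode: Mode) -> tuple[str, ...]:
    return PANELS["HR"] if mode is Mode.HR_ROI else PANELS["HMP"]


@dataclass(frozen=True)
class FrameMeta:
    """Geometry of one imaged frame (an HR ROI or a whole HMP section)."""

    width_px: int = 1024
    height_px: int = 1024
    pixel_size_um: float = 0.1058
    mode: Mode = Mode.HR_ROI

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise CellValidationError("frame dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise CellValidationError("pixel_size_um must be positive")

    @property
    def panel(self) -> tuple[str, ...]:
        return panel_for_mode(self.mode)

    @property
    def area_mm2(self) -> float:
        """Frame area in mm^2 (used to convert intensities to counts)."""
        return self.width_px * self.height_px * (self.pixel_size_um * 1e-3) ** 2


@dataclass
class CellRecord:
    """One detected or simulated cell.

    ``mask`` is an optional ``(n, 2)`` integer array of ``(x, y)`` pixel
    coordinates; when present ``area_px`` equals its row count.
    """

    cell_id: int
    x: float
    y: float
    base_class: str
    markers: frozenset[str] = frozenset()
    mask: np.ndarray | None = None
    area_px: float = 0.0
    confidence: float = 1.0
    phenotype: str | None = None

    def __post_init__(self) -> None:
        self.markers = frozenset(self.markers)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=np.int64).reshape(-1, 2)
            self.area_px = float(len(self.mask))
        if not 0.0 <= self.confidence <= 1.0:
            raise CellValidationError(
                f"cell {self.cell_id}: confidence {self.confidence} outside [0, 1]"
            )
        if self.area_px < 0:
            raise CellValidationError(f"cell {self.cell_id}: negative area")

    @property
    def mask_set(self) -> frozenset[tuple[int, int]]:
        if self.mask is None:
            return frozenset()
        return frozenset(map(tuple, self.mask))


@dataclass
class CellMap:
    """All cells of one ROI or whole section, plus frame and cohort metadata."""

    frame: FrameMeta
    cells: list[CellRecord] = field(default_factory=list)
    roi_id: str = "roi0"
    biopsy_id: str = "unknown"
    outcome: Outcome = Outcome.unknown
    chronicity: int | None = None

    def __post_init__(self) -> None:
        self.outcome = Outcome(self.outcome)
        self.validate()

    def validate(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise CellValidationError(f"{self.roi_id}: duplicate cell_ids")
        panel = self.frame.panel
        for c in self.cells:
            if c.base_class not in panel:
                raise CellValidationError(
                    f"cell {c.cell_id}: class {c.base_class!r} not in panel {panel}"
                )
            if not (0 <= c.x <= self.frame.width_px and 0 <= c.y <= self.frame.height_px):
                raise CellValidationError(
                    f"cell {c.cell_id}: centroid ({c.x}, {c.y}) outside frame"
                )
            bad = c.markers - set(MARKERS)
            if bad:
                raise CellValidationError(f"cell {c.cell_id}: unknown markers {bad}")

    def __len__(self) -> int:
        return len(self.cells)

    def centroids(self) -> np.ndarray:
        """(n, 2) float array of (x, y) centroids."""
        if not self.cells:
            return np.empty((0, 2))
        return np.array([[c.x, c.y] for c in self.cells], dtype=float)

    def classes(self) -> np.ndarray:
        return np.array([c.base_class for c in self.cells], dtype=object)

    def copy(self) -> "CellMap":
        return CellMap(
            frame=self.frame,
            cells=[replace(c) for c in self.cells],
            roi_id=self.roi_id,
            biopsy_id=self.biopsy_id,
            outcome=self.outcome,
            chronicity=self.chronicity,
        )


@dataclass
class CohortTable:
    """Per-biopsy metadata: outcome group, ROI count, chronicity score."""

    entries: dict[str, tuple[Outcome, int, int | None]] = field(default_factory=dict)

    def add(self, biopsy_id: str, outcome: Outcome, n_rois: int, chronicity: int | None = None) -> None:
        if n_rois < 1:
            raise CellValidationError(f"{biopsy_id}: n_rois must be >= 1")
        self.entries[biopsy_id] = (Outcome(outcome), int(n_rois), chronicity)

    def outcome(self, biopsy_id: str) -> Outcome:
        return self.entries[biopsy_id][0]

    def n_rois(self, biopsy_id: str) -> int:
        return self.entries[biopsy_id][1]

    def biopsies(self, outcome: Outcome | None = None, pool_current: bool = False):
        """Biopsy ids, optionally restricted to one outcome group.

        With ``pool_current`` the ESRD_current group is folded into ESRD_pos,
        matching the two-group analyses.
        """
        out = []
        for b, (o, _, _) in self.entries.items():
            eff = Outcome.ESRD_pos if (pool_current and o is Outcome.ESRD_current) else o
            if outcome is None or eff is outcome:
                out.append(b)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"biopsy_id": b, "outcome": o.value, "n_rois": n, "chronicity": c}
            for b, (o, n, c) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["biopsy_id", "outcome", "n_rois", "chronicity"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        df = pd.read_csv(path)
        required = {"biopsy_id", "outcome", "n_rois"}
        missing = required - set(df.columns)
        if missing:
            raise CellTableFormatError(f"cohort table missing columns: {sorted(missing)}")
        table = cls()
        for _, row in df.iterrows():
            chron = row.get("chronicity")
            chron = None if pd.isna(chron) else int(chron)
            table.add(str(row["biopsy_id"]), Outcome(row["outcome"]), int(row["n_rois"]), chron)
        return table


def px_to_um(length_px: float, pixel_size_um: float) -> float:
    """Convert a length in pixels to microns.

    E.g. the 100 px neighborhood radius of the HR dataset corresponds to
    ``100 * 0.1058 = 10.58`` um (~10.6 um, about one cell body).
    """
    if length_px < 0 or pixel_size_um < 0:
        raise ValueError("px_to_um requires nonnegative inputs")
    return length_px * pixel_size_um


# ---------------------------------------------------------------------------
# Cell-table I/O
# ---------------------------------------------------------------------------

_COLUMNS = [
    "cell_id",
    "roi_id",
    "x",
    "y",
    "base_class",
    "markers",
    "confidence",
    "area_px",
    "phenotype",
    "biopsy_id",
    "outcome",
    "chronicity",
]


def _mask_geojson_path(path: Path) -> Path:
    return path.with_name(path.stem + "_masks.geojson")


def write_cell_table(cellmap: CellMap, path) -> None:
    """Write a CellMap as a CSV table (one row per cell, fixed column order).

    Pixel masks, when present, are written to a side GeoJSON file
    ``<stem>_masks.geojson`` as the union of the unit pixel squares of each
    cell, keyed by ``cell_id``.  Writing the same CellMap twice produces
    byte-identical files.
    """
    path = Path(path)
    rows = []
    for c in sorted(cellmap.cells, key=lambda c: c.cell_id):
        rows.append(
            {
                "cell_id": c.cell_id,
                "roi_id": cellmap.roi_id,
                "x": repr(float(c.x)),
                "y": repr(float(c.y)),
                "base_class": c.base_class,
                "markers": ";".join(sorted(c.markers)),
                "confidence": repr(float(c.confidence)),
                "area_px": repr(float(c.area_px)),
                "phenotype": c.phenotype or "",
                "biopsy_id": cellmap.biopsy_id,
                "outcome": cellmap.outcome.value,
                "chronicity": "" if cellmap.chronicity is None else cellmap.chronicity,
            }
        )
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, index=False)

    masked = [c for c in cellmap.cells if c.mask is not None]
    if masked:
        features = []
        for c in sorted(masked, key=lambda c: c.cell_id):
            geom = unary_union([box(x, y, x + 1, y + 1) for x, y in c.mask])
            features.append(
                {
                    "type": "Feature",
                    "properties": {"cell_id": c.cell_id},
                    "geometry": mapping(geom),
                }
            )
        gj = {"type": "FeatureCollection", "features": features}
        _mask_geojson_path(path).write_text(json.dumps(gj, sort_keys=True))


def _rasterize_pixels(geom) -> np.ndarray:
    """Recover the pixel set of a union-of-unit-squares geometry.

    A pixel belongs to the set iff its center lies inside the geometry; for
    geometries built by :func:`write_cell_table` this is exact.
    """
    minx, miny, maxx, maxy = geom.bounds
    xs = np.arange(int(np.floor(minx)), int(np.ceil(maxx)))
    ys = np.arange(int(np.floor(miny)), int(np.ceil(maxy)))
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    from shapely import contains_xy

    keep = contains_xy(geom, gx.ravel() + 0.5, gy.ravel() + 0.5)
    pix = np.column_stack([gx.ravel()[keep], gy.ravel()[keep]])
    return pix.astype(np.int64)


def read_cell_table(path, frame: FrameMeta) -> CellMap:
    """Read a cell table written by :func:`write_cell_table`.

    Raises :class:`CellTableFormatError` when a required column is absent and
    :class:`CellValidationError` for out-of-frame centroids or class labels
    outside the frame's panel.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"markers": str, "phenotype": str}, keep_default_na=False)
    required = ["cell_id", "x", "y", "base_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CellTableFormatError(f"cell table missing required column(s): {missing}")

    masks: dict[int, np.ndarray] = {}
    gj_path = _mask_geojson_path(path)
    if gj_path.exists():
        gj = json.loads(gj_path.read_text())
        for feat in gj["features"]:
            masks[int(feat["properties"]["cell_id"])] = _rasterize_pixels(
                shape(feat["geometry"])
            )

    cells = []
    for _, row in df.iterrows():
        cid = int(row["cell_id"])
        markers = frozenset(
            m for m in str(row.get("markers", "")).split(";") if m
        )
        pheno = str(row.get("phenotype", "")) or None
        cells.append(
            CellRecord(
                cell_id=cid,
                x=float(row["x"]),
                y=float(row["y"]),
                base_class=str(row["base_class"]),
                markers=markers,
                mask=masks.get(cid),
                area_px=float(row.get("area_px", 0.0) or 0.0),
                confidence=float(row.get("confidence", 1.0) or 1.0),
                phenotype=pheno,
            )
        )

    if len(df):
        roi_id = str(df["roi_id"].iloc[0]) if "roi_id" in df.columns else "roi0"
        biopsy_id = str(df["biopsy_id"].iloc[0]) if "biopsy_id" in df.columns else "unknown"
        outcome = Outcome(df["outcome"].iloc[0]) if "outcome" in df.columns else Outcome.unknown
        chron = None
        if "chronicity" in df.columns and str(df["chronicity"].iloc[0]) != "":
            chron = int(df["chronicity"].iloc[0])
    else:
        roi_id, biopsy_id, outcome, chron = "roi0", "unknown", Outcome.unknown, None

    return CellMap(
        frame=frame,
        cells=cells,
        roi_id=roi_id,
        biopsy_id=biopsy_id,
        outcome=outcome,
        chronicity=chron,
    )
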