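"""Polar-map data model, grid geometry, AHA segmentation and file I/O.

A myocardial-perfusion polar map ("bullseye") is stored as a flat vector of
460 nonnegative relative-uptake values sampled on 20 concentric rings of 23
angular sectors each (ring 0 = apex, ring 19 = base).  The grid carries the
standard AHA 17-segment division and the segment-to-coronary-territory
assignment (LAD / RCA / LCX) used for coarse localization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_RINGS = 20
N_SECTORS = 23
N_NODES = N_RINGS * N_SECTORS  # 460
N_SEGMENTS = 17

TERRITORIES = ("LAD", "RCA", "LCX")

#: Cerqueira-style assignment of AHA segments to coronary beds.
SEGMENT_TERRITORY = {
    1: "LAD", 2: "LAD", 7: "LAD", 8: "LAD", 13: "LAD", 14: "LAD", 17: "LAD",
    3: "RCA", 4: "RCA", 9: "RCA", 10: "RCA", 15: "RCA",
    5: "LCX", 6: "LCX", 11: "LCX", 12: "LCX", 16: "LCX",
}


class PolarMapError(ValueError):
    """Invalid polar-map data (wrong size, negative or degenerate values)."""


@dataclass
class PolarMap:
    """One perfusion sample: 460 uptake values plus labels.

    Parameters
    ----------
    values
        Relative tracer uptake per node, nonnegative, length 460.
    condition
        ``"rest"`` or ``"stress"``.
    label
        ``"normal"``, ``"abnormal"`` or ``None`` when unlabeled.
    segment_truth
        Optional 17 binary flags marking expert-annotated pathological
        segments (index 0 = AHA segment 1).
    sample_id
        Opaque identifier.
    """

    values: np.ndarray
    condition: str = "rest"
    label: str | None = None
    segment_truth: np.ndarray | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_NODES,):
            raise PolarMapError(
                f"polar map needs exactly {N_NODES} values, got {self.values.shape}"
            )
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise PolarMapError("polar-map values must be finite and nonnegative")
        if self.condition not in ("rest", "stress"):
            raise PolarMapError(f"unknown condition {self.condition!r}")
        if self.label not in (None, "normal", "abnormal"):
            raise PolarMapError(f"unknown label {self.label!r}")
        if self.segment_truth is not None:
            self.segment_truth = np.asarray(self.segment_truth, dtype=int)
            if self.segment_truth.shape != (N_SEGMENTS,):
                raise PolarMapError("segment_truth needs 17 flags")
            if not np.isin(self.segment_truth, (0, 1)).all():
                raise PolarMapError("segment_truth flags must be 0/1")


def node_index(ring: int, sector: int) -> int:
    """Flat index of grid node (ring, sector); row-major, rings outermost."""
    if not (0 <= ring < N_RINGS and 0 <= sector < N_SECTORS):
        raise IndexError(f"(ring={ring}, sector={sector}) outside 20x23 grid")
    return ring * N_SECTORS + sector


def _sector_angle_deg(sector: int) -> float:
    # angular center of a sector; angle 0 = anterior wall, counterclockwise
    return (sector + 0.5) * 360.0 / N_SECTORS


def _segment_of_node(ring: int, sector: int) -> int:
    angle = _sector_angle_deg(sector)
    if ring <= 4:  # apical cap
        return 17
    if ring <= 9:  # apical band: 4 x 90 deg, anterior/septal/inferior/lateral
        span = int(((angle + 45.0) % 360.0) // 90.0)
        return 13 + span
    # mid (rings 10-14) and basal (15-19) bands: 6 x 60 deg starting with
    # the anterior segment centered on angle 0
    span = int(((angle + 30.0) % 360.0) // 60.0)
    base = 7 if ring <= 14 else 1
    return base + span


@dataclass(frozen=True)
class PolarGrid:
    """Fixed 20-ring x 23-sector geometry with AHA-17 segment assignment."""

    n_rings: int = N_RINGS
    n_sectors: int = N_SECTORS
    segment_of: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.segment_of is None:
            seg = np.empty(N_NODES, dtype=int)
            for r in range(N_RINGS):
                for s in range(N_SECTORS):
                    seg[node_index(r, s)] = _segment_of_node(r, s)
            object.__setattr__(self, "segment_of", seg)

    def nodes_of_segment(self, seg: int) -> np.ndarray:
        if not 1 <= seg <= N_SEGMENTS:
            raise ValueError(f"AHA segment id must be 1..17, got {seg}")
        return np.flatnonzero(self.segment_of == seg)

    def to_frame(self) -> pd.DataFrame:
        """Audit table: node, ring, sector, segment, territory."""
        rows = []
        for r in range(N_RINGS):
            for s in range(N_SECTORS):
                seg = self.segment_of[node_index(r, s)]
                rows.append((node_index(r, s), r, s, seg, SEGMENT_TERRITORY[seg]))
        return pd.DataFrame(rows, columns=["node", "ring", "sector", "segment", "territory"])


def assign_segments(grid: PolarGrid | None = None) -> np.ndarray:
    """Per-node AHA segment ids (length 460, values 1..17)."""
    return (grid or PolarGrid()).segment_of.copy()


def territory_of_segment(seg: int) -> str:
    """Coronary bed (LAD/RCA/LCX) supplying an AHA segment."""
    if seg not in SEGMENT_TERRITORY:
        raise ValueError(f"AHA segment id must be 1..17, got {seg}")
    return SEGMENT_TERRITORY[seg]


def segments_of_territory(territory: str) -> list[int]:
    if territory not in TERRITORIES:
        raise ValueError(f"unknown territory {territory!r}")
    return sorted(s for s, t in SEGMENT_TERRITORY.items() if t == territory)


def territory_truth_from_segments(segment_truth: np.ndarray) -> np.ndarray:
    """Per-territory flags (LAD, RCA, LCX order): OR over the bed's segments."""
    flags = np.asarray(segment_truth, dtype=int)
    return np.array(
        [int(any(flags[s - 1] for s in segments_of_territory(t))) for t in TERRITORIES]
    )


def normalize_map(pm: PolarMap) -> PolarMap:
    """Divide by the map's highest perfusion value so the maximum is 1."""
    peak = pm.values.max()
    if peak <= 0:
        raise PolarMapError(f"cannot normalize all-zero map {pm.sample_id!r}")
    return replace(pm, values=pm.values / peak)


def reshape_to_raster(pm: PolarMap) -> np.ndarray:
    """23x20 raster (sectors x rings) used by the 2-D CNN baseline.

    Column c holds ring c, so flattening column-major recovers the vector.
    """
    return pm.values.reshape(N_RINGS, N_SECTORS).T


# ---------------------------------------------------------------------------
# Delimited-text I/O
#
# One sample per row: sample_id, condition, label, seg01..seg17, v000..v459.
# ---------------------------------------------------------------------------

_SEG_COLS = [f"seg{i:02d}" for i in range(1, N_SEGMENTS + 1)]
_VAL_COLS = [f"v{i:03d}" for i in range(N_NODES)]
TABLE_COLUMNS = ["sample_id", "condition", "label", *_SEG_COLS, *_VAL_COLS]


def write_polarmap_table(maps: Iterable[PolarMap], path) -> None:
    rows = []
    for pm in maps:
        truth = (
            ["NA"] * N_SEGMENTS
            if pm.segment_truth is None
            else [int(v) for v in pm.segment_truth]
        )
        rows.append(
            [pm.sample_id, pm.condition, pm.label or "NA", *truth, *pm.values]
        )
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, index=False)


def read_polarmap_table(path) -> list[PolarMap]:
    """Read a polar-map CSV table, validating schema row by row."""
    try:
        df = pd.read_csv(path, dtype={"sample_id": str}, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing or list(df.columns) != TABLE_COLUMNS:
        raise PolarMapError(
            f"{path}: header must be exactly the polar-map schema "
            f"(missing {missing[:3]}...)" if missing else f"{path}: unexpected columns"
        )
    maps: list[PolarMap] = []
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after header
        label = row["label"]
        if label == "NA":
            label = None
        truth_raw = [row[c] for c in _SEG_COLS]
        if all(str(v) == "NA" for v in truth_raw):
            truth = None
        else:
            try:
                truth = np.array([int(v) for v in truth_raw])
            except ValueError as exc:
                raise PolarMapError(f"{path} line {line}: bad segment flag ({exc})")
        try:
            values = np.array([float(row[c]) for c in _VAL_COLS])
            maps.append(
                PolarMap(
                    values=values,
                    condition=row["condition"],
                    label=label,
                    segment_truth=truth,
                    sample_id=row["sample_id"],
                )
            )
        except (ValueError, PolarMapError) as exc:
            raise PolarMapError(f"{path} line {line}: {exc}") from exc
    return maps


def stack_values(maps: Sequence[PolarMap]) -> np.ndarray:
    """(n_samples, 460) value matrix."""
    return np.stack([pm.values for pm in maps])


def labels_binary(maps: Sequence[PolarMap]) -> np.ndarray:
    """0 = normal, 1 = abnormal; raises on unlabeled maps."""
    out = np.empty(len(maps), dtype=int)
    for i, pm in enumerate(maps):
        if pm.label is None:
            raise PolarMapError(f"map {pm.sample_id!r} is unlabeled")
        out[i] = 1 if pm.label == "abnormal" else 0
    return out
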