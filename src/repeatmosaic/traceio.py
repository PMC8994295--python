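"""Fragment-analysis I/O: peak tables, size calibration, and modal-allele calling.

Capillary-electrophoresis genotyping of a tandem repeat (here a 6 bp CCCTCT
unit) produces a ladder of peaks separated by one repeat unit.  This module
reads GeneMapper-style peak tables, fits a linear bp <-> repeat-unit
calibration against sizing standards of known repeat length, bins peaks to
integer repeat units, and calls the modal allele (the tallest peak of the
distribution), which serves as the reference for all downstream instability
metrics.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "SizeCalibration",
    "AlleleDistribution",
    "ParseError",
    "CalibrationError",
    "read_peak_table",
    "read_peak_tables",
    "write_peak_table_csv",
    "fit_calibration",
    "call_distribution",
]

logger = logging.getLogger(__name__)

#: bp added per repeat unit for a hexameric repeat
REPEAT_UNIT_BP = 6.0

PEAK_TABLE_COLUMNS = ("sample_id", "locus", "size_bp", "height")


class ParseError(ValueError):
    """Raised when a peak-table file cannot be parsed."""


class CalibrationError(ValueError):
    """Raised when sizing standards are inconsistent with a hexameric repeat."""


@dataclass(frozen=True)
class PeakTable:
    """One fragment-analysis trace: (size_bp, height) pairs for one sample/locus.

    Peaks are stored sorted by fragment size; duplicate sizes must be merged
    before construction (see :func:`read_peak_table`).
    """

    sample_id: str
    locus: str
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("PeakTable requires at least one peak")
        sizes = [p[0] for p in self.peaks]
        heights = [p[1] for p in self.peaks]
        if any(h < 0 for h in heights):
            raise ValueError("peak heights must be non-negative")
        ordered = tuple(sorted(self.peaks, key=lambda p: p[0]))
        szs = [p[0] for p in ordered]
        if any(szs[i] >= szs[i + 1] for i in range(len(szs) - 1)):
            raise ValueError("peak sizes must be unique; merge duplicates first")
        object.__setattr__(self, "peaks", ordered)
        del sizes, heights

    @property
    def sizes_bp(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks], dtype=float)

    @property
    def heights(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks], dtype=float)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class SizeCalibration:
    """Linear map between fragment size (bp) and repeat units.

    size_bp = intercept_bp + slope_bp_per_repeat * repeat_units

    The slope must be close to 6 bp per repeat for a hexameric unit; the
    intercept is the constant flanking sequence amplified around the repeat.
    ``accurate_range_bp`` delimits the window over which sizing against the
    standards is accurate (about 32-70 repeats by default); repeat lengths
    outside it are estimated by extrapolating the line and flagged.
    """

    slope_bp_per_repeat: float
    intercept_bp: float
    accurate_range_bp: tuple[float, float] = (330.0, 560.0)
    standards_used: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (5.5 <= self.slope_bp_per_repeat <= 6.5):
            raise CalibrationError(
                f"slope {self.slope_bp_per_repeat:.3f} bp/repeat outside [5.5, 6.5]; "
                "not consistent with a 6 bp repeat unit"
            )
        lo, hi = self.accurate_range_bp
        if lo >= hi:
            raise ValueError("accurate_range_bp must be (low, high) with low < high")

    def repeats_to_bp(self, repeat_units: float) -> float:
        return self.intercept_bp + self.slope_bp_per_repeat * repeat_units

    def bp_to_repeats(self, size_bp: float) -> tuple[int, bool]:
        """Convert a fragment size to integer repeat units.

        Returns ``(repeat_units, extrapolated)``; *extrapolated* is True when
        the size falls outside the accurate sizing window and the length is a
        molecular-weight estimate rather than a standards-anchored call.
        """
        if size_bp <= self.intercept_bp:
            raise ValueError(
                f"fragment of {size_bp} bp is not longer than the {self.intercept_bp} bp "
                "flanking sequence: no repeat content"
            )
        repeat = int(round((size_bp - self.intercept_bp) / self.slope_bp_per_repeat))
        lo, hi = self.accurate_range_bp
        extrapolated = not (lo <= size_bp <= hi)
        return repeat, extrapolated


@dataclass(frozen=True)
class AlleleDistribution:
    """Repeat-unit-indexed weights (peak heights or molecule counts).

    ``entries`` maps integer repeat length -> non-negative weight.  The modal
    repeat is the entry of maximal weight; ties are broken toward the smaller
    repeat, which is conservative against calling spurious expansion.
    ``out_of_range_flags`` marks repeat lengths sized by extrapolation.
    """

    locus: str
    entries: Mapping[int, float]
    modal_repeat: int
    out_of_range_flags: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("AlleleDistribution requires at least one entry")
        if any(w < 0 for w in self.entries.values()):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "entries", dict(self.entries))
        object.__setattr__(self, "out_of_range_flags", frozenset(self.out_of_range_flags))
        wmax = max(self.entries.values())
        if self.entries.get(self.modal_repeat, -1.0) < wmax:
            raise ValueError("modal_repeat must carry the maximal weight")

    @classmethod
    def from_entries(
        cls,
        locus: str,
        entries: Mapping[int, float],
        out_of_range_flags: Iterable[int] = (),
    ) -> "AlleleDistribution":
        """Build a distribution, calling the modal allele (ties -> smaller)."""
        if not entries:
            raise ValueError("empty allele distribution")
        modal = modal_allele(entries)
        return cls(locus, dict(entries), modal, frozenset(out_of_range_flags))

    def delta_items(self) -> list[tuple[int, float]]:
        """(repeat - modal, weight) pairs sorted by delta."""
        return sorted((r - self.modal_repeat, w) for r, w in self.entries.items())

    @property
    def total_weight(self) -> float:
        return float(sum(self.entries.values()))

    def __len__(self) -> int:
        return len(self.entries)


def modal_allele(entries: Mapping[int, float]) -> int:
    """Tallest-peak allele call; ties broken toward the smaller repeat."""
    return min(entries, key=lambda r: (-entries[r], r))


def _validate_frame(df: pd.DataFrame, path: object) -> pd.DataFrame:
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    n_na_height = int(df["height"].isna().sum())
    if n_na_height:
        logger.info("%s: dropped %d row(s) with missing height", path, n_na_height)
        df = df.dropna(subset=["height"]).copy()
    for col in ("size_bp", "height"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise ParseError(f"{path}: non-numeric {col} at row {row}: {df[col][bad].iloc[0]!r}")
        df[col] = pd.to_numeric(df[col])
    if df.empty:
        raise ParseError(f"{path}: no peaks")
    return df


def _table_from_group(sample_id: str, locus: str, group: pd.DataFrame) -> PeakTable:
    merged = group.groupby("size_bp", as_index=True)["height"].sum()
    n_dup = len(group) - len(merged)
    if n_dup:
        warnings.warn(
            f"{sample_id}/{locus}: {n_dup} duplicate size_bp row(s); heights summed",
            stacklevel=3,
        )
    peaks = tuple(zip(merged.index.astype(float), merged.to_numpy(dtype=float)))
    return PeakTable(sample_id=sample_id, locus=locus, peaks=peaks)


def read_peak_tables(path) -> list[PeakTable]:
    """Read a peak-table CSV holding one or more (sample_id, locus) traces."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: no peaks (empty file)") from exc
    df = _validate_frame(df, path)
    tables = []
    for (sample_id, locus), group in df.groupby(["sample_id", "locus"], sort=True):
        tables.append(_table_from_group(str(sample_id), str(locus), group))
    return tables


def read_peak_table(path, locus: str | None = None, sample_id: str | None = None) -> PeakTable:
    """Read a single trace from a peak-table CSV.

    ``locus``/``sample_id`` filter the file; exactly one trace must remain.
    """
    tables = read_peak_tables(path)
    if locus is not None:
        tables = [t for t in tables if t.locus == locus]
    if sample_id is not None:
        tables = [t for t in tables if t.sample_id == sample_id]
    if not tables:
        raise ParseError(f"{path}: no peaks matching locus={locus!r} sample_id={sample_id!r}")
    if len(tables) > 1:
        raise ParseError(
            f"{path}: {len(tables)} traces match; pass locus/sample_id to disambiguate"
        )
    return tables[0]


def write_peak_table_csv(tables: Sequence[PeakTable], path) -> None:
    rows = [
        {"sample_id": t.sample_id, "locus": t.locus, "size_bp": s, "height": h}
        for t in tables
        for s, h in t.peaks
    ]
    pd.DataFrame(rows, columns=list(PEAK_TABLE_COLUMNS)).to_csv(path, index=False)


def fit_calibration(
    standards: Sequence[tuple[float, float]],
    accurate_range_bp: tuple[float, float] = (330.0, 560.0),
) -> SizeCalibration:
    """Least-squares line through (repeat_units, size_bp) sizing standards.

    At least two standards are required; the fitted slope must land in
    [5.5, 6.5] bp/repeat or the calibration is rejected.
    """
    if len(standards) < 2:
        raise CalibrationError("need at least 2 sizing standards")
    repeats = np.array([s[0] for s in standards], dtype=float)
    sizes = np.array([s[1] for s in standards], dtype=float)
    if np.ptp(repeats) == 0:
        raise CalibrationError("standards must span more than one repeat length")
    slope, intercept = np.polyfit(repeats, sizes, 1)
    return SizeCalibration(
        slope_bp_per_repeat=float(slope),
        intercept_bp=float(intercept),
        accurate_range_bp=accurate_range_bp,
        standards_used=tuple((float(r), float(s)) for r, s in standards),
    )


def default_sizing_standards() -> list[tuple[float, float]]:
    """Repeat sizing standards of 37, 44 and 50 units on the default line
    (6 bp/repeat, 138 bp flank)."""
    return [(37.0, 360.0), (44.0, 402.0), (50.0, 438.0)]


def default_calibration() -> SizeCalibration:
    return fit_calibration(default_sizing_standards())


def call_distribution(table: PeakTable, calib: SizeCalibration) -> AlleleDistribution:
    """Bin peaks to integer repeat units and call the modal allele.

    Peaks binning to the same repeat unit have their heights summed (heights
    proxy molecule counts).  Peaks outside the accurate sizing window are
    retained but flagged as extrapolated.
    """
    entries: dict[int, float] = {}
    flags: set[int] = set()
    collisions = 0
    for size_bp, height in table.peaks:
        repeat, extrapolated = calib.bp_to_repeats(size_bp)
        if repeat in entries:
            collisions += 1
        entries[repeat] = entries.get(repeat, 0.0) + height
        if extrapolated:
            flags.add(repeat)
    if collisions:
        warnings.warn(
            f"{table.sample_id}/{table.locus}: {collisions} peak(s) binned to an "
            "already-occupied repeat unit; heights summed",
            stacklevel=2,
        )
    return AlleleDistribution.from_entries(table.locus, entries, flags)
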