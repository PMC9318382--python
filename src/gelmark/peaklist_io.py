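"""Reading and writing peak lists, sample metadata, and MRM area tables.

The native exchange format is plain TSV with a mandatory header. Peak
tables carry three columns (``mz``, ``intensity``, ``rt``); MRM tables
carry ``sample_id``, ``marker_id``, ``area``. Centroided MS1 spectra from
mzML files can be ingested through the same :class:`PeakList` contract.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .constants import SCAN_RANGE

logger = logging.getLogger(__name__)

VALID_SPECIES = frozenset({"donkey", "horse", "cattle", "pig", "unknown"})
VALID_KINDS = frozenset({"reference", "homemade", "commercial"})

#: Marker ids accepted in MRM measurement tables: the four quantified
#: species-specific markers plus the pharmacopoeia donkey marker.
QUANTIFIED_MARKERS = frozenset({"CP", "DM4", "HM1", "CM2", "PM2"})

PEAK_COLUMNS = ("mz", "intensity", "rt")


class PeakTableFormatError(ValueError):
    """Raised when a peak or MRM table does not match the expected schema."""


class SpectrumPeak(NamedTuple):
    """One centroided MS1 peak: m/z (Th), intensity (counts), RT (min)."""

    mz: float
    intensity: float
    rt: float


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one gelatin sample within a run set."""

    sample_id: str
    species: str = "unknown"
    batch: str = "1"
    kind: str = "reference"

    def __post_init__(self) -> None:
        if self.species not in VALID_SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown sample kind {self.kind!r}")
        if self.kind == "commercial" and self.species != "unknown":
            raise ValueError("commercial samples must have species='unknown'")


@dataclass
class PeakList:
    """All centroid peaks of one sample, sorted by (rt, mz)."""

    meta: SampleMeta
    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(PEAK_COLUMNS)))

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.table.columns]
        if missing:
            raise PeakTableFormatError(f"peak table missing column(s): {', '.join(missing)}")
        self.table = (
            self.table.loc[:, list(PEAK_COLUMNS)]
            .astype(float)
            .sort_values(["rt", "mz"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def peaks(self) -> list[SpectrumPeak]:
        return [SpectrumPeak(*row) for row in self.table.itertuples(index=False)]

    def filtered(self, scan_range: tuple[float, float] = SCAN_RANGE) -> "PeakList":
        """Restrict to the scan range (inclusive on both bounds)."""
        lo, hi = scan_range
        kept = self.table[(self.table.mz >= lo) & (self.table.mz <= hi)]
        n_removed = len(self.table) - len(kept)
        if n_removed:
            logger.info(
                "%s: removed %d peak(s) outside scan range [%g, %g]",
                self.meta.sample_id, n_removed, lo, hi,
            )
        return PeakList(self.meta, kept.reset_index(drop=True))


def read_peak_table(
    path: str | Path,
    meta: SampleMeta,
    scan_range: tuple[float, float] = SCAN_RANGE,
) -> PeakList:
    """Read a TSV/CSV peak table and apply the scan-range ingestion filter.

    The delimiter is sniffed from the header line (tab wins over comma).
    An empty file yields an empty :class:`PeakList` with a warning.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        logger.warning("%s: empty peak table", path)
        return PeakList(meta)
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in PEAK_COLUMNS if c not in table.columns]
    if missing:
        raise PeakTableFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return PeakList(meta, table).filtered(scan_range)


def write_peak_table(peaklist: PeakList, path: str | Path) -> Path:
    """Write a :class:`PeakList` back to TSV (round-trips to 1e-6)."""
    path = Path(path)
    peaklist.table.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_mzml(
    path: str | Path,
    meta: SampleMeta,
    scan_range: tuple[float, float] = SCAN_RANGE,
) -> PeakList:
    """Ingest centroided MS1 spectra from an mzML file.

    Requires :mod:`pyteomics`. Profile-mode spectra are not supported;
    every MS1 spectrum's peak array is taken as centroids at the spectrum's
    scan start time (converted to minutes).
    """
    from pyteomics import mzml as _mzml  # optional dependency

    rows: list[tuple[float, float, float]] = []
    with _mzml.MzML(str(path)) as reader:
        for spectrum in reader:
            if spectrum.get("ms level") != 1:
                continue
            scan = spectrum["scanList"]["scan"][0]
            rt = float(scan["scan start time"])
            unit = getattr(scan.get("scan start time"), "unit_info", "minute")
            if unit and "second" in str(unit):
                rt /= 60.0
            mzs = np.asarray(spectrum["m/z array"], dtype=float)
            ints = np.asarray(spectrum["intensity array"], dtype=float)
            rows.extend(zip(mzs, ints, np.full(len(mzs), rt)))
    table = pd.DataFrame(rows, columns=list(PEAK_COLUMNS))
    return PeakList(meta, table).filtered(scan_range)


def read_mrm_table(
    path: str | Path,
    known_markers: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Read an MRM measurement table (sample_id, marker_id, area).

    Areas must be non-negative; marker ids must belong to ``known_markers``
    (default: the quantified marker set).
    """
    known = frozenset(known_markers) if known_markers is not None else QUANTIFIED_MARKERS
    path = Path(path)
    text = path.read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    table = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    missing = [c for c in ("sample_id", "marker_id", "area") if c not in table.columns]
    if missing:
        raise PeakTableFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    table["area"] = table["area"].astype(float)
    if (table["area"] < 0).any():
        bad = table.loc[table["area"] < 0].iloc[0]
        raise ValueError(
            f"{path}: negative peak area {bad.area} for sample {bad.sample_id}"
        )
    unknown = set(table["marker_id"]) - known
    if unknown:
        raise ValueError(f"{path}: unknown marker id(s): {sorted(unknown)}")
    return table.loc[:, ["sample_id", "marker_id", "area"]]


def write_report(results, path: str | Path) -> Path:
    """Serialize a pipeline product: DataFrames to TSV, mappings to JSON.

    Reals are written with 6 decimals so re-reading reproduces them to
    1e-6; integers round-trip bit-exact.
    """
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, sep="\t", index=False, float_format="%.6f")
    elif isinstance(results, dict):
        path.write_text(json.dumps(results, indent=2, default=_json_default) + "\n")
    elif hasattr(results, "to_frame"):
        results.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
    elif hasattr(results, "to_dict"):
        path.write_text(json.dumps(results.to_dict(), indent=2, default=_json_default) + "\n")
    else:
        raise TypeError(f"cannot serialize {type(results).__name__} as a report")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), 6)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")
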