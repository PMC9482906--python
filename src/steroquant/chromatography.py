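"""Extracted-ion chromatograms and peak integration.

This module replaces the vendor processing step: centroided full-scan (or PRM)
data is reduced to one extracted-ion chromatogram (XIC) per quantifier ion at
a fixed absolute m/z tolerance (default 5 mmu = 0.005 Th), and chromatographic
peaks are integrated by trapezoidal integration above a linear baseline drawn
between the detected peak bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .panel import Panel, assign_internal_standard

__all__ = [
    "ScanSeries",
    "Chromatogram",
    "PeakMeasurement",
    "extract_xic",
    "integrate_peak",
    "read_mzml",
    "read_area_table",
    "measure_sample",
    "DEFAULT_MZ_TOLERANCE",
]

DEFAULT_MZ_TOLERANCE = 0.005  # Th (5 mmu)
DEFAULT_RT_WINDOW = 0.2  # minutes, peak search half-window around expected RT
BOUNDARY_FRACTION = 0.001  # stop walking bounds when intensity falls below this x apex
LOCAL_MIN_FRACTION = 0.05  # ... or at a local minimum below this x apex
DETECTION_SNR = 3.0  # apex must exceed this x the median background


@dataclass
class ScanSeries:
    """Ordered centroided scans of one polarity (one acquisition channel)."""

    polarity: str
    scans: list[tuple[float, np.ndarray, np.ndarray]]  # (rt_min, mz, intensity)

    def __post_init__(self) -> None:
        rts = [s[0] for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise DataError("scan retention times must be strictly increasing")
        clean = []
        for rt, mz, inten in self.scans:
            mz = np.asarray(mz, dtype=float)
            inten = np.asarray(inten, dtype=float)
            if mz.shape != inten.shape:
                raise DataError("centroid m/z and intensity arrays differ in length")
            if np.any(inten < 0):
                raise DataError("centroid intensities must be non-negative")
            order = np.argsort(mz, kind="stable")
            clean.append((float(rt), mz[order], inten[order]))
        self.scans = clean

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def rt(self) -> np.ndarray:
        return np.array([s[0] for s in self.scans])


@dataclass
class Chromatogram:
    """One XIC: summed centroid intensity within ±tolerance of target m/z."""

    target_mz: float
    tolerance: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise DataError("chromatogram rt/intensity arrays differ in length")
        if self.rt.size > 1 and np.any(np.diff(self.rt) <= 0):
            raise DataError("chromatogram rt must be strictly increasing")


@dataclass
class PeakMeasurement:
    """Integrated peak of one analyte in one sample."""

    analyte: str
    sample_id: str
    area: float  # counts * min
    apex_rt: float
    apex_intensity: float
    flags: set[str] = field(default_factory=set)

    @property
    def detected(self) -> bool:
        return "not_detected" not in self.flags


def extract_xic(
    scans: ScanSeries, target_mz: float, tolerance: float = DEFAULT_MZ_TOLERANCE
) -> Chromatogram:
    """Extract the ion chromatogram for ``target_mz`` at absolute ``tolerance``.

    Each scan contributes one point: the sum of the intensities of all
    centroids with ``|mz - target_mz| <= tolerance`` (zero when none match).
    An empty scan series yields an empty chromatogram.
    """
    if tolerance <= 0:
        raise DataError("m/z tolerance must be > 0")
    n = len(scans.scans)
    rt = np.empty(n)
    intensity = np.empty(n)
    lo, hi = target_mz - tolerance, target_mz + tolerance
    for i, (t, mz, inten) in enumerate(scans.scans):
        rt[i] = t
        a = np.searchsorted(mz, lo, side="left")
        b = np.searchsorted(mz, hi, side="right")
        intensity[i] = inten[a:b].sum() if b > a else 0.0
    return Chromatogram(target_mz=target_mz, tolerance=tolerance, rt=rt, intensity=intensity)


def _walk_bound(intensity: np.ndarray, apex_idx: int, step: int, apex: float) -> int:
    """Walk from the apex until the signal dies off or a valley is reached."""
    i = apex_idx
    n = intensity.size
    while 0 < i < n - 1:
        j = i + step
        if intensity[j] <= BOUNDARY_FRACTION * apex:
            return j
        # local minimum well below the apex ends the peak (shoulder of a neighbour)
        if (
            intensity[j] <= LOCAL_MIN_FRACTION * apex
            and 0 < j < n - 1
            and intensity[j] <= intensity[j - 1]
            and intensity[j] <= intensity[j + 1]
        ):
            return j
        i = j
    return min(max(i + step, 0), n - 1)


def integrate_peak(
    xic: Chromatogram,
    expected_rt: float,
    rt_window: float = DEFAULT_RT_WINDOW,
    analyte: str = "",
    sample_id: str = "",
) -> PeakMeasurement:
    """Integrate the chromatographic peak nearest ``expected_rt``.

    The apex is the maximum point within ``expected_rt ± rt_window``. Peak
    bounds are walked outward from the apex until the intensity falls below
    0.1% of the apex or a local minimum below 5% of the apex is reached; the
    area is the trapezoidal integral above a straight baseline drawn between
    the two boundary points. The peak is flagged ``not_detected`` when the
    apex does not exceed 3x the median intensity outside the search window.
    """
    if rt_window <= 0:
        raise DataError("rt_window must be > 0")
    rt, intensity = xic.rt, xic.intensity
    flags: set[str] = set()
    in_window = (rt >= expected_rt - rt_window) & (rt <= expected_rt + rt_window)
    if rt.size == 0 or not in_window.any():
        return PeakMeasurement(analyte, sample_id, 0.0, expected_rt, 0.0, {"not_detected"})

    window_idx = np.nonzero(in_window)[0]
    apex_idx = window_idx[np.argmax(intensity[window_idx])]
    apex = intensity[apex_idx]

    outside = intensity[~in_window]
    background = float(np.median(outside)) if outside.size else 0.0
    if apex <= 0 or apex < DETECTION_SNR * background:
        return PeakMeasurement(
            analyte, sample_id, 0.0, float(rt[apex_idx]), float(apex), {"not_detected"}
        )

    left = _walk_bound(intensity, apex_idx, -1, apex)
    right = _walk_bound(intensity, apex_idx, +1, apex)
    seg_rt = rt[left : right + 1]
    seg_int = intensity[left : right + 1]
    baseline = np.interp(seg_rt, [seg_rt[0], seg_rt[-1]], [seg_int[0], seg_int[-1]])
    area = float(np.trapezoid(np.clip(seg_int - baseline, 0.0, None), seg_rt))

    if abs(rt[apex_idx] - expected_rt) > 0.5 * rt_window:
        flags.add("rt_shift")
    return PeakMeasurement(
        analyte, sample_id, area, float(rt[apex_idx]), float(apex), flags
    )


def read_mzml(path: str | Path) -> dict[str, ScanSeries]:
    """Read centroided MS1 spectra from an mzML file, split by polarity."""
    from pyteomics import mzml as pymzml

    by_polarity: dict[str, list[tuple[float, np.ndarray, np.ndarray]]] = {}
    with pymzml.read(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level", 1) != 1:
                continue
            polarity = "negative" if "negative scan" in spec else "positive"
            scan_start = spec["scanList"]["scan"][0]
            rt = float(scan_start["scan start time"])
            # pyteomics reports unit via unit_info; seconds -> minutes
            if getattr(scan_start["scan start time"], "unit_info", "minute") == "second":
                rt /= 60.0
            by_polarity.setdefault(polarity, []).append(
                (rt, np.asarray(spec["m/z array"]), np.asarray(spec["intensity array"]))
            )
    return {
        pol: ScanSeries(polarity=pol, scans=sorted(scans, key=lambda s: s[0]))
        for pol, scans in by_polarity.items()
    }


def read_area_table(path: str | Path) -> pd.DataFrame:
    """Read a pre-integrated peak-area table.

    Expected columns: ``sample_id, analyte, area, is_area`` (extra columns are
    preserved). This is the entry point when integration was done elsewhere.
    """
    df = pd.read_csv(path)
    missing = {"sample_id", "analyte", "area", "is_area"} - set(df.columns)
    if missing:
        raise DataError(f"area table {path} lacks columns: {sorted(missing)}")
    return df


def measure_sample(
    scans_by_polarity: dict[str, ScanSeries],
    panel: Panel,
    sample_id: str = "",
    tolerance: float = DEFAULT_MZ_TOLERANCE,
    rt_window: float = DEFAULT_RT_WINDOW,
) -> pd.DataFrame:
    """XIC-extract and integrate every panel analyte and internal standard.

    Returns a tidy area table (sample_id, analyte, area, is_area, flags) ready
    for calibration, with each analyte normalized against its assigned
    internal standard measured in the same run.
    """
    is_areas: dict[str, float] = {}
    for std in panel.internal_standards:
        series = scans_by_polarity.get(std.polarity)
        if series is None:
            continue
        xic = extract_xic(series, std.mz, tolerance)
        peak = integrate_peak(xic, std.expected_rt, rt_window, std.id, sample_id)
        is_areas[std.id] = peak.area if peak.detected else 0.0

    rows = []
    for s in panel.steroids:
        series = scans_by_polarity.get(s.polarity)
        if series is None:
            rows.append((sample_id, s.abbreviation, 0.0, 0.0, "not_detected"))
            continue
        xic = extract_xic(series, s.mz, tolerance)
        peak = integrate_peak(xic, s.expected_rt, rt_window, s.abbreviation, sample_id)
        std = assign_internal_standard(s, panel)
        rows.append(
            (
                sample_id,
                s.abbreviation,
                peak.area,
                is_areas.get(std.id, 0.0),
                ";".join(sorted(peak.flags)),
            )
        )
    return pd.DataFrame(rows, columns=["sample_id", "analyte", "area", "is_area", "flags"])
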