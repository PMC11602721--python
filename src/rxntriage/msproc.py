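"""LC-MS processing: chromatogram peak detection, per-peak spectrum
extraction, and targeted / assembly-table m/z matching.

Two acquisition modes are supported. Gradient runs carry a chromatographic
separation: the total-ion chromatogram is peak-picked, the mass spectra under
each main peak are averaged, and expected masses are matched against those
spectra. Direct-injection runs (column bypassed, used for supramolecular
screens) are collapsed to a single time-averaged spectrum and matched against
the precalculated assembly charge-ladder table.

Tolerances default to 0.5 Da with a 2% relative-intensity floor, appropriate
for unit-resolution single-quadrupole data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chemspace import MzTable

__all__ = [
    "MassSpectrum",
    "LcmsRun",
    "ChromPeak",
    "TargetMatch",
    "MsMatchResult",
    "MsModeError",
    "detect_chrom_peaks",
    "extract_peak_spectrum",
    "main_peaks",
    "match_targeted",
    "match_assembly_table",
    "average_spectra",
    "DEFAULT_MZ_TOL",
    "DEFAULT_REL_AREA_MIN",
    "DEFAULT_REL_INT_FLOOR",
]

DEFAULT_MZ_TOL = 0.5  # Da
DEFAULT_REL_AREA_MIN = 0.10
DEFAULT_REL_INT_FLOOR = 0.02
DEFAULT_MIN_PROMINENCE = 0.05  # fraction of TIC max
DEFAULT_MIN_SEPARATION = 0.05  # minutes
DEFAULT_SMOOTH_WINDOW = 5  # points
DEFAULT_MZ_BIN = 0.1  # Da, re-centroiding bin width


class MsModeError(ValueError):
    """Operation applied to the wrong acquisition mode."""


@dataclass
class MassSpectrum:
    """Centroided spectrum: ascending m/z, non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1D arrays of equal length")
        if self.mz.size:
            if np.any(self.mz <= 0):
                raise ValueError("m/z values must be positive")
            if np.any(np.diff(self.mz) < 1e-6):
                raise ValueError("m/z values must be ascending without duplicates")
            if np.any(self.intensity < 0):
                raise ValueError("intensities must be non-negative")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())

    def above_floor(self, rel_floor: float) -> "MassSpectrum":
        """Peaks with intensity >= rel_floor x base peak."""
        if self.mz.size == 0:
            return MassSpectrum(np.empty(0), np.empty(0))
        keep = self.intensity >= rel_floor * self.intensity.max()
        return MassSpectrum(self.mz[keep], self.intensity[keep])


@dataclass
class LcmsRun:
    """A run: strictly increasing scan times (minutes) + one spectrum each."""

    mode: str  # "gradient" | "direct_injection"
    times: np.ndarray
    scans: list[MassSpectrum]
    chromatogram: np.ndarray | None = None  # TIC; computed from scans if None

    def __post_init__(self):
        if self.mode not in ("gradient", "direct_injection"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size != len(self.scans):
            raise ValueError("one scan per time point required")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("scan times must be strictly increasing")
        if self.chromatogram is None:
            self.chromatogram = np.array([s.tic for s in self.scans], dtype=float)
        else:
            self.chromatogram = np.asarray(self.chromatogram, dtype=float)
            if self.chromatogram.shape != self.times.shape:
                raise ValueError("chromatogram must match scan times in length")

    def averaged_spectrum(self, mz_bin: float = DEFAULT_MZ_BIN) -> MassSpectrum:
        """Time-averaged spectrum (the matching input for direct injection)."""
        return average_spectra(self.scans, mz_bin=mz_bin)


@dataclass(frozen=True)
class ChromPeak:
    """A detected chromatographic peak with valley-to-valley integration."""

    apex_time: float
    start_time: float
    end_time: float
    area: float
    relative_area: float

    def __post_init__(self):
        if not self.start_time < self.apex_time < self.end_time:
            raise ValueError("require start < apex < end")
        if not 0.0 <= self.relative_area <= 1.0 + 1e-9:
            raise ValueError("relative_area must lie in [0, 1]")


@dataclass(frozen=True)
class TargetMatch:
    target: str
    observed_mz: float
    expected_mz: float
    charge: int = 1
    counterions: int | None = None
    peak_time: float | None = None


@dataclass
class MsMatchResult:
    """MS verdict plus every individual m/z match behind it."""

    passed: bool
    matches: list[TargetMatch] = field(default_factory=list)
    charge_state_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "matches": [vars(m) for m in self.matches],
            "charge_state_counts": dict(self.charge_state_counts),
        }


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or y.size < window:
        return y.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(y, kernel, mode="same")


def detect_chrom_peaks(
    run: LcmsRun,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> list[ChromPeak]:
    """Prominence-based peak detection on the smoothed TIC.

    Local maxima with prominence >= ``min_prominence`` x TIC max are kept,
    maxima closer than ``min_separation`` minutes are merged (taller apex
    wins), and each peak is integrated trapezoidally between the valleys
    separating it from its neighbours (trace edges at the extremes).
    """
    from scipy.signal import find_peaks

    if run.mode != "gradient":
        raise MsModeError(
            "peak detection requires a gradient run; for direct injection "
            "match against run.averaged_spectrum() instead"
        )
    t, tic = run.times, run.chromatogram
    if t.size < 2:
        raise ValueError("need at least two time points")
    top = float(tic.max()) if tic.size else 0.0
    if top <= 0:
        return []
    y = _smooth(tic, smooth_window)
    idx, _ = find_peaks(y, prominence=min_prominence * top)
    # merge apexes closer than min_separation
    merged: list[int] = []
    for i in idx:
        if merged and t[i] - t[merged[-1]] < min_separation:
            if y[i] > y[merged[-1]]:
                merged[-1] = int(i)
        else:
            merged.append(int(i))
    if not merged:
        return []
    # valley bounds between consecutive apexes, edges at the extremes
    bounds = [0]
    for a, b in zip(merged[:-1], merged[1:]):
        bounds.append(a + int(np.argmin(y[a : b + 1])))
    bounds.append(t.size - 1)
    areas = []
    for k, apex in enumerate(merged):
        lo, hi = bounds[k], bounds[k + 1]
        areas.append(float(np.trapezoid(tic[lo : hi + 1], t[lo : hi + 1])))
    total = sum(areas)
    peaks = []
    for k, apex in enumerate(merged):
        lo, hi = bounds[k], bounds[k + 1]
        peaks.append(
            ChromPeak(
                apex_time=float(t[apex]),
                start_time=float(t[lo]),
                end_time=float(t[hi]),
                area=areas[k],
                relative_area=areas[k] / total if total > 0 else 0.0,
            )
        )
    return peaks


def average_spectra(
    scans: Sequence[MassSpectrum],
    weights: Sequence[float] | None = None,
    mz_bin: float = DEFAULT_MZ_BIN,
) -> MassSpectrum:
    """Weighted average of centroided scans, re-centroided by m/z binning.

    Sticks are pooled, weighted by scan, grouped into ``mz_bin``-wide bins and
    replaced by the intensity-weighted centroid of each bin.
    """
    if not scans:
        raise ValueError("no scans to average")
    if weights is None:
        weights = np.ones(len(scans))
    weights = np.asarray(weights, dtype=float)
    wsum = weights.sum()
    if wsum <= 0:
        weights = np.ones(len(scans))
        wsum = float(len(scans))
    all_mz = np.concatenate([s.mz for s in scans]) if scans else np.empty(0)
    all_int = (
        np.concatenate([w / wsum * s.intensity for w, s in zip(weights, scans)])
        if scans
        else np.empty(0)
    )
    if all_mz.size == 0:
        return MassSpectrum(np.empty(0), np.empty(0))
    bins = np.round(all_mz / mz_bin).astype(np.int64)
    order = np.argsort(bins, kind="stable")
    bins, all_mz, all_int = bins[order], all_mz[order], all_int[order]
    uniq, start = np.unique(bins, return_index=True)
    mz_out, int_out = [], []
    for k, s in enumerate(start):
        e = start[k + 1] if k + 1 < len(start) else len(bins)
        inten = all_int[s:e].sum()
        if inten <= 0:
            continue
        mz_out.append(float(np.average(all_mz[s:e], weights=all_int[s:e])))
        int_out.append(float(inten))
    return MassSpectrum(np.asarray(mz_out), np.asarray(int_out))


def extract_peak_spectrum(
    run: LcmsRun,
    peak: ChromPeak,
    mz_bin: float = DEFAULT_MZ_BIN,
) -> MassSpectrum:
    """TIC-weighted average of the scans under one chromatographic peak."""
    sel = (run.times >= peak.start_time - 1e-12) & (run.times <= peak.end_time + 1e-12)
    scans = [s for s, keep in zip(run.scans, sel) if keep]
    if not scans:
        raise ValueError(
            f"no scans between {peak.start_time} and {peak.end_time} minutes"
        )
    weights = [s.tic for s in scans]
    return average_spectra(scans, weights=weights, mz_bin=mz_bin)


def main_peaks(
    peaks: Sequence[ChromPeak],
    rel_area_min: float = DEFAULT_REL_AREA_MIN,
) -> list[ChromPeak]:
    """Peaks carrying at least ``rel_area_min`` of the total peak area."""
    return [p for p in peaks if p.relative_area >= rel_area_min]


def match_targeted(
    run: LcmsRun,
    expected: Sequence[tuple[str, float]],
    tol: float = DEFAULT_MZ_TOL,
    rel_area_min: float = DEFAULT_REL_AREA_MIN,
    rel_int_floor: float = DEFAULT_REL_INT_FLOOR,
    **detect_kwargs,
) -> MsMatchResult:
    """Is any anticipated product mass among the main chromatographic peaks?

    Detects peaks, keeps the main ones by relative area, extracts each peak's
    averaged spectrum, and matches every expected (label, m/z) against its
    sticks above the relative-intensity floor. Passes on >= 1 match.
    """
    if not expected:
        raise ValueError("empty expected-target list")
    peaks = main_peaks(detect_chrom_peaks(run, **detect_kwargs), rel_area_min)
    matches: list[TargetMatch] = []
    for p in peaks:
        spec = extract_peak_spectrum(run, p).above_floor(rel_int_floor)
        if spec.mz.size == 0:
            continue
        for label, want in expected:
            d = np.abs(spec.mz - want)
            j = int(np.argmin(d))
            if d[j] <= tol:
                matches.append(
                    TargetMatch(
                        target=label,
                        observed_mz=float(spec.mz[j]),
                        expected_mz=float(want),
                        peak_time=p.apex_time,
                    )
                )
    return MsMatchResult(passed=bool(matches), matches=matches)


def match_assembly_table(
    spectrum: MassSpectrum,
    table: MzTable,
    tol: float | None = None,
    min_charge_states: int = 2,
    rel_int_floor: float = DEFAULT_REL_INT_FLOOR,
) -> MsMatchResult:
    """Charge-ladder matching against the precalculated assembly table.

    For each table entry, counts how many distinct (z, n) ladder values find a
    spectrum stick (above the relative-intensity floor) within ``tol``. The
    spectrum passes when any single assembly accounts for at least
    ``min_charge_states`` different charge combinations — the guard against
    chance matches in a large look-up table.
    """
    if table.n_entries == 0:
        raise ValueError("empty m/z look-up table")
    if tol is None:
        tol = table.tolerance
    obs = spectrum.above_floor(rel_int_floor)
    matches: list[TargetMatch] = []
    counts: dict[str, int] = {}
    if obs.mz.size:
        for entry in table.entries:
            seen = 0
            for z, n, want in entry.ladder:
                d = np.abs(obs.mz - want)
                j = int(np.argmin(d))
                if d[j] <= tol:
                    seen += 1
                    matches.append(
                        TargetMatch(
                            target=entry.entry_id,
                            observed_mz=float(obs.mz[j]),
                            expected_mz=float(want),
                            charge=z,
                            counterions=n,
                        )
                    )
            if seen:
                counts[entry.entry_id] = seen
    passed = any(c >= min_charge_states for c in counts.values())
    return MsMatchResult(passed=passed, matches=matches, charge_state_counts=counts)
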