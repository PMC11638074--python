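"""MALDI-TOF readout of the mass-tagged DUB assay.

Processing chain for reflectron-mode spectra of released monoUb species
(window 7,820-9,200 m/z): Savitzky-Golay smoothing, morphological top-hat
baseline subtraction, peak detection at a signal-to-noise threshold of 5,
single-point internal calibration on the uniformly 15N-labeled Ub standard
(reference 8,669.470 m/z), assignment of peaks to the theoretical moiety
masses, and quantification as

    percent cleaved = (area_monoUb / area_15N_standard)
                      x ([15N standard] / [substrate]) x 100.

Peak detection is a documented surrogate for the vendor SNAP algorithm:
local maxima on the processed trace, robust noise from the median absolute
deviation of peak-free regions, and an envelope-width validation band
derived from the instrument resolution (an intact ~8.5 kDa protein is an
unresolved averagine-composition isotope envelope whose width is set by
m/R).  Centroids are intensity-weighted means over the envelope support;
areas are trapezoidal integrals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, signal

from .mass_engine import MoietyMassTable

__all__ = [
    "Spectrum",
    "PeakDetectionParams",
    "Peak",
    "PeakSet",
    "QuantInput",
    "QuantResult",
    "CalibrationError",
    "REFERENCE_STANDARD_MZ",
    "DEFAULT_WINDOW",
    "smooth",
    "subtract_baseline",
    "detect_peaks",
    "process_spectrum",
    "calibrate_internal",
    "assign_peaks",
    "quantify_cleavage",
    "quantify_spectrum",
    "normalize_panel",
    "aggregate_replicates",
    "read_spectrum",
    "write_spectrum",
]

#: Empirical m/z of the uniformly 15N-labeled Ub internal standard used for
#: single-point calibration.
REFERENCE_STANDARD_MZ = 8669.470
DEFAULT_WINDOW = (7820.0, 9200.0)


class CalibrationError(RuntimeError):
    """Internal standard not found; the spectrum must be rejected."""


@dataclass(frozen=True)
class Spectrum:
    """Sampled (m/z, intensity) trace."""

    mz: np.ndarray
    intensity: np.ndarray
    window: tuple[float, float] = DEFAULT_WINDOW
    calibrated: bool = False

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", it)
        if mz.ndim != 1 or mz.shape != it.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if len(mz) >= 2 and not np.all(np.diff(mz) > 0):
            raise ValueError("m/z values must be strictly increasing")
        if not np.all(np.isfinite(it)):
            raise ValueError("intensities must be finite")

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.mz)))


@dataclass(frozen=True)
class PeakDetectionParams:
    """Tunables of the detection surrogate.

    ``sg_window`` defaults to 2 x (expected FWHM / step) + 1 points;
    ``tophat_width`` (Da) must exceed the envelope width so peaks survive
    the opening; the width band accepts measured FWHMs within
    ``width_band`` x expected FWHM (= m/resolution).
    """

    snr_threshold: float = 5.0
    resolution: float = 1000.0
    sg_window: int | None = None
    sg_order: int = 3
    tophat_width: float = 85.0
    width_band: tuple[float, float] = (0.5, 1.5)
    assign_tolerance: float = 2.0
    standard_search_tolerance: float = 5.0

    def __post_init__(self):
        if self.snr_threshold <= 0:
            raise ValueError("S/N threshold must be positive")
        if self.sg_window is not None and (self.sg_window % 2 == 0 or self.sg_window <= self.sg_order):
            raise ValueError("sg_window must be odd and greater than sg_order")

    def expected_fwhm(self, mz: float) -> float:
        return mz / self.resolution

    def resolved_sg_window(self, spectrum: Spectrum) -> int:
        if self.sg_window is not None:
            return self.sg_window
        center = 0.5 * (spectrum.mz[0] + spectrum.mz[-1])
        pts = max(1, int(round(self.expected_fwhm(center) / spectrum.step)))
        return 2 * pts + 1


@dataclass(frozen=True)
class Peak:
    centroid: float
    area: float
    height: float
    snr: float
    fwhm: float


@dataclass(frozen=True)
class PeakSet:
    peaks: tuple[Peak, ...]
    noise: float
    params: PeakDetectionParams
    calibrated: bool = False
    calibration_shift: float = 0.0

    def __len__(self) -> int:
        return len(self.peaks)

    def nearest(self, mz: float) -> Peak | None:
        if not self.peaks:
            return None
        return min(self.peaks, key=lambda p: abs(p.centroid - mz))


def smooth(spectrum: Spectrum, params: PeakDetectionParams = PeakDetectionParams()) -> Spectrum:
    """Savitzky-Golay smoothing; polynomial traces of degree <= order pass unchanged."""
    window = params.resolved_sg_window(spectrum)
    if window > len(spectrum.mz):
        raise ValueError(f"smoothing window ({window} points) longer than the trace")
    out = signal.savgol_filter(spectrum.intensity, window, params.sg_order)
    return replace(spectrum, intensity=out)


def subtract_baseline(spectrum: Spectrum, params: PeakDetectionParams = PeakDetectionParams()) -> Spectrum:
    """Morphological top-hat: signal minus its grey opening.

    The structuring element (``tophat_width`` Da) is wider than any peak
    envelope, so flat/slow baseline maps to ~0 while peak areas are
    preserved within a few percent.
    """
    if params.tophat_width <= 0:
        raise ValueError("structuring element width must be positive")
    size = max(3, int(round(params.tophat_width / spectrum.step)))
    opened = ndimage.grey_opening(spectrum.intensity, size=size, mode="nearest")
    return replace(spectrum, intensity=spectrum.intensity - opened)


def _robust_noise(y: np.ndarray) -> float:
    """Noise of the peak-free regions: MAD-based clipping of peaks, then the
    standard deviation of the remaining (smoothing-correlated) residual."""
    med = np.median(y)
    mad_sigma = 1.4826 * np.median(np.abs(y - med))
    if mad_sigma > 0:
        quiet = y[np.abs(y - med) < 5 * mad_sigma]
        if len(quiet) > 10:
            sigma = float(np.std(quiet))
            if sigma > 0:
                return sigma
        return float(mad_sigma)
    return float(np.std(y) or 1e-12)


def detect_peaks(spectrum: Spectrum, params: PeakDetectionParams = PeakDetectionParams()) -> PeakSet:
    """Detect, validate and integrate peak envelopes on a processed trace.

    Expects a smoothed, baseline-subtracted spectrum.  Candidates are local
    maxima separated by at least one expected envelope width; a candidate
    is kept when its height is >= ``snr_threshold`` x the robust noise and
    its measured FWHM falls inside the validation band.
    """
    if len(spectrum.intensity) == 0:
        raise ValueError("empty spectrum")
    # heights are measured from the residual level of the processed trace:
    # a morphological opening maps noise onto a non-negative band, so zero
    # is not the local background
    y = spectrum.intensity - np.median(spectrum.intensity)
    step = spectrum.step
    center = 0.5 * (spectrum.mz[0] + spectrum.mz[-1])
    fwhm_pts = max(1, int(round(params.expected_fwhm(center) / step)))
    noise = _robust_noise(y)
    # prominence keeps ripples riding on a larger peak's tail from counting
    # as peaks of their own; two envelopes closer than 2 x FWHM are not
    # resolvable at this resolution, so only the taller one is kept
    idx, _ = signal.find_peaks(y, height=params.snr_threshold * noise,
                               prominence=params.snr_threshold * noise,
                               distance=2 * fwhm_pts)
    peaks: list[Peak] = []
    if len(idx):
        widths, _, _, _ = signal.peak_widths(y, idx, rel_height=0.5)
    for i, pk in enumerate(idx):
        fwhm_meas = widths[i] * step
        expected = params.expected_fwhm(spectrum.mz[pk])
        lo, hi = params.width_band
        if not (lo * expected <= fwhm_meas <= hi * expected):
            continue
        half = 2 * fwhm_pts
        sl = slice(max(0, pk - half), min(len(y), pk + half + 1))
        w = np.clip(y[sl], 0, None)
        if w.sum() <= 0:
            continue
        centroid = float(np.average(spectrum.mz[sl], weights=w))
        area = float(np.trapezoid(w, spectrum.mz[sl]))
        peaks.append(Peak(centroid, area, float(y[pk]), float(y[pk] / noise), float(fwhm_meas)))
    # shoulder suppression: a candidate >= 20x smaller than a neighbor
    # within 3 expected FWHMs is a flank artifact of that neighbor
    # (baseline-subtraction residue), not a resolvable species
    kept = [p for p in peaks if not any(
        q.height >= 20 * p.height
        and abs(q.centroid - p.centroid) < 3 * params.expected_fwhm(p.centroid)
        for q in peaks)]
    return PeakSet(tuple(kept), noise, params)


def process_spectrum(spectrum: Spectrum, params: PeakDetectionParams = PeakDetectionParams()) -> PeakSet:
    """smooth -> top-hat baseline subtraction -> peak detection."""
    return detect_peaks(subtract_baseline(smooth(spectrum, params), params), params)


def calibrate_internal(
    peaks: PeakSet,
    reference_mz: float = REFERENCE_STANDARD_MZ,
    search_tolerance: float | None = None,
) -> PeakSet:
    """Single-point constant-offset calibration on the internal standard.

    The largest-area peak within ``search_tolerance`` of ``reference_mz``
    is taken as the 15N standard and all centroids are shifted so it sits
    at ``reference_mz`` exactly.  Raises :class:`CalibrationError` when no
    candidate is found -- an uncalibratable spectrum is rejected, never
    passed through silently.
    """
    tol = search_tolerance if search_tolerance is not None else peaks.params.standard_search_tolerance
    candidates = [p for p in peaks.peaks if abs(p.centroid - reference_mz) <= tol]
    if not candidates:
        raise CalibrationError(
            f"internal standard not found within +/-{tol} Da of {reference_mz}; spectrum rejected")
    standard = max(candidates, key=lambda p: p.area)
    shift = reference_mz - standard.centroid
    shifted = tuple(replace(p, centroid=p.centroid + shift) for p in peaks.peaks)
    return replace(peaks, peaks=shifted, calibrated=True,
                   calibration_shift=peaks.calibration_shift + shift)


@dataclass(frozen=True)
class Assignment:
    """Peak-to-moiety assignment against a theoretical mass table."""

    assigned: Mapping[str, Peak]
    unassigned: tuple[Peak, ...]
    conflicts: tuple[tuple[str, Peak], ...]


def assign_peaks(peaks: PeakSet, table: MoietyMassTable, tolerance: float | None = None) -> Assignment:
    """Assign each peak to the nearest theoretical moiety m/z within tolerance.

    Requires a distinguishable table (min pairwise gap > 2 x tolerance) so
    nearest-neighbor assignment is unambiguous; when several peaks fall on
    one moiety the largest area wins and the rest are reported as
    conflicts.
    """
    tol = tolerance if tolerance is not None else peaks.params.assign_tolerance
    mzs = sorted(table.mzs)
    gaps = [b - a for a, b in zip(mzs, mzs[1:])]
    if gaps and min(gaps) <= 2 * tol:
        raise ValueError(
            f"moiety table min gap {min(gaps):.2f} Da <= 2 x tolerance {tol:.2f} Da: assignment ambiguous")
    best: dict[str, Peak] = {}
    conflicts: list[tuple[str, Peak]] = []
    unassigned: list[Peak] = []
    for p in peaks.peaks:
        row = min(table.rows, key=lambda r: abs(r.mz - p.centroid))
        if abs(row.mz - p.centroid) > tol:
            unassigned.append(p)
            continue
        cur = best.get(row.unit_id)
        if cur is None:
            best[row.unit_id] = p
        elif p.area > cur.area:
            conflicts.append((row.unit_id, cur))
            best[row.unit_id] = p
        else:
            conflicts.append((row.unit_id, p))
    return Assignment(best, tuple(unassigned), tuple(conflicts))


@dataclass(frozen=True)
class QuantInput:
    """Inputs to the percent-cleaved equation for one moiety."""

    area_moiety: float
    area_standard: float
    standard_conc: float = 0.8
    substrate_conc: float = 0.96

    def __post_init__(self):
        if self.area_moiety < 0 or self.area_standard < 0:
            raise ValueError("peak areas must be non-negative")
        if self.standard_conc <= 0 or self.substrate_conc <= 0:
            raise ValueError("concentrations must be positive")


def quantify_cleavage(q: QuantInput) -> float:
    """percent = (area_moiety / area_standard) x ([standard]/[substrate]) x 100.

    Values above 100 are returned as-is (flag downstream, never clip).
    Raises on a zero/absent standard area.
    """
    if q.area_standard == 0:
        raise ValueError("internal standard area is zero; spectrum cannot be quantified")
    return (q.area_moiety / q.area_standard) * (q.standard_conc / q.substrate_conc) * 100.0


def quantify_spectrum(
    spectrum: Spectrum,
    table: MoietyMassTable,
    standard_mz: float = REFERENCE_STANDARD_MZ,
    params: PeakDetectionParams = PeakDetectionParams(),
    standard_conc: float = 0.8,
    substrate_conc: float = 0.96,
) -> dict[str, float]:
    """Full pipeline for one spectrum: per-moiety percent cleaved.

    Moieties with no assigned peak quantify as 0 (nothing released).
    """
    peaks = process_spectrum(spectrum, params)
    peaks = calibrate_internal(peaks, reference_mz=standard_mz)
    standard = peaks.nearest(standard_mz)
    assert standard is not None  # calibration guarantees a standard peak
    assignment = assign_peaks(peaks, table)
    out: dict[str, float] = {}
    for row in table.rows:
        pk = assignment.assigned.get(row.unit_id)
        area = pk.area if pk is not None else 0.0
        out[row.unit_id] = quantify_cleavage(
            QuantInput(area, standard.area, standard_conc, substrate_conc))
    return out


# ---------------------------------------------------------------------------
# Panel aggregation and normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantResult:
    """Percent cleaved for one (enzyme, substrate, moiety) cell."""

    dub: str
    substrate: str
    moiety: str
    replicates: tuple[float, ...]
    is_control: bool = False
    is_distal_48ub3: bool = False

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def flagged_over_100(self) -> bool:
        return any(v > 100.0 for v in self.replicates)


def normalize_panel(results: Sequence[QuantResult], mode: str = "none"):
    """Normalize a DUB x (substrate, moiety) panel of percent-cleaved values.

    ``control_substrate`` divides every value of a DUB by that DUB's
    control-substrate percent (rows flagged ``is_control``);
    ``distal_48Ub3`` divides by the percent for the distal moiety of the
    homotypic K48 trimer (rows flagged ``is_distal_48ub3``); ``none``
    returns raw percents.  Returns ``(matrix, flags)`` where ``matrix`` is
    a pandas DataFrame indexed by DUB with (substrate, moiety) columns and
    ``flags`` lists DUBs whose reference is missing or zero (their rows are
    kept as NaN, not dropped).
    """
    import pandas as pd

    if mode not in ("none", "control_substrate", "distal_48Ub3"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    refs: dict[str, float] = {}
    if mode != "none":
        flag_attr = "is_control" if mode == "control_substrate" else "is_distal_48ub3"
        for r in results:
            if getattr(r, flag_attr):
                refs[r.dub] = r.mean
    records = {}
    flags: list[str] = []
    for r in results:
        if mode == "none":
            val = r.mean
        else:
            ref = refs.get(r.dub)
            if ref is None or ref == 0:
                if r.dub not in flags:
                    flags.append(r.dub)
                val = float("nan")
            else:
                val = r.mean / ref
        records.setdefault(r.dub, {})[(r.substrate, r.moiety)] = val
    matrix = pd.DataFrame.from_dict(records, orient="index")
    matrix.index.name = "dub"
    return matrix, flags


def aggregate_replicates(results: Sequence[QuantResult]):
    """Heat-map table (mean per cell) plus the individual replicate points.

    Returns ``(heatmap, points)``: ``heatmap`` is a DUB x (substrate,
    moiety) DataFrame of means with an ``n`` recorded per cell in
    ``points``; ``points`` is a tidy DataFrame retaining every replicate
    value (cells with a single replicate carry n = 1).
    """
    import pandas as pd

    rows = []
    for r in results:
        if len(r.replicates) < 1:
            raise ValueError("each cell needs at least one replicate")
        for i, v in enumerate(r.replicates):
            rows.append({"dub": r.dub, "substrate": r.substrate, "moiety": r.moiety,
                         "replicate": i + 1, "percent": v, "n": len(r.replicates)})
    points = pd.DataFrame(rows)
    heatmap = points.pivot_table(index="dub", columns=["substrate", "moiety"],
                                 values="percent", aggfunc="mean")
    return heatmap, points


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_spectrum(path: str, window: tuple[float, float] = DEFAULT_WINDOW) -> Spectrum:
    """Read a spectrum from two-column text (m/z, intensity) or mzML."""
    if str(path).lower().endswith(".mzml"):
        from pyteomics import mzml

        with mzml.MzML(str(path)) as reader:
            spec = next(iter(reader))
        mz = np.asarray(spec["m/z array"], dtype=float)
        it = np.asarray(spec["intensity array"], dtype=float)
    else:
        data = np.loadtxt(path)
        mz, it = data[:, 0], data[:, 1]
    keep = (mz >= window[0]) & (mz <= window[1])
    return Spectrum(mz[keep], it[keep], window=window)


def write_spectrum(spectrum: Spectrum, path: str) -> None:
    """Write a spectrum as two-column (m/z TAB intensity) text."""
    np.savetxt(path, np.column_stack([spectrum.mz, spectrum.intensity]),
               fmt="%.6f\t%.6f")
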