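"""Downstream quantification of a simulated run: XIC extraction, peak
integration, heavy/light ratios and absolute amounts, calibration curves with
limit of detection, replicate CVs, protein rollup, and the sample matrix
that distinguishes below-LOD from technically missing values.

The central clinical logic: a target whose heavy reference was acquired but
whose endogenous light partner yields no signal is *below the limit of
detection* — a statement about the sample — whereas a target whose heavy
reference never fired is *missing* — a statement about the measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .engine import RunResult
from .instrument import Provenance, ScanType
from .scheduling import TriggerTarget

__all__ = [
    "Status",
    "Chromatogram",
    "QuantResult",
    "CalibrationCurve",
    "QuantMatrix",
    "extract_xic",
    "integrate_peak",
    "quantify_pair",
    "quantify_pair_dia",
    "fit_calibration",
    "replicate_cv",
    "protein_rollup",
    "completeness",
]


class Status(str, Enum):
    QUANTIFIED = "quantified"
    BELOW_LOD = "below_LOD"
    MISSING = "missing"


_SOURCES = {
    "ms1_precursor": (ScanType.MS1,),
    "msxprm_fragment": (ScanType.MSXPRM,),
    "dia_ms2_fragment": (ScanType.DIA_MS2,),
}


@dataclass
class Chromatogram:
    """Extracted ion chromatogram of one m/z trace."""

    times: np.ndarray
    intensities: np.ndarray
    source: str
    mz: float
    ppm_tol: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")

    def __len__(self) -> int:
        return len(self.times)


def extract_xic(
    run: RunResult,
    mz: float,
    ppm_tol: float,
    rt_window: tuple[float, float] | None = None,
    source: str = "msxprm_fragment",
    target_id: str | None = None,
) -> Chromatogram:
    """One chromatogram point per matching scan: summed intensity of peaks
    within ppm_tol of mz (zero when no peak matches)."""
    scan_types = _SOURCES[source]
    times, intensities, floors = [], [], []
    for scan in run.scans:
        if scan.request.scan_type not in scan_types:
            continue
        if target_id is not None and scan.target_id != target_id:
            continue
        if rt_window is not None and not rt_window[0] <= scan.start_s <= rt_window[1]:
            continue
        times.append(scan.start_s)
        intensities.append(scan.spectrum.match(mz, ppm_tol))
        floors.append(scan.spectrum.noise_floor)
    baseline = float(np.median(floors)) if floors else 0.0
    return Chromatogram(
        times=np.array(times),
        intensities=np.array(intensities),
        source=source,
        mz=mz,
        ppm_tol=ppm_tol,
        baseline=baseline,
    )


def extract_dia_window_xic(
    run: RunResult,
    fragment_mz: float,
    precursor_mz: float,
    ppm_tol: float,
    rt_window: tuple[float, float] | None = None,
) -> Chromatogram:
    """Fragment XIC restricted to the DIA MS2 scans whose isolation window
    contains the precursor."""
    times, intensities, floors = [], [], []
    for scan in run.scans:
        if scan.request.scan_type is not ScanType.DIA_MS2:
            continue
        center, width = scan.request.isolation_windows[0]
        if not center - width / 2 <= precursor_mz < center + width / 2:
            continue
        if rt_window is not None and not rt_window[0] <= scan.start_s <= rt_window[1]:
            continue
        times.append(scan.start_s)
        intensities.append(scan.spectrum.match(fragment_mz, ppm_tol))
        floors.append(scan.spectrum.noise_floor)
    baseline = float(np.median(floors)) if floors else 0.0
    return Chromatogram(
        np.array(times), np.array(intensities), "dia_ms2_fragment",
        fragment_mz, ppm_tol, baseline,
    )


def integrate_peak(chrom: Chromatogram, boundary_factor: float = 0.0) -> float:
    """Trapezoidal area of the contiguous region around the apex whose points
    exceed ``boundary_factor x baseline`` (with a zero baseline, the
    contiguous nonzero region)."""
    if len(chrom) < 2:
        return 0.0
    y = chrom.intensities
    if not np.any(y > 0):
        return 0.0
    cut = boundary_factor * chrom.baseline
    apex = int(np.argmax(y))
    if y[apex] <= cut:
        return 0.0
    lo = apex
    while lo > 0 and y[lo - 1] > cut:
        lo -= 1
    hi = apex
    while hi < len(y) - 1 and y[hi + 1] > cut:
        hi += 1
    if hi == lo:
        return 0.0
    return float(np.trapezoid(y[lo : hi + 1], chrom.times[lo : hi + 1]))


def _pair_traces(
    run: RunResult, target: TriggerTarget, ppm_tol: float
) -> tuple[Chromatogram, Chromatogram, int]:
    """Summed heavy- and light-fragment traces from the target's MSxPRM
    scans, plus the scan count."""
    scans = [
        s
        for s in run.scans
        if s.target_id == target.target_id
        and s.provenance in (Provenance.MSXPRM, Provenance.STANDALONE_PRM)
    ]
    times = np.array([s.start_s for s in scans])
    heavy = np.zeros(len(scans))
    light = np.zeros(len(scans))
    floors = np.array([s.spectrum.noise_floor for s in scans]) if scans else np.array([])
    for i, s in enumerate(scans):
        heavy[i] = sum(s.spectrum.match(f, ppm_tol) for f in target.fragments)
        light[i] = sum(s.spectrum.match(f, ppm_tol) for f in target.light_fragments())
    baseline = float(np.median(floors)) if len(floors) else 0.0
    hc = Chromatogram(times, heavy, "msxprm_fragment", target.heavy_mz, ppm_tol, baseline)
    lc = Chromatogram(times, light, "msxprm_fragment", target.light_mz, ppm_tol, baseline)
    return hc, lc, len(scans)


@dataclass
class QuantResult:
    """Quantification outcome for one target in one run."""

    target_id: str
    sample: str
    light_area: float
    heavy_area: float
    ratio: float  # light/heavy; nan when undefined
    amount_estimate_fmol: float  # ratio x spiked heavy amount; nan when undefined
    status: Status
    n_scans: int


def quantify_pair(
    run: RunResult,
    target: TriggerTarget,
    spiked_heavy_fmol: float,
    min_scans: int = 3,
    ppm_tol: float = 10.0,
) -> QuantResult:
    """Quantify one heavy/light pair from its multiplexed-PRM traces.

    Statuses: ``quantified`` needs both channels integrable from at least
    ``min_scans`` points; ``below_LOD`` means the heavy reference was
    acquired and quantified but the light channel gave no integrable signal;
    ``missing`` means the heavy reference itself was never acquired.
    """
    heavy_trace, light_trace, n_scans = _pair_traces(run, target, ppm_tol)
    heavy_points = int(np.sum(heavy_trace.intensities > 0))
    light_points = int(np.sum(light_trace.intensities > 0))
    heavy_area = integrate_peak(heavy_trace) if heavy_points >= min_scans else 0.0
    light_area = integrate_peak(light_trace) if light_points >= min_scans else 0.0
    heavy_ok = heavy_area > 0
    light_ok = light_area > 0
    if heavy_ok and light_ok:
        status = Status.QUANTIFIED
        ratio = light_area / heavy_area
        amount = ratio * spiked_heavy_fmol
    elif heavy_ok:
        status = Status.BELOW_LOD
        ratio = np.nan
        amount = np.nan
    else:
        status = Status.MISSING
        ratio = np.nan
        amount = np.nan
    return QuantResult(
        target_id=target.target_id,
        sample=run.sample_name,
        light_area=light_area,
        heavy_area=heavy_area,
        ratio=ratio,
        amount_estimate_fmol=amount,
        status=status,
        n_scans=n_scans,
    )


def quantify_pair_dia(
    run: RunResult,
    target: TriggerTarget,
    spiked_heavy_fmol: float,
    min_scans: int = 3,
    min_fragments: int = 3,
    ppm_tol: float = 10.0,
) -> QuantResult:
    """DIA-arm detection and quantification of the light peptide.

    A deliberately simple stand-in for a spectral-library search: the light
    peptide counts as DIA-detected when its precursor is seen in MS1 and at
    least ``min_fragments`` of its fragments each give >= ``min_scans``
    points in the DIA window covering the precursor. DIA has no spike-in
    reference to certify absence, so undetected targets are ``missing``.
    """
    rt = target.rt_window
    ms1 = extract_xic(run, target.light_mz, ppm_tol, rt, source="ms1_precursor")
    ms1_points = int(np.sum(ms1.intensities > 0))
    frag_areas = []
    detected_fragments = 0
    for fmz in target.light_fragments():
        trace = extract_dia_window_xic(run, fmz, target.light_mz, ppm_tol, rt)
        if int(np.sum(trace.intensities > 0)) >= min_scans:
            detected_fragments += 1
            frag_areas.append(integrate_peak(trace))
    detected = ms1_points >= min_scans and detected_fragments >= min_fragments
    n_scans = len(ms1)
    if detected:
        heavy_area = sum(
            integrate_peak(extract_dia_window_xic(run, fmz, target.heavy_mz, ppm_tol, rt))
            for fmz in target.fragments
        )
        light_area = float(sum(frag_areas))
        ratio = light_area / heavy_area if heavy_area > 0 else np.nan
        amount = ratio * spiked_heavy_fmol if heavy_area > 0 else np.nan
        return QuantResult(
            target.target_id, run.sample_name, light_area, heavy_area,
            ratio, amount, Status.QUANTIFIED, n_scans,
        )
    return QuantResult(
        target.target_id, run.sample_name, 0.0, 0.0, np.nan, np.nan,
        Status.MISSING, n_scans,
    )


@dataclass
class CalibrationCurve:
    """Log-log dilution calibration with a detection-based LOD."""

    points: list[tuple[float, float]]  # (nominal fmol, measured ratio)
    slope: float
    intercept: float
    r_squared: float
    lod_fmol: float
    unfit: bool = False

    @property
    def below_lod_report(self) -> str:
        return f"< {self.lod_fmol:.3g} fmol/μl"


def fit_calibration(
    results: list[QuantResult],
    nominal_fmol: list[float],
    spiked_heavy_fmol: float,
) -> CalibrationCurve:
    """Least squares on log10(nominal) vs log10(measured ratio) over the
    quantified points; the LOD is the smallest nominal level quantified in at
    least half of its replicates. With fewer than three quantified levels the
    slope/intercept are flagged unfit but the LOD is still reported."""
    if len(results) != len(nominal_fmol):
        raise ValueError("one nominal level per quant result required")
    by_level: dict[float, list[QuantResult]] = {}
    for res, level in zip(results, nominal_fmol):
        by_level.setdefault(level, []).append(res)
    detected_levels = sorted(
        level
        for level, group in by_level.items()
        if level > 0
        and sum(r.status is Status.QUANTIFIED for r in group) >= len(group) / 2
    )
    lod = detected_levels[0] if detected_levels else np.nan
    points = [
        (level, r.ratio)
        for level, group in sorted(by_level.items())
        for r in group
        if r.status is Status.QUANTIFIED and level > 0
    ]
    n_levels = len({p[0] for p in points})
    if n_levels >= 3:
        x = np.log10([p[0] for p in points])
        y = np.log10([p[1] for p in points])
        fit = stats.linregress(x, y)
        return CalibrationCurve(
            points, float(fit.slope), float(fit.intercept),
            float(fit.rvalue**2), float(lod),
        )
    return CalibrationCurve(points, np.nan, np.nan, np.nan, float(lod), unfit=True)


def replicate_cv(areas) -> float:
    """Coefficient of variation (%) across replicates: 100 x sd / mean with
    the sample standard deviation; undefined (nan) for a zero mean."""
    areas = np.asarray(areas, dtype=float)
    if len(areas) < 2:
        raise ValueError("CV needs at least two replicates")
    mean = areas.mean()
    if mean == 0:
        return np.nan
    return float(100.0 * areas.std(ddof=1) / mean)


def protein_rollup(
    peptide_quantities: list[tuple[float, Status]],
) -> tuple[float, Status]:
    """Protein-level quantity: mean of quantified peptide amounts; a protein
    whose peptides are all below LOD inherits below_LOD, and one with no
    heavy evidence at all is missing."""
    if not peptide_quantities:
        raise ValueError("at least one peptide required")
    quantified = [q for q, s in peptide_quantities if s is Status.QUANTIFIED]
    if quantified:
        return float(np.mean(quantified)), Status.QUANTIFIED
    if any(s is Status.BELOW_LOD for _, s in peptide_quantities):
        return np.nan, Status.BELOW_LOD
    return np.nan, Status.MISSING


@dataclass
class QuantMatrix:
    """Proteins (or peptides) x samples, each cell a (value, status) pair."""

    values: pd.DataFrame
    statuses: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.statuses.index) or not self.values.columns.equals(
            self.statuses.columns
        ):
            raise ValueError("value and status frames must be aligned")

    def completeness(self, count_below_lod_as_informative: bool = False) -> float:
        return completeness(self, count_below_lod_as_informative)

    def to_tsv(self, path) -> None:
        """Paired value/status columns per sample."""
        out = pd.DataFrame(index=self.values.index)
        for col in self.values.columns:
            out[f"{col}.value"] = self.values[col]
            out[f"{col}.status"] = self.statuses[col].map(
                lambda s: s.value if isinstance(s, Status) else s
            )
        out.to_csv(path, sep="\t", index_label="row")


def completeness(matrix: QuantMatrix, count_below_lod_as_informative: bool = False) -> float:
    """Percentage of matrix cells carrying information: quantified cells, or
    quantified plus below-LOD cells when the flag is set (a below-LOD cell is
    an informative statement about the sample, not a technical gap)."""
    statuses = matrix.statuses.values.ravel()
    if statuses.size == 0:
        raise ValueError("matrix is empty")
    ok = {Status.QUANTIFIED, Status.QUANTIFIED.value}
    if count_below_lod_as_informative:
        ok |= {Status.BELOW_LOD, Status.BELOW_LOD.value}
    n_ok = sum(1 for s in statuses if s in ok)
    return 100.0 * n_ok / statuses.size
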