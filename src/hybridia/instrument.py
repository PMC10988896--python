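"""Orbitrap-like instrument model: ion accumulation under an AGC target,
resolution-dependent transient times, and spectrum generation with mass and
intensity noise.

Peak intensities are reported as collected ion charges: a peak's expected
value is ``flux(t) x injection_time``, and when accumulation is AGC-limited
the total collected charge caps at the AGC target — which is how abundant
co-isolated species mask scarce ones. A diffuse chemical-noise floor grows
with isolation width and injection time, so wide DIA windows carry a higher
floor than narrow multiplexed-PRM windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .samples import (
    IONS_PER_FMOL,
    PeptideSpecies,
    SampleDefinition,
    fragment_panel,
    isotope_envelope,
)

__all__ = [
    "ScanType",
    "Provenance",
    "ScanRequest",
    "Spectrum",
    "ScanRecord",
    "injection_time",
    "scan_duration",
    "Instrument",
    "CompiledSample",
    "TRANSIENT_S",
    "SCAN_OVERHEAD_S",
]

# Transient length by resolving power at m/z 200 (linear in resolution) and a
# fixed inter-scan overhead. Model constants, declared rather than fitted.
TRANSIENT_S = {7500: 0.016, 15000: 0.032, 30000: 0.064, 60000: 0.128, 120000: 0.256}
SCAN_OVERHEAD_S = 0.005

# Electronic noise floor (charges) and diffuse chemical-noise ion-current
# density (charges per second per Th of isolation width).
ELECTRONIC_FLOOR_CHARGES = 5.0
DIFFUSE_NOISE_DENSITY = 60.0

MZ_PPM_SIGMA = 2.0
INTENSITY_JITTER = 0.05


class ScanType(str, Enum):
    MS1 = "MS1"
    DIA_MS2 = "DIA_MS2"
    VALIDATION_MS2 = "VALIDATION_MS2"
    MSXPRM = "MSxPRM"


class Provenance(str, Enum):
    DIA_CYCLE = "dia_cycle"
    TRIGGER_VALIDATION = "trigger_validation"
    MSXPRM = "msxprm"
    STANDALONE_PRM = "standalone_prm"


@dataclass(frozen=True)
class ScanRequest:
    """One scan to execute: what to isolate and with which settings."""

    scan_type: ScanType
    isolation_windows: tuple[tuple[float, float], ...]  # (center, width) Th
    resolution: int
    max_injection_ms: float
    agc_target: float
    collision: bool

    def __post_init__(self) -> None:
        if self.scan_type is ScanType.MS1 and self.isolation_windows:
            raise ValueError("MS1 scans take no isolation window")
        if self.scan_type is not ScanType.MS1 and not self.isolation_windows:
            raise ValueError(f"{self.scan_type.value} scans need isolation windows")
        if self.scan_type is ScanType.MSXPRM and len(self.isolation_windows) != 2:
            raise ValueError("MSxPRM scans multiplex exactly two isolation windows")
        if any(w <= 0 for _, w in self.isolation_windows):
            raise ValueError("isolation window widths must be > 0")
        if self.resolution not in TRANSIENT_S:
            raise ValueError(
                f"unsupported resolution {self.resolution}; "
                f"supported: {sorted(TRANSIENT_S)}"
            )


@dataclass
class Spectrum:
    """Centroided spectrum: m/z-sorted peaks plus the scan's noise floor."""

    mz: np.ndarray
    intensity: np.ndarray
    noise_floor: float

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")

    def match(self, mz: float, ppm_tol: float) -> float:
        """Summed intensity of peaks within ppm_tol of mz (0 if none)."""
        tol = mz * ppm_tol * 1e-6
        lo = np.searchsorted(self.mz, mz - tol)
        hi = np.searchsorted(self.mz, mz + tol)
        return float(self.intensity[lo:hi].sum())


@dataclass
class ScanRecord:
    """One executed scan with its timing and resulting spectrum."""

    request: ScanRequest
    start_s: float
    injection_ms: float
    duration_s: float
    spectrum: Spectrum
    provenance: Provenance
    target_id: str | None = None


def injection_time(total_flux: float, agc_target: float, max_injection_ms: float) -> float:
    """Ion accumulation time (ms) to reach the AGC target, capped at the
    maximum; zero incoming flux accumulates for the full maximum."""
    if total_flux < 0:
        raise ValueError("total_flux must be >= 0")
    if total_flux == 0:
        return max_injection_ms
    return min(max_injection_ms, 1000.0 * agc_target / total_flux)


def scan_duration(resolution: int, injection_ms: float) -> float:
    """Wall-clock cost of one scan: the accumulation and the transient run
    in parallel, plus a fixed overhead."""
    try:
        transient = TRANSIENT_S[resolution]
    except KeyError:
        raise ValueError(
            f"unsupported resolution {resolution}; supported: {sorted(TRANSIENT_S)}"
        ) from None
    return max(injection_ms / 1000.0, transient) + SCAN_OVERHEAD_S


class CompiledSample:
    """Array view of a SampleDefinition for fast per-scan evaluation."""

    def __init__(self, sample: SampleDefinition, n_iso: int = 4):
        self.sample = sample
        species = sorted(sample.species, key=lambda s: s.rt_apex_s)
        self.species = species
        n = len(species)
        self.rt = np.array([s.rt_apex_s for s in species])
        self.sigma = np.array([s.peak_sigma_s for s in species])
        self.amp = np.array(
            [s.amount_fmol * IONS_PER_FMOL / (s.peak_sigma_s * np.sqrt(2 * np.pi))
             for s in species]
        )
        self.env_mz = np.zeros((n, n_iso))
        self.env_ab = np.zeros((n, n_iso))
        self.frag_mz = []
        self.frag_frac = []
        for i, s in enumerate(species):
            env = isotope_envelope(s, n_iso)
            self.env_mz[i] = env.mz
            self.env_ab[i] = env.abundance
            fmz, ffrac = fragment_panel(s.sequence, s.label)
            self.frag_mz.append(fmz)
            self.frag_frac.append(ffrac)
        self.max_sigma = float(self.sigma.max()) if n else 1.0

    def active(self, t: float, n_sigma: float = 5.0) -> np.ndarray:
        """Indices of species eluting at time t (within n_sigma of apex)."""
        lo = np.searchsorted(self.rt, t - n_sigma * self.max_sigma)
        hi = np.searchsorted(self.rt, t + n_sigma * self.max_sigma)
        return np.arange(lo, hi)

    def flux(self, idx: np.ndarray, t: float) -> np.ndarray:
        return self.amp[idx] * np.exp(
            -((t - self.rt[idx]) ** 2) / (2.0 * self.sigma[idx] ** 2)
        )


class Instrument:
    """Executes ScanRequests against a compiled sample at a given clock time.

    With ``noise=False`` the instrument is exactly linear: every peak equals
    flux x injection time, the floor is zero and nothing is censored.
    """

    def __init__(
        self,
        compiled: CompiledSample,
        rng: np.random.Generator | None = None,
        noise: bool = True,
        scan_range: tuple[float, float] = (400.0, 1210.0),
    ):
        self.compiled = compiled
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.noise = noise
        self.scan_range = scan_range

    # -- spectrum synthesis -------------------------------------------------

    def acquire(self, request: ScanRequest, t: float) -> tuple[Spectrum, float]:
        """Acquire one spectrum at clock time t; returns (spectrum, IT ms)."""
        comp = self.compiled
        idx = comp.active(t)
        fluxes = comp.flux(idx, t)
        keep = fluxes > 1e-12
        idx, fluxes = idx[keep], fluxes[keep]

        if request.scan_type is ScanType.MS1:
            return self._acquire_ms1(request, idx, fluxes)
        return self._acquire_ms2(request, idx, fluxes)

    def _acquire_ms1(self, request, idx, fluxes):
        comp = self.compiled
        lo, hi = self.scan_range
        in_range = (comp.env_mz[idx] >= lo) & (comp.env_mz[idx] <= hi)
        frac = (comp.env_ab[idx] * in_range).sum(axis=1)
        total = float((fluxes * frac).sum())
        it_ms = injection_time(total, request.agc_target, request.max_injection_ms)
        it_s = it_ms / 1000.0
        peak_mz = comp.env_mz[idx][in_range]
        peak_flux = (fluxes[:, None] * comp.env_ab[idx])[in_range]
        width_total = hi - lo
        return self._finish(peak_mz, peak_flux * it_s, it_s, width_total), it_ms

    def _acquire_ms2(self, request, idx, fluxes):
        comp = self.compiled
        windows = request.isolation_windows
        # fraction of each species' envelope inside any window
        inside = np.zeros_like(comp.env_ab[idx])
        for center, width in windows:
            wlo, whi = center - width / 2.0, center + width / 2.0
            inside = np.maximum(
                inside, (comp.env_mz[idx] >= wlo) & (comp.env_mz[idx] < whi)
            )
        iso_frac = (comp.env_ab[idx] * inside).sum(axis=1)
        sel = iso_frac > 0
        idx, fluxes, iso_frac = idx[sel], fluxes[sel], iso_frac[sel]
        iso_flux = fluxes * iso_frac
        total = float(iso_flux.sum())
        it_ms = injection_time(total, request.agc_target, request.max_injection_ms)
        it_s = it_ms / 1000.0
        mz_parts, flux_parts = [], []
        for j, species_i in enumerate(idx):
            if request.collision:
                mz_parts.append(comp.frag_mz[species_i])
                flux_parts.append(iso_flux[j] * comp.frag_frac[species_i])
            else:
                mz_parts.append(comp.env_mz[species_i])
                flux_parts.append(fluxes[j] * comp.env_ab[species_i])
        peak_mz = np.concatenate(mz_parts) if mz_parts else np.empty(0)
        peak_flux = np.concatenate(flux_parts) if flux_parts else np.empty(0)
        width_total = sum(w for _, w in windows)
        return self._finish(peak_mz, peak_flux * it_s, it_s, width_total), it_ms

    def _finish(self, peak_mz, charges, it_s: float, width_total: float) -> Spectrum:
        peak_mz = np.asarray(peak_mz, dtype=float).ravel()
        charges = np.asarray(charges, dtype=float).ravel()
        if not self.noise:
            order = np.argsort(peak_mz)
            keep = charges[order] > 0
            return Spectrum(peak_mz[order][keep], charges[order][keep], 0.0)
        floor = ELECTRONIC_FLOOR_CHARGES + DIFFUSE_NOISE_DENSITY * width_total * it_s
        observed = self.rng.poisson(charges).astype(float)
        observed *= self.rng.lognormal(0.0, INTENSITY_JITTER, size=observed.shape)
        keep = observed >= floor
        peak_mz, observed = peak_mz[keep], observed[keep]
        peak_mz = peak_mz * (
            1.0 + self.rng.normal(0.0, MZ_PPM_SIGMA * 1e-6, size=peak_mz.shape)
        )
        order = np.argsort(peak_mz)
        return Spectrum(peak_mz[order], observed[order], floor)
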