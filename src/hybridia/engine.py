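"""The hybrid PRM/DIA acquisition state machine.

Runs DIA cycles and, on every MS1 scan, checks a watch list of spiked heavy
reference peptides. A heavy precursor seen above the intensity threshold
inside its retention-time window triggers a fast validation MS2 scan; if
enough declared fragments confirm, a multiplexed PRM scan co-isolating the
heavy reference and its endogenous light partner in two narrow windows is
acquired, and the target is dynamically excluded for a few seconds. The same
machinery also drives stand-alone DIA and time-scheduled stand-alone PRM for
three-way comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .config import MethodConfig, TriggerConfig
from .instrument import (
    CompiledSample,
    Instrument,
    Provenance,
    ScanRecord,
    ScanRequest,
    ScanType,
    Spectrum,
    scan_duration,
)
from .samples import SampleDefinition
from .scheduling import TriggerTarget, max_concurrency

__all__ = [
    "DiaCyclePlan",
    "WatchState",
    "WatchEntry",
    "TriggerEvent",
    "RunResult",
    "ScheduleError",
    "plan_dia_cycle",
    "check_triggers",
    "validate_candidate",
    "emit_msxprm",
    "run_acquisition",
]

logger = logging.getLogger(__name__)


class ScheduleError(RuntimeError):
    """A scheduled-PRM method demands more concurrent scan time than exists."""


@dataclass(frozen=True)
class DiaCyclePlan:
    """One DIA cycle: MS2 isolation windows tiling the scan range half-open,
    with an MS1 scan inserted every ``ms2_per_ms1`` MS2 scans."""

    scan_range: tuple[float, float]
    window_width: float
    ms2_per_ms1: int
    windows: tuple[tuple[float, float], ...]  # (center, width)
    ms1_resolution: int = 60000
    ms2_resolution: int = 30000

    @property
    def n_ms2(self) -> int:
        return len(self.windows)

    @property
    def n_ms1(self) -> int:
        return int(np.ceil(self.n_ms2 / self.ms2_per_ms1))


def plan_dia_cycle(
    low: float,
    high: float,
    width: float,
    ms2_per_ms1: int,
    ms1_resolution: int = 60000,
    ms2_resolution: int = 30000,
) -> DiaCyclePlan:
    """Tile [low, high) with half-open windows of the given width; the last
    window is truncated so the tiling is exact with no gaps or overlaps."""
    if width <= 0:
        raise ValueError("window width must be > 0")
    if high <= low:
        raise ValueError("scan range high must exceed low")
    if ms2_per_ms1 < 1:
        raise ValueError("ms2_per_ms1 must be >= 1")
    n = int(np.ceil((high - low) / width))
    windows = []
    for i in range(n):
        wlo = low + i * width
        whi = min(high, wlo + width)
        windows.append(((wlo + whi) / 2.0, whi - wlo))
    return DiaCyclePlan(
        scan_range=(low, high),
        window_width=width,
        ms2_per_ms1=ms2_per_ms1,
        windows=tuple(windows),
        ms1_resolution=ms1_resolution,
        ms2_resolution=ms2_resolution,
    )


class WatchState(str, Enum):
    OUTSIDE_WINDOW = "outside_window"
    ARMED = "armed"
    EXCLUDED = "excluded"


@dataclass
class WatchEntry:
    """Real-time state of one watched trigger target."""

    target: TriggerTarget
    excluded_until_s: float = -np.inf
    trigger_count: int = 0

    def state(self, t: float) -> WatchState:
        lo, hi = self.target.rt_window
        if not lo <= t <= hi:
            return WatchState.OUTSIDE_WINDOW
        if t < self.excluded_until_s:
            return WatchState.EXCLUDED
        return WatchState.ARMED


@dataclass
class TriggerEvent:
    """One step on a trigger decision path, for the run log."""

    t_s: float
    target_id: str
    kind: str  # candidate | validated | rejected | acquired | excluded_skip


@dataclass
class RunResult:
    """Scan records, trigger events and bookkeeping for one simulated run."""

    mode: str
    sample_name: str
    scans: list[ScanRecord]
    events: list[TriggerEvent]
    watch: list[WatchEntry]
    method: MethodConfig
    run_length_s: float
    dia_cycles: int
    seed: int

    @property
    def n_msxprm(self) -> int:
        return sum(
            1
            for s in self.scans
            if s.provenance in (Provenance.MSXPRM, Provenance.STANDALONE_PRM)
        )

    def scans_for_target(self, target_id: str) -> list[ScanRecord]:
        return [s for s in self.scans if s.target_id == target_id]

    def scan_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": [s.start_s for s in self.scans],
                "type": [s.request.scan_type.value for s in self.scans],
                "provenance": [s.provenance.value for s in self.scans],
                "target_id": [s.target_id or "" for s in self.scans],
                "windows": [
                    ";".join(f"{c:.4f}:{w:.2f}" for c, w in s.request.isolation_windows)
                    for s in self.scans
                ],
                "injection_ms": [s.injection_ms for s in self.scans],
                "duration_s": [s.duration_s for s in self.scans],
                "n_peaks": [len(s.spectrum.mz) for s in self.scans],
            }
        )

    def event_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": [e.t_s for e in self.events],
                "target_id": [e.target_id for e in self.events],
                "event": [e.kind for e in self.events],
            }
        )


def check_triggers(
    ms1_spectrum: Spectrum,
    watch_list: list[WatchEntry],
    t: float,
    config: TriggerConfig,
) -> list[WatchEntry]:
    """Watch entries whose heavy precursor is seen in this MS1 spectrum:
    inside the RT window, armed, a peak within ppm tolerance of the heavy
    m/z, and that signal at or above the intensity threshold."""
    candidates = []
    for entry in watch_list:
        if entry.state(t) is not WatchState.ARMED:
            continue
        threshold = (
            entry.target.intensity_threshold
            if entry.target.intensity_threshold is not None
            else config.intensity_threshold
        )
        if ms1_spectrum.match(entry.target.heavy_mz, config.ppm_tol) >= threshold:
            candidates.append(entry)
    candidates.sort(key=lambda e: e.target.heavy_mz)
    return candidates


def validate_candidate(
    validation_spectrum: Spectrum,
    target: TriggerTarget,
    config: TriggerConfig,
) -> bool:
    """True iff enough declared heavy fragments are matched above the scan's
    noise floor within the ppm tolerance."""
    if len(target.fragments) < config.min_validated_fragments:
        raise ValueError(
            f"target {target.target_id} declares {len(target.fragments)} fragments; "
            f"at least {config.min_validated_fragments} required"
        )
    matched = sum(
        1
        for fmz in target.fragments
        if validation_spectrum.match(fmz, config.ppm_tol)
        > validation_spectrum.noise_floor
    )
    return matched >= config.min_validated_fragments


def emit_msxprm(target: TriggerTarget, t: float, config: TriggerConfig) -> ScanRequest:
    """The 2-plex quantification scan: two narrow windows co-isolating the
    heavy reference and its endogenous light partner."""
    return ScanRequest(
        scan_type=ScanType.MSXPRM,
        isolation_windows=(
            (target.heavy_mz, config.msxprm_isolation_width),
            (target.light_mz, config.msxprm_isolation_width),
        ),
        resolution=config.msxprm_resolution,
        max_injection_ms=config.max_injection_ms,
        agc_target=config.agc_target,
        collision=True,
    )


def _validation_request(target: TriggerTarget, config: TriggerConfig) -> ScanRequest:
    return ScanRequest(
        scan_type=ScanType.VALIDATION_MS2,
        isolation_windows=((target.heavy_mz, config.msxprm_isolation_width),),
        resolution=config.validation_resolution,
        max_injection_ms=config.validation_max_injection_ms,
        agc_target=config.agc_target,
        collision=True,
    )


class _Clock:
    """Run clock advanced by every executed scan."""

    def __init__(self, instrument: Instrument):
        self.t = 0.0
        self.instrument = instrument
        self.scans: list[ScanRecord] = []

    def execute(
        self,
        request: ScanRequest,
        provenance: Provenance,
        target_id: str | None = None,
    ) -> ScanRecord:
        spectrum, it_ms = self.instrument.acquire(request, self.t)
        duration = scan_duration(request.resolution, it_ms)
        record = ScanRecord(
            request=request,
            start_s=self.t,
            injection_ms=it_ms,
            duration_s=duration,
            spectrum=spectrum,
            provenance=provenance,
            target_id=target_id,
        )
        self.scans.append(record)
        self.t += duration
        return record


def run_acquisition(
    sample: SampleDefinition,
    method: MethodConfig,
    mode: str,
    targets: list[TriggerTarget] | None = None,
    run_length_s: float | None = None,
    seed: int = 0,
    noise: bool = True,
    compiled: CompiledSample | None = None,
) -> RunResult:
    """Simulate one LC-MS/MS run in ``dia``, ``prm`` or ``hybrid`` mode."""
    if mode not in ("dia", "prm", "hybrid"):
        raise ValueError(f"mode must be dia, prm or hybrid, got {mode!r}")
    targets = list(targets or [])
    run_length = run_length_s if run_length_s is not None else method.run_length_s
    if compiled is None:
        compiled = CompiledSample(sample)
    rng = np.random.default_rng(seed)
    instrument = Instrument(
        compiled, rng=rng, noise=noise, scan_range=method.scan_range
    )
    clock = _Clock(instrument)
    watch = [WatchEntry(t) for t in targets]
    events: list[TriggerEvent] = []

    if mode == "prm":
        result_cycles = _run_prm(clock, watch, method, run_length, events)
    else:
        result_cycles = _run_dia_or_hybrid(
            clock, watch if mode == "hybrid" else [], method, run_length, events
        )
    return RunResult(
        mode=mode,
        sample_name=sample.name,
        scans=clock.scans,
        events=events,
        watch=watch,
        method=method,
        run_length_s=run_length,
        dia_cycles=result_cycles,
        seed=seed,
    )


def _ms1_request(method: MethodConfig) -> ScanRequest:
    return ScanRequest(
        scan_type=ScanType.MS1,
        isolation_windows=(),
        resolution=method.ms1_resolution,
        max_injection_ms=method.ms1_max_injection_ms,
        agc_target=method.ms1_agc,
        collision=False,
    )


def _run_dia_or_hybrid(
    clock: _Clock,
    watch: list[WatchEntry],
    method: MethodConfig,
    run_length: float,
    events: list[TriggerEvent],
) -> int:
    plan = plan_dia_cycle(
        method.scan_range[0],
        method.scan_range[1],
        method.window_width,
        method.ms2_per_ms1,
        method.ms1_resolution,
        method.ms2_resolution,
    )
    trig = method.trigger
    ms1_req = _ms1_request(method)
    ms2_reqs = [
        ScanRequest(
            scan_type=ScanType.DIA_MS2,
            isolation_windows=(window,),
            resolution=method.ms2_resolution,
            max_injection_ms=method.ms2_max_injection_ms,
            agc_target=method.ms2_agc,
            collision=True,
        )
        for window in plan.windows
    ]
    cycles = 0
    while clock.t < run_length:
        for i, ms2_req in enumerate(ms2_reqs):
            if i % plan.ms2_per_ms1 == 0:
                ms1_record = clock.execute(ms1_req, Provenance.DIA_CYCLE)
                if watch:
                    _service_triggers(clock, ms1_record, watch, trig, events)
            clock.execute(ms2_req, Provenance.DIA_CYCLE)
        cycles += 1
    return cycles


def _service_triggers(
    clock: _Clock,
    ms1_record: ScanRecord,
    watch: list[WatchEntry],
    trig: TriggerConfig,
    events: list[TriggerEvent],
) -> None:
    """Validation + MSxPRM for every candidate on this MS1 scan, in ascending
    heavy-m/z order, before the DIA cycle resumes."""
    candidates = check_triggers(ms1_record.spectrum, watch, ms1_record.start_s, trig)
    for entry in candidates:
        tid = entry.target.target_id
        events.append(TriggerEvent(ms1_record.start_s, tid, "candidate"))
        validation = clock.execute(
            _validation_request(entry.target, trig),
            Provenance.TRIGGER_VALIDATION,
            target_id=tid,
        )
        if not validate_candidate(validation.spectrum, entry.target, trig):
            events.append(TriggerEvent(validation.start_s, tid, "rejected"))
            continue
        events.append(TriggerEvent(validation.start_s, tid, "validated"))
        msx = clock.execute(
            emit_msxprm(entry.target, clock.t, trig),
            Provenance.MSXPRM,
            target_id=tid,
        )
        entry.trigger_count += 1
        entry.excluded_until_s = msx.start_s + trig.exclusion_s
        events.append(TriggerEvent(msx.start_s, tid, "acquired"))


def _run_prm(
    clock: _Clock,
    watch: list[WatchEntry],
    method: MethodConfig,
    run_length: float,
    events: list[TriggerEvent],
) -> int:
    """Time-scheduled stand-alone PRM: MS1 survey scans interleaved with
    MSxPRM scans of every target whose RT window contains the clock, each
    resampled every exclusion period."""
    trig = method.trigger
    profile = max_concurrency([w.target for w in watch])
    msxprm_s = scan_duration(trig.msxprm_resolution, trig.max_injection_ms)
    ms1_s = scan_duration(method.ms1_resolution, method.ms1_max_injection_ms)
    worst = profile.maximum * msxprm_s + ms1_s
    if worst > trig.exclusion_s:
        raise ScheduleError(
            f"{profile.maximum} concurrent targets need {worst:.2f} s per "
            f"{trig.exclusion_s:.2f} s sampling interval; schedule infeasible"
        )
    ms1_req = _ms1_request(method)
    next_due = {w.target.target_id: -np.inf for w in watch}
    while clock.t < run_length:
        clock.execute(ms1_req, Provenance.DIA_CYCLE)
        for entry in sorted(watch, key=lambda w: w.target.heavy_mz):
            target = entry.target
            if not target.rt_window[0] <= clock.t <= target.rt_window[1]:
                continue
            if clock.t < next_due[target.target_id]:
                continue
            msx = clock.execute(
                emit_msxprm(target, clock.t, trig),
                Provenance.STANDALONE_PRM,
                target_id=target.target_id,
            )
            entry.trigger_count += 1
            next_due[target.target_id] = msx.start_s + trig.exclusion_s
            events.append(TriggerEvent(msx.start_s, target.target_id, "acquired"))
    return 0
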