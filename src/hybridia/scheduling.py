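"""Trigger-target lists and schedule analysis: parsing/writing the
tab-separated target-list layout, sweep-line concurrency profiling of
retention-time windows, and duty-cycle feasibility for growing panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemistry import ARG10_SHIFT, LYS8_SHIFT
from .config import MethodConfig
from .instrument import TRANSIENT_S, SCAN_OVERHEAD_S

__all__ = [
    "TriggerTarget",
    "ConcurrencyProfile",
    "parse_target_list",
    "write_target_list",
    "max_concurrency",
    "duty_cycle_report",
    "targets_from_pairs",
]

TARGET_COLUMNS = [
    "target_id",
    "heavy_mz",
    "charge",
    "rt_start_s",
    "rt_end_s",
    "light_mz",
    "fragment_mz_list",
]


@dataclass(frozen=True)
class TriggerTarget:
    """One watched heavy reference with its paired endogenous light species
    and the declared heavy fragment m/z values used for trigger validation."""

    target_id: str
    heavy_mz: float
    charge: int
    rt_window: tuple[float, float]
    light_mz: float
    fragments: tuple[float, ...]
    intensity_threshold: float | None = None  # None -> method default

    def __post_init__(self) -> None:
        if self.rt_window[1] <= self.rt_window[0]:
            raise ValueError(
                f"target {self.target_id}: rt_end must be after rt_start"
            )
        if self.light_mz >= self.heavy_mz:
            raise ValueError(
                f"target {self.target_id}: light_mz must be below heavy_mz"
            )

    @property
    def label_shift(self) -> float:
        """Neutral heavy-label mass shift implied by the pair m/z gap."""
        gap = (self.heavy_mz - self.light_mz) * self.charge
        for shift in (LYS8_SHIFT, ARG10_SHIFT):
            if abs(gap - shift) <= 0.01:
                return shift
        return gap

    def light_fragments(self) -> tuple[float, ...]:
        """Expected light-channel fragment m/z (label-bearing y ions,
        singly charged, shifted down by the full label mass)."""
        return tuple(f - self.label_shift for f in self.fragments)


def write_target_list(targets: list[TriggerTarget], path) -> None:
    df = pd.DataFrame(
        {
            "target_id": [t.target_id for t in targets],
            "heavy_mz": [repr(float(t.heavy_mz)) for t in targets],
            "charge": [int(t.charge) for t in targets],
            "rt_start_s": [repr(float(t.rt_window[0])) for t in targets],
            "rt_end_s": [repr(float(t.rt_window[1])) for t in targets],
            "light_mz": [repr(float(t.light_mz)) for t in targets],
            "fragment_mz_list": [
                ";".join(repr(float(f)) for f in t.fragments) for t in targets
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def parse_target_list(path, rt_units: str = "s") -> list[TriggerTarget]:
    """Parse a tab-separated trigger-target list.

    Columns: target_id, heavy_mz, charge, rt_start_s, rt_end_s, light_mz,
    fragment_mz_list (semicolon-separated). With ``rt_units='min'`` (or RT
    column headers ending in ``_min``) retention times are converted from
    minutes to seconds. Malformed rows raise with their row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if any(c.endswith("_min") for c in cols):
        rt_units = "min"
        df.columns = [c.replace("_min", "_s") for c in cols]
    missing = [c for c in TARGET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"target list missing columns: {missing}")
    scale = 60.0 if rt_units == "min" else 1.0
    targets = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            frags = tuple(float(f) for f in str(row.fragment_mz_list).split(";") if f)
            if not frags:
                raise ValueError("no fragments declared")
            target = TriggerTarget(
                target_id=str(row.target_id),
                heavy_mz=float(row.heavy_mz),
                charge=int(row.charge),
                rt_window=(float(row.rt_start_s) * scale, float(row.rt_end_s) * scale),
                light_mz=float(row.light_mz),
                fragments=frags,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"target list row {i}: {exc}") from None
        targets.append(target)
    return targets


def targets_from_pairs(
    pairs,
    rt_half_window_s: float = 18.0,
    intensity_threshold: float | None = None,
) -> list[TriggerTarget]:
    """Build trigger targets from (light, heavy) species pairs, declaring the
    heavy fragment panel and an RT window centered on the known apex."""
    targets = []
    for light, heavy in pairs:
        targets.append(
            TriggerTarget(
                target_id=f"{heavy.sequence}/{heavy.charge}",
                heavy_mz=heavy.precursor_mz,
                charge=heavy.charge,
                rt_window=(
                    heavy.rt_apex_s - rt_half_window_s,
                    heavy.rt_apex_s + rt_half_window_s,
                ),
                light_mz=light.precursor_mz,
                fragments=tuple(float(f) for f in heavy.fragment_mzs()),
                intensity_threshold=intensity_threshold,
            )
        )
    return targets


@dataclass
class ConcurrencyProfile:
    """Active-target count over time from a sweep over window endpoints."""

    breakpoints: np.ndarray  # sorted event times
    counts: np.ndarray       # active count on [breakpoints[i], breakpoints[i+1])
    maximum: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.breakpoints[:-1], "active_targets": self.counts})


def max_concurrency(targets: list[TriggerTarget]) -> ConcurrencyProfile:
    """Sweep-line over RT-window starts/ends; windows are closed intervals,
    so a window ending exactly when another starts counts as overlapping."""
    if not targets:
        return ConcurrencyProfile(np.array([0.0]), np.array([], dtype=int), 0)
    starts = np.array([t.rt_window[0] for t in targets])
    ends = np.array([t.rt_window[1] for t in targets])
    # closed intervals: process starts before ends at equal times
    events = np.concatenate(
        [np.stack([starts, np.zeros_like(starts)], axis=1),
         np.stack([ends, np.ones_like(ends)], axis=1)]
    )
    order = np.lexsort((events[:, 1], events[:, 0]))
    events = events[order]
    times, deltas = events[:, 0], np.where(events[:, 1] == 0, 1, -1)
    counts = np.cumsum(deltas)
    profile_counts = counts[:-1]
    return ConcurrencyProfile(times, profile_counts, int(counts.max()))


def duty_cycle_report(
    targets: list[TriggerTarget],
    method: MethodConfig,
    bin_s: float = 60.0,
    run_length_s: float | None = None,
    cycle_ceiling_s: float | None = None,
) -> pd.DataFrame:
    """Worst-case duty-cycle budget per time bin.

    Assumes every target active in a bin fires once per exclusion period,
    each firing costing one fast validation scan plus one MSxPRM scan.
    Columns: time_bin_s, active_targets, dia_time_fraction,
    triggered_time_fraction, expected_cycle_time_s, over_ceiling.
    """
    run_length = run_length_s if run_length_s is not None else method.run_length_s
    trig = method.trigger
    validation_s = max(
        TRANSIENT_S[trig.validation_resolution],
        trig.validation_max_injection_ms / 1000.0,
    ) + SCAN_OVERHEAD_S
    msxprm_s = max(
        TRANSIENT_S[trig.msxprm_resolution], trig.max_injection_ms / 1000.0
    ) + SCAN_OVERHEAD_S
    event_s = validation_s + msxprm_s

    n_windows = int(np.ceil((method.scan_range[1] - method.scan_range[0]) / method.window_width))
    n_ms1 = int(np.ceil(n_windows / method.ms2_per_ms1))
    ms1_s = max(
        TRANSIENT_S[method.ms1_resolution], method.ms1_max_injection_ms / 1000.0
    ) + SCAN_OVERHEAD_S
    ms2_s = max(
        TRANSIENT_S[method.ms2_resolution], method.ms2_max_injection_ms / 1000.0
    ) + SCAN_OVERHEAD_S
    dia_cycle_s = n_ms1 * ms1_s + n_windows * ms2_s

    edges = np.arange(0.0, run_length + bin_s, bin_s)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        active = sum(
            1 for t in targets if t.rt_window[0] <= hi and t.rt_window[1] >= lo
        )
        triggered_per_s = active * event_s / trig.exclusion_s
        triggered_fraction = min(1.0, triggered_per_s)
        dia_fraction = 1.0 - triggered_fraction
        # one DIA cycle plus the triggered work accrued over its span
        cycle_time = dia_cycle_s / max(dia_fraction, 1e-9)
        rows.append(
            {
                "time_bin_s": lo,
                "active_targets": active,
                "dia_time_fraction": dia_fraction,
                "triggered_time_fraction": triggered_fraction,
                "expected_cycle_time_s": cycle_time,
                "over_ceiling": bool(
                    cycle_ceiling_s is not None and cycle_time > cycle_ceiling_s
                ),
            }
        )
    return pd.DataFrame(rows)
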