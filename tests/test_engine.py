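"""Acquisition engine: DIA cycle planning, trigger chain, run modes."""

import numpy as np
import pytest

from hybridia.chemistry import LYS8_SHIFT
from hybridia.config import MethodConfig, TriggerConfig
from hybridia.engine import (
    ScheduleError,
    WatchEntry,
    WatchState,
    check_triggers,
    emit_msxprm,
    plan_dia_cycle,
    run_acquisition,
    validate_candidate,
)
from hybridia.instrument import Provenance, ScanType, Spectrum
from hybridia.scheduling import TriggerTarget


class TestPlanDiaCycle:
    def test_standard_method_geometry(self):
        plan = plan_dia_cycle(400, 1210, 15, 18)
        assert plan.n_ms2 == 54
        assert plan.n_ms1 == 3

    def test_small_plan(self):
        plan = plan_dia_cycle(100, 200, 50, 18)
        assert plan.n_ms2 == 2
        assert plan.n_ms1 == 1

    def test_last_window_truncated_half_open(self):
        plan = plan_dia_cycle(400, 1211, 15, 18)
        assert plan.n_ms2 == 55
        center, width = plan.windows[-1]
        assert (center - width / 2, center + width / 2) == (1210.0, 1211.0)

    def test_windows_tile_exactly(self):
        plan = plan_dia_cycle(400, 1210, 15, 18)
        edges = [c - w / 2 for c, w in plan.windows] + [
            plan.windows[-1][0] + plan.windows[-1][1] / 2
        ]
        assert edges[0] == 400.0 and edges[-1] == 1210.0
        inner_highs = [c + w / 2 for c, w in plan.windows[:-1]]
        np.testing.assert_allclose(inner_highs, edges[1:-1], atol=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="width"):
            plan_dia_cycle(400, 1210, 0, 18)
        with pytest.raises(ValueError, match="high"):
            plan_dia_cycle(1210, 400, 15, 18)


def _target(heavy_mz=600.0, rt=(90.0, 110.0), n_frag=6, threshold=None):
    frags = tuple(300.0 + 50.0 * i for i in range(n_frag))
    return TriggerTarget(
        target_id="T1",
        heavy_mz=heavy_mz,
        charge=2,
        rt_window=rt,
        light_mz=heavy_mz - LYS8_SHIFT / 2,
        fragments=frags,
        intensity_threshold=threshold,
    )


def _spectrum(mzs, intensities, floor=0.0):
    order = np.argsort(mzs)
    return Spectrum(np.asarray(mzs, float)[order], np.asarray(intensities, float)[order], floor)


class TestCheckTriggers:
    config = TriggerConfig(ppm_tol=10.0, intensity_threshold=1e5)

    def test_out_of_tolerance_peak_not_candidate(self):
        spec = _spectrum([600.0 * (1 + 11e-6)], [1e6])
        entry = WatchEntry(_target())
        assert check_triggers(spec, [entry], 100.0, self.config) == []

    def test_below_threshold_not_candidate(self):
        spec = _spectrum([600.0], [9.9e4])
        entry = WatchEntry(_target())
        assert check_triggers(spec, [entry], 100.0, self.config) == []

    def test_armed_in_window_above_threshold_is_candidate(self):
        spec = _spectrum([600.0 * (1 + 5e-6)], [2e5])
        entry = WatchEntry(_target())
        assert check_triggers(spec, [entry], 100.0, self.config) == [entry]

    def test_outside_rt_window_or_excluded_skipped(self):
        spec = _spectrum([600.0], [1e6])
        entry = WatchEntry(_target())
        assert check_triggers(spec, [entry], 200.0, self.config) == []
        entry.excluded_until_s = 105.0
        assert entry.state(100.0) is WatchState.EXCLUDED
        assert check_triggers(spec, [entry], 100.0, self.config) == []

    def test_candidates_sorted_by_mz(self):
        t_low, t_high = _target(500.0), _target(700.0)
        t_high = TriggerTarget(
            "T2", 700.0, 2, (90, 110), 700.0 - LYS8_SHIFT / 2, t_high.fragments
        )
        spec = _spectrum([500.0, 700.0], [1e6, 1e6])
        entries = [WatchEntry(t_high), WatchEntry(t_low)]
        got = check_triggers(spec, entries, 100.0, self.config)
        assert [e.target.heavy_mz for e in got] == [500.0, 700.0]


class TestValidateCandidate:
    config = TriggerConfig(min_validated_fragments=4)

    def test_all_fragments_matched(self):
        target = _target()
        spec = _spectrum(list(target.fragments), [100.0] * 6, floor=5.0)
        assert validate_candidate(spec, target, self.config) is True

    def test_too_few_fragments_matched(self):
        target = _target()
        spec = _spectrum(list(target.fragments[:3]), [100.0] * 3, floor=5.0)
        assert validate_candidate(spec, target, self.config) is False

    def test_target_with_too_few_declared_fragments_rejected(self):
        target = _target(n_frag=3)
        spec = _spectrum(list(target.fragments), [100.0] * 3, floor=5.0)
        with pytest.raises(ValueError, match="declares 3 fragments"):
            validate_candidate(spec, target, self.config)

    def test_decoy_spectra_rejected(self):
        """Random co-eluting decoy fragment sets fail validation >= 99%."""
        target = _target()
        rng = np.random.default_rng(1234)
        false_accepts = 0
        n = 300
        for _ in range(n):
            decoy_mz = rng.uniform(200, 1200, size=6)
            spec = _spectrum(decoy_mz, [1000.0] * 6, floor=5.0)
            if validate_candidate(spec, target, self.config):
                false_accepts += 1
        assert false_accepts / n <= 0.01


class TestEmitMsxprm:
    def test_two_narrow_windows_split_by_label_shift(self):
        config = TriggerConfig()
        req = emit_msxprm(_target(), 100.0, config)
        assert req.scan_type is ScanType.MSXPRM
        assert len(req.isolation_windows) == 2
        (c_heavy, w1), (c_light, w2) = req.isolation_windows
        assert w1 == w2 == 1.4
        assert c_heavy - c_light == pytest.approx(8.014199 / 2, abs=1e-6)


class TestRunAcquisition:
    def test_invalid_mode_rejected(self, small_panel, method):
        with pytest.raises(ValueError, match="mode"):
            run_acquisition(small_panel["sample"], method, "dda")

    def test_clock_time_conservation(self, hybrid_run):
        total = sum(s.duration_s for s in hybrid_run.scans)
        end = hybrid_run.scans[-1].start_s + hybrid_run.scans[-1].duration_s
        assert total == pytest.approx(end, abs=1e-9)
        starts = [s.start_s for s in hybrid_run.scans]
        assert all(b > a for a, b in zip(starts, starts[1:]))

    def test_msxprm_scans_inside_rt_windows(self, hybrid_run, small_panel):
        windows = {t.target_id: t.rt_window for t in small_panel["targets"]}
        msx = [s for s in hybrid_run.scans if s.provenance is Provenance.MSXPRM]
        assert msx
        for s in msx:
            lo, hi = windows[s.target_id]
            assert lo <= s.start_s <= hi

    def test_undetectable_heavy_never_triggers(self, method):
        from hybridia.samples import SampleDefinition, make_pair
        from hybridia.scheduling import targets_from_pairs

        light, heavy = make_pair("ELVISLIVESK", 2, 1.0, 1e-6, 100.0)
        sample = SampleDefinition("dim", [light, heavy])
        targets = targets_from_pairs([(light, heavy)])
        run = run_acquisition(
            sample, method, "hybrid", targets=targets, run_length_s=150.0, seed=3
        )
        assert run.n_msxprm == 0

    def test_prm_impossible_schedule_reported(self, method):
        from hybridia.samples import SampleDefinition, make_pair
        from hybridia.scheduling import targets_from_pairs

        pairs = []
        seqs = ["ELVISLIVESK", "DFDQNQGEVVK", "LFDLVDGFAESTK", "NQDWLGVSR"]
        for i, seq in enumerate(seqs * 12):
            light, heavy = make_pair(seq, 2 + i % 3, 1.0, 100.0, 100.0)
            if any(p[0].id == light.id for p in pairs):
                continue
            pairs.append((light, heavy))
        targets = targets_from_pairs(pairs, rt_half_window_s=50.0)
        # force a slow MSxPRM scan so concurrent demand exceeds the interval
        slow = MethodConfig(
            trigger=TriggerConfig(max_injection_ms=500.0, exclusion_s=5.0)
        )
        sample = SampleDefinition("jam", [s for p in pairs for s in p])
        with pytest.raises(ScheduleError, match="concurrent"):
            run_acquisition(
                sample, slow, "prm", targets=targets, run_length_s=200.0, seed=1
            )

    def test_prm_samples_each_target_about_once_per_exclusion(
        self, small_panel, method
    ):
        run = run_acquisition(
            small_panel["sample"],
            method,
            "prm",
            targets=small_panel["targets"],
            run_length_s=small_panel["run_length"],
            seed=8,
            compiled=small_panel["compiled"],
        )
        assert run.n_msxprm > 0
        for t in small_panel["targets"]:
            starts = [s.start_s for s in run.scans_for_target(t.target_id)]
            gaps = np.diff(starts)
            assert np.all(gaps >= method.trigger.exclusion_s - 1e-9)
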