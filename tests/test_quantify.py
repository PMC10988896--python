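"""Quantification: XICs, peak integration, ratios, calibration, rollup."""

import numpy as np
import pytest

from hybridia.config import MethodConfig
from hybridia.engine import run_acquisition
from hybridia.instrument import CompiledSample
from hybridia.quantify import (
    CalibrationCurve,
    Chromatogram,
    QuantMatrix,
    QuantResult,
    Status,
    completeness,
    extract_xic,
    fit_calibration,
    integrate_peak,
    protein_rollup,
    quantify_pair,
    replicate_cv,
)
from hybridia.samples import SampleDefinition, make_pair
from hybridia.scheduling import targets_from_pairs


def _chrom(times, values, baseline=0.0):
    return Chromatogram(
        np.asarray(times, float), np.asarray(values, float),
        "msxprm_fragment", 500.0, 10.0, baseline,
    )


class TestIntegratePeak:
    def test_flat_zero_trace(self):
        assert integrate_peak(_chrom([0, 1, 2], [0, 0, 0])) == 0.0

    def test_dense_gaussian_matches_closed_form(self):
        a, sigma, apex = 1000.0, 6.0, 100.0
        t = np.linspace(apex - 36, apex + 36, 2000)
        y = a * np.exp(-((t - apex) ** 2) / (2 * sigma**2))
        area = integrate_peak(_chrom(t, y))
        assert area == pytest.approx(a * sigma * np.sqrt(2 * np.pi), rel=0.01)

    def test_matches_rectangle_rule_oracle_at_10hz(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 60, 0.1)
        y = 500 * np.exp(-((t - 30) ** 2) / 18.0) + rng.uniform(0, 1e-9, t.size)
        area = integrate_peak(_chrom(t, y))
        rect = float(np.sum(y) * 0.1)
        assert area == pytest.approx(rect, rel=0.005)

    def test_too_few_points(self):
        assert integrate_peak(_chrom([1.0], [5.0])) == 0.0


def _noiseless_run(light_amount, heavy_amount=100.0, sigma=6.0, seed=0):
    light, heavy = make_pair(
        "ELVISLIVESK", 2, light_amount, heavy_amount, 100.0, peak_sigma_s=sigma
    )
    sample = SampleDefinition("q", [light, heavy])
    targets = targets_from_pairs([(light, heavy)])
    method = MethodConfig()
    run = run_acquisition(
        sample, method, "hybrid", targets=targets, run_length_s=160.0,
        seed=seed, noise=False,
    )
    return run, targets[0]


class TestQuantifyPair:
    def test_equal_amounts_give_unit_ratio(self):
        run, target = _noiseless_run(100.0)
        res = quantify_pair(run, target, 100.0)
        assert res.status is Status.QUANTIFIED
        assert res.ratio == pytest.approx(1.0, abs=0.01)

    def test_absent_light_is_below_lod(self):
        run, target = _noiseless_run(0.0)
        res = quantify_pair(run, target, 100.0)
        assert res.status is Status.BELOW_LOD
        assert res.heavy_area > 0

    def test_undetectable_heavy_is_missing(self):
        run, target = _noiseless_run(1.0, heavy_amount=1e-6)
        res = quantify_pair(run, target, 100.0)
        assert res.status is Status.MISSING
        assert res.n_scans == 0

    def test_ratio_invariant_to_shared_peak_width(self):
        ratios = []
        for sigma in (4.0, 8.0):
            run, target = _noiseless_run(10.0, sigma=sigma)
            ratios.append(quantify_pair(run, target, 100.0).ratio)
        assert ratios[0] == pytest.approx(ratios[1], rel=0.01)


class TestExtractXic:
    def test_no_scans_gives_empty_trace(self):
        run, target = _noiseless_run(1.0, heavy_amount=1e-6)
        trace = extract_xic(run, 500.0, 10.0, source="msxprm_fragment")
        assert len(trace) == 0

    def test_tolerance_subset_monotonicity(self):
        run, target = _noiseless_run(100.0)
        wide = extract_xic(run, target.fragments[0], 20.0, source="msxprm_fragment",
                           target_id=target.target_id)
        narrow = extract_xic(run, target.fragments[0], 2.0, source="msxprm_fragment",
                             target_id=target.target_id)
        assert np.all(narrow.intensities <= wide.intensities + 1e-12)


class TestCalibration:
    def _results(self, levels, ratios, statuses=None):
        out, nominal = [], []
        for level, ratio in zip(levels, ratios):
            status = Status.QUANTIFIED if np.isfinite(ratio) else Status.BELOW_LOD
            out.append(
                QuantResult("T", "s", 1.0, 1.0, ratio, ratio * 100.0
                            if np.isfinite(ratio) else np.nan, status, 5)
            )
            nominal.append(level)
        return out, nominal

    def test_perfect_ratios_fit_unit_slope(self):
        levels = [100.0, 10.0, 1.0, 0.1]
        results, nominal = self._results(levels, [lv / 100.0 for lv in levels])
        curve = fit_calibration(results, nominal, 100.0)
        assert curve.slope == pytest.approx(1.0, abs=1e-9)
        assert curve.r_squared > 0.999
        assert curve.lod_fmol == 0.1

    def test_lod_never_exceeds_lowest_detected_level(self):
        levels = [100.0, 10.0, 1.0, 0.1, 0.01]
        ratios = [1.0, 0.1, 0.01, np.nan, np.nan]
        results, nominal = self._results(levels, ratios)
        curve = fit_calibration(results, nominal, 100.0)
        assert curve.lod_fmol == 1.0
        detected = [lv for lv, r in zip(levels, ratios) if np.isfinite(r)]
        assert curve.lod_fmol <= min(detected)

    def test_below_lod_report_format(self):
        curve = CalibrationCurve([], 1.0, 0.0, 1.0, 0.0101)
        assert curve.below_lod_report == "< 0.0101 fmol/μl"

    def test_under_three_levels_flagged_unfit(self):
        results, nominal = self._results([10.0, 1.0], [0.1, 0.01])
        curve = fit_calibration(results, nominal, 100.0)
        assert curve.unfit
        assert curve.lod_fmol == 1.0


class TestReplicateCv:
    def test_identical_replicates(self):
        assert replicate_cv([5.0, 5.0, 5.0]) == 0.0

    def test_closed_form_pair(self):
        assert replicate_cv([1.0, 2.0]) == pytest.approx(47.14045, abs=1e-4)

    def test_zero_mean_undefined(self):
        assert np.isnan(replicate_cv([0.0, 0.0]))

    def test_needs_two(self):
        with pytest.raises(ValueError):
            replicate_cv([1.0])


class TestProteinRollup:
    def test_single_peptide_identity(self):
        assert protein_rollup([(2.5, Status.QUANTIFIED)]) == (2.5, Status.QUANTIFIED)

    def test_mean_of_quantified(self):
        value, status = protein_rollup(
            [(2.0, Status.QUANTIFIED), (4.0, Status.QUANTIFIED)]
        )
        assert value == 3.0 and status is Status.QUANTIFIED

    def test_all_below_lod_propagates(self):
        value, status = protein_rollup(
            [(np.nan, Status.BELOW_LOD), (np.nan, Status.BELOW_LOD)]
        )
        assert status is Status.BELOW_LOD

    def test_mixed_missing_and_below_lod(self):
        _, status = protein_rollup(
            [(np.nan, Status.MISSING), (np.nan, Status.BELOW_LOD)]
        )
        assert status is Status.BELOW_LOD


class TestCompleteness:
    def _matrix(self, statuses):
        import pandas as pd

        status_df = pd.DataFrame(statuses)
        values = status_df.map(lambda s: 1.0 if s == "quantified" else np.nan)
        return QuantMatrix(values, status_df)

    def test_all_quantified(self):
        m = self._matrix([["quantified"] * 2] * 2)
        assert completeness(m) == 100.0

    def test_one_missing_of_four(self):
        m = self._matrix([["quantified", "quantified"], ["quantified", "missing"]])
        assert completeness(m) == 75.0

    def test_below_lod_flag_monotone(self):
        m = self._matrix([["quantified", "below_LOD"], ["missing", "below_LOD"]])
        assert completeness(m) == 25.0
        assert completeness(m, count_below_lod_as_informative=True) == 75.0
        assert completeness(m, True) >= completeness(m)

    def test_matrix_tsv(self, tmp_path):
        import pandas as pd

        m = self._matrix([["quantified", "missing"]])
        m.to_tsv(tmp_path / "m.tsv")
        df = pd.read_csv(tmp_path / "m.tsv", sep="\t")
        assert "0.status" in df.columns and "1.status" in df.columns
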