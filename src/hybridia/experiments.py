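"""Preset in-silico experiments: the dilution-series three-mode comparison,
the target-count stress test, and the clinical marker-panel matrix.

Each preset regenerates its samples, targets and runs from (parameters,
seed) alone, so outputs are byte-reproducible. Presets default to compressed
desk-scale gradients with background density chosen to match the co-elution
load of a full-length run; the method parameters themselves (window widths,
trigger thresholds, exclusion, injection times) are the full-scale ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import MethodConfig
from .engine import RunResult, run_acquisition
from .instrument import CompiledSample
from .quantify import (
    QuantMatrix,
    Status,
    completeness,
    quantify_pair,
    quantify_pair_dia,
    replicate_cv,
)
from .samples import (
    PeptideSpecies,
    SampleDefinition,
    dilution_series,
    generate_background,
    make_pair,
)
from .scheduling import TriggerTarget, targets_from_pairs

__all__ = [
    "make_panel_pairs",
    "run_dilution_experiment",
    "run_target_count_stress",
    "run_marker_panel",
    "replicate_correlation_summary",
]

_AA = np.array(list("GASPVTLINDQEMHFYW"))


def make_panel_pairs(
    n_pairs: int,
    seed: int,
    rt_range_s: tuple[float, float],
    light_fmol: float = 100.0,
    heavy_fmol: float = 100.0,
    peak_sigma_s: float = 6.0,
    mz_range_th: tuple[float, float] = (400.0, 1210.0),
) -> list[tuple[PeptideSpecies, PeptideSpecies]]:
    """A reproducible spike-in panel of heavy/light pairs with apexes evenly
    spread over the gradient (jittered), emulating a synthetic-peptide set."""
    rng = np.random.default_rng(seed)
    apexes = np.linspace(rt_range_s[0], rt_range_s[1], n_pairs)
    apexes = apexes + rng.uniform(-2.0, 2.0, size=n_pairs)
    pairs = []
    while len(pairs) < n_pairs:
        length = int(rng.integers(7, 15))
        seq = "".join(rng.choice(_AA, size=length)) + ("K" if rng.random() < 0.5 else "R")
        charge = 2 if rng.random() < 0.7 else 3
        light, heavy = make_pair(
            seq, charge, light_fmol, heavy_fmol,
            rt_apex_s=float(apexes[len(pairs)]), peak_sigma_s=peak_sigma_s,
        )
        if not mz_range_th[0] <= light.precursor_mz <= mz_range_th[1] - 20:
            continue
        if any(p[0].sequence == seq for p in pairs):
            continue
        pairs.append((light, heavy))
    return pairs


def _quantify_run(run, targets, heavy_fmol, mode):
    if mode == "dia":
        return [quantify_pair_dia(run, t, heavy_fmol) for t in targets]
    return [quantify_pair(run, t, heavy_fmol) for t in targets]


def run_dilution_experiment(
    seed: int = 0,
    n_pairs: int = 24,
    levels_fmol: tuple[float, ...] = (100.0, 10.0, 1.0, 0.1, 0.01),
    heavy_fmol: float = 100.0,
    n_replicates: int = 3,
    run_length_s: float = 300.0,
    n_background: int = 200,
    modes: tuple[str, ...] = ("hybrid", "dia", "prm"),
    method: MethodConfig | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Dilution-series comparison of hybrid, stand-alone DIA and scheduled
    PRM on identical samples: per (level, mode) the detection rate, median
    inter-replicate CV of the light areas, and median relative error of the
    absolute amount estimate."""
    if len(levels_fmol) < 2 or n_replicates < 2:
        raise ValueError("need >= 2 dilution levels and >= 2 replicates")
    method = method or MethodConfig(run_length_s=run_length_s)
    rng = np.random.default_rng(seed)
    pairs = make_panel_pairs(n_pairs, seed, (60.0, run_length_s - 60.0),
                             heavy_fmol=heavy_fmol)
    background = generate_background(
        n_background, seed + 1, rt_range_s=(0.0, run_length_s)
    )
    samples = dilution_series(pairs, list(levels_fmol), heavy_fmol, background, seed)
    targets = targets_from_pairs(pairs)

    rows = []
    per_run = []
    for level, sample in zip(levels_fmol, samples):
        compiled = CompiledSample(sample)
        for mode in modes:
            for rep in range(n_replicates):
                run_seed = int(rng.integers(2**31))
                run = run_acquisition(
                    sample, method, mode,
                    targets=targets, run_length_s=run_length_s,
                    seed=run_seed, compiled=compiled,
                )
                results = _quantify_run(run, targets, heavy_fmol, mode)
                for res in results:
                    per_run.append(
                        {
                            "level_fmol": level,
                            "mode": mode,
                            "replicate": rep,
                            "target_id": res.target_id,
                            "status": res.status.value,
                            "light_area": res.light_area,
                            "amount_estimate_fmol": res.amount_estimate_fmol,
                        }
                    )
    detail = pd.DataFrame(per_run)
    for (level, mode), grp in detail.groupby(["level_fmol", "mode"], sort=False):
        quantified = grp[grp.status == "quantified"]
        detection_rate = len(quantified) / len(grp)
        cvs = []
        for _, tgrp in quantified.groupby("target_id"):
            if len(tgrp) >= 2:
                cvs.append(replicate_cv(tgrp.light_area.to_numpy()))
        recovery = (
            (quantified.amount_estimate_fmol - level).abs() / level
            if level > 0
            else pd.Series(dtype=float)
        )
        rows.append(
            {
                "level_fmol": level,
                "mode": mode,
                "n_pair_measurements": len(grp),
                "detection_rate": detection_rate,
                "median_cv_pct": float(np.median(cvs)) if cvs else np.nan,
                "median_recovery_error": (
                    float(recovery.median()) if len(recovery) else np.nan
                ),
            }
        )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "dilution_summary.tsv", sep="\t", index=False)
        detail.to_csv(out / "dilution_detail.tsv", sep="\t", index=False)
    return table


def run_target_count_stress(
    seed: int = 0,
    panel_sizes: tuple[int, ...] = (60, 120, 179),
    n_replicates: int = 3,
    run_length_s: float = 960.0,
    n_background: int = 150,
    light_fmol: float = 100.0,
    heavy_fmol: float = 100.0,
    method: MethodConfig | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Hybrid acquisition under growing trigger panels on one common sample:
    DIA cycles completed, MSxPRM scans acquired, and the fraction of targets
    quantified with inter-replicate CV <= 20% and <= 10%."""
    if list(panel_sizes) != sorted(panel_sizes):
        raise ValueError("panel sizes must be ascending")
    method = method or MethodConfig(run_length_s=run_length_s)
    rng = np.random.default_rng(seed)
    n_max = max(panel_sizes)
    pairs = make_panel_pairs(
        n_max, seed, (60.0, run_length_s - 60.0),
        light_fmol=light_fmol, heavy_fmol=heavy_fmol,
    )
    background = generate_background(
        n_background, seed + 1, rt_range_s=(0.0, run_length_s)
    )
    species = [s for pair in pairs for s in pair] + background
    sample = SampleDefinition(name="stress", species=species, seed=seed)
    compiled = CompiledSample(sample)
    all_targets = targets_from_pairs(pairs)

    rows = []
    for size in panel_sizes:
        targets = all_targets[:size]
        runs: list[RunResult] = []
        for rep in range(n_replicates):
            run_seed = int(rng.integers(2**31))
            runs.append(
                run_acquisition(
                    sample, method, "hybrid",
                    targets=targets, run_length_s=run_length_s,
                    seed=run_seed, compiled=compiled,
                )
            )
        areas = {t.target_id: [] for t in targets}
        identified = {t.target_id: 0 for t in targets}
        for run in runs:
            for t in targets:
                res = quantify_pair(run, t, heavy_fmol)
                if res.status is Status.QUANTIFIED:
                    identified[t.target_id] += 1
                    areas[t.target_id].append(res.light_area)
        cvs = {
            tid: replicate_cv(a) for tid, a in areas.items() if len(a) >= 2
        }
        n_identified = sum(1 for v in identified.values() if v == n_replicates)
        rows.append(
            {
                "panel_size": size,
                "dia_cycles": float(np.mean([r.dia_cycles for r in runs])),
                "msxprm_scans": float(np.mean([r.n_msxprm for r in runs])),
                "n_identified_all_reps": n_identified,
                "frac_cv_le_20": (
                    sum(1 for v in cvs.values() if v <= 20.0) / size if size else np.nan
                ),
                "frac_cv_le_10": (
                    sum(1 for v in cvs.values() if v <= 10.0) / size if size else np.nan
                ),
            }
        )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "target_stress_summary.tsv", sep="\t", index=False)
    return table


def run_marker_panel(
    seed: int = 0,
    n_pairs: int = 30,
    n_samples: int = 12,
    n_replicates: int = 2,
    heavy_fmol: float = 100.0,
    run_length_s: float = 240.0,
    n_background: int = 120,
    zero_fraction: float = 0.2,
    abundance_decades: tuple[float, float] = (-2.0, 2.0),
    method: MethodConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """The clinical marker-panel design: one trigger panel monitored across a
    cohort of synthetic samples whose light (endogenous) abundances are
    log-uniform over four decades with a fraction of structural zeros.

    Returns hybrid and DIA QuantMatrix objects (proteins x sample.replicate
    columns), the ground-truth amounts, and a completeness summary.
    """
    method = method or MethodConfig(run_length_s=run_length_s)
    rng = np.random.default_rng(seed)
    pairs = make_panel_pairs(
        n_pairs, seed, (50.0, run_length_s - 50.0), heavy_fmol=heavy_fmol
    )
    background = generate_background(
        n_background, seed + 1, rt_range_s=(0.0, run_length_s)
    )
    targets = targets_from_pairs(pairs)
    proteins = [f"P{i:02d}" for i in range(n_pairs)]

    # ground-truth light abundances per (protein, sample)
    truth = np.zeros((n_pairs, n_samples))
    for j in range(n_samples):
        zeros = rng.random(n_pairs) < zero_fraction
        amounts = 10.0 ** rng.uniform(*abundance_decades, size=n_pairs)
        truth[:, j] = np.where(zeros, 0.0, amounts)

    columns = [f"S{j:02d}.r{r}" for j in range(n_samples) for r in range(n_replicates)]
    mats = {
        mode: {
            "value": pd.DataFrame(np.nan, index=proteins, columns=columns),
            "status": pd.DataFrame(Status.MISSING.value, index=proteins, columns=columns),
        }
        for mode in ("hybrid", "dia")
    }
    from dataclasses import replace as _replace

    for j in range(n_samples):
        species = []
        for i, (light, heavy) in enumerate(pairs):
            species.append(_replace(light, amount_fmol=float(truth[i, j])))
            species.append(heavy)
        species.extend(background)
        sample = SampleDefinition(name=f"S{j:02d}", species=species, seed=seed)
        compiled = CompiledSample(sample)
        for r in range(n_replicates):
            col = f"S{j:02d}.r{r}"
            for mode in ("hybrid", "dia"):
                run_seed = int(rng.integers(2**31))
                run = run_acquisition(
                    sample, method, mode,
                    targets=targets, run_length_s=run_length_s,
                    seed=run_seed, compiled=compiled,
                )
                results = _quantify_run(run, targets, heavy_fmol, mode)
                for prot, res in zip(proteins, results):
                    mats[mode]["value"].loc[prot, col] = res.amount_estimate_fmol
                    mats[mode]["status"].loc[prot, col] = res.status.value

    hybrid = QuantMatrix(mats["hybrid"]["value"], mats["hybrid"]["status"])
    dia = QuantMatrix(mats["dia"]["value"], mats["dia"]["status"])
    summary = pd.DataFrame(
        [
            {
                "mode": "hybrid",
                "completeness_pct": completeness(hybrid),
                "completeness_with_below_lod_pct": completeness(hybrid, True),
            },
            {
                "mode": "dia",
                "completeness_pct": completeness(dia),
                "completeness_with_below_lod_pct": completeness(dia, True),
            },
        ]
    )
    result = {
        "hybrid": hybrid,
        "dia": dia,
        "truth": pd.DataFrame(
            truth, index=proteins, columns=[f"S{j:02d}" for j in range(n_samples)]
        ),
        "summary": summary,
        "targets": targets,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hybrid.to_tsv(out / "marker_matrix_hybrid.tsv")
        dia.to_tsv(out / "marker_matrix_dia.tsv")
        summary.to_csv(out / "marker_completeness.tsv", sep="\t", index=False)
        result["truth"].to_csv(out / "marker_truth.tsv", sep="\t", index_label="protein")
    return result


def replicate_correlation_summary(matrix: QuantMatrix) -> dict:
    """Mean Pearson correlation of log10 quantified values between technical
    replicates of the same sample versus between unrelated columns."""
    values = np.log10(matrix.values.where(matrix.values > 0))
    cols = list(values.columns)
    rep_pairs, other_pairs = [], []
    corr = values.corr(min_periods=3)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            c = corr.loc[a, b]
            if np.isnan(c):
                continue
            if a.split(".")[0] == b.split(".")[0]:
                rep_pairs.append(c)
            else:
                other_pairs.append(c)
    return {
        "replicate_mean_r": float(np.mean(rep_pairs)) if rep_pairs else np.nan,
        "non_replicate_mean_r": float(np.mean(other_pairs)) if other_pairs else np.nan,
    }
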