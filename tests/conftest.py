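"""Shared fixtures: small synthetic panels and pre-built runs reused across
test modules to keep the suite fast."""

import numpy as np
import pytest

from hybridia import CompiledSample, MethodConfig, run_acquisition
from hybridia.experiments import make_panel_pairs
from hybridia.samples import SampleDefinition, generate_background
from hybridia.scheduling import targets_from_pairs


@pytest.fixture(scope="session")
def method():
    return MethodConfig()


@pytest.fixture(scope="session")
def small_panel():
    """12 heavy/light pairs (light 1 fmol, heavy 100 fmol) in a light
    background over a 240 s gradient."""
    run_length = 240.0
    pairs = make_panel_pairs(12, 11, (50.0, run_length - 50.0),
                             light_fmol=1.0, heavy_fmol=100.0)
    background = generate_background(80, 12, rt_range_s=(0.0, run_length))
    sample = SampleDefinition(
        "small_panel", [s for p in pairs for s in p] + background
    )
    return {
        "pairs": pairs,
        "sample": sample,
        "targets": targets_from_pairs(pairs),
        "compiled": CompiledSample(sample),
        "run_length": run_length,
    }


@pytest.fixture(scope="session")
def hybrid_run(small_panel, method):
    return run_acquisition(
        small_panel["sample"],
        method,
        "hybrid",
        targets=small_panel["targets"],
        run_length_s=small_panel["run_length"],
        seed=99,
        compiled=small_panel["compiled"],
    )


@pytest.fixture(scope="session")
def noiseless_panel():
    """Mixed-truth panel for deterministic status checks: half the lights
    present at 1 fmol, half structurally absent."""
    run_length = 240.0
    pairs = make_panel_pairs(20, 21, (50.0, run_length - 50.0),
                             light_fmol=1.0, heavy_fmol=100.0)
    from dataclasses import replace

    species = []
    truth_present = {}
    for i, (light, heavy) in enumerate(pairs):
        present = i % 2 == 0
        truth_present[f"{heavy.sequence}/{heavy.charge}"] = present
        species.append(replace(light, amount_fmol=1.0 if present else 0.0))
        species.append(heavy)
    background = generate_background(40, 22, rt_range_s=(0.0, run_length))
    species += background
    sample = SampleDefinition("noiseless_panel", species)
    return {
        "sample": sample,
        "targets": targets_from_pairs(pairs),
        "compiled": CompiledSample(sample),
        "truth_present": truth_present,
        "run_length": run_length,
    }


@pytest.fixture(scope="session")
def noiseless_hybrid_run(noiseless_panel, method):
    return run_acquisition(
        noiseless_panel["sample"],
        method,
        "hybrid",
        targets=noiseless_panel["targets"],
        run_length_s=noiseless_panel["run_length"],
        seed=5,
        noise=False,
        compiled=noiseless_panel["compiled"],
    )
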