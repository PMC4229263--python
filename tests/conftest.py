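"""Shared fixtures: rigs and calibrations are expensive, so build once per session."""

from __future__ import annotations

import numpy as np
import pytest

from facemocap import (
    NoiseSpec,
    calibrate_dlt,
    default_rig,
    simulate_wand_sweep,
    t_rod,
)


@pytest.fixture(scope="session")
def rig():
    return default_rig()


@pytest.fixture(scope="session")
def wand():
    return t_rod()


@pytest.fixture(scope="session")
def noiseless_calibration(rig, wand):
    sweep = simulate_wand_sweep(rig, wand, 3000, NoiseSpec(0.0), seed=101)
    return calibrate_dlt(sweep, wand, seed=101)


@pytest.fixture(scope="session")
def noisy_calibration(rig, wand):
    """Default-noise calibration from a protocol-length sweep."""
    sweep = simulate_wand_sweep(rig, wand, 3000, NoiseSpec(0.5), seed=202)
    return calibrate_dlt(sweep, wand, seed=202)
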