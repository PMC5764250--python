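import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lcmsqc
from lcmsqc.synthetic_data import RunRecipe

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def clean_qc1():
    """A noiseless QC1 acquisition with a -3 ppm calibration offset."""
    recipe = RunRecipe.for_panel(
        "QC1", seed=11, mass_offset_ppm=-3.0, noise_rel=0.0, baseline_peaks=0
    )
    run, truth = lcmsqc.generate_run(recipe)
    return recipe, run, truth


@pytest.fixture(scope="session")
def small_qc1():
    """A small in-control QC1 acquisition with default noise."""
    recipe = RunRecipe.for_panel("QC1", seed=23, gradient_length=450.0)
    run, truth = lcmsqc.generate_run(recipe)
    return recipe, run, truth


def single_peptide_recipe(**overrides) -> RunRecipe:
    """A minimal one-peptide run for window-boundary experiments.

    The peak is narrow (sd 2 s, support ±8 s) relative to the offsets being
    swept, so capture is decided by the matching window alone.
    """
    from lcmsqc.synthetic_data import PeakSpec

    defaults = dict(
        panel="QC1",
        gradient_length=600.0,
        scan_interval=1.0,
        peaks=(PeakSpec(rt=300.0, amplitude=1e6, sigma=2.0, sequence="LVNELTEFAK"),),
        ms2_per_ms1=0,
        noise_rel=0.0,
        baseline_peaks=0,
        seed=0,
    )
    defaults.update(overrides)
    return RunRecipe(**defaults)
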