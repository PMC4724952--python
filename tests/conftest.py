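"""Shared fixtures.

The expensive end-to-end run on the default synthetic genome is computed once
per session and shared by the annotation-recovery, clustering, hotspot and
report-shape tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from tbescan.pipeline import PipelineConfig, compare_to_truth, run_pipeline
from tbescan.synth import SynthConfig


@pytest.fixture(scope="session")
def default_report():
    """Full pipeline on the default synthetic genome (seed 42, ~3 Mb)."""
    return run_pipeline(PipelineConfig(synthetic=SynthConfig()))


@pytest.fixture(scope="session")
def default_scorecard(default_report):
    return compare_to_truth(default_report)


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast synthetic genome for generator unit tests."""
    from tbescan.synth import simulate_genome

    cfg = SynthConfig(
        seed=7,
        n_contigs=8,
        contig_length_bp=40_000,
        copies_per_family=3,
        satellite_units=((380, 30), (170, 40)),
    )
    return simulate_genome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
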