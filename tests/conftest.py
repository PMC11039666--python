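"""Shared fixtures: a small synthetic bundle exercised by several suites."""

import logging

import pytest

from sewaves.pipeline import config_from_bundle, run_pipeline
from sewaves.synthetic_data import SimulationConfig, TruthTable, simulate_bundle

logging.disable(logging.INFO)

SMALL_COUNTS = {
    "stable": 8,
    "condition_invariant": 6,
    "lost": 10,
    "wave_2d": 8,
    "wave_4d": 10,
    "wave_8d": 8,
}
SMALL_TF_COUNTS = {
    "stable": 2,
    "condition_invariant": 2,
    "lost": 4,
    "wave_2d": 3,
    "wave_4d": 4,
    "wave_8d": 3,
}


def small_config(**overrides) -> SimulationConfig:
    kwargs = dict(
        class_counts=dict(SMALL_COUNTS),
        tf_counts=dict(SMALL_TF_COUNTS),
        n_typical=60,
        n_crc_tfs=5,
        n_snps=3,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small noiseless bundle: (bundle_dir, manifest, truth)."""
    bundle_dir = tmp_path_factory.mktemp("bundle")
    manifest, truth = simulate_bundle(small_config(), seed=7, out_dir=bundle_dir)
    return bundle_dir, manifest, truth


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    """Full pipeline run on the small bundle: (out_dir, report, truth)."""
    bundle_dir, _, truth = small_bundle
    out_dir = tmp_path_factory.mktemp("run")
    report = run_pipeline(config_from_bundle(bundle_dir, out_dir))
    return out_dir, report, truth
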