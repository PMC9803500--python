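"""Shared fixtures: phantoms and cohorts generated at test time."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from vrsquant import (
    CohortConfig,
    PhantomConfig,
    VRsStructureSpec,
    add_rician_noise,
    default_cohort_config,
    generate_cohort,
    generate_phantom,
    random_structure_specs,
)


@pytest.fixture(scope="session")
def empty_phantom():
    """Structure-free phantom (noiseless) with its ground truth."""
    return generate_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def one_tube_phantom():
    """A single through-plane cylinder of radius 0.75 mm, length 8 mm."""
    spec = VRsStructureSpec(
        kind="circular",
        center=(80, 80, 16),
        orientation=(0.0, 0.0, 1.0),
        length_mm=8.0,
        radius_mm=0.75,
    )
    cfg = PhantomConfig(structures=(spec,))
    vol, truth = generate_phantom(cfg)
    return cfg, vol, truth


@pytest.fixture(scope="session")
def default_phantom():
    """25 random structures, noiseless volume + truth + the config."""
    cfg = PhantomConfig(seed=7)
    specs = random_structure_specs(np.random.default_rng(7), 25, cfg)
    cfg = dataclasses.replace(cfg, structures=specs)
    vol, truth = generate_phantom(cfg)
    return cfg, vol, truth


@pytest.fixture(scope="session")
def noisy_default_phantom(default_phantom):
    cfg, vol, truth = default_phantom
    noisy = add_rician_noise(vol, cfg.noise_sigma, np.random.default_rng(cfg.seed))
    return cfg, noisy, truth


@pytest.fixture(scope="session")
def phantom_recovery():
    """Recovered vs true metrics over 20 random noisy phantoms
    (10-40 structures each, default noise)."""
    from vrsquant import PipelineConfig, run_subject_pipeline

    rows = []
    for i in range(20):
        rng = np.random.default_rng(1000 + i)
        n = int(rng.integers(10, 41))
        cfg = PhantomConfig(seed=1000 + i)
        specs = random_structure_specs(rng, n, cfg)
        cfg = dataclasses.replace(cfg, structures=specs)
        vol, truth = generate_phantom(cfg)
        noisy = add_rician_noise(vol, cfg.noise_sigma, rng)
        m = run_subject_pipeline(noisy, PipelineConfig(seed=1000 + i))
        rows.append(
            (truth.vrs_count, m.vrs_count, truth.vrs_volume_mm3, m.vrs_volume_mm3)
        )
    return np.array(rows)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(default_cohort_config(seed=0))


@pytest.fixture(scope="session")
def large_cohort():
    """20 000 subjects per group, for moment/correlation recovery checks."""
    base = default_cohort_config(seed=0)
    big = CohortConfig(
        groups=tuple(dataclasses.replace(g, n=20_000) for g in base.groups), seed=0
    )
    return generate_cohort(big)
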