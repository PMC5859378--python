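"""Shared fixtures: small simulated populations and toy matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from carpgs.simdata import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Two-block miniature of the study design (300 offspring, 200 QTL)."""
    return SimConfig(n_blocks=2, n_offspring=300, n_qtl=200, seed=42)


@pytest.fixture(scope="session")
def small_pop(small_cfg):
    """Small simulated population with 800 markers, default founder pool."""
    return simulate_population(small_cfg, n_markers=800)


@pytest.fixture(scope="session")
def le_pop():
    """Population with unrelated, linkage-equilibrium founders."""
    cfg = SimConfig(n_blocks=2, n_offspring=300, n_qtl=200, seed=7,
                    founder_model="unrelated",
                    genotyping_error_rate=0.0, missing_rate=0.0)
    return simulate_population(cfg, n_markers=800)


@pytest.fixture()
def toy_grm_genotypes():
    """3 individuals x 4 loci whose VanRaden G is known by hand."""
    from carpgs.genotypes import GenotypeMatrix

    dosages = np.array([[0, 1, 2, 1], [2, 1, 0, 1], [1, 1, 1, 1]], dtype=np.int8)
    return GenotypeMatrix(dosages, np.array(["i1", "i2", "i3"], dtype=object))
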